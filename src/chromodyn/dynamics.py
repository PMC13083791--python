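"""Open/closed state matrices and the endpoint/timing module classifier.

A union interval is classed by its accessibility at the two anchor samples
(start anchor, e.g. MEF; end anchor, e.g. ESC):

    open/open   -> PO   open/closed -> OC
    closed/open -> CO   closed/closed -> NE

OC and CO intervals additionally carry a timing submodule: the earliest
position (1-based over the non-anchor timepoints, with index K reserved for
"endpoint only") from which the interval adopts and thereafter maintains the
end-anchor state. NE extends the published three-class scheme so that every
union interval receives exactly one label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, UsageError
from .intervals import PeakSet, SampleKey, UnionIntervalSet, overlap_bases

__all__ = [
    "TimeAxis",
    "DEFAULT_AXIS",
    "StateMatrix",
    "ModuleLabel",
    "ModuleAssignment",
    "BASE_CLASSES",
    "call_state_matrix",
    "classify_endpoint",
    "assign_timing",
    "classify_condition",
    "classify_all",
    "count_modules",
    "module_columns",
    "module_venn",
    "shared_excluding",
]

BASE_CLASSES = ("PO", "OC", "CO", "NE")


@dataclass(frozen=True)
class TimeAxis:
    """Ordered timepoint axis with a start and an end anchor."""

    timepoints: tuple
    start_anchor: str = "MEF"
    end_anchor: str = "ESC"

    def __post_init__(self) -> None:
        tps = tuple(self.timepoints)
        object.__setattr__(self, "timepoints", tps)
        if len(set(tps)) != len(tps):
            raise ConfigurationError(f"duplicate timepoints in axis: {tps}")
        for anchor in (self.start_anchor, self.end_anchor):
            if anchor not in tps:
                raise ConfigurationError(f"anchor {anchor!r} not on axis {tps}")
        if self.start_anchor == self.end_anchor:
            raise ConfigurationError("start and end anchors must differ")
        if tps[0] != self.start_anchor or tps[-1] != self.end_anchor:
            raise ConfigurationError(
                "axis must begin with the start anchor and end with the end anchor"
            )
        if len(tps) < 3:
            raise ConfigurationError("axis needs at least one non-anchor timepoint")

    @property
    def intermediates(self) -> tuple:
        return tuple(
            tp for tp in self.timepoints
            if tp not in (self.start_anchor, self.end_anchor)
        )

    @property
    def n_submodules(self) -> int:
        """K: number of timing submodules = non-anchor timepoints + 1."""
        return len(self.intermediates) + 1


DEFAULT_AXIS = TimeAxis(("MEF", "D0", "D3", "D5", "D7", "ESC"))


@dataclass(frozen=True)
class ModuleLabel:
    """Base class plus timing submodule (submodule only for OC/CO)."""

    base_class: str
    submodule: Optional[int] = None

    def __post_init__(self) -> None:
        if self.base_class not in BASE_CLASSES:
            raise ValueError(f"unknown base class {self.base_class!r}")
        if self.base_class in ("OC", "CO"):
            if self.submodule is None or self.submodule < 1:
                raise ValueError(f"{self.base_class} requires a submodule >= 1")
        elif self.submodule is not None:
            raise ValueError(f"{self.base_class} carries no submodule")

    @property
    def code(self) -> str:
        if self.submodule is None:
            return self.base_class
        return f"{self.base_class}{self.submodule}"


@dataclass(frozen=True)
class StateMatrix:
    """Boolean open/closed calls: union intervals x (condition, timepoint) samples."""

    union: UnionIntervalSet
    samples: tuple
    states: np.ndarray  # (n_intervals, n_samples), True = open
    axis: TimeAxis = DEFAULT_AXIS

    def __post_init__(self) -> None:
        samples = tuple(self.samples)
        object.__setattr__(self, "samples", samples)
        states = np.asarray(self.states, dtype=bool)
        object.__setattr__(self, "states", states)
        if states.shape != (len(self.union), len(samples)):
            raise ValueError(
                f"state grid shape {states.shape} does not match "
                f"{len(self.union)} intervals x {len(samples)} samples"
            )
        if len(set(samples)) != len(samples):
            raise ConfigurationError("duplicate (condition, timepoint) sample keys")

    def column(self, sample: SampleKey) -> np.ndarray:
        try:
            return self.states[:, self.samples.index(sample)]
        except ValueError:
            raise ConfigurationError(f"sample {sample} absent from state matrix")

    def _anchor_sample(self, timepoint: str) -> SampleKey:
        hits = [s for s in self.samples if s.timepoint == timepoint]
        if len(hits) != 1:
            raise ConfigurationError(
                f"expected exactly one shared anchor sample at {timepoint!r}, "
                f"found {len(hits)}"
            )
        return hits[0]

    @property
    def start_anchor_sample(self) -> SampleKey:
        return self._anchor_sample(self.axis.start_anchor)

    @property
    def end_anchor_sample(self) -> SampleKey:
        return self._anchor_sample(self.axis.end_anchor)

    @property
    def conditions(self) -> tuple:
        anchors = (self.axis.start_anchor, self.axis.end_anchor)
        seen = []
        for s in self.samples:
            if s.timepoint not in anchors and s.condition not in seen:
                seen.append(s.condition)
        return tuple(seen)

    def condition_trajectory(self, condition: str) -> np.ndarray:
        """States at the condition's non-anchor timepoints, axis order."""
        cols = []
        missing = []
        for tp in self.axis.intermediates:
            key = SampleKey(condition, tp)
            if key in self.samples:
                cols.append(self.column(key))
            else:
                missing.append(key)
        if missing:
            raise ConfigurationError(
                "missing samples for condition "
                f"{condition!r}: {', '.join(map(str, missing))}"
            )
        return np.column_stack(cols)


def call_state_matrix(
    union: UnionIntervalSet,
    peak_sets: Sequence[PeakSet],
    axis: TimeAxis = DEFAULT_AXIS,
    min_overlap: Optional[float] = None,
) -> StateMatrix:
    """Call each union interval open/closed against every sample's peaks.

    An interval is open in a sample when it overlaps that sample's peaks by
    >= 1 base, or by >= ``min_overlap`` fraction of its length when set.
    """
    samples = []
    for ps in peak_sets:
        if ps.sample is None:
            raise ConfigurationError("every peak set must carry a SampleKey")
        if ps.sample in samples:
            raise ConfigurationError(f"duplicate sample key {ps.sample}")
        samples.append(ps.sample)
    for anchor in (axis.start_anchor, axis.end_anchor):
        if not any(s.timepoint == anchor for s in samples):
            raise ConfigurationError(f"missing anchor sample at {anchor!r}")
    lengths = union.lengths
    cols = []
    for ps in peak_sets:
        bases = overlap_bases(union.intervals, ps.intervals)
        if min_overlap is None:
            cols.append(bases > 0)
        else:
            cols.append(bases >= min_overlap * lengths)
    states = np.column_stack(cols) if cols else np.zeros((len(union), 0), bool)
    return StateMatrix(union=union, samples=tuple(samples), states=states, axis=axis)


def classify_endpoint(start_open: bool, end_open: bool) -> str:
    """Base class from the two anchor states."""
    if start_open:
        return "PO" if end_open else "OC"
    return "CO" if end_open else "NE"


def assign_timing(trajectory: Sequence[bool], endpoint_state: bool) -> int:
    """Earliest 1-based position from which the end-anchor state is maintained.

    ``trajectory`` holds the states at the non-anchor timepoints followed by
    the end anchor itself; its final element must equal ``endpoint_state``.
    """
    traj = [bool(x) for x in trajectory]
    if not traj:
        raise UsageError("empty trajectory")
    if traj[-1] != bool(endpoint_state):
        raise ValueError(
            "trajectory end does not match the declared endpoint state"
        )
    t = len(traj)
    while t > 1 and traj[t - 2] == endpoint_state:
        t -= 1
    return t


def _timing_vector(traj: np.ndarray, endpoint: np.ndarray) -> np.ndarray:
    """Vectorized assign_timing over rows of a (n, K) trajectory matrix."""
    mismatch = traj != endpoint[:, None]
    # last mismatching position (or -1), submodule = that position + 2 (1-based)
    k = traj.shape[1]
    idx = np.where(
        mismatch.any(axis=1), k - 1 - np.argmax(mismatch[:, ::-1], axis=1), -1
    )
    return (idx + 2).astype(np.int64)


@dataclass(frozen=True)
class ModuleAssignment:
    """Per-interval module labels for one condition over one union set."""

    condition: str
    union: UnionIntervalSet
    labels: tuple
    n_submodules: int
    provenance: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.union):
            raise ValueError("one label per union interval required")

    def codes(self) -> np.ndarray:
        return np.array([lab.code for lab in self.labels])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "interval_id": f"U{i + 1:06d}",
                "base_class": lab.base_class,
                "submodule": "" if lab.submodule is None else lab.submodule,
            }
            for i, (iv, lab) in enumerate(zip(self.union.intervals, self.labels))
        ]
        return pd.DataFrame(
            rows,
            columns=["chrom", "start", "end", "interval_id", "base_class", "submodule"],
        )


def classify_condition(
    matrix: StateMatrix,
    condition: str,
    require_detection: bool = False,
    timing_condition: Optional[str] = None,
) -> ModuleAssignment:
    """Assign a module label to every union interval for one condition.

    Base classes come from the shared anchors; timing comes from the
    condition's own trajectory toward the end anchor. ``timing_condition``
    substitutes another condition's trajectory (e.g. the control, for
    control-anchored row ordering). With ``require_detection``, intervals
    never open in the condition's samples or anchors are forced to NE.
    """
    start_col = matrix.column(matrix.start_anchor_sample)
    end_col = matrix.column(matrix.end_anchor_sample)
    traj = matrix.condition_trajectory(timing_condition or condition)
    full = np.column_stack([traj, end_col])
    timing = _timing_vector(full, end_col)

    own_traj = matrix.condition_trajectory(condition)
    detected = start_col | end_col | own_traj.any(axis=1)

    labels = []
    for i in range(len(matrix.union)):
        base = classify_endpoint(bool(start_col[i]), bool(end_col[i]))
        if require_detection and not detected[i]:
            labels.append(ModuleLabel("NE"))
        elif base in ("OC", "CO"):
            labels.append(ModuleLabel(base, int(timing[i])))
        else:
            labels.append(ModuleLabel(base))
    provenance = {
        "start_anchor": str(matrix.start_anchor_sample),
        "end_anchor": str(matrix.end_anchor_sample),
        "timing_condition": timing_condition or condition,
        "require_detection": require_detection,
    }
    return ModuleAssignment(
        condition=condition,
        union=matrix.union,
        labels=tuple(labels),
        n_submodules=matrix.axis.n_submodules,
        provenance=provenance,
    )


def classify_all(
    matrix: StateMatrix,
    conditions: Optional[Sequence[str]] = None,
    mode: str = "per-condition",
    anchor_condition: Optional[str] = None,
    require_detection: bool = False,
) -> dict:
    """Classify every condition.

    ``mode="per-condition"`` re-runs timing on each condition's trajectory;
    ``mode="anchored"`` reuses ``anchor_condition``'s trajectory for all.
    """
    if mode not in ("per-condition", "anchored"):
        raise UsageError(f"unknown classification mode {mode!r}")
    if mode == "anchored" and not anchor_condition:
        raise UsageError("anchored mode requires anchor_condition")
    conds = tuple(conditions) if conditions else matrix.conditions
    return {
        c: classify_condition(
            matrix,
            c,
            require_detection=require_detection,
            timing_condition=anchor_condition if mode == "anchored" else None,
        )
        for c in conds
    }


def module_columns(n_submodules: int) -> list:
    cols = ["PO"]
    cols += [f"OC{i}" for i in range(1, n_submodules + 1)]
    cols += [f"CO{i}" for i in range(1, n_submodules + 1)]
    cols.append("NE")
    return cols


def count_modules(assignments: Iterable[ModuleAssignment]) -> pd.DataFrame:
    """Count intervals per module for each condition (rows sum to union size)."""
    assignments = list(assignments)
    if not assignments:
        raise UsageError("no assignments to count")
    union = assignments[0].union
    k = assignments[0].n_submodules
    cols = module_columns(k)
    rows = {}
    for asg in assignments:
        if asg.union.intervals != union.intervals:
            raise ValueError("assignments span different union sets")
        counts = dict.fromkeys(cols, 0)
        for lab in asg.labels:
            counts[lab.code] += 1
        rows[asg.condition] = counts
    table = pd.DataFrame.from_dict(rows, orient="index")[cols]
    table.index.name = "condition"
    return table


def _class_members(asg: ModuleAssignment, classes: frozenset) -> set:
    return {i for i, lab in enumerate(asg.labels) if lab.base_class in classes}


def module_venn(
    assignments: Mapping[str, ModuleAssignment],
    classes: Sequence[str],
    exclude: Sequence[str] = (),
) -> pd.DataFrame:
    """Partition union intervals by which conditions place them in ``classes``.

    Returns one row per non-empty condition combination with a boolean
    membership column per condition and a ``count`` column; rows sum to the
    size of the union of the per-condition class sets.
    """
    classes = frozenset(classes)
    if not classes:
        raise UsageError("empty class subset")
    unknown = classes - set(BASE_CLASSES)
    if unknown:
        raise UsageError(f"unknown classes: {sorted(unknown)}")
    conds = [c for c in assignments if c not in set(exclude)]
    if len(conds) < 2:
        raise UsageError("module_venn needs >= 2 conditions after exclusion")
    members = {c: _class_members(assignments[c], classes) for c in conds}
    combos: dict = {}
    for i in set.union(*members.values()):
        key = tuple(i in members[c] for c in conds)
        combos[key] = combos.get(key, 0) + 1
    rows = [
        {**{c: k for c, k in zip(conds, key)}, "count": n}
        for key, n in sorted(combos.items(), reverse=True)
    ]
    return pd.DataFrame(rows, columns=[*conds, "count"])


def shared_excluding(
    assignments: Mapping[str, ModuleAssignment],
    classes: Sequence[str],
    exclude: Sequence[str],
) -> int:
    """Count intervals in ``classes`` for every condition not excluded."""
    conds = [c for c in assignments if c not in set(exclude)]
    if not conds:
        raise UsageError("all conditions excluded")
    classes = frozenset(classes)
    sets = [_class_members(assignments[c], classes) for c in conds]
    return len(set.intersection(*sets))
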