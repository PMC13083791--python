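"""Seeded synthetic-study generator with planted ground truth.

Emits every pipeline input — per-sample time-course peak files with planted
module structure and per-call flicker noise, differential-expression tables
with planted cross-system categories, reference anchor expression, a TSS
table, and binding peaks drawn at class-specific rates — together with truth
tables sufficient to score every downstream stage.

One root seed; each stage draws from its own substream keyed by a stable
label, so adding a stage never perturbs earlier draws.
"""

from __future__ import annotations

import os
import re
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .dynamics import DEFAULT_AXIS, ModuleLabel, TimeAxis, module_columns
from .errors import CapacityError, ConfigurationError, ValidationError
from .intervals import (
    GenomicInterval,
    PeakSet,
    SampleKey,
    UnionIntervalSet,
    write_narrowpeak,
)

__all__ = [
    "AccessibilityConfig",
    "DEConfig",
    "BindingConfig",
    "SimulationConfig",
    "study_config",
    "planted_states",
    "simulate_accessibility",
    "simulate_de",
    "simulate_binding",
    "simulate_study",
    "write_study",
]

REFERENCE_CONDITION = "reference"  # owner of the shared anchor samples
PEAK_NEG_LOG10_Q = 10.0  # emitted q = 1e-10, well inside any FDR threshold


def _rng(seed: int, label: str) -> np.random.Generator:
    """Substream derived from the root seed by a stable label hash."""
    return np.random.default_rng([int(seed), zlib.crc32(label.encode())])


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AccessibilityConfig:
    module_counts: Mapping[str, int]
    interval_length: tuple = (200, 1000)
    gap: tuple = (500, 2000)
    flicker_noise: float = 0.0
    condition_submodule_shift: Mapping[str, int] = field(default_factory=dict)

    def validate(self, axis: TimeAxis, conditions: Sequence[str]) -> None:
        allowed = set(module_columns(axis.n_submodules))
        unknown = set(self.module_counts) - allowed
        if unknown:
            raise ConfigurationError(
                f"accessibility.module_counts: unknown modules {sorted(unknown)}"
            )
        if any(v < 0 for v in self.module_counts.values()):
            raise ConfigurationError("accessibility.module_counts: counts must be >= 0")
        if not (0 <= self.flicker_noise <= 1):
            raise ConfigurationError("accessibility.flicker_noise must be in [0, 1]")
        if self.gap[0] < 1:
            raise ConfigurationError("accessibility.gap minimum must be >= 1")
        if not (0 < self.interval_length[0] <= self.interval_length[1]):
            raise ConfigurationError("accessibility.interval_length must be positive")
        unknown_conds = set(self.condition_submodule_shift) - set(conditions)
        if unknown_conds:
            raise ConfigurationError(
                "accessibility.condition_submodule_shift: unknown conditions "
                f"{sorted(unknown_conds)}"
            )


@dataclass(frozen=True)
class DEConfig:
    genes_per_category: Mapping[str, int]
    effect_mean: float = 2.0
    effect_sd: float = 0.5
    effect_floor: float = 1.1  # keeps planted effects above the default gate
    null_lfc_sd: float = 0.5  # Normal(0, 0.25): variance 0.25
    planted_p_max: float = 1e-4

    def validate(self, systems: Sequence[str]) -> None:
        pattern = re.compile(
            r"^(null|none|common_(up|down)|specific_(up|down):.+|pair_(up|down):.+\+.+)$"
        )
        for key, count in self.genes_per_category.items():
            if not pattern.match(key):
                raise ConfigurationError(
                    f"de.genes_per_category: unparseable category {key!r}"
                )
            if count < 0:
                raise ConfigurationError("de.genes_per_category: counts must be >= 0")
            for sys_name in _category_systems(key):
                if sys_name not in systems:
                    raise ConfigurationError(
                        f"de.genes_per_category: {key!r} names unknown system "
                        f"{sys_name!r} (declared: {list(systems)})"
                    )


def _category_systems(category: str) -> list:
    if ":" not in category:
        return []
    return category.split(":", 1)[1].split("+")


@dataclass(frozen=True)
class BindingConfig:
    rates: Mapping[str, float] = field(default_factory=dict)
    peak_shrink: tuple = (0.3, 0.8)

    def validate(self) -> None:
        for cls, rate in self.rates.items():
            if cls not in ("PO", "OC", "CO", "NE"):
                raise ConfigurationError(f"binding.rates: unknown class {cls!r}")
            if not (0 <= rate <= 1):
                raise ValidationError(
                    f"binding.rates[{cls}] must be in [0, 1], got {rate}"
                )
        if not (0 < self.peak_shrink[0] <= self.peak_shrink[1] <= 1):
            raise ConfigurationError("binding.peak_shrink must satisfy 0 < lo <= hi <= 1")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    genome: Mapping[str, int]
    conditions: tuple
    accessibility: AccessibilityConfig
    de: DEConfig
    binding: BindingConfig
    axis: TimeAxis = DEFAULT_AXIS

    def __post_init__(self) -> None:
        object.__setattr__(self, "conditions", tuple(self.conditions))
        if not self.conditions:
            raise ConfigurationError("conditions: at least one condition required")
        if not self.genome or any(v <= 0 for v in self.genome.values()):
            raise ConfigurationError("genome: chromosome lengths must be positive")
        self.accessibility.validate(self.axis, self.conditions)
        self.de.validate(self.de_systems)
        self.binding.validate()

    @property
    def de_systems(self) -> tuple:
        """Treatment systems: every condition except the first (the control)."""
        return self.conditions[1:] if len(self.conditions) > 1 else self.conditions

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        for key in ("seed", "genome", "conditions"):
            if key not in data:
                raise ConfigurationError(f"simulation config: missing field {key!r}")
        axis_spec = data.get("axis", {})
        axis = (
            TimeAxis(
                tuple(axis_spec["timepoints"]),
                axis_spec.get("start_anchor", "MEF"),
                axis_spec.get("end_anchor", "ESC"),
            )
            if axis_spec
            else DEFAULT_AXIS
        )
        acc_spec = dict(data.get("accessibility", {}))
        if "module_counts" not in acc_spec:
            raise ConfigurationError(
                "simulation config: missing field 'accessibility.module_counts'"
            )
        acc = AccessibilityConfig(
            module_counts=dict(acc_spec["module_counts"]),
            interval_length=tuple(acc_spec.get("interval_length", (200, 1000))),
            gap=tuple(acc_spec.get("gap", (500, 2000))),
            flicker_noise=float(acc_spec.get("flicker_noise", 0.0)),
            condition_submodule_shift=dict(
                acc_spec.get("condition_submodule_shift", {})
            ),
        )
        de_spec = dict(data.get("de", {}))
        de = DEConfig(
            genes_per_category=dict(de_spec.get("genes_per_category", {})),
            effect_mean=float(de_spec.get("effect_mean", 2.0)),
            effect_sd=float(de_spec.get("effect_sd", 0.5)),
            effect_floor=float(de_spec.get("effect_floor", 1.1)),
            null_lfc_sd=float(de_spec.get("null_lfc_sd", 0.5)),
            planted_p_max=float(de_spec.get("planted_p_max", 1e-4)),
        )
        bind_spec = dict(data.get("binding", {}))
        binding = BindingConfig(
            rates=dict(bind_spec.get("rates", {})),
            peak_shrink=tuple(bind_spec.get("peak_shrink", (0.3, 0.8))),
        )
        return cls(
            seed=int(data["seed"]),
            genome=dict(data["genome"]),
            conditions=tuple(data["conditions"]),
            accessibility=acc,
            de=de,
            binding=binding,
            axis=axis,
        )

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "genome": dict(self.genome),
            "conditions": list(self.conditions),
            "axis": {
                "timepoints": list(self.axis.timepoints),
                "start_anchor": self.axis.start_anchor,
                "end_anchor": self.axis.end_anchor,
            },
            "accessibility": {
                "module_counts": dict(self.accessibility.module_counts),
                "interval_length": list(self.accessibility.interval_length),
                "gap": list(self.accessibility.gap),
                "flicker_noise": self.accessibility.flicker_noise,
                "condition_submodule_shift": dict(
                    self.accessibility.condition_submodule_shift
                ),
            },
            "de": {
                "genes_per_category": dict(self.de.genes_per_category),
                "effect_mean": self.de.effect_mean,
                "effect_sd": self.de.effect_sd,
                "effect_floor": self.de.effect_floor,
                "null_lfc_sd": self.de.null_lfc_sd,
                "planted_p_max": self.de.planted_p_max,
            },
            "binding": {
                "rates": dict(self.binding.rates),
                "peak_shrink": list(self.binding.peak_shrink),
            },
        }


def study_config(
    seed: int,
    module_counts: Optional[Mapping[str, int]] = None,
    flicker_noise: float = 0.0,
    n_null_genes: int = 300,
    conditions: Sequence[str] = ("dsRed", "RoraLow", "RoraHigh", "RoraDNTD"),
    binding_rates: Optional[Mapping[str, float]] = None,
) -> SimulationConfig:
    """A study-shaped config: control + three arms over the default axis."""
    conditions = tuple(conditions)
    if module_counts is None:
        module_counts = {
            "PO": 1000,
            "OC1": 500, "OC2": 400, "OC3": 300, "OC4": 250, "OC5": 150,
            "CO1": 600, "CO2": 500, "CO3": 400, "CO4": 300, "CO5": 200,
            "NE": 400,
        }
    total = sum(module_counts.values())
    per_chrom = 4_000_000 * max(1, total // 1200)
    genome = {f"chr{i}": per_chrom for i in range(1, 5)}
    systems = conditions[1:]
    categories = {"common_up": 40, "common_down": 40}
    for s in systems:
        categories[f"specific_up:{s}"] = 20
        categories[f"specific_down:{s}"] = 20
    if len(systems) >= 2:
        categories[f"pair_up:{systems[0]}+{systems[1]}"] = 15
    categories["null"] = n_null_genes
    return SimulationConfig(
        seed=seed,
        genome=genome,
        conditions=conditions,
        accessibility=AccessibilityConfig(
            module_counts=dict(module_counts), flicker_noise=flicker_noise
        ),
        de=DEConfig(genes_per_category=categories),
        binding=BindingConfig(
            rates=dict(binding_rates or {"PO": 0.30, "OC": 0.10, "CO": 0.05})
        ),
    )


# ---------------------------------------------------------------------------
# accessibility
# ---------------------------------------------------------------------------


def planted_states(label: ModuleLabel, n_submodules: int) -> tuple:
    """True (start, intermediates..., end) open states for a planted label.

    PO is open throughout; NE is closed at both anchors but transiently open
    at every intermediate (so the interval is detectable in at least one
    sample). CO with submodule m opens from intermediate position m onward
    (m = K means endpoint-only); OC mirrors this for closing.
    """
    k = n_submodules
    n_mid = k - 1
    if label.base_class == "PO":
        return (True, (True,) * n_mid, True)
    if label.base_class == "NE":
        return (False, (True,) * n_mid, False)
    m = label.submodule
    if label.base_class == "CO":
        return (False, tuple(i >= m for i in range(1, n_mid + 1)), True)
    return (True, tuple(i < m for i in range(1, n_mid + 1)), False)


@dataclass(frozen=True)
class AccessibilitySimulation:
    config: SimulationConfig
    union: UnionIntervalSet
    samples: tuple
    true_states: np.ndarray
    observed_states: np.ndarray
    sample_peaks: Mapping[SampleKey, PeakSet]
    labels_by_condition: Mapping[str, tuple]
    truth: pd.DataFrame


def _build_labels(config: SimulationConfig) -> list:
    labels = []
    for code in module_columns(config.axis.n_submodules):
        count = config.accessibility.module_counts.get(code, 0)
        if code in ("PO", "NE"):
            lab = ModuleLabel(code)
        else:
            lab = ModuleLabel(code[:2], int(code[2:]))
        labels.extend([lab] * count)
    if not labels:
        raise ConfigurationError("accessibility.module_counts sums to zero")
    return labels


def _place_intervals(config: SimulationConfig, n: int, rng) -> list:
    lmin, lmax = config.accessibility.interval_length
    gmin, gmax = config.accessibility.gap
    lengths = rng.integers(lmin, lmax + 1, size=n)
    gaps = rng.integers(gmin, gmax + 1, size=n)
    chroms = list(config.genome.items())
    intervals = []
    ci, pos = 0, 0
    for i in range(n):
        start = pos + int(gaps[i])
        end = start + int(lengths[i])
        while ci < len(chroms) and end > chroms[ci][1]:
            ci += 1
            pos = 0
            start = pos + int(gaps[i])
            end = start + int(lengths[i])
        if ci >= len(chroms):
            raise CapacityError(
                f"genome too small: placed {i} of {n} requested intervals"
            )
        intervals.append(GenomicInterval(chroms[ci][0], start, end))
        pos = end
    return intervals


def _shift_label(label: ModuleLabel, shift: int, k: int) -> ModuleLabel:
    if shift == 0 or label.base_class not in ("OC", "CO"):
        return label
    return ModuleLabel(label.base_class, min(max(label.submodule + shift, 1), k))


def simulate_accessibility(config: SimulationConfig) -> AccessibilitySimulation:
    axis = config.axis
    k = axis.n_submodules
    base_labels = _build_labels(config)
    n = len(base_labels)
    layout_rng = _rng(config.seed, "accessibility.layout")
    intervals = _place_intervals(config, n, layout_rng)
    order = layout_rng.permutation(n)
    base_labels = [base_labels[j] for j in order]

    labels_by_condition = {}
    for cond in config.conditions:
        shift = config.accessibility.condition_submodule_shift.get(cond, 0)
        labels_by_condition[cond] = tuple(
            _shift_label(lab, shift, k) for lab in base_labels
        )

    samples = [SampleKey(REFERENCE_CONDITION, axis.start_anchor)]
    for cond in config.conditions:
        samples.extend(SampleKey(cond, tp) for tp in axis.intermediates)
    samples.append(SampleKey(REFERENCE_CONDITION, axis.end_anchor))
    samples = tuple(samples)

    true_states = np.zeros((n, len(samples)), dtype=bool)
    for i in range(n):
        start_open, _, end_open = planted_states(base_labels[i], k)
        true_states[i, 0] = start_open
        true_states[i, -1] = end_open
    col = 1
    for cond in config.conditions:
        for i in range(n):
            _, mids, _ = planted_states(labels_by_condition[cond][i], k)
            true_states[i, col : col + len(mids)] = mids
        col += len(axis.intermediates)

    noise_rng = _rng(config.seed, "accessibility.noise")
    flips = noise_rng.random(true_states.shape) < config.accessibility.flicker_noise
    observed = true_states ^ flips

    sample_peaks = {}
    for j, key in enumerate(samples):
        ivs = tuple(
            GenomicInterval(
                iv.chrom, iv.start, iv.end, name=f"U{i + 1:06d}", score=100.0
            )
            for i, iv in enumerate(intervals)
            if observed[i, j]
        )
        sample_peaks[key] = PeakSet(intervals=ivs, sample=key)

    truth = pd.DataFrame(
        {
            "interval_id": [f"U{i + 1:06d}" for i in range(n)],
            "chrom": [iv.chrom for iv in intervals],
            "start": [iv.start for iv in intervals],
            "end": [iv.end for iv in intervals],
            "base_class": [lab.base_class for lab in base_labels],
        }
    )
    for cond in config.conditions:
        truth[f"module_{cond}"] = [lab.code for lab in labels_by_condition[cond]]

    return AccessibilitySimulation(
        config=config,
        union=UnionIntervalSet(intervals=tuple(intervals), n_sources=len(samples)),
        samples=samples,
        true_states=true_states,
        observed_states=observed,
        sample_peaks=sample_peaks,
        labels_by_condition=labels_by_condition,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

_ANCHOR_BINS = ("ESC_high", "MEF_high", "neutral")
_BIN_RATIO = {"ESC_high": (2.5, 8.0), "neutral": (0.8, 1.25), "MEF_high": (0.18, 0.4)}


@dataclass(frozen=True)
class DESimulation:
    config: SimulationConfig
    records: pd.DataFrame
    reference: pd.DataFrame
    truth: pd.DataFrame


def _category_plan(category: str, systems: Sequence[str]) -> tuple:
    """(sign, active systems) for a planted category; sign 0 means null."""
    if category in ("null", "none"):
        return 0, ()
    if category.startswith("common_"):
        return (1 if category.endswith("up") else -1), tuple(systems)
    head, names = category.split(":", 1)
    sign = 1 if head.endswith("up") else -1
    return sign, tuple(names.split("+"))


def simulate_de(config: SimulationConfig) -> DESimulation:
    systems = config.de_systems
    rng = _rng(config.seed, "de")
    de = config.de
    genes, categories = [], []
    idx = 0
    for category, count in de.genes_per_category.items():
        for _ in range(count):
            idx += 1
            genes.append(f"g{idx:05d}")
            categories.append("none" if category in ("null", "none") else category)

    bins = [str(_ANCHOR_BINS[b]) for b in rng.integers(0, len(_ANCHOR_BINS), len(genes))]
    expr_mef = rng.uniform(5.0, 20.0, len(genes))
    ratios = np.array([rng.uniform(*_BIN_RATIO[b]) for b in bins])
    expr_esc = np.maximum((expr_mef + 1.0) * ratios - 1.0, 0.0)

    rows = []
    for gene, category in zip(genes, categories):
        sign, active = _category_plan(category, systems)
        for system in systems:
            for tp in config.axis.intermediates:
                if sign != 0 and system in active:
                    lfc = sign * max(
                        rng.normal(de.effect_mean, de.effect_sd), de.effect_floor
                    )
                    p = rng.uniform(0.0, de.planted_p_max)
                elif sign != 0:
                    # planted gene, inactive system: guaranteed non-significant
                    lfc = rng.uniform(-0.9, 0.9)
                    p = rng.uniform(0.0, 1.0)
                else:
                    lfc = rng.normal(0.0, de.null_lfc_sd)
                    p = rng.uniform(0.0, 1.0)
                rows.append((gene, system, tp, lfc, p))
    records = pd.DataFrame(
        rows, columns=["gene", "system", "timepoint", "log2fc", "pvalue"]
    )
    reference = pd.DataFrame(
        {"gene": genes, "expr_mef": expr_mef, "expr_esc": expr_esc}
    )
    truth = pd.DataFrame(
        {"gene": genes, "category": categories, "anchor_bin": bins}
    )
    return DESimulation(
        config=config, records=records, reference=reference, truth=truth
    )


# ---------------------------------------------------------------------------
# binding peaks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BindingSimulation:
    config: SimulationConfig
    peaks: PeakSet
    truth: pd.DataFrame


def simulate_binding(
    config: SimulationConfig, accessibility: AccessibilitySimulation
) -> BindingSimulation:
    rng = _rng(config.seed, "binding")
    shrink_lo, shrink_hi = config.binding.peak_shrink
    peaks, rows = [], []
    idx = 0
    base_classes = accessibility.truth["base_class"].tolist()
    for i, iv in enumerate(accessibility.union.intervals):
        cls = base_classes[i]
        rate = config.binding.rates.get(cls, 0.0)
        hosts = rng.random() < rate  # one draw per region keeps streams aligned
        frac = rng.uniform(shrink_lo, shrink_hi)
        offset_u = rng.random()
        if not hosts:
            continue
        plen = max(1, int(iv.length * frac))
        offset = int(offset_u * (iv.length - plen + 1))
        idx += 1
        name = f"bp{idx:05d}"
        peaks.append(
            GenomicInterval(
                iv.chrom, iv.start + offset, iv.start + offset + plen,
                name=name, score=50.0,
            )
        )
        rows.append((name, f"U{i + 1:06d}", cls))
    truth = pd.DataFrame(rows, columns=["peak", "interval_id", "atac_class"])
    return BindingSimulation(
        config=config,
        peaks=PeakSet(intervals=tuple(peaks), sample=SampleKey("binding", "D0")),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# whole study + file layout
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudySimulation:
    config: SimulationConfig
    accessibility: AccessibilitySimulation
    de: DESimulation
    binding: BindingSimulation
    tss_table: pd.DataFrame


def _make_tss_table(
    de_sim: DESimulation, accessibility: AccessibilitySimulation
) -> pd.DataFrame:
    """Place each gene's TSS at a union-interval midpoint (cycled)."""
    ivs = accessibility.union.intervals
    rows = []
    for i, gene in enumerate(de_sim.truth["gene"]):
        iv = ivs[(i * 7) % len(ivs)]  # stride decorrelates gene and module order
        rows.append((gene, iv.chrom, iv.midpoint, "+" if i % 2 == 0 else "-"))
    return pd.DataFrame(rows, columns=["gene", "chrom", "tss", "strand"])


def simulate_study(config: SimulationConfig) -> StudySimulation:
    accessibility = simulate_accessibility(config)
    de_sim = simulate_de(config)
    binding = simulate_binding(config, accessibility)
    return StudySimulation(
        config=config,
        accessibility=accessibility,
        de=de_sim,
        binding=binding,
        tss_table=_make_tss_table(de_sim, accessibility),
    )


def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_study(study: StudySimulation, outdir) -> dict:
    """Write all synthetic inputs, truth tables and stage configs.

    Returns a mapping of logical names to paths (relative to ``outdir``).
    Identical configs produce byte-identical trees.
    """
    outdir = os.fspath(outdir)
    for sub in ("peaks", "tables", "truth"):
        os.makedirs(os.path.join(outdir, sub), exist_ok=True)
    paths = {}

    sample_entries = []
    for key in study.accessibility.samples:
        rel = f"peaks/{key.condition}_{key.timepoint}.narrowPeak"
        write_narrowpeak(
            study.accessibility.sample_peaks[key],
            os.path.join(outdir, rel),
            neg_log10_q=PEAK_NEG_LOG10_Q,
        )
        sample_entries.append(
            {"condition": key.condition, "timepoint": key.timepoint, "path": rel}
        )
        paths[f"peaks:{key}"] = rel

    rel = "peaks/binding.narrowPeak"
    write_narrowpeak(
        study.binding.peaks, os.path.join(outdir, rel), neg_log10_q=PEAK_NEG_LOG10_Q
    )
    paths["binding_peaks"] = rel

    for name, df in (
        ("tables/de_records.tsv", study.de.records),
        ("tables/reference_expression.tsv", study.de.reference),
        ("tables/tss_table.tsv", study.tss_table),
        ("truth/accessibility.tsv", study.accessibility.truth),
        ("truth/de.tsv", study.de.truth),
        ("truth/binding.tsv", study.binding.truth),
    ):
        _write_tsv(df, os.path.join(outdir, name))
        paths[name] = name

    config = study.config
    atac_cfg = {
        "axis": {
            "timepoints": list(config.axis.timepoints),
            "start_anchor": config.axis.start_anchor,
            "end_anchor": config.axis.end_anchor,
        },
        "format": "narrowpeak",
        "q_max": 0.05,
        "samples": sample_entries,
        "conditions": list(config.conditions),
        "venn": {"classes": ["OC"], "exclude": [config.conditions[0]]},
    }
    deg_cfg = {
        "de_table": "tables/de_records.tsv",
        "reference_expression": "tables/reference_expression.tsv",
        "systems": list(config.de_systems),
        "p_max": 0.05,
        "lfc_min": 1.0,
        "anchor_fc": 2.0,
    }
    integrate_cfg = {
        "tss_table": "tables/tss_table.tsv",
        "binding_peaks": "peaks/binding.narrowPeak",
        "binding_format": "narrowpeak",
        "occupancy_condition": config.conditions[0],
        "promoter_window": 3000,
        "link_mode": "window",
    }
    for name, cfg in (
        ("classify_atac.yaml", atac_cfg),
        ("classify_deg.yaml", deg_cfg),
        ("integrate.yaml", integrate_cfg),
    ):
        with open(os.path.join(outdir, name), "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)
        paths[name] = name
    return paths
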