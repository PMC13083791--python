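"""Cross-system differential-expression module scheme.

Stages: per-timepoint direction calls under p/effect thresholds, a
within-system consistency filter (opposing directions across timepoints
exclude the gene), a cross-system truth table naming common / pairwise /
system-specific categories, anchor-expression binning, and the peak-timepoint
ranking used to order genes within a category.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UsageError, ValidationError

__all__ = [
    "DEFAULT_P_MAX",
    "DEFAULT_LFC_MIN",
    "call_directions",
    "consistency_filter",
    "categorize_directions",
    "cross_system_categorize",
    "anchor_bin",
    "anchor_bin_table",
    "rank_key",
    "order_genes",
]

DEFAULT_P_MAX = 0.05
DEFAULT_LFC_MIN = 1.0

DE_COLUMNS = ["gene", "system", "timepoint", "log2fc", "pvalue"]


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in DE_COLUMNS if c not in records.columns]
    if missing:
        raise ValidationError(f"differential table missing columns: {missing}")
    p = records["pvalue"].to_numpy(dtype=float)
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    if records.duplicated(["gene", "system", "timepoint"]).any():
        dup = records[records.duplicated(["gene", "system", "timepoint"])].iloc[0]
        raise ValidationError(
            f"duplicate record for ({dup['gene']}, {dup['system']}, "
            f"{dup['timepoint']})"
        )
    return records


def call_directions(
    records: pd.DataFrame,
    p_max: float = DEFAULT_P_MAX,
    lfc_min: float = DEFAULT_LFC_MIN,
    adjust: bool = False,
) -> pd.DataFrame:
    """Call up/down/ns per (gene, system, timepoint).

    up: log2fc > lfc_min and p < p_max; down symmetric; else ns. With
    ``adjust``, p-values are Benjamini-Hochberg corrected within each
    (system, timepoint) stratum before thresholding.
    """
    if not (0 < p_max < 1):
        raise ValidationError(f"p_max must be in (0,1), got {p_max}")
    if lfc_min <= 0:
        raise ValidationError(f"lfc_min must be > 0, got {lfc_min}")
    records = _check_records(records)
    out = records.copy()
    pcol = out["pvalue"].to_numpy(dtype=float)
    if adjust:
        pcol = pcol.copy()
        for _, idx in out.groupby(["system", "timepoint"]).groups.items():
            loc = out.index.get_indexer(idx)
            pcol[loc] = stats.false_discovery_control(pcol[loc], method="bh")
    lfc = out["log2fc"].to_numpy(dtype=float)
    sig = pcol < p_max
    call = np.where(
        sig & (lfc > lfc_min), "up", np.where(sig & (lfc < -lfc_min), "down", "ns")
    )
    out["call"] = call
    return out


def consistency_filter(calls: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-timepoint calls to one direction per (gene, system).

    A gene with both up and down calls within a system is ``excluded``.
    """
    if "call" not in calls.columns:
        raise ValidationError("expected a 'call' column (run call_directions first)")
    grouped = calls.groupby(["gene", "system"])["call"].agg(
        any_up=lambda s: (s == "up").any(),
        any_down=lambda s: (s == "down").any(),
    )
    direction = np.where(
        grouped["any_up"] & grouped["any_down"],
        "excluded",
        np.where(
            grouped["any_up"], "up", np.where(grouped["any_down"], "down", "ns")
        ),
    )
    out = grouped.reset_index()[["gene", "system"]]
    out["direction"] = direction
    return out


def categorize_directions(directions: Sequence[str], systems: Sequence[str]) -> str:
    """Name the cross-system category for one gene's per-system directions.

    Truth table over {up, down, ns, excluded}^systems: all up -> common_up;
    exactly two up, rest ns -> pair_up:A+B; exactly one up, rest ns ->
    specific_up:S (down symmetric); any excluded, or up and down mixed across
    systems -> discordant; all ns -> none.
    """
    if len(directions) != len(systems):
        raise UsageError("one direction per system required")
    for d in directions:
        if d not in ("up", "down", "ns", "excluded"):
            raise ValidationError(f"unknown direction {d!r}")
    if "excluded" in directions:
        return "discordant"
    ups = [s for s, d in zip(systems, directions) if d == "up"]
    downs = [s for s, d in zip(systems, directions) if d == "down"]
    if ups and downs:
        return "discordant"
    for hits, tag in ((ups, "up"), (downs, "down")):
        if not hits:
            continue
        if len(hits) == len(systems):
            return f"common_{tag}"
        if len(hits) == 1:
            return f"specific_{tag}:{hits[0]}"
        if len(hits) == 2:
            return f"pair_{tag}:{hits[0]}+{hits[1]}"
        # 3+ systems up with others ns: shared but not universal
        return f"pair_{tag}:{'+'.join(hits)}"
    return "none"


def cross_system_categorize(
    system_calls: pd.DataFrame, systems: Sequence[str]
) -> pd.DataFrame:
    """Categorize every gene across the declared systems.

    Genes absent from a system's table are treated as ns.
    """
    systems = list(systems)
    if not systems:
        raise UsageError("at least one system required")
    missing = set(system_calls["system"]) - set(systems)
    if missing:
        raise ValidationError(f"undeclared systems in calls: {sorted(missing)}")
    wide = (
        system_calls.pivot_table(
            index="gene", columns="system", values="direction", aggfunc="first"
        )
        .reindex(columns=systems)
        .fillna("ns")
    )
    categories = [
        categorize_directions([wide.at[g, s] for s in systems], systems)
        for g in wide.index
    ]
    out = wide.reset_index()
    out.columns.name = None
    out["category"] = categories
    return out[["gene", *systems, "category"]]


def anchor_bin(
    expr_start: float,
    expr_end: float,
    fc: float = 2.0,
    pseudocount: float = 1.0,
) -> str:
    """Bin a gene by its end-anchor / start-anchor expression ratio.

    ESC_high when (end + eps)/(start + eps) >= fc, MEF_high when <= 1/fc,
    else neutral. The pseudocount guards zero expression on RPKM-scale input.
    """
    if fc <= 1:
        raise ValidationError(f"fc must be > 1, got {fc}")
    if expr_start < 0 or expr_end < 0:
        raise ValidationError("expression values must be non-negative")
    ratio = (expr_end + pseudocount) / (expr_start + pseudocount)
    if ratio >= fc:
        return "ESC_high"
    if ratio <= 1.0 / fc:
        return "MEF_high"
    return "neutral"


def anchor_bin_table(
    reference: pd.DataFrame, fc: float = 2.0, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Vectorized anchor_bin over a (gene, expr_mef, expr_esc) table."""
    for col in ("gene", "expr_mef", "expr_esc"):
        if col not in reference.columns:
            raise ValidationError(f"reference expression table missing {col!r}")
    out = reference.copy()
    out["anchor_bin"] = [
        anchor_bin(m, e, fc=fc, pseudocount=pseudocount)
        for m, e in zip(out["expr_mef"], out["expr_esc"])
    ]
    return out


def rank_key(direction: str, trajectory: Mapping[str, float]) -> tuple:
    """Ordering key for one gene: (extreme timepoint index, -magnitude).

    Up genes rank by their argmax timepoint, down genes by argmin; ties go to
    the earliest timepoint, then stronger magnitude sorts first.
    """
    if direction not in ("up", "down"):
        raise UsageError(f"rank_key needs direction up|down, got {direction!r}")
    items = list(trajectory.items())
    if not items:
        raise UsageError("empty trajectory")
    values = [v for _, v in items]
    if direction == "up":
        best = max(values)
        idx = values.index(best)  # earliest tie wins
        return (idx, items[idx][0], -best)
    best = min(values)
    idx = values.index(best)
    return (idx, items[idx][0], best)


def order_genes(
    expr: pd.DataFrame,
    direction: str,
    timepoints: Sequence[str],
) -> list:
    """Sort genes of one direction by rank_key over ``timepoints`` columns.

    ``expr`` is indexed by gene with one column per timepoint.
    """
    keys = {
        g: rank_key(direction, {tp: expr.at[g, tp] for tp in timepoints})
        for g in expr.index
    }
    return sorted(expr.index, key=lambda g: (keys[g], g))
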