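"""Peak-to-gene annotation, gene-set overlap enrichment, and
accessibility-class occupancy metrics for binding peak sets."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UsageError, ValidationError
from .intervals import GenomicInterval, PeakSet, overlap_bases

__all__ = [
    "TSSRecord",
    "FEATURE_CLASSES",
    "DEFAULT_PROMOTER_WINDOW",
    "read_tss_table",
    "annotate_feature",
    "annotate_features",
    "feature_distribution",
    "link_peaks_to_genes",
    "OverlapResult",
    "gene_set_overlap",
    "bh_adjust",
    "OccupancyRecord",
    "occupancy_by_class",
]

FEATURE_CLASSES = ("promoter", "exon", "intron", "distal_intergenic")
DEFAULT_PROMOTER_WINDOW = 3000


@dataclass(frozen=True)
class TSSRecord:
    """One gene's primary transcription start site, optionally with exons."""

    gene: str
    chrom: str
    tss: int
    strand: str = "+"
    exons: tuple = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be +/-, got {self.strand!r}")
        if self.tss < 0:
            raise ValidationError(f"TSS must be >= 0, got {self.tss}")
        exons = tuple(tuple(map(int, e)) for e in self.exons)
        for s, e in exons:
            if not 0 <= s < e:
                raise ValidationError(f"bad exon interval [{s}, {e})")
        object.__setattr__(self, "exons", exons)

    @property
    def body(self) -> Optional[tuple]:
        """Gene-body span inferred from declared exons, or None."""
        if not self.exons:
            return None
        return (min(s for s, _ in self.exons), max(e for _, e in self.exons))


def read_tss_table(path) -> list:
    """Read a TSV of gene/chrom/tss/strand (optional exons column).

    Exons are encoded as comma-separated start-end pairs, e.g.
    ``100-200,400-500``. Duplicate genes warn; the first declaration wins.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str})
    for col in ("gene", "chrom", "tss", "strand"):
        if col not in df.columns:
            raise ValidationError(f"TSS table missing column {col!r}")
    records = []
    seen = set()
    for _, row in df.iterrows():
        if row["gene"] in seen:
            warnings.warn(f"duplicate TSS entry for {row['gene']}; keeping first")
            continue
        seen.add(row["gene"])
        exons = ()
        if "exons" in df.columns and isinstance(row.get("exons"), str) and row["exons"]:
            exons = tuple(
                tuple(map(int, part.split("-"))) for part in row["exons"].split(",")
            )
        records.append(
            TSSRecord(row["gene"], row["chrom"], int(row["tss"]), row["strand"], exons)
        )
    return records


def _promoter_interval(rec: TSSRecord, window: int) -> tuple:
    return (max(0, rec.tss - window), rec.tss + window)


def annotate_feature(
    peak: GenomicInterval,
    genes: Sequence[TSSRecord],
    promoter_window: int = DEFAULT_PROMOTER_WINDOW,
) -> str:
    """Classify a peak by its midpoint: promoter > exon > intron > distal."""
    if promoter_window <= 0:
        raise ValidationError("promoter_window must be > 0")
    if not genes:
        raise UsageError("empty gene table")
    mid = peak.midpoint
    in_exon = in_body = False
    for rec in genes:
        if rec.chrom != peak.chrom:
            continue
        lo, hi = _promoter_interval(rec, promoter_window)
        if lo <= mid < hi:
            return "promoter"
        for s, e in rec.exons:
            if s <= mid < e:
                in_exon = True
        body = rec.body
        if body and body[0] <= mid < body[1]:
            in_body = True
    if in_exon:
        return "exon"
    if in_body:
        return "intron"
    return "distal_intergenic"


def annotate_features(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[TSSRecord],
    promoter_window: int = DEFAULT_PROMOTER_WINDOW,
) -> list:
    return [annotate_feature(p, genes, promoter_window) for p in peaks]


def feature_distribution(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[TSSRecord],
    promoter_window: int = DEFAULT_PROMOTER_WINDOW,
) -> pd.DataFrame:
    """Count and proportion of peaks per feature class (proportions sum to 1)."""
    labels = annotate_features(peaks, genes, promoter_window)
    counts = {cls: labels.count(cls) for cls in FEATURE_CLASSES}
    total = len(labels)
    return pd.DataFrame(
        {
            "feature": FEATURE_CLASSES,
            "count": [counts[c] for c in FEATURE_CLASSES],
            "proportion": [
                counts[c] / total if total else 0.0 for c in FEATURE_CLASSES
            ],
        }
    )


def link_peaks_to_genes(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[TSSRecord],
    mode: str = "window",
    window: int = DEFAULT_PROMOTER_WINDOW,
) -> set:
    """Genes linked to peaks by TSS-window overlap or nearest-TSS assignment.

    window mode: a gene is linked when its +/-window TSS region overlaps any
    peak. nearest mode: each peak links its minimum-distance gene(s); exact
    ties link all tied genes.
    """
    if mode not in ("window", "nearest"):
        raise UsageError(f"unknown linking mode {mode!r}")
    if mode == "window":
        if window <= 0:
            raise ValidationError("window mode requires window > 0")
        windows = [
            GenomicInterval(rec.chrom, *_promoter_interval(rec, window))
            for rec in genes
        ]
        hit = overlap_bases(windows, peaks) > 0
        return {rec.gene for rec, h in zip(genes, hit) if h}
    linked: set = set()
    for peak in peaks:
        best = None
        best_genes: list = []
        for rec in genes:
            if rec.chrom != peak.chrom:
                continue
            if peak.start <= rec.tss < peak.end:
                d = 0
            elif rec.tss < peak.start:
                d = peak.start - rec.tss
            else:
                d = rec.tss - (peak.end - 1)
            if best is None or d < best:
                best, best_genes = d, [rec.gene]
            elif d == best:
                best_genes.append(rec.gene)
        linked.update(best_genes)
    return linked


@dataclass(frozen=True)
class OverlapResult:
    """Overlap of two gene sets within a universe, with hypergeometric p."""

    set_a_size: int
    set_b_size: int
    universe_size: int
    overlap_size: int
    p_enrich: float
    members: tuple

    def __post_init__(self) -> None:
        if not (
            self.overlap_size
            <= min(self.set_a_size, self.set_b_size)
            <= self.universe_size
        ):
            raise ValidationError("overlap/set/universe sizes are inconsistent")


def gene_set_overlap(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> OverlapResult:
    """Intersect two gene sets and score over-representation.

    p is the hypergeometric upper tail P(X >= k) with population = universe,
    successes = |set_a|, draws = |set_b|.
    """
    a, b, u = set(set_a), set(set_b), set(universe)
    if not a <= u or not b <= u:
        raise ValidationError("gene sets must be subsets of the universe")
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, len(u), len(a), len(b)))
    return OverlapResult(
        set_a_size=len(a),
        set_b_size=len(b),
        universe_size=len(u),
        overlap_size=k,
        p_enrich=min(p, 1.0),
        members=tuple(sorted(a & b)),
    )


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return stats.false_discovery_control(np.asarray(pvalues, float), method="bh")


@dataclass(frozen=True)
class OccupancyRecord:
    """Binding-peak occupancy of one accessibility class."""

    atac_class: str
    n_regions: int
    n_overlapping_peaks: int
    raw_fraction: float
    normalized: float


def occupancy_by_class(
    binding_peaks: PeakSet,
    class_regions: Mapping[str, Sequence[GenomicInterval]],
) -> list:
    """Partition binding peaks over accessibility classes and normalize.

    Each peak goes to the class with the largest base overlap (ties break to
    the earlier class in mapping order); peaks touching no class fall into
    ``outside``. ``normalized`` divides overlapping-peak count by the class's
    region count, correcting for class size.
    """
    classes = list(class_regions)
    all_regions = [
        (iv, cls) for cls in classes for iv in class_regions[cls]
    ]
    all_regions.sort(key=lambda t: t[0].sort_key)
    for (a, _), (b, _) in zip(all_regions, all_regions[1:]):
        if a.overlaps(b):
            raise ValidationError(
                f"class regions must be disjoint; {a} overlaps {b}"
            )
    peaks = list(binding_peaks.intervals)
    n_peaks = len(peaks)
    overlap = np.zeros((n_peaks, len(classes)), dtype=np.int64)
    for j, cls in enumerate(classes):
        overlap[:, j] = overlap_bases(peaks, class_regions[cls])
    assigned = np.full(n_peaks, -1, dtype=np.int64)
    hit = overlap.max(axis=1) > 0 if n_peaks else np.zeros(0, bool)
    if n_peaks:
        assigned[hit] = np.argmax(overlap[hit], axis=1)  # argmax ties -> first
    records = []
    for j, cls in enumerate(classes):
        n_regions = len(class_regions[cls])
        n_over = int((assigned == j).sum())
        records.append(
            OccupancyRecord(
                atac_class=cls,
                n_regions=n_regions,
                n_overlapping_peaks=n_over,
                raw_fraction=n_over / n_peaks if n_peaks else 0.0,
                normalized=n_over / n_regions if n_regions else float("nan"),
            )
        )
    n_out = int((assigned == -1).sum())
    records.append(
        OccupancyRecord(
            atac_class="outside",
            n_regions=0,
            n_overlapping_peaks=n_out,
            raw_fraction=n_out / n_peaks if n_peaks else 0.0,
            normalized=float("nan"),
        )
    )
    return records
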