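"""Relative mtDNA quantification from low-pass sequencing reads.

The mtDNA ratio of a biopsy is the ratio of mitochondrial read counts to the
read counts of a stable autosomal normalization interval, after excluding
reads that are unmapped, duplicated, secondary/supplementary, low-MAPQ or
poorly aligned. The normalization interval is screened from a reference
panel of presumed-euploid samples: among candidate windows on the autosomes
with the lowest population aneuploidy frequency, the window whose fraction
of total autosomal reads varies least across samples (minimum coefficient
of variation) is selected. In clinical practice this lands on chromosome 6.

Coordinates are 0-based half-open throughout; SAM's 1-based positions are
converted on read by the `reads` module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import MT_NAMES, SEX_CHROMS, GenomicBin, validate_bins
from .reads import ReadSet

__all__ = [
    "QcConfig",
    "QcStats",
    "BinCountMatrix",
    "NormalizationInterval",
    "MtDnaRatio",
    "filter_reads",
    "count_bin_reads",
    "screen_normalization_interval",
    "compute_mtdna_ratio",
    "DEFAULT_ANEUPLOIDY_FREQ",
]

# Order in which filters are applied; a removed read is attributed to the
# first filter it fails.
FILTER_ORDER = ("unmapped", "duplicate", "secondary", "low_mapq", "poor_alignment")


@dataclass(frozen=True)
class QcConfig:
    """Read-level QC thresholds.

    Defaults (MAPQ >= 20, mismatch fraction <= 0.1, duplicates and
    secondary/supplementary alignments dropped) are conventional for
    read-count applications of low-pass libraries; all are configurable.
    "Poor alignment" is operationalised as edit-distance fraction
    NM / aligned length; setting ``max_mismatch_frac=1.0`` disables it.
    """

    min_mapq: int = 20
    max_mismatch_frac: float = 0.1
    drop_duplicates: bool = True
    drop_secondary: bool = True

    def __post_init__(self) -> None:
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")
        if not (0.0 <= self.max_mismatch_frac <= 1.0):
            raise ValueError("max_mismatch_frac must be in [0, 1]")


@dataclass
class QcStats:
    """Per-filter removal counts for one sample."""

    input: int = 0
    unmapped: int = 0
    duplicate: int = 0
    secondary: int = 0
    low_mapq: int = 0
    poor_alignment: int = 0
    retained: int = 0

    def removed(self) -> int:
        return (self.unmapped + self.duplicate + self.secondary
                + self.low_mapq + self.poor_alignment)

    def as_dict(self) -> dict[str, int]:
        return {
            "input": self.input,
            **{name: getattr(self, name) for name in FILTER_ORDER},
            "retained": self.retained,
        }


def filter_reads(reads: ReadSet, qc: QcConfig = QcConfig()) -> tuple[ReadSet, QcStats]:
    """Apply the QC filters; attribution follows :data:`FILTER_ORDER`.

    Returns the retained reads and per-filter removal counts; the counts are
    conservative: input = retained + sum of removals.
    """
    stats = QcStats(input=len(reads))
    alive = np.ones(len(reads), dtype=bool)

    def strike(mask: np.ndarray, name: str) -> None:
        hit = alive & mask
        setattr(stats, name, int(hit.sum()))
        alive[hit] = False

    strike(reads.is_unmapped, "unmapped")
    if qc.drop_duplicates:
        strike(reads.is_duplicate, "duplicate")
    if qc.drop_secondary:
        strike(reads.is_secondary_or_supplementary, "secondary")
    strike(reads.data["mapq"] < qc.min_mapq, "low_mapq")
    aligned = reads.data["aligned_len"]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(aligned > 0, reads.data["nm"] / np.maximum(aligned, 1), np.inf)
    strike(frac > qc.max_mismatch_frac, "poor_alignment")

    stats.retained = int(alive.sum())
    return reads.select(alive), stats


@dataclass
class BinCountMatrix:
    """Samples x bins raw read counts plus per-sample mtDNA counts."""

    sample_ids: list[str]
    bins: list[GenomicBin]
    counts: np.ndarray            # (n_samples, n_bins) non-negative ints
    mt_counts: np.ndarray         # (n_samples,)
    qc_stats: list[QcStats] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.mt_counts = np.asarray(self.mt_counts)
        if self.counts.shape != (len(self.sample_ids), len(self.bins)):
            raise ValueError("counts shape does not match samples x bins")
        if self.mt_counts.shape != (len(self.sample_ids),):
            raise ValueError("mt_counts length does not match samples")
        if (self.counts < 0).any() or (self.mt_counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def bin_chroms(self) -> np.ndarray:
        return np.array([b.chrom for b in self.bins])

    @classmethod
    def stack(cls, matrices: Sequence["BinCountMatrix"]) -> "BinCountMatrix":
        if not matrices:
            raise ValueError("nothing to stack")
        first = matrices[0]
        for m in matrices[1:]:
            if m.bins != first.bins:
                raise ValueError("cannot stack matrices with differing bins")
        return cls(
            sample_ids=[s for m in matrices for s in m.sample_ids],
            bins=first.bins,
            counts=np.vstack([m.counts for m in matrices]),
            mt_counts=np.concatenate([m.mt_counts for m in matrices]),
            qc_stats=[q for m in matrices for q in m.qc_stats],
        )


def count_bin_reads(
    reads: ReadSet,
    bins: Sequence[GenomicBin],
    sample_id: str = "sample",
    mt_contigs: Iterable[str] = MT_NAMES,
    on_undeclared: str = "error",
    qc_stats: QcStats | None = None,
) -> BinCountMatrix:
    """Assign retained reads to the bin containing their leftmost coordinate.

    Reads on a mitochondrial contig accumulate in ``mt_counts``. Reads on a
    contig with no declared bins raise by default (``on_undeclared="error"``)
    or are discarded (``"discard"``).
    """
    if not bins:
        raise ValueError("empty bin list")
    validate_bins(bins)
    if on_undeclared not in ("error", "discard"):
        raise ValueError("on_undeclared must be 'error' or 'discard'")

    mt = set(mt_contigs)
    starts_by_chrom: dict[str, np.ndarray] = {}
    ends_by_chrom: dict[str, np.ndarray] = {}
    binidx_by_chrom: dict[str, np.ndarray] = {}
    for i, b in enumerate(bins):
        starts_by_chrom.setdefault(b.chrom, [])
        ends_by_chrom.setdefault(b.chrom, [])
        binidx_by_chrom.setdefault(b.chrom, [])
        starts_by_chrom[b.chrom].append(b.start)
        ends_by_chrom[b.chrom].append(b.end)
        binidx_by_chrom[b.chrom].append(i)
    for chrom in starts_by_chrom:
        starts_by_chrom[chrom] = np.asarray(starts_by_chrom[chrom])
        ends_by_chrom[chrom] = np.asarray(ends_by_chrom[chrom])
        binidx_by_chrom[chrom] = np.asarray(binidx_by_chrom[chrom])

    counts = np.zeros(len(bins), dtype=np.int64)
    mt_count = 0

    ref_ids = reads.data["ref_id"]
    positions = reads.data["pos"]
    unmapped = reads.is_unmapped
    if unmapped.any():
        raise ValueError("count_bin_reads expects filtered (mapped) reads")

    for rid, name in enumerate(reads.references):
        sel = ref_ids == rid
        n_here = int(sel.sum())
        if n_here == 0:
            continue
        if name in mt:
            mt_count += n_here
            continue
        if name not in starts_by_chrom:
            if on_undeclared == "error":
                raise ValueError(f"read on undeclared contig {name!r}")
            continue
        pos = positions[sel]
        starts = starts_by_chrom[name]
        ends = ends_by_chrom[name]
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
        if not ok.all():
            if on_undeclared == "error":
                bad = pos[~ok][0]
                raise ValueError(f"read at {name}:{bad} falls outside declared bins")
            idx = idx[ok]
        np.add.at(counts, binidx_by_chrom[name][idx], 1)

    return BinCountMatrix(
        sample_ids=[sample_id],
        bins=list(bins),
        counts=counts[None, :],
        mt_counts=np.array([mt_count]),
        qc_stats=[qc_stats] if qc_stats is not None else [],
    )


@dataclass(frozen=True)
class NormalizationInterval:
    """Autosomal window used as the denominator of the mtDNA ratio."""

    chrom: str
    start: int
    end: int
    stability_score: float = math.nan   # CV of across-sample read fraction
    aneuploidy_freq: float = math.nan

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("invalid interval coordinates")


# Stand-in per-chromosome aneuploidy frequencies: SYNTHETIC placeholder table
# with chromosome 6 minimal, matching its published reputation as the least
# aneuploid somatic chromosome. Replace with a literature-derived table for
# real analyses.
DEFAULT_ANEUPLOIDY_FREQ: dict[str, float] = {
    "1": 0.040, "2": 0.045, "3": 0.042, "4": 0.055, "5": 0.040,
    "6": 0.020, "7": 0.045, "8": 0.050, "9": 0.055, "10": 0.050,
    "11": 0.048, "12": 0.040, "13": 0.080, "14": 0.070, "15": 0.090,
    "16": 0.110, "17": 0.060, "18": 0.085, "19": 0.075, "20": 0.065,
    "21": 0.120, "22": 0.130,
}


def screen_normalization_interval(
    reference: BinCountMatrix,
    aneuploidy_freq: Mapping[str, float] = DEFAULT_ANEUPLOIDY_FREQ,
    window_bins: int = 10,
    sex_chroms: Iterable[str] = SEX_CHROMS,
    mt_contigs: Iterable[str] = MT_NAMES,
    return_report: bool = False,
):
    """Select the most stable autosomal window on the least-aneuploid
    chromosome(s) from a presumed-euploid reference panel.

    For every run of ``window_bins`` consecutive bins on one autosome, the
    per-sample fraction of total autosomal counts is computed; the window's
    stability score is the coefficient of variation (sd/mean, ddof=1) of
    that fraction across samples. Candidates are restricted to chromosomes
    attaining the minimum aneuploidy frequency; the minimum-CV window wins,
    ties broken by bin order (genome declaration order, then start).

    Returns the interval, or ``(interval, report)`` with a per-window
    DataFrame when ``return_report`` is set.
    """
    if reference.n_samples < 2:
        raise ValueError("interval screening needs at least 2 reference samples")
    if window_bins < 1:
        raise ValueError("window_bins must be >= 1")

    excluded = set(sex_chroms) | set(mt_contigs)
    chroms = reference.bin_chroms()
    autosomal = ~np.isin(chroms, sorted(excluded))
    if not autosomal.any():
        raise ValueError("no autosomal bins in reference")

    present = [str(c) for c in dict.fromkeys(chroms[autosomal])]
    missing = [c for c in present if c not in aneuploidy_freq]
    if missing:
        raise ValueError(f"aneuploidy frequency table lacks chromosomes: {missing}")

    totals = reference.counts[:, autosomal].sum(axis=1).astype(float)
    if (totals <= 0).any():
        bad = [reference.sample_ids[i] for i in np.flatnonzero(totals <= 0)]
        raise ValueError(f"reference samples with zero autosomal counts: {bad}")

    min_freq = min(aneuploidy_freq[c] for c in present)
    eligible = {c for c in present if aneuploidy_freq[c] == min_freq}

    rows = []
    best = None  # (cv, order_index)
    order = 0
    for chrom in present:
        idx = np.flatnonzero((chroms == chrom) & autosomal)
        if len(idx) < window_bins:
            continue
        # cumulative sums across the chromosome's bins, per sample
        sub = reference.counts[:, idx].astype(float)
        csum = np.concatenate(
            [np.zeros((reference.n_samples, 1)), np.cumsum(sub, axis=1)], axis=1
        )
        n_windows = len(idx) - window_bins + 1
        for w in range(n_windows):
            window_counts = csum[:, w + window_bins] - csum[:, w]
            frac = window_counts / totals
            mean = frac.mean()
            cv = math.inf if mean == 0 else float(frac.std(ddof=1) / mean)
            start = reference.bins[idx[w]].start
            end = reference.bins[idx[w + window_bins - 1]].end
            in_race = chrom in eligible
            rows.append((chrom, start, end, cv, aneuploidy_freq[chrom], in_race))
            if in_race and (best is None or cv < best[0]):
                best = (cv, order, chrom, start, end)
            order += 1

    if best is None:
        raise ValueError(
            f"no chromosome with >= {window_bins} bins among the least-aneuploid set"
        )

    cv, _, chrom, start, end = best
    interval = NormalizationInterval(
        chrom=chrom, start=start, end=end,
        stability_score=cv, aneuploidy_freq=aneuploidy_freq[chrom],
    )
    if not return_report:
        return interval
    report = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "cv", "aneuploidy_freq", "eligible"],
    )
    return interval, report


@dataclass
class MtDnaRatio:
    """Normalized mitochondrial quantity of one sample with provenance."""

    sample_id: str
    value: float
    reads_mt: int
    reads_interval: int
    interval: NormalizationInterval
    scale: float = 1.0
    undefined: bool = False
    below_min_reads: bool = False


def compute_mtdna_ratio(
    counts: BinCountMatrix,
    interval: NormalizationInterval,
    scale: float = 1.0,
    min_mt_reads: int = 0,
) -> list[MtDnaRatio]:
    """mtDNA ratio per sample: ``scale * mt_counts / interval counts``.

    The ratio is invariant to uniform rescaling of all counts. A zero
    denominator yields an undefined (NaN) ratio; ``min_mt_reads`` flags
    samples whose mitochondrial evidence is too thin to call a valid
    detection (reported, never silently dropped).
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    in_interval = np.array(
        [b.chrom == interval.chrom and b.start >= interval.start and b.end <= interval.end
         for b in counts.bins]
    )
    if not in_interval.any():
        raise ValueError("normalization interval covers no declared bins")
    denom = counts.counts[:, in_interval].sum(axis=1)

    out = []
    for i, sample in enumerate(counts.sample_ids):
        mt = int(counts.mt_counts[i])
        d = int(denom[i])
        undefined = d == 0
        value = math.nan if undefined else scale * mt / d
        out.append(
            MtDnaRatio(
                sample_id=sample, value=value, reads_mt=mt, reads_interval=d,
                interval=interval, scale=scale, undefined=undefined,
                below_min_reads=mt < min_mt_reads,
            )
        )
    return out


def ratios_to_frame(ratios: Sequence[MtDnaRatio]) -> pd.DataFrame:
    """Tabular view of per-sample ratios for CSV export."""
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in ratios],
            "value": [r.value for r in ratios],
            "reads_mt": [r.reads_mt for r in ratios],
            "reads_interval": [r.reads_interval for r in ratios],
            "interval": [f"{r.interval.chrom}:{r.interval.start}-{r.interval.end}"
                         for r in ratios],
            "scale": [r.scale for r in ratios],
            "undefined": [r.undefined for r in ratios],
            "below_min_reads": [r.below_min_reads for r in ratios],
        }
    )
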