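"""Synthetic aligned reads for a biopsied, amplified, low-pass library.

The generative model: a biopsy of ``n_cells`` cells contributes nuclear
template in proportion to copy number (2 per autosome, or the aneuploid
state) and mitochondrial template in proportion to ``mt_copies_per_cell``.
Read counts per genomic bin are Poisson with mean proportional to template
mass; given the per-bin nuclear coverage, the expected mitochondrial count
is ``coverage * mt_copies_per_cell * mt_length / (2 * bin_size)`` — the
biopsied cell number cancels out of the ratio, as it does in the assay.

Four contamination classes (duplicate-flagged, unmapped, low-MAPQ,
high-edit-distance) are injected at configured fractions of the total read
stream, independently of genomic position, which is exactly why the QC
filters leave the mt/nuclear ratio unbiased. No base-level sequence is
simulated: quantification uses only positions, flags and quality fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ..genome import Genome, GenomicBin, toy_genome, validate_bins
from ..reads import FLAG_DUPLICATE, FLAG_UNMAPPED, ReadSet

__all__ = ["SimReadConfig", "SimulatedReads", "simulate_biopsy_reads"]

# Field values emitted per class; clean reads pass the default QcConfig,
# each contaminated class fails exactly one of its filters.
CLEAN_MAPQ = 60
CLEAN_ALIGNED_LEN = 100
LOW_MAPQ_RANGE = (0, 20)        # below the default min_mapq of 20
POOR_ALIGNMENT_NM = 30          # 0.30 of aligned length, above the 0.1 default


@dataclass(frozen=True)
class SimReadConfig:
    """Parameters of the biopsy/amplification/sequencing emulation.

    ``nuclear_coverage`` is the expected read count of one full-width
    disomic bin. ``aneuploidy_spec`` lists whole-chromosome states as
    (chromosome, copies) with copies in {1, 2, 3}.
    """

    n_cells: int = 5
    mt_copies_per_cell: float = 1000.0
    nuclear_coverage: float = 100.0
    frac_duplicates: float = 0.05
    frac_unmapped: float = 0.03
    frac_low_mapq: float = 0.05
    frac_poor_alignment: float = 0.02
    aneuploidy_spec: tuple[tuple[str, int], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if self.mt_copies_per_cell <= 0:
            raise ValueError("mt_copies_per_cell must be positive")
        if self.nuclear_coverage <= 0:
            raise ValueError("nuclear_coverage must be positive")
        fracs = self.fractions
        if any(not (0.0 <= f <= 1.0) for f in fracs.values()):
            raise ValueError("contamination fractions must lie in [0, 1]")
        if sum(fracs.values()) >= 1.0:
            raise ValueError("contamination fractions must sum to less than 1")
        chroms = [c for c, _ in self.aneuploidy_spec]
        if len(chroms) != len(set(chroms)):
            raise ValueError("each chromosome may appear at most once in aneuploidy_spec")
        for c, state in self.aneuploidy_spec:
            if state not in (1, 2, 3):
                raise ValueError(f"copy-number state for {c} must be 1, 2 or 3")

    @property
    def fractions(self) -> dict[str, float]:
        return {
            "duplicate": self.frac_duplicates,
            "unmapped": self.frac_unmapped,
            "low_mapq": self.frac_low_mapq,
            "poor_alignment": self.frac_poor_alignment,
        }


@dataclass
class SimulatedReads:
    """Generated reads plus the exact generative truth used."""

    reads: ReadSet
    config: SimReadConfig
    #: expected mt reads divided by the expected count of one full-width
    #: disomic bin; truth for a w-bin normalization window is this / w.
    true_mt_per_bin_ratio: float
    expected_bin_counts: np.ndarray
    expected_mt_count: float
    n_by_class: dict[str, int] = field(default_factory=dict)

    def true_ratio_for_interval(self, n_bins: int) -> float:
        return self.true_mt_per_bin_ratio / n_bins


def simulate_biopsy_reads(
    config: SimReadConfig,
    bins: Sequence[GenomicBin],
    genome: Genome | None = None,
    mt_contig: str = "MT",
) -> SimulatedReads:
    """Draw one sample's read set over the given nuclear bin tiling.

    Per-bin clean counts are Poisson with mean coverage x (bin length /
    full bin width) x (copy state / 2); mitochondrial counts are Poisson
    with the mean described in the module docstring. Contaminated reads are
    appended at rates ``f_c / (1 - sum f)`` of the clean total so each class
    is the expected fraction ``f_c`` of the final stream, then the stream
    is shuffled. Identical config (including seed) gives identical output.
    """
    if not bins:
        raise ValueError("empty bin list")
    validate_bins(bins)
    if genome is None:
        genome = toy_genome()
    if mt_contig not in genome:
        raise ValueError(f"mt contig {mt_contig!r} not declared in genome")
    for c, _ in config.aneuploidy_spec:
        if c not in {b.chrom for b in bins}:
            raise ValueError(f"aneuploidy_spec names chromosome {c!r} with no bins")

    rng = np.random.default_rng(config.seed)

    chroms = np.array([b.chrom for b in bins])
    starts = np.array([b.start for b in bins], dtype=np.int64)
    ends = np.array([b.end for b in bins], dtype=np.int64)
    widths = (ends - starts).astype(float)
    full_width = float(widths.max())

    state = np.full(len(bins), 2.0)
    for c, s in config.aneuploidy_spec:
        state[chroms == c] = float(s)

    lam_bins = config.nuclear_coverage * (widths / full_width) * (state / 2.0)
    lam_mt = (
        config.nuclear_coverage
        * config.mt_copies_per_cell
        * genome[mt_contig]
        / (2.0 * full_width)
    )
    true_ratio = lam_mt / config.nuclear_coverage

    references = list(dict.fromkeys(chroms)) + [mt_contig]
    ref_index = {name: i for i, name in enumerate(references)}
    bin_ref = np.array([ref_index[c] for c in chroms], dtype=np.int32)
    mt_ref = ref_index[mt_contig]
    mt_len = genome[mt_contig]

    def draw_positions(bin_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(ref_id, pos) for reads assigned to nuclear bins / the mt contig;
        bin index len(bins) denotes the mt contig."""
        is_mt = bin_idx == len(bins)
        ref = np.where(is_mt, mt_ref, bin_ref[np.minimum(bin_idx, len(bins) - 1)])
        lo = np.where(is_mt, 0, starts[np.minimum(bin_idx, len(bins) - 1)])
        hi = np.where(is_mt, mt_len, ends[np.minimum(bin_idx, len(bins) - 1)])
        pos = rng.integers(lo, hi)
        return ref.astype(np.int32), pos.astype(np.int64)

    # clean reads: per-bin Poisson counts, positions uniform within bin
    clean_counts = rng.poisson(lam_bins)
    clean_mt = int(rng.poisson(lam_mt))
    clean_bin_idx = np.concatenate(
        [np.repeat(np.arange(len(bins)), clean_counts),
         np.full(clean_mt, len(bins), dtype=np.int64)]
    )
    n_clean = len(clean_bin_idx)

    fracs = config.fractions
    f_total = sum(fracs.values())
    expected_clean = float(lam_bins.sum() + lam_mt)

    parts_ref, parts_pos, parts_mapq, parts_flag, parts_nm, parts_len = [], [], [], [], [], []
    n_by_class = {"clean": n_clean}

    ref, pos = draw_positions(clean_bin_idx)
    parts_ref.append(ref)
    parts_pos.append(pos)
    parts_mapq.append(np.full(n_clean, CLEAN_MAPQ, dtype=np.int16))
    parts_flag.append(np.zeros(n_clean, dtype=np.uint16))
    parts_nm.append(np.zeros(n_clean, dtype=np.int32))
    parts_len.append(np.full(n_clean, CLEAN_ALIGNED_LEN, dtype=np.int32))

    # contaminated reads land anywhere, with probability proportional to
    # template mass, so they cannot bias the mt/nuclear ratio
    probs = np.concatenate([lam_bins, [lam_mt]])
    probs = probs / probs.sum()

    for name, frac in fracs.items():
        n_c = int(rng.poisson(expected_clean * frac / (1.0 - f_total))) if frac > 0 else 0
        n_by_class[name] = n_c
        if n_c == 0:
            continue
        if name == "unmapped":
            parts_ref.append(np.full(n_c, -1, dtype=np.int32))
            parts_pos.append(np.full(n_c, -1, dtype=np.int64))
            parts_mapq.append(np.zeros(n_c, dtype=np.int16))
            parts_flag.append(np.full(n_c, FLAG_UNMAPPED, dtype=np.uint16))
            parts_nm.append(np.zeros(n_c, dtype=np.int32))
            parts_len.append(np.zeros(n_c, dtype=np.int32))
            continue
        bin_idx = rng.choice(len(bins) + 1, size=n_c, p=probs)
        ref, pos = draw_positions(bin_idx)
        parts_ref.append(ref)
        parts_pos.append(pos)
        if name == "duplicate":
            parts_mapq.append(np.full(n_c, CLEAN_MAPQ, dtype=np.int16))
            parts_flag.append(np.full(n_c, FLAG_DUPLICATE, dtype=np.uint16))
            parts_nm.append(np.zeros(n_c, dtype=np.int32))
        elif name == "low_mapq":
            parts_mapq.append(rng.integers(*LOW_MAPQ_RANGE, size=n_c).astype(np.int16))
            parts_flag.append(np.zeros(n_c, dtype=np.uint16))
            parts_nm.append(np.zeros(n_c, dtype=np.int32))
        else:  # poor_alignment
            parts_mapq.append(np.full(n_c, CLEAN_MAPQ, dtype=np.int16))
            parts_flag.append(np.zeros(n_c, dtype=np.uint16))
            parts_nm.append(np.full(n_c, POOR_ALIGNMENT_NM, dtype=np.int32))
        parts_len.append(np.full(n_c, CLEAN_ALIGNED_LEN, dtype=np.int32))

    readset = ReadSet.from_arrays(
        references,
        np.concatenate(parts_ref),
        np.concatenate(parts_pos),
        np.concatenate(parts_mapq),
        np.concatenate(parts_flag),
        np.concatenate(parts_nm),
        np.concatenate(parts_len),
    )
    order = rng.permutation(len(readset))
    readset = readset.select(order)

    return SimulatedReads(
        reads=readset,
        config=config,
        true_mt_per_bin_ratio=float(true_ratio),
        expected_bin_counts=lam_bins,
        expected_mt_count=float(lam_mt),
        n_by_class=n_by_class,
    )
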