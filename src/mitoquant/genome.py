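"""Reference genome declaration and genomic binning.

The quantification pipeline never touches sequence: it only needs contig
names, contig lengths and a tiling of the nuclear genome into fixed-width
bins. A scaled-down genome (1/100 of the GRCh38 contig lengths, plus the
full-length 16,569 bp mitochondrial contig) is the default for simulation
and testing; full-size naming/lengths are a constructor away.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "GenomicBin",
    "Genome",
    "toy_genome",
    "make_bins",
    "read_bed",
    "write_bed",
    "MT_NAMES",
    "SEX_CHROMS",
]

#: Contig names recognised as the mitochondrial genome (configurable at call
#: sites that accept ``mt_contigs``).
MT_NAMES = frozenset({"MT", "chrM", "chrMT"})

#: Contig names treated as sex chromosomes (excluded from autosomal totals).
SEX_CHROMS = frozenset({"X", "Y", "chrX", "chrY"})

# GRCh38 primary-assembly contig lengths (bp).
_GRCH38_LENGTHS = {
    "1": 248_956_422, "2": 242_193_529, "3": 198_295_559, "4": 190_214_555,
    "5": 181_538_259, "6": 170_805_979, "7": 159_345_973, "8": 145_138_636,
    "9": 138_394_717, "10": 133_797_422, "11": 135_086_622, "12": 133_275_309,
    "13": 114_364_328, "14": 107_043_718, "15": 101_991_189, "16": 90_338_345,
    "17": 83_257_441, "18": 80_373_285, "19": 58_617_616, "20": 64_444_167,
    "21": 46_709_983, "22": 50_818_468, "X": 156_040_895, "Y": 57_227_415,
}

MT_LENGTH = 16_569


@dataclass(frozen=True, order=True)
class GenomicBin:
    """Half-open, 0-based genomic interval used as a counting unit."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid bin {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


class Genome:
    """Ordered mapping of contig name to length.

    Contig order is meaningful: bins, SAM headers and screening tie-breaks
    all follow declaration order.
    """

    def __init__(self, lengths: Mapping[str, int]):
        if not lengths:
            raise ValueError("genome must declare at least one contig")
        for name, length in lengths.items():
            if length <= 0:
                raise ValueError(f"contig {name!r} has non-positive length {length}")
        self._lengths = dict(lengths)

    @property
    def contigs(self) -> list[str]:
        return list(self._lengths)

    def __contains__(self, name: str) -> bool:
        return name in self._lengths

    def __getitem__(self, name: str) -> int:
        return self._lengths[name]

    def __len__(self) -> int:
        return len(self._lengths)

    def items(self):
        return self._lengths.items()

    def autosomes(
        self,
        sex_chroms: Iterable[str] = SEX_CHROMS,
        mt_contigs: Iterable[str] = MT_NAMES,
    ) -> list[str]:
        excluded = set(sex_chroms) | set(mt_contigs)
        return [c for c in self._lengths if c not in excluded]

    def mt_contig(self, mt_contigs: Iterable[str] = MT_NAMES) -> str | None:
        for c in self._lengths:
            if c in set(mt_contigs):
                return c
        return None


def toy_genome(scale: int = 100, include_sex: bool = True) -> Genome:
    """Scaled-down human genome: GRCh38 contig lengths divided by ``scale``
    plus a full-length mitochondrial contig named ``MT``.

    ``scale=1`` gives full-size contigs with the same plain (non-"chr")
    naming convention.
    """
    if scale < 1:
        raise ValueError("scale must be >= 1")
    lengths: dict[str, int] = {}
    for name, length in _GRCH38_LENGTHS.items():
        if not include_sex and name in ("X", "Y"):
            continue
        lengths[name] = length // scale
    lengths["MT"] = MT_LENGTH
    return Genome(lengths)


def make_bins(
    genome: Genome,
    bin_size: int = 1_000_000,
    contigs: Sequence[str] | None = None,
    mt_contigs: Iterable[str] = MT_NAMES,
) -> list[GenomicBin]:
    """Tile nuclear contigs with fixed-width bins (last bin may be partial).

    The mitochondrial contig is never binned: mt reads are counted against
    the whole contig.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    mt = set(mt_contigs)
    if contigs is None:
        contigs = [c for c in genome.contigs if c not in mt]
    bins: list[GenomicBin] = []
    for chrom in contigs:
        if chrom in mt:
            continue
        length = genome[chrom]
        for start in range(0, length, bin_size):
            bins.append(GenomicBin(chrom, start, min(start + bin_size, length)))
    if not bins:
        raise ValueError("no bins produced: check contig selection and bin size")
    return bins


def validate_bins(bins: Sequence[GenomicBin]) -> None:
    """Check per-chromosome sortedness and non-overlap."""
    by_chrom: dict[str, list[GenomicBin]] = {}
    for b in bins:
        by_chrom.setdefault(b.chrom, []).append(b)
    for chrom, chrom_bins in by_chrom.items():
        for prev, cur in zip(chrom_bins, chrom_bins[1:]):
            if cur.start < prev.end:
                raise ValueError(
                    f"bins on {chrom} overlap or are unsorted: {prev} then {cur}"
                )


def read_bed(path) -> list[GenomicBin]:
    """Read bins from a 3+ column BED file (0-based half-open)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": int, "end": int},
    )
    bins = [GenomicBin(r.chrom, r.start, r.end) for r in df.itertuples()]
    validate_bins(bins)
    return bins


def write_bed(bins: Sequence[GenomicBin], path) -> None:
    pd.DataFrame(
        {"chrom": [b.chrom for b in bins],
         "start": [b.start for b in bins],
         "end": [b.end for b in bins]}
    ).to_csv(path, sep="\t", header=False, index=False)
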