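"""Aligned-read container and SAM/BAM I/O.

Quantification uses only position, flags, mapping quality and edit distance
— never bases — so reads are held in a columnar :class:`ReadSet` backed by
numpy arrays. This keeps filtering and counting vectorised for the
million-read inputs typical of low-pass PGT-A libraries, while pysam handles
the on-disk formats.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pysam

from .genome import Genome

__all__ = ["AlignedRead", "ReadSet", "read_alignments", "write_sam"]

# SAM flag bits used by the QC filters.
FLAG_UNMAPPED = 0x4
FLAG_SECONDARY = 0x100
FLAG_DUPLICATE = 0x400
FLAG_SUPPLEMENTARY = 0x800

_DTYPE = np.dtype(
    [
        ("ref_id", np.int32),      # index into ReadSet.references; -1 = unmapped
        ("pos", np.int64),         # 0-based leftmost coordinate; -1 = unmapped
        ("mapq", np.int16),
        ("flag", np.uint16),
        ("nm", np.int32),          # edit distance (NM tag)
        ("aligned_len", np.int32), # aligned query length
    ]
)


@dataclass(frozen=True)
class AlignedRead:
    """Single-read view; ``chrom`` is None for unmapped reads."""

    chrom: str | None
    pos: int
    mapq: int
    is_unmapped: bool
    is_duplicate: bool
    is_secondary_or_supplementary: bool
    nm: int
    aligned_len: int

    def __post_init__(self) -> None:
        if not self.is_unmapped and self.aligned_len > 0 and self.nm > self.aligned_len:
            raise ValueError("edit distance exceeds aligned length")


class ReadSet:
    """Columnar collection of aligned reads.

    Parameters
    ----------
    data : structured ndarray with fields ref_id/pos/mapq/flag/nm/aligned_len
    references : contig names that ``ref_id`` indexes into
    """

    def __init__(self, data: np.ndarray, references: Sequence[str]):
        if data.dtype != _DTYPE:
            raise TypeError("ReadSet data must use the canonical read dtype")
        self.data = data
        self.references = list(references)

    # -- constructors ------------------------------------------------------

    @classmethod
    def empty(cls, references: Sequence[str]) -> "ReadSet":
        return cls(np.empty(0, dtype=_DTYPE), references)

    @classmethod
    def from_arrays(
        cls,
        references: Sequence[str],
        ref_id,
        pos,
        mapq,
        flag,
        nm,
        aligned_len,
    ) -> "ReadSet":
        n = len(ref_id)
        data = np.empty(n, dtype=_DTYPE)
        data["ref_id"] = ref_id
        data["pos"] = pos
        data["mapq"] = mapq
        data["flag"] = flag
        data["nm"] = nm
        data["aligned_len"] = aligned_len
        return cls(data, references)

    @classmethod
    def from_records(
        cls, records: Sequence[AlignedRead], references: Sequence[str] | None = None
    ) -> "ReadSet":
        if references is None:
            seen: dict[str, None] = {}
            for r in records:
                if r.chrom is not None:
                    seen.setdefault(r.chrom, None)
            references = list(seen)
        index = {name: i for i, name in enumerate(references)}
        data = np.empty(len(records), dtype=_DTYPE)
        for i, r in enumerate(records):
            flag = 0
            if r.is_unmapped:
                flag |= FLAG_UNMAPPED
            if r.is_duplicate:
                flag |= FLAG_DUPLICATE
            if r.is_secondary_or_supplementary:
                flag |= FLAG_SECONDARY
            data[i] = (
                -1 if r.chrom is None else index[r.chrom],
                -1 if r.is_unmapped else r.pos,
                r.mapq,
                flag,
                r.nm,
                r.aligned_len,
            )
        return cls(data, references)

    # -- basic container behaviour ----------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    def __iter__(self) -> Iterator[AlignedRead]:
        for row in self.data:
            unmapped = bool(row["flag"] & FLAG_UNMAPPED)
            yield AlignedRead(
                chrom=None if unmapped else self.references[row["ref_id"]],
                pos=int(row["pos"]),
                mapq=int(row["mapq"]),
                is_unmapped=unmapped,
                is_duplicate=bool(row["flag"] & FLAG_DUPLICATE),
                is_secondary_or_supplementary=bool(
                    row["flag"] & (FLAG_SECONDARY | FLAG_SUPPLEMENTARY)
                ),
                nm=int(row["nm"]),
                aligned_len=int(row["aligned_len"]),
            )

    def select(self, mask: np.ndarray) -> "ReadSet":
        return ReadSet(self.data[mask], self.references)

    # -- derived columns ---------------------------------------------------

    @property
    def is_unmapped(self) -> np.ndarray:
        return (self.data["flag"] & FLAG_UNMAPPED) != 0

    @property
    def is_duplicate(self) -> np.ndarray:
        return (self.data["flag"] & FLAG_DUPLICATE) != 0

    @property
    def is_secondary_or_supplementary(self) -> np.ndarray:
        return (self.data["flag"] & (FLAG_SECONDARY | FLAG_SUPPLEMENTARY)) != 0

    def chrom_names(self) -> list[str | None]:
        return [
            None if u else self.references[i]
            for u, i in zip(self.is_unmapped, self.data["ref_id"])
        ]


def read_alignments(path, require_nm: bool = True) -> ReadSet:
    """Load a SAM/BAM file into a :class:`ReadSet`.

    Records without an NM tag get ``nm=0`` when ``require_nm`` is False,
    otherwise an error names the offending record index.
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        references = list(fh.references)
        rows = []
        for i, rec in enumerate(fh.fetch(until_eof=True)):
            if rec.is_unmapped:
                rows.append((-1, -1, rec.mapping_quality, rec.flag, 0, 0))
                continue
            try:
                nm = rec.get_tag("NM")
            except KeyError:
                if require_nm:
                    raise ValueError(f"record {i} lacks an NM tag") from None
                nm = 0
            aligned_len = rec.query_alignment_length or rec.infer_query_length() or 0
            rows.append(
                (rec.reference_id, rec.reference_start, rec.mapping_quality,
                 rec.flag, nm, aligned_len)
            )
    data = np.array(rows, dtype=_DTYPE) if rows else np.empty(0, dtype=_DTYPE)
    return ReadSet(data, references)


def write_sam(reads: ReadSet, path, genome: Genome) -> None:
    """Write minimal SAM records (no bases/qualities) with @SQ headers from
    the declared genome. A ``.bam`` suffix selects BGZF-compressed output."""
    for name in reads.references:
        if name not in genome:
            raise ValueError(f"read reference {name!r} not in genome")
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": length} for name, length in genome.items()],
    }
    name_to_tid = {sq["SN"]: tid for tid, sq in enumerate(header["SQ"])}
    tid_of = np.array([name_to_tid[name] for name in reads.references], dtype=np.int64) \
        if reads.references else np.empty(0, dtype=np.int64)

    mode = "wb" if str(path).endswith(".bam") else "w"
    with pysam.AlignmentFile(str(path), mode, header=header) as out:
        for i, row in enumerate(reads.data):
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = f"r{i}"
            rec.flag = int(row["flag"])
            rec.mapping_quality = int(row["mapq"])
            if row["flag"] & FLAG_UNMAPPED:
                rec.reference_id = -1
                rec.reference_start = -1
            else:
                rec.reference_id = int(tid_of[row["ref_id"]])
                rec.reference_start = int(row["pos"])
                if row["aligned_len"] > 0:
                    rec.cigarstring = f"{int(row['aligned_len'])}M"
                rec.set_tag("NM", int(row["nm"]))
            out.write(rec)
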