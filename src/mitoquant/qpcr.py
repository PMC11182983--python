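"""qPCR-based relative mtDNA quantification (2^dCt of two gene pairs).

The assay pairs two mitochondrial genes with two single-copy nuclear genes
(ND1/BECN1 and ND6/NEB). For each pair, dCt = mean Ct(nuclear) - mean
Ct(mitochondrial); the mtDNA ratio is the mean of 2^dCt over the two pairs.
The sign convention makes abundant mtDNA (earlier mitochondrial
amplification, lower Ct) give a ratio above 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["QpcrPlate", "QpcrResult", "compute_qpcr_ratio", "read_plates_csv",
           "results_to_frame"]

GENES = ("ND1", "BECN1", "ND6", "NEB")
#: (mitochondrial, nuclear) gene pairings.
PAIRS = (("ND1", "BECN1"), ("ND6", "NEB"))

DEFAULT_CT_CEILING = 40.0


@dataclass
class QpcrPlate:
    """Replicate Ct values for one sample across the four assay genes.

    Replicate counts may differ between genes (failed wells are simply
    absent); Ct values must be positive and at most the cycle ceiling.
    """

    sample_id: str
    ct_nd1: list[float] = field(default_factory=list)
    ct_becn1: list[float] = field(default_factory=list)
    ct_nd6: list[float] = field(default_factory=list)
    ct_neb: list[float] = field(default_factory=list)
    ct_ceiling: float = DEFAULT_CT_CEILING

    def __post_init__(self) -> None:
        for gene in GENES:
            for ct in self.cts(gene):
                if not (0 < ct <= self.ct_ceiling):
                    raise ValueError(
                        f"{self.sample_id}/{gene}: Ct {ct} outside (0, {self.ct_ceiling}]"
                    )

    def cts(self, gene: str) -> list[float]:
        return getattr(self, f"ct_{gene.lower()}")


@dataclass
class QpcrResult:
    sample_id: str
    ratio: float
    delta_ct_pair1: float   # BECN1 - ND1
    delta_ct_pair2: float   # NEB - ND6
    undefined: bool = False
    n_valid: dict[str, int] = field(default_factory=dict)


def compute_qpcr_ratio(
    plate: QpcrPlate,
    ceiling_is_nondetect: bool = True,
) -> QpcrResult:
    """Mean 2^dCt over the two mitochondrial/nuclear pairs.

    Ct values sitting exactly at the cycle ceiling are treated as
    non-detections and excluded when ``ceiling_is_nondetect`` (the default);
    a gene left with no valid replicate makes the result undefined (NaN,
    flagged) rather than raising.
    """
    means: dict[str, float] = {}
    n_valid: dict[str, int] = {}
    for gene in GENES:
        cts = np.asarray(plate.cts(gene), dtype=float)
        if ceiling_is_nondetect and cts.size:
            cts = cts[cts < plate.ct_ceiling]
        n_valid[gene] = int(cts.size)
        means[gene] = float(cts.mean()) if cts.size else math.nan

    if any(n_valid[g] == 0 for g in GENES):
        return QpcrResult(plate.sample_id, math.nan, math.nan, math.nan,
                          undefined=True, n_valid=n_valid)

    d1 = means["BECN1"] - means["ND1"]
    d2 = means["NEB"] - means["ND6"]
    ratio = (2.0 ** d1 + 2.0 ** d2) / 2.0
    return QpcrResult(plate.sample_id, ratio, d1, d2, n_valid=n_valid)


def read_plates_csv(path, ct_ceiling: float = DEFAULT_CT_CEILING) -> list[QpcrPlate]:
    """Read long-format plate data: columns sample_id, gene, replicate, ct."""
    df = pd.read_csv(path)
    required = {"sample_id", "gene", "ct"}
    if not required.issubset(df.columns):
        raise ValueError(f"plate CSV needs columns {sorted(required)}")
    plates = []
    for sample_id, grp in df.groupby("sample_id", sort=False):
        kwargs = {f"ct_{g.lower()}": [] for g in GENES}
        for _, row in grp.iterrows():
            gene = str(row["gene"]).upper()
            if gene not in GENES:
                raise ValueError(f"unknown gene {row['gene']!r} for {sample_id}")
            kwargs[f"ct_{gene.lower()}"].append(float(row["ct"]))
        plates.append(QpcrPlate(sample_id=str(sample_id), ct_ceiling=ct_ceiling, **kwargs))
    return plates


def results_to_frame(results: Sequence[QpcrResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "delta_ct_pair1": [r.delta_ct_pair1 for r in results],
            "delta_ct_pair2": [r.delta_ct_pair2 for r in results],
            "ratio": [r.ratio for r in results],
            "undefined": [r.undefined for r in results],
        }
    )
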