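"""Within-blastocyst concordance and biopsy-vs-media comparison.

A blastocyst is biopsied at three sites — trophectoderm near the inner cell
mass (close TE), trophectoderm opposite it (distant TE), and the ICM itself
— and the agreement of mtDNA ratios across sites is summarised by pairwise
Spearman rank correlations. Biopsies whose whole-genome amplification
failed carry no ratio and are handled by pairwise deletion, never
imputation. Spent-culture-media vs biopsy comparisons use the Mann-Whitney
U test.

The rank statistics are implemented here (mid-ranks for ties, exact small-
sample p-values by permutation enumeration / the U null-distribution
recurrence, asymptotic approximations otherwise) so their exact behaviour
is under the package's control and testable against independent oracles.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

__all__ = [
    "BiopsyRecord",
    "ConcordanceResult",
    "SITES",
    "SITE_PAIRS",
    "spearman_rho",
    "mann_whitney_u",
    "pairwise_site_concordance",
    "site_summary",
    "read_biopsies_csv",
    "biopsies_to_frame",
]

SITES = ("close_TE", "distant_TE", "ICM", "spent_media")

#: The three within-blastocyst comparisons, in reporting order.
SITE_PAIRS = (
    ("close_TE", "ICM"),
    ("distant_TE", "ICM"),
    ("close_TE", "distant_TE"),
)


@dataclass
class BiopsyRecord:
    """One biopsy (or media sample) of one embryo."""

    embryo_id: str
    site: str
    mtdna_ratio: float | None = None
    amplification_failed: bool = False
    maternal_age: float | None = None

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValueError(f"unknown biopsy site {self.site!r}")
        if self.amplification_failed:
            self.mtdna_ratio = None
        elif self.mtdna_ratio is None:
            raise ValueError("non-failed record requires a ratio")
        elif self.mtdna_ratio < 0:
            raise ValueError("mtDNA ratio must be non-negative")

    @property
    def informative(self) -> bool:
        return not self.amplification_failed and self.mtdna_ratio is not None


# ---------------------------------------------------------------------------
# Spearman rank correlation
# ---------------------------------------------------------------------------

@dataclass
class SpearmanResult:
    rho: float
    p_value: float
    n: int
    method: str               # "exact" or "t-approx"
    degenerate: bool = False  # constant input, rho undefined


@lru_cache(maxsize=16)
def _perm_d2_distribution(n: int) -> np.ndarray:
    """Sum of squared rank differences for every permutation of 1..n."""
    identity = np.arange(1, n + 1)
    perms = np.array(list(itertools.permutations(range(1, n + 1))), dtype=np.int16)
    d = perms - identity
    return np.einsum("ij,ij->i", d, d).astype(np.int64)


def spearman_rho(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "auto",
    exact_max_n: int = 9,
) -> SpearmanResult:
    """Spearman's rho with a two-sided p-value.

    rho is the Pearson correlation of mid-ranks (ties share average ranks).
    For small tie-free samples (n <= ``exact_max_n``) the p-value is exact,
    from full enumeration of rank permutations; otherwise it uses the
    t-approximation with n - 2 degrees of freedom. ``method`` may force
    "exact" or "approx".
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values must be filtered by the caller")
    if method not in ("auto", "exact", "approx"):
        raise ValueError("method must be auto, exact or approx")

    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(math.nan, math.nan, n, "undefined", degenerate=True)

    rx = _st.rankdata(x)
    ry = _st.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))

    has_ties = len(np.unique(x)) < n or len(np.unique(y)) < n
    use_exact = method == "exact" or (method == "auto" and n <= exact_max_n and not has_ties)
    if use_exact and has_ties:
        raise ValueError("exact permutation p is undefined in the presence of ties")

    if use_exact:
        # no ties: rho is a bijection of sum d^2, enumerate it
        d2_obs = float(np.sum((rx - ry) ** 2))
        d2 = _perm_d2_distribution(n)
        denom = n * (n * n - 1)
        rho_perm = 1.0 - 6.0 * d2 / denom
        p = float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-12))
        return SpearmanResult(rho, p, n, "exact")

    if abs(rho) == 1.0:
        p = float(np.finfo(float).tiny)
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(min(1.0, 2.0 * _st.t.sf(abs(t), df=n - 2)))
        p = max(p, float(np.finfo(float).tiny))
    return SpearmanResult(rho, p, n, "t-approx")


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

@dataclass
class MannWhitneyResult:
    u: float           # U statistic of the first group
    p_value: float
    n_a: int
    n_b: int
    method: str        # "exact" or "normal-approx"
    degenerate: bool = False


@lru_cache(maxsize=64)
def _u_null_counts(n: int, m: int) -> tuple[int, ...]:
    """Number of (n, m)-group rank arrangements giving each U value.

    Classic recurrence c(n, m, u) = c(n-1, m, u-m) + c(n, m-1, u) with
    c(0, m, 0) = c(n, 0, 0) = 1; valid in the absence of ties.
    """
    umax = n * m
    # table[i][j] is the count vector over u for group sizes (i, j)
    prev_row = [np.array([1], dtype=object)] * (m + 1)   # i = 0
    for i in range(1, n + 1):
        row = [np.array([1], dtype=object)]              # j = 0
        for j in range(1, m + 1):
            size = i * j + 1
            a = np.zeros(size, dtype=object)
            shifted = prev_row[j]                         # c(i-1, j, u-j)
            a[j:j + len(shifted)] += shifted
            b = row[j - 1]                                # c(i, j-1, u)
            a[: len(b)] += b
            row.append(a)
        prev_row = row
    out = prev_row[m]
    assert len(out) == umax + 1
    return tuple(int(v) for v in out)


def _tie_corrected_sigma(n_a: int, n_b: int, all_values: np.ndarray) -> float:
    n = n_a + n_b
    _, tie_counts = np.unique(all_values, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    return math.sqrt(max(var, 0.0))


def mann_whitney_u(
    a: Sequence[float],
    b: Sequence[float],
    method: str = "auto",
    exact_max_n: int = 10,
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    U is computed from mid-rank sums, so ``u + u_other = n_a * n_b`` always
    holds. The p-value is exact (null-distribution recurrence) when the
    smaller group has at most ``exact_max_n`` observations and there are no
    ties; otherwise a normal approximation with tie and continuity
    corrections is used. ``method="exact"`` forces the recurrence at any
    sample size (tie-free data only).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("missing values must be filtered by the caller")
    if method not in ("auto", "exact", "approx"):
        raise ValueError("method must be auto, exact or approx")

    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = _st.rankdata(pooled)
    r_a = float(ranks[:n_a].sum())
    u_a = r_a - n_a * (n_a + 1) / 2.0

    has_ties = len(np.unique(pooled)) < n_a + n_b
    if has_ties and np.ptp(pooled) == 0:
        return MannWhitneyResult(u_a, 1.0, n_a, n_b, "degenerate", degenerate=True)

    use_exact = method == "exact" or (
        method == "auto" and min(n_a, n_b) <= exact_max_n and not has_ties
    )
    if use_exact and has_ties:
        raise ValueError("exact U p-value is undefined in the presence of ties")

    if use_exact:
        counts = np.array(_u_null_counts(n_a, n_b), dtype=float)
        total = counts.sum()
        u_int = int(round(u_a))
        p_le = counts[: u_int + 1].sum() / total
        p_ge = counts[u_int:].sum() / total
        p = float(min(1.0, 2.0 * min(p_le, p_ge)))
        return MannWhitneyResult(u_a, p, n_a, n_b, "exact")

    mean = n_a * n_b / 2.0
    sigma = _tie_corrected_sigma(n_a, n_b, pooled)
    if sigma == 0.0:
        return MannWhitneyResult(u_a, 1.0, n_a, n_b, "degenerate", degenerate=True)
    diff = u_a - mean
    cc = 0.5 if diff != 0 else 0.0
    z = (diff - math.copysign(cc, diff)) / sigma
    p = float(min(1.0, 2.0 * _st.norm.sf(abs(z))))
    return MannWhitneyResult(u_a, p, n_a, n_b, "normal-approx")


# ---------------------------------------------------------------------------
# Site concordance
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceResult:
    site_pair: tuple[str, str]
    n_pairs: int
    rho: float
    p_value: float
    available: bool = True


def pairwise_site_concordance(
    records: Sequence[BiopsyRecord],
    min_pairs: int = 3,
) -> list[ConcordanceResult]:
    """Spearman concordance for each within-blastocyst site pair.

    For each pair of sites, only embryos where both biopsies amplified
    contribute (pairwise-complete deletion); the number of such matched
    pairs is reported alongside rho. A pair with fewer than ``min_pairs``
    informative embryos is flagged unavailable.
    """
    by_embryo: dict[str, dict[str, BiopsyRecord]] = {}
    for rec in records:
        sites = by_embryo.setdefault(rec.embryo_id, {})
        if rec.site in sites:
            raise ValueError(f"duplicate record for ({rec.embryo_id}, {rec.site})")
        sites[rec.site] = rec

    results = []
    for site_a, site_b in SITE_PAIRS:
        xs, ys = [], []
        for sites in by_embryo.values():
            ra, rb = sites.get(site_a), sites.get(site_b)
            if ra is not None and rb is not None and ra.informative and rb.informative:
                xs.append(ra.mtdna_ratio)
                ys.append(rb.mtdna_ratio)
        if len(xs) < min_pairs:
            results.append(
                ConcordanceResult((site_a, site_b), len(xs), math.nan, math.nan,
                                  available=False)
            )
            continue
        sp = spearman_rho(xs, ys)
        results.append(
            ConcordanceResult((site_a, site_b), sp.n, sp.rho, sp.p_value,
                              available=not sp.degenerate)
        )
    return results


def site_summary(records: Sequence[BiopsyRecord]) -> pd.DataFrame:
    """Per-site accounting: biopsies taken, amplification failures, mean
    ratio and mean maternal age among informative samples."""
    rows = []
    for site in SITES:
        recs = [r for r in records if r.site == site]
        if not recs:
            continue
        ratios = [r.mtdna_ratio for r in recs if r.informative]
        ages = [r.maternal_age for r in recs if r.informative and r.maternal_age is not None]
        rows.append(
            {
                "site": site,
                "n_biopsies": len(recs),
                "amplification_failed": sum(r.amplification_failed for r in recs),
                "n_informative": len(ratios),
                "mean_ratio": float(np.mean(ratios)) if ratios else math.nan,
                "mean_age": float(np.mean(ages)) if ages else math.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def biopsies_to_frame(records: Sequence[BiopsyRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "embryo_id": [r.embryo_id for r in records],
            "site": [r.site for r in records],
            "mtdna_ratio": [r.mtdna_ratio for r in records],
            "amplification_failed": [r.amplification_failed for r in records],
            "maternal_age": [r.maternal_age for r in records],
        }
    )


def read_biopsies_csv(path) -> list[BiopsyRecord]:
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        failed = bool(row.get("amplification_failed", False))
        ratio = row.get("mtdna_ratio")
        age = row.get("maternal_age")
        records.append(
            BiopsyRecord(
                embryo_id=str(row["embryo_id"]),
                site=str(row["site"]),
                mtdna_ratio=None if failed or pd.isna(ratio) else float(ratio),
                amplification_failed=failed or pd.isna(ratio),
                maternal_age=None if age is None or pd.isna(age) else float(age),
            )
        )
    return records
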