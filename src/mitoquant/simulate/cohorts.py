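"""Synthetic clinical cohorts: time-lapse embryos and transfer cycles.

Two generators share one effect specification:

* ``simulate_timelapse_cohort`` draws morphokinetic timing vectors from a
  multivariate Gaussian with a configured correlation structure, enforces
  the developmental event order tPNf < t2 < ... < tEB by
  rejection-resampling, and generates the mtDNA ratio linearly in day of
  expanded-blastocyst formation, gender and tEB plus Gaussian noise.
* ``simulate_transfer_cohort`` draws cycle covariates from configurable
  marginals and the four early-pregnancy endpoints as a nested clinical
  progression (HCG -> sac -> FHB -> 14 weeks): each later endpoint is drawn
  only among successes at the previous one, with per-stage conditional
  odds ratios applied on the logit of the conditional success probability.
  With all odds ratios at 1, marginal prevalences equal ``baseline_rates``.

Default effect sizes are the study's reported point estimates (linear-model
CI midpoints; per-endpoint odds-ratio columns); noise scales, covariate
marginals and baseline rates are not derivable from published summaries and
are fixed once at realistic values (see the methods note).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ..regression import ENDPOINTS, TIMING_FEATURES, TimelapseRecord, TransferRecord

__all__ = ["CohortEffectSpec", "simulate_timelapse_cohort", "simulate_transfer_cohort"]

logger = logging.getLogger(__name__)

DEFAULT_TIMING_MEANS: dict[str, float] = {
    "tPNf": 23.0, "t2": 27.0, "t4": 38.0, "t6": 50.0, "t8": 56.0,
    "tM": 85.0, "tSB": 96.0, "tB": 104.0, "tEB": 111.0,
}
DEFAULT_TIMING_SDS: dict[str, float] = {
    "tPNf": 3.0, "t2": 3.0, "t4": 4.0, "t6": 4.5, "t8": 5.0,
    "tM": 6.0, "tSB": 6.0, "tB": 6.5, "tEB": 7.0,
}

#: Endpoint covariates the odds ratios act on (coded scale).
ENDPOINT_COVARIATES = (
    "oocyte_source", "maternal_age", "em_thickness", "day_of_formation",
    "expansion_state", "icm_grade", "te_grade", "gender", "mtdna_ratio",
)

# Per-stage conditional odds ratios, one column per endpoint (reported
# study estimates used as the generating truth).
DEFAULT_ENDPOINT_ORS: dict[str, dict[str, float]] = {
    "hcg_pos": {
        "oocyte_source": 1.37, "maternal_age": 0.97, "em_thickness": 1.06,
        "day_of_formation": 0.71, "expansion_state": 0.77, "icm_grade": 1.33,
        "te_grade": 1.41, "gender": 1.22, "mtdna_ratio": 1.00,
    },
    "sac_pos": {
        "oocyte_source": 1.26, "maternal_age": 0.97, "em_thickness": 1.10,
        "day_of_formation": 0.78, "expansion_state": 0.87, "icm_grade": 1.26,
        "te_grade": 1.36, "gender": 1.19, "mtdna_ratio": 1.00,
    },
    "fhb_pos": {
        "oocyte_source": 1.22, "maternal_age": 0.98, "em_thickness": 1.08,
        "day_of_formation": 0.71, "expansion_state": 0.88, "icm_grade": 1.18,
        "te_grade": 1.37, "gender": 1.13, "mtdna_ratio": 0.98,
    },
    "ongoing_14wk": {
        "oocyte_source": 1.29, "maternal_age": 0.97, "em_thickness": 1.09,
        "day_of_formation": 0.69, "expansion_state": 0.88, "icm_grade": 1.10,
        "te_grade": 1.46, "gender": 1.12, "mtdna_ratio": 0.98,
    },
}

DEFAULT_BASELINE_RATES = (0.66, 0.57, 0.53, 0.50)


def _default_corr(k: int, rho: float = 0.6) -> np.ndarray:
    idx = np.arange(k)
    return rho ** np.abs(idx[:, None] - idx[None, :])


@dataclass
class CohortEffectSpec:
    """Effect sizes, noise and sampling structure shared by both cohorts."""

    n: int = 307
    seed: int = 0
    # linear-model truth: ratio ~ day + gender(male=1) + tEB
    beta_day: float = 2.58
    beta_gender: float = 0.98
    beta_tEB: float = -0.125
    sigma_ratio: float = 2.0
    mean_ratio: float = 2.7
    timing_means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TIMING_MEANS))
    timing_sds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TIMING_SDS))
    timing_corr: np.ndarray = field(default_factory=lambda: _default_corr(len(TIMING_FEATURES)))
    # endpoint-model truth
    endpoint_ORs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ENDPOINT_ORS.items()}
    )
    baseline_rates: tuple[float, float, float, float] = DEFAULT_BASELINE_RATES

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("cohort size n must be positive")
        if self.sigma_ratio < 0:
            raise ValueError("sigma_ratio must be non-negative")
        k = len(TIMING_FEATURES)
        missing = [f for f in TIMING_FEATURES if f not in self.timing_means
                   or f not in self.timing_sds]
        if missing:
            raise ValueError(f"timing means/sds missing features: {missing}")
        means = [self.timing_means[f] for f in TIMING_FEATURES]
        if any(not a < b for a, b in zip(means, means[1:])):
            raise ValueError("timing means must increase in event order")
        if any(self.timing_sds[f] < 0 for f in TIMING_FEATURES):
            raise ValueError("timing sds must be non-negative")
        corr = np.asarray(self.timing_corr, dtype=float)
        if corr.shape != (k, k):
            raise ValueError(f"timing_corr must be {k}x{k}")
        if not np.allclose(corr, corr.T, atol=1e-10):
            raise ValueError("timing_corr must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
            raise ValueError("timing_corr must have unit diagonal")
        if np.linalg.eigvalsh(corr).min() < -1e-8:
            raise ValueError("timing_corr must be positive semi-definite")
        self.timing_corr = corr
        for endpoint, ors in self.endpoint_ORs.items():
            if endpoint not in ENDPOINTS:
                raise ValueError(f"unknown endpoint {endpoint!r}")
            unknown = set(ors) - set(ENDPOINT_COVARIATES)
            if unknown:
                raise ValueError(f"odds ratios on unknown covariates: {sorted(unknown)}")
            if any(v <= 0 for v in ors.values()):
                raise ValueError("odds ratios must be positive")
        if len(self.baseline_rates) != len(ENDPOINTS):
            raise ValueError("need one baseline rate per endpoint")
        if any(not (0.0 < r < 1.0) for r in self.baseline_rates):
            raise ValueError("baseline rates must lie in (0, 1)")
        if any(b > a for a, b in zip(self.baseline_rates, self.baseline_rates[1:])):
            raise ValueError("baseline rates must be non-increasing along the "
                             "clinical progression")


def _day_from_teb(teb: np.ndarray) -> np.ndarray:
    """Calendar day of expanded-blastocyst formation from tEB (hours)."""
    return (4 + np.searchsorted([96.0, 120.0, 144.0], teb, side="right")).clip(4, 7)


def _draw_ordered_timings(spec: CohortEffectSpec, rng: np.random.Generator) -> np.ndarray:
    means = np.array([spec.timing_means[f] for f in TIMING_FEATURES])
    sds = np.array([spec.timing_sds[f] for f in TIMING_FEATURES])
    cov = spec.timing_corr * np.outer(sds, sds)
    out = np.empty((spec.n, len(TIMING_FEATURES)))
    filled = 0
    resampled = 0
    for _ in range(1000):
        need = spec.n - filled
        if need == 0:
            break
        draw = rng.multivariate_normal(means, cov, size=need, method="cholesky")
        ok = (np.diff(draw, axis=1) > 0).all(axis=1)
        k = int(ok.sum())
        out[filled:filled + k] = draw[ok]
        filled += k
        resampled += need - k
    else:
        raise RuntimeError("event-order rejection sampling failed to converge; "
                           "check timing means/sds/correlation")
    if resampled:
        logger.info("timeline generator resampled %d draws to honour event order",
                    resampled)
    return out


def simulate_timelapse_cohort(spec: CohortEffectSpec) -> list[TimelapseRecord]:
    """Generate a time-lapse cohort with the configured effect structure.

    Every record satisfies the strict event-order invariant. The ratio
    model's intercept is centred so the in-sample expected ratio equals
    ``spec.mean_ratio``.
    """
    rng = np.random.default_rng(spec.seed)
    timings = _draw_ordered_timings(spec, rng)
    teb = timings[:, TIMING_FEATURES.index("tEB")]
    day = _day_from_teb(teb)
    male = rng.random(spec.n) < 0.5
    expansion = rng.choice([4, 5, 6], size=spec.n, p=[0.15, 0.70, 0.15])

    linpred = (spec.beta_day * day + spec.beta_gender * male.astype(float)
               + spec.beta_tEB * teb)
    intercept = spec.mean_ratio - float(linpred.mean())
    ratio = intercept + linpred + rng.normal(0.0, spec.sigma_ratio, size=spec.n)

    records = []
    for i in range(spec.n):
        kwargs = {f: float(timings[i, j]) for j, f in enumerate(TIMING_FEATURES)}
        records.append(
            TimelapseRecord(
                embryo_id=f"TL{i + 1:04d}",
                day_of_formation=int(day[i]),
                expansion_score=int(expansion[i]),
                gender="male" if male[i] else "female",
                mtdna_ratio=float(ratio[i]),
                **kwargs,
            )
        )
    return records


# covariate marginals for the transfer cohort (coded means used to centre
# the odds-ratio effects so marginal prevalences track baseline_rates)
_GRADES = np.array(["C", "B", "A"])
_GRADE_PROBS = np.array([0.08, 0.57, 0.35])


def simulate_transfer_cohort(spec: CohortEffectSpec) -> list[TransferRecord]:
    """Generate an euploid single-embryo-transfer cohort with nested
    endpoints drawn per the clinical progression."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    donor = rng.random(n) < 0.15
    age = np.clip(rng.normal(36.0, 4.5, size=n), 21.0, 47.0)
    em = np.clip(rng.normal(10.5, 1.8, size=n), 6.0, 16.0)
    day = rng.choice([4, 5, 6, 7], size=n, p=[0.02, 0.62, 0.33, 0.03])
    expansion = rng.choice([4, 5, 6], size=n, p=[0.15, 0.70, 0.15])
    icm = rng.choice(3, size=n, p=_GRADE_PROBS)       # 0=C,1=B,2=A
    te = rng.choice(3, size=n, p=_GRADE_PROBS)
    male = rng.random(n) < 0.5
    # mildly right-censored Gaussian: matches the assay's reported ratio
    # scale without the heavy upper tail a lognormal would impose
    mtdna = np.clip(rng.normal(2.7, 1.8, size=n), 0.05, None)

    coded = {
        "oocyte_source": donor.astype(float),
        "maternal_age": age,
        "em_thickness": em,
        "day_of_formation": day.astype(float),
        "expansion_state": expansion.astype(float),
        "icm_grade": (icm + 1).astype(float),         # C/B/A -> 1/2/3
        "te_grade": (te + 1).astype(float),
        "gender": male.astype(float),
        "mtdna_ratio": mtdna,
    }
    centred = {k: v - v.mean() for k, v in coded.items()}

    success = np.ones(n, dtype=bool)
    outcomes: dict[str, np.ndarray] = {}
    prev_rate = 1.0
    for endpoint, rate in zip(ENDPOINTS, spec.baseline_rates):
        p_cond = rate / prev_rate
        logit = math.log(p_cond / (1.0 - p_cond)) * np.ones(n)
        for cov_name, odds in spec.endpoint_ORs.get(endpoint, {}).items():
            logit += math.log(odds) * centred[cov_name]
        p = 1.0 / (1.0 + np.exp(-logit))
        draw = rng.random(n) < p
        success = success & draw
        outcomes[endpoint] = success.copy()
        prev_rate = rate

    records = []
    for i in range(n):
        records.append(
            TransferRecord(
                cycle_id=f"C{i + 1:05d}",
                oocyte_source="donor" if donor[i] else "self",
                maternal_age=float(age[i]),
                em_thickness=float(em[i]),
                day_of_formation=int(day[i]),
                expansion_state=int(expansion[i]),
                icm_grade=str(_GRADES[icm[i]]),
                te_grade=str(_GRADES[te[i]]),
                gender="male" if male[i] else "female",
                mtdna_ratio=float(mtdna[i]),
                hcg_pos=bool(outcomes["hcg_pos"][i]),
                sac_pos=bool(outcomes["sac_pos"][i]),
                fhb_pos=bool(outcomes["fhb_pos"][i]),
                ongoing_14wk=bool(outcomes["ongoing_14wk"][i]),
            )
        )
    return records
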