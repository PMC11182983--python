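"""Inferential models: mtDNA ratio vs morphokinetics, and pregnancy endpoints.

Two stages mirror the clinical analysis chain:

* a multivariate **linear** model of the mtDNA ratio on morphokinetic
  timings (t4 ... tEB, the biopsy time point) and static embryo profile
  (day of expanded-blastocyst formation, expansion score, gender), with
  optional pairwise interaction terms;
* four multivariate **logistic** models of the early-pregnancy endpoints
  (serum HCG, gestational sac, fetal heartbeat, ongoing pregnancy at 14
  weeks) on maternal and embryonic covariates plus the mtDNA ratio,
  reported as odds ratios with Wald 95% CIs.

OLS and IRLS are implemented directly (closed-form / Newton with
step-halving) so that convergence behaviour, Wald inference and failure
modes (collinearity, separation) are explicit and testable.

Coding conventions (defaults, all overridable): gender male=1/female=0;
oocyte source donor=1/self=0; Gardner grades A/B/C -> 3/2/1; day of
formation and expansion entered as integers. Reported effects are per unit
of these codings. Missing data are handled complete-case per model with the
used sample size reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st
from scipy.special import expit

from .concordance import spearman_rho

__all__ = [
    "TimelapseRecord",
    "TransferRecord",
    "TermResult",
    "ModelResult",
    "CollinearityError",
    "build_design",
    "fit_linear",
    "fit_logistic",
    "fit_ratio_model",
    "run_endpoint_models",
    "feature_screen",
    "TIMING_FEATURES",
    "ENDPOINTS",
    "DEFAULT_CODINGS",
    "DEFAULT_LINEAR_FEATURES",
    "DEFAULT_LINEAR_INTERACTIONS",
    "DEFAULT_ENDPOINT_COVARIATES",
    "DEFAULT_ENDPOINT_INTERACTIONS",
]

#: Morphokinetic events in developmental order (hours post insemination).
TIMING_FEATURES = ("tPNf", "t2", "t4", "t6", "t8", "tM", "tSB", "tB", "tEB")

#: Early-pregnancy endpoints in clinical progression order.
ENDPOINTS = ("hcg_pos", "sac_pos", "fhb_pos", "ongoing_14wk")

GENDER_CODES = {"male": 1, "female": 0}
OOCYTE_CODES = {"donor": 1, "self": 0}
GRADE_CODES = {"A": 3, "B": 2, "C": 1}

DEFAULT_CODINGS: dict[str, dict[str, int]] = {
    "gender": GENDER_CODES,
    "oocyte_source": OOCYTE_CODES,
    "icm_grade": GRADE_CODES,
    "te_grade": GRADE_CODES,
}

DEFAULT_LINEAR_FEATURES = (
    "day_of_formation", "expansion_score", "gender",
    "t4", "t6", "tM", "tSB", "tB", "tEB",
)
DEFAULT_LINEAR_INTERACTIONS = (
    ("day_of_formation", "gender"),
    ("day_of_formation", "tEB"),
    ("gender", "tEB"),
)

DEFAULT_ENDPOINT_COVARIATES = (
    "oocyte_source", "maternal_age", "em_thickness", "day_of_formation",
    "expansion_state", "icm_grade", "te_grade", "gender", "mtdna_ratio",
)
#: Endpoint-specific interaction terms assessed in the augmented fits.
DEFAULT_ENDPOINT_INTERACTIONS: dict[str, tuple[tuple[str, str], ...]] = {
    "hcg_pos": (("te_grade", "gender"),),
    "sac_pos": (("maternal_age", "te_grade"),),
}

_Z975 = float(_st.norm.ppf(0.975))


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclass
class TimelapseRecord:
    """One embryo's morphokinetic timing vector, static profile and ratio."""

    embryo_id: str
    tPNf: float | None
    t2: float | None
    t4: float | None
    t6: float | None
    t8: float | None
    tM: float | None
    tSB: float | None
    tB: float | None
    tEB: float | None
    day_of_formation: int
    expansion_score: int
    gender: str
    mtdna_ratio: float

    def __post_init__(self) -> None:
        if self.gender not in GENDER_CODES:
            raise ValueError(f"gender must be one of {sorted(GENDER_CODES)}")
        if self.day_of_formation not in (4, 5, 6, 7):
            raise ValueError("day_of_formation must be in 4..7")
        if self.expansion_score not in (4, 5, 6):
            raise ValueError("expansion_score must be in 4..6")
        timings = [getattr(self, f) for f in TIMING_FEATURES]
        if all(t is not None for t in timings):
            for a, b in zip(timings, timings[1:]):
                if not a < b:
                    raise ValueError(
                        f"{self.embryo_id}: timings must strictly increase in event order"
                    )

    @property
    def has_missing_timings(self) -> bool:
        return any(getattr(self, f) is None for f in TIMING_FEATURES)


@dataclass
class TransferRecord:
    """One euploid single-embryo-transfer cycle with its four endpoints."""

    cycle_id: str
    oocyte_source: str
    maternal_age: float
    em_thickness: float
    day_of_formation: int
    expansion_state: int
    icm_grade: str
    te_grade: str
    gender: str
    mtdna_ratio: float
    hcg_pos: bool
    sac_pos: bool
    fhb_pos: bool
    ongoing_14wk: bool

    def __post_init__(self) -> None:
        if self.oocyte_source not in OOCYTE_CODES:
            raise ValueError(f"oocyte_source must be one of {sorted(OOCYTE_CODES)}")
        if self.gender not in GENDER_CODES:
            raise ValueError(f"gender must be one of {sorted(GENDER_CODES)}")
        for g in (self.icm_grade, self.te_grade):
            if g not in GRADE_CODES:
                raise ValueError(f"grade must be one of {sorted(GRADE_CODES)}")
        # clinical progression: each success implies all earlier ones
        chain = [self.hcg_pos, self.sac_pos, self.fhb_pos, self.ongoing_14wk]
        for earlier, later in zip(chain, chain[1:]):
            if later and not earlier:
                raise ValueError(
                    f"{self.cycle_id}: endpoint chain violates clinical progression"
                )


def timelapse_to_frame(records: Sequence[TimelapseRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"embryo_id": r.embryo_id}
        for f in TIMING_FEATURES:
            row[f] = getattr(r, f)
        row.update(
            day_of_formation=r.day_of_formation,
            expansion_score=r.expansion_score,
            gender=r.gender,
            mtdna_ratio=r.mtdna_ratio,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def transfers_to_frame(records: Sequence[TransferRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def read_timelapse_csv(path) -> list[TimelapseRecord]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        kwargs = {f: (None if pd.isna(row[f]) else float(row[f])) for f in TIMING_FEATURES}
        out.append(
            TimelapseRecord(
                embryo_id=str(row["embryo_id"]),
                day_of_formation=int(row["day_of_formation"]),
                expansion_score=int(row["expansion_score"]),
                gender=str(row["gender"]),
                mtdna_ratio=float(row["mtdna_ratio"]),
                **kwargs,
            )
        )
    return out


def read_transfers_csv(path) -> list[TransferRecord]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        out.append(
            TransferRecord(
                cycle_id=str(row["cycle_id"]),
                oocyte_source=str(row["oocyte_source"]),
                maternal_age=float(row["maternal_age"]),
                em_thickness=float(row["em_thickness"]),
                day_of_formation=int(row["day_of_formation"]),
                expansion_state=int(row["expansion_state"]),
                icm_grade=str(row["icm_grade"]),
                te_grade=str(row["te_grade"]),
                gender=str(row["gender"]),
                mtdna_ratio=float(row["mtdna_ratio"]),
                hcg_pos=bool(row["hcg_pos"]),
                sac_pos=bool(row["sac_pos"]),
                fhb_pos=bool(row["fhb_pos"]),
                ongoing_14wk=bool(row["ongoing_14wk"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

class CollinearityError(ValueError):
    """Raised for a rank-deficient design; names the offending columns."""

    def __init__(self, columns: Sequence[str]):
        self.columns = list(columns)
        super().__init__(f"design matrix is rank deficient; collinear columns: {self.columns}")


@dataclass
class Design:
    X: np.ndarray
    columns: list[str]
    y: np.ndarray | None
    n_used: int
    n_dropped: int


def _code_column(series: pd.Series, name: str, codings: Mapping[str, Mapping]) -> pd.Series:
    if series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
        if name not in codings:
            raise ValueError(f"no coding declared for categorical feature {name!r}")
        mapping = codings[name]
        unknown = set(series.dropna()) - set(mapping)
        if unknown:
            raise ValueError(f"unknown levels {sorted(unknown)} in feature {name!r}")
        return series.map(mapping).astype(float)
    return series.astype(float)


def build_design(
    data: pd.DataFrame | Sequence,
    features: Sequence[str],
    interactions: Sequence[tuple[str, str]] = (),
    response: str | None = None,
    codings: Mapping[str, Mapping] = DEFAULT_CODINGS,
    check_rank: bool = True,
) -> Design:
    """Assemble an intercept + main-effect + interaction design matrix.

    Continuous features pass through; categoricals are coded by the declared
    mapping (gender male=1, donor oocyte=1, grades A/B/C -> 3/2/1 by
    default). Interaction columns are elementwise products of the coded
    main-effect columns. Rows with missing values in any used column are
    dropped and counted (complete-case).
    """
    if not isinstance(data, pd.DataFrame):
        first = data[0] if len(data) else None
        if isinstance(first, TimelapseRecord):
            data = timelapse_to_frame(data)
        elif isinstance(first, TransferRecord):
            data = transfers_to_frame(data)
        else:
            data = pd.DataFrame(data)

    for pair in interactions:
        if len(pair) != 2:
            raise ValueError("interactions must be pairs of feature names")
    needed = list(dict.fromkeys(
        list(features) + [f for pair in interactions for f in pair]
    ))
    missing_cols = [f for f in needed + ([response] if response else []) if f not in data.columns]
    if missing_cols:
        raise ValueError(f"features not present in data: {missing_cols}")

    coded = pd.DataFrame(index=data.index)
    for name in needed:
        coded[name] = _code_column(data[name], name, codings)
    if response is not None:
        resp = data[response]
        resp = resp.astype(float) if resp.dtype != object else _code_column(resp, response, codings)
        coded["__response__"] = resp

    complete = coded.dropna()
    n_dropped = len(coded) - len(complete)

    columns = ["intercept"] + list(features)
    blocks = [np.ones(len(complete))] + [complete[f].to_numpy() for f in features]
    for a, b in interactions:
        columns.append(f"{a}:{b}")
        blocks.append(complete[a].to_numpy() * complete[b].to_numpy())
    X = np.column_stack(blocks) if blocks else np.empty((len(complete), 0))

    if check_rank and X.shape[0] > 0 and X.shape[1] > 0:
        _, rmat = np.linalg.qr(X, mode="reduced")
        diag = np.abs(np.diag(rmat))
        tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
        if (diag <= tol).any():
            # identify dependent columns via pivoted QR for a useful message
            from scipy.linalg import qr as _sqr

            _, rr, piv = _sqr(X, mode="economic", pivoting=True)
            dd = np.abs(np.diag(rr))
            bad = [columns[piv[i]] for i in range(len(dd)) if dd[i] <= tol]
            raise CollinearityError(bad or columns)

    y = complete["__response__"].to_numpy() if response is not None else None
    return Design(X=X, columns=columns, y=y, n_used=X.shape[0], n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# Model results
# ---------------------------------------------------------------------------

@dataclass
class TermResult:
    name: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    odds_ratio: float | None = None
    or_ci_low: float | None = None
    or_ci_high: float | None = None


@dataclass
class ModelResult:
    kind: str                      # "linear" or "logistic"
    terms: list[TermResult]
    n_used: int
    converged: bool = True
    degenerate: bool = False
    n_iter: int | None = None
    deviance_path: list[float] = field(default_factory=list)

    def term(self, name: str) -> TermResult:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.terms:
            row = {
                "term": t.name, "estimate": t.estimate, "se": t.se,
                "ci_low": t.ci_low, "ci_high": t.ci_high, "p_value": t.p_value,
            }
            if self.kind == "logistic":
                row.update(odds_ratio=t.odds_ratio, or_ci_low=t.or_ci_low,
                           or_ci_high=t.or_ci_high)
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Linear model (OLS)
# ---------------------------------------------------------------------------

def fit_linear(design: Design) -> ModelResult:
    """Ordinary least squares with t-based 95% CIs and two-sided p-values.

    Standard errors come from the unbiased residual variance (df = n - p).
    A singular cross-product matrix raises; an exactly-fitting response
    yields zero SEs and a degenerate flag.
    """
    X, y = design.X, design.y
    if y is None:
        raise ValueError("design has no response")
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than parameters ({p})")

    xtx = X.T @ X
    try:
        beta = np.linalg.solve(xtx, X.T @ y)
    except np.linalg.LinAlgError:
        raise CollinearityError(design.columns) from None

    resid = y - X @ beta
    rss = float(resid @ resid)
    df = n - p
    sigma2 = rss / df
    degenerate = math.isclose(rss, 0.0, abs_tol=1e-12 * max(1.0, float(y @ y)))

    cov = sigma2 * np.linalg.inv(xtx)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    if degenerate:
        se = np.zeros_like(se)
    tq = float(_st.t.ppf(0.975, df))

    terms = []
    for j, name in enumerate(design.columns):
        if degenerate or se[j] == 0.0:
            tval, pval = math.inf, math.nan
        else:
            tval = beta[j] / se[j]
            pval = float(min(1.0, 2.0 * _st.t.sf(abs(tval), df)))
            pval = max(pval, float(np.finfo(float).tiny))
        terms.append(
            TermResult(
                name=name, estimate=float(beta[j]), se=float(se[j]),
                ci_low=float(beta[j] - tq * se[j]), ci_high=float(beta[j] + tq * se[j]),
                p_value=pval,
            )
        )
    return ModelResult(kind="linear", terms=terms, n_used=n, degenerate=degenerate)


def fit_ratio_model(
    records: Sequence[TimelapseRecord] | pd.DataFrame,
    features: Sequence[str] = DEFAULT_LINEAR_FEATURES,
    interactions: Sequence[tuple[str, str]] = (),
    codings: Mapping[str, Mapping] = DEFAULT_CODINGS,
) -> ModelResult:
    """Linear model of the mtDNA ratio on morphokinetic + static features."""
    design = build_design(records, features, interactions,
                          response="mtdna_ratio", codings=codings)
    return fit_linear(design)


# ---------------------------------------------------------------------------
# Logistic model (IRLS)
# ---------------------------------------------------------------------------

_MU_EPS = 1e-10
_SEPARATION_BOUND = 30.0  # |log-odds| beyond this signals (quasi-)separation


def _deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, _MU_EPS, 1 - _MU_EPS)
    return float(-2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def fit_logistic(
    design: Design,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> ModelResult:
    """Maximum-likelihood logistic regression via IRLS (Newton-Raphson with
    step-halving, so the deviance never increases between iterations).

    Convergence: max absolute coefficient change below ``tol`` within
    ``max_iter`` iterations. Wald SEs come from the inverse observed
    information; odds ratios and their 95% CIs are exponentiated Wald.
    Complete or quasi-complete separation (coefficients running away) is
    flagged as non-converged; its estimates must not be trusted.
    """
    X, y = design.X, design.y
    if y is None:
        raise ValueError("design has no response")
    y = np.asarray(y, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("logistic response must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")

    n, p = X.shape
    beta = np.zeros(p)
    mu = expit(X @ beta)
    dev = _deviance(y, mu)
    path = [dev]
    converged = False
    separated = False
    it = 0

    for it in range(1, max_iter + 1):
        w = np.clip(mu * (1 - mu), _MU_EPS, None)
        xtwx = X.T @ (w[:, None] * X)
        score = X.T @ (y - mu)
        try:
            delta = np.linalg.solve(xtwx, score)
        except np.linalg.LinAlgError:
            separated = True
            break

        # step-halving keeps the deviance monotone non-increasing
        step = 1.0
        for _ in range(25):
            cand = beta + step * delta
            mu_cand = expit(X @ cand)
            dev_cand = _deviance(y, mu_cand)
            if dev_cand <= dev + 1e-12:
                break
            step /= 2.0
        beta = beta + step * delta
        mu = expit(X @ beta)
        dev = _deviance(y, mu)
        path.append(dev)

        if np.max(np.abs(beta[1:] if p > 1 else beta)) > _SEPARATION_BOUND and \
           np.max(np.abs(step * delta)) > tol:
            separated = True
            break
        if np.max(np.abs(step * delta)) < tol:
            converged = True
            break

    w = np.clip(mu * (1 - mu), _MU_EPS, None)
    xtwx = X.T @ (w[:, None] * X)
    try:
        cov = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))

    terms = []
    for j, name in enumerate(design.columns):
        b, s = float(beta[j]), float(se[j])
        if separated or s == 0.0 or not math.isfinite(s):
            z, pval = math.nan, math.nan
        else:
            z = b / s
            pval = float(min(1.0, 2.0 * _st.norm.sf(abs(z))))
            pval = max(pval, float(np.finfo(float).tiny))
        lo, hi = b - _Z975 * s, b + _Z975 * s
        terms.append(
            TermResult(
                name=name, estimate=b, se=s, ci_low=lo, ci_high=hi, p_value=pval,
                odds_ratio=math.exp(b) if abs(b) < 700 else math.inf,
                or_ci_low=math.exp(lo) if abs(lo) < 700 else (0.0 if lo < 0 else math.inf),
                or_ci_high=math.exp(hi) if abs(hi) < 700 else (0.0 if hi < 0 else math.inf),
            )
        )
    return ModelResult(
        kind="logistic", terms=terms, n_used=n,
        converged=converged and not separated, n_iter=it, deviance_path=path,
    )


# ---------------------------------------------------------------------------
# Endpoint models and feature screening
# ---------------------------------------------------------------------------

@dataclass
class EndpointModels:
    """One logistic fit per endpoint; a failed endpoint does not abort the
    others (its error message is recorded instead)."""

    results: dict[str, ModelResult]
    errors: dict[str, str]
    interaction_results: dict[str, ModelResult] = field(default_factory=dict)


def run_endpoint_models(
    cohort: Sequence[TransferRecord] | pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_ENDPOINT_COVARIATES,
    interactions: Mapping[str, Sequence[tuple[str, str]]] | None = None,
    codings: Mapping[str, Mapping] = DEFAULT_CODINGS,
) -> EndpointModels:
    """Fit the same covariate set against each of the four endpoints.

    The primary fit per endpoint is main-effects only. Endpoint-specific
    interaction pairs (by default TE grade x gender for HCG and maternal age
    x TE grade for gestational sac) are assessed in a secondary, augmented
    fit stored separately, so interaction collinearity cannot disturb the
    primary effect estimates.
    """
    if interactions is None:
        interactions = DEFAULT_ENDPOINT_INTERACTIONS
    if not isinstance(cohort, pd.DataFrame):
        cohort = transfers_to_frame(cohort)

    results: dict[str, ModelResult] = {}
    extra: dict[str, ModelResult] = {}
    errors: dict[str, str] = {}
    for endpoint in ENDPOINTS:
        try:
            design = build_design(cohort, covariates, response=endpoint, codings=codings)
            design.y = design.y.astype(float)
            results[endpoint] = fit_logistic(design)
            pairs = tuple(interactions.get(endpoint, ()))
            if pairs:
                aug = build_design(cohort, covariates, interactions=pairs,
                                   response=endpoint, codings=codings)
                aug.y = aug.y.astype(float)
                extra[endpoint] = fit_logistic(aug)
        except Exception as exc:  # noqa: BLE001 - per-endpoint isolation
            errors[endpoint] = f"{type(exc).__name__}: {exc}"
    return EndpointModels(results=results, errors=errors, interaction_results=extra)


@dataclass
class ScreenResult:
    matrix: pd.DataFrame          # all-pairs Spearman over timings + ratio
    selected: list[str]
    n_records: int


def feature_screen(
    records: Sequence[TimelapseRecord] | pd.DataFrame,
    threshold: float = 0.1,
    always_keep: Sequence[str] = ("tEB",),
    subset: Mapping[str, object] | None = None,
) -> ScreenResult:
    """All-pairs Spearman matrix over timing features and the mtDNA ratio.

    A timing feature passes the screen when |rho| with the ratio reaches
    ``threshold`` (weak correlations in the 0.1-0.2 range are the expected
    scale) or when listed in ``always_keep`` as timeline-relevant (tEB, the
    biopsy time point, by default). ``subset`` applies equality filters
    (e.g. day-5, expansion-5, male-only) before screening.
    """
    if not isinstance(records, pd.DataFrame):
        records = timelapse_to_frame(records)
    df = records.copy()
    if subset:
        for col, val in subset.items():
            df = df[df[col] == val]

    cols = list(TIMING_FEATURES) + ["mtdna_ratio"]
    df = df[cols].dropna()
    if len(df) < 3:
        raise ValueError("fewer than 3 complete records after filtering")

    k = len(cols)
    mat = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            r = spearman_rho(df[cols[i]], df[cols[j]], method="approx")
            mat[i, j] = mat[j, i] = r.rho
    matrix = pd.DataFrame(mat, index=cols, columns=cols)

    selected = [
        f for f in TIMING_FEATURES
        if abs(matrix.loc[f, "mtdna_ratio"]) >= threshold or f in set(always_keep)
    ]
    return ScreenResult(matrix=matrix, selected=selected, n_records=len(df))
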