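"""Synthetic multi-biopsy sets: three sites per blastocyst.

Each embryo carries a latent log-ratio drawn with between-embryo spread;
each biopsy site observes it with independent within-embryo noise, and ICM
biopsies get an additive log-scale shift (the ICM runs systematically
higher than the trophectoderm). Ratios are exponentiated, so they stay
positive and — because exp is strictly monotone — the rank structure, and
hence any Spearman analysis, is exactly that of the Gaussian latents. For
those latents the expected pairwise rank correlation follows the classic
attenuation sigma_b^2 / (sigma_b^2 + sigma_w^2).

The within/between variance components are not observable in published
summaries; the defaults are chosen for clear test signal and documented in
the methods note.
"""

from __future__ import annotations

import math

import numpy as np

from ..concordance import BiopsyRecord

__all__ = ["simulate_multibiopsy_set"]

EMBRYO_SITES = ("close_TE", "distant_TE", "ICM")


def simulate_multibiopsy_set(
    n_embryos: int = 29,
    within_embryo_sd: float = 0.15,
    between_embryo_sd: float = 0.50,
    icm_shift: float = 0.26,
    amp_fail_rate: float = 0.0,
    seed: int = 0,
    icm_extra_sd: float = 0.35,
    mean_log_ratio: float = math.log(0.78),
    age_mean: float = 34.5,
    age_sd: float = 4.0,
) -> list[BiopsyRecord]:
    """Three biopsy records (close TE, distant TE, ICM) per embryo.

    ``within_embryo_sd``/``between_embryo_sd``/``icm_shift`` act on the log
    scale. ``icm_extra_sd`` is additional ICM-only dispersion (the
    epiblast/hypoblast lineage tracks the embryo latent less tightly than
    the trophectoderm, which is what makes TE-TE concordance exceed TE-ICM
    concordance). Each record is independently marked amplification-failed
    with probability ``amp_fail_rate``. Same seed, same records.
    """
    if n_embryos <= 0:
        raise ValueError("n_embryos must be positive")
    if within_embryo_sd < 0 or between_embryo_sd < 0 or icm_extra_sd < 0:
        raise ValueError("standard deviations must be non-negative")
    if not (0.0 <= amp_fail_rate <= 1.0):
        raise ValueError("amp_fail_rate must be in [0, 1]")

    rng = np.random.default_rng(seed)
    records: list[BiopsyRecord] = []
    for i in range(n_embryos):
        latent = mean_log_ratio + rng.normal(0.0, between_embryo_sd)
        age = float(np.clip(rng.normal(age_mean, age_sd), 20.0, 46.0))
        for site in EMBRYO_SITES:
            log_ratio = latent + rng.normal(0.0, within_embryo_sd)
            if site == "ICM":
                log_ratio += icm_shift + rng.normal(0.0, icm_extra_sd)
            failed = bool(rng.random() < amp_fail_rate)
            records.append(
                BiopsyRecord(
                    embryo_id=f"E{i + 1:03d}",
                    site=site,
                    mtdna_ratio=None if failed else float(math.exp(log_ratio)),
                    amplification_failed=failed,
                    maternal_age=age,
                )
            )
    return records
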