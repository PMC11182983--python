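"""Synthetic qPCR plates for the two mitochondrial/nuclear gene pairs.

Nuclear-gene Cts sit at configurable baselines; mitochondrial-gene Cts are
offset by -log2(true_ratio) (an abundant template crosses threshold
earlier), plus independent Gaussian well noise. Recomputing 2^dCt from a
zero-noise plate recovers the true ratio exactly.
"""

from __future__ import annotations

import math

import numpy as np

from ..qpcr import QpcrPlate

__all__ = ["simulate_qpcr_plate"]


def simulate_qpcr_plate(
    true_ratio: float,
    ct_noise_sd: float = 0.25,
    n_replicates: int = 3,
    seed: int = 0,
    sample_id: str = "sim",
    nuclear_baselines: tuple[float, float] = (30.0, 31.0),
    ct_ceiling: float = 40.0,
) -> QpcrPlate:
    """Generate replicate Cts for ND1/BECN1 and ND6/NEB.

    ``nuclear_baselines`` are the mean Cts of BECN1 and NEB respectively;
    the paired mitochondrial genes sit log2(true_ratio) cycles earlier.
    Same seed, same plate.
    """
    if true_ratio <= 0:
        raise ValueError("true_ratio must be positive")
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be non-negative")
    if n_replicates <= 0:
        raise ValueError("n_replicates must be positive")

    rng = np.random.default_rng(seed)
    offset = math.log2(true_ratio)
    b1, b2 = nuclear_baselines

    def wells(mean: float) -> list[float]:
        cts = mean + rng.normal(0.0, ct_noise_sd, size=n_replicates)
        return [float(np.clip(ct, 1.0, ct_ceiling)) for ct in cts]

    return QpcrPlate(
        sample_id=sample_id,
        ct_nd1=wells(b1 - offset),
        ct_becn1=wells(b1),
        ct_nd6=wells(b2 - offset),
        ct_neb=wells(b2),
        ct_ceiling=ct_ceiling,
    )
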