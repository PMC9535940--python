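"""Crooks-consistent Gaussian work-sample generator.

Forward work is drawn from ``Normal(dG + sigma^2 / (2 kT), sigma^2)`` and
reverse work (work of the reverse process) from
``Normal(-dG + sigma^2 / (2 kT), sigma^2)``; this pair satisfies the Crooks
fluctuation relation exactly, so both nonequilibrium estimators must
recover ``dG`` in the large-sample limit.
"""

from __future__ import annotations

import numpy as np

from ..energetics import DEFAULT_KT, WorkSampleSet


def simulate_work_samples(
    dG_true: float,
    sigma: float,
    n: int,
    kT: float = DEFAULT_KT,
    seed: int = 0,
) -> WorkSampleSet:
    """Generate ``n`` forward and ``n`` reverse work values (kJ/mol)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    if kT <= 0:
        raise ValueError("kT must be > 0")
    rng = np.random.default_rng(seed)
    dissipated = sigma**2 / (2.0 * kT)
    forward = rng.normal(dG_true + dissipated, sigma, n)
    reverse = rng.normal(-dG_true + dissipated, sigma, n)
    return WorkSampleSet(forward=forward, reverse=reverse, kT=kT)
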