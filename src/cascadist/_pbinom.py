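"""Poisson-binomial pmf by convolution of Bernoulli masses."""

from __future__ import annotations

import numpy as np
from scipy import signal

# exact iterative convolution below this count; FFT above
_FFT_THRESHOLD = 64


def poisson_binomial_pmf(probs) -> np.ndarray:
    """pmf of the sum of independent Bernoulli(p_k) variables.

    Returns an array of length ``len(probs) + 1`` over counts 0..m.
    Exact pairwise convolution for small m; FFT-based convolution beyond,
    with round-off negatives clipped and the result renormalized.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.size == 0:
        return np.ones(1)
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("Bernoulli probabilities must lie in [0, 1]")
    if probs.size < _FFT_THRESHOLD:
        pmf = np.ones(1)
        for p in probs:
            pmf = np.convolve(pmf, [1.0 - p, p])
        return pmf
    masses = [np.array([1.0 - p, p]) for p in probs]
    while len(masses) > 1:
        nxt = []
        for k in range(0, len(masses) - 1, 2):
            nxt.append(signal.fftconvolve(masses[k], masses[k + 1]))
        if len(masses) % 2:
            nxt.append(masses[-1])
        masses = nxt
    pmf = np.clip(masses[0], 0.0, None)
    return pmf / pmf.sum()
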