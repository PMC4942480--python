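"""Canonical haemodynamic response function."""

from __future__ import annotations

import numpy as np
from scipy import stats


def double_gamma_hrf(
    t: np.ndarray,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Evaluate the canonical double-gamma HRF at times ``t`` (seconds).

    Difference of two gamma densities (unit scale): a positive lobe with
    shape ``peak_delay`` and an undershoot with shape ``undershoot_delay``
    scaled by ``ratio``.  With the defaults the response peaks ~5 s after
    onset and undershoots around 15 s, the usual convention in fMRI GLMs.
    Zero for t < 0.
    """
    t = np.asarray(t, dtype=float)
    h = stats.gamma.pdf(t, peak_delay) - ratio * stats.gamma.pdf(t, undershoot_delay)
    return np.where(t < 0, 0.0, h)
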