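"""Independent oracles used by the test suite.

These deliberately re-derive quantities by brute force (exhaustive grid
search, closed forms) rather than calling the package's own optimised code
paths, so a test comparing the two is a genuine cross-check.
"""

import numpy as np
from scipy.special import log_ndtr


def grid_search_mle(values, k, n, thresh_step=0.01, n_slopes=200):
    """Exhaustive grid-search maximum likelihood for the cumulative-normal
    psychometric model: threshold grid 0-12 (0.01 steps), slope grid
    0.05-10 log-spaced.  Returns (threshold, slope, nll)."""
    values = np.asarray(values, dtype=float)
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    T = np.arange(0.0, 12.0 + 1e-9, thresh_step)
    S = np.geomspace(0.05, 10.0, n_slopes)
    z = (values[None, None, :] - T[:, None, None]) / S[None, :, None]
    nll = -(k[None, None, :] * log_ndtr(z)
            + (n - k)[None, None, :] * log_ndtr(-z)).sum(axis=-1)
    i, j = np.unravel_index(np.argmin(nll), nll.shape)
    return float(T[i]), float(S[j]), float(nll[i, j])


def psychometric_nll(values, k, n, threshold, slope):
    """Negative log-likelihood of a (threshold, slope) pair."""
    values = np.asarray(values, dtype=float)
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    z = (values - threshold) / slope
    return float(-(k * log_ndtr(z) + (n - k) * log_ndtr(-z)).sum())
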