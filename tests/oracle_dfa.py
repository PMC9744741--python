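"""Independent reference DFA used to cross-check the package implementation.

Deliberately written as a plain, loop-based transcription of the textbook
procedure (cumulative-sum profile, per-window polynomial detrend via
numpy.polyfit, pooled RMS residual, log-log least-squares slope) sharing no
code with neurogaze.dynamics.
"""

import numpy as np


def reference_dfa(x, scale_lo, scale_hi, n_scales=15, overlap=0.5,
                  detrend_order=1):
    """Return (scales, F(s), exponent) for a 1-D series."""
    x = np.asarray(x, dtype=float)
    profile = np.cumsum(x - np.mean(x))
    scales = np.unique(np.round(
        np.exp(np.linspace(np.log(scale_lo), np.log(scale_hi), n_scales))
    ).astype(int))
    fluct = []
    for s in scales:
        step = max(int(round(s * (1 - overlap))), 1)
        sq_sum = 0.0
        count = 0
        start = 0
        while start + s <= len(profile):
            window = profile[start:start + s]
            t = np.arange(s)
            coeffs = np.polyfit(t, window, detrend_order)
            resid = window - np.polyval(coeffs, t)
            sq_sum += np.sum(resid ** 2)
            count += s
            start += step
        fluct.append(np.sqrt(sq_sum / count))
    fluct = np.asarray(fluct)
    slope, _ = np.polyfit(np.log(scales), np.log(fluct), 1)
    return scales, fluct, slope
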