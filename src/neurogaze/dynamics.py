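"""Long-range temporal correlations: amplitude envelopes, DFA, fixation series.

Detrended fluctuation analysis (DFA) quantifies how the root-mean-square
residual fluctuation F(s) of the linearly detrended cumulative-sum profile
grows with window length s; the log-log slope is the scaling exponent
(0.5 for an uncorrelated signal, approaching 1 for strong long memory).
Here DFA is applied to the alpha-band amplitude envelope of EEG (per
channel) and to the binary fixation/saccade sequence extracted from gaze
velocity — the two signal classes whose exponents the study design relates.

Default DFA parameters (1–20 s windows, 15 log-spaced scales, 50% overlap,
order-1 detrending) follow common practice for EEG envelope LRTC analysis
and are fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
from scipy import signal as sps

from .preprocess import Recording
from .spectral import BandDefinition
from .synth import GazeRecording

logger = logging.getLogger(__name__)

__all__ = [
    "EnvelopeSeries", "FixationSeries", "DFAResult", "DFAParams",
    "amplitude_envelope", "dfa", "dfa_exponent", "extract_fixations",
    "behavioural_dfa", "ALPHA_BAND",
]

ALPHA_BAND = BandDefinition("alpha", 7.5, 12.0)


@dataclass(frozen=True)
class EnvelopeSeries:
    """Per-channel amplitude envelope of a band-passed recording."""
    values: np.ndarray         # channels × samples, >= 0
    fs: float
    band: BandDefinition
    trim: int                  # samples trimmed per edge before DFA


@dataclass(frozen=True)
class FixationSeries:
    """Binary fixation (0) / saccade (1) sequence at the gaze rate."""
    states: np.ndarray
    fs: float
    n_fixations: int


@dataclass(frozen=True)
class DFAResult:
    scales: np.ndarray         # window lengths, samples
    fluctuations: np.ndarray   # F(s)
    exponent: float            # log-log slope
    fit_rmse: float            # residual RMSE of the log-log fit


@dataclass(frozen=True)
class DFAParams:
    """Scale range in seconds, scale count, window overlap, detrend order."""
    scale_lo_s: float = 1.0
    scale_hi_s: float = 20.0
    n_scales: int = 15
    overlap: float = 0.5
    detrend_order: int = 1


def amplitude_envelope(rec: Recording, band: BandDefinition = ALPHA_BAND,
                       order: int = 66) -> EnvelopeSeries:
    """Band-pass (zero-phase FIR of the stated order) then analytic-signal magnitude.

    ``trim`` marks half the filter order per edge as unreliable; callers
    should drop it before DFA (``dfa`` on an :class:`EnvelopeSeries` does).
    """
    if order >= rec.n_samples:
        raise ValueError("filter order must be below the recording length")
    taps = sps.firwin(order + 1, [band.lo, band.hi], pass_zero=False, fs=rec.fs)
    filt = sps.fftconvolve(rec.data, taps[None, :], mode="same", axes=1)
    env = np.abs(sps.hilbert(filt, axis=1))
    return EnvelopeSeries(values=env, fs=rec.fs, band=band, trim=order // 2)


def _dfa_core(x: np.ndarray, scales: np.ndarray, overlap: float,
              detrend_order: int) -> np.ndarray:
    """F(s) for each row of x (2-D: series × samples) at each scale."""
    prof = np.cumsum(np.asarray(x, dtype=np.float64)
                     - x.mean(axis=1, dtype=np.float64, keepdims=True), axis=1)
    n = prof.shape[1]
    fl = np.empty((x.shape[0], len(scales)))
    for si, s in enumerate(scales):
        step = max(int(round(s * (1.0 - overlap))), 1)
        starts = np.arange(0, n - s + 1, step)
        idx = starts[:, None] + np.arange(s)[None, :]
        w = prof[:, idx]                              # series × windows × s
        t = np.arange(s, dtype=float)
        a = np.vander(t, detrend_order + 1, increasing=True)
        pinv = np.linalg.pinv(a)                      # (order+1) × s
        coef = w @ pinv.T                             # series × windows × (order+1)
        resid = w - coef @ a.T
        fl[:, si] = np.sqrt(np.mean(resid ** 2, axis=(1, 2)))
    return fl


def dfa(series, scale_lo: int = None, scale_hi: int = None, n_scales: int = 15,
        overlap: float = 0.5, detrend_order: int = 1, fs: float = None,
        params: DFAParams = None) -> DFAResult:
    """Detrended fluctuation analysis of one series (or an EnvelopeSeries).

    Parameters
    ----------
    series : 1-D array, 2-D array (series × samples) or EnvelopeSeries
        Input signal(s).  For an EnvelopeSeries the edge-trim samples are
        dropped and scales come from ``params`` (seconds) at the series' fs.
    scale_lo, scale_hi : int
        Smallest/largest window length in samples; ``scale_hi`` must not
        exceed a quarter of the series length.
    overlap : float
        Fractional window overlap in [0, 1).

    Returns a :class:`DFAResult` (for 2-D input, ``exponent``/``fluctuations``
    are arrays over rows).
    """
    if isinstance(series, EnvelopeSeries):
        fs = series.fs
        tr = series.trim
        x = series.values[:, tr: series.values.shape[1] - tr].astype(np.float64)
        p = params or DFAParams(overlap=overlap, detrend_order=detrend_order,
                                n_scales=n_scales)
        scale_lo = int(round(p.scale_lo_s * fs))
        scale_hi = int(round(p.scale_hi_s * fs))
        n_scales, overlap, detrend_order = p.n_scales, p.overlap, p.detrend_order
    else:
        x = np.atleast_2d(np.asarray(series, dtype=float))
        if params is not None:
            if fs is None:
                raise ValueError("params in seconds require fs")
            scale_lo = int(round(params.scale_lo_s * fs))
            scale_hi = int(round(params.scale_hi_s * fs))
            n_scales, overlap, detrend_order = (params.n_scales, params.overlap,
                                                params.detrend_order)
    n = x.shape[1]
    if scale_lo is None or scale_hi is None:
        scale_lo, scale_hi = max(4, n // 1000), n // 4
    scale_hi = min(scale_hi, n // 4)
    if scale_hi <= scale_lo:
        raise ValueError("scale range collapsed: series too short for these scales")
    if n < 4 * scale_lo:
        raise ValueError("series length must be at least 4x the smallest scale")
    if np.any(x.std(axis=1) == 0):
        raise ValueError("constant series has zero fluctuations")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")

    scales = np.unique(np.round(np.geomspace(scale_lo, scale_hi, n_scales)).astype(int))
    fl = _dfa_core(x, scales, overlap, detrend_order)
    logs = np.log(scales)
    logf = np.log(fl)
    design = np.column_stack([logs, np.ones_like(logs)])
    coef, *_ = np.linalg.lstsq(design, logf.T, rcond=None)
    slopes = coef[0]
    resid = logf.T - design @ coef
    rmse = np.sqrt(np.mean(resid ** 2, axis=0))
    one = x.shape[0] == 1 and not isinstance(series, EnvelopeSeries) \
        and np.asarray(series).ndim == 1
    if one:
        return DFAResult(scales=scales, fluctuations=fl[0],
                         exponent=float(slopes[0]), fit_rmse=float(rmse[0]))
    return DFAResult(scales=scales, fluctuations=fl, exponent=slopes, fit_rmse=rmse)


def dfa_exponent(x: np.ndarray, fs: float, params: DFAParams = DFAParams()) -> float:
    """Convenience: DFA exponent of a 1-D series with scales given in seconds."""
    hi = min(int(round(params.scale_hi_s * fs)), len(np.atleast_1d(x)) // 4)
    res = dfa(x, scale_lo=int(round(params.scale_lo_s * fs)), scale_hi=hi,
              n_scales=params.n_scales, overlap=params.overlap,
              detrend_order=params.detrend_order)
    return res.exponent


def envelope_dfa_exponents(rec: Recording, band: BandDefinition = ALPHA_BAND,
                           order: int = 66, params: DFAParams = DFAParams(),
                           env_fs: float = 25.0) -> np.ndarray:
    """Per-channel DFA exponents of the band amplitude envelope.

    The envelope is band-limited well below the smallest DFA fit scale
    (1 s), so it is block-averaged down to ``env_fs`` before DFA; this
    leaves the exponent over the 1–20 s fit range unchanged while making
    whole-cohort runs cheap.  Set ``env_fs`` to the recording rate to
    disable downsampling.
    """
    env = amplitude_envelope(rec, band, order)
    x = env.values[:, env.trim: env.values.shape[1] - env.trim]
    dec = max(int(round(rec.fs / env_fs)), 1)
    if dec > 1:
        n = (x.shape[1] // dec) * dec
        x = x[:, :n].reshape(x.shape[0], -1, dec).mean(axis=2)
    fs_eff = rec.fs / dec
    res = dfa(x, fs=fs_eff, params=params)
    return np.atleast_1d(res.exponent)


def extract_fixations(gaze: GazeRecording, velocity_threshold: float = 30.0,
                      min_fix_ms: float = 50.0, min_sacc_ms: float = 10.0) -> FixationSeries:
    """Velocity-threshold fixation/saccade labelling with minimum-duration merging.

    Samples with velocity above ``velocity_threshold`` (deg/s) are saccades;
    runs shorter than the minimum durations are merged into the surrounding
    state (shortest runs first).
    """
    v = np.asarray(gaze.velocity, dtype=float)
    if v.size == 0:
        raise ValueError("empty gaze trace")
    states = (v > velocity_threshold).astype(np.int8)
    min_len = {0: int(round(min_fix_ms / 1000.0 * gaze.fs_gaze)),
               1: int(round(min_sacc_ms / 1000.0 * gaze.fs_gaze))}
    states = _merge_short_runs(states, min_len)
    n_fix = _count_runs(states, 0)
    return FixationSeries(states=states, fs=gaze.fs_gaze, n_fixations=n_fix)


def _runs(states: np.ndarray):
    """(start, length, value) for each run."""
    edges = np.flatnonzero(np.diff(states)) + 1
    starts = np.concatenate([[0], edges])
    lengths = np.diff(np.concatenate([starts, [len(states)]]))
    return starts, lengths, states[starts]


def _merge_short_runs(states: np.ndarray, min_len: dict) -> np.ndarray:
    states = states.copy()
    while True:
        starts, lengths, vals = _runs(states)
        # interior runs shorter than their state's minimum
        short = [(lengths[i], i) for i in range(1, len(starts) - 1)
                 if lengths[i] < min_len[int(vals[i])]]
        if not short:
            break
        _, i = min(short)
        states[starts[i]: starts[i] + lengths[i]] = 1 - vals[i]
    return states


def _count_runs(states: np.ndarray, value: int) -> int:
    _, _, vals = _runs(states)
    return int(np.sum(vals == value))


def behavioural_dfa(fix: FixationSeries, params: DFAParams = DFAParams()) -> DFAResult:
    """DFA of the binary fixation series (the behavioural LRTC exponent)."""
    if fix.n_fixations < 10:
        logger.warning("only %d fixations: DFA exponent may be unstable",
                       fix.n_fixations)
    return dfa(fix.states.astype(float), fs=fix.fs, params=params)
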