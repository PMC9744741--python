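"""Synthetic cohort generator: phenotyped subjects, EEG recordings, gaze traces.

This module emulates a two-group resting-state study: "static" viewers
(long fixations, PC1 > 1) and "dynamic" viewers (short fixations, PC1 < -1).
Each subject carries ground-truth generative parameters — individual alpha
frequency, per-band oscillation gains, and Hurst exponents driving the
long-range temporal correlations (LRTCs) of the alpha amplitude envelope and
of the fixation sequence — so that every downstream estimator can be tested
against the truth it is supposed to recover.

Group structure baked into the defaults (eyes open unless stated):

* static viewers have **stronger occipital alpha**, **weaker frontal beta**
  and **weaker occipital gamma** relative power;
* static viewers have a **lower individual alpha frequency**
  (group medians 9.5 vs 10.5 Hz);
* static viewers have **higher Hurst exponents** for both the alpha envelope
  and the fixation sequence;
* eyes-closed alpha gain is drawn from the **same** distribution in both
  groups (the arousal control: no eyes-closed alpha group difference).

No generative model for either signal class is established in the resting
EEG / eye-movement literature this emulates; the constructions here (fGn-
modulated narrowband alpha over a 1/f background; log-normal fixation
durations driven by fGn) are explicit stand-ins chosen because their LRTC
ground truth is analytic (the DFA exponent of fractional Gaussian noise
equals its Hurst exponent).  See docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .montage import Montage

__all__ = [
    "GroupParams", "CohortSpec", "SubjectRecord", "GazeRecording",
    "synth_fgn", "make_cohort", "synth_eeg", "synth_gaze",
    "DEFAULT_GROUP_PARAMS",
]

# stream ids for counter-based seed fan-out: adding a subject or a stream
# never perturbs the draws of another
_STREAM_COHORT = 1
_STREAM_EEG_EO = 2
_STREAM_EEG_EC = 3
_STREAM_GAZE = 4


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(
        np.random.SeedSequence(int(seed), spawn_key=tuple(int(k) for k in key))))


@dataclass(frozen=True)
class GroupParams:
    """Per-group (mean, sd) for each generative parameter.

    Gains are relative amplitude multipliers on the oscillatory components
    (unit background std); ``iaf_hz`` is the alpha peak frequency; Hurst
    exponents live in (0.5, 1) for long memory; fixation durations are
    log-normal (seconds) and saccade durations near-constant (ms).
    """
    iaf_hz: tuple = (10.0, 0.6)
    alpha_gain_eo: tuple = (1.12, 0.15)
    alpha_gain_ec: tuple = (1.1, 0.70)
    beta_gain: tuple = (0.23, 0.055)
    gamma_gain: tuple = (0.35, 0.07)
    hurst_alpha: tuple = (0.72, 0.05)
    hurst_fix: tuple = (0.72, 0.05)
    fixation_log_mean: tuple = (np.log(0.30), 0.05)
    fixation_log_sd: tuple = (0.80, 0.01)
    saccade_dur_ms: tuple = (30.0, 4.0)


#: Default study conditions: the group contrasts the pipeline must detect at
#: n = 19/21 (alpha/beta/gamma relative power, IAF medians 9.5 vs 10.5 Hz,
#: envelope and fixation LRTCs) with eyes-closed alpha kept group-identical.
DEFAULT_GROUP_PARAMS = {
    "static": GroupParams(
        iaf_hz=(9.5, 0.6),
        alpha_gain_eo=(1.21, 0.15),
        alpha_gain_ec=(1.1, 0.70),
        beta_gain=(0.18, 0.055),
        gamma_gain=(0.28, 0.07),
        hurst_alpha=(0.82, 0.05),
        hurst_fix=(0.82, 0.05),
        fixation_log_mean=(np.log(0.30), 0.05),
        fixation_log_sd=(0.80, 0.01),
        saccade_dur_ms=(30.0, 4.0),
    ),
    "dynamic": GroupParams(
        iaf_hz=(10.5, 0.6),
        alpha_gain_eo=(1.02, 0.15),
        alpha_gain_ec=(1.1, 0.70),
        beta_gain=(0.28, 0.055),
        gamma_gain=(0.42, 0.07),
        hurst_alpha=(0.65, 0.05),
        hurst_fix=(0.65, 0.05),
        fixation_log_mean=(np.log(0.26), 0.05),
        fixation_log_sd=(0.80, 0.01),
        saccade_dur_ms=(30.0, 4.0),
    ),
}

# sign with which each parameter loads on the latent "staticness" trait that
# also generates PC1 (PC1 > 0 <=> more static)
_TRAIT_SIGNS = {
    "iaf_hz": -1.0, "alpha_gain_eo": +1.0, "alpha_gain_ec": 0.0,
    "beta_gain": -1.0, "gamma_gain": -1.0, "hurst_alpha": +1.0,
    "hurst_fix": +1.0, "fixation_log_mean": 0.0, "fixation_log_sd": 0.0,
    "saccade_dur_ms": 0.0,
}
_TRAIT_COUPLING = 0.5  # within-group correlation of parameters with PC1

_HURST_CLIP = (0.62, 0.88)


@dataclass(frozen=True)
class CohortSpec:
    """Study design: group sizes, sampling rates, durations, group parameters.

    ``duration_s`` is the EEG length per condition; ``gaze_duration_s`` the
    free-viewing gaze-trace length (10 min by default, matching the
    behavioural sessions the fixation LRTC analysis rests on).
    """
    n_static: int = 19
    n_dynamic: int = 21
    seed: int = 0
    duration_s: float = 100.0
    gaze_duration_s: float = 600.0
    fs_eeg: float = 250.0
    fs_gaze: float = 500.0
    group_params: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_PARAMS))

    def __post_init__(self):
        if self.n_static < 0 or self.n_dynamic < 0:
            raise ValueError("group sizes must be non-negative")
        if self.fs_eeg <= 0 or self.fs_gaze <= 0:
            raise ValueError("sampling rates must be positive")
        for g, p in self.group_params.items():
            for name in ("hurst_alpha", "hurst_fix"):
                mu, sd = getattr(p, name)
                if not (0.5 <= mu < 1.0):
                    raise ValueError(f"{g}.{name} mean must be in [0.5, 1)")
        # all synthesized oscillations live below 47 Hz
        if self.fs_eeg < 2 * 47:
            raise ValueError("fs_eeg must exceed twice the highest synthesized frequency")


@dataclass(frozen=True)
class SubjectRecord:
    """Ground truth for one synthetic subject."""
    subject_id: str
    group: str                      # "static" | "dynamic"
    pc1_score: float                # > 1 static, < -1 dynamic
    iaf_true: float                 # Hz
    alpha_gain_eo: float
    alpha_gain_ec: float
    beta_gain: float
    gamma_gain: float
    hurst_alpha: float
    hurst_fix: float
    fixation_log_mean: float
    fixation_log_sd: float
    saccade_dur_ms: float


@dataclass(frozen=True)
class GazeRecording:
    """Gaze velocity trace with its ground-truth fixation/saccade labelling."""
    velocity: np.ndarray            # deg/s
    true_state: np.ndarray          # 0 = fixation, 1 = saccade
    fs_gaze: float


def synth_fgn(n: int, hurst: float, seed=0) -> np.ndarray:
    """Exact fractional Gaussian noise via Davies–Harte circulant embedding.

    Returns a stationary zero-mean series of length ``n`` with theoretical
    unit variance whose DFA scaling exponent equals ``hurst`` (H = 0.5 is
    white noise; H -> 1 is strong long memory).

    Parameters
    ----------
    n : int
        Series length (>= 2).
    hurst : float
        Hurst exponent in (0, 1).
    seed : int or numpy.random.Generator
        Randomness source; deterministic for a fixed integer seed.
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError("hurst must lie in the open interval (0, 1)")
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else _rng(seed)

    k = np.arange(n + 1, dtype=float)
    h2 = 2.0 * hurst
    gamma = 0.5 * (np.abs(k + 1) ** h2 - 2 * np.abs(k) ** h2 + np.abs(k - 1) ** h2)
    # circulant embedding of the covariance; eigenvalues are non-negative for fGn
    c = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.fft.rfft(c).real
    lam = np.maximum(lam, 0.0)  # clip tiny negative round-off

    m = len(c)
    # rfft of a real vector of length m has m//2 + 1 entries
    nf = m // 2 + 1
    z = rng.standard_normal(nf) + 1j * rng.standard_normal(nf)
    z[0] = z[0].real * np.sqrt(2)
    if m % 2 == 0:
        z[-1] = z[-1].real * np.sqrt(2)
    w = np.sqrt(lam / (2.0 * m)) * z
    x = np.fft.irfft(w, n=m) * m
    return x[:n]


def make_cohort(spec: CohortSpec) -> list:
    """Draw the cohort: ``n_static + n_dynamic`` phenotyped subjects.

    PC1 scores and generative parameters share a latent per-subject trait so
    that, across the cohort, PC1 correlates positively with eyes-open alpha
    gain and both Hurst exponents, and negatively with IAF, beta and gamma
    gains — the direction pattern the downstream statistics are built to
    detect.  Deterministic for a fixed ``spec.seed``.
    """
    records = []
    groups = [("static", spec.n_static, +1.0), ("dynamic", spec.n_dynamic, -1.0)]
    idx = 0
    for group, count, sign in groups:
        params = spec.group_params[group]
        for _ in range(count):
            rng = _rng(spec.seed, _STREAM_COHORT, idx)
            trait = rng.standard_normal()          # latent staticness (group-centred)
            # pc1 monotone in the latent trait within each group; |pc1| > 1 always
            pc1 = sign * max(2.0 + 0.6 * trait, 1.05)
            draws = {}
            eps_all = {}
            for name in GroupParams.__dataclass_fields__:
                eps_all[name] = rng.standard_normal()
            # one LRTC trait expressed in both brain and behaviour: the two
            # Hurst exponents share most of their subject-level variation
            eps_all["hurst_fix"] = (0.8 * eps_all["hurst_alpha"]
                                    + 0.6 * eps_all["hurst_fix"])
            for name in GroupParams.__dataclass_fields__:
                mu, sd = getattr(params, name)
                load = _TRAIT_SIGNS[name] * _TRAIT_COUPLING * sign
                val = mu + sd * (load * trait
                                 + np.sqrt(1 - _TRAIT_COUPLING ** 2) * eps_all[name])
                draws[name] = val
            for name in ("hurst_alpha", "hurst_fix"):
                draws[name] = float(np.clip(draws[name], *_HURST_CLIP))
            draws["alpha_gain_eo"] = max(draws["alpha_gain_eo"], 0.05)
            draws["alpha_gain_ec"] = max(draws["alpha_gain_ec"], 0.50)
            draws["beta_gain"] = max(draws["beta_gain"], 0.02)
            draws["gamma_gain"] = max(draws["gamma_gain"], 0.02)
            draws["saccade_dur_ms"] = max(draws["saccade_dur_ms"], 10.0)
            records.append(SubjectRecord(
                subject_id=f"S{idx + 1:03d}", group=group, pc1_score=float(pc1),
                iaf_true=float(np.clip(draws["iaf_hz"], 8.7, 10.9)),
                alpha_gain_eo=float(draws["alpha_gain_eo"]),
                alpha_gain_ec=float(draws["alpha_gain_ec"]),
                beta_gain=float(draws["beta_gain"]),
                gamma_gain=float(draws["gamma_gain"]),
                hurst_alpha=float(draws["hurst_alpha"]),
                hurst_fix=float(draws["hurst_fix"]),
                fixation_log_mean=float(draws["fixation_log_mean"]),
                fixation_log_sd=float(max(draws["fixation_log_sd"], 0.05)),
                saccade_dur_ms=float(draws["saccade_dur_ms"]),
            ))
            idx += 1
    return records


def _one_over_f(n: int, chi: float, fs: float, rng, size: int = 1) -> np.ndarray:
    """Unit-std 1/f^chi background noise via spectral shaping (size × n)."""
    white = rng.standard_normal((size, n), dtype=np.float32)
    spec_w = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(f, dtype=np.float32)
    shape[1:] = (f[1:] ** (-chi / 2.0)).astype(np.float32)
    x = np.fft.irfft(spec_w * shape[None, :], n=n, axis=1)
    sd = x.std(axis=1, keepdims=True)
    x = x / np.where(sd > 0, sd, 1.0)
    return x[0] if size == 1 else x


def _background_field(n: int, chi: float, fs: float, montage: Montage, rng,
                      n_sources: int = 32, kernel_deg: float = 50.0,
                      local_frac: float = 0.1) -> np.ndarray:
    """Spatially coherent 1/f^chi background (channels × samples).

    A surrogate for the spatial smoothness that volume conduction imposes on
    real scalp EEG: ``n_sources`` global 1/f sources at random scalp
    directions are mixed into each channel with Gaussian-in-angle weights
    (``kernel_deg`` SD), plus a small independent per-channel component.
    Neighbouring channels end up strongly correlated, as on a real net,
    without any head-model claim.
    """
    src_dir = rng.standard_normal((n_sources, 3))
    src_dir /= np.linalg.norm(src_dir, axis=1, keepdims=True)
    ang = np.arccos(np.clip(montage.positions @ src_dir.T, -1, 1))
    w = np.exp(-0.5 * (np.rad2deg(ang) / kernel_deg) ** 2)
    w /= np.linalg.norm(w, axis=1, keepdims=True)
    sources = _one_over_f(n, chi, fs, rng, size=n_sources)
    local = _one_over_f(n, chi, fs, rng, size=montage.n_channels)
    field = np.sqrt(1 - local_frac) * (w @ sources) + np.sqrt(local_frac) * local
    return field


def _narrowband(n: int, lo: float, hi: float, fs: float, rng,
                size: int = 1) -> np.ndarray:
    """Unit-std band-limited noise: white noise through a zero-phase FIR."""
    taps = sps.firwin(int(4 * fs / (hi - lo)) // 2 * 2 + 1, [lo, hi],
                      pass_zero=False, fs=fs).astype(np.float32)
    half = len(taps) // 2
    x = sps.fftconvolve(rng.standard_normal((size, n + len(taps)), dtype=np.float32),
                        taps[None, :], mode="same", axes=1)
    x = x[:, half: half + n]
    sd = x.std(axis=1, keepdims=True)
    x = x / np.where(sd > 0, sd, 1.0)
    return x[0] if size == 1 else x


def _narrowband_const_env(n: int, f0: float, fs: float, rng,
                          sigma_hz: float = 0.4) -> np.ndarray:
    """Constant-envelope narrowband carrier peaked at ``f0``.

    White noise is spectrally shaped by a Gaussian centred at ``f0``
    (sd ``sigma_hz``), then reduced to the cosine of its analytic phase.
    The result has unit variance, a spectral peak exactly at ``f0`` that is
    well inside ``f0 ± 1`` Hz, and no amplitude fluctuations of its own —
    so an imposed amplitude modulation is what an envelope estimator sees.
    Used for the alpha carrier, whose envelope dynamics are ground truth;
    beta/gamma carriers stay plain narrowband noise.
    """
    white = rng.standard_normal(n, dtype=np.float32)
    spec_w = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.exp(-0.5 * ((f - f0) / sigma_hz) ** 2).astype(np.float32)
    x = np.fft.irfft(spec_w * shape, n=n)
    a = sps.hilbert(x)
    # unit-amplitude cosine has variance 1/2; rescale to unit variance
    return (np.cos(np.angle(a)) * np.sqrt(2.0)).astype(np.float32)


def _envelope_from_fgn(n: int, hurst: float, rng, depth: float = 0.5) -> np.ndarray:
    """Positive slow modulator carrying Hurst-exponent long memory."""
    g = synth_fgn(n, hurst, rng)
    return np.maximum(1.0 + depth * g, 0.05)


# regional amplitude weights for the group-specific oscillations (1 in the
# home region, near-zero elsewhere so the group contrasts stay focal).  The
# face channels take the dipole's return lobe: at synthesis time the face
# weights are set so the focal topography sums to zero across the montage,
# making it invariant under average referencing (no common-mode leakage of
# the group effect into distant scalp channels).
_ALPHA_W = {"occipital": 1.0, "other": 0.05, "frontal": 0.02, "face": 0.0}
_BETA_W = {"frontal": 1.0, "other": 0.05, "occipital": 0.02, "face": 0.0}
_GAMMA_W = {"occipital": 1.0, "other": 0.05, "frontal": 0.02, "face": 0.0}

# group-independent diffuse rhythms: everyone has widespread alpha and beta on
# top of the focal group components; their subject-level amplitude variation
# is drawn identically in both groups.  Eyes-closed diffuse alpha is both
# stronger and far more variable across subjects than eyes-open alpha — the
# classic Berger effect with its large individual differences — which is what
# keeps the eyes-open/eyes-closed reactivity ratio uninformative about group.
_DIFFUSE_ALPHA = {"eyes_open": 0.85, "eyes_closed": 0.5}
_DIFFUSE_BETA = 0.25
_DIFFUSE_SIGMA = {"eyes_open": 0.25, "eyes_closed": 0.25}

_CONDITION_STREAMS = {"eyes_open": _STREAM_EEG_EO, "eyes_closed": _STREAM_EEG_EC}


def synth_eeg(subject: SubjectRecord, montage: Montage, condition: str,
              duration_s: float = 100.0, fs: float = 250.0, seed: int = 0,
              background_chi: float = 1.0, amplitude_uv: float = 10.0,
              channel_noise: float = 0.2):
    """Synthesize one multichannel resting-state EEG recording.

    Each channel is ``1/f^chi`` background plus three narrowband oscillations:

    * alpha — band-limited noise in ``iaf_true ± 1`` Hz whose amplitude is
      modulated by fractional Gaussian noise with exponent ``hurst_alpha``
      (this is what gives the alpha envelope its LRTCs), weighted toward
      occipital channels;
    * beta (15–25 Hz), weighted toward frontal channels;
    * gamma (35–45 Hz), weighted toward occipital channels.

    In ``eyes_closed`` the alpha gain is ``alpha_gain_ec`` (drawn from the
    same distribution in both groups) and gamma is strongly suppressed.
    The three oscillation fields are spatially coherent (one source waveform
    per band, scaled per channel) with independent per-channel noise mixed
    in, and the background is a spatially smooth source mixture (see
    :func:`_background_field`), so neighbouring channels correlate strongly
    as they do on a real net.

    Returns a :class:`neurogaze.preprocess.Recording`.
    """
    from .preprocess import Recording  # local import to avoid a cycle

    if condition not in _CONDITION_STREAMS:
        raise ValueError("condition must be 'eyes_open' or 'eyes_closed'")
    regions = set(montage.regions)
    if "occipital" not in regions or "frontal" not in regions:
        raise ValueError("montage must tag occipital and frontal regions")

    n = int(round(duration_s * fs))
    sub_idx = int(subject.subject_id.lstrip("S"))
    rng = _rng(seed, _CONDITION_STREAMS[condition], sub_idx)

    if condition == "eyes_open":
        a_gain, g_gain = subject.alpha_gain_eo, subject.gamma_gain
    else:
        a_gain, g_gain = subject.alpha_gain_ec, subject.gamma_gain * 0.2
    b_gain = subject.beta_gain

    n_ch = montage.n_channels
    regions = montage.regions
    cn = channel_noise
    data = _background_field(n, background_chi, fs, montage, rng)

    lo, hi = subject.iaf_true - 1.0, subject.iaf_true + 1.0
    env = _envelope_from_fgn(n, subject.hurst_alpha, rng)
    # diffuse amplitudes: same distribution in both groups; a zero focal gain
    # disables the band entirely (degenerate pure-1/f subject)
    a_dif = _DIFFUSE_ALPHA[condition] * rng.lognormal(0.0, _DIFFUSE_SIGMA[condition])
    if condition == "eyes_closed":
        # the subject's (group-independent) eyes-closed alpha level scales the
        # whole field, focal and diffuse alike: eyes-closed alpha varies a lot
        # between people, coherently across the scalp
        a_dif *= subject.alpha_gain_ec / 1.1
    b_dif = _DIFFUSE_BETA * rng.lognormal(0.0, _DIFFUSE_SIGMA["eyes_open"])
    if a_gain <= 0:
        a_dif = 0.0
    if b_gain <= 0:
        b_dif = 0.0

    def add_band(band_lo, band_hi, w_focal, g_focal, g_diffuse, modulator=None):
        if g_focal <= 0 and g_diffuse <= 0:
            return
        if modulator is not None:
            # one shared constant-envelope carrier for the modulated (alpha)
            # band: summing independent carriers would reintroduce envelope
            # interference noise on top of the imposed fGn modulation
            f0 = 0.5 * (band_lo + band_hi)
            car_f = car_d = _narrowband_const_env(n, f0, fs, rng)
            local = None
        else:
            car_f = _narrowband(n, band_lo, band_hi, fs, rng)
            car_d = _narrowband(n, band_lo, band_hi, fs, rng)
            local = _narrowband(n, band_lo, band_hi, fs, rng, size=n_ch)
        wf_raw = np.array([w_focal[r] for r in regions])
        face = np.array([r == "face" for r in regions])
        if face.any():
            # dipolar return lobe on the (statistics-excluded) face channels
            wf_raw[face] = -wf_raw.sum() / face.sum()
        else:
            wf_raw -= wf_raw.mean()
        wf = g_focal * wf_raw
        # diffuse weights tilt with electrode height so the diffuse rhythm is
        # not a pure common mode (average referencing would cancel that)
        wd_prof = (1.0 + montage.positions[:, 2]) ** 1.5
        wd = g_diffuse * wd_prof / wd_prof.mean()
        if local is None:
            osc = np.outer(wf + wd, car_f) * modulator[None, :]
        else:
            osc = ((1 - cn) * (np.outer(wf, car_f) + np.outer(wd, car_d))
                   + cn * (wf + wd)[:, None] * local)
        data[:] += osc

    add_band(lo, hi, _ALPHA_W, a_gain, a_dif, modulator=env)
    add_band(15.0, 25.0, _BETA_W, b_gain, b_dif)
    add_band(35.0, 45.0, _GAMMA_W, g_gain, 0.0)
    data *= amplitude_uv

    impedances = rng.uniform(5.0, 40.0, size=n_ch)
    return Recording(data=data, fs=float(fs), labels=montage.labels,
                     condition=condition, impedances=impedances)


def synth_gaze(subject: SubjectRecord, duration_s: float = 600.0,
               fs_gaze: float = 500.0, seed: int = 0) -> GazeRecording:
    """Synthesize a gaze velocity trace with ground-truth fixation labelling.

    Fixation durations are log-normal, ``exp(mu + sd * g_k)`` with ``g`` a
    fractional Gaussian noise of exponent ``hurst_fix`` over event index —
    long memory in the duration sequence is what puts the binary fixation
    series' DFA exponent in (0.5, 1).  Saccades are short and near-constant
    with a ballistic (half-sine) velocity profile peaking well above typical
    detection thresholds; fixations carry low-velocity jitter.

    The state trace starts and ends with a fixation and states alternate.
    """
    sub_idx = int(subject.subject_id.lstrip("S"))
    rng = _rng(seed, _STREAM_GAZE, sub_idx)

    mean_fix = float(np.exp(subject.fixation_log_mean + subject.fixation_log_sd ** 2 / 2))
    mean_evt = mean_fix + subject.saccade_dur_ms / 1000.0
    # generous budget: a persistent fGn sample path can drift toward long
    # durations, and running out of events would leave a constant tail
    n_events = int(duration_s / mean_evt * 4.0) + 64
    g = synth_fgn(n_events, subject.hurst_fix, rng)
    fix_dur = np.exp(subject.fixation_log_mean + subject.fixation_log_sd * g)
    sac_dur = np.clip(rng.normal(subject.saccade_dur_ms, 4.0, n_events), 12.0, None) / 1000.0

    n = int(round(duration_s * fs_gaze))
    state = np.zeros(n, dtype=np.int8)
    velocity = np.abs(rng.normal(0.0, 2.0, n)) + rng.uniform(0.0, 3.0, n)
    t = 0
    k = 0
    n_fix = 0
    while t < n and k < n_events:
        nf = max(int(round(fix_dur[k] * fs_gaze)), 2)
        t_end = min(t + nf, n)
        n_fix += 1
        t = t_end
        if t >= n:
            break
        ns = max(int(round(sac_dur[k] * fs_gaze)), 3)
        t_end = min(t + ns, n)
        state[t:t_end] = 1
        peak = rng.normal(220.0, 30.0)
        prof = np.sin(np.pi * (np.arange(t_end - t) + 0.5) / ns)
        velocity[t:t_end] = peak * prof + np.abs(rng.normal(0, 5, t_end - t))
        t = t_end
        k += 1
    if n_fix < 2:
        raise ValueError("duration too short to contain at least two fixations")
    # guarantee the trace ends in a fixation
    if state[-1] == 1:
        last = n - 1
        while last >= 0 and state[last] == 1:
            last -= 1
        state[last + 1:] = 0
        velocity[last + 1:] = np.abs(rng.normal(0.0, 2.0, n - last - 1)) + 1.0
    return GazeRecording(velocity=velocity, true_state=state, fs_gaze=float(fs_gaze))
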