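"""Welch spectra, relative band power, individual alpha frequency, reactivity.

Relative band power is the trapezoidal integral of the per-channel PSD over a
band divided by the integral over the whole analysed range (1–45 Hz by
default), making it scale-invariant.  The individual alpha frequency (IAF)
is the dominant peak of the occipital-average eyes-closed spectrum in
7–13 Hz; a boundary maximum is reported with ``is_true_peak=False`` so the
subject can be excluded rather than guessed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .montage import Montage
from .preprocess import Recording

__all__ = [
    "Spectrum", "BandDefinition", "BandPowerMap", "IAFResult",
    "DEFAULT_BANDS", "DEFAULT_NORM_RANGE",
    "welch_psd", "relative_power", "detect_iaf", "alpha_reactivity",
]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo: float
    hi: float

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError("band lo must be below hi")


#: The five canonical analysis bands.
DEFAULT_BANDS = (
    BandDefinition("delta", 1.0, 3.0),
    BandDefinition("theta", 3.5, 7.0),
    BandDefinition("alpha", 7.5, 12.0),
    BandDefinition("beta", 12.5, 32.0),
    BandDefinition("gamma", 32.5, 45.0),
)

#: Whole-spectrum normalization range (outermost analysed band edges).
DEFAULT_NORM_RANGE = (1.0, 45.0)


@dataclass(frozen=True)
class Spectrum:
    """Per-channel PSD on a uniform frequency grid (µV²/Hz)."""
    freqs: np.ndarray
    power: np.ndarray          # channels × freqs
    fs: float
    condition: str = ""
    labels: tuple = ()

    def __post_init__(self):
        df = np.diff(self.freqs)
        if not (df > 0).all() or not np.allclose(df, df[0]):
            raise ValueError("frequency grid must be strictly increasing and uniform")
        if np.any(self.power < 0):
            raise ValueError("PSD must be non-negative")

    @property
    def resolution(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass(frozen=True)
class BandPowerMap:
    """Per-channel relative power for each band (dimensionless fractions)."""
    bands: tuple               # band names
    values: np.ndarray         # channels × bands, each in [0, 1]
    labels: tuple = ()

    def band(self, name: str) -> np.ndarray:
        return self.values[:, self.bands.index(name)]


@dataclass(frozen=True)
class IAFResult:
    """Individual alpha frequency from the occipital-average spectrum."""
    iaf: float
    is_true_peak: bool


def welch_psd(rec: Recording, resolution: float = 0.5) -> Spectrum:
    """Welch PSD with Hamming taper, 50% overlap, density scaling.

    The segment length is ``fs / resolution`` samples, which makes the grid
    spacing exactly ``resolution`` whenever fs is divisible by 2·resolution.
    """
    nperseg = int(round(rec.fs / resolution))
    if rec.n_samples < 2 * nperseg:
        raise ValueError("recording shorter than two Welch segments at this resolution")
    f, pxx = sps.welch(rec.data, fs=rec.fs, window="hamming", nperseg=nperseg,
                       noverlap=nperseg // 2, scaling="density", axis=1)
    return Spectrum(freqs=f, power=pxx, fs=rec.fs, condition=rec.condition,
                    labels=rec.labels)


def _band_integral(spec: Spectrum, lo: float, hi: float) -> np.ndarray:
    f = spec.freqs
    if lo < f[0] or hi > f[-1]:
        raise ValueError(f"band [{lo}, {hi}] outside the spectrum grid "
                         f"[{f[0]}, {f[-1]}]")
    mask = (f >= lo - 1e-9) & (f <= hi + 1e-9)
    return np.trapezoid(spec.power[:, mask], f[mask], axis=1)


def relative_power(spec: Spectrum, bands=DEFAULT_BANDS,
                   norm_range=DEFAULT_NORM_RANGE) -> BandPowerMap:
    """Relative band power: band integral ÷ whole-range integral, per channel."""
    total = _band_integral(spec, *norm_range)
    total = np.where(total > 0, total, np.nan)
    vals = np.column_stack([_band_integral(spec, b.lo, b.hi) / total for b in bands])
    return BandPowerMap(bands=tuple(b.name for b in bands), values=vals,
                        labels=spec.labels)


def detect_iaf(spec_ec: Spectrum, montage: Montage,
               search_lo: float = 7.0, search_hi: float = 13.0) -> IAFResult:
    """Locate the individual alpha frequency on the occipital-average spectrum.

    The candidate is the argmax of the occipital-average PSD on
    ``[search_lo, search_hi]``; it is a *true* peak only if it is a strict
    local maximum (greater than both adjacent bins) and not a boundary bin
    of the search range.  Subjects whose candidate fails that check should
    be excluded, mirroring manual spectrum vetting.
    """
    occ = montage.channel_indices("occipital")
    if occ.size == 0:
        raise ValueError("montage has no occipital channels")
    avg = spec_ec.power[occ].mean(axis=0)
    f = spec_ec.freqs
    mask = (f >= search_lo - 1e-9) & (f <= search_hi + 1e-9)
    idx = np.flatnonzero(mask)
    k = idx[np.argmax(avg[idx])]
    at_boundary = k == idx[0] or k == idx[-1]
    strict_local_max = (0 < k < len(f) - 1) and avg[k] > avg[k - 1] and avg[k] > avg[k + 1]
    return IAFResult(iaf=float(f[k]), is_true_peak=bool(strict_local_max and not at_boundary))


def alpha_reactivity(map_eo: BandPowerMap, map_ec: BandPowerMap,
                     band: str = "alpha", orientation: str = "eo_over_ec") -> float:
    """Arousal-reactivity index: global (channel-mean) alpha relative power ratio.

    ``orientation`` selects eyes-open/eyes-closed (default) or its inverse;
    report which orientation was used alongside the value.
    """
    eo = float(np.nanmean(map_eo.band(band)))
    ec = float(np.nanmean(map_ec.band(band)))
    num, den = (eo, ec) if orientation == "eo_over_ec" else (ec, eo)
    if den <= 0:
        raise ValueError("denominator alpha power is zero")
    return num / den
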