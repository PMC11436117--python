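"""Parameterization of power spectra into periodic and aperiodic components.

A power spectrum (in log10 power over linearly spaced frequencies) is modeled
as the sum of an aperiodic Lorentzian background

    L(F) = b - log10(k + F^chi)

with broadband offset ``b``, knee ``k`` (0 in *fixed* mode, where L is a
straight line in log-log space with slope -chi) and exponent ``chi``, plus N
Gaussian oscillatory peaks

    G_n(F) = a * exp(-(F - C)^2 / (2 w^2))

with peak power ``a`` (log10 units above the background), center frequency
``C`` (Hz) and standard deviation ``w`` (Hz).

Fitting is staged: a robust aperiodic fit that down-weights bins lying above
an initial fit (i.e. oscillatory regions), iterative extraction of Gaussian
peaks from the flattened residual, a joint least-squares refinement of all
Gaussians, an aperiodic re-fit on the peak-removed spectrum, and a final
joint refinement of every parameter together.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .spectra import PowerSpectrum

# Canonical EEG frequency bands, half-open [low, high) so shared edges are
# unambiguous (8 Hz belongs to alpha, not theta).
DEFAULT_BANDS = (
    ("delta", 1.0, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 13.0),
    ("beta", 13.0, 30.0),
    ("gamma", 30.0, 45.0),
)

DEFAULT_FIT_RANGE = (1.0, 45.0)


@dataclass(frozen=True)
class BandDefinition:
    """Frequency band, half-open interval [low, high) in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"band {self.name}: low must be < high")

    def contains(self, freq: float) -> bool:
        return self.low <= freq < self.high

    def mask(self, freqs: np.ndarray) -> np.ndarray:
        return (freqs >= self.low) & (freqs < self.high)


def standard_bands() -> list[BandDefinition]:
    return [BandDefinition(n, lo, hi) for n, lo, hi in DEFAULT_BANDS]


@dataclass
class AperiodicParams:
    """Aperiodic (1/f-like) background parameters."""

    offset: float
    exponent: float
    knee: float = 0.0

    def __post_init__(self) -> None:
        if self.knee < 0:
            raise ValueError("knee must be >= 0")


@dataclass
class PeakParams:
    """One Gaussian oscillatory peak: power (log10), center (Hz), width (Hz)."""

    power: float
    center: float
    width: float


@dataclass
class PeakSettings:
    """Peak-extraction configuration.

    ``width_limits`` bound the full width at half maximum (FWHM) of candidate
    peaks in Hz; internally FWHM = 2*sqrt(2*ln 2) * w.  ``rel_threshold`` is
    the minimum peak height in units of the SD of the flattened residual;
    ``min_height`` is an absolute floor in log10 power.
    """

    max_n_peaks: int = 6
    rel_threshold: float = 2.0
    min_height: float = 0.10
    width_limits: tuple[float, float] = (0.5, 12.0)


_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class SpectralModel:
    """Result of a spectral parameterization."""

    aperiodic: AperiodicParams
    peaks: list[PeakParams]
    fit_range: tuple[float, float]
    r_squared: float
    mae_log: float
    mode: str = "fixed"
    converged: bool = True
    channel_label: str = ""

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    def to_dict(self) -> dict:
        return {
            "aperiodic": {"offset": self.aperiodic.offset,
                          "knee": self.aperiodic.knee,
                          "exponent": self.aperiodic.exponent},
            "peaks": [{"cf": p.center, "pw": p.power, "bw": p.width}
                      for p in self.peaks],
            "r_squared": self.r_squared,
            "mae": self.mae_log,
            "fit_range": list(self.fit_range),
            "mode": self.mode,
            "converged": self.converged,
            "channel": self.channel_label,
        }


def evaluate_aperiodic(aperiodic: AperiodicParams, freqs: np.ndarray) -> np.ndarray:
    """L(F) = b - log10(k + F^chi) in log10 power."""
    freqs = np.asarray(freqs, dtype=float)
    if aperiodic.knee == 0 and np.any(freqs <= 0):
        raise ValueError("frequencies must be positive in fixed mode (k = 0)")
    return aperiodic.offset - np.log10(aperiodic.knee + freqs ** aperiodic.exponent)


def evaluate_peaks(peaks: list[PeakParams], freqs: np.ndarray) -> np.ndarray:
    """Sum of Gaussian peaks, log10 power units."""
    freqs = np.asarray(freqs, dtype=float)
    out = np.zeros_like(freqs)
    for p in peaks:
        out += p.power * np.exp(-((freqs - p.center) ** 2) / (2.0 * p.width ** 2))
    return out


def evaluate_model(aperiodic: AperiodicParams, peaks: list[PeakParams],
                   freqs: np.ndarray) -> np.ndarray:
    """Full model log10 spectrum: L(F) + sum_n G_n(F)."""
    return evaluate_aperiodic(aperiodic, freqs) + evaluate_peaks(peaks, freqs)


# ---------------------------------------------------------------------------
# fitting internals
# ---------------------------------------------------------------------------

def _fit_aperiodic_ols(freqs: np.ndarray, logpow: np.ndarray,
                       mode: str) -> AperiodicParams:
    if mode == "fixed":
        # straight line in log-log space; chi = -slope, b = intercept
        slope, intercept = np.polyfit(np.log10(freqs), logpow, 1)
        return AperiodicParams(offset=float(intercept), exponent=float(-slope))
    # knee mode: nonlinear fit seeded from the fixed-mode line
    line = _fit_aperiodic_ols(freqs, logpow, "fixed")

    def f(F, b, k, chi):
        return b - np.log10(k + F ** chi)

    p0 = [line.offset, 1.0, max(line.exponent, 0.1)]
    popt, _ = curve_fit(f, freqs, logpow, p0=p0, maxfev=5000,
                        bounds=([-np.inf, 0.0, -np.inf], [np.inf, np.inf, np.inf]))
    return AperiodicParams(offset=float(popt[0]), knee=float(popt[1]),
                           exponent=float(popt[2]))


def _fit_aperiodic_robust(freqs: np.ndarray, logpow: np.ndarray,
                          mode: str) -> AperiodicParams:
    """Aperiodic fit down-weighting bins far above an initial fit.

    Bins whose positive flattened residual exceeds its 2.5th percentile are
    excluded, which removes oscillatory peak regions from the background fit.
    """
    initial = _fit_aperiodic_ols(freqs, logpow, mode)
    flat = logpow - evaluate_aperiodic(initial, freqs)
    flat = np.where(flat < 0, 0.0, flat)
    thresh = np.percentile(flat, 2.5)
    mask = flat <= thresh
    if mask.sum() < max(4, freqs.size // 10):
        return initial
    return _fit_aperiodic_ols(freqs[mask], logpow[mask], mode)


def _guess_width(flat: np.ndarray, freqs: np.ndarray, idx: int,
                 settings: PeakSettings) -> float:
    """Half-height extent around the residual maximum, converted to sd."""
    half = flat[idx] / 2.0
    lo = idx
    while lo > 0 and flat[lo] > half:
        lo -= 1
    hi = idx
    while hi < flat.size - 1 and flat[hi] > half:
        hi += 1
    fwhm = max(freqs[hi] - freqs[lo], freqs[1] - freqs[0])
    w = fwhm / _FWHM
    w_lo, w_hi = settings.width_limits[0] / _FWHM, settings.width_limits[1] / _FWHM
    return float(np.clip(w, w_lo, w_hi))


def _extract_peaks(freqs: np.ndarray, flat: np.ndarray,
                   settings: PeakSettings) -> list[PeakParams]:
    """Iteratively pull Gaussian guesses out of the flattened residual.

    Single-bin spikes (residual maxima whose neighbors carry < 1/4 of the
    height) are skipped — they are unresolvable at the spectral resolution.
    Of two guesses closer than 1.5 times the wider one's SD, only the
    stronger is kept, so one noisy peak cannot split into two.
    """
    flat = flat.copy()
    guesses: list[PeakParams] = []
    blocked: list[int] = []
    for _ in range(settings.max_n_peaks + 4):
        if len(guesses) >= settings.max_n_peaks:
            break
        search = flat.copy()
        search[blocked] = -np.inf
        idx = int(np.argmax(search))
        height = float(flat[idx])
        sd = float(np.std(flat))
        if height < settings.min_height or height < settings.rel_threshold * sd:
            break
        # a resolvable peak must keep at least half its height one bin away
        # (FWHM >= ~2 bins); sharper maxima are unresolvable noise spikes
        neighbors = [flat[j] for j in (idx - 1, idx + 1) if 0 <= j < flat.size]
        if neighbors and max(neighbors) < height / 2.0:
            blocked.append(idx)
            continue
        w = _guess_width(flat, freqs, idx, settings)
        guess = PeakParams(power=height, center=float(freqs[idx]), width=w)
        guesses.append(guess)
        flat -= evaluate_peaks([guess], freqs)
    return _drop_overlapping(guesses)


def _drop_overlapping(guesses: list[PeakParams],
                      proximity: float = 1.5) -> list[PeakParams]:
    """Keep only the strongest of any pair of guesses closer than
    ``proximity`` times the wider one's SD."""
    kept: list[PeakParams] = []
    for g in sorted(guesses, key=lambda p: -p.power):
        if all(abs(g.center - k.center) >= proximity * max(g.width, k.width)
               for k in kept):
            kept.append(g)
    return kept


def _multi_gauss(freqs: np.ndarray, *params: float) -> np.ndarray:
    out = np.zeros_like(freqs)
    for i in range(0, len(params), 3):
        a, c, w = params[i:i + 3]
        out += a * np.exp(-((freqs - c) ** 2) / (2.0 * w ** 2))
    return out


def _multi_gauss_jac(freqs: np.ndarray, *params: float) -> np.ndarray:
    jac = np.empty((freqs.size, len(params)))
    for i in range(0, len(params), 3):
        a, c, w = params[i:i + 3]
        d = freqs - c
        e = np.exp(-d ** 2 / (2.0 * w ** 2))
        jac[:, i] = e
        jac[:, i + 1] = a * e * d / w ** 2
        jac[:, i + 2] = a * e * d ** 2 / w ** 3
    return jac


def _refine_peaks(freqs: np.ndarray, flat: np.ndarray, guesses: list[PeakParams],
                  settings: PeakSettings) -> tuple[list[PeakParams], bool]:
    """Joint least-squares fit of all Gaussians on the flattened spectrum."""
    if not guesses:
        return [], True
    p0, lo, hi = [], [], []
    w_lo, w_hi = settings.width_limits[0] / _FWHM, settings.width_limits[1] / _FWHM
    f_lo, f_hi = freqs[0], freqs[-1]
    for g in guesses:
        p0 += [g.power, g.center, g.width]
        # centers may move at most 2 SD from their guess (prevents drift)
        lo += [0.0, max(f_lo, g.center - 2 * g.width), w_lo]
        hi += [np.inf, min(f_hi, g.center + 2 * g.width), w_hi]
    try:
        popt, _ = curve_fit(_multi_gauss, freqs, flat, p0=p0, bounds=(lo, hi),
                            jac=_multi_gauss_jac, maxfev=3000)
        converged = True
    except RuntimeError:
        popt, converged = np.asarray(p0), False
    peaks = [PeakParams(power=float(popt[i]), center=float(popt[i + 1]),
                        width=float(popt[i + 2]))
             for i in range(0, len(popt), 3)]
    peaks = [p for p in peaks if p.power >= settings.min_height]
    peaks.sort(key=lambda p: p.center)
    return peaks, converged


def _joint_refine(freqs: np.ndarray, logpow: np.ndarray, ap: AperiodicParams,
                  peaks: list[PeakParams], mode: str,
                  settings: PeakSettings) -> tuple[AperiodicParams, list[PeakParams], bool]:
    """Final simultaneous refinement of aperiodic and peak parameters."""
    n_ap = 2 if mode == "fixed" else 3

    def model(F, *params):
        if mode == "fixed":
            b, chi = params[:2]
            k = 0.0
        else:
            b, k, chi = params[:3]
        out = b - np.log10(np.maximum(k + F ** chi, 1e-300))
        return out + _multi_gauss(F, *params[n_ap:])

    p0 = [ap.offset, ap.exponent] if mode == "fixed" else [ap.offset, ap.knee, ap.exponent]
    lo = [-np.inf, -np.inf] if mode == "fixed" else [-np.inf, 0.0, -np.inf]
    hi = [np.inf] * n_ap
    w_lo, w_hi = settings.width_limits[0] / _FWHM, settings.width_limits[1] / _FWHM
    for p in peaks:
        p0 += [p.power, p.center, p.width]
        lo += [0.0, max(freqs[0], p.center - 2 * p.width),
               min(w_lo, p.width)]
        hi += [np.inf, min(freqs[-1], p.center + 2 * p.width),
               max(w_hi, p.width)]
    jac = None
    if mode == "fixed":
        def jac(F, *params):  # noqa: E306 - analytic jacobian, fixed mode
            out = np.empty((F.size, len(params)))
            out[:, 0] = 1.0
            out[:, 1] = -np.log10(F)
            if len(params) > 2:
                out[:, 2:] = _multi_gauss_jac(F, *params[2:])
            return out
    try:
        popt, _ = curve_fit(model, freqs, logpow, p0=p0,
                            bounds=(lo, hi), jac=jac, maxfev=3000)
    except RuntimeError:
        return ap, peaks, False
    if mode == "fixed":
        ap_out = AperiodicParams(offset=float(popt[0]), exponent=float(popt[1]))
    else:
        ap_out = AperiodicParams(offset=float(popt[0]), knee=float(popt[1]),
                                 exponent=float(popt[2]))
    pk = [PeakParams(power=float(popt[i]), center=float(popt[i + 1]),
                     width=float(popt[i + 2]))
          for i in range(n_ap, len(popt), 3)]
    pk = [p for p in pk if p.power >= settings.min_height]
    pk.sort(key=lambda p: p.center)
    return ap_out, pk, True


def fit_spectrum(spectrum: PowerSpectrum,
                 fit_range: tuple[float, float] = DEFAULT_FIT_RANGE,
                 mode: str = "fixed",
                 peak_settings: PeakSettings | None = None) -> SpectralModel:
    """Fit the periodic + aperiodic model to a measured power spectrum.

    Parameters
    ----------
    spectrum : PowerSpectrum
        Linear-power spectrum; only bins inside ``fit_range`` (and > 0 Hz)
        are used, and the fit runs on log10 power.
    fit_range : (low, high)
        Frequency interval in Hz; default 1-45 Hz, the union of the
        delta-gamma bands.
    mode : {"fixed", "knee"}
        Fixed mode pins the knee at 0 (straight line in log-log space).
    """
    if mode not in ("fixed", "knee"):
        raise ValueError("mode must be 'fixed' or 'knee'")
    settings = peak_settings or PeakSettings()
    m = (spectrum.freqs >= fit_range[0]) & (spectrum.freqs <= fit_range[1])
    m &= spectrum.freqs > 0
    freqs = spectrum.freqs[m]
    power = spectrum.power[m]
    if freqs.size < 10:
        raise ValueError("need at least 10 frequency bins inside fit_range")
    if np.any(power <= 0):
        raise ValueError("power must be strictly positive inside fit_range")
    logpow = np.log10(power)

    ap0 = _fit_aperiodic_robust(freqs, logpow, mode)
    flat = logpow - evaluate_aperiodic(ap0, freqs)
    guesses = _extract_peaks(freqs, flat, settings)
    peaks, conv1 = _refine_peaks(freqs, flat, guesses, settings)
    residual_ap = logpow - evaluate_peaks(peaks, freqs)
    ap1 = _fit_aperiodic_ols(freqs, residual_ap, mode)
    ap, peaks, conv2 = _joint_refine(freqs, logpow, ap1, peaks, mode, settings)

    modeled = evaluate_model(ap, peaks, freqs)
    resid = logpow - modeled
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((logpow - logpow.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return SpectralModel(aperiodic=ap, peaks=peaks, fit_range=tuple(fit_range),
                         r_squared=float(np.clip(r2, 0.0, 1.0)),
                         mae_log=float(np.mean(np.abs(resid))), mode=mode,
                         converged=conv1 and conv2,
                         channel_label=spectrum.channel_label)


def band_features(model: SpectralModel, spectrum: PowerSpectrum,
                  band: BandDefinition, periodic_statistic: str = "mean_power"):
    """Band-wise features of a fitted model + measured spectrum.

    Returns (periodic_power, psd_power, aperiodic_offset, aperiodic_exponent).

    * ``periodic_power`` — mean of the modeled periodic component (sum of
      Gaussians, log10 units) over the band's bins, or 0 when no fitted
      peak's center lies inside [low, high).  With
      ``periodic_statistic="max_peak"``, the largest peak power ``a`` among
      peaks centered in the band instead.
    * ``psd_power`` — mean log10 measured power over band bins.
    * The aperiodic offset and exponent are band-independent model
      parameters, repeated for convenience.
    """
    lo, hi = model.fit_range
    if band.low < lo or band.high > hi + 1e-12:
        raise ValueError(f"band {band.name} [{band.low}, {band.high}) outside "
                         f"fit range [{lo}, {hi}]")
    bins = band.mask(spectrum.freqs) & (spectrum.freqs > 0)
    if not bins.any():
        raise ValueError(f"no spectrum bins inside band {band.name}")
    in_band = [p for p in model.peaks if band.contains(p.center)]
    if not in_band:
        periodic = 0.0
    elif periodic_statistic == "max_peak":
        periodic = max(p.power for p in in_band)
    elif periodic_statistic == "mean_power":
        periodic = float(np.mean(evaluate_peaks(model.peaks, spectrum.freqs[bins])))
    else:
        raise ValueError("periodic_statistic must be 'mean_power' or 'max_peak'")
    psd_power = float(np.mean(np.log10(spectrum.power[bins])))
    return (periodic, psd_power, model.aperiodic.offset, model.aperiodic.exponent)
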