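"""Synthetic resting-state EEG cohorts with depression-like structure.

Generates two groups (healthy controls and a depressed group) of multichannel
EEG whose spectra carry the statistical structure the downstream analysis
assumes:

* a 1/f-shaped aperiodic background per channel, with group-dependent
  offset and exponent (synthesized by inverse-FFT amplitude shaping of white
  Gaussian noise, amplitude proportional to f^(-chi/2));
* narrowband theta and alpha oscillations (white noise bandpassed with a
  4th-order zero-phase Butterworth filter) whose log10 power differs between
  groups by a configurable standardized gap per scalp region;
* source-level stand-in features emitted directly as regional values (no
  inverse solution is simulated), with attenuated group gaps;
* Beck-Depression-Inventory-like total/anhedonia/melancholia scores linked
  to a chosen generative feature through a Gaussian copula on ranks, with
  group-specific score ranges (controls < 7, depressed >= 13 on the total).

Every random draw derives from the single integer seed in the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, sosfiltfilt
from scipy.special import ndtri

from .features import DEFAULT_REGION_MAP, REGIONS, all_region_channels, region_of
from .spectra import PowerSpectrum
from .specparam import AperiodicParams, PeakParams, evaluate_model

HC = "HC"
MDD = "MDD"


@dataclass(frozen=True)
class GroupAperiodic:
    """Between-subject distribution of aperiodic parameters for one group."""

    offset_mean: float
    offset_sd: float
    exponent_mean: float
    exponent_sd: float

    def __post_init__(self) -> None:
        if self.offset_sd < 0 or self.exponent_sd < 0:
            raise ValueError("standard deviations must be >= 0")


@dataclass(frozen=True)
class OscillationSpec:
    """One narrowband oscillation, configured per band.

    ``hc_logpow`` / ``mdd_logpow`` give the group mean log10 oscillation
    variance (uV^2) per scalp region; ``subject_sd`` the between-subject SD
    of the band's log-power (shared across regions within a subject);
    ``channel_sd`` an independent per-channel jitter.
    """

    band: str
    center: float
    bandwidth: float
    hc_logpow: dict[str, float]
    mdd_logpow: dict[str, float]
    subject_sd: float = 0.3
    channel_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.subject_sd < 0 or self.channel_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")


@dataclass(frozen=True)
class BehaviorTarget:
    """Target rank correlation between a generative feature and a score."""

    score: str
    feature: str
    rho: float

    def __post_init__(self) -> None:
        if abs(self.rho) >= 1:
            raise ValueError("target |rho| must be < 1")


# Group score ranges (inclusive, integer scores): controls scored < 7 on the
# total, the depressed group >= 13, mirroring the inclusion thresholds.
DEFAULT_SCORE_RANGES: dict[str, dict[str, tuple[int, int]]] = {
    "bdi": {HC: (0, 6), MDD: (13, 35)},
    "bdi_anh": {HC: (0, 2), MDD: (1, 8)},
    "bdi_mel": {HC: (0, 4), MDD: (3, 10)},
}

# Standardized group gaps (in units of subject_sd) targeting the effect sizes
# the analysis is meant to detect: strongest for parietal theta and frontal
# alpha oscillatory power.
_THETA_TARGET_G = {"frontal": 0.60, "central": 0.60, "temporal": 0.60,
                   "parietal": 0.80, "occipital": 0.76}
# Alpha gaps carry a 1/1.2 calibration factor: the log-power -> fitted
# periodic-feature mapping has gain ~1.2 in the alpha band (measured on the
# full synthesis -> Welch -> parameterization chain), so the generative gap
# is shrunk to land the *realized* standardized effect on target.
_ALPHA_TARGET_G = {"frontal": 0.82 / 1.2, "central": 0.60 / 1.2,
                   "temporal": 0.60 / 1.2, "parietal": 0.70 / 1.2,
                   "occipital": 0.70 / 1.2}
_THETA_HC = {"frontal": 0.90, "central": 0.90, "temporal": 0.80,
             "parietal": 1.00, "occipital": 0.90}
_ALPHA_HC = {"frontal": 1.00, "central": 1.00, "temporal": 0.90,
             "parietal": 1.30, "occipital": 1.40}


def _mdd_means(hc: dict[str, float], target_g: dict[str, float],
               sd: float) -> dict[str, float]:
    return {r: hc[r] - target_g[r] * sd for r in hc}


def default_oscillations() -> tuple[OscillationSpec, ...]:
    sd = 0.3
    return (
        OscillationSpec("theta", center=6.0, bandwidth=2.0,
                        hc_logpow=dict(_THETA_HC),
                        mdd_logpow=_mdd_means(_THETA_HC, _THETA_TARGET_G, sd),
                        subject_sd=sd),
        OscillationSpec("alpha", center=10.0, bandwidth=3.0,
                        hc_logpow=dict(_ALPHA_HC),
                        mdd_logpow=_mdd_means(_ALPHA_HC, _ALPHA_TARGET_G, sd),
                        subject_sd=sd),
    )


def default_behavior() -> tuple[BehaviorTarget, ...]:
    # scores driven by the true parietal theta oscillatory log-power; the
    # strongest link targets the anhedonia subscale
    return (
        BehaviorTarget("bdi", "parietal_theta_logpow", -0.35),
        BehaviorTarget("bdi_anh", "parietal_theta_logpow", -0.40),
        BehaviorTarget("bdi_mel", "parietal_theta_logpow", -0.25),
    )


@dataclass(frozen=True)
class CohortConfig:
    """Full description of a synthetic cohort.

    Defaults reproduce the study conditions: 74 controls vs 40 depressed
    subjects, the 60 region-mapped 10-20 electrodes, 500 Hz sampling, 60 s
    of resting EEG per subject.
    """

    n_hc: int = 74
    n_mdd: int = 40
    channel_labels: tuple[str, ...] = tuple(all_region_channels())
    sfreq: float = 500.0
    duration: float = 60.0
    aperiodic_hc: GroupAperiodic = GroupAperiodic(0.30, 0.30, 1.20, 0.25)
    aperiodic_mdd: GroupAperiodic = GroupAperiodic(0.30, 0.30, 0.955, 0.25)
    exponent_channel_sd: float = 0.05
    oscillations: tuple[OscillationSpec, ...] = field(
        default_factory=default_oscillations)
    behavior: tuple[BehaviorTarget, ...] = field(default_factory=default_behavior)
    score_ranges: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SCORE_RANGES.items()})
    source_attenuation: float = 0.5
    min_seg_seconds: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hc < 1 or self.n_mdd < 1:
            raise ValueError("need at least one subject per group")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        max_edge = max((o.center + o.bandwidth / 2 for o in self.oscillations),
                       default=0.0)
        if self.sfreq <= 2 * max_edge:
            raise ValueError("sfreq must exceed twice the highest band edge")
        if self.duration < 2 * self.min_seg_seconds:
            raise ValueError(
                f"duration {self.duration} s too short for {self.min_seg_seconds}-s "
                "Welch segmentation (need at least two segments)")


@dataclass
class SubjectRecord:
    """One synthetic subject: signals, labels, scores and generative truth."""

    subject_id: str
    group: str
    data: np.ndarray | None  # channels x samples, uV
    channel_labels: tuple[str, ...]
    scores: dict[str, int] = field(default_factory=dict)
    source_features: dict = field(default_factory=dict)
    truth: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# model spectra (for fit-recovery studies)
# ---------------------------------------------------------------------------

def make_model_spectrum(aperiodic: AperiodicParams,
                        peaks: list[PeakParams],
                        freq_range: tuple[float, float] = (1.0, 45.0),
                        freq_step: float = 0.5,
                        noise_sd: float = 0.0,
                        seed: int = 0) -> PowerSpectrum:
    """Evaluate the spectral model on a frequency grid, optionally adding
    Gaussian noise in log10 space; linear power is ``10**(L + sum G + eps)``."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if freq_range[0] <= 0 and aperiodic.knee == 0:
        raise ValueError("freq_range must be positive in fixed mode")
    n = int(round((freq_range[1] - freq_range[0]) / freq_step)) + 1
    freqs = freq_range[0] + freq_step * np.arange(n)
    logpow = evaluate_model(aperiodic, peaks, freqs)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        logpow = logpow + rng.normal(0.0, noise_sd, size=freqs.size)
    return PowerSpectrum(freqs, 10.0 ** logpow, channel_label="model")


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------

def aperiodic_noise(n_samples: int, sfreq: float, offset: float,
                    exponent: float, rng: np.random.Generator) -> np.ndarray:
    """1/f-shaped Gaussian noise with one-sided PSD 10**offset * f**-exponent.

    Synthesized by drawing independent complex Gaussian Fourier coefficients
    with amplitude proportional to f^(-exponent/2) and inverse-transforming.
    """
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sfreq)
    target_psd = np.zeros_like(freqs)
    target_psd[1:] = 10.0 ** offset / freqs[1:] ** exponent
    amp = np.sqrt(target_psd * sfreq * n_samples / 2.0)
    coeff = amp * (rng.standard_normal(freqs.size)
                   + 1j * rng.standard_normal(freqs.size)) / np.sqrt(2.0)
    coeff[0] = 0.0
    if n_samples % 2 == 0:
        coeff[-1] = amp[-1] * rng.standard_normal()
    return np.fft.irfft(coeff, n=n_samples)


def narrowband_noise(n_samples: int, sfreq: float, center: float,
                     bandwidth: float, variance: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Band-limited oscillatory process: white noise bandpassed with a
    4th-order zero-phase Butterworth filter, rescaled to the given variance."""
    lo = max(center - bandwidth / 2.0, 0.1)
    hi = min(center + bandwidth / 2.0, sfreq / 2.0 * 0.99)
    sos = butter(4, [lo, hi], btype="bandpass", fs=sfreq, output="sos")
    pad = int(2 * sfreq)
    x = sosfiltfilt(sos, rng.standard_normal(n_samples + 2 * pad))[pad:pad + n_samples]
    s = np.std(x)
    if s == 0:
        return np.zeros(n_samples)
    return x * (np.sqrt(variance) / s)


def _subject_truth_and_signal(cfg: CohortConfig, group: str,
                              rng: np.random.Generator,
                              signals: bool) -> tuple[dict, dict, np.ndarray | None]:
    ap = cfg.aperiodic_hc if group == HC else cfg.aperiodic_mdd
    offset = rng.normal(ap.offset_mean, ap.offset_sd)
    exponent = rng.normal(ap.exponent_mean, ap.exponent_sd)
    truth: dict[str, float] = {"offset": offset, "exponent": exponent}
    for r in REGIONS:
        truth[f"{r}_exponent"] = exponent
    truth["parietal_exponent"] = exponent

    band_logpow: dict[tuple[str, str], float] = {}
    for osc in cfg.oscillations:
        means = osc.hc_logpow if group == HC else osc.mdd_logpow
        subj_dev = rng.normal(0.0, osc.subject_sd)
        for region, mean in means.items():
            lp = mean + subj_dev
            band_logpow[(osc.band, region)] = lp
            truth[f"{region}_{osc.band}_logpow"] = lp

    n = int(round(cfg.duration * cfg.sfreq))
    data = None
    if signals:
        data = np.empty((len(cfg.channel_labels), n), dtype=np.float32)
        for i, ch in enumerate(cfg.channel_labels):
            region = region_of(ch) or "frontal"
            chan_exp = exponent + rng.normal(0.0, cfg.exponent_channel_sd)
            sig = aperiodic_noise(n, cfg.sfreq, offset, chan_exp, rng)
            for osc in cfg.oscillations:
                lp = band_logpow.get((osc.band, region))
                if lp is None:
                    continue
                lp_ch = lp + rng.normal(0.0, osc.channel_sd)
                sig = sig + narrowband_noise(n, cfg.sfreq, osc.center,
                                             osc.bandwidth, 10.0 ** lp_ch, rng)
            data[i] = sig
    return truth, band_logpow, data


def _source_features(cfg: CohortConfig, truth: dict, group: str,
                     rng: np.random.Generator) -> dict:
    """Direct regional stand-ins for source-level features.

    Each source value is the subject's generative value plus independent
    noise scaled so the standardized group gap is attenuated by
    ``source_attenuation`` (default: half the electrode-level effect).
    """
    att = cfg.source_attenuation
    extra = np.sqrt(max(1.0 / att ** 2 - 1.0, 0.0)) if att > 0 else np.inf
    src: dict = {}
    for osc in cfg.oscillations:
        sd = osc.subject_sd if osc.subject_sd > 0 else 0.3
        for region in osc.hc_logpow:
            base = truth[f"{region}_{osc.band}_logpow"]
            src[("periodic", region, osc.band)] = base + rng.normal(0, sd * extra)
            src[("psd", region, osc.band)] = base + rng.normal(0, sd * extra)
    exp_sd = max(cfg.aperiodic_hc.exponent_sd, cfg.aperiodic_mdd.exponent_sd, 0.1)
    for region in REGIONS:
        src[("aperiodic", region, None)] = (truth["exponent"]
                                            + rng.normal(0, exp_sd * extra))
    return src


def make_cohort(config: CohortConfig, signals: bool = True) -> list[SubjectRecord]:
    """Generate the full cohort; deterministic given ``config.seed``.

    With ``signals=False`` only the generative truth, source features and
    behavioral scores are produced (``data`` is None) — a fast path for
    feature-level simulation studies.
    """
    root = np.random.SeedSequence(config.seed)
    subject_seeds = root.spawn(config.n_hc + config.n_mdd)
    score_seed = np.random.SeedSequence(entropy=root.entropy, spawn_key=(10 ** 6,))

    cohort: list[SubjectRecord] = []
    groups = [HC] * config.n_hc + [MDD] * config.n_mdd
    for i, (group, ss) in enumerate(zip(groups, subject_seeds)):
        rng = np.random.default_rng(ss)
        truth, _, data = _subject_truth_and_signal(config, group, rng, signals)
        src = _source_features(config, truth, group, rng)
        cohort.append(SubjectRecord(
            subject_id=f"sub-{i + 1:03d}", group=group, data=data,
            channel_labels=tuple(config.channel_labels),
            source_features=src, truth=truth))
    attach_behavioral_scores(cohort, config.behavior, config.score_ranges,
                             seed=score_seed)
    return cohort


# ---------------------------------------------------------------------------
# behavioral scores
# ---------------------------------------------------------------------------

def _rank_normal(values: np.ndarray) -> np.ndarray:
    """Rank-based normal scores (van der Waerden)."""
    order = np.argsort(np.argsort(values, kind="stable"), kind="stable")
    return ndtri((order + 1.0) / (len(values) + 1.0))


def attach_behavioral_scores(cohort: list[SubjectRecord],
                             behavior: tuple[BehaviorTarget, ...],
                             score_ranges: dict | None = None,
                             seed: int | np.random.SeedSequence = 0) -> list[SubjectRecord]:
    """Draw integer clinical scores rank-linked to generative features.

    For each score a latent variable is built from the driving feature's
    rank-normal scores via a Gaussian copula (latent = rho' z + sqrt(1-rho'^2) eps
    with rho' = 2 sin(pi rho / 6), the Pearson equivalent of the Spearman
    target).  Within each group, subjects' latent ranks are mapped uniformly
    onto the group's integer score range, so group inclusion thresholds are
    respected by construction.
    """
    ranges = score_ranges or DEFAULT_SCORE_RANGES
    rng = np.random.default_rng(seed)
    groups = np.array([s.group for s in cohort])
    for target in behavior:
        if abs(target.rho) >= 1:
            raise ValueError("target |rho| must be < 1")
        feat = np.array([s.truth[target.feature] for s in cohort])
        z = _rank_normal(feat)
        rho_p = 2.0 * np.sin(np.pi * target.rho / 6.0)
        latent = rho_p * z + np.sqrt(1.0 - rho_p ** 2) * rng.standard_normal(len(cohort))
        for group in (HC, MDD):
            idx = np.where(groups == group)[0]
            if idx.size == 0:
                continue
            lo, hi = ranges[target.score][group]
            order = np.argsort(np.argsort(latent[idx], kind="stable"), kind="stable")
            u = (order + 0.5) / idx.size
            scores = np.rint(lo + u * (hi - lo)).astype(int)
            for j, sc in zip(idx, scores):
                cohort[j].scores[target.score] = int(sc)
    return cohort
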