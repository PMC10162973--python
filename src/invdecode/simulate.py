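"""Synthetic source-level EEG cohorts with a controllable inversion effect.

The generator emulates the statistical structure the downstream analysis
assumes for ROI-level cortical activity around a visual stimulus:

* an N170-like evoked deflection -- a Gaussian-windowed negative wave
  peaking ~170 ms post-stimulus at designated "effect" ROIs, which for the
  inverted orientation is larger (amplitude gain) and later (latency delay),
* a condition-dependent induced theta burst -- an amplitude-modulated
  sinusoid with per-trial random phase, so it cancels in the trial average
  but survives in total (mixed) power; its post-stimulus power is scaled
  for inverted stimuli,
* 1/f^alpha Gaussian background noise, independent across ROIs.

Effects are confined to ``effect_rois``; with a shared seed the
upright/inverted difference is exactly zero everywhere else, which gives
every downstream stage a ground truth.  Vertex-level bundles (3 signals per
cortical vertex) can be generated from any ROI trace to exercise the PCA
reduction.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Mapping, Sequence

import numpy as np

from .atlas import DK_ROI_NAMES, N_ROIS, roi_indices
from .datatypes import INVERTED, LABELS, STIMULI, UPRIGHT, StimulusDataset, TrialMatrix


class ConfigurationError(ValueError):
    """Raised for invalid generator configuration."""


@dataclass(frozen=True)
class EffectSpec:
    """Condition-difference specification for one stimulus type.

    Amplitudes are in arbitrary source-activity units; only relative
    condition differences matter downstream.  The defaults encode a
    moderately strong inversion effect at two right-hemisphere ROIs
    (lateral occipital and superior parietal cortex): inverted stimuli
    evoke a 50% larger deflection delayed by 15 ms, and double the induced
    theta power.  A control (house-like) stimulus is obtained with
    :func:`null_effect` (all gains 1, delay 0).
    """

    effect_rois: tuple[str, ...] = ("lateraloccipital-rh", "superiorparietal-rh")
    evoked_peak_time_upright: float = 0.170  # s
    evoked_peak_delay_inverted: float = 0.015  # s
    evoked_amp_upright: float = 2.25  # a.u.
    evoked_amp_gain_inverted: float = 1.5
    evoked_sigma: float = 0.025  # s, width of the Gaussian deflection
    theta_freq: float = 5.0  # Hz
    theta_burst_window: tuple[float, float] = (0.05, 0.45)  # s
    theta_amp_upright: float = 0.5  # a.u.
    theta_power_gain_inverted: float = 2.0
    noise_sd: float = 1.0  # a.u.
    spectral_exponent: float = 1.0  # alpha in 1/f^alpha
    subject_amp_sd: float = 0.1  # between-subject evoked-gain SD

    def __post_init__(self) -> None:
        unknown = set(self.effect_rois) - set(DK_ROI_NAMES)
        if unknown:
            raise ConfigurationError(f"unknown ROI id(s): {sorted(unknown)}")
        if self.evoked_amp_gain_inverted <= 0 or self.theta_power_gain_inverted <= 0:
            raise ConfigurationError("gains must be > 0")
        a, b = self.theta_burst_window
        if not (0.0 <= a < b <= 0.5):
            raise ConfigurationError("theta burst window must lie within [0, 0.5] s")
        if self.noise_sd < 0 or self.evoked_sigma <= 0:
            raise ConfigurationError("noise_sd must be >= 0 and evoked_sigma > 0")

    def peak_time(self, condition: int) -> float:
        return self.evoked_peak_time_upright + (
            self.evoked_peak_delay_inverted if condition == INVERTED else 0.0
        )

    def evoked_amp(self, condition: int) -> float:
        return self.evoked_amp_upright * (
            self.evoked_amp_gain_inverted if condition == INVERTED else 1.0
        )

    def theta_amp(self, condition: int) -> float:
        gain = self.theta_power_gain_inverted if condition == INVERTED else 1.0
        return self.theta_amp_upright * np.sqrt(gain)  # power gain -> amplitude sqrt


def null_effect(base: EffectSpec | None = None) -> EffectSpec:
    """An EffectSpec with no condition difference (control stimulus).

    The evoked deflection and theta burst are still present, but identical
    for upright and inverted orientations.
    """
    base = base or EffectSpec()
    kw = asdict(base)
    kw["effect_rois"] = tuple(base.effect_rois)
    kw["theta_burst_window"] = tuple(base.theta_burst_window)
    kw.update(evoked_amp_gain_inverted=1.0, evoked_peak_delay_inverted=0.0,
              theta_power_gain_inverted=1.0)
    return EffectSpec(**kw)


def default_effects() -> dict[str, EffectSpec]:
    """Per-stimulus EffectSpecs: face and body carry the inversion effect,
    house is the no-difference control."""
    face = EffectSpec()
    return {"face": face, "body": face, "house": null_effect(face)}


@dataclass
class VertexBundle:
    """Vertex-level signals of one ROI: 3 source orientations per vertex."""

    roi_id: str
    signals: np.ndarray  # (3 * n_vertices, T)
    fs: float = 200.0
    t0: float = -1.0

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2 or self.signals.shape[0] % 3 or self.signals.shape[0] < 3:
            raise ConfigurationError(
                f"vertex bundle needs 3*N_r rows (N_r >= 1), got shape {self.signals.shape}"
            )
        if not np.all(np.isfinite(self.signals)):
            raise ConfigurationError("vertex bundle contains non-finite values")

    @property
    def n_vertices(self) -> int:
        return self.signals.shape[0] // 3


def _one_over_f_noise(
    rng: np.random.Generator, n_rows: int, n_samples: int, fs: float, alpha: float, sd: float
) -> np.ndarray:
    """Gaussian noise with power spectrum proportional to 1/f^alpha."""
    if sd == 0:
        return np.zeros((n_rows, n_samples))
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-alpha / 2.0)
    spec = rng.standard_normal((n_rows, freqs.size)) + 1j * rng.standard_normal(
        (n_rows, freqs.size)
    )
    x = np.fft.irfft(spec * shape, n=n_samples, axis=1)
    std = x.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return x * (sd / std)


def _theta_envelope(t: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Hann envelope supported on the burst window, zero elsewhere."""
    a, b = window
    env = np.zeros_like(t)
    inside = (t >= a) & (t <= b)
    env[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * (t[inside] - a) / (b - a)))
    return env


def generate_roi_trial(
    condition: int | str,
    effect: EffectSpec,
    seed: int,
    fs: float = 200.0,
    subject: int = 0,
    stimulus: str = "face",
    subject_gain: float = 1.0,
) -> TrialMatrix:
    """Generate one synthetic ROI-level trial spanning [-1, 1) s.

    All random draws (noise, theta phase) depend only on ``seed``, never on
    ``condition``, so generating both conditions with the same seed yields a
    difference signal that is exactly zero outside ``effect_rois``.

    Parameters
    ----------
    condition : 0/'upright' or 1/'inverted'
    fs : sampling rate; 200 Hz by default, 1000 Hz exercises the resampler.
    subject_gain : multiplicative evoked-amplitude factor (between-subject
        variability; drawn once per subject by :func:`generate_cohort`).
    """
    if isinstance(condition, str):
        try:
            condition = LABELS[condition]
        except KeyError:
            raise ConfigurationError(f"unknown condition {condition!r}") from None
    if condition not in (UPRIGHT, INVERTED):
        raise ConfigurationError(f"condition must be 0/1, got {condition}")
    if seed < 0:
        raise ConfigurationError("seed must be >= 0")

    n = int(round(2.0 * fs))
    t = -1.0 + np.arange(n) / fs
    rng = np.random.default_rng(seed)

    # Draw order fixed and condition-independent: noise, then phases.
    X = _one_over_f_noise(rng, N_ROIS, n, fs, effect.spectral_exponent, effect.noise_sd)
    idx = roi_indices(effect.effect_rois)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(idx))

    amp = effect.evoked_amp(condition) * subject_gain
    if amp != 0.0:
        wave = -amp * np.exp(-0.5 * ((t - effect.peak_time(condition)) / effect.evoked_sigma) ** 2)
        X[idx] += wave
    th_amp = effect.theta_amp(condition)
    if th_amp != 0.0:
        env = _theta_envelope(t, effect.theta_burst_window)
        for r, phi in zip(idx, phases):
            X[r] += th_amp * env * np.sin(2.0 * np.pi * effect.theta_freq * t + phi)

    return TrialMatrix(X=X, y=condition, subject=subject, stimulus=stimulus, fs=fs, t0=-1.0)


def generate_vertex_bundle(
    roi_trial_row: np.ndarray,
    n_vertices: int,
    mixing_seed: int,
    noise_sd: float = 0.0,
    roi_id: str = "lateraloccipital-rh",
    fs: float = 200.0,
    t0: float = -1.0,
    weights: np.ndarray | None = None,
) -> VertexBundle:
    """Expand one ROI time course into 3*n_vertices vertex-level signals.

    Each row is ``w_k * signal + noise`` with mixing weights drawn once per
    bundle from U(-1, 1); one randomly chosen weight is forced to
    ``|w_k| > 0.5`` so the ROI signal dominates at least one vertex signal.
    Pass ``weights`` to override the draw (e.g. all ones).
    """
    if n_vertices < 1:
        raise ConfigurationError("n_vertices must be >= 1")
    sig = np.asarray(roi_trial_row, dtype=float)
    if sig.ndim != 1:
        raise ConfigurationError("roi_trial_row must be a 1-D time series")
    rng = np.random.default_rng(mixing_seed)
    k = 3 * n_vertices
    if weights is None:
        w = rng.uniform(-1.0, 1.0, size=k)
        j = rng.integers(k)
        w[j] = rng.uniform(0.5, 1.0) * (1.0 if rng.uniform() < 0.5 else -1.0)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (k,):
            raise ConfigurationError(f"weights must have shape ({k},)")
    rows = w[:, None] * sig[None, :]
    if noise_sd > 0:
        rows = rows + noise_sd * rng.standard_normal(rows.shape)
    return VertexBundle(roi_id=roi_id, signals=rows, fs=fs, t0=t0)


def generate_cohort(
    n_subjects: int,
    trials_per_condition: int,
    effects: Mapping[str, EffectSpec] | None = None,
    seed: int = 0,
    fs: float = 200.0,
    stimuli: Sequence[str] = STIMULI,
) -> dict[str, list[StimulusDataset]]:
    """Generate a balanced multi-subject cohort for each stimulus type.

    Returns a mapping ``stimulus -> [StimulusDataset per subject]``; each
    dataset holds ``2 * trials_per_condition`` trials (equal upright and
    inverted counts).  Fully reproducible from ``seed``.
    """
    if n_subjects < 2:
        raise ConfigurationError("need at least 2 subjects")
    if trials_per_condition < 1:
        raise ConfigurationError("need at least 1 trial per condition")
    effects = dict(effects) if effects is not None else default_effects()
    missing = [s for s in stimuli if s not in effects]
    if missing:
        raise ConfigurationError(f"missing EffectSpec for stimulus: {missing}")

    master = np.random.default_rng(seed)
    cohort: dict[str, list[StimulusDataset]] = {s: [] for s in stimuli}
    for subj in range(n_subjects):
        gain_rng = np.random.default_rng(master.integers(2**31))
        for stim in stimuli:
            eff = effects[stim]
            gain = float(max(0.2, 1.0 + eff.subject_amp_sd * gain_rng.standard_normal()))
            trials = []
            for cond in (UPRIGHT, INVERTED):
                for _ in range(trials_per_condition):
                    ts = int(master.integers(2**31))
                    trials.append(
                        generate_roi_trial(
                            cond, eff, seed=ts, fs=fs, subject=subj,
                            stimulus=stim, subject_gain=gain,
                        )
                    )
            cohort[stim].append(StimulusDataset(trials=trials, subject=subj, stimulus=stim))
    return cohort
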