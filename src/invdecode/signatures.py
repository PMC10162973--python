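"""Temporal and spectral signatures of the selected ROIs.

Once the most inversion-discriminant ROIs are identified, their activity is
characterized in the time domain (event-related potentials, ERPs) and the
time-frequency domain (event-related desynchronization/synchronization,
ERD/S, from squared complex-Morlet wavelet coefficients normalized to the
pre-stimulus baseline).  Upright-vs-inverted differences are assessed with
nonparametric cluster-based permutation tests on the paired per-subject
data: a paired t-statistic is thresholded pointwise, contiguous
supra-threshold points form clusters whose mass (summed t) is compared to
a null distribution of maximal cluster masses obtained by random
subject-wise sign flips of the condition difference.

ERD/S is computed per trial before any averaging, so induced (non
phase-locked) oscillations survive: the maps reflect the mixed (evoked +
induced) activity the decoder sees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.stats import t as t_dist

from ._kernels import max_cluster_mass_rows
from .datatypes import StimulusDataset, TrialMatrix, ValidationError
from .reduction import DegenerateInputError

DEFAULT_FREQS = np.arange(4.0, 41.0)  # Hz, 1 Hz steps


def morlet_cycles(freqs: np.ndarray) -> np.ndarray:
    """Wavelet cycles n(f) = max(3, f/2): fixed time resolution at low
    frequencies, increasing spectral resolution above 6 Hz."""
    freqs = np.asarray(freqs, dtype=float)
    return np.maximum(3.0, freqs / 2.0)


# -- ERP ---------------------------------------------------------------------


def compute_erp(trials) -> np.ndarray:
    """Pointwise mean across trials (a list of TrialMatrix or an (M, R, T)
    array); linear in its inputs."""
    if isinstance(trials, np.ndarray):
        X = trials
    else:
        trials = list(trials)
        if not trials:
            raise ValidationError("cannot average an empty trial collection")
        X = np.stack([tr.X if isinstance(tr, TrialMatrix) else np.asarray(tr)
                      for tr in trials])
    if X.size == 0:
        raise ValidationError("cannot average an empty trial collection")
    return X.mean(axis=0)


def condition_erps(datasets: Sequence[StimulusDataset]) -> dict[int, np.ndarray]:
    """Per-condition ERPs stacked over subjects: {label: (n_subj, R, T)}."""
    out = {}
    for label in (0, 1):
        per_subj = []
        for ds in datasets:
            sel = ds.select(label)
            if not sel:
                raise ValidationError(
                    f"subject {ds.subject} has no trials with label {label}"
                )
            per_subj.append(compute_erp(sel))
        out[label] = np.stack(per_subj)
    return out


# -- time-frequency / ERD-S --------------------------------------------------


@dataclass
class TimeFreqMap:
    """One ROI/condition time-frequency representation."""

    power: np.ndarray  # (F, T): raw power or ERD/S (fractional change)
    freqs: np.ndarray
    times: np.ndarray
    kind: str = "erds"  # 'power' | 'erds'

    def __post_init__(self) -> None:
        if self.power.shape != (len(self.freqs), len(self.times)):
            raise ValidationError("power must be (n_freqs, n_times)")


def trial_power(
    x: np.ndarray, fs: float, freqs: np.ndarray = DEFAULT_FREQS,
    n_cycles: np.ndarray | None = None, pad: int = 128,
) -> np.ndarray:
    """Squared complex-Morlet wavelet transform of single-ROI trials.

    ``x`` is (T,) or (M, T).  The signal is reflect-padded so the longest
    (lowest-frequency) wavelet fits; edge contamination is handled
    downstream through the cone-of-influence mask.  Returns (M, F, T).
    """
    from mne.time_frequency import tfr_array_morlet

    x = np.atleast_2d(np.asarray(x, dtype=float))
    if n_cycles is None:
        n_cycles = morlet_cycles(freqs)
    xp = np.pad(x, ((0, 0), (pad, pad)), mode="reflect")
    power = tfr_array_morlet(
        xp[:, None, :], sfreq=fs, freqs=np.asarray(freqs, dtype=float),
        n_cycles=n_cycles, output="power", verbose=False,
    )[:, 0]
    return power[..., pad:-pad]


def erds_map(
    trial: np.ndarray, fs: float = 200.0, t0: float = -0.5,
    freqs: np.ndarray = DEFAULT_FREQS, n_cycles: np.ndarray | None = None,
    baseline: tuple[float, float] = (-0.5, 0.0),
) -> TimeFreqMap:
    """ERD/S of one single-ROI trial spanning the baseline interval.

    ERD/S(f, t) = (P(f, t) - B(f)) / B(f) with B(f) the mean power over the
    pre-stimulus baseline; by construction the baseline mean of each row
    is zero, and values are bounded below by -1.
    """
    trial = np.asarray(trial, dtype=float)
    if trial.ndim != 1:
        raise ValidationError("erds_map expects a single-ROI time series")
    times = t0 + np.arange(trial.size) / fs
    base = (times >= baseline[0] - 1e-9) & (times < baseline[1] - 1e-9)
    if not base.any():
        raise ValidationError("series does not cover the baseline interval")
    P = trial_power(trial, fs, freqs, n_cycles)[0]
    B = P[:, base].mean(axis=1)
    if np.any(B <= 0):
        raise DegenerateInputError("zero baseline power at some frequency")
    return TimeFreqMap(power=(P - B[:, None]) / B[:, None],
                       freqs=np.asarray(freqs, dtype=float), times=times)


def subject_condition_erds(
    datasets: Sequence[StimulusDataset], roi: int,
    freqs: np.ndarray = DEFAULT_FREQS, baseline: tuple[float, float] = (-0.5, 0.0),
) -> dict[int, np.ndarray]:
    """Trial-averaged ERD/S per subject and condition at one ROI.

    Returns {label: (n_subj, F, T)}.  ERD/S is computed per trial (mixed
    activity) and then averaged within subject/condition.
    """
    n_cycles = morlet_cycles(freqs)
    out: dict[int, list[np.ndarray]] = {0: [], 1: []}
    for ds in datasets:
        X, y = ds.stacked()
        times = ds.trials[0].times
        base = (times >= baseline[0] - 1e-9) & (times < baseline[1] - 1e-9)
        P = trial_power(X[:, roi, :], ds.fs, freqs, n_cycles)  # (M, F, T)
        B = P[:, :, base].mean(axis=2)
        if np.any(B <= 0):
            raise DegenerateInputError("zero baseline power at some frequency")
        E = (P - B[:, :, None]) / B[:, :, None]
        for label in (0, 1):
            if not np.any(y == label):
                raise ValidationError(f"no trials with label {label}")
            out[label].append(E[y == label].mean(axis=0))
    return {k: np.stack(v) for k, v in out.items()}


def coi_exclude_mask(
    freqs: np.ndarray, times: np.ndarray, n_cycles: np.ndarray | None = None,
) -> np.ndarray:
    """Cone-of-influence mask: True where wavelet edge effects dominate.

    The e-folding half-width sqrt(2) * sigma_t(f) with
    sigma_t = n_cycles / (2 pi f) is excluded at both epoch edges.
    """
    freqs = np.asarray(freqs, dtype=float)
    if n_cycles is None:
        n_cycles = morlet_cycles(freqs)
    width = np.sqrt(2.0) * n_cycles / (2.0 * np.pi * freqs)
    t0, t1 = times[0], times[-1]
    return ((times[None, :] - t0) < width[:, None]) | (
        (t1 - times[None, :]) < width[:, None]
    )


# -- cluster-based permutation tests ----------------------------------------


@dataclass
class ClusterResult:
    """Clusters, their masses, permutation p-values and the t map."""

    clusters: list[np.ndarray]  # boolean masks over the tested points
    masses: np.ndarray  # summed t per cluster (signed)
    pvalues: np.ndarray
    t_obs: np.ndarray
    threshold: float
    null_distribution: np.ndarray = field(repr=False, default=None)
    alpha: float = 0.05

    @property
    def significant(self) -> list[np.ndarray]:
        return [c for c, p in zip(self.clusters, self.pvalues) if p < self.alpha]

    @property
    def significant_masses(self) -> np.ndarray:
        return self.masses[self.pvalues < self.alpha]


def _paired_t_maps(signs: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Paired t maps for all sign-flip permutations, vectorized.

    The per-point sum of squares is flip-invariant, so every permutation's
    t map follows from a single (P, n_subj) x (n_subj, n_points) product.
    """
    n = D.shape[0]
    ss = (D * D).sum(axis=0)  # invariant under sign flips
    m = signs @ D / n
    var = (ss - n * m * m) / (n - 1)
    var = np.maximum(var, 1e-300)
    return m / np.sqrt(var / n)


def _observed_clusters(t_obs: np.ndarray, thr: float, adjacency: str):
    if adjacency == "1d":
        structure = np.ones(3, dtype=bool)
        label = lambda mask: ndimage.label(mask, structure=structure)
    else:  # 2-D lattice, 4-neighbour connectivity
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
        label = lambda mask: ndimage.label(mask, structure=structure)
    clusters, masses = [], []
    for sign in (1.0, -1.0):
        lab, n_lab = label(sign * t_obs > thr)
        for k in range(1, n_lab + 1):
            mask = lab == k
            clusters.append(mask)
            masses.append(float(t_obs[mask].sum()))
    return clusters, np.asarray(masses)


def _null_max_masses(t_perm: np.ndarray, thr: float, shape, adjacency: str) -> np.ndarray:
    if adjacency == "1d":
        return max_cluster_mass_rows(t_perm, thr)
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    out = np.zeros(t_perm.shape[0])
    for p in range(t_perm.shape[0]):
        tp = t_perm[p].reshape(shape)
        best = 0.0
        for sign in (1.0, -1.0):
            lab, n_lab = ndimage.label(sign * tp > thr, structure=structure)
            if n_lab:
                sums = ndimage.sum_labels(sign * tp, lab, index=np.arange(1, n_lab + 1))
                best = max(best, float(sums.max()))
        out[p] = best
    return out


def _cluster_test(
    cond_a: np.ndarray, cond_b: np.ndarray, adjacency: str,
    n_perm: int, alpha: float, seed: int | None,
    exclude: np.ndarray | None, threshold: float | None,
) -> ClusterResult:
    A = np.asarray(cond_a, dtype=float)
    B = np.asarray(cond_b, dtype=float)
    if A.shape != B.shape:
        raise ValidationError(f"condition shapes differ: {A.shape} vs {B.shape}")
    n = A.shape[0]
    if n < 5:
        raise ValidationError("cluster test needs at least 5 subjects")
    D = (A - B).reshape(n, -1)
    shape = A.shape[1:]
    if threshold is None:
        threshold = float(t_dist.ppf(1.0 - alpha / 2.0, df=n - 1))

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    signs[0] = 1.0  # identity permutation included
    t_all = _paired_t_maps(signs, D)
    if exclude is not None:
        excl = np.asarray(exclude, dtype=bool).reshape(-1)
        t_all[:, excl] = 0.0
    t_obs = t_all[0].reshape(shape)

    clusters, masses = _observed_clusters(t_obs, threshold, adjacency)
    null = _null_max_masses(t_all, threshold, shape, adjacency)
    pvals = np.array([float(np.mean(null >= abs(m))) for m in masses])
    return ClusterResult(clusters=clusters, masses=masses, pvalues=pvals,
                         t_obs=t_obs, threshold=threshold,
                         null_distribution=null, alpha=alpha)


def cluster_test_time(
    cond_a: np.ndarray, cond_b: np.ndarray, n_perm: int = 5000,
    alpha: float = 0.05, seed: int | None = 0,
    exclude: np.ndarray | None = None, threshold: float | None = None,
) -> ClusterResult:
    """Paired cluster permutation test on (n_subjects, n_times) ERPs.

    Cluster-forming threshold defaults to the two-tailed parametric t
    critical value at ``alpha`` with df = n - 1; the null distribution is
    the maximal cluster mass over subject-wise sign flips of the paired
    differences (the identity flip is included as the first permutation).
    """
    if np.asarray(cond_a).ndim != 2:
        raise ValidationError("cluster_test_time expects (n_subjects, n_times)")
    return _cluster_test(cond_a, cond_b, "1d", n_perm, alpha, seed, exclude, threshold)


def cluster_test_timefreq(
    cond_a: np.ndarray, cond_b: np.ndarray, n_perm: int = 5000,
    alpha: float = 0.05, seed: int | None = 0,
    exclude: np.ndarray | None = None, threshold: float | None = None,
) -> ClusterResult:
    """Paired cluster permutation test on (n_subjects, n_freqs, n_times)
    ERD/S maps with 4-neighbour adjacency across the (f, t) lattice.

    Pass ``exclude`` (e.g. a cone-of-influence mask) to drop edge-
    contaminated points from cluster formation.
    """
    if np.asarray(cond_a).ndim != 3:
        raise ValidationError(
            "cluster_test_timefreq expects (n_subjects, n_freqs, n_times)"
        )
    return _cluster_test(cond_a, cond_b, "2d", n_perm, alpha, seed, exclude, threshold)
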