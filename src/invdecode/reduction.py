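"""Reduction of source-level activity to the canonical decoder input.

Pipeline per trial: anti-aliased resampling to 200 Hz, cropping to
[-0.5, 0.5) s around stimulus onset, per-ROI first-principal-component
extraction with a polarity rule for vertex-level data, and train-statistics
standardization.  The decoder consumes the post-stimulus block [0, 0.5) s:
a 68 x 100 matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.signal import resample_poly
from sklearn.decomposition import PCA

from .datatypes import StimulusDataset, TrialMatrix, ValidationError
from .datatypes import assemble_stimulus_dataset  # noqa: F401  (re-export)
from .simulate import VertexBundle


class DegenerateInputError(ValueError):
    """Raised for zero-variance inputs that admit no meaningful reduction."""


def resample_and_crop(
    signal: np.ndarray,
    fs_in: float,
    t0: float,
    fs_out: float = 200.0,
    window: tuple[float, float] = (-0.5, 0.5),
) -> tuple[np.ndarray, float]:
    """Resample a multichannel series and crop it to a half-open time window.

    Resampling uses a polyphase FIR anti-aliasing filter (linear phase,
    group delay compensated), so sample ``k`` of the output corresponds to
    time ``t0 + k / fs_out``.  The crop is half-open ``[t_a, t_b)``: the
    output has exactly ``(t_b - t_a) * fs_out`` samples and stimulus onset
    (t = 0) is the first sample of the post-stimulus block.

    Returns ``(cropped, t_a)``.
    """
    x = np.atleast_2d(np.asarray(signal, dtype=float))
    if fs_out > fs_in:
        raise ValidationError(f"fs_out={fs_out} exceeds fs_in={fs_in}")
    if fs_out != fs_in:
        frac = Fraction(fs_out / fs_in).limit_denominator(1000)
        x = resample_poly(x, frac.numerator, frac.denominator, axis=-1)
    t_a, t_b = window
    n_out = x.shape[-1]
    k_a = int(round((t_a - t0) * fs_out))
    n_keep = int(round((t_b - t_a) * fs_out))
    if k_a < 0 or k_a + n_keep > n_out:
        raise ValidationError(
            f"crop window [{t_a}, {t_b}) outside signal span starting at {t0}"
        )
    return x[..., k_a : k_a + n_keep], t_a


def roi_first_component(bundle: VertexBundle) -> np.ndarray:
    """Reduce a vertex bundle to its first principal component time course.

    PCA is computed per trial with the 3*N_r vertex signals as features and
    time samples as observations (features mean-centered).  The inherent
    sign ambiguity of the component is removed by requiring that its
    extremum (sample of largest absolute value) has the same polarity as
    the extremum of the centered vertex signal with the largest absolute
    loading on the component.  Pinning the sign to the dominant feature
    makes the output equivariant under a global sign flip of the bundle
    (the output flips with the data) and independent of the SVD backend's
    internal sign convention.
    """
    X = bundle.signals  # (features, T)
    if X.shape[1] < 2:
        raise ValidationError("need at least 2 time samples for PCA")
    centered = X - X.mean(axis=1, keepdims=True)
    if not np.any(centered):
        raise DegenerateInputError("zero-variance vertex bundle")
    pca = PCA(n_components=1)
    scores = pca.fit_transform(centered.T)[:, 0]  # (T,)
    loadings = pca.components_[0]  # (features,)
    f_star = centered[np.argmax(np.abs(loadings))]
    s_score = np.sign(scores[np.argmax(np.abs(scores))])
    s_feat = np.sign(f_star[np.argmax(np.abs(f_star))])
    if s_score != s_feat:
        scores = -scores
    return scores


@dataclass(frozen=True)
class Standardizer:
    """Affine transform fitted on training trials: x -> (x - mu) / sd.

    By default ``mu`` and ``sd`` are scalars over all entries of all
    training trials; with per-ROI fitting they are length-68 columns.
    """

    mu: np.ndarray
    sd: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mu) / self.sd

    @classmethod
    def fit(cls, train: np.ndarray, per_roi: bool = False) -> "Standardizer":
        """Fit on an (M, R, T) stack of training trials."""
        if train.size == 0:
            raise ValidationError("empty training set")
        if per_roi:
            mu = train.mean(axis=(0, 2), keepdims=True)[0]
            sd = train.std(axis=(0, 2), keepdims=True)[0]
        else:
            mu = np.asarray(train.mean())
            sd = np.asarray(train.std())
        if np.any(sd == 0):
            raise DegenerateInputError("zero training variance")
        return cls(mu=mu, sd=sd)


def standardize_split(
    train: np.ndarray,
    val: np.ndarray | None = None,
    test: np.ndarray | None = None,
    per_roi: bool = False,
):
    """Standardize train/val/test stacks using training statistics only.

    Returns ``(train_z, val_z, test_z, scaler)``; val/test pass through as
    ``None`` when absent.  The same affine transform (train mean/SD) is
    applied to every set, so no test statistics leak into the inputs.
    """
    scaler = Standardizer.fit(np.asarray(train, dtype=float), per_roi=per_roi)
    out = [scaler.transform(np.asarray(s, dtype=float)) if s is not None else None
           for s in (train, val, test)]
    return (*out, scaler)


def decoder_view(trial: TrialMatrix) -> np.ndarray:
    """Extract the 68 x 100 post-stimulus block [0, 0.5) s from a trial."""
    fs = trial.fs
    k0 = int(round((0.0 - trial.t0) * fs))
    k1 = k0 + int(round(0.5 * fs))
    if fs != 200.0 or k0 < 0 or k1 > trial.X.shape[1]:
        raise ValidationError(
            "decoder input requires a 200 Hz trial covering [0, 0.5) s; "
            "run resample_and_crop first"
        )
    return trial.X[:, k0:k1]


def reduce_trial(trial: TrialMatrix, fs_out: float = 200.0,
                 window: tuple[float, float] = (-0.5, 0.5)) -> TrialMatrix:
    """Resample and crop one ROI-level trial to the canonical epoch."""
    X, t_a = resample_and_crop(trial.X, trial.fs, trial.t0, fs_out, window)
    return TrialMatrix(X=X, y=trial.y, subject=trial.subject,
                       stimulus=trial.stimulus, fs=fs_out, t0=t_a)


def reduce_dataset(ds: StimulusDataset, **kw) -> StimulusDataset:
    return StimulusDataset(trials=[reduce_trial(tr, **kw) for tr in ds.trials],
                           subject=ds.subject, stimulus=ds.stimulus)


def reduce_cohort(cohort: dict[str, list[StimulusDataset]], **kw) -> dict[str, list[StimulusDataset]]:
    """Reduce every dataset of a cohort to 200 Hz, [-0.5, 0.5) s epochs."""
    return {stim: [reduce_dataset(ds, **kw) for ds in dss] for stim, dss in cohort.items()}


def dataset_decoder_arrays(ds: StimulusDataset) -> tuple[np.ndarray, np.ndarray]:
    """Stack a dataset's decoder inputs: (M, 68, 100) and labels (M,)."""
    X = np.stack([decoder_view(tr) for tr in ds.trials])
    y = np.array([tr.y for tr in ds.trials], dtype=int)
    return X, y
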