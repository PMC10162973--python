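"""Core containers: single-trial ROI activity and per-subject datasets.

A :class:`TrialMatrix` holds one trial's ROI x time activity together with
its orientation label; a :class:`StimulusDataset` collects all trials of one
subject for one stimulus type (both orientations).  These are the units the
decoder, the explanation stage and the signature analyses consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .atlas import N_ROIS

#: Orientation label codes.
UPRIGHT, INVERTED = 0, 1
LABELS = {"upright": UPRIGHT, "inverted": INVERTED}
STIMULI = ("face", "body", "house")


class ValidationError(ValueError):
    """Raised when trial/dataset contracts are violated."""


@dataclass
class TrialMatrix:
    """One trial: activity of all ROIs over time.

    Parameters
    ----------
    X : ndarray, shape (R, T)
        ROI activity, rows ordered as :data:`invdecode.atlas.DK_ROI_NAMES`.
    y : int
        Orientation label, 0 = upright, 1 = inverted.
    subject : int
        Subject index.
    stimulus : str
        One of ``'face' | 'body' | 'house'``.
    fs : float
        Sampling rate in Hz.
    t0 : float
        Time (s) of the first sample relative to stimulus onset.
    """

    X: np.ndarray
    y: int
    subject: int = 0
    stimulus: str = "face"
    fs: float = 200.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValidationError(f"trial matrix must be 2-D, got shape {self.X.shape}")
        if self.X.shape[0] != N_ROIS:
            raise ValidationError(
                f"trial matrix must have {N_ROIS} ROI rows, got {self.X.shape[0]}"
            )
        if not np.all(np.isfinite(self.X)):
            raise ValidationError("trial matrix contains non-finite values")
        if self.y not in (UPRIGHT, INVERTED):
            raise ValidationError(f"label must be 0 (upright) or 1 (inverted), got {self.y}")
        if self.stimulus not in STIMULI:
            raise ValidationError(f"unknown stimulus {self.stimulus!r}")

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds: ``t0 + k / fs``."""
        return self.t0 + np.arange(self.X.shape[1]) / self.fs

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape


@dataclass
class StimulusDataset:
    """All trials of one subject for one stimulus type, both orientations."""

    trials: list[TrialMatrix] = field(default_factory=list)
    subject: int = 0
    stimulus: str = "face"

    def __post_init__(self) -> None:
        if not self.trials:
            raise ValidationError("a StimulusDataset needs at least one trial")
        ref = self.trials[0]
        for tr in self.trials:
            if tr.subject != self.subject or tr.stimulus != self.stimulus:
                raise ValidationError("trial subject/stimulus mismatch with dataset")
            if tr.shape != ref.shape or tr.fs != ref.fs:
                raise ValidationError(
                    f"inconsistent trial shape/rate: {tr.shape}@{tr.fs} vs {ref.shape}@{ref.fs}"
                )

    @property
    def M(self) -> int:
        """Number of trials."""
        return len(self.trials)

    @property
    def fs(self) -> float:
        return self.trials[0].fs

    @property
    def t0(self) -> float:
        return self.trials[0].t0

    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(X, y)`` with X of shape (M, R, T) and y of shape (M,)."""
        X = np.stack([tr.X for tr in self.trials])
        y = np.array([tr.y for tr in self.trials], dtype=int)
        return X, y

    def select(self, label: int) -> list[TrialMatrix]:
        return [tr for tr in self.trials if tr.y == label]


def assemble_stimulus_dataset(
    trials: Sequence[np.ndarray] | Iterable[np.ndarray],
    labels: Sequence[int],
    subject: int,
    stimulus: str,
    fs: float = 200.0,
    t0: float = 0.0,
) -> StimulusDataset:
    """Bundle raw trial matrices and labels into a validated dataset.

    Rejects empty inputs, length mismatches and inconsistent trial shapes.
    """
    trials = list(trials)
    labels = list(labels)
    if not trials:
        raise ValidationError("empty trial collection")
    if len(trials) != len(labels):
        raise ValidationError(f"{len(trials)} trials but {len(labels)} labels")
    tms = [
        TrialMatrix(X=np.asarray(X), y=int(y), subject=subject, stimulus=stimulus, fs=fs, t0=t0)
        for X, y in zip(trials, labels)
    ]
    return StimulusDataset(trials=tms, subject=subject, stimulus=stimulus)
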