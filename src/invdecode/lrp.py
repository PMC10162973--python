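"""Epsilon-rule layer-wise relevance propagation for the trained decoder.

The pre-softmax class score of the inverted condition, o_1, is decomposed
backward through the network onto the 68 x 100 input, yielding a signed
relevance map: positive values mark input samples that pushed the decision
toward "inverted".  Per-trial maps of the inverted test trials are averaged
within each cross-validation fold (over trials, then over the random
initializations), and each ROI's fold-level *inversion relevance score* is
the maximum signed relevance inside the 150-200 ms window where the
N170 component is modulated by stimulus inversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .atlas import DK_ROI_NAMES
from .datatypes import TrialMatrix, ValidationError
from .decoder import DecoderModel


@dataclass(frozen=True)
class LRPConfig:
    """Settings of the epsilon-rule backward pass."""

    epsilon: float = 1e-6  # stabilizer added to each layer's denominators
    target_class: int = 1  # 1 = inverted

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValidationError("epsilon must be > 0")


@dataclass
class RelevanceMap:
    """Signed relevance with the shape of the explained input."""

    values: np.ndarray  # (R, T)
    fs: float = 200.0
    t0: float = 0.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("relevance map contains non-finite values")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.shape[1]) / self.fs


@dataclass
class RelevanceScoreTable:
    """Per-fold, per-ROI inversion relevance scores RS_{i, l}."""

    scores: pd.DataFrame  # folds x ROIs
    window: tuple[float, float] = (0.150, 0.200)

    @property
    def n_folds(self) -> int:
        return len(self.scores)

    def fold_mean(self) -> pd.Series:
        return self.scores.mean(axis=0)


def lrp_explain_trial(
    model: DecoderModel, X: TrialMatrix | np.ndarray, cfg: LRPConfig | None = None
) -> RelevanceMap:
    """Explain one (standardized) trial with the epsilon rule.

    The input must be standardized exactly as at training time.  Returns a
    signed map with the trial's shape; its sum approximates the propagated
    class score o_1 (biases and batch-norm shifts absorb the difference).
    """
    cfg = cfg or LRPConfig()
    x = X.X if isinstance(X, TrialMatrix) else np.asarray(X, dtype=float)
    if x.shape != (model.config.n_rois, model.config.n_times):
        raise ValidationError(
            f"input shape {x.shape} does not match model input "
            f"({model.config.n_rois}, {model.config.n_times})"
        )
    R = model.net.lrp(x[None], epsilon=cfg.epsilon, target=cfg.target_class)[0]
    return RelevanceMap(values=R, provenance={"target_class": cfg.target_class})


def _lrp_batch(model: DecoderModel, X: np.ndarray, cfg: LRPConfig) -> np.ndarray:
    return model.net.lrp(X, epsilon=cfg.epsilon, target=cfg.target_class)


def fold_relevance_map(
    models: Sequence[DecoderModel],
    inverted_test_trials: np.ndarray,
    cfg: LRPConfig | None = None,
) -> RelevanceMap:
    """Average per-trial maps over trials, then over seed models.

    ``inverted_test_trials`` is the (N, R, T) stack of the fold's inverted
    test trials, standardized with the fold's training statistics.
    """
    cfg = cfg or LRPConfig()
    X = np.asarray(inverted_test_trials, dtype=float)
    if X.ndim != 3 or X.shape[0] == 0:
        raise ValidationError("need a non-empty (N, R, T) stack of inverted trials")
    per_seed = np.stack([_lrp_batch(m, X, cfg).mean(axis=0) for m in models])
    return RelevanceMap(values=per_seed.mean(axis=0),
                        provenance={"n_trials": X.shape[0], "n_seeds": len(models)})


def relevance_scores(
    fold_maps: Sequence[RelevanceMap],
    window: tuple[float, float] = (0.150, 0.200),
    roi_names: Sequence[str] = DK_ROI_NAMES,
) -> RelevanceScoreTable:
    """Extract RS_{i, l}: per fold and ROI, the maximum signed relevance
    within the (inclusive) time window."""
    if not fold_maps:
        raise ValidationError("no fold maps given")
    rows = []
    for fm in fold_maps:
        t = fm.times
        sel = (t >= window[0] - 1e-9) & (t <= window[1] + 1e-9)
        if not sel.any():
            raise ValidationError(
                f"window {window} outside the epoch [{t[0]}, {t[-1]}]"
            )
        rows.append(fm.values[:, sel].max(axis=1))
    scores = pd.DataFrame(np.stack(rows), columns=list(roi_names))
    scores.index.name = "fold"
    return RelevanceScoreTable(scores=scores, window=window)


def explain_protocol(loso_result, cfg: LRPConfig | None = None,
                     window: tuple[float, float] = (0.150, 0.200)) -> RelevanceScoreTable:
    """Fold maps + relevance scores for a finished LOSO protocol."""
    cfg = cfg or LRPConfig()
    maps = []
    for fold in loso_result.folds:
        if fold.test_inverted is None or not fold.models:
            raise ValidationError(
                "LOSO result lacks stored models/test trials; rerun the "
                "protocol with keep_models=True"
            )
        maps.append(fold_relevance_map(fold.models, fold.test_inverted, cfg))
    return relevance_scores(maps, window=window)
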