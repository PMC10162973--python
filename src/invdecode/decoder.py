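"""The compact CNN orientation decoder and its cross-validation protocol.

One decoder per stimulus type discriminates upright vs. inverted trials
from the 68 x 100 ROI-level input.  The architecture is deliberately small
(1502 trainable parameters with the default configuration) to suit the
few-hundred-trial training sets of a leave-one-subject-out (LOSO) scheme:

    temporal convolution (4 kernels, 1 x 33, same padding, no bias)
    -> batch norm -> depthwise spatial convolution (68 x 1 kernels,
    depth multiplier 2 => 8 feature maps, no bias) -> batch norm -> ReLU
    -> average pooling (factor 2 in time) -> dropout (p = 0.25)
    -> dense layer (2 units) -> softmax

The LOSO protocol holds each subject out in turn, trains the decoder under
several random initializations on the remaining subjects (10% of training
trials held out for early stopping), and averages test metrics over seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from ._ensemble import EnsembleCNN, fit_ensemble, make_windows
from ._net import CompactCNN, softmax
from .datatypes import INVERTED, StimulusDataset, ValidationError
from .reduction import Standardizer, dataset_decoder_arrays, standardize_split


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class DecoderConfig:
    """Architecture hyperparameters of the compact CNN."""

    n_temporal_kernels: int = 4
    temporal_kernel_len: int = 33
    spatial_depth_multiplier: int = 2
    pool_factor: int = 2
    dropout_p: float = 0.25
    n_outputs: int = 2
    n_rois: int = 68
    n_times: int = 100

    def __post_init__(self) -> None:
        if self.n_times % self.pool_factor:
            raise ConfigurationError(
                f"pool factor {self.pool_factor} must divide T={self.n_times}"
            )

    @property
    def n_spatial_kernels(self) -> int:
        return self.n_temporal_kernels * self.spatial_depth_multiplier

    def expected_parameter_count(self) -> int:
        """Closed-form count of learnable scalars, layer by layer."""
        k, L = self.n_temporal_kernels, self.temporal_kernel_len
        c = self.n_spatial_kernels
        t_pooled = self.n_times // self.pool_factor
        return (
            k * L              # temporal conv weights (no bias)
            + 2 * k            # batch-norm scale + shift
            + c * self.n_rois  # depthwise spatial conv weights (no bias)
            + 2 * c            # batch-norm scale + shift
            + self.n_outputs * c * t_pooled + self.n_outputs  # dense + bias
        )


@dataclass(frozen=True)
class TrainingHyper:
    """Optimizer settings: adaptive-moment gradient descent (Adam) with
    early stopping on validation loss."""

    lr: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 500
    patience: int = 20
    val_fraction: float = 0.1

    @classmethod
    def desk_scale(cls) -> "TrainingHyper":
        """Reduced-compute settings for small synthetic cohorts: a larger
        step size compensates for the few optimization steps per epoch that
        a ~200-trial training set provides."""
        return cls(lr=3e-3, max_epochs=60, patience=8)


@dataclass
class Prediction:
    """Class scores o_k and the corresponding softmax probabilities."""

    class_scores: np.ndarray  # (N, 2)
    probabilities: np.ndarray  # (N, 2)


class DecoderModel:
    """A (possibly trained) decoder: parameters theta + config + metadata."""

    def __init__(self, config: DecoderConfig, seed: int = 0,
                 net: CompactCNN | None = None):
        self.config = config
        self.net = net if net is not None else CompactCNN(
            n_rois=config.n_rois, n_times=config.n_times,
            n_temporal=config.n_temporal_kernels,
            kernel_len=config.temporal_kernel_len,
            multiplier=config.spatial_depth_multiplier,
            pool=config.pool_factor, dropout_p=config.dropout_p,
            n_out=config.n_outputs, seed=seed,
        )
        self.training_meta: dict = {"seed": seed, "epochs_run": 0, "fold": None}

    def _check(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        if X.shape[1:] != (self.config.n_rois, self.config.n_times):
            raise ValidationError(
                f"expected trials of shape ({self.config.n_rois}, "
                f"{self.config.n_times}), got {X.shape[1:]}"
            )
        return X

    def predict(self, X: np.ndarray) -> Prediction:
        X = self._check(X)
        o = self.net.forward(X, training=False)
        return Prediction(class_scores=o, probabilities=softmax(o))

    def predict_labels(self, X: np.ndarray) -> np.ndarray:
        return self.predict(X).class_scores.argmax(axis=1)


def build_decoder(config: DecoderConfig | None = None, seed: int = 0) -> DecoderModel:
    """Instantiate the decoder with reproducible initialization."""
    return DecoderModel(config or DecoderConfig(), seed=seed)


def count_trainable_parameters(model: DecoderModel) -> int:
    """Exact count of learnable scalars in the built network."""
    return model.net.count_parameters()


def train_decoder(
    train: tuple[np.ndarray, np.ndarray],
    val: tuple[np.ndarray, np.ndarray],
    seed: int = 0,
    hyper: TrainingHyper | None = None,
    config: DecoderConfig | None = None,
) -> DecoderModel:
    """Train a single decoder on standardized inputs.

    ``train`` / ``val`` are ``(X, y)`` with X of shape (N, R, T).  Training
    minimizes cross-entropy and restores the parameters of the best
    validation-loss epoch.  Deterministic given ``seed`` and ``hyper``.
    """
    hyper = hyper or TrainingHyper()
    config = config or DecoderConfig()
    Xt, yt = train
    Xv, yv = val
    if len(Xv) == 0:
        raise ConfigurationError("empty validation set")
    ens = EnsembleCNN(
        seeds=[seed], n_rois=config.n_rois, n_times=config.n_times,
        n_temporal=config.n_temporal_kernels, kernel_len=config.temporal_kernel_len,
        multiplier=config.spatial_depth_multiplier, pool=config.pool_factor,
        dropout_p=config.dropout_p, n_out=config.n_outputs,
    )
    hist = fit_ensemble(ens, Xt, yt, Xv, yv, lr=hyper.lr,
                        batch_size=hyper.batch_size, max_epochs=hyper.max_epochs,
                        patience=hyper.patience, data_seed=seed)
    model = DecoderModel(config, seed=seed, net=ens.extract(0))
    model.training_meta.update(seed=seed, epochs_run=int(hist["epochs_run"]),
                               best_epoch=int(hist["best_epoch"][0]))
    return model


def evaluate_decoder(model: DecoderModel, test: tuple[np.ndarray, np.ndarray]):
    """Confusion matrix (rows = true, cols = predicted) and accuracy."""
    Xte, yte = test
    pred = model.predict_labels(Xte)
    n_c = model.config.n_outputs
    cm = np.zeros((n_c, n_c), dtype=int)
    for t, p in zip(np.asarray(yte, dtype=int), pred):
        cm[t, p] += 1
    acc = float(np.trace(cm) / cm.sum())
    return cm, acc


@dataclass
class FoldResult:
    """Metrics and artifacts of one leave-one-subject-out fold."""

    subject: int
    stimulus: str
    seeds: list[int]
    models: list[DecoderModel] = field(repr=False, default_factory=list)
    scaler: Standardizer | None = field(repr=False, default=None)
    seed_accuracies: np.ndarray | None = None
    confusion: np.ndarray | None = None  # mean over seeds
    accuracy: float = np.nan  # mean over seeds
    test_inverted: np.ndarray | None = field(repr=False, default=None)


@dataclass
class LOSOResult:
    """All folds of the protocol for one stimulus type."""

    stimulus: str
    folds: list[FoldResult]

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([f.accuracy for f in self.folds])

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.folds:
            for seed, acc in zip(f.seeds, f.seed_accuracies):
                rows.append(dict(stimulus=f.stimulus, subject=f.subject,
                                 seed=seed, accuracy=acc))
        return pd.DataFrame(rows)


def _val_split_seed(data_seed: int, fold: int) -> int:
    return int(np.random.SeedSequence([data_seed, fold]).generate_state(1)[0] % (2**31))


def run_loso_protocol(
    datasets: Sequence[StimulusDataset],
    n_seeds: int = 10,
    seeds: Sequence[int] | None = None,
    hyper: TrainingHyper | None = None,
    config: DecoderConfig | None = None,
    data_seed: int = 0,
    dry_run: bool = False,
    keep_models: bool = True,
):
    """Leave-one-subject-out cross-validation with multi-seed training.

    For every held-out subject the decoder is trained once per seed on the
    pooled trials of all other subjects (with a stratified 10% validation
    split) and evaluated on the held-out subject; metrics are averaged
    across seeds.  With ``dry_run=True`` the planned training runs are
    enumerated without fitting.
    """
    if len(datasets) < 2:
        raise ConfigurationError("LOSO needs at least 2 subjects")
    seeds = list(seeds) if seeds is not None else list(range(n_seeds))
    hyper = hyper or TrainingHyper()
    config = config or DecoderConfig()
    stimulus = datasets[0].stimulus

    if dry_run:
        return [
            dict(stimulus=stimulus, held_out_subject=ds.subject, seed=seed)
            for ds in datasets
            for seed in seeds
        ]

    arrays = [dataset_decoder_arrays(ds) for ds in datasets]
    folds: list[FoldResult] = []
    for i, ds in enumerate(datasets):
        X_pool = np.concatenate([arrays[j][0] for j in range(len(datasets)) if j != i])
        y_pool = np.concatenate([arrays[j][1] for j in range(len(datasets)) if j != i])
        Xte, yte = arrays[i]
        Xt, Xv, yt, yv = train_test_split(
            X_pool, y_pool, test_size=hyper.val_fraction, stratify=y_pool,
            random_state=_val_split_seed(data_seed, i),
        )
        Xt, Xv, Xte_z, scaler = standardize_split(Xt, Xv, Xte)

        ens = EnsembleCNN(
            seeds=seeds, n_rois=config.n_rois, n_times=config.n_times,
            n_temporal=config.n_temporal_kernels,
            kernel_len=config.temporal_kernel_len,
            multiplier=config.spatial_depth_multiplier, pool=config.pool_factor,
            dropout_p=config.dropout_p, n_out=config.n_outputs,
        )
        fit_ensemble(ens, Xt, yt, Xv, yv, lr=hyper.lr, batch_size=hyper.batch_size,
                     max_epochs=hyper.max_epochs, patience=hyper.patience,
                     data_seed=_val_split_seed(data_seed, 10_000 + i))

        o = ens.forward(make_windows(Xte_z, ens.L, ens.dtype), training=False)
        pred = o.argmax(axis=2)  # (N, S)
        n_c = config.n_outputs
        cms = np.zeros((len(seeds), n_c, n_c))
        for s in range(len(seeds)):
            for t, p in zip(yte, pred[:, s]):
                cms[s, t, p] += 1
        seed_acc = np.array([np.trace(cms[s]) / cms[s].sum() for s in range(len(seeds))])

        models = []
        if keep_models:
            for s, seed in enumerate(seeds):
                m = DecoderModel(config, seed=seed, net=ens.extract(s))
                m.training_meta.update(fold=i, seed=seed)
                models.append(m)
        folds.append(FoldResult(
            subject=ds.subject, stimulus=stimulus, seeds=seeds, models=models,
            scaler=scaler, seed_accuracies=seed_acc, confusion=cms.mean(axis=0),
            accuracy=float(seed_acc.mean()),
            test_inverted=Xte_z[yte == INVERTED] if keep_models else None,
        ))
    return LOSOResult(stimulus=stimulus, folds=folds)


def compare_stimulus_accuracies(
    acc_face: np.ndarray, acc_body: np.ndarray, acc_house: np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise Wilcoxon signed-rank tests between stimulus accuracies.

    All three pairwise comparisons are run and Bonferroni-corrected by a
    factor 3; each stimulus is additionally tested against the 0.5 chance
    level (one-sample signed-rank on accuracy - 0.5, corrected within its
    own 3-test family).
    """
    from .selection import wilcoxon_signed_rank

    accs = {"face": np.asarray(acc_face, dtype=float),
            "body": np.asarray(acc_body, dtype=float),
            "house": np.asarray(acc_house, dtype=float)}
    n = {k: len(v) for k, v in accs.items()}
    if len(set(n.values())) != 1:
        raise ValidationError(f"fold-accuracy vectors differ in length: {n}")

    rows = []
    pairs = [("face", "body"), ("face", "house"), ("body", "house")]
    for a, b in pairs:
        res = wilcoxon_signed_rank(accs[a], accs[b], alternative="two-sided")
        rows.append(dict(
            test=f"{a} vs {b}", kind="pairwise", statistic=res.statistic,
            p_raw=res.pvalue, p_corrected=min(1.0, res.pvalue * len(pairs)),
            direction=np.sign(np.median(accs[a] - accs[b])),
        ))
    for k, v in accs.items():
        res = wilcoxon_signed_rank(v - 0.5, alternative="greater")
        rows.append(dict(
            test=f"{k} vs chance", kind="vs-chance", statistic=res.statistic,
            p_raw=res.pvalue, p_corrected=min(1.0, res.pvalue * 3),
            direction=np.sign(np.median(v - 0.5)),
        ))
    df = pd.DataFrame(rows)
    df["significant"] = df["p_corrected"] < alpha
    return df
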