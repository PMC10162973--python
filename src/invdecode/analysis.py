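"""Model/Results interface for the full inversion-decoding analysis.

:class:`InversionAnalysis` is built from a cohort of per-subject stimulus
datasets; :meth:`~InversionAnalysis.fit` runs the complete protocol --
leave-one-subject-out decoding per stimulus type, relevance propagation,
score extraction and the three-criterion ROI selection -- and returns an
:class:`InversionAnalysisResults` holding accuracies, statistical
comparisons, relevance tables and selections, with a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import StimulusDataset, ValidationError
from .decoder import (DecoderConfig, LOSOResult, TrainingHyper,
                      compare_stimulus_accuracies, run_loso_protocol)
from .lrp import LRPConfig, RelevanceScoreTable, explain_protocol
from .selection import SelectionResult, select_relevant_rois

SOCIAL_STIMULI = ("face", "body")
CONTROL_STIMULUS = "house"


class InversionAnalysis:
    """The end-to-end upright-vs-inverted decoding analysis of one cohort.

    Parameters
    ----------
    cohort : mapping stimulus -> list of StimulusDataset (one per subject)
        Reduced 200 Hz datasets whose trials cover the decoder window.
    seeds : random initializations per fold (the full protocol uses 10).
    hyper : optimizer settings; defaults to the reduced-compute
        configuration suited to small synthetic cohorts.
    """

    def __init__(
        self,
        cohort: Mapping[str, Sequence[StimulusDataset]],
        decoder_config: DecoderConfig | None = None,
        lrp_config: LRPConfig | None = None,
        seeds: Sequence[int] = (0, 1, 2),
        hyper: TrainingHyper | None = None,
        alpha: float = 0.05,
        relevance_window: tuple[float, float] = (0.150, 0.200),
    ):
        if not cohort:
            raise ValidationError("empty cohort")
        n_subj = {s: len(dss) for s, dss in cohort.items()}
        if len(set(n_subj.values())) != 1:
            raise ValidationError(f"subject counts differ across stimuli: {n_subj}")
        self.cohort = {s: list(dss) for s, dss in cohort.items()}
        self.decoder_config = decoder_config or DecoderConfig()
        self.lrp_config = lrp_config or LRPConfig()
        self.seeds = list(seeds)
        self.hyper = hyper or TrainingHyper.desk_scale()
        self.alpha = alpha
        self.relevance_window = relevance_window

    @property
    def n_subjects(self) -> int:
        return len(next(iter(self.cohort.values())))

    def dry_run(self) -> list[dict]:
        """Enumerate all planned training runs without fitting."""
        runs = []
        for stim, dss in self.cohort.items():
            runs.extend(run_loso_protocol(dss, seeds=self.seeds, dry_run=True))
        return runs

    def fit(self, data_seed: int = 0, progress: bool = False) -> "InversionAnalysisResults":
        loso: dict[str, LOSOResult] = {}
        relevance: dict[str, RelevanceScoreTable] = {}
        for stim, dss in self.cohort.items():
            if progress:
                print(f"[invdecode] LOSO protocol: {stim} "
                      f"({len(dss)} folds x {len(self.seeds)} seeds)")
            loso[stim] = run_loso_protocol(
                dss, seeds=self.seeds, hyper=self.hyper,
                config=self.decoder_config, data_seed=data_seed,
            )
            relevance[stim] = explain_protocol(
                loso[stim], self.lrp_config, window=self.relevance_window
            )

        selections: dict[str, SelectionResult] = {}
        if CONTROL_STIMULUS in relevance:
            for stim in SOCIAL_STIMULI:
                if stim not in relevance:
                    continue
                try:
                    selections[stim] = select_relevant_rois(
                        relevance[stim], relevance[CONTROL_STIMULUS], self.alpha
                    )
                except ValidationError as err:
                    import warnings

                    warnings.warn(f"ROI selection skipped for {stim}: {err}",
                                  stacklevel=2)

        comparisons = None
        if all(s in loso for s in ("face", "body", "house")):
            comparisons = compare_stimulus_accuracies(
                loso["face"].accuracies, loso["body"].accuracies,
                loso["house"].accuracies, alpha=self.alpha,
            )
        return InversionAnalysisResults(
            model=self, loso=loso, relevance=relevance,
            selections=selections, comparisons=comparisons,
        )


@dataclass
class InversionAnalysisResults:
    """Fitted-protocol results: accuracies, relevance, selections."""

    model: InversionAnalysis
    loso: dict[str, LOSOResult]
    relevance: dict[str, RelevanceScoreTable]
    selections: dict[str, SelectionResult]
    comparisons: pd.DataFrame | None = None

    @property
    def accuracies(self) -> pd.DataFrame:
        """Fold x stimulus table of seed-averaged decoding accuracies."""
        return pd.DataFrame({s: r.accuracies for s, r in self.loso.items()})

    def selected_rois(self, stimulus: str) -> list[str]:
        return self.selections[stimulus].selected if stimulus in self.selections else []

    def summary(self) -> str:
        lines = ["Inversion decoding analysis", "=" * 27]
        acc = self.accuracies
        lines.append(f"subjects (folds): {len(acc)}   seeds per fold: "
                     f"{len(self.model.seeds)}")
        lines.append("")
        lines.append("Decoding accuracy (mean +/- SEM across folds)")
        for stim in acc.columns:
            v = acc[stim].to_numpy()
            lines.append(f"  {stim:<6s} {v.mean():.3f} +/- {v.std(ddof=1)/np.sqrt(len(v)):.3f}")
        if self.comparisons is not None:
            lines.append("")
            lines.append("Accuracy comparisons (Wilcoxon signed-rank, Bonferroni x3)")
            for _, row in self.comparisons.iterrows():
                star = "*" if row.significant else " "
                lines.append(f"  {row.test:<16s} p_corr = {row.p_corrected:.4g} {star}")
        for stim, sel in self.selections.items():
            lines.append("")
            rois = ", ".join(sel.selected) if sel.selected else "(none)"
            lines.append(f"Most relevant ROIs ({stim} vs house): {rois}")
        return "\n".join(lines)

    # -- plotting -----------------------------------------------------------

    def plot_relevance(self, stimulus: str, ax=None):
        """Bar plot of fold-mean relevance scores, atlas order."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(12, 3))
        means = self.relevance[stimulus].fold_mean()
        sems = self.relevance[stimulus].scores.sem(axis=0)
        ax.bar(range(len(means)), means.to_numpy(), yerr=sems.to_numpy())
        ax.set_xticks(range(len(means)))
        ax.set_xticklabels(means.index, rotation=90, fontsize=5)
        ax.set_ylabel("inversion relevance score")
        ax.set_title(f"{stimulus}: fold-mean RS (150-200 ms)")
        return ax
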