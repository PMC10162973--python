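"""End-to-end pipeline orchestration with file artifacts and a manifest.

Stages: simulate -> reduce -> train (LOSO x seeds x stimuli) -> explain ->
select -> signatures.  Every stage writes its artifacts to the output
directory so stages can be rerun and inspected independently; a manifest
records the configuration, seeds, package versions and a content hash of
every produced file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import SOCIAL_STIMULI, InversionAnalysis
from .datatypes import STIMULI
from .decoder import DecoderConfig, TrainingHyper
from .io import load_cohort, save_cohort
from .lrp import LRPConfig
from .reduction import reduce_cohort
from .signatures import (cluster_test_time, cluster_test_timefreq,
                         coi_exclude_mask, condition_erps,
                         subject_condition_erds)
from .simulate import default_effects, generate_cohort
from .atlas import roi_index


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one pipeline run."""

    n_subjects: int = 8
    trials_per_condition: int = 16
    effects: dict = field(default_factory=default_effects)
    fs: float = 200.0
    seed: int = 0
    seeds: tuple = (0, 1, 2)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    hyper: TrainingHyper = field(default_factory=TrainingHyper.desk_scale)
    lrp: LRPConfig = field(default_factory=LRPConfig)
    alpha: float = 0.05
    n_perm: int = 5000
    outdir: str = "invdecode_output"

    @classmethod
    def full_protocol(cls, **kw) -> "PipelineConfig":
        """The full-size protocol: 23 subjects, 16 trials/condition,
        10 random initializations."""
        kw.setdefault("n_subjects", 23)
        kw.setdefault("seeds", tuple(range(10)))
        kw.setdefault("hyper", TrainingHyper())
        return cls(**kw)

    def to_json(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            if isinstance(o, tuple):
                return list(o)
            raise TypeError(f"not JSON-serializable: {o!r}")

        return json.dumps(dataclasses.asdict(self), default=enc, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class Pipeline:
    """Stage runner; every stage reads/writes files under ``cfg.outdir``."""

    def __init__(self, cfg: PipelineConfig):
        self.cfg = cfg
        self.outdir = Path(cfg.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self._timings: dict[str, float] = {}

    # individual stages ------------------------------------------------------

    def simulate(self) -> Path:
        cfg = self.cfg
        t0 = time.time()
        cohort = generate_cohort(cfg.n_subjects, cfg.trials_per_condition,
                                 cfg.effects, seed=cfg.seed, fs=cfg.fs)
        path = save_cohort(self.outdir / "cohort_raw.h5", cohort,
                           seed=cfg.seed, effects=cfg.effects)
        self._timings["simulate"] = time.time() - t0
        return path

    def reduce(self) -> Path:
        t0 = time.time()
        cohort = load_cohort(self.outdir / "cohort_raw.h5")
        reduced = reduce_cohort(cohort)
        path = save_cohort(self.outdir / "cohort_reduced.h5", reduced,
                           seed=self.cfg.seed)
        self._timings["reduce"] = time.time() - t0
        return path

    def analyse(self, progress: bool = True):
        """Train + explain + select in one pass (shares trained models)."""
        cfg = self.cfg
        t0 = time.time()
        reduced = load_cohort(self.outdir / "cohort_reduced.h5")
        model = InversionAnalysis(reduced, decoder_config=cfg.decoder,
                                  lrp_config=cfg.lrp, seeds=cfg.seeds,
                                  hyper=cfg.hyper, alpha=cfg.alpha)
        res = model.fit(data_seed=cfg.seed, progress=progress)

        for stim, loso in res.loso.items():
            loso.metrics_frame().to_csv(self.outdir / f"metrics_{stim}.csv", index=False)
        if res.comparisons is not None:
            res.comparisons.to_csv(self.outdir / "accuracy_comparisons.csv", index=False)
        for stim, rs in res.relevance.items():
            rs.scores.to_csv(self.outdir / f"relevance_scores_{stim}.csv")
        for stim, sel in res.selections.items():
            sel.report.to_csv(self.outdir / f"selection_{stim}.csv")
        (self.outdir / "summary.txt").write_text(res.summary() + "\n")
        self._timings["analyse"] = time.time() - t0
        return res

    def signatures(self, results=None) -> Path:
        """ERP and ERD/S characterization of the selected (or effect) ROIs."""
        cfg = self.cfg
        t0 = time.time()
        reduced = load_cohort(self.outdir / "cohort_reduced.h5")
        rois: list[str] = []
        if results is not None:
            for stim in SOCIAL_STIMULI:
                rois.extend(results.selected_rois(stim))
        if not rois:  # fall back to the generator's designated effect ROIs
            rois = list(cfg.effects[SOCIAL_STIMULI[0]].effect_rois)
        rois = sorted(set(rois))

        rows = []
        for stim in SOCIAL_STIMULI:
            if stim not in reduced:
                continue
            erps = condition_erps(reduced[stim])
            for roi in rois:
                ri = roi_index(roi)
                res_t = cluster_test_time(
                    erps[1][:, ri, :], erps[0][:, ri, :], n_perm=cfg.n_perm,
                    alpha=cfg.alpha, seed=cfg.seed,
                )
                times = reduced[stim][0].trials[0].times
                for mask, mass, p in zip(res_t.clusters, res_t.masses, res_t.pvalues):
                    rows.append(dict(stimulus=stim, roi=roi, domain="time",
                                     t_start=float(times[mask][0]),
                                     t_end=float(times[mask][-1]),
                                     mass=mass, p=p))
                erds = subject_condition_erds(reduced[stim], ri)
                freqs = np.arange(4.0, 41.0)
                post = times >= 0
                excl = coi_exclude_mask(freqs, times)[:, post]
                res_tf = cluster_test_timefreq(
                    erds[1][:, :, post], erds[0][:, :, post], n_perm=cfg.n_perm,
                    alpha=cfg.alpha, seed=cfg.seed, exclude=excl,
                )
                for mask, mass, p in zip(res_tf.clusters, res_tf.masses, res_tf.pvalues):
                    fsel = freqs[mask.any(axis=1)]
                    rows.append(dict(stimulus=stim, roi=roi, domain="time-frequency",
                                     f_min=float(fsel.min()), f_max=float(fsel.max()),
                                     mass=mass, p=p))
        pd.DataFrame(rows).to_csv(self.outdir / "signature_clusters.csv", index=False)
        self._timings["signatures"] = time.time() - t0
        return self.outdir / "signature_clusters.csv"

    def write_manifest(self) -> Path:
        files = sorted(p for p in self.outdir.iterdir() if p.is_file()
                       and p.name != "manifest.json")
        manifest = {
            "package_version": __version__,
            "config": json.loads(self.cfg.to_json()),
            "timings_s": {k: round(v, 3) for k, v in self._timings.items()},
            "files": {p.name: _sha256(p) for p in files},
        }
        path = self.outdir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return path


def run_pipeline(cfg: PipelineConfig, progress: bool = True):
    """Execute simulate -> reduce -> analyse -> signatures -> manifest."""
    pipe = Pipeline(cfg)
    pipe.simulate()
    pipe.reduce()
    res = pipe.analyse(progress=progress)
    pipe.signatures(res)
    pipe.write_manifest()
    return res
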