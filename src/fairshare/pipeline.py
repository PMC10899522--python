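"""End-to-end orchestration: simulate -> metrics -> fit -> compare -> PPC -> report.

A :class:`PipelineConfig` (YAML round-trippable) drives the full analysis on
either a simulated cohort pair or an existing trial-level CSV.  Every stage
writes its artifact into the output directory and registers it, with seeds
and convergence summaries, in ``manifest.json``; rerunning with the same
config and seeds reproduces all outputs (MCMC included, since the sampler
seeds derive deterministically from the master seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import ChoiceDataset, read_dataset, write_dataset
from .hba import HierarchicalChoiceModel, McmcConfig
from .metrics import aggregate, mixed_anova, posthoc_pairwise
from .report import (
    condition_contrast,
    evidence_category,
    group_contrast,
    posterior_predict,
    ppc_correlations,
)
from .selection import compare
from .simulate import default_cohort_specs, simulate_cohort

log = logging.getLogger("fairshare")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything a full run needs; defaults mirror the study design."""

    out_dir: str = "fairshare_run"
    seed: int = 0
    dataset_path: str | None = None  # None -> simulate a cohort pair
    n_children: int = 34
    n_adults: int = 31
    sigma0: float = 0.5
    generating_model: str = "M4"
    models: tuple = ("M1", "M2", "M3", "M4", "M5")
    chains: int = 3
    warmup: int = 2000
    samples: int = 2000
    target_accept: float = 0.9
    ppc_mode: str = "means"
    verbosity: str = "INFO"

    def reduced(self) -> "PipelineConfig":
        """A small-scale preset (fewer subjects, short chains) for smoke runs."""
        return dataclasses.replace(
            self, n_children=8, n_adults=8, chains=2, warmup=300, samples=300
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; returns the output directory.

    Stages: dataset (simulate or load), deviation metrics + mixed ANOVA +
    post-hocs, per-group fits of every candidate model, LOOIC/WAIC
    comparison, posterior predictive check of the winning model, and the
    evidence report (parameters vs 0, role/frame contrasts, cross-group
    contrasts).  Any stage failure raises with the stage name; artifacts
    written so far are retained.
    """
    logging.basicConfig(level=config.verbosity)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "stages": {},
        "warnings": [],
    }
    config.to_yaml(out / "config.yaml")

    def stage(name):
        def wrap(fn):
            t0 = time.time()
            log.info("stage %s ...", name)
            try:
                result = fn()
            except Exception as exc:
                manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            manifest["stages"][name] = {"status": "ok", "seconds": round(time.time() - t0, 2)}
            return result

        return wrap

    @stage("dataset")
    def dataset() -> ChoiceDataset:
        if config.dataset_path:
            return read_dataset(config.dataset_path, strict_design=True)
        specs = default_cohort_specs(
            config.n_children, config.n_adults, config.sigma0, seed=config.seed
        )
        parts = [simulate_cohort(s, config.generating_model) for s in specs.values()]
        table = pd.concat([p.table for p in parts], ignore_index=True)
        gt = pd.concat([p.ground_truth for p in parts], ignore_index=True)
        ds = ChoiceDataset(table, gt)
        write_dataset(ds, out / "dataset.csv")
        return ds

    ds = dataset

    @stage("metrics")
    def metrics():
        summ = aggregate(ds)
        summ.to_csv(out / "deviation_summaries.csv", index=False)
        results = {}
        for resp in ("selfish_dev", "equal_dev"):
            res = mixed_anova(summ, resp)
            res.table.to_csv(out / f"anova_{resp}.csv", index=False)
            ph = posthoc_pairwise(summ, resp)
            ph.to_csv(out / f"posthoc_{resp}.csv", index=False)
            log.info("ANOVA (%s):\n%s", resp, res)
            results[resp] = res
        return results

    _ = metrics

    @stage("fit")
    def fits():
        cfg = McmcConfig(
            chains=config.chains,
            warmup=config.warmup,
            samples=config.samples,
            seed=config.seed,
            target_accept=config.target_accept,
        )
        by_group: dict = {}
        for group in ds.groups:
            sub = ds.for_group(group)
            by_group[group] = {}
            for mid in config.models:
                fit = HierarchicalChoiceModel(sub, mid).fit(config=cfg)
                fit.save(out / f"fit_{group}_{mid}.csv")
                by_group[group][mid] = fit
                if not fit.converged:
                    manifest["warnings"].append(
                        {"stage": "fit", "group": group, "model": mid, "max_rhat": fit.max_rhat}
                    )
                log.info("fitted %s/%s: max R-hat %.3f", group, mid, fit.max_rhat)
        manifest["n_fitted_models"] = sum(len(v) for v in by_group.values())
        return by_group

    fits_by_group = fits

    @stage("compare")
    def comparison():
        winners = {}
        for group, fits in fits_by_group.items():
            table = compare({mid: f.pointwise_loglik() for mid, f in fits.items()})
            table.table.to_csv(out / f"comparison_{group}.csv", index=False)
            log.info("model comparison (%s):\n%s", group, table)
            winners[group] = table.winner
        return winners

    winners = comparison

    @stage("ppc")
    def ppc():
        for group, fits in fits_by_group.items():
            fit = fits[winners[group]]
            rep = posterior_predict(fit, mode=config.ppc_mode, seed=config.seed)
            res = ppc_correlations(ds.for_group(group), rep)
            res.correlations.to_csv(out / f"ppc_{group}.csv", index=False)
            log.info("PPC (%s, winner %s):\n%s", group, winners[group], res)

    _ = ppc

    @stage("report")
    def report():
        rows = []
        for group, fits in fits_by_group.items():
            fit = fits[winners[group]]
            for fam in fit.spec.weight_names:
                for k in range(1, 5):
                    rep = evidence_category(fit.group_level(fam, k), f"mu_{fam}[{k}], {group}")
                    rows.append(rep)
                for axis in ("role", "frame"):
                    _, rep = condition_contrast(fit, fam, axis)
                    rows.append(rep)
        groups = list(fits_by_group)
        if len(groups) == 2:
            fa = fits_by_group[groups[0]][winners[groups[0]]]
            fb = fits_by_group[groups[1]][winners[groups[1]]]
            if fa.spec.id == fb.spec.id:
                common = fa.spec.weight_names
                for fam in common:
                    for role in ("first", "third"):
                        _, rep = group_contrast(fa, fb, fam, role, seed=config.seed)
                        rows.append(rep)
        df = pd.DataFrame(
            {
                "name": [r.name for r in rows],
                "mean": [r.mean for r in rows],
                "hdi95_lo": [r.hdi95[0] for r in rows],
                "hdi95_hi": [r.hdi95[1] for r in rows],
                "hdi975_lo": [r.hdi975[0] for r in rows],
                "hdi975_hi": [r.hdi975[1] for r in rows],
                "category": [r.category for r in rows],
                "direction": [r.direction for r in rows],
            }
        )
        df.to_csv(out / "evidence_report.csv", index=False)
        for r in rows:
            log.info("%s", r)

    _ = report

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
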