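"""End-to-end pipeline: simulate/ingest -> marginal screen -> prune/tiers ->
pair tests -> permutation threshold -> validation selection (-> meta)."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .calibration import permute_min_p, significance_threshold
from .cohort import (CohortConfig, DiseaseModel, GenotypeMatrix,
                     InteractionTerm, SnpSpec, simulate_case_control)
from .meta import bonferroni_validation_alpha, fixed_effects_meta
from .pedio import (read_annotation, read_ped_map, write_annotation,
                    write_pairs, write_ped_map, write_results)
from .screen import InteractionScreen
from .selection import build_tiers, enumerate_pairs, marginal_screen

log = logging.getLogger("episcreen")

__all__ = ["RunConfig", "run_pipeline", "cohort_config_from_dict"]


@dataclass
class RunConfig:
    """Pipeline configuration; thresholds default to the tiered-screen
    conventions (r^2 < 0.5 independence, marginal tiers 1e-3/1e-2, FWER
    0.05, 3-orders-of-magnitude validation window)."""

    out_dir: str = "episcreen_out"
    ped_prefix: str | None = None       # ingest mode
    annotation: str | None = None
    cohort: dict | None = None          # simulate mode (cohort spec dict)
    analyses: tuple[str, ...] = ("1", "2", "3a", "3b")
    r2_max: float = 0.5
    marginal_thresholds: tuple[float, float] = (1e-3, 1e-2)
    fwer: float = 0.05
    validation_window: float = 1e3
    n_perm: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.r2_max <= 1:
            raise ValueError("r2_max must be in (0, 1]")
        if not 0 < self.fwer < 1:
            raise ValueError("fwer must be in (0, 1)")
        for t in self.marginal_thresholds:
            if not 0 < t < 1:
                raise ValueError("marginal thresholds must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "marginal_thresholds" in raw:
            raw["marginal_thresholds"] = tuple(raw["marginal_thresholds"])
        if "analyses" in raw:
            raw["analyses"] = tuple(str(a) for a in raw["analyses"])
        return cls(**raw)

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        d["analyses"] = list(self.analyses)
        d["marginal_thresholds"] = list(self.marginal_thresholds)
        return d


def cohort_config_from_dict(raw: dict, seed: int) -> CohortConfig:
    """Build a CohortConfig from a plain (YAML-friendly) dict."""
    specs = tuple(SnpSpec(**s) for s in raw.get("snps", []))
    dm = raw.get("disease_model", {})
    terms = tuple(
        InteractionTerm(t["snp_a"], t["snp_b"], t.get("model", "addxadd"),
                        float(t.get("log_or", 0.0)),
                        offsets=np.array(t["offsets"]) if "offsets" in t else None)
        for t in dm.get("interaction_terms", []))
    model = DiseaseModel(intercept=float(dm.get("intercept", np.log(0.01 / 0.99))),
                         marginal_effects={k: float(v) for k, v in
                                           dm.get("marginal_effects", {}).items()},
                         interaction_terms=terms)
    return CohortConfig(n_cases=int(raw.get("n_cases", 2967)),
                        n_controls=int(raw.get("n_controls", 3075)),
                        snp_specs=specs, disease_model=model, seed=seed,
                        missing_rate=float(raw.get("missing_rate", 0.0)))


def run_pipeline(config: RunConfig) -> Path:
    """Execute the staged workflow; returns the artifact directory.

    Per-analysis bookkeeping (set sizes, pair counts, feasible counts,
    thresholds) is logged and written to ``counts.tsv``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.as_dict()

    # stage 1: cohort
    if config.cohort is not None:
        cc = cohort_config_from_dict(config.cohort, config.seed)
        g = simulate_case_control(cc)
        write_ped_map(g, out / "cohort")
        log.info("simulated cohort: %d cases, %d controls, %d SNPs",
                 int(g.phenotype.sum()), int((g.phenotype == 0).sum()), g.n_snps)
    elif config.ped_prefix is not None:
        g, _records = read_ped_map(config.ped_prefix)
        if config.annotation:
            tiers = read_annotation(config.annotation)
            for s in g.snp_ids:
                g.snp_meta.setdefault(s, {})["tier"] = tiers.get(s, "none")
        log.info("ingested cohort: %d samples, %d SNPs", g.n_samples, g.n_snps)
    else:
        raise ValueError("config must provide either 'cohort' or 'ped_prefix'")

    # stage 2: marginal screen + tiers
    records = marginal_screen(g)
    write_annotation(records, out / "annotation.tsv")
    plans = build_tiers(records, g, config.marginal_thresholds, config.r2_max)
    plans = [p for p in plans if p.analysis_id in config.analyses]

    counts_rows = []
    for plan in plans:
        pairs = enumerate_pairs(plan)
        write_pairs(pairs, out / f"pairs_{plan.analysis_id}.tsv")
        if not pairs:
            log.warning("Analysis %s: zero pairs", plan.analysis_id)
            counts_rows.append((plan.analysis_id, len(plan.set_a),
                                len(plan.set_b or []), 0, 0, np.nan, np.nan))
            continue
        res = InteractionScreen(g, pairs, plan.test).fit()
        res.calibrate(n_perm=config.n_perm, seed=config.seed)
        thr = res.threshold(config.fwer)
        write_results(res.results, out / f"results_{plan.analysis_id}.tsv",
                      seed=config.seed, config=cfg_dict)
        cand = res.validation_candidates(config.fwer, config.validation_window)
        write_results(cand, out / f"validation_candidates_{plan.analysis_id}.tsv",
                      seed=config.seed, config=cfg_dict)
        log.info("Analysis %s: |A|=%d |B|=%s pairs=%d feasible=%d min_p=%.3g "
                 "threshold=%.3g carried=%d", plan.analysis_id, len(plan.set_a),
                 len(plan.set_b) if plan.set_b else "-", len(pairs),
                 res.n_feasible, res.min_p, thr, len(cand))
        counts_rows.append((plan.analysis_id, len(plan.set_a),
                            len(plan.set_b or []), len(pairs),
                            res.n_feasible, res.min_p, thr))

    import pandas as pd
    pd.DataFrame(counts_rows, columns=["analysis", "n_set_a", "n_set_b",
                                       "n_pairs", "n_feasible", "min_p",
                                       "threshold"]).to_csv(
        out / "counts.tsv", sep="\t", index=False)
    with open(out / "run_config.yaml", "w") as fh:
        yaml.safe_dump(cfg_dict, fh)
    return out
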