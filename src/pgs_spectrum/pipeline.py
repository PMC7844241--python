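"""End-to-end orchestration: simulate -> score -> multipgs -> assoc -> overlap.

A single :class:`RunConfig` (optionally loaded from YAML) drives the stages;
per-stage seeds are derived from the master seed and the stage name so that
re-running one stage is unaffected by the draw counts of the others.  Every
run writes a manifest (parameters, seeds, file checksums) plus four report
tables: univariate associations, elastic-net coefficient summaries,
decile/age-bin tables, and phenotype-overlap confusion matrices.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, io_formats, multipgs, overlap, pgs_engine, synthdata

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "score", "multipgs", "assoc", "overlap")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return zlib.crc32(f"{master_seed}:{stage}".encode()) % (2 ** 31)


def _demo_simulation() -> synthdata.SimulationConfig:
    """Demo-scale cohort: same structure as the full default, smaller n."""
    return synthdata.SimulationConfig(
        n_subjects_per_ancestry={"EA": 1200, "AA": 600},
        n_variants=1000, n_blocks=50)


@dataclass
class RunConfig:
    out_dir: str = "pgs_run"
    master_seed: int = 2021
    stages: tuple = ALL_STAGES
    simulation: synthdata.SimulationConfig = field(
        default_factory=_demo_simulation)
    # scoring
    method: str = "clump_pt"          # or "ldpred_inf"
    p_max: float = 0.05
    r2_max: float = 0.1
    window_kb: float = 500.0
    radius: int = 250
    ldpred_h2: float = 0.2
    n_pcs: int = 10
    # multipgs
    n_repetitions: int = 25
    n_permutations: int = 25
    alpha_grid: tuple = (0.0, 0.5, 1.0)
    n_lambdas: int = 8
    cv_folds: int = 5
    # assoc / overlap
    outcome: str = "ps"
    covars: tuple = assoc.DEFAULT_COVARS
    overlap_pairs: tuple = (("adhd", "ps"), ("adhd_symptoms", "ps"))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", {})
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        if sim:
            specs = sim.pop("trait_specs", None)
            simcfg = synthdata.SimulationConfig(
                **{k: v for k, v in sim.items()
                   if k in synthdata.SimulationConfig.__dataclass_fields__})
            if specs is not None:
                simcfg.trait_specs = [synthdata.TraitSpec(**s) for s in specs]
            cfg.simulation = simcfg
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: RunConfig) -> Path:
    """Execute the enabled stages in order; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"master_seed": config.master_seed,
                      "stages": list(config.stages), "seeds": {}, "files": {},
                      "parameters": {
                          "method": config.method, "p_max": config.p_max,
                          "r2_max": config.r2_max, "window_kb": config.window_kb,
                          "radius": config.radius, "n_pcs": config.n_pcs,
                          "n_repetitions": config.n_repetitions,
                          "n_permutations": config.n_permutations,
                      }}
    study = None
    scores = None

    if "simulate" in config.stages:
        seed = stage_seed(config.master_seed, "simulate")
        manifest["seeds"]["simulate"] = seed
        config.simulation.seed = seed
        logger.info("stage simulate: seed=%d", seed)
        study = synthdata.simulate_study(config.simulation)
        io_formats.write_cohort(study.cohort, out / "cohort.tsv")
        study.variants.to_csv(out / "variants.tsv", sep="\t", index=False)
        io_formats.write_genotypes_tsv(study.variants, study.genotypes,
                                       out / "genotypes.tsv")
        for name, ss in study.sumstats.items():
            io_formats.write_sumstats(ss, out / f"sumstats_{name}.tsv.gz")

    if "score" in config.stages:
        if study is None:
            raise RuntimeError("score stage requires the simulate stage")
        seed = stage_seed(config.master_seed, "score")
        manifest["seeds"]["score"] = seed
        logger.info("stage score: method=%s", config.method)
        ld = pgs_engine.build_ld_view(study.genotypes, radius=config.radius)
        pcs = pgs_engine.group_pcs(study.genotypes, k=config.n_pcs)
        cols = {}
        for name, ss in study.sumstats.items():
            w = pgs_engine.harmonize(ss, study.variants)
            if config.method == "clump_pt":
                w = pgs_engine.clump_and_threshold(
                    w, ld, p_max=config.p_max, r2_max=config.r2_max,
                    window_kb=config.window_kb)
            elif config.method == "ldpred_inf":
                w = pgs_engine.ldpred_inf(
                    w, ld, h2=config.ldpred_h2,
                    n=int(ss.table["N"].iloc[0]), m=w.n_variants)
            else:
                raise ValueError(f"unknown scoring method {config.method!r}")
            cols[name] = pgs_engine.corrected_scores(
                study.genotypes, w, k_pcs=config.n_pcs, pcs=pcs)
        scores = pd.DataFrame(cols)
        scores.insert(0, "id", study.genotypes.subject_ids)
        scores.to_csv(out / "scores.tsv", sep="\t", index=False)

    cohort = study.cohort if study is not None else None
    trait_names = [s.name for s in config.simulation.trait_specs]

    if "multipgs" in config.stages:
        if scores is None or cohort is None:
            raise RuntimeError("multipgs stage requires score stage outputs")
        seed = stage_seed(config.master_seed, "multipgs")
        manifest["seeds"]["multipgs"] = seed
        X = scores[trait_names]
        y = cohort[config.outcome].to_numpy()
        run_rec = multipgs.repeat_and_permute(
            X, y, n_repetitions=config.n_repetitions,
            n_permutations=config.n_permutations,
            group=cohort["ancestry"].to_numpy(), seed=seed,
            alpha_grid=config.alpha_grid, folds=config.cv_folds,
            n_lambdas=config.n_lambdas)
        run_rec.summary().to_csv(out / "multipgs_coefficients.tsv", sep="\t",
                                 index=False)
        pd.DataFrame({"repetition_auc": run_rec.repetition_aucs}).to_csv(
            out / "multipgs_repetition_auc.tsv", sep="\t", index=False)
        pd.DataFrame({"permutation_auc": run_rec.permutation_aucs}).to_csv(
            out / "multipgs_permutation_auc.tsv", sep="\t", index=False)
        manifest["multipgs"] = {"mean_auc": run_rec.mean_auc,
                                "empirical_p": run_rec.empirical_p}

    if "assoc" in config.stages:
        if scores is None or cohort is None:
            raise RuntimeError("assoc stage requires score stage outputs")
        rows = []
        cohorts = {"All": np.ones(len(cohort), bool)}
        for anc in pd.unique(cohort["ancestry"]):
            cohorts[str(anc)] = (cohort["ancestry"] == anc).to_numpy()
        for trait in trait_names:
            for label, mask in cohorts.items():
                sub = cohort.loc[mask].reset_index(drop=True)
                try:
                    r = assoc.fit_univariate(
                        scores.loc[mask, trait].to_numpy(), sub[config.outcome],
                        covars=config.covars, data=sub, trait=trait,
                        cohort=label)
                except assoc.AssocError:
                    continue
                rows.append(dict(trait=trait, cohort=label, n=r.n,
                                 or_per_sd=r.or_per_sd, ci_low=r.ci95[0],
                                 ci_high=r.ci95[1], p=r.p))
        table1 = pd.DataFrame(rows)
        table1.to_csv(out / "assoc_univariate.tsv", sep="\t", index=False)
        cutoff = assoc.bonferroni_threshold(len(trait_names),
                                            len(cohorts))
        manifest["assoc"] = {"bonferroni_raw": cutoff.raw,
                             "bonferroni_reported": cutoff.reported}
        # decile + age-bin tables for the strongest trait in the full cohort
        if not table1.empty:
            top = (table1[table1.cohort == "All"]
                   .sort_values("p").iloc[0]["trait"])
            dec = assoc.decile_contrast(scores[top].to_numpy(),
                                        cohort[config.outcome].to_numpy())
            dec.proportions.assign(trait=top).to_csv(
                out / "assoc_deciles.tsv", sep="\t", index=False)
            inter = assoc.test_interaction(
                scores[top].to_numpy(), cohort[config.outcome].to_numpy(),
                "age", covars=config.covars, data=cohort)
            inter.stratified.assign(trait=top,
                                    p_interaction=inter.p_interaction).to_csv(
                out / "assoc_age_bins.tsv", sep="\t", index=False)
            manifest["assoc"]["top_trait"] = str(top)
            manifest["assoc"]["decile_or_top_vs_bottom"] = dec.or_top_vs_bottom

    if "overlap" in config.stages:
        if cohort is None:
            raise RuntimeError("overlap stage requires the simulate stage")
        table = overlap.overlap_table(cohort, list(config.overlap_pairs),
                                      by="ancestry")
        table.to_csv(out / "overlap_contingency.tsv", sep="\t", index=False)

    for f in sorted(out.glob("*.tsv")) + sorted(out.glob("*.tsv.gz")):
        manifest["files"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=float))
    _write_report(out, manifest)
    return out


def _write_report(out: Path, manifest: dict) -> None:
    """Human-readable HTML index of the run's tables."""
    parts = ["<html><head><title>pgs-spectrum run</title></head><body>",
             "<h1>pgs-spectrum run report</h1>",
             f"<p>master seed: {manifest['master_seed']}</p>"]
    for name in sorted(manifest["files"]):
        if name.endswith(".tsv") and not name.startswith(("genotypes",
                                                          "variants")):
            try:
                df = pd.read_csv(out / name, sep="\t")
            except Exception:                            # noqa: BLE001
                continue
            parts.append(f"<h2>{name}</h2>")
            parts.append(df.head(30).to_html(index=False))
    parts.append("</body></html>")
    (out / "report.html").write_text("\n".join(parts))
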