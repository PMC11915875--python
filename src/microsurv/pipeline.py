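"""End-to-end orchestration: preprocess -> diversity -> associations ->
risk score -> immune links, with a manifest recording seed and config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from microsurv import __version__, diversity, immune
from microsurv import io as msio
from microsurv import preprocess, risk_score, survival_meta

log = logging.getLogger("microsurv")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All knobs of an end-to-end run; loadable from YAML."""

    cohorts: list  # list of {"counts": path, "metadata": path}
    outdir: str
    immune_table: str | None = None
    expression: str | None = None
    gene_sets: str | None = None
    filter: dict = field(default_factory=dict)
    pseudocount: float = 1.0
    batch_center: bool = True
    outcomes: tuple = ("os", "rfs")
    n_iter: int = 100
    subsample_frac: float = 0.9
    alpha: float = 0.05
    threshold: float = 0.60
    n_perm: int = 500
    permanova_perms: int = 999
    ties: str = "efron"
    covariates: tuple = survival_meta.DEFAULT_COVARIATES
    seed: int = 0

    def __post_init__(self):
        if not self.cohorts:
            raise msio.ValidationError("no cohort inputs configured")
        for entry in self.cohorts:
            for key in ("counts", "metadata"):
                if not Path(entry[key]).exists():
                    raise msio.ValidationError(
                        f"input file not found: {entry[key]}")
        if not 0 < self.subsample_frac <= 1:
            raise msio.ValidationError("subsample_frac must be in (0, 1]")
        if not 0 < self.alpha < 1 or not 0 < self.threshold <= 1:
            raise msio.ValidationError("alpha/threshold out of range")
        if self.ties not in ("efron", "breslow"):
            raise msio.ValidationError(f"unknown tie method {self.ties!r}")

    @classmethod
    def from_yaml(cls, path):
        raw = yaml.safe_load(Path(path).read_text())
        raw.setdefault("outdir", "results")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise msio.ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_inputs(config):
    counts_list, meta_list = [], []
    for entry in config.cohorts:
        counts = msio.read_counts(entry["counts"])
        meta = msio.read_metadata(entry["metadata"])
        missing = counts.index.difference(meta.index)
        if len(missing):
            raise msio.ValidationError(
                f"samples without metadata: {list(missing[:3])}")
        counts_list.append(counts)
        meta_list.append(meta.loc[counts.index])
    taxa = counts_list[0].columns
    for c in counts_list[1:]:
        if not c.columns.equals(taxa):
            raise msio.ValidationError("cohorts disagree on the taxon set")
    return pd.concat(counts_list), pd.concat(meta_list)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write all reports under ``config.outdir``.

    Returns the manifest (also written as ``manifest.json``).  Deterministic
    under identical config and seed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": config.seed,
                "config_hash": config.config_hash(), "reports": {},
                "stages": []}
    t0 = _time.perf_counter()

    def _stage(name):
        log.info("stage %-12s elapsed %6.1fs", name,
                 _time.perf_counter() - t0)
        manifest["stages"].append(
            {"stage": name, "elapsed_s": round(_time.perf_counter() - t0, 2)})

    def _write(name, frame, **kw):
        path = outdir / name
        msio.write_matrix(frame, path, **kw)
        manifest["reports"][name] = str(path)

    counts, metadata = _load_inputs(config)
    _stage("load")

    # --- preprocess ---------------------------------------------------
    spec = preprocess.FilterSpec(**config.filter)
    filtered, audit = preprocess.filter_taxa(counts, spec)
    clr = preprocess.clr_transform(filtered, config.pseudocount)
    if config.batch_center and metadata["cohort"].nunique() > 1:
        clr = preprocess.batch_center(clr, metadata["cohort"])
    _write("filter_audit.tsv", audit, index_name="taxon")
    _write("clr.tsv", clr.values)
    _stage("preprocess")

    # --- diversity ----------------------------------------------------
    alpha = diversity.alpha_diversity(filtered)
    _write("alpha_diversity.tsv", alpha)
    Z, _ = survival_meta.build_covariate_matrix(
        metadata, tuple(c for c in config.covariates if c != "stage"))
    alpha_tests = diversity.alpha_group_tests(
        alpha, metadata["stage"],
        pd.DataFrame(Z, index=metadata.index))
    _write("alpha_group_tests.tsv", alpha_tests, index_name="index")
    alpha_surv = pd.concat(
        {oc: diversity.alpha_survival(alpha, metadata, oc)
         for oc in config.outcomes}, names=["outcome"])
    _write("alpha_survival.tsv", alpha_surv, index_name="outcome")
    jsd = diversity.jsd_matrix(filtered)
    _write("jsd.tsv", jsd)
    perma = {}
    for oc in config.outcomes:
        Zc, _ = survival_meta.build_covariate_matrix(metadata,
                                                     config.covariates)
        perma[oc] = diversity.permanova(
            jsd, metadata[f"{oc}_event"], covariates=pd.DataFrame(
                Zc, index=metadata.index),
            n_perm=config.permanova_perms, strata=metadata["cohort"],
            seed=config.seed)
    (outdir / "permanova.json").write_text(json.dumps(perma, indent=2))
    manifest["reports"]["permanova.json"] = str(outdir / "permanova.json")
    _stage("diversity")

    # --- per-species associations, stability, permutation -------------
    rng = np.random.SeedSequence(config.seed)
    stage_seeds = rng.generate_state(2 * len(config.outcomes)) % (2**31)
    selections, associations = {}, {}
    for i, oc in enumerate(config.outcomes):
        assoc = survival_meta.species_associations(
            clr.values, metadata, oc, config.covariates, config.ties)
        sel = survival_meta.stability_select(
            clr.values, metadata, oc, n_iter=config.n_iter,
            frac=config.subsample_frac, alpha=config.alpha,
            threshold=config.threshold, seed=int(stage_seeds[2 * i]),
            covariates=config.covariates, ties=config.ties)
        perm = survival_meta.permutation_test(
            clr.values, metadata, oc, sel, n_perm=config.n_perm,
            seed=int(stage_seeds[2 * i + 1]), covariates=config.covariates,
            ties=config.ties)
        assoc["O_j"] = sel.frequency
        assoc["selected"] = sel.selected
        assoc["p_perm"] = perm.p_perm
        assoc["q_value"] = perm.q_value
        _write(f"associations_{oc}.tsv", assoc, index_name="taxon")
        selections[oc] = sel
        associations[oc] = assoc
    _stage("associations")

    # --- risk score ----------------------------------------------------
    mrs_summaries = {}
    mrs_by_outcome = {}
    for oc in config.outcomes:
        sel = selections[oc]
        if not sel.selected_taxa:
            log.warning("no species selected for %s; MRS skipped", oc)
            mrs_summaries[oc] = {"n_species": 0}
            continue
        mrs = risk_score.build_mrs(clr.values, sel, associations[oc])
        mrs_by_outcome[oc] = mrs
        pooled, per_cohort = risk_score.cox_mrs(mrs, metadata, oc,
                                                config.covariates)
        km = risk_score.km_logrank(mrs, metadata, oc)
        _write(f"mrs_{oc}.tsv", pd.DataFrame(
            {"mrs": mrs.score, "raw_mrs": mrs.raw_score,
             "risk_group": km.groups}))
        _write(f"km_{oc}.tsv", km.curves.set_index("group"),
               index_name="group")
        strata_tables = []
        for strat in ("smoking", "stage"):
            tab = risk_score.stratified_rerun(mrs, metadata, oc, strat,
                                              config.covariates)
            if len(tab):
                strata_tables.append(tab)
        if strata_tables:
            _write(f"mrs_strata_{oc}.tsv",
                   pd.concat(strata_tables, ignore_index=True)
                   .set_index("stratum"), index_name="stratum")
        mrs_summaries[oc] = {
            "n_species": len(sel.selected_taxa),
            "species": sel.selected_taxa,
            "hr_per_sd": pooled.hr,
            "ci95": list(pooled.ci95),
            "p_meta": pooled.p_meta,
            "hr_per_raw_unit": float(np.exp(
                pooled.beta_pooled / mrs.raw_sd)),
            "per_cohort": {c: {"hr": f.hr, "ci95": list(f.ci95), "p": f.p}
                           for c, f in per_cohort.items()},
            "logrank_chi2": km.logrank_chi2, "logrank_p": km.logrank_p,
            "deviance_p": km.lr_p,
            "median_survival": km.median_survival,
        }
    (outdir / "mrs_summary.json").write_text(
        json.dumps(mrs_summaries, indent=2, default=str))
    manifest["reports"]["mrs_summary.json"] = str(outdir / "mrs_summary.json")
    _stage("risk_score")

    # --- immune / expression links -------------------------------------
    if config.immune_table and mrs_by_outcome:
        immune_tab = msio.read_matrix(config.immune_table)
        logit = pd.concat(
            {oc: immune.logistic_assoc(immune_tab, m, metadata,
                                       config.covariates)
             for oc, m in mrs_by_outcome.items()}, names=["outcome"])
        _write("immune_logistic.tsv", logit, index_name="outcome")
        sel_taxa = sorted({t for s in selections.values()
                           for t in s.selected_taxa})
        corr = immune.spearman_matrix(clr.values[sel_taxa], immune_tab)
        _write("immune_spearman.tsv", corr.set_index("feature"),
               index_name="feature")
        if config.expression:
            expr = msio.read_matrix(config.expression).T  # genes x samples
            gcorr = immune.spearman_matrix(clr.values[sel_taxa], expr)
            _write("gene_spearman.tsv", gcorr.set_index("feature"),
                   index_name="feature")
            if config.gene_sets:
                sets = msio.read_gmt(config.gene_sets)
                n_feat = max(gcorr["feature"].nunique(), 1)
                best = gcorr.groupby("target")["p"].min() * n_feat
                correlated = sorted(best.index[best < 0.05])
                if correlated:
                    ora = immune.hypergeom_ora(correlated,
                                               list(expr.columns), sets)
                    _write("pathway_ora.tsv", ora, index_name="gene_set")
        _stage("immune")

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
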