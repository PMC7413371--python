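"""End-to-end orchestration: simulate -> preprocess -> train -> associate ->
condition -> heritability -> eQTM -> expression association -> triads ->
annotate/enrich, with one config, deterministic seeding, and a manifest of
per-stage record counts and output checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as annotate_mod
from . import condh2, formats, integrate, models, mwas, preprocess, synthio

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ScenarioBundle", "simulate_scenario", "run_pipeline"]

_SCENARIO_DEFAULTS = {
    "n_samples": 800,
    "blocks": [[40, 0.6]] * 10,
    "n_cpgs": 200,
    "cis_h2": 0.3,
    "n_causal_per_cpg": 2,
    "probe_snp_fraction": 0.05,
    "n_liability_cpgs": 3,
    "liability_effect": 0.25,
    "prevalence": 0.12,
    "n_cases": 2000,
    "n_controls": 2000,
    "n_ref_samples": 1200,
    "n_genes": 20,
    "eqtm_slope": 1.5,
    "expression_noise_sd": 0.25,
}


@dataclass
class RunConfig:
    """Single configuration object for a pipeline run."""

    seed: int = 0
    out_dir: str = "methylwas_run"
    scenario: dict = field(default_factory=dict)
    training: dict = field(default_factory=dict)
    constants: dict = field(default_factory=dict)
    pairing_window: int = 500_000
    flank: int = 1000
    stages: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for sub, ref in [
            ("scenario", _SCENARIO_DEFAULTS),
            ("training", {f: None for f in models.TrainingConfig.__dataclass_fields__}),
            ("constants", {f: None for f in condh2.PipelineConfig.__dataclass_fields__}),
        ]:
            bad = set(d.get(sub, {})) - set(ref)
            if bad:
                raise ValueError(f"unknown {sub} key(s): {sorted(bad)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class ScenarioBundle:
    """All synthetic inputs of one scenario plus its ground truth."""

    panel: synthio.GenotypePanel
    covariates: pd.DataFrame
    methylome: synthio.MethylomePanel
    truth: synthio.TruthBundle
    expression: synthio.ExpressionPanel
    gwas: pd.DataFrame
    ref_panel: synthio.GenotypePanel
    risk_snps: pd.DataFrame


def simulate_scenario(scenario: dict | None = None, seed: int = 0) -> ScenarioBundle:
    """Generate a full study scenario with known ground truth.

    A handful of CpGs carry liability effects; each such CpG's strongest
    causal SNP becomes a known risk SNP (emulating GWAS-discovered index
    variants), and the first liability CpG is linked to a gene so that a
    direction-consistent triad is planted.
    """
    sc = dict(_SCENARIO_DEFAULTS)
    sc.update(scenario or {})
    rng = np.random.default_rng(seed)
    s_geno, s_cov, s_meth, s_expr, s_gwas, s_ref = rng.integers(0, 2**31 - 1, 6)

    panel = synthio.simulate_genotypes(
        sc["n_samples"], [tuple(b) for b in sc["blocks"]], seed=int(s_geno)
    )
    covariates = synthio.simulate_covariates(panel.sample_ids, seed=int(s_cov))
    methylome, truth = synthio.simulate_methylome(
        panel, sc["n_cpgs"], sc["cis_h2"], sc["n_causal_per_cpg"],
        covariates, seed=int(s_meth),
        probe_snp_fraction=sc["probe_snp_fraction"],
    )
    # liability CpGs: unflagged CpGs with real causal SNPs
    eligible = [
        r.id for r in methylome.cpg_table.itertuples(index=False)
        if not r.probe_snp_flag and len(truth.cpg_causal[r.id][0]) > 0
    ]
    lia = eligible[: sc["n_liability_cpgs"]]
    effects = {cid: sc["liability_effect"] for cid in lia}
    synthio.define_disease_model(truth, effects, sc["prevalence"])

    # known risk SNPs: strongest causal SNP of each liability CpG
    rows = []
    vt = panel.variant_table.set_index("id")
    for cid in lia:
        ids, eff = truth.cpg_causal[cid]
        top = ids[int(np.argmax(np.abs(eff)))]
        rows.append({"id": top, "chrom": vt.loc[top, "chrom"],
                     "pos": int(vt.loc[top, "pos"])})
    risk_snps = pd.DataFrame(rows, columns=["id", "chrom", "pos"])

    links = []
    gene_pool = lia + [c for c in eligible if c not in lia]
    for k in range(sc["n_genes"]):
        cid = gene_pool[k % len(gene_pool)]
        slope = sc["eqtm_slope"] if k < len(lia) else 0.0
        links.append((cid, f"gene{k:03d}", slope))
    expression = synthio.simulate_expression(
        methylome, panel, links, noise_sd=sc["expression_noise_sd"],
        seed=int(s_expr), truth=truth,
    )
    gwas = synthio.simulate_gwas_summary(
        panel, truth, sc["n_cases"], sc["n_controls"], seed=int(s_gwas)
    )
    ref_panel = synthio.GenotypePanel(
        [f"R{i:05d}" for i in range(sc["n_ref_samples"])],
        panel.variant_table.copy(),
        synthio.draw_dosages(panel, sc["n_ref_samples"],
                             np.random.default_rng(int(s_ref))),
        dict(panel.block_corr),
    )
    return ScenarioBundle(panel, covariates, methylome, truth, expression,
                          gwas, ref_panel, risk_snps)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": cfg.seed, "stages": {}, "checksums": {}}
    tcfg = models.TrainingConfig(**{**cfg.training, "seed": cfg.seed})
    consts = condh2.PipelineConfig(**cfg.constants)

    def record(stage, **counts):
        manifest["stages"][stage] = counts
        logger.info("stage %s: %s", stage, counts)

    try:
        bundle = simulate_scenario(cfg.scenario, cfg.seed)
        record("simulate", n_samples=bundle.panel.n_samples,
               n_variants=bundle.panel.n_variants,
               n_cpgs=len(bundle.methylome.cpg_table),
               n_genes=len(bundle.expression.gene_table))
        formats.write_gwas_summary(bundle.gwas, out / "gwas.tsv")
        formats.write_cpg_table(bundle.methylome.cpg_table, out / "cpgs.tsv")

        # preprocess: QN across samples -> rank-INT per CpG -> residualize
        qn = preprocess.quantile_normalize_samples(bundle.methylome.betas)
        rin = preprocess.rank_inverse_normal(qn)
        resid = preprocess.residualize(rin, bundle.covariates)
        record("preprocess", n_features=resid.shape[1])

        # train models
        store = {}
        cpg_tab = bundle.methylome.cpg_table
        for j, crow in enumerate(cpg_tab.itertuples(index=False)):
            cis = models.select_cis_variants(
                crow.chrom, crow.pos, bundle.panel, tcfg.window_halfwidth
            )
            if cis.size == 0:
                continue
            store[crow.id] = models.train_feature_model(
                crow.id, resid[:, j], bundle.panel.dosages[:, cis],
                bundle.panel.variant_table.iloc[cis], tcfg,
                chrom=crow.chrom, pos=crow.pos,
            )
        retained, excl = models.apply_model_filters(store, cpg_tab,
                                                    tcfg.r2_threshold)
        formats.write_model_store(retained, out / "models")
        record("train", n_trained=len(store), n_retained=len(retained), **excl)

        # summary association
        n_tests = len(retained)
        threshold = mwas.bonferroni_threshold(n_tests) if n_tests else np.nan
        assoc = {}
        aligned_map = {}
        for fid, m in retained.items():
            aligned, _ = formats.harmonize_alleles(m.weights, bundle.gwas)
            if len(aligned) == 0:
                continue
            ld = mwas.build_ld_reference(bundle.ref_panel,
                                         aligned["variant_id"].tolist())
            res = mwas.summary_association(m, aligned, ld)
            if np.isfinite(res.z):
                assoc[fid] = res
                aligned_map[fid] = aligned
        assoc_df = pd.DataFrame(
            [
                {"feature_id": r.feature_id, "zscore": r.z,
                 "effect_size": r.beta_per_sd, "or_per_sd": r.or_per_sd,
                 "pvalue": r.p, "sigma_feature": r.sigma_feature,
                 "n_snps_used": r.n_snps_used}
                for r in assoc.values()
            ]
        )
        assoc_df.to_csv(out / "assoc.tsv", sep="\t", index=False)
        significant = [f for f, r in assoc.items() if r.p <= threshold]
        record("assoc", n_tested=len(assoc), n_significant=len(significant),
               bonferroni_threshold=threshold)

        # conditional analysis + novelty
        cond_rows = []
        cpg_pos = cpg_tab.set_index("id")
        for fid in significant:
            crow = cpg_pos.loc[fid]
            novel = condh2.classify_locus_novelty(
                crow["chrom"], crow["pos"], bundle.risk_snps,
                consts.novel_distance,
            )
            same = bundle.risk_snps[bundle.risk_snps["chrom"] == crow["chrom"]]
            if len(same) == 0:
                cond_rows.append({"feature_id": fid, "novel": novel,
                                  "index_snp": None,
                                  "z_marginal": assoc[fid].z,
                                  "z_conditional": assoc[fid].z,
                                  "classification": "novel-independent"})
                continue
            index_snp = same.iloc[
                int(np.argmin(np.abs(same["pos"].to_numpy() - crow["pos"])))
            ]["id"]
            joint_ids = aligned_map[fid]["variant_id"].tolist()
            if index_snp not in joint_ids:
                joint_ids = joint_ids + [index_snp]
            ld_joint = mwas.build_ld_reference(bundle.ref_panel, joint_ids)
            cr = condh2.conditional_association(
                retained[fid], aligned_map[fid], ld_joint, index_snp,
                bundle.gwas, threshold, marginal=assoc[fid],
            )
            cls = ("novel-independent"
                   if novel and cr.classification == "independent-of-known"
                   else cr.classification)
            cond_rows.append({"feature_id": fid, "novel": novel,
                              "index_snp": index_snp,
                              "z_marginal": cr.z_marginal,
                              "z_conditional": cr.z_conditional,
                              "classification": cls})
        cond_df = pd.DataFrame(cond_rows)
        cond_df.to_csv(out / "conditional.tsv", sep="\t", index=False)
        keep_cls = {"novel-independent", "independent-of-known"}
        indep = ([r["feature_id"] for r in cond_rows
                  if r["classification"] in keep_cls] or significant)
        record("condition", n_conditional=len(cond_rows),
               n_independent=len(indep))

        # heritability / FRR over the independent associated CpGs
        h2_fit = None
        if indep:
            sub_store = {f: retained[f] for f in indep}
            l = condh2.predicted_meth_ld_scores(sub_store, bundle.ref_panel)
            z = np.array([assoc[f].z for f in indep])
            h2_fit = condh2.estimate_h2_ldsc(
                z, l.loc[indep].to_numpy(), consts.gwas_n_total, M=len(indep)
            )
            with open(out / "h2.json", "w") as fh:
                json.dump({"M": h2_fit.M, "h2": h2_fit.h2,
                           "h2_se": h2_fit.h2_se,
                           "frr_explained": h2_fit.frr_explained}, fh, indent=1)
            record("h2", M=h2_fit.M, h2=h2_fit.h2,
                   frr_explained=h2_fit.frr_explained)

        # eQTM on significant CpGs
        sig_tab = cpg_tab[cpg_tab["id"].isin(significant)]
        pairs = integrate.pair_cpg_genes(sig_tab, bundle.expression.gene_table,
                                         cfg.pairing_window)
        eqtm = integrate.eqtm_regression(bundle.methylome, bundle.expression,
                                         bundle.covariates, pairs)
        eqtm_df = pd.DataFrame([vars(e) for e in eqtm])
        eqtm_df.to_csv(out / "eqtm.tsv", sep="\t", index=False)
        eqtm_sig = [e for e in eqtm if e.q < 0.05]
        record("eqtm", n_pairs=len(pairs), n_tested=len(eqtm),
               n_fdr05=len(eqtm_sig))

        # expression models + association for candidate target genes
        target_genes = sorted({e.gene_id for e in eqtm_sig})
        expr_store, expr_assoc = integrate.expression_models_and_assoc(
            bundle.expression, bundle.panel, bundle.gwas, bundle.ref_panel,
            tcfg, gene_ids=target_genes,
        )
        expr_map = {r.feature_id: r for r in expr_assoc}
        record("expr_assoc", n_genes_modeled=len(expr_store),
               n_assoc=len(expr_assoc))

        # triads
        triads = []
        for e in eqtm_sig:
            if e.cpg_id in assoc and e.gene_id in expr_map:
                expr_res = expr_map[e.gene_id]
                q = getattr(expr_res, "q", np.nan)
                if np.isfinite(q) and q < 0.05:
                    triads.append(integrate.triad_consistency(
                        assoc[e.cpg_id], e, expr_res))
        triad_df = pd.DataFrame([vars(t) for t in triads])
        triad_df.to_csv(out / "triads.tsv", sep="\t", index=False)
        record("triads", n_triads=len(triads),
               n_consistent=int(sum(t.consistent for t in triads)))

        # annotation + enrichment with a deterministic toy gene model
        gene_model = _scenario_gene_model(bundle)
        tested_ann = annotate_mod.annotate_cpgs(cpg_tab, gene_model, cfg.flank)
        assoc_ann = tested_ann[tested_ann["cpg_id"].isin(significant)]
        enrich = annotate_mod.category_enrichment(assoc_ann, tested_ann)
        enrich.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        record("annotate", n_annotated=len(tested_ann),
               n_categories=int((enrich["n_assoc"] > 0).sum()))
    except Exception as exc:  # halt with stage context + partial manifest
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        manifest["failed_after"] = list(manifest["stages"])
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        raise

    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["checksums"][f.name] = _sha256(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest


def _scenario_gene_model(bundle: ScenarioBundle) -> pd.DataFrame:
    """Deterministic transcript model derived from the scenario genes."""
    rows = []
    for g in bundle.expression.gene_table.itertuples(index=False):
        s, e = int(g.start), int(g.end)
        if s > e:
            s, e = e, s
        third = max((e - s) // 3, 1)
        rows.append(
            {
                "chrom": g.chrom, "strand": g.strand,
                "tx_start": s, "tx_end": e,
                "cds_start": s + third // 2, "cds_end": e - third // 2,
                "exon_starts": [s, s + third + 10, e - third + 10],
                "exon_ends": [s + third, e - third, e],
                "gene_id": g.id, "coding_flag": True,
            }
        )
    return annotate_mod.make_gene_model(rows)
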