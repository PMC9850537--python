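"""End-to-end orchestration: simulate -> prep -> kinship -> fit -> transform
-> GWAS, as a configured, logged, resumable run.

The two-step design matches standard single-step practice: (co)variance
components are estimated first on the pedigree model, then held fixed for a
shorter H-matrix chain whose GEBV feed the SNP back-solving.  Every stage
writes its outputs plus a manifest entry (checksum, timing); a stage is
skipped on re-run when its outputs exist and their checksums match.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gebv as gebv_mod
from . import gwas as gwas_mod
from .genomic import blend_and_tune_G, build_G, build_H_inverse, snp_qc
from .legendre import (CoeffCovariances, LegendreBasis, age_covariances,
                       basis_matrix, component_ratio_summaries,
                       heritability_repeatability_by_age)
from .model import GibbsConfig, ModelSpec, gibbs_run, summarize_posterior
from .pedigree import build_A, build_A_inverse, extract_A22
from .prep import AGE_GROUP_MEANS, prepare, summarize_scores
from .simulate import SimConfig, default_components, gene_drop_genotypes, \
    read_dataset, simulate_pedigree, simulate_phenotypes, write_dataset

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    """Declarative pipeline configuration (YAML-loadable)."""

    outdir: str = "temprrm_run"
    seed: int = 0
    sim: dict = field(default_factory=dict)       # SimConfig overrides
    model: dict = field(default_factory=dict)     # ModelSpec overrides
    chain: dict = field(default_factory=dict)     # GibbsConfig overrides
    gwas_chain: dict = field(default_factory=dict)
    gwas: dict = field(default_factory=dict)      # window size, top-n ...
    stages: tuple = ("simulate", "prep", "kinship", "fit", "gwas", "report")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the configured stages; returns the manifest dictionary."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    manifest = {"seed": cfg.seed, "stages": {}}
    if manifest_path.exists():
        try:
            manifest = json.loads(manifest_path.read_text())
            manifest.setdefault("stages", {})
        except json.JSONDecodeError:
            pass

    def stage_done(name, files):
        entry = manifest["stages"].get(name)
        if not entry or entry.get("status") != "ok":
            return False
        for f, digest in entry.get("checksums", {}).items():
            p = Path(f)
            if not p.exists() or _checksum(p) != digest:
                return False
        return bool(files is None or all(Path(f).exists() for f in files))

    def record(name, t0, files, status="ok", error=None):
        manifest["stages"][name] = {
            "status": status,
            "seconds": round(time.time() - t0, 3),
            "checksums": {str(f): _checksum(Path(f)) for f in files
                          if Path(f).exists()},
        }
        if error:
            manifest["stages"][name]["error"] = error
        manifest_path.write_text(json.dumps(manifest, indent=1))

    sim_cfg = SimConfig(**{"seed": cfg.seed, **cfg.sim})
    spec = ModelSpec(**cfg.model)
    data_dir = outdir / "data"

    try:
        if "simulate" in cfg.stages:
            files = [data_dir / f for f in
                     ("pedigree.csv", "phenotypes.csv", "genotypes.tsv",
                      "snps.map", "truth.csv", "truth.json")]
            if not stage_done("simulate", files):
                t0 = time.time()
                ped = simulate_pedigree(sim_cfg)
                geno = gene_drop_genotypes(ped, sim_cfg)
                pheno, truth = simulate_phenotypes(ped, sim_cfg)
                write_dataset(ped, geno, pheno, data_dir, truth=truth,
                              components=sim_cfg.true_components,
                              thresholds=sim_cfg.thresholds)
                record("simulate", t0, files)

        data = read_dataset(data_dir)
        ped, pheno = data["pedigree"], data["phenotypes"]

        if "prep" in cfg.stages:
            t0 = time.time()
            prepped, log = prepare(pheno)
            prepped.to_csv(outdir / "phenotypes_prepped.csv", index=False)
            log.to_frame().to_csv(outdir / "drop_log.csv", index=False)
            summarize_scores(prepped, by="age_group").to_csv(
                outdir / "score_summary.csv", index=False)
            record("prep", t0, [outdir / "phenotypes_prepped.csv",
                                outdir / "drop_log.csv"])
        else:
            prepped = pheno

        A_inv = build_A_inverse(ped)
        kinship = A_inv
        if "kinship" in cfg.stages and "genotypes" in data:
            t0 = time.time()
            M, snp_map, report = snp_qc(data["genotypes"], data["snp_map"])
            report.to_frame().to_csv(outdir / "qc_report.csv", index=False)
            A = build_A(ped)
            A22 = extract_A22(A, list(M.index))
            G = build_G(M)
            G_star = blend_and_tune_G(G, A22)
            H_inv = build_H_inverse(A_inv, A22, G_star)
            record("kinship", t0, [outdir / "qc_report.csv"])
        else:
            M = snp_map = H_inv = None

        chain = None
        if "fit" in cfg.stages:
            t0 = time.time()
            gibbs_cfg = GibbsConfig(**{"seed": cfg.seed, **cfg.chain})
            chain = gibbs_run(prepped, spec, gibbs_cfg, kinship)
            vc, coeff_gebv = summarize_posterior(chain)
            vc.to_csv(outdir / "variance_components.csv", index=False)
            coeff_gebv.to_csv(outdir / "gebv_coefficients.csv")
            chain.component_frame().to_csv(outdir / "chain_samples.csv",
                                           index=False)
            chain.save_npz(outdir / "chain.npz")
            record("fit", t0, [outdir / "variance_components.csv",
                               outdir / "gebv_coefficients.csv"])

        if "gwas" in cfg.stages and M is not None and chain is not None:
            t0 = time.time()
            post = CoeffCovariances(
                G_u=chain.G_u.mean(axis=0), R_p=chain.R_p.mean(axis=0),
                R_q=chain.R_q.mean(axis=0),
                sigma2_e=float(chain.sigma2_e.mean()))
            gwas_cfg = GibbsConfig(**{"iterations": 10_000, "burn_in": 5_000,
                                      "thin": 5, "seed": cfg.seed,
                                      **cfg.gwas_chain})
            ss_chain = gibbs_run(prepped, spec, gwas_cfg, H_inv,
                                 fix_components=post)
            geno_gebv = ss_chain.gebv.loc[
                [a for a in M.index if a in set(ss_chain.gebv.index)]]
            effects = gwas_mod.backsolve_snp_effects(M, geno_gebv)
            ages = list(AGE_GROUP_MEANS)
            by_age = gwas_mod.snp_effects_by_age(effects, spec.basis, ages,
                                                 snp_map=snp_map)
            by_age.to_csv(outdir / "snp_effects_by_age.csv")
            size = int(cfg.gwas.get("window_size", 5))
            weff = gwas_mod.window_effects(
                by_age.drop(columns=["chrom", "pos"]), snp_map, size=size)
            weff.to_csv(outdir / "window_effects.csv", index=False)
            tot = {c: float(post.G_u[i, i])
                   for i, c in enumerate(effects.columns)}
            wvar = gwas_mod.window_variance_explained(M, effects, snp_map,
                                                      tot, size=size)
            wvar.to_csv(outdir / "window_variance.csv", index=False)
            top = gwas_mod.select_top_windows(
                weff, criterion=weff.columns[-1],
                n=int(cfg.gwas.get("top_n", 20)))
            top.to_csv(outdir / "top_windows.csv", index=False)
            record("gwas", t0, [outdir / "window_effects.csv",
                                outdir / "top_windows.csv"])

        if "report" in cfg.stages and chain is not None:
            t0 = time.time()
            post = CoeffCovariances(
                G_u=chain.G_u.mean(axis=0), R_p=chain.R_p.mean(axis=0),
                R_q=chain.R_q.mean(axis=0),
                sigma2_e=float(chain.sigma2_e.mean()))
            T = basis_matrix(np.asarray(AGE_GROUP_MEANS), spec.basis)
            ac = age_covariances(post, T, age_labels=list(AGE_GROUP_MEANS))
            h2, rep = heritability_repeatability_by_age(ac, post.sigma2_e)
            pd.DataFrame({"age_days": AGE_GROUP_MEANS, "h2": h2,
                          "repeatability": rep}).to_csv(
                outdir / "h2_by_age.csv", index=False)
            if spec.order >= 1:
                ratios = component_ratio_summaries(post)
                (outdir / "ratios.json").write_text(json.dumps(ratios, indent=1))
                rep_tab = gebv_mod.gebv_report(chain.gebv, spec.basis,
                                               list(AGE_GROUP_MEANS))
                rep_tab.to_csv(outdir / "gebv_report.csv")
            record("report", t0, [outdir / "h2_by_age.csv"])
    except Exception as err:  # noqa: BLE001 - manifest must record failures
        record("failed_stage", time.time(), [], status="failed",
               error=f"{type(err).__name__}: {err}")
        raise

    return manifest
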