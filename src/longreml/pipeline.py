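"""End-to-end orchestration: QC -> GRM/PCs -> two-stage trajectories ->
GREML heritability (B0 and B1 per trait, FDR across traits) -> chromosomal
partition for the top longitudinal-heritability trait -> trajectory GWAS.

Every stage's table is persisted as TSV under the configured output
directory, and a run manifest records configuration, input checksums, and
per-stage subject/SNP counts so identical inputs reproduce identical output.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import SignificanceConfig, bh_fdr, classify_hits, genomic_inflation, run_gwas
from .exceptions import ParameterError, PipelineError
from .genotype import apply_sample_filters, apply_snp_filters, read_plink, write_plink
from .greml import chromosome_length_correlation, fit_chromosomal, fit_greml
from .grm import compute_grm, compute_pcs, partition_by_chromosome, write_grm_gcta, write_pcs
from .simulate import (
    SimulationConfig,
    read_phenotypes,
    simulate_genotypes,
    simulate_longitudinal_phenotypes,
    write_phenotypes,
)
from .twostage import (
    TraitConfig,
    apply_trait_transforms,
    estimate_period_weights,
    exclude_sparse_trait_periods,
    filter_min_measurements,
    fit_subject_trajectories,
)


@dataclass
class PipelineConfig:
    """Paths, thresholds, and model settings for one full run."""

    genotypes: str
    phenotypes: str
    outdir: str
    traits: list[TraitConfig]
    hwe_thr: float = 1e-5
    maf_thr: float = 0.05
    snp_call_thr: float = 0.95
    sample_miss_thr: float = 0.05
    min_measurements: int = 3
    max_period_missing: float = 0.5
    n_pcs: int = 10
    reml_max_iter: int = 100
    significance: SignificanceConfig = field(default_factory=SignificanceConfig)
    run_gwas: bool = True
    chromosomal: str = "auto"   # "auto" | "none" | a trait name
    weight_mode: str = "inverse"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        traits = [TraitConfig(**t) for t in raw.pop("traits")]
        sig = SignificanceConfig(**raw.pop("significance", {}))
        return cls(traits=traits, significance=sig, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class RunManifest:
    version: str
    config_hash: str
    input_checksums: dict
    stage_counts: dict
    warnings: list

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _checksum_inputs(config: PipelineConfig) -> dict:
    sums = {}
    geno = Path(config.genotypes)
    for ext in (".bed", ".bim", ".fam"):
        f = geno.with_suffix(ext)
        if f.exists():
            sums[f.name] = _sha256(f)
    ph = Path(config.phenotypes)
    if ph.exists():
        sums[ph.name] = _sha256(ph)
    return sums


def run_full(config: PipelineConfig) -> RunManifest:
    """Execute the whole analysis; returns the run manifest (also persisted).

    Any stage failure raises :class:`PipelineError` naming the stage.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict = {}
    caught: list[str] = []

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")

        # --- genotype QC -------------------------------------------------
        geno = _stage("read_genotypes", lambda: read_plink(config.genotypes))
        counts["input"] = {"subjects": geno.n_subjects, "snps": geno.n_snps}

        geno, sample_report = _stage(
            "sample_qc", lambda: apply_sample_filters(geno, config.sample_miss_thr)
        )
        geno2, snp_report = _stage(
            "snp_qc",
            lambda: apply_snp_filters(
                geno, config.hwe_thr, config.maf_thr, config.snp_call_thr
            ),
        )
        geno = geno2
        (out / "qc_samples.json").write_text(sample_report.to_json() + "\n")
        (out / "qc_snps.json").write_text(snp_report.to_json() + "\n")
        counts["post_qc"] = {"subjects": geno.n_subjects, "snps": geno.n_snps}

        # --- relatedness -------------------------------------------------
        grm = _stage("grm", lambda: compute_grm(geno))
        write_grm_gcta(grm, out / "grm_all")
        pcs = _stage("pca", lambda: compute_pcs(grm, k=config.n_pcs))
        write_pcs(pcs, out / "pcs.tsv")
        pc_df = pcs.ids.copy()
        for j in range(pcs.k):
            pc_df[f"PC{j + 1}"] = pcs.scores[:, j]

        # --- phenotypes --------------------------------------------------
        pheno = _stage("read_phenotypes", lambda: read_phenotypes(config.phenotypes))
        pheno = _stage(
            "transforms", lambda: apply_trait_transforms(pheno, config.traits)
        )
        pheno, sparse_report = _stage(
            "sparse_periods",
            lambda: exclude_sparse_trait_periods(pheno, config.max_period_missing),
        )
        sparse_report.to_csv(out / "period_exclusions.tsv", sep="\t", index=False)
        pheno = _stage(
            "min_measurements",
            lambda: filter_min_measurements(pheno, config.min_measurements),
        )
        counts["phenotype_rows"] = int(len(pheno))

        # subjects must be genotyped; align everything to genotype order
        iids = geno.sample_meta["iid"]
        pheno = pheno[pheno["subject_id"].isin(set(iids))].reset_index(drop=True)

        # --- two-stage trajectories -------------------------------------
        weight_tables, traj_tables = [], []
        for cfg in config.traits:
            if not (pheno["trait"] == cfg.name).any():
                caught.append(f"trait {cfg.name} absent from phenotype table")
                continue
            w = _stage(
                f"weights[{cfg.name}]",
                lambda cfg=cfg: estimate_period_weights(pheno, cfg.name, pcs=pc_df),
            )
            weight_tables.append(w)
            tr = _stage(
                f"trajectories[{cfg.name}]",
                lambda cfg=cfg, w=w: fit_subject_trajectories(
                    pheno, w, cfg.name, weight_mode=config.weight_mode
                ),
            )
            traj_tables.append(tr)
        if not traj_tables:
            raise PipelineError("stage 'trajectories' failed: no usable traits")
        weights = pd.concat(weight_tables, ignore_index=True)
        trajectories = pd.concat(traj_tables, ignore_index=True)
        weights.to_csv(out / "period_weights.tsv", sep="\t", index=False)
        trajectories.to_csv(out / "trajectories.tsv", sep="\t", index=False)
        counts["trajectory_rows"] = int(len(trajectories))

        # --- GREML per trait, B0 and B1 ---------------------------------
        sex_by_iid = geno.sample_meta.set_index("iid")["sex"]
        grms_by_chrom = None
        herit_rows = []
        fits = {}
        for tr in traj_tables:
            trait = tr["trait"].iat[0]
            aligned = tr.set_index("subject_id").reindex(iids)
            ok = aligned["B0"].notna().to_numpy()
            idx = np.where(ok)[0]
            if idx.size < 30:
                caught.append(f"trait {trait}: too few subjects for GREML; skipped")
                continue
            A = grm.values[np.ix_(idx, idx)]
            Xcov = np.column_stack(
                [
                    np.ones(idx.size),
                    aligned["mean_age"].to_numpy(float)[idx],
                    sex_by_iid.reindex(iids).to_numpy(float)[idx],
                ]
            )
            for response in ("B0", "B1"):
                y = aligned[response].to_numpy(float)[idx]
                fit = _stage(
                    f"greml[{trait}:{response}]",
                    lambda y=y, Xcov=Xcov, A=A: fit_greml(
                        y, Xcov, [A], component_labels=["all"],
                        max_iter=config.reml_max_iter,
                    ),
                )
                fits[(trait, response)] = (fit, idx)
                herit_rows.append(
                    {
                        "trait": trait,
                        "response": response,
                        "n": fit.n,
                        "h2": fit.h2,
                        "se": fit.se_h2,
                        "sigma2_g": float(fit.sigma2_g.sum()),
                        "sigma2_e": fit.sigma2_e,
                        "logL0": fit.loglik_null,
                        "logL1": fit.loglik,
                        "LRT": fit.lrt,
                        "p": fit.pvalue,
                        "status": fit.status,
                    }
                )
        herit = pd.DataFrame(herit_rows)
        if herit.empty:
            raise PipelineError("stage 'greml' failed: no trait could be fit")
        for response in ("B0", "B1"):
            mask = herit["response"] == response
            herit.loc[mask, "fdr"] = bh_fdr(herit.loc[mask, "p"])
        herit.to_csv(out / "heritability.tsv", sep="\t", index=False)
        counts["heritability_fits"] = int(len(herit))

        # --- chromosomal partition for the top-B1 trait ------------------
        if config.chromosomal != "none":
            b1 = herit[herit["response"] == "B1"]
            if config.chromosomal == "auto":
                top_trait = b1.sort_values("h2", ascending=False)["trait"].iat[0]
            else:
                top_trait = config.chromosomal
                if top_trait not in set(b1["trait"]):
                    raise PipelineError(
                        f"stage 'chromosomal' failed: no B1 fit for trait {top_trait!r}"
                    )
            fit, idx = fits[(top_trait, "B1")]
            grms_by_chrom = _stage(
                "chromosome_grms", lambda: partition_by_chromosome(geno)
            )
            sub_grms = [g.values[np.ix_(idx, idx)] for g in grms_by_chrom]
            labels = [g.component for g in grms_by_chrom]
            tr = traj_tables[[t["trait"].iat[0] for t in traj_tables].index(top_trait)]
            aligned = tr.set_index("subject_id").reindex(iids)
            y = aligned["B1"].to_numpy(float)[idx]
            Xcov = np.column_stack(
                [
                    np.ones(idx.size),
                    aligned["mean_age"].to_numpy(float)[idx],
                    sex_by_iid.reindex(iids).to_numpy(float)[idx],
                ]
            )
            cfit = _stage(
                "chromosomal_greml",
                lambda: fit_chromosomal(
                    y, Xcov, sub_grms, component_labels=labels,
                    max_iter=config.reml_max_iter,
                ),
            )
            snp_counts = np.array([g.m for g in grms_by_chrom], dtype=float)
            r, p_r = chromosome_length_correlation(cfit.h2_per_component, snp_counts)
            chrom_table = pd.DataFrame(
                {
                    "chrom": labels,
                    "n_snps": snp_counts.astype(int),
                    "h2_c": cfit.h2_per_component,
                    "se": cfit.se_sigma2[:-1] / cfit.total_variance,
                }
            )
            chrom_table.to_csv(out / f"chromosomal_{top_trait}_B1.tsv", sep="\t", index=False)
            (out / "chromosome_length_correlation.json").write_text(
                json.dumps({"trait": top_trait, "r": r, "p": p_r}) + "\n"
            )
            counts["chromosomal"] = {"trait": top_trait, "status": cfit.status}

        # --- GWAS --------------------------------------------------------
        if config.run_gwas:
            gwas_tables = []
            for (trait, response), (fit, idx) in fits.items():
                tr = traj_tables[[t["trait"].iat[0] for t in traj_tables].index(trait)]
                aligned = tr.set_index("subject_id").reindex(iids)
                y = aligned[response].to_numpy(float)
                cov = np.column_stack(
                    [
                        aligned["mean_age"].to_numpy(float),
                        sex_by_iid.reindex(iids).to_numpy(float),
                        pcs.scores,
                    ]
                )
                res = _stage(
                    f"gwas[{trait}:{response}]",
                    lambda y=y, cov=cov, trait=trait, response=response: run_gwas(
                        y, geno, cov, model_tag=f"{trait}:{response}"
                    ),
                )
                gwas_tables.append(res)
            gwas = classify_hits(pd.concat(gwas_tables, ignore_index=True), config.significance)
            gwas.to_csv(out / "gwas.tsv", sep="\t", index=False)
            hits = gwas[gwas["category"].isin(["genome_wide", "suggestive"])]
            hits.to_csv(out / "gwas_hits.tsv", sep="\t", index=False)
            lambdas = {
                tag: genomic_inflation(grp["p"].dropna())[0]
                for tag, grp in gwas.groupby("model")
            }
            (out / "lambda_gc.json").write_text(json.dumps(lambdas, indent=2) + "\n")
            gwas[["model", "chrom", "pos", "p"]].to_csv(
                out / "manhattan.tsv", sep="\t", index=False
            )
            counts["gwas_tests"] = int(gwas["p"].notna().sum())

        caught.extend(str(w.message) for w in wrec)

    cfg_dict = config.to_dict()
    manifest = RunManifest(
        version=__version__,
        config_hash=hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        input_checksums=_checksum_inputs(config),
        stage_counts=counts,
        warnings=caught,
    )
    manifest.write(out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# demo data
# ---------------------------------------------------------------------------

#: (name, transform, h2_B0, h2_B1, mean level on the simulated scale)
DEMO_TRAITS = [
    ("trait_a", "identity", 0.5, 0.2, 0.0),
    ("trait_b", "identity", 0.3, 0.0, 0.0),
    ("trait_c", "identity", 0.0, 0.0, 0.0),
    ("trait_d", "log", 0.4, 0.1, 3.0),
]


def make_demo_dataset(
    outdir: str | Path,
    seed: int = 0,
    n_subjects: int = 300,
    n_snps: int = 1000,
    traits: list[tuple] | None = None,
    missing_visit_prob: float = 0.1,
) -> PipelineConfig:
    """Write a small coherent cohort (genotypes + long phenotypes + truth
    sidecars + config) that :func:`run_full` can consume without edits.

    Four traits by default, with mixed heritabilities and one trait simulated
    on the log scale (exponentiated before writing, so the pipeline's log
    transform recovers it).  The seed changes the data, never the schema.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    traits = traits if traits is not None else DEMO_TRAITS

    base = SimulationConfig(
        n_subjects=n_subjects,
        n_snps=n_snps,
        maf_range=(0.02, 0.5),      # leaves a few SNPs for the MAF filter
        missing_visit_prob=missing_visit_prob,
        seed=seed,
    )
    geno = simulate_genotypes(base)

    # sprinkle missing genotype calls so QC has work to do
    rng = np.random.default_rng([seed, 99])
    miss = rng.random(geno.dosages.shape) < 0.01
    geno.dosages[miss] = np.nan

    tables = []
    for name, transform, h2_b0, h2_b1, mean_level in traits:
        cfg = SimulationConfig(
            n_subjects=n_subjects,
            n_snps=n_snps,
            maf_range=(0.02, 0.5),
            h2_B0=h2_b0,
            h2_B1=h2_b1,
            missing_visit_prob=missing_visit_prob,
            mean_level=mean_level,
            seed=seed,
        )
        table, truth = simulate_longitudinal_phenotypes(geno, cfg, trait_name=name)
        if transform == "log":
            table = table.assign(value=np.exp(table["value"]))
        truth.write(outdir / f"truth_{name}")
        tables.append(table)
    write_phenotypes(pd.concat(tables, ignore_index=True), outdir / "phenotypes.tsv")
    write_plink(geno, outdir / "geno")

    config = PipelineConfig(
        genotypes=str(outdir / "geno"),
        phenotypes=str(outdir / "phenotypes.tsv"),
        outdir=str(outdir / "results"),
        traits=[TraitConfig(name, transform) for name, transform, *_ in traits],
        seed=seed,
    )
    cfg_dict = config.to_dict()
    cfg_dict["traits"] = [
        {"name": t.name, "transform": t.transform, "group": t.group} for t in config.traits
    ]
    cfg_dict["significance"] = asdict(config.significance)
    (outdir / "config.yaml").write_text(yaml.safe_dump(cfg_dict, sort_keys=False))
    return config
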