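#!/usr/bin/env python
"""Genotype QC and relatedness: sample/SNP filters, GRM, top-10 PCs.

Reads the cohort written by 01_simulate_cohort.py, applies the strict QC
thresholds (HWE p < 1e-5, MAF < 0.05, call rate < 95%, sample missingness
> 5%), and stores the post-QC genotypes, the GCTA-format GRM and the PC
covariate file under scratch/.  A QC summary table goes to results/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from longreml import (
    apply_sample_filters, apply_snp_filters, compute_grm, compute_pcs,
    read_plink, write_grm_gcta, write_plink,
)
from longreml.grm import write_pcs

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def main() -> None:
    geno = read_plink(COHORT / "geno")
    geno, sample_report = apply_sample_filters(geno)
    geno, snp_report = apply_snp_filters(geno)
    write_plink(geno, COHORT / "geno_qc")

    grm = compute_grm(geno)
    write_grm_gcta(grm, COHORT / "grm_all")
    pcs = compute_pcs(grm, k=10)
    write_pcs(pcs, COHORT / "pcs.tsv")

    RESULTS.mkdir(exist_ok=True)
    summary = {
        "samples": json.loads(sample_report.to_json()),
        "snps": json.loads(snp_report.to_json()),
        "grm_mean_diagonal": float(np.diag(grm.values).mean()),
        "grm_mean_offdiagonal": float(grm.values[np.triu_indices(grm.n_subjects, 1)].mean()),
        "pc_eigenvalues": [float(v) for v in pcs.eigenvalues],
    }
    (RESULTS / "qc_relatedness_summary.json").write_text(json.dumps(summary, indent=2) + "\n")

    print(f"samples: {sample_report.n_kept}/{sample_report.n_input} kept "
          f"({sample_report.removed})")
    print(f"SNPs:    {snp_report.n_kept}/{snp_report.n_input} kept "
          f"({snp_report.removed})")
    print(f"GRM mean diagonal {summary['grm_mean_diagonal']:.4f} "
          f"(≈1 expected for unrelated subjects)")
    print("top-3 PC eigenvalues:", np.round(pcs.eigenvalues[:3], 3),
          "- no structure simulated, spectrum should be flat")
    _ = pd


if __name__ == "__main__":
    main()
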