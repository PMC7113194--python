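#!/usr/bin/env python
"""GREML heritability of trait levels (B0) and longitudinal changes (B1).

For each of the 16 traits, fits the single-GRM variance-component model to B0
and B1 separately (covariates: subject mean age and sex), computes the
boundary-mixture LRT p-value, and adjusts across traits by Benjamini-Hochberg
within each response.  Writes the two heritability tables to results/ and
reports which traits remain FDR-significant for longitudinal change.
"""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from longreml import bh_fdr, fit_greml, read_plink
from longreml.grm import read_grm_gcta
from longreml.pipeline import PipelineConfig

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def main() -> None:
    config = PipelineConfig.from_yaml(COHORT / "config.yaml")
    geno = read_plink(COHORT / "geno_qc")
    grm = read_grm_gcta(COHORT / "grm_all")
    iids = geno.sample_meta["iid"]
    sex = geno.sample_meta.set_index("iid")["sex"]

    rows = []
    for cfg in config.traits:
        traj = pd.read_csv(
            COHORT / f"trajectories_{cfg.name}.tsv", sep="\t", dtype={"subject_id": str}
        ).set_index("subject_id").reindex(iids)
        idx = np.where(traj["B0"].notna().to_numpy())[0]
        X = np.column_stack(
            [
                np.ones(idx.size),
                traj["mean_age"].to_numpy(float)[idx],
                sex.reindex(iids).to_numpy(float)[idx],
            ]
        )
        A = grm.values[np.ix_(idx, idx)]
        for resp in ("B0", "B1"):
            y = traj[resp].to_numpy(float)[idx]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_greml(y, X, [A])
            rows.append(
                {
                    "trait": cfg.name, "response": resp, "n": fit.n,
                    "h2": fit.h2, "se": fit.se_h2, "p": fit.pvalue,
                    "status": fit.status,
                }
            )
    herit = pd.DataFrame(rows)
    for resp in ("B0", "B1"):
        mask = herit["response"] == resp
        herit.loc[mask, "fdr"] = bh_fdr(herit.loc[mask, "p"])

    for resp in ("B0", "B1"):
        tab = herit[herit["response"] == resp].sort_values("h2", ascending=False)
        tab.to_csv(RESULTS / f"heritability_{resp}.tsv", sep="\t", index=False)

    b1 = herit[herit["response"] == "B1"].sort_values("h2", ascending=False)
    sig = b1[b1["fdr"] < 0.05]
    print("top B1 heritability:",
          b1[["trait", "h2", "se", "p", "fdr"]].head(3).round(4).to_string(index=False))
    print(f"{len(sig)} trait(s) FDR-significant for longitudinal change:",
          ", ".join(sig["trait"]))


if __name__ == "__main__":
    main()
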