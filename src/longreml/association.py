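"""Per-SNP linear-regression GWAS on trajectory summaries, with FDR utilities.

Each SNP is tested by ordinary least squares of the response (a subject-level
B0 or B1 vector) on intercept + additive dosage + covariates (typically mean
age, sex, and the top genetic principal components), with a two-sided t-test
on the dosage coefficient.  Subjects with a missing dosage are dropped per
SNP.  Genome-wide (p < 1e-7) and suggestive (p < 1e-5) thresholds use strict
inequalities; Benjamini-Hochberg adjustment is shared with the heritability
report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ParameterError
from .genotype import GenotypeMatrix

_CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, df=1))  # 0.4549...


@dataclass(frozen=True)
class SignificanceConfig:
    genome_wide: float = 1e-7
    suggestive: float = 1e-5
    fdr_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not self.genome_wide <= self.suggestive:
            raise ParameterError("genome-wide threshold must not exceed suggestive")


def run_gwas(
    response: pd.Series | np.ndarray,
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame | np.ndarray | None = None,
    model_tag: str = "",
) -> pd.DataFrame:
    """OLS association of every SNP with a subject-level response.

    ``response`` must be aligned with ``genotypes`` rows (NaN allowed; those
    subjects are dropped).  Monomorphic SNPs after subsetting yield NA rows
    with a ``reason``.  Raises on rank-deficient covariates.
    """
    y = np.asarray(response, dtype=float).ravel()
    n = genotypes.n_subjects
    if y.size != n:
        raise ParameterError(f"response length {y.size} != {n} genotyped subjects")

    if covariates is None:
        C = np.ones((n, 1))
    else:
        C = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
    base_ok = np.isfinite(y) & np.isfinite(C).all(axis=1)
    if np.linalg.matrix_rank(C[base_ok]) < C.shape[1]:
        raise ParameterError("covariate matrix is rank deficient")

    maf = genotypes.maf()
    hwe = genotypes.hwe_pvalues()
    meta = genotypes.snp_meta

    rows = []
    D = genotypes.dosages
    for j in range(genotypes.n_snps):
        x = D[:, j]
        ok = base_ok & np.isfinite(x)
        rec = {
            "snp_id": meta["snp_id"].iat[j],
            "chrom": meta["chrom"].iat[j],
            "pos": meta["pos"].iat[j],
            "a1": meta["a1"].iat[j],
            "a2": meta["a2"].iat[j],
            "maf": maf[j],
            "hwe_p": hwe[j],
            "model": model_tag,
        }
        xj = x[ok]
        too_few = ok.sum() < C.shape[1] + 2
        if too_few or np.all(xj == xj[0]):
            rec.update(
                n=int(ok.sum()), beta=np.nan, se=np.nan, t=np.nan, p=np.nan,
                reason="insufficient data" if too_few else "monomorphic",
            )
            rows.append(rec)
            continue

        G = np.column_stack([C[ok], xj])
        yj = y[ok]
        beta, _, rank, _ = np.linalg.lstsq(G, yj, rcond=None)
        resid = yj - G @ beta
        dof = int(ok.sum()) - rank
        s2 = float(resid @ resid) / dof
        XtX_inv = np.linalg.pinv(G.T @ G)
        se = float(np.sqrt(max(s2 * XtX_inv[-1, -1], 0.0)))
        b = float(beta[-1])
        if se == 0.0:
            t = np.inf if b != 0 else 0.0
        else:
            t = b / se
        p = float(2.0 * stats.t.sf(abs(t), dof))
        p = max(p, np.nextafter(0, 1))  # perfect fits underflow to the smallest tail
        rec.update(n=int(ok.sum()), beta=b, se=se, t=t, p=p, reason="")
        rows.append(rec)
    return pd.DataFrame(rows)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1);
    NA inputs propagate to NA outputs and do not count toward m."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    q = p[ok]
    if q.size == 0:
        return out
    if (q <= 0).any() or (q > 1).any():
        raise ParameterError("p-values must lie in (0, 1]")
    m = q.size
    order = np.argsort(q, kind="stable")
    ranked = q[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adjusted, 1.0)
    out[ok] = adj
    return out


def classify_hits(results: pd.DataFrame, config: SignificanceConfig | None = None) -> pd.DataFrame:
    """Tag each SNP as genome_wide / suggestive / ns (strict '<' comparisons)
    and return the table sorted by p within each model tag."""
    config = config or SignificanceConfig()
    out = results.copy()
    p = out["p"].to_numpy(dtype=float)
    cat = np.where(
        p < config.genome_wide, "genome_wide", np.where(p < config.suggestive, "suggestive", "ns")
    )
    cat = np.where(np.isfinite(p), cat, "na")
    out["category"] = cat
    sort_cols = ["model", "p"] if "model" in out.columns else ["p"]
    return out.sort_values(sort_cols, kind="stable").reset_index(drop=True)


def genomic_inflation(pvalues) -> tuple[float, pd.DataFrame]:
    """Genomic-control lambda and an observed-vs-expected -log10 p table.

    lambda is the median association chi-square (from two-sided p-values, 1 df)
    divided by the theoretical null median 0.4549.
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ParameterError("no finite p-values")
    chi2 = stats.chi2.isf(p, df=1)
    lam = float(np.median(chi2) / _CHI2_MEDIAN_1DF)
    obs = np.sort(p)
    expected = (np.arange(1, p.size + 1) - 0.5) / p.size
    qq = pd.DataFrame(
        {"expected_neglog10": -np.log10(expected), "observed_neglog10": -np.log10(obs)}
    )
    return lam, qq
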