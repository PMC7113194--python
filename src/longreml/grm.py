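"""Genetic relationship matrices and principal-component covariates.

The realized-relationship estimator follows the GCTA form: off-diagonal

    A_jk = (1/m) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))

and a distinct diagonal

    A_jj = 1 + (1/m) * sum_i (x_ij^2 - (1 + 2 p_i) x_ij + 2 p_i^2) / (2 p_i (1 - p_i))

with allele frequencies p_i estimated in-sample and missing genotypes handled
by pairwise deletion (per-pair SNP counts are kept).  With many independent
HWE markers the mean diagonal approaches 1 and off-diagonals approach 0 for
unrelated subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError, ParameterError
from .genotype import GenotypeMatrix


@dataclass
class GRM:
    """Symmetric relationship matrix with per-pair SNP counts."""

    values: np.ndarray          # (n, n) float64, symmetric
    n_snps: np.ndarray          # (n, n) int, SNPs used per pair
    ids: pd.DataFrame           # columns fid, iid
    component: str = "all"      # "all" or a chromosome label

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        """Nominal SNP count of the component (max over pairs)."""
        return int(self.n_snps.max())


@dataclass
class PCScores:
    """Top-k principal components of a GRM, ordered by decreasing eigenvalue."""

    scores: np.ndarray          # (n, k), eigenvector * sqrt(eigenvalue)
    eigenvalues: np.ndarray     # (k,)
    ids: pd.DataFrame

    @property
    def k(self) -> int:
        return self.scores.shape[1]


def compute_grm(
    genotypes: GenotypeMatrix, component: str | int = "all", missing: str = "pairwise"
) -> GRM:
    """Build the realized-relationship matrix from post-QC genotypes.

    ``component`` restricts to one chromosome; monomorphic SNPs are excluded
    with a warning.  ``missing='pairwise'`` (default) divides each pair by its
    own non-missing SNP count; ``missing='mean'`` divides by the full count
    (equivalent to imputing missing dosages at 2p).
    """
    if missing not in ("pairwise", "mean"):
        raise ParameterError(f"unknown missing-data mode {missing!r}")

    if component == "all":
        X = genotypes.dosages
        ids = genotypes.sample_meta[["fid", "iid"]].reset_index(drop=True)
        label = "all"
    else:
        mask = genotypes.snp_meta["chrom"].to_numpy() == int(component)
        if not mask.any():
            raise ParameterError(f"no SNPs on chromosome {component}")
        X = genotypes.dosages[:, mask]
        ids = genotypes.sample_meta[["fid", "iid"]].reset_index(drop=True)
        label = str(int(component))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(X, axis=0) / 2.0
    poly = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    if not poly.all():
        warnings.warn(
            f"excluding {int((~poly).sum())} monomorphic/all-missing SNPs from GRM",
            stacklevel=2,
        )
        X = X[:, poly]
        p = p[poly]
    if X.shape[1] == 0:
        raise ParameterError("no polymorphic SNPs available for the GRM")

    het = 2.0 * p * (1.0 - p)
    obs = np.isfinite(X)
    U = np.where(obs, (X - 2.0 * p) / np.sqrt(het), 0.0)

    numer = U @ U.T
    counts = obs.astype(np.float64) @ obs.astype(np.float64).T
    if missing == "mean":
        counts = np.full_like(counts, X.shape[1])
    if (counts == 0).any():
        raise ParameterError("some subject pairs share zero non-missing SNPs")

    A = numer / counts
    # GCTA diagonal: 1 + mean of (x^2 - (1+2p) x + 2p^2) / 2p(1-p) over observed SNPs
    diag_terms = np.where(obs, (X * X - (1.0 + 2.0 * p) * X + 2.0 * p * p) / het, 0.0)
    np.fill_diagonal(A, 1.0 + diag_terms.sum(axis=1) / np.diag(counts))

    return GRM(values=A, n_snps=np.round(counts).astype(int), ids=ids, component=label)


def partition_by_chromosome(genotypes: GenotypeMatrix) -> list[GRM]:
    """One GRM per autosome present in the panel (empty chromosomes skipped)."""
    grms: list[GRM] = []
    present = sorted(set(int(c) for c in genotypes.snp_meta["chrom"]))
    for c in range(1, 23):
        if c not in present:
            warnings.warn(f"chromosome {c} has no SNPs; skipped", stacklevel=2)
            continue
        grms.append(compute_grm(genotypes, component=c))
    return grms


def aggregate_grms(grms: list[GRM]) -> GRM:
    """SNP-count-weighted average of component GRMs.

    With no missing data this reproduces the genome-wide GRM exactly
    (the estimator is a per-SNP average).
    """
    numer = np.zeros_like(grms[0].values)
    diag_numer = np.zeros(grms[0].n_subjects)
    counts = np.zeros_like(grms[0].n_snps)
    for g in grms:
        numer += g.values * g.n_snps
        diag_numer += (np.diag(g.values) - 1.0) * np.diag(g.n_snps)
        counts += g.n_snps
    A = numer / counts
    np.fill_diagonal(A, 1.0 + diag_numer / np.diag(counts))
    return GRM(values=A, n_snps=counts, ids=grms[0].ids, component="aggregate")


def compute_pcs(grm: GRM, k: int = 10) -> PCScores:
    """Top-k eigenvectors of A scaled by sqrt(eigenvalue).

    The sign of each component is fixed by making its largest-magnitude
    loading positive, so covariate files are reproducible.
    """
    n = grm.n_subjects
    if k > n - 1:
        raise ParameterError(f"k={k} principal components require at least {k + 1} subjects")
    if not np.isfinite(grm.values).all():
        raise ParameterError("GRM contains non-finite entries")

    eigval, eigvec = np.linalg.eigh(grm.values)
    order = np.argsort(eigval)[::-1][:k]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    for j in range(k):
        i = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    scores = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
    return PCScores(scores=scores, eigenvalues=eigval, ids=grm.ids.copy())


def write_pcs(pcs: PCScores, path: str | Path) -> None:
    """Tab-separated covariate file: FID IID PC1..PCk."""
    df = pcs.ids.copy()
    for j in range(pcs.k):
        df[f"PC{j + 1}"] = pcs.scores[:, j]
    df.to_csv(path, sep="\t", index=False)


def read_pcs(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"fid": str, "iid": str})


# ---------------------------------------------------------------------------
# GCTA binary GRM dialect
# ---------------------------------------------------------------------------

def _tri_size(n: int) -> int:
    return n * (n + 1) // 2


def write_grm_gcta(grm: GRM, prefix: str | Path) -> None:
    """Write prefix.grm.bin / prefix.grm.N.bin / prefix.grm.id.

    Lower triangle (diagonal included), row-major, little-endian float32.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n = grm.n_subjects
    il = np.tril_indices(n)
    grm.values[il].astype("<f4").tofile(f"{prefix}.grm.bin")
    grm.n_snps[il].astype("<f4").tofile(f"{prefix}.grm.N.bin")
    grm.ids[["fid", "iid"]].to_csv(f"{prefix}.grm.id", sep="\t", header=False, index=False)


def read_grm_gcta(prefix: str | Path, component: str = "all") -> GRM:
    """Read a GCTA binary GRM triple; sizes must match the id file."""
    prefix = Path(prefix)
    ids = pd.read_csv(
        f"{prefix}.grm.id", sep=r"\s+", header=None, names=["fid", "iid"], dtype=str
    )
    n = len(ids)
    expected = _tri_size(n)

    tri = np.fromfile(f"{prefix}.grm.bin", dtype="<f4")
    if tri.size != expected:
        raise FormatError(
            f"{prefix}.grm.bin holds {tri.size} floats but {n} ids need {expected}"
        )
    tri_n = np.fromfile(f"{prefix}.grm.N.bin", dtype="<f4")
    if tri_n.size != expected:
        raise FormatError(
            f"{prefix}.grm.N.bin holds {tri_n.size} floats but {n} ids need {expected}"
        )

    A = np.zeros((n, n))
    counts = np.zeros((n, n))
    il = np.tril_indices(n)
    A[il] = tri
    counts[il] = tri_n
    A = A + A.T - np.diag(np.diag(A))
    counts = counts + counts.T - np.diag(np.diag(counts))
    return GRM(values=A, n_snps=np.round(counts).astype(int), ids=ids, component=component)
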