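"""Genotype container, PLINK bed/bim/fam I/O, and variant/sample quality control.

Genotypes are held as a subjects x SNPs dosage matrix counting copies of
allele1 (A1), with ``numpy.nan`` marking missing calls.  QC mirrors standard
GWAS practice: variants are removed for Hardy-Weinberg disequilibrium, low
minor-allele frequency, or low call rate; samples are removed for high
genotype missingness.  All thresholds use strict inequalities.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import FormatError, ParameterError, PipelineError

_PLINK_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01

# 2-bit PLINK codes -> A1 dosage. 0b00 hom A1, 0b10 het, 0b11 hom A2, 0b01 missing.
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


@dataclass
class GenotypeMatrix:
    """Dosage matrix (subjects x SNPs, copies of A1) with per-axis metadata.

    ``snp_meta`` columns: chrom, snp_id, cm, pos, a1, a2.
    ``sample_meta`` columns: fid, iid, father, mother, sex, phenotype.
    """

    dosages: np.ndarray
    snp_meta: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        n, m = self.dosages.shape
        if len(self.snp_meta) != m:
            raise ParameterError(f"snp_meta has {len(self.snp_meta)} rows for {m} SNPs")
        if len(self.sample_meta) != n:
            raise ParameterError(
                f"sample_meta has {len(self.sample_meta)} rows for {n} subjects"
            )
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ParameterError("dosages must be 0, 1, 2 or missing (nan)")

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def allele1_frequencies(self) -> np.ndarray:
        """Sample frequency of A1 per SNP, over non-missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-missing SNP -> nan
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele1_frequencies()
        return np.minimum(p, 1.0 - p)

    def snp_call_rates(self) -> np.ndarray:
        # exact integer ratio so strict threshold comparisons are stable
        n = self.dosages.shape[0]
        return (~np.isnan(self.dosages)).sum(axis=0) / n

    def snp_missing_rates(self) -> np.ndarray:
        n = self.dosages.shape[0]
        return np.isnan(self.dosages).sum(axis=0) / n

    def sample_call_rates(self) -> np.ndarray:
        m = self.dosages.shape[1]
        return (~np.isnan(self.dosages)).sum(axis=1) / m

    def sample_missing_rates(self) -> np.ndarray:
        m = self.dosages.shape[1]
        return np.isnan(self.dosages).sum(axis=1) / m

    def genotype_counts(self) -> np.ndarray:
        """Per-SNP (n_hom_a1, n_het, n_hom_a2) counts over non-missing calls."""
        d = self.dosages
        return np.stack(
            [np.nansum(d == 2.0, axis=0), np.nansum(d == 1.0, axis=0), np.nansum(d == 0.0, axis=0)],
            axis=1,
        ).astype(int)

    def hwe_pvalues(self, method: str = "chisq") -> np.ndarray:
        counts = self.genotype_counts()
        return np.array([hwe_test(h1, het, h2, method=method) for h1, het, h2 in counts])

    def subset(self, samples: np.ndarray | None = None, snps: np.ndarray | None = None) -> "GenotypeMatrix":
        """Return a copy restricted to the given boolean/int indexers."""
        d = self.dosages
        sm = self.sample_meta
        vm = self.snp_meta
        if samples is not None:
            d = d[samples, :]
            sm = sm.iloc[np.arange(len(sm))[samples]].reset_index(drop=True)
        if snps is not None:
            d = d[:, snps]
            vm = vm.iloc[np.arange(len(vm))[snps]].reset_index(drop=True)
        return GenotypeMatrix(d.copy(), vm.copy(), sm.copy())


@dataclass
class QCReport:
    """Bookkeeping for one filtering pass; removed + kept = input."""

    axis: str  # "snp" or "sample"
    n_input: int
    removed: dict = field(default_factory=dict)
    n_kept: int = 0

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())

    def check_conserved(self) -> None:
        if self.n_removed + self.n_kept != self.n_input:
            raise AssertionError("QC counts not conserved")

    def to_json(self) -> str:
        return json.dumps(
            {"axis": self.axis, "n_input": self.n_input, "removed": self.removed, "n_kept": self.n_kept}
        )

    def to_tsv(self) -> str:
        lines = ["rule\tremoved"]
        lines += [f"{rule}\t{n}" for rule, n in self.removed.items()]
        lines.append(f"kept\t{self.n_kept}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam
# ---------------------------------------------------------------------------

def write_plink(genotypes: GenotypeMatrix, prefix: str | Path) -> None:
    """Write bed (SNP-major v1.00) + bim + fam files at ``prefix``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = genotypes.dosages.shape

    # dosage -> 2-bit code: 2 -> 00, 1 -> 10, 0 -> 11, nan -> 01
    d = genotypes.dosages
    codes = np.full((m, n), 0b01, dtype=np.uint8)  # SNP-major
    dt = d.T
    codes[dt == 2.0] = 0b00
    codes[dt == 1.0] = 0b10
    codes[dt == 0.0] = 0b11

    n_pad = (-n) % 4
    if n_pad:
        pad = np.zeros((m, n_pad), dtype=np.uint8)  # padding bits are hom A1 (00)
        codes = np.concatenate([codes, pad], axis=1)
    codes = codes.reshape(m, -1, 4)
    packed = codes[:, :, 0] | codes[:, :, 1] << 2 | codes[:, :, 2] << 4 | codes[:, :, 3] << 6

    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_PLINK_MAGIC + bytes([_SNP_MAJOR]))
        fh.write(packed.astype(np.uint8).tobytes())

    genotypes.snp_meta[["chrom", "snp_id", "cm", "pos", "a1", "a2"]].to_csv(
        prefix.with_suffix(".bim"), sep="\t", header=False, index=False
    )
    genotypes.sample_meta[["fid", "iid", "father", "mother", "sex", "phenotype"]].to_csv(
        prefix.with_suffix(".fam"), sep="\t", header=False, index=False
    )


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK bed/bim/fam triple into a :class:`GenotypeMatrix`."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": int, "snp_id": str, "pos": int, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype={"fid": str, "iid": str},
    )
    n, m = len(fam), len(bim)

    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if len(raw) < 3 or raw[:2] != _PLINK_MAGIC:
        raise FormatError(f"{prefix}.bed: bad magic bytes (not a PLINK v1 bed file)")
    if raw[2] != _SNP_MAJOR:
        raise FormatError(f"{prefix}.bed: only SNP-major mode (0x01) is supported")
    bytes_per_snp = math.ceil(n / 4)
    expected = 3 + bytes_per_snp * m
    if len(raw) != expected:
        raise FormatError(
            f"{prefix}.bed: {len(raw)} bytes, expected {expected} for "
            f"{n} samples x {m} SNPs (truncated or inconsistent bim/fam)"
        )

    packed = np.frombuffer(raw[3:], dtype=np.uint8).reshape(m, bytes_per_snp)
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    codes[:, 0::4] = packed & 0b11
    codes[:, 1::4] = (packed >> 2) & 0b11
    codes[:, 2::4] = (packed >> 4) & 0b11
    codes[:, 3::4] = (packed >> 6) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T.copy()

    return GenotypeMatrix(dosages, bim, fam)


# ---------------------------------------------------------------------------
# Hardy-Weinberg equilibrium
# ---------------------------------------------------------------------------

def hwe_test(n_hom_ref: int, n_het: int, n_hom_alt: int, method: str = "chisq") -> float:
    """Goodness-of-fit p-value against HWE proportions at the sample frequency.

    ``method='chisq'`` is the 1-df chi-square test; ``method='exact'`` is the
    conditional exact test enumerating heterozygote counts at fixed allele
    counts.  A monomorphic SNP returns p = 1 by convention.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ParameterError(f"negative genotype count in {counts}")
    n = sum(counts)
    if n < 1:
        raise ParameterError("empty genotype counts")

    n_a = 2 * n_hom_ref + n_het  # copies of the ref allele
    if n_a == 0 or n_a == 2 * n:
        return 1.0

    if method == "chisq":
        p = n_a / (2 * n)
        q = 1.0 - p
        expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
        observed = np.array(counts, dtype=float)
        stat = float(np.sum((observed - expected) ** 2 / expected))
        return float(stats.chi2.sf(stat, df=1))
    if method == "exact":
        return _hwe_exact(n_het, n_a, n)
    raise ParameterError(f"unknown HWE method {method!r}")


def _hwe_exact(n_het: int, n_a: int, n: int) -> float:
    """Conditional exact HWE test (sum of heterozygote-count probabilities
    no larger than the observed one, at fixed allele counts)."""
    rare = min(n_a, 2 * n - n_a)
    if n_het > rare or (rare - n_het) % 2 != 0:
        raise ParameterError("inconsistent het count for allele totals")

    # log P(n_het | rare, n) up to a shared constant, via log-factorials
    lf = np.zeros(2 * n + 1)
    lf[1:] = np.cumsum(np.log(np.arange(1, 2 * n + 1)))

    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    logp = hets * math.log(2.0) + lf[n] - lf[hets] - lf[hom_rare] - lf[hom_common]
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()

    obs = prob[hets == n_het][0]
    return float(min(1.0, prob[prob <= obs * (1 + 1e-10)].sum()))


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def apply_snp_filters(
    genotypes: GenotypeMatrix,
    hwe_thr: float = 1e-5,
    maf_thr: float = 0.05,
    call_thr: float = 0.95,
    hwe_method: str = "chisq",
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove SNPs with HWE p < hwe_thr, MAF < maf_thr or call rate < call_thr.

    A SNP failing several rules is attributed to the first failing rule in the
    order HWE -> MAF -> call rate.  Raises :class:`PipelineError` if no SNP
    survives.
    """
    for thr in (hwe_thr, maf_thr, call_thr):
        if not 0.0 <= thr <= 1.0:
            raise ParameterError(f"threshold {thr} outside [0, 1]")

    hwe_p = genotypes.hwe_pvalues(method=hwe_method)
    maf = genotypes.maf()
    call = genotypes.snp_call_rates()

    fail_hwe = hwe_p < hwe_thr
    fail_maf = maf < maf_thr
    fail_call = call < call_thr
    first_maf = fail_maf & ~fail_hwe
    first_call = fail_call & ~fail_hwe & ~fail_maf
    keep = ~(fail_hwe | fail_maf | fail_call)

    report = QCReport(
        axis="snp",
        n_input=genotypes.n_snps,
        removed={
            "hwe": int(fail_hwe.sum()),
            "maf": int(first_maf.sum()),
            "call_rate": int(first_call.sum()),
        },
        n_kept=int(keep.sum()),
    )
    report.check_conserved()
    if report.n_kept == 0:
        raise PipelineError("SNP QC removed every variant; nothing left to analyse")
    return genotypes.subset(snps=keep), report


def apply_sample_filters(
    genotypes: GenotypeMatrix, miss_thr: float = 0.05
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove subjects whose genotype missing rate is strictly above miss_thr."""
    if not 0.0 <= miss_thr <= 1.0:
        raise ParameterError(f"threshold {miss_thr} outside [0, 1]")
    miss = genotypes.sample_missing_rates()
    keep = ~(miss > miss_thr)
    report = QCReport(
        axis="sample",
        n_input=genotypes.n_subjects,
        removed={"missingness": int((~keep).sum())},
        n_kept=int(keep.sum()),
    )
    report.check_conserved()
    if report.n_kept == 0:
        raise PipelineError("sample QC removed every subject")
    return genotypes.subset(samples=keep), report
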