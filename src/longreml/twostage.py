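"""Two-stage longitudinal trajectory model.

Stage 1 estimates period- and trait-specific residual variances ``w_jk`` by
regressing the trait cross-sectionally (within each visit period) on sex, age
and the top genetic principal components.  Stage 2 fits, for every subject,
a weighted least-squares line of the trait on age centred at the subject's
own mean observed age; the intercept B0 is the subject's expected trait value
at that age and the slope B1 is the average annual change.  Observations from
noisier periods are down-weighted (weight proportional to 1/w_jk).

Inclusion rules applied around the model: skewed traits may be
log-transformed; a whole (trait, period) cell is excluded when its missing
rate exceeds 0.5; and a subject enters a trait's analysis only with at least
three non-missing measurements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError, ParameterError

TRAIT_GROUPS = ("anthropometric", "biochemistry", "cardiopulmonary", "red blood cell")


@dataclass(frozen=True)
class TraitConfig:
    """Per-trait analysis settings."""

    name: str
    transform: str = "identity"  # "identity" | "log"
    group: str = "anthropometric"

    def __post_init__(self) -> None:
        if self.transform not in ("identity", "log"):
            raise ParameterError(f"unknown transform {self.transform!r}")


def health_trait_panel() -> list[TraitConfig]:
    """A 16-trait panel of common health indices (four groups; skewed traits
    log-transformed), useful as a realistic multi-trait demo configuration."""
    return [
        TraitConfig("Height", "identity", "anthropometric"),
        TraitConfig("Waist", "identity", "anthropometric"),
        TraitConfig("Weight", "identity", "anthropometric"),
        TraitConfig("BMI", "identity", "anthropometric"),
        TraitConfig("HbA1c", "log", "biochemistry"),
        TraitConfig("GLU0", "log", "biochemistry"),
        TraitConfig("LDL", "identity", "biochemistry"),
        TraitConfig("HDL", "log", "biochemistry"),
        TraitConfig("TCHL", "identity", "biochemistry"),
        TraitConfig("TG", "log", "biochemistry"),
        TraitConfig("SBP", "log", "cardiopulmonary"),
        TraitConfig("DBP", "identity", "cardiopulmonary"),
        TraitConfig("FVC", "identity", "cardiopulmonary"),
        TraitConfig("FEV1", "identity", "cardiopulmonary"),
        TraitConfig("FEV1_FVC", "identity", "cardiopulmonary"),
        TraitConfig("Hb", "identity", "red blood cell"),
    ]


def apply_trait_transforms(
    pheno: pd.DataFrame, trait_configs: list[TraitConfig]
) -> pd.DataFrame:
    """Natural-log transform flagged traits; non-positive values become missing
    (with a warning); identity traits pass through untouched."""
    out = pheno.copy()
    for cfg in trait_configs:
        if cfg.transform != "log":
            continue
        mask = out["trait"] == cfg.name
        vals = out.loc[mask, "value"]
        bad = mask & (out["value"] <= 0)
        n_bad = int(bad.sum())
        if n_bad:
            warnings.warn(
                f"{cfg.name}: {n_bad} non-positive values set missing before log",
                stacklevel=2,
            )
            out.loc[bad, "value"] = np.nan
        with np.errstate(invalid="ignore"):
            out.loc[mask, "value"] = np.log(out.loc[mask, "value"].astype(float))
        _ = vals
    return out


def exclude_sparse_trait_periods(
    pheno: pd.DataFrame, max_missing: float = 0.5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop every (trait, period) cell whose missing rate is strictly above
    ``max_missing``.  Missing rate is 1 - observed / subjects-in-table.

    Returns the reduced table and a report of the excluded cells.
    """
    n_subjects = pheno["subject_id"].nunique()
    rows = []
    drop = pd.Series(False, index=pheno.index)
    for (trait, period), grp in pheno.groupby(["trait", "period"]):
        n_obs = int(grp["value"].notna().sum())
        miss = 1.0 - n_obs / n_subjects
        excluded = miss > max_missing
        rows.append(
            {"trait": trait, "period": period, "missing_rate": miss, "excluded": excluded}
        )
        if excluded:
            drop.loc[grp.index] = True
    report = pd.DataFrame(rows)
    return pheno.loc[~drop].reset_index(drop=True), report


def filter_min_measurements(pheno: pd.DataFrame, min_obs: int = 3) -> pd.DataFrame:
    """Per trait, keep only subjects with at least ``min_obs`` non-missing visits."""
    counts = (
        pheno.assign(obs=pheno["value"].notna())
        .groupby(["trait", "subject_id"])["obs"]
        .transform("sum")
    )
    return pheno.loc[counts >= min_obs].reset_index(drop=True)


def estimate_period_weights(
    pheno: pd.DataFrame,
    trait: str,
    pcs: pd.DataFrame | None = None,
    min_extra_df: int = 2,
) -> pd.DataFrame:
    """Stage 1: per-period residual variance of the trait after covariate
    adjustment (intercept + sex + age + PCs), across subjects of that period.

    Returns a table with columns trait, period, w, n, excluded.  Periods with
    too few subjects relative to the covariate count are excluded with a
    warning; an exactly-zero residual variance raises
    :class:`DegenerateDataError` naming the cell.
    """
    pc_cols = []
    pc_lookup = None
    if pcs is not None:
        pc_cols = [c for c in pcs.columns if c.upper().startswith("PC")]
        pc_lookup = pcs.set_index("iid")[pc_cols] if "iid" in pcs.columns else pcs[pc_cols]

    sub = pheno.loc[(pheno["trait"] == trait) & pheno["value"].notna()]
    rows = []
    for period, grp in sub.groupby("period"):
        cols = [np.ones(len(grp)), grp["sex"].to_numpy(float), grp["age"].to_numpy(float)]
        if pc_lookup is not None:
            cols.extend(
                pc_lookup.reindex(grp["subject_id"])[c].to_numpy(float) for c in pc_cols
            )
        X = np.column_stack(cols)
        y = grp["value"].to_numpy(float)
        n, p = X.shape
        if n < p + min_extra_df + 1:
            warnings.warn(
                f"{trait} period {period}: {n} subjects cannot support {p} covariates; excluded",
                stacklevel=2,
            )
            rows.append({"trait": trait, "period": period, "w": np.nan, "n": n, "excluded": True})
            continue
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = n - rank
        w = float(resid @ resid) / dof
        if w <= np.finfo(float).eps * max(1.0, float(y @ y)):
            raise DegenerateDataError(
                f"{trait} period {period}: zero residual variance (trait is an exact "
                "linear function of the covariates)"
            )
        rows.append({"trait": trait, "period": period, "w": w, "n": n, "excluded": False})
    return pd.DataFrame(rows)


def fit_subject_trajectories(
    pheno: pd.DataFrame,
    weights: pd.DataFrame,
    trait: str,
    weight_mode: str = "inverse",
) -> pd.DataFrame:
    """Stage 2: per-subject weighted regression on centred age.

    For each subject the model ``y_ij = B0 + B1 (age_ij - mean(age_i)) + e``
    is fit by weighted least squares, with observation weight ``1/w_jk``
    (``weight_mode='inverse'``, the standard heteroscedasticity correction;
    down-weights noisy periods) or ``w_jk`` (``weight_mode='literal'``).
    ``mean(age_i)`` is the unweighted mean of the subject's observed ages.

    Observations from periods without a usable weight are excluded.  Subjects
    with fewer than two distinct observation ages are dropped with a warning.
    Returns columns subject_id, trait, B0, B1, mean_age, n_obs, sigma2 where
    sigma2 is the weighted residual variance (0 when only 2 observations).
    """
    if weight_mode not in ("inverse", "literal"):
        raise ParameterError(f"unknown weight_mode {weight_mode!r}")

    wtab = weights.loc[(weights["trait"] == trait) & ~weights["excluded"]]
    w_by_period = wtab.set_index("period")["w"]

    sub = pheno.loc[(pheno["trait"] == trait) & pheno["value"].notna()].copy()
    sub["w_period"] = sub["period"].map(w_by_period)
    sub = sub.loc[sub["w_period"].notna()]
    sub["omega"] = 1.0 / sub["w_period"] if weight_mode == "inverse" else sub["w_period"]

    # centred age (unweighted per-subject mean of observed ages)
    sub["mean_age"] = sub.groupby("subject_id")["age"].transform("mean")
    sub["x"] = sub["age"] - sub["mean_age"]

    sub["_wx"] = sub["omega"] * sub["x"]
    sub["_wy"] = sub["omega"] * sub["value"]
    sub["_wxx"] = sub["omega"] * sub["x"] ** 2
    sub["_wxy"] = sub["omega"] * sub["x"] * sub["value"]

    g = sub.groupby("subject_id", sort=True)
    agg = pd.DataFrame(
        {
            "n_obs": g.size(),
            "mean_age": g["mean_age"].first(),
            "n_ages": g["age"].nunique(),
        }
    )
    sums = g[["omega", "_wx", "_wy", "_wxx", "_wxy"]].sum()
    sw, swx, swy, swxx, swxy = (
        sums["omega"],
        sums["_wx"],
        sums["_wy"],
        sums["_wxx"],
        sums["_wxy"],
    )

    det = sw * swxx - swx**2
    usable = (agg["n_ages"] >= 2) & (det > np.finfo(float).eps * np.maximum(sw * swxx, 1.0))
    n_drop = int((~usable).sum())
    if n_drop:
        warnings.warn(
            f"{trait}: {n_drop} subjects dropped (fewer than two distinct ages)",
            stacklevel=2,
        )

    b0 = (swxx * swy - swx * swxy) / det
    b1 = (sw * swxy - swx * swy) / det

    # weighted residual variance per subject
    sub["fit"] = sub["subject_id"].map(b0) + sub["subject_id"].map(b1) * sub["x"]
    sub["wres2"] = sub["omega"] * (sub["value"] - sub["fit"]) ** 2
    rss = sub.groupby("subject_id")["wres2"].sum()
    sigma2 = (rss / (agg["n_obs"] - 2).clip(lower=1)).where(agg["n_obs"] > 2, 0.0)

    out = pd.DataFrame(
        {
            "subject_id": agg.index,
            "trait": trait,
            "B0": b0,
            "B1": b1,
            "mean_age": agg["mean_age"],
            "n_obs": agg["n_obs"],
            "sigma2": sigma2,
        }
    ).loc[usable]
    return out.reset_index(drop=True)
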