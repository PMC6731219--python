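"""Clinical models: CIMP scoring, driver-mutation rules, the log-count
multiple regression, the stratified disease-specific Cox model, and
validation false-positive-rate estimation.

The regression models log(1 + insertion count) on CIMP-H, allelic-imbalance
fraction (per 10% of the genome), TP53, MSI, mean coverage (/10 reads), age
(/10 years), sex, Dukes stage, and proximal location.  The Cox model uses
insertion count (/10), MSI, CIMP-H, BRAF, age categories [55, 75) and
>= 75, sex, Dukes stage, and AI (/10%), with the baseline hazard stratified
by tumor location; disease-specific death is the event, all else censors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

CIMP_GENES = ("CACNA1G", "CDKN2A", "CRABP1", "IGF2", "MLH1", "NEUROG1",
              "RUNX3", "SOCS1")

KRAS_CODONS = (12, 13, 61, 117, 146)


@dataclass
class ModelFit:
    """Uniform container for regression and survival fits."""

    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    hr: np.ndarray | None = None
    hr_ci: np.ndarray | None = None
    gof_stat: float | None = None
    gof_p: float | None = None
    diagnostics: dict = field(default_factory=dict)
    n: int = 0

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame({"term": self.terms, "coef": self.coef,
                            "se": self.se, "z": self.z, "p": self.p})
        if self.hr is not None:
            out["hr"] = self.hr
            out["hr_low"] = self.hr_ci[:, 0]
            out["hr_high"] = self.hr_ci[:, 1]
        return out


# ---------------------------------------------------------------------------
# CIMP

def methylation_thresholds(probe_table: pd.DataFrame,
                           n_sd: float = 3.0) -> pd.Series:
    """Per-probe hypermethylation threshold from normal samples:
    mean + n_sd * SD of the normal ratios."""
    normals = probe_table[probe_table["is_normal"]]
    if not len(normals):
        raise ValueError("no normal samples to derive thresholds from")
    g = normals.groupby("probe_id")["ratio"]
    return g.mean() + n_sd * g.std(ddof=1).fillna(0.0)


def score_cimp(probe_table: pd.DataFrame, n_sd: float = 3.0,
               gene_probe_fraction: float = 0.25,
               cimp_high_min_genes: int = 5
               ) -> tuple[pd.Series, pd.DataFrame]:
    """Classify tumors CIMP-H / CIMP-L from MS-MLPA probe ratios.

    A probe is methylated when its tumor ratio exceeds the normal-derived
    threshold; a gene is methylated when >= 25% of its probes are; a tumor
    with 5-8 methylated genes (of the 8-gene panel) is CIMP-H, 0-4 CIMP-L.
    Returns (per-sample class, per-sample per-gene methylation calls).
    """
    genes_present = set(probe_table["gene"])
    missing = set(CIMP_GENES) - genes_present
    if missing:
        raise ValueError(f"missing CIMP panel genes: {sorted(missing)}")
    thr = methylation_thresholds(probe_table, n_sd)
    tumors = probe_table[~probe_table["is_normal"]].copy()
    tumors["methylated"] = tumors["ratio"] > tumors["probe_id"].map(thr)
    gene_calls = (tumors.groupby(["sample", "gene"])["methylated"]
                  .mean() >= gene_probe_fraction).rename("gene_methylated")
    gene_calls = gene_calls.reset_index()
    n_meth = (gene_calls[gene_calls["gene_methylated"]]
              .groupby("sample").size())
    samples = sorted(tumors["sample"].unique())
    n_meth = n_meth.reindex(samples, fill_value=0)
    classes = pd.Series(
        np.where(n_meth >= cimp_high_min_genes, "CIMP-H", "CIMP-L"),
        index=n_meth.index, name="cimp")
    return classes, gene_calls


# ---------------------------------------------------------------------------
# driver mutations

def classify_driver_mutations(variants: pd.DataFrame,
                              min_coverage: int = 4,
                              min_allelic_fraction: float = 10.0,
                              min_quality: float = 20.0) -> pd.DataFrame:
    """Per-sample KRAS/BRAF/TP53 mutation flags.

    Variants failing the coverage / allelic-fraction (%) / quality filters
    are dropped.  KRAS is positive at non-synonymous changes in codons
    12, 13, 61, 117, 146 (any transcript); BRAF only at V600E; TP53 at any
    non-synonymous change.
    """
    ok = ((variants["coverage"] >= min_coverage)
          & (variants["allelic_fraction"] >= min_allelic_fraction)
          & (variants["quality"] >= min_quality))
    v = variants.loc[ok]
    nonsyn = v["consequence"] == "non_synonymous"
    kras = v.loc[nonsyn & (v["gene"] == "KRAS")
                 & (v["codon"].isin(KRAS_CODONS)), "sample"]
    braf = v.loc[nonsyn & (v["gene"] == "BRAF")
                 & (v["protein_change"] == "V600E"), "sample"]
    tp53 = v.loc[nonsyn & (v["gene"] == "TP53"), "sample"]
    samples = sorted(variants["sample"].unique())
    return pd.DataFrame({
        "sample": samples,
        "kras": [s in set(kras) for s in samples],
        "braf": [s in set(braf) for s in samples],
        "tp53": [s in set(tp53) for s in samples],
    })


# ---------------------------------------------------------------------------
# design matrices

def _regression_design(records: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame(index=records.index)
    X["CIMP-H"] = (records["cimp"] == "CIMP-H").astype(float)
    X["AI (/10%)"] = records["ai_fraction"].astype(float) * 10.0
    X["TP53"] = records["tp53"].astype(float)
    X["MSI"] = (records["msi"] == "MSI").astype(float)
    X["Coverage (/10)"] = records["mean_coverage"].astype(float) / 10.0
    X["Age (/10)"] = records["age"].astype(float) / 10.0
    X["Male"] = (records["sex"] == "male").astype(float)
    for stage in "BCD":
        X[f"Dukes {stage}"] = (records["dukes_stage"] == stage).astype(float)
    X["Proximal"] = (records["location"] == "proximal").astype(float)
    return X


def _cox_design(records: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame(index=records.index)
    X["Insertions (/10)"] = records["insertion_count"].astype(float) / 10.0
    X["MSI"] = (records["msi"] == "MSI").astype(float)
    X["CIMP-H"] = (records["cimp"] == "CIMP-H").astype(float)
    X["BRAF"] = records["braf"].astype(float)
    age = records["age"].astype(float)
    X["Age [55,75)"] = ((age >= 55) & (age < 75)).astype(float)
    X["Age >= 75"] = (age >= 75).astype(float)
    X["Male"] = (records["sex"] == "male").astype(float)
    for stage in "BCD":
        X[f"Dukes {stage}"] = (records["dukes_stage"] == stage).astype(float)
    X["AI (/10%)"] = records["ai_fraction"].astype(float) * 10.0
    return X


def _complete_cases(records: pd.DataFrame,
                    cols: list[str]) -> pd.DataFrame:
    return records.dropna(subset=[c for c in cols
                                  if c in records]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# regression

def fit_log_count_regression(records: pd.DataFrame,
                             offset: float = 1.0) -> ModelFit:
    """OLS for log(offset + insertion count) on the clinical covariates.

    Complete cases only.  Reports coefficient/SE/z/p per term, Pearson
    chi-square goodness of fit (sum of squared standardized residuals vs
    chi-square with n - p df), and variance inflation factors.
    """
    import statsmodels.api as sm
    from statsmodels.stats.outliers_influence import (
        variance_inflation_factor)

    cols = ["insertion_count", "cimp", "ai_fraction", "tp53", "msi",
            "mean_coverage", "age", "sex", "dukes_stage", "location"]
    rec = _complete_cases(records, cols)
    counts = rec["insertion_count"].astype(float)
    if offset == 0 and (counts == 0).any():
        raise ValueError("zero counts with offset 0; use a positive offset")
    y = np.log(counts + offset)
    X = _regression_design(rec)
    Xc = sm.add_constant(X, prepend=True)
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        i, j = np.unravel_index(np.nanargmax(corr.values), corr.shape)
        raise ValueError(
            "perfect collinearity in design matrix (e.g. between "
            f"{corr.index[i]!r} and {corr.columns[j]!r})")
    res = sm.OLS(y, Xc).fit()
    resid_std = res.resid / np.sqrt(res.scale)
    gof = float((resid_std ** 2).sum())
    df = res.df_resid
    gof_p = float(sps.chi2.sf(gof, df))
    vif = {X.columns[k]: float(variance_inflation_factor(
        Xc.to_numpy(), k + 1)) for k in range(X.shape[1])}
    terms = list(Xc.columns)
    return ModelFit(
        terms=["Intercept"] + terms[1:], coef=res.params.to_numpy(),
        se=res.bse.to_numpy(), z=res.tvalues.to_numpy(),
        p=res.pvalues.to_numpy(), gof_stat=gof, gof_p=gof_p,
        diagnostics={"vif": vif, "r2": float(res.rsquared),
                     "df_resid": float(df)},
        n=len(rec))


# ---------------------------------------------------------------------------
# survival

def fit_disease_specific_cox(records: pd.DataFrame,
                             level: float = 0.95) -> ModelFit:
    """Stratified Cox model for disease-specific survival.

    Partial-likelihood fit with the baseline hazard stratified by tumor
    location; disease-specific death is the event.  Diagnostics include the
    Grambsch-Therneau scaled-Schoenfeld proportional-hazards test per term.
    """
    from lifelines import CoxPHFitter
    from lifelines.statistics import proportional_hazard_test

    cols = ["insertion_count", "msi", "cimp", "braf", "age", "sex",
            "dukes_stage", "ai_fraction", "location", "followup_days",
            "event"]
    rec = _complete_cases(records, cols)
    if int(rec["event"].sum()) == 0:
        raise ValueError("no events: every record is censored")
    X = _cox_design(rec)
    data = X.copy()
    data["followup_days"] = rec["followup_days"].astype(float)
    data["event"] = rec["event"].astype(int)
    data["location"] = rec["location"]
    for loc, sub in data.groupby("location"):
        if sub["event"].sum() == 0:
            import logging
            logging.getLogger(__name__).warning(
                "stratum %r has no events", loc)
    cph = CoxPHFitter()
    cph.fit(data, duration_col="followup_days", event_col="event",
            strata=["location"])
    coef = cph.params_.to_numpy()
    se = cph.standard_errors_.to_numpy()
    zs = coef / se
    pvals = 2 * sps.norm.sf(np.abs(zs))
    zq = sps.norm.ppf(0.5 + level / 2)
    hr = np.exp(coef)
    hr_ci = np.exp(np.column_stack([coef - zq * se, coef + zq * se]))
    try:
        ph = proportional_hazard_test(cph, data, time_transform="rank")
        ph_p = {t: float(p) for t, p in ph.summary["p"].items()}
    except Exception:  # degenerate designs in tiny fixtures
        ph_p = {}
    return ModelFit(
        terms=list(cph.params_.index), coef=coef, se=se, z=zs, p=pvals,
        hr=hr, hr_ci=hr_ci,
        gof_stat=float(cph.log_likelihood_),
        diagnostics={"proportional_hazards_p": ph_p,
                     "n_events": int(rec["event"].sum())},
        n=len(rec))


def hazard_ratio_from_coefficient(coefficient: float, se: float,
                                  level: float = 0.95
                                  ) -> tuple[float, float, float]:
    """HR = exp(coef) with exp(coef +/- z * se) confidence bounds."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    zq = sps.norm.ppf(0.5 + level / 2)
    return (float(np.exp(coefficient)),
            float(np.exp(coefficient - zq * se)),
            float(np.exp(coefficient + zq * se)))


# ---------------------------------------------------------------------------
# validation FPR

@dataclass
class ValidationTally:
    n_reviewed: int
    n_true: int
    false_positive_rate: float
    ci_low: float
    ci_high: float


def clopper_pearson(k: int, n: int, level: float = 0.95
                    ) -> tuple[float, float]:
    """Exact binomial confidence interval from beta quantiles."""
    alpha = 1 - level
    lo = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def wilson_interval(k: int, n: int, level: float = 0.95
                    ) -> tuple[float, float]:
    z = sps.norm.ppf(0.5 + level / 2)
    phat = k / n
    denom = 1 + z ** 2 / n
    center = (phat + z ** 2 / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z ** 2 / (4 * n ** 2)) / denom
    return float(max(center - half, 0.0)), float(min(center + half, 1.0))


def estimate_false_positive_rate(labels, level: float = 0.95,
                                 method: str = "clopper-pearson"
                                 ) -> ValidationTally:
    """Validation FPR with an exact binomial CI.

    ``labels`` is an iterable of booleans (True = judged a true somatic
    insertion).  Rate = n_false / n.
    """
    labels = [bool(x) for x in labels]
    n = len(labels)
    if n == 0:
        raise ValueError("no validation labels")
    n_true = sum(labels)
    n_false = n - n_true
    ci_fn = {"clopper-pearson": clopper_pearson,
             "wilson": wilson_interval}[method]
    lo, hi = ci_fn(n_false, n, level)
    return ValidationTally(n, n_true, n_false / n, lo, hi)
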