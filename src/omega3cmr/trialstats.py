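"""Genotype-stratified treatment-effect statistics for a two-arm trial.

The cohort is a :class:`pandas.DataFrame` with one row per patient and the
column dictionary in :data:`COLUMN_DICT`: identifiers (``patient_id``,
``genotype`` in {AA, AG, GG}, ``arm`` in {drug, placebo}, ``race``), the
hematocrit, RBC fatty-acid columns, and paired ``<endpoint>_baseline`` /
``<endpoint>_6mo`` measurements for imaging endpoints and serum biomarkers.

All treatment contrasts are computed on 6-month change scores
(followup - baseline; for volumes, ECV and biomarkers a negative change is
improvement).  Arms are compared per genotype stratum with a two-sample
t-test (Welch by default), responder status is >= 10% relative improvement
in LVESVi, and fatty-acid/remodeling coupling is summarized by Spearman rank
correlation.  Missing data are handled complete-case per analysis, with
exclusion counts logged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateDataError, DomainError, InsufficientDataError

logger = logging.getLogger(__name__)

ARMS = ("drug", "placebo")

#: Endpoints measured at baseline and 6 months (column stems).
PAIRED_ENDPOINTS = (
    "lvesvi",          # LV end-systolic volume index, mL/m^2
    "lvedvi",          # LV end-diastolic volume index, mL/m^2
    "ecv_noninfarct",  # non-infarct extracellular volume fraction, percent
    "infarct_size",    # infarct mass, grams
    "lvef",            # LV ejection fraction, percent
    "ntprobnp",        # NT-proBNP, pg/mL
    "galectin3",       # galectin-3, ng/mL
    "lipoprotein_a",   # lipoprotein(a), mg/dL
    "hscrp",           # high-sensitivity CRP, mg/L
    "epa",             # EPA, % of RBC fatty acids
    "dha",             # DHA, % of RBC fatty acids
    "o3i",             # omega-3 index (EPA+DHA), %
)

#: Full cohort column dictionary: column -> description.
COLUMN_DICT = {
    "patient_id": "unique patient identifier",
    "genotype": "rs1535 genotype: AA, AG or GG",
    "arm": "randomized assignment: drug (omega-3) or placebo",
    "race": "self-reported racial category",
    "hct": "hematocrit, fraction of blood volume",
    "ara_pct": "arachidonic acid, % of RBC fatty acids",
    "la_pct": "linoleic acid, % of RBC fatty acids",
    **{
        f"{stem}_{visit}": f"{stem} at {visit}"
        for stem in PAIRED_ENDPOINTS
        for visit in ("baseline", "6mo")
    },
}


@dataclass(frozen=True)
class StratifiedEffect:
    """Per-genotype drug-vs-placebo contrast on a change score."""

    genotype: str
    outcome: str
    mean_change_drug: float
    mean_change_placebo: float
    sd_drug: float
    sd_placebo: float
    n_drug: int
    n_placebo: int
    p_value: float
    log_transformed: bool = False


@dataclass(frozen=True)
class ResponderOdds:
    """Per-arm odds of >= 10% LVESVi improvement and their ratio."""

    odds_drug: float
    odds_placebo: float
    odds_ratio: float
    n_responders_drug: int
    n_nonresponders_drug: int
    n_responders_placebo: int
    n_nonresponders_placebo: int
    infinite: bool = False

    @property
    def odds_ratio_1dp(self) -> float:
        """Odds ratio rounded to one decimal for reporting."""
        return round(self.odds_ratio, 1)


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int


@dataclass(frozen=True)
class ComparisonResult:
    statistic: float
    p_value: float
    test: str


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    p_value: float
    n: int


def odds_ratio(odds_drug: float, odds_placebo: float) -> float:
    """Ratio of drug to placebo odds."""
    if odds_placebo <= 0:
        raise DomainError("placebo odds must be positive for a finite odds ratio")
    return odds_drug / odds_placebo


def change_score(
    df: pd.DataFrame, outcome: str, log_transform: bool = False
) -> pd.Series:
    """6-month change score ``<outcome>_6mo - <outcome>_baseline`` per patient.

    With ``log_transform`` the change is computed on the natural-log scale
    (i.e. log(followup) - log(baseline)); rows with non-positive values are
    excluded and logged.  Rows with missing values are excluded and logged.
    """
    base = df[f"{outcome}_baseline"]
    follow = df[f"{outcome}_6mo"]
    ok = base.notna() & follow.notna()
    n_missing = int((~ok).sum())
    if log_transform:
        positive = ok & (base > 0) & (follow > 0)
        n_nonpos = int((ok & ~positive).sum())
        if n_nonpos:
            logger.info(
                "%s: excluded %d records with non-positive values before log transform",
                outcome,
                n_nonpos,
            )
        ok = positive
    if n_missing:
        logger.info("%s: excluded %d records with missing values", outcome, n_missing)
    if log_transform:
        return np.log(follow[ok]) - np.log(base[ok])
    return follow[ok] - base[ok]


def stratified_effect(
    df: pd.DataFrame,
    outcome: str,
    genotype: str,
    log_transform: bool = False,
    ttest: str = "welch",
) -> StratifiedEffect:
    """Drug-vs-placebo contrast on the change score within one genotype stratum.

    ``ttest`` selects the two-sample test flavor: ``"welch"`` (unequal
    variances, default) or ``"pooled"`` (classic Student).
    """
    if ttest not in ("welch", "pooled"):
        raise DomainError(f"ttest must be 'welch' or 'pooled', got {ttest!r}")
    stratum = df[df["genotype"] == genotype]
    changes = change_score(stratum, outcome, log_transform=log_transform)
    arm = stratum.loc[changes.index, "arm"]
    drug = changes[arm == "drug"].to_numpy(float)
    placebo = changes[arm == "placebo"].to_numpy(float)
    if len(drug) < 2 or len(placebo) < 2:
        raise InsufficientDataError(
            f"genotype {genotype}, outcome {outcome}: need >= 2 records per arm "
            f"(got {len(drug)} drug, {len(placebo)} placebo)"
        )
    res = stats.ttest_ind(drug, placebo, equal_var=(ttest == "pooled"))
    return StratifiedEffect(
        genotype=genotype,
        outcome=outcome,
        mean_change_drug=float(drug.mean()),
        mean_change_placebo=float(placebo.mean()),
        sd_drug=float(drug.std(ddof=1)),
        sd_placebo=float(placebo.std(ddof=1)),
        n_drug=len(drug),
        n_placebo=len(placebo),
        p_value=float(res.pvalue),
        log_transformed=log_transform,
    )


def responder_odds(
    df: pd.DataFrame,
    improvement_fraction: float = 0.10,
    haldane_correction: bool = False,
    relative: bool = True,
) -> ResponderOdds:
    """Odds of LVESVi improvement per arm and their ratio (drug / placebo).

    A responder improves LVESVi by at least ``improvement_fraction`` of the
    baseline value, i.e. (baseline - followup)/baseline >= fraction (the
    default, ``relative=True``), or by at least ``improvement_fraction``
    mL/m^2 absolutely when ``relative=False``.  With a zero cell, odds (and
    the ratio) become infinite and are flagged; the optional
    Haldane-Anscombe correction adds 0.5 to every cell instead.
    """
    base = df["lvesvi_baseline"]
    follow = df["lvesvi_6mo"]
    ok = base.notna() & follow.notna() & (base > 0)
    improvement = base[ok] - follow[ok]
    if relative:
        responder = (improvement / base[ok]) >= improvement_fraction
    else:
        responder = improvement >= improvement_fraction
    arm = df.loc[responder.index, "arm"]

    cells = {}
    for a in ARMS:
        in_arm = responder[arm == a]
        cells[a] = (int(in_arm.sum()), int((~in_arm).sum()))
    (rd, nd), (rp, np_) = cells["drug"], cells["placebo"]
    if rd + nd == 0 or rp + np_ == 0:
        raise InsufficientDataError("an arm has no analyzable records")

    def _odds(r: int, n: int) -> float:
        if haldane_correction:
            return (r + 0.5) / (n + 0.5)
        return r / n if n > 0 else float("inf")

    od, op = _odds(rd, nd), _odds(rp, np_)
    infinite = not (np.isfinite(od) and np.isfinite(op) and op > 0)
    if infinite:
        logger.warning("zero cell in responder table; odds ratio is infinite/undefined")
        or_ = float("inf") if op == 0 or not np.isfinite(od) else od / op
    else:
        or_ = od / op
    return ResponderOdds(
        odds_drug=od,
        odds_placebo=op,
        odds_ratio=or_,
        n_responders_drug=rd,
        n_nonresponders_drug=nd,
        n_responders_placebo=rp,
        n_nonresponders_placebo=np_,
        infinite=infinite,
    )


def delta_correlation(df: pd.DataFrame, fatty_acid: str) -> CorrelationResult:
    """Spearman correlation between a fatty-acid 6-month change and the LVESVi change."""
    if fatty_acid not in ("epa", "dha", "o3i"):
        raise DomainError(f"fatty_acid must be one of epa/dha/o3i, got {fatty_acid!r}")
    d_fat = change_score(df, fatty_acid)
    d_lvesvi = change_score(df, "lvesvi")
    joined = pd.concat({"fat": d_fat, "lvesvi": d_lvesvi}, axis=1).dropna()
    if len(joined) < 3:
        raise InsufficientDataError("need >= 3 complete pairs for a rank correlation")
    if joined["fat"].nunique() == 1 or joined["lvesvi"].nunique() == 1:
        raise DegenerateDataError("a variable is constant; rank correlation undefined")
    rho, p = stats.spearmanr(joined["fat"], joined["lvesvi"])
    return CorrelationResult(rho=float(rho), p_value=float(p), n=len(joined))


def baseline_comparison(
    df: pd.DataFrame, variable: str, kind: str
) -> ComparisonResult:
    """Compare a baseline characteristic across the three genotypes.

    ``kind="categorical"`` runs a chi-square test on the genotype x category
    contingency table; ``kind="continuous"`` runs a one-way ANOVA.
    """
    sub = df[["genotype", variable]].dropna()
    groups = [g[variable].to_numpy() for _, g in sub.groupby("genotype")]
    if len(groups) < 2:
        raise InsufficientDataError("need >= 2 genotype groups with data")
    if kind == "continuous":
        if any(len(g) < 2 for g in groups):
            raise InsufficientDataError("each genotype group needs >= 2 observations")
        f, p = stats.f_oneway(*groups)
        return ComparisonResult(statistic=float(f), p_value=float(p), test="anova")
    if kind == "categorical":
        tab = pd.crosstab(sub["genotype"], sub[variable])
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            raise InsufficientDataError("contingency table is degenerate")
        chi2, p, _, _ = stats.chi2_contingency(tab.to_numpy())
        return ComparisonResult(statistic=float(chi2), p_value=float(p), test="chi2")
    raise DomainError(f"kind must be 'categorical' or 'continuous', got {kind!r}")


def paired_visit_test(
    values_baseline, values_6mo, n_comparisons: int = 1
) -> float:
    """Bonferroni-adjusted paired Wilcoxon signed-rank p-value.

    The raw two-sided p from the paired Wilcoxon test of baseline vs 6-month
    values is multiplied by ``n_comparisons`` and capped at 1.
    """
    base = np.asarray(values_baseline, dtype=float)
    follow = np.asarray(values_6mo, dtype=float)
    if base.shape != follow.shape or base.ndim != 1:
        raise DomainError("paired vectors must be 1-D and of equal length")
    if base.size < 5:
        raise InsufficientDataError("need >= 5 pairs")
    if n_comparisons < 1:
        raise DomainError("n_comparisons must be >= 1")
    diffs = follow - base
    if np.all(diffs == 0):
        raise DegenerateDataError("all paired differences are zero")
    res = stats.wilcoxon(base, follow)
    return min(1.0, float(res.pvalue) * n_comparisons)


def subgroup_filter(df: pd.DataFrame, race: str = "Caucasian") -> pd.DataFrame:
    """Restrict the cohort to one self-reported racial category.

    Every other operation composes with the filtered frame.  An empty result
    warns rather than raising.
    """
    if "race" not in df.columns:
        raise DomainError("cohort has no 'race' column")
    out = df[df["race"] == race]
    if out.empty:
        warnings.warn(f"no records with race == {race!r}", UserWarning, stacklevel=2)
    return out


def median_split(values) -> np.ndarray:
    """Label each value 'low' (<= sample median) or 'high' (> median).

    Values equal to the median go to 'low'.  All-identical input warns and
    yields all-'low' labels.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)] if np.isnan(v).any() else v
    if v.size < 2:
        raise InsufficientDataError("need >= 2 non-missing values")
    if np.ptp(v) == 0:
        warnings.warn("all values identical; median split is degenerate", UserWarning,
                      stacklevel=2)
    med = np.median(v)
    return np.where(v <= med, "low", "high")


def biomarker_cmr_regression(
    df: pd.DataFrame,
    biomarker: str,
    cmr_variable: str,
    log_biomarker: bool = False,
) -> RegressionResult:
    """Simple OLS of a CMR variable on a (optionally log-transformed) biomarker."""
    sub = df[[biomarker, cmr_variable]].dropna()
    x = sub[biomarker].to_numpy(float)
    y = sub[cmr_variable].to_numpy(float)
    if log_biomarker:
        keep = x > 0
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info(
                "%s: excluded %d non-positive values before log transform",
                biomarker,
                n_dropped,
            )
        x, y = np.log(x[keep]), y[keep]
    if x.size < 3:
        raise InsufficientDataError("need >= 3 complete pairs")
    if np.ptp(x) == 0:
        raise DegenerateDataError("predictor is constant; design is singular")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_value=float(fit.pvalue),
        n=int(x.size),
    )
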