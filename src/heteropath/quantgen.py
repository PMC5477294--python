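"""Phenotype statistics for multi-environment trials and seedling assays.

Covers variance components and entry-mean heritability on balanced
genotype x environment x replicate layouts, least-significant-difference
comparisons against a reference entry, Pearson correlation tables,
hormone inhibitor response ratios, mid-parent heterosis, and
prediction of plant height from the two inhibitor responses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VarianceComponents",
    "UnbalancedDesignError",
    "variance_components",
    "entry_mean_heritability",
    "lsd_compare",
    "hormone_response",
    "correlation_table",
    "midparent_heterosis",
    "multiple_correlation",
    "predict_pht",
]


class UnbalancedDesignError(ValueError):
    """Raised when the trial layout is too unbalanced for moment estimation."""


@dataclass
class VarianceComponents:
    """Moment estimates from the two-way random model.

    sigma2_g, sigma2_ge, sigma2_e are the genotypic, genotype x
    environment, and error variance components; r replicates per
    location, n locations.  Negative method-of-moments estimates are
    truncated to zero (the raw values are kept for diagnostics).
    """

    sigma2_g: float
    sigma2_ge: float
    sigma2_e: float
    r: int
    n: int
    ms_g: float = float("nan")
    ms_ge: float = float("nan")
    ms_e: float = float("nan")
    df_g: int = 0
    df_ge: int = 0
    df_e: int = 0

    def __post_init__(self) -> None:
        if min(self.sigma2_g, self.sigma2_ge, self.sigma2_e) < 0:
            raise ValueError("variance components must be non-negative")


def _balanced_cube(pheno: pd.DataFrame, trait: str) -> tuple[np.ndarray, int, int, int]:
    sub = pheno[pheno["trait"] == trait]
    if sub.empty:
        raise ValueError(f"no records for trait {trait!r}")
    if sub.duplicated(["entry", "environment", "replicate"]).any():
        raise ValueError("duplicate (entry, environment, replicate) records")
    counts = sub.groupby(["entry", "environment"]).size()
    r = int(counts.iloc[0])
    if (counts != r).any():
        raise UnbalancedDesignError(
            "unequal replication across genotype x environment cells; "
            "subset the data to a balanced layout before estimating "
            "variance components"
        )
    wide = sub.pivot_table(
        index="entry", columns=["environment", "replicate"], values="value"
    )
    if wide.isna().any().any():
        raise UnbalancedDesignError("missing genotype x environment cells")
    g = wide.shape[0]
    n = sub["environment"].nunique()
    cube = wide.to_numpy().reshape(g, n, r)
    return cube, g, n, r


def variance_components(pheno: pd.DataFrame, trait: str) -> VarianceComponents:
    """Method-of-moments variance components from a balanced trial.

    Two-way random model with replicates nested in environment.  With
    MS_G, MS_GE, MS_E the genotype, interaction, and residual mean
    squares: sigma2_g = (MS_G - MS_GE)/(r n), sigma2_ge =
    (MS_GE - MS_E)/r, sigma2_e = MS_E; negative estimates truncate to 0.
    """
    cube, g, n, r = _balanced_cube(pheno, trait)
    grand = cube.mean()
    gm = cube.mean(axis=(1, 2))  # genotype means
    em = cube.mean(axis=(0, 2))  # environment means
    cm = cube.mean(axis=2)  # cell means

    ss_g = n * r * ((gm - grand) ** 2).sum()
    ss_ge = r * ((cm - gm[:, None] - em[None, :] + grand) ** 2).sum()
    ss_e = ((cube - cm[:, :, None]) ** 2).sum()
    df_g, df_ge, df_e = g - 1, (g - 1) * (n - 1), g * n * (r - 1)
    ms_g = ss_g / df_g
    ms_ge = ss_ge / df_ge if df_ge > 0 else 0.0
    ms_e = ss_e / df_e if df_e > 0 else 0.0
    return VarianceComponents(
        sigma2_g=max((ms_g - ms_ge) / (r * n), 0.0),
        sigma2_ge=max((ms_ge - ms_e) / r, 0.0),
        sigma2_e=ms_e,
        r=r,
        n=n,
        ms_g=ms_g,
        ms_ge=ms_ge,
        ms_e=ms_e,
        df_g=df_g,
        df_ge=df_ge,
        df_e=df_e,
    )


def entry_mean_heritability(vc: VarianceComponents) -> float:
    """h2 = sigma2_g / (sigma2_g + sigma2_ge/n + sigma2_e/(r n)).

    Heritability of genotype means over n locations with r replicates
    each; always in [0, 1].
    """
    denom = vc.sigma2_g + vc.sigma2_ge / vc.n + vc.sigma2_e / (vc.r * vc.n)
    if denom == 0:
        raise ValueError("all variance components are zero; h2 undefined")
    return vc.sigma2_g / denom


def lsd_compare(
    pheno: pd.DataFrame,
    reference_entry: str,
    trait: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher's LSD of every entry mean against a reference entry.

    LSD = t(1 - alpha/2, df_error) * sqrt(2 MS_E / m) where m is the
    (harmonic mean) number of observations per entry mean and MS_E the
    residual mean square of the two-way fit.  Returns per-entry mean,
    difference to the reference, and a flag in
    {"greater", "less", "indistinguishable"}.
    """
    sub = pheno[pheno["trait"] == trait]
    if reference_entry not in set(sub["entry"]):
        raise ValueError(f"reference entry {reference_entry!r} not present")
    vc = variance_components(pheno, trait)
    counts = sub.groupby("entry").size()
    m = len(counts) / (1.0 / counts).sum()  # harmonic mean replication
    lsd = stats.t.ppf(1 - alpha / 2, vc.df_e) * np.sqrt(2 * vc.ms_e / m)
    means = sub.groupby("entry")["value"].mean()
    diff = means - means[reference_entry]
    flag = np.where(diff > lsd, "greater", np.where(diff < -lsd, "less", "indistinguishable"))
    return pd.DataFrame({"mean": means, "diff": diff, "flag": flag, "lsd": lsd})


def hormone_response(assay: pd.DataFrame) -> pd.DataFrame:
    """Per-entry inhibitor response ratios from mesocotyl lengths.

    BR response = mean(MP)/mean(MW) and GA response = mean(MU)/mean(MW)
    over replicates, where MP, MU, MW are mean mesocotyl lengths under
    Pcz, Ucz, and water.  Entries without a water control are excluded
    with a warning.
    """
    required = {"entry", "MW", "MP", "MU"}
    if not required.issubset(assay.columns):
        raise ValueError(f"assay table needs columns {sorted(required)}")
    means = assay.groupby("entry")[["MW", "MP", "MU"]].mean()
    no_water = means["MW"].isna() | (means["MW"] <= 0)
    if no_water.any():
        warnings.warn(
            f"entries without usable water control excluded: {list(means.index[no_water])}"
        )
        means = means[~no_water]
    return pd.DataFrame(
        {
            "BR_response": means["MP"] / means["MW"],
            "GA_response": means["MU"] / means["MW"],
        }
    )


def correlation_table(traits: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations with two-sided p-values.

    ``traits`` is a per-entry wide table (rows entries, columns trait
    values).  Missing values are handled pairwise-complete; a constant
    trait yields NaN cells (flagged by warning).  Returns (r, p).
    """
    cols = list(traits.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            pair = traits[[a, b]].dropna()
            if len(pair) < 3:
                raise ValueError(f"fewer than 3 complete pairs for ({a}, {b})")
            if pair[a].nunique() == 1 or pair[b].nunique() == 1:
                warnings.warn(f"constant trait in pair ({a}, {b}); correlation undefined")
                r.loc[a, b] = r.loc[b, a] = np.nan
                p.loc[a, b] = p.loc[b, a] = np.nan
                continue
            res = stats.pearsonr(pair[a], pair[b])
            r.loc[a, b] = r.loc[b, a] = res.statistic
            p.loc[a, b] = p.loc[b, a] = res.pvalue
    return r, p


def midparent_heterosis(f1: float, p1: float, p2: float) -> tuple[float, float]:
    """Mid-parent heterosis: F1 minus the parental mean.

    Returns (absolute MPH, percent MPH relative to the mid-parent).
    """
    if not np.all(np.isfinite([f1, p1, p2])):
        raise ValueError("inputs must be finite")
    mid = (p1 + p2) / 2.0
    mph = f1 - mid
    return mph, 100.0 * mph / mid


def multiple_correlation(
    corr: pd.DataFrame, response: str, predictors: tuple[str, str]
) -> float:
    """Multiple correlation of a response with two predictors.

    R = sqrt((r1^2 + r2^2 - 2 r1 r2 r12) / (1 - r12^2)) where r1, r2
    are the response-predictor correlations and r12 the correlation
    between the predictors.  Equals the in-sample correlation between
    the two-predictor least-squares fit and the observed response.
    """
    corr = pd.DataFrame(corr)
    if not np.allclose(corr.to_numpy(), corr.to_numpy().T):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr.to_numpy()), 1.0):
        raise ValueError("correlation matrix must have unit diagonal")
    x1, x2 = predictors
    r1 = float(corr.loc[response, x1])
    r2 = float(corr.loc[response, x2])
    r12 = float(corr.loc[x1, x2])
    if abs(r12) >= 1.0:
        raise ValueError("predictors are collinear (|r12| = 1)")
    num = r1**2 + r2**2 - 2.0 * r1 * r2 * r12
    return float(np.sqrt(num / (1.0 - r12**2)))


def predict_pht(responses: pd.DataFrame, pht: pd.Series) -> dict:
    """Least-squares prediction of plant height from inhibitor responses.

    Fits PHT ~ BR_response + GA_response over complete entries and
    returns the coefficients, fitted values, and the in-sample
    correlation r between fitted and observed PHT.
    """
    import statsmodels.api as sm

    data = responses.join(pht.rename("PHT"), how="inner").dropna()
    if len(data) < 4:
        raise ValueError("need at least 4 complete entries")
    X = sm.add_constant(data[["BR_response", "GA_response"]])
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient design (collinear responses)")
    fit = sm.OLS(data["PHT"], X).fit()
    fitted = pd.Series(fit.fittedvalues, index=data.index)
    r = float(np.corrcoef(fitted, data["PHT"])[0, 1])
    return {"coefficients": fit.params.to_dict(), "fitted": fitted, "r": r, "n": len(data)}
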