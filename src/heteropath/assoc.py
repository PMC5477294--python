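"""Single-marker association scan with ancestry covariates.

Each marker is tested by least squares of the trait on an intercept,
the ancestry-fraction covariates Q (last column dropped, since rows sum
to one), and an additive genotype code (0/1/2 for recurrent-homozygous,
heterozygous, donor-homozygous).  The family-wise threshold divides the
error rate by an effective number of independent tests obtained from
the eigenvalues of the per-chromosome marker correlation matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_core import DONOR_HOM, HET, MarkerMatrix, MISSING, RP_HOM

ADDITIVE_CODE = {RP_HOM: 0.0, HET: 1.0, DONOR_HOM: 2.0, MISSING: np.nan}

__all__ = [
    "MultipleTestingPlan",
    "glm_q_scan",
    "simple_m_eff",
    "significance_threshold",
    "declare_hits",
    "additive_matrix",
]


def additive_matrix(matrix: MarkerMatrix) -> pd.DataFrame:
    """Entries x markers additive dosage codes (NaN for missing)."""
    arr = matrix.calls.to_numpy(dtype="U1")
    coded = np.full(arr.shape, np.nan)
    for code, value in ADDITIVE_CODE.items():
        coded[arr == code] = value
    return pd.DataFrame(coded, index=matrix.calls.index, columns=matrix.calls.columns)


def glm_q_scan(
    geno: MarkerMatrix, pheno: pd.Series, Q: pd.DataFrame, trait: str = "trait"
) -> pd.DataFrame:
    """Per-marker fixed-effects scan with population-structure covariates.

    Returns one row per testable marker with the additive-effect
    estimate, its standard error, and a two-sided t-test p-value.
    Monomorphic markers (after alignment) and markers leaving fewer
    observations than parameters are skipped with a warning.  P-values
    below the smallest positive float are reported at that floor.
    """
    entries = geno.calls.index.intersection(pheno.index).intersection(Q.index)
    if len(entries) == 0:
        raise ValueError("no shared entries between genotypes, phenotype, and Q")
    if not np.allclose(Q.loc[entries].sum(axis=1), 1.0):
        raise ValueError("Q rows must sum to 1")
    y_all = pheno.loc[entries].to_numpy(dtype=float)
    # drop the last ancestry column: rows sum to one, so it is redundant
    q_all = Q.loc[entries].to_numpy(dtype=float)[:, :-1]
    dosage = additive_matrix(geno).loc[entries]
    ann = geno.markers

    rows, skipped = [], []
    for marker in dosage.columns:
        x = dosage[marker].to_numpy()
        mask = ~np.isnan(x) & ~np.isnan(y_all)
        xm, ym, qm = x[mask], y_all[mask], q_all[mask]
        if np.nanstd(xm) == 0:
            skipped.append(marker)
            continue
        X = np.column_stack([np.ones(mask.sum()), qm, xm])
        n, k = X.shape
        if n <= k:
            skipped.append(marker)
            continue
        coef, _, rank, _ = np.linalg.lstsq(X, ym, rcond=None)
        resid = ym - X @ coef
        dof = n - rank
        s2 = resid @ resid / dof
        xtx_inv = np.linalg.pinv(X.T @ X)
        se = float(np.sqrt(s2 * xtx_inv[-1, -1]))
        beta = float(coef[-1])
        if se == 0:
            pval = np.finfo(float).tiny
        else:
            t = beta / se
            pval = max(2.0 * stats.t.sf(abs(t), dof), np.finfo(float).tiny)
        rows.append(
            {
                "marker": marker,
                "chrom": ann.at[marker, "chrom"],
                "bp": ann.at[marker, "bp"],
                "effect": beta,
                "se": se,
                "p_value": pval,
                "trait": trait,
                "n": n,
            }
        )
    if skipped:
        warnings.warn(f"{len(skipped)} markers skipped (monomorphic or underdetermined)")
    return pd.DataFrame(rows)


def simple_m_eff(geno: MarkerMatrix, C: float = 0.995) -> int:
    """Effective number of independent tests from marker correlations.

    Per chromosome, the eigenvalues of the marker-marker Pearson
    correlation matrix (additive coding, missing calls mean-imputed
    for the correlation only) are sorted; the chromosome's effective
    count is the smallest k whose top-k eigenvalues capture a fraction
    C of the total.  Chromosome counts are summed.  Constant markers
    are excluded with a warning.
    """
    if not 0 < C <= 1:
        raise ValueError("C must be in (0, 1]")
    dosage = additive_matrix(geno)
    ann = geno.markers
    total = 0
    n_constant = 0
    for _, markers in ann.groupby("chrom").groups.items():
        block = dosage[list(markers)].to_numpy()
        col_mean = np.nanmean(block, axis=0)
        inds = np.where(np.isnan(block))
        block[inds] = np.take(col_mean, inds[1])
        sd = block.std(axis=0)
        keep = sd > 0
        n_constant += int((~keep).sum())
        block = block[:, keep]
        if block.shape[1] == 0:
            continue
        corr = np.corrcoef(block, rowvar=False)
        corr = np.atleast_2d(corr)
        eigvals = np.sort(np.linalg.eigvalsh(corr))[::-1]
        eigvals = np.clip(eigvals, 0.0, None)
        frac = np.cumsum(eigvals) / eigvals.sum()
        total += int(np.searchsorted(frac, C - 1e-12) + 1)
    if n_constant:
        warnings.warn(f"{n_constant} constant markers excluded from m_eff")
    return total


@dataclass(frozen=True)
class MultipleTestingPlan:
    """Family-wise plan: threshold = alpha_family / m_eff (Bonferroni)."""

    m_eff: int
    alpha_family: float = 0.05

    def __post_init__(self) -> None:
        if self.m_eff < 1:
            raise ValueError("m_eff must be >= 1")

    @property
    def threshold(self) -> float:
        return self.alpha_family / self.m_eff

    @classmethod
    def from_genotypes(
        cls, geno: MarkerMatrix, alpha_family: float = 0.05, C: float = 0.995
    ) -> "MultipleTestingPlan":
        return cls(m_eff=simple_m_eff(geno, C=C), alpha_family=alpha_family)


def significance_threshold(plan: MultipleTestingPlan) -> float:
    """Per-test p-value threshold of the plan."""
    return plan.threshold


def declare_hits(results: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Markers at or below the per-test threshold, sorted by p-value."""
    if results.empty:
        raise ValueError("association results are empty")
    hits = results[results["p_value"] <= threshold]
    return hits.sort_values("p_value").reset_index(drop=True)
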