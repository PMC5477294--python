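"""Recursive path models: ML fitting, fit indices, and model search.

A recursive path model is an acyclic system of linear structural
equations among observed variables.  The implied covariance is
Sigma = (I - B)^-1 P (I - B)^-T, where B holds the path coefficients
and P the residual/exogenous variances (plus covariances among
declared exogenous variables).  Models are fitted by minimizing the
Wishart maximum-likelihood discrepancy

    F_ML = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p .

For recursive models with uncorrelated residuals the discrepancy
decouples equation by equation, so the minimizer is the per-equation
least-squares solution computed from S; this closed form is used
directly (numerical optimization from arbitrary starts reaches the
same point, which the test suite exercises as an independent route).
The chi-square statistic is (N - 1) F_ML at the optimum, and model
search scores every acyclic edge subset under role constraints against
a battery of fit-index thresholds with minimum-AIC tie-breaking.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_VARIABLES = ("heterozygosity", "GA", "BR", "PHT")

#: Fit-index acceptance battery: a model passes only if every index
#: clears its threshold (indices undefined at df = 0 fail the battery,
#: so saturated models are excluded).
DEFAULT_CRITERIA = {
    "p_chi2": (">", 0.05),
    "RMSEA": ("<", 0.05),
    "CFI": (">", 0.95),
    "GFI": (">", 0.8),
    "AGFI": (">", 0.9),
    "NFI": (">", 0.9),
    "RFI": (">", 0.9),
    "IFI": (">", 0.9),
}

__all__ = [
    "PathModel",
    "FitIndices",
    "SearchResult",
    "implied_covariance",
    "fit_path_model",
    "fit_indices",
    "enumerate_models",
    "model_search",
    "ml_discrepancy",
    "DEFAULT_CRITERIA",
    "DEFAULT_VARIABLES",
]


@dataclass(frozen=True)
class PathModel:
    """Directed acyclic path model over observed variables.

    ``edges`` are (source, target) pairs; ``exogenous`` lists variables
    that never receive edges and whose covariances are free parameters
    when there are at least two of them.  Every variable carries one
    free variance parameter (exogenous variance or residual variance),
    and every edge one free coefficient.
    """

    variables: tuple
    edges: frozenset
    exogenous: tuple = ()

    def __post_init__(self) -> None:
        names = set(self.variables)
        for src, dst in self.edges:
            if src not in names or dst not in names:
                raise ValueError(f"edge ({src}, {dst}) uses unknown variable")
            if src == dst:
                raise ValueError("self-loops are not allowed")
            if dst in self.exogenous:
                raise ValueError(f"exogenous variable {dst!r} cannot receive edges")
        if self.topological_order() is None:
            raise ValueError("edge set contains a cycle; model must be recursive")
        if self.n_free_parameters > self.n_moments:
            raise ValueError("more free parameters than covariance moments")

    def parents(self, var: str) -> list:
        return sorted(src for src, dst in self.edges if dst == var)

    def topological_order(self):
        """Variables sorted so parents precede children; None if cyclic."""
        remaining = set(self.variables)
        out = []
        while remaining:
            free = [
                v
                for v in self.variables
                if v in remaining
                and not any(src in remaining for src in self.parents(v))
            ]
            if not free:
                return None
            out.extend(free)
            remaining -= set(free)
        return out

    @property
    def n_moments(self) -> int:
        p = len(self.variables)
        return p * (p + 1) // 2

    @property
    def n_phi(self) -> int:
        k = len(self.exogenous)
        return k * (k - 1) // 2

    @property
    def n_free_parameters(self) -> int:
        return len(self.edges) + len(self.variables) + self.n_phi

    @property
    def df(self) -> int:
        return self.n_moments - self.n_free_parameters


def implied_covariance(
    model: PathModel, B: dict, psi: dict, phi: dict | None = None
) -> pd.DataFrame:
    """Sigma(theta) = (I - B)^-1 P (I - B)^-T for given parameter values.

    ``B`` maps edges to coefficients, ``psi`` variables to variances,
    ``phi`` exogenous pairs to covariances.
    """
    p = len(model.variables)
    idx = {v: i for i, v in enumerate(model.variables)}
    Bm = np.zeros((p, p))
    for (src, dst), coef in B.items():
        Bm[idx[dst], idx[src]] = coef
    P = np.zeros((p, p))
    for v, var in psi.items():
        P[idx[v], idx[v]] = var
    for (u, v), cov in (phi or {}).items():
        P[idx[u], idx[v]] = P[idx[v], idx[u]] = cov
    eye_b = np.eye(p) - Bm
    # acyclic B with zero diagonal makes I - B unipotent (det = 1)
    assert abs(np.linalg.det(eye_b)) > 1e-12
    inv = np.linalg.inv(eye_b)
    sigma = inv @ P @ inv.T
    return pd.DataFrame(sigma, index=model.variables, columns=model.variables)


def ml_discrepancy(sigma: np.ndarray, S: np.ndarray) -> float:
    """Wishart ML discrepancy F_ML between implied and sample covariance."""
    sigma = np.asarray(sigma, dtype=float)
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    sign, logdet_sigma = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf
    _, logdet_s = np.linalg.slogdet(S)
    val = logdet_sigma + np.trace(S @ np.linalg.inv(sigma)) - logdet_s - p
    return float(max(val, 0.0))


def fit_path_model(model: PathModel, S: pd.DataFrame, N: int) -> tuple[dict, "FitIndices"]:
    """Maximum-likelihood fit of a recursive path model to S with N cases.

    Returns (estimates, fit indices).  Estimates contain the edge
    coefficients ``B``, the variances ``psi``, exogenous covariances
    ``phi``, the implied covariance matrix, and convergence
    diagnostics.  Heywood cases (non-positive residual variance) are
    flagged.
    """
    S = pd.DataFrame(S, index=model.variables, columns=model.variables).astype(float)
    p = len(model.variables)
    if N <= p:
        raise ValueError("N must exceed the number of variables")
    if np.linalg.eigvalsh(S.to_numpy()).min() <= 0:
        raise ValueError("sample covariance matrix must be positive definite")

    B: dict = {}
    psi: dict = {}
    heywood = []
    for v in model.variables:
        parents = model.parents(v)
        if parents:
            spp = S.loc[parents, parents].to_numpy()
            spy = S.loc[parents, v].to_numpy()
            beta = np.linalg.solve(spp, spy)
            for par, coef in zip(parents, beta):
                B[(par, v)] = float(coef)
            resid = float(S.loc[v, v] - spy @ beta)
        else:
            resid = float(S.loc[v, v])
        if resid <= 0:
            heywood.append(v)
        psi[v] = resid
    phi = {
        (u, v): float(S.loc[u, v])
        for u, v in itertools.combinations(model.exogenous, 2)
    }
    sigma = implied_covariance(model, B, psi, phi)
    fml = ml_discrepancy(sigma.to_numpy(), S.to_numpy())
    chi2 = (N - 1) * fml

    base_chi2, base_df = _baseline_fit(S.to_numpy(), N)
    indices = fit_indices(
        chi2_model=chi2,
        df_model=model.df,
        chi2_baseline=base_chi2,
        df_baseline=base_df,
        N=N,
        q=model.n_free_parameters,
        sigma=sigma.to_numpy(),
        S=S.to_numpy(),
    )
    estimates = {
        "B": B,
        "psi": psi,
        "phi": phi,
        "sigma": sigma,
        "F_ML": fml,
        "heywood": heywood,
    }
    return estimates, indices


def _baseline_fit(S: np.ndarray, N: int) -> tuple[float, int]:
    """Independence model: only variances free, Sigma = diag(S)."""
    p = S.shape[0]
    _, logdet_s = np.linalg.slogdet(S)
    fml = float(np.sum(np.log(np.diag(S))) - logdet_s)
    return (N - 1) * max(fml, 0.0), p * (p - 1) // 2


@dataclass
class FitIndices:
    """Chi-square and descriptive fit indices of one fitted model.

    Indices that are undefined for a saturated model (df = 0) are
    ``None`` rather than numbers.
    """

    chi2: float
    df: int
    p_chi2: float | None
    RMSEA: float | None
    CFI: float
    GFI: float
    AGFI: float | None
    NFI: float
    RFI: float | None
    IFI: float
    AIC: float
    N: int
    q: int

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "chi2", "df", "p_chi2", "RMSEA", "CFI", "GFI", "AGFI",
            "NFI", "RFI", "IFI", "AIC", "N", "q",
        )}


def fit_indices(
    chi2_model: float,
    df_model: int,
    chi2_baseline: float,
    df_baseline: int,
    N: int,
    q: int,
    sigma: np.ndarray | None = None,
    S: np.ndarray | None = None,
) -> FitIndices:
    """Fit-index battery from model and baseline chi-square statistics.

    The baseline is the independence model (free variances only) on the
    same data.  GFI/AGFI need the implied and sample covariance
    matrices; when they are not supplied those indices are computed as
    1 (exact fit) only if chi2 is zero, otherwise a ValueError is
    raised.
    """
    chi2 = float(chi2_model)
    excess = max(chi2 - df_model, 0.0)
    excess_b = max(chi2_baseline - df_baseline, 0.0)

    p_chi2 = float(stats.chi2.sf(chi2, df_model)) if df_model > 0 else None
    rmsea = (
        math.sqrt(excess / (df_model * (N - 1))) if df_model > 0 else None
    )
    denom = max(excess_b, excess)
    cfi = 1.0 if denom == 0 else 1.0 - excess / denom
    cfi = min(max(cfi, 0.0), 1.0)
    nfi = 1.0 if chi2_baseline == 0 else (chi2_baseline - chi2) / chi2_baseline
    rfi = (
        None
        if df_model == 0
        else 1.0 - (chi2 / df_model) / (chi2_baseline / df_baseline)
    )
    ifi_denom = chi2_baseline - df_model
    ifi = 1.0 if ifi_denom == 0 else (chi2_baseline - chi2) / ifi_denom

    if sigma is not None and S is not None:
        sigma_inv_s = np.linalg.solve(np.asarray(sigma, float), np.asarray(S, float))
        p = sigma_inv_s.shape[0]
        resid = sigma_inv_s - np.eye(p)
        gfi = 1.0 - np.trace(resid @ resid) / np.trace(sigma_inv_s @ sigma_inv_s)
        gfi = float(min(max(gfi, 0.0), 1.0))
        agfi = (
            None
            if df_model == 0
            else 1.0 - (p * (p + 1) / (2.0 * df_model)) * (1.0 - gfi)
        )
    elif chi2 == 0:
        gfi, agfi = 1.0, None if df_model == 0 else 1.0
    else:
        raise ValueError("GFI requires the implied and sample covariance matrices")

    return FitIndices(
        chi2=chi2,
        df=df_model,
        p_chi2=p_chi2,
        RMSEA=rmsea,
        CFI=cfi,
        GFI=gfi,
        AGFI=agfi,
        NFI=float(nfi),
        RFI=None if rfi is None else float(rfi),
        IFI=float(ifi),
        AIC=chi2 + 2.0 * q,
        N=N,
        q=q,
    )


def enumerate_models(
    variables=DEFAULT_VARIABLES,
    exogenous_only: tuple = ("heterozygosity",),
    sink_only: tuple = ("PHT",),
) -> list:
    """All acyclic edge subsets respecting role constraints.

    ``exogenous_only`` variables receive no edges; ``sink_only``
    variables emit none.  Guarded to at most 6 variables.
    """
    if len(variables) > 6:
        raise ValueError("enumeration limited to at most 6 variables")
    allowed = [
        (src, dst)
        for src in variables
        for dst in variables
        if src != dst and dst not in exogenous_only and src not in sink_only
    ]
    models = []
    for r in range(len(allowed) + 1):
        for subset in itertools.combinations(allowed, r):
            try:
                models.append(
                    PathModel(
                        variables=tuple(variables),
                        edges=frozenset(subset),
                        exogenous=tuple(v for v in variables if v in exogenous_only),
                    )
                )
            except ValueError:
                continue  # cyclic or over-parameterized subset
    return models


#: Incremental indices compare against the independence baseline; when
#: the baseline itself fits the data (nothing to improve on) they are
#: degenerate (e.g. NFI of the empty model is identically 0) and do not
#: bind in the battery.
INCREMENTAL_INDICES = ("CFI", "NFI", "RFI", "IFI")


def _passes(indices: FitIndices, criteria: dict, baseline_fits: bool = False) -> dict:
    audit = {}
    for name, (op, threshold) in criteria.items():
        value = getattr(indices, name)
        if baseline_fits and name in INCREMENTAL_INDICES:
            audit[name] = True
        elif value is None:
            audit[name] = False
        elif op == ">":
            audit[name] = value > threshold
        elif op == "<":
            audit[name] = value < threshold
        else:
            raise ValueError(f"unknown comparison {op!r}")
    return audit


@dataclass
class SearchResult:
    passing_models: list
    best: tuple | None
    audit: pd.DataFrame
    all_fits: list = field(repr=False, default_factory=list)

    def best_edges(self) -> frozenset | None:
        return None if self.best is None else self.best[0].edges


def model_search(
    S: pd.DataFrame,
    N: int,
    criteria: dict | None = None,
    variables=DEFAULT_VARIABLES,
    exogenous_only: tuple = ("heterozygosity",),
    sink_only: tuple = ("PHT",),
    standardize: bool = True,
) -> SearchResult:
    """Exhaustive fit of every admissible model with AIC selection.

    Each enumerated model is fitted to S (converted to a correlation
    matrix when ``standardize``); a model passes when every criterion
    in the battery holds (indices unavailable at df = 0 count as
    failures, excluding saturated models).  The winner is the passing
    model with minimum AIC.  When nothing passes, the audit is still
    returned in full.
    """
    criteria = DEFAULT_CRITERIA if criteria is None else criteria
    S = pd.DataFrame(S, index=variables, columns=variables).astype(float)
    if standardize:
        d = np.sqrt(np.diag(S.to_numpy()))
        S = S / np.outer(d, d)
    base_chi2, base_df = _baseline_fit(S.to_numpy(), N)
    baseline_fits = stats.chi2.sf(base_chi2, base_df) > 0.05
    rows = []
    passing = []
    fits = []
    for model in enumerate_models(variables, exogenous_only, sink_only):
        estimates, indices = fit_path_model(model, S, N)
        audit = _passes(indices, criteria, baseline_fits=baseline_fits)
        ok = all(audit.values())
        edge_label = ";".join(sorted(f"{s}->{t}" for s, t in model.edges))
        rows.append(
            {
                "edges": edge_label,
                "n_edges": len(model.edges),
                "df": model.df,
                "AIC": indices.AIC,
                "chi2": indices.chi2,
                "passes": ok,
                **{f"pass_{k}": v for k, v in audit.items()},
            }
        )
        fits.append((model, estimates, indices))
        if ok:
            passing.append((model, estimates, indices))
    best = min(passing, key=lambda t: t[2].AIC) if passing else None
    return SearchResult(
        passing_models=passing,
        best=best,
        audit=pd.DataFrame(rows).sort_values("AIC").reset_index(drop=True),
        all_fits=fits,
    )
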