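"""Marker quality control, imputation, and donor-genome accounting.

Genotype calls are coded with single characters: ``A`` recurrent-parent
homozygous, ``H`` heterozygous, ``B`` donor homozygous, ``N`` missing.
Backcross introgression families carry donor alleles almost exclusively
in heterozygous state, so their donor genome proportion (DGP) is half
the heterozygosity percentage; doubled-haploid lines carry donor
alleles only in homozygous state, so their DGP equals the
donor-homozygous percentage.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

RP_HOM = "A"
HET = "H"
DONOR_HOM = "B"
MISSING = "N"
CALL_CODES = (RP_HOM, HET, DONOR_HOM, MISSING)

__all__ = [
    "MarkerMatrix",
    "QCReport",
    "qc_markers",
    "impute_knn",
    "heterozygosity",
    "donor_homozygosity",
    "donor_genome_proportion",
    "expected_dgp",
    "RP_HOM",
    "HET",
    "DONOR_HOM",
    "MISSING",
]


@dataclass
class MarkerMatrix:
    """Entries x markers call table plus positioned marker annotations.

    Parameters
    ----------
    calls
        DataFrame indexed by entry, columns are marker ids, values in
        ``{"A", "H", "B", "N"}``.
    markers
        DataFrame indexed by marker id with columns ``chrom`` and ``bp``
        (1-based physical position).
    meta
        Optional per-entry metadata (generation, family, ...).
    """

    calls: pd.DataFrame
    markers: pd.DataFrame
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if list(self.calls.columns) != list(self.markers.index):
            if set(self.calls.columns) != set(self.markers.index):
                raise ValueError("calls columns and marker annotations disagree")
            self.markers = self.markers.loc[list(self.calls.columns)]
        bad = set(np.unique(self.calls.to_numpy())) - set(CALL_CODES)
        if bad:
            raise ValueError(f"unknown call codes: {sorted(bad)}")
        dup = self.markers.duplicated(subset=["chrom", "bp"])
        if dup.any():
            raise ValueError("duplicate (chromosome, bp) marker positions")

    @property
    def n_entries(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def subset_markers(self, keep: list) -> "MarkerMatrix":
        return MarkerMatrix(
            calls=self.calls.loc[:, keep].copy(),
            markers=self.markers.loc[keep].copy(),
            meta=self.meta,
        )


@dataclass
class QCReport:
    n_input_markers: int
    n_dropped_rp_missing: int
    n_dropped_rp_het: int
    n_dropped_missingness: int
    n_dropped_maf: int
    n_retained: int
    dropped: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = (
            self.n_dropped_rp_missing
            + self.n_dropped_rp_het
            + self.n_dropped_missingness
            + self.n_dropped_maf
            + self.n_retained
        )
        assert total == self.n_input_markers, "QC tallies do not add up"

    def as_dict(self) -> dict:
        return {
            "n_input_markers": self.n_input_markers,
            "n_dropped_rp_missing": self.n_dropped_rp_missing,
            "n_dropped_rp_het": self.n_dropped_rp_het,
            "n_dropped_missingness": self.n_dropped_missingness,
            "n_dropped_maf": self.n_dropped_maf,
            "n_retained": self.n_retained,
        }


def qc_markers(
    matrix: MarkerMatrix,
    rp_calls: pd.DataFrame,
    maf_threshold: float = 0.05,
    max_missing: float = 0.05,
    rp_het_limit: int = 3,
) -> tuple[MarkerMatrix, QCReport]:
    """Sequential marker filters against recurrent-parent (RP) controls.

    Rules are applied in a fixed order so the report tallies are
    unambiguous: (1) markers missing across *all* RP individuals,
    (2) markers heterozygous in >= ``rp_het_limit`` RP individuals
    (residual heterozygosity in a fixed inbred should not recur at one
    position), (3) markers with more than ``max_missing`` missing calls
    across the study entries, (4) markers with minor allele frequency
    <= ``maf_threshold`` (a heterozygous call contributes one copy of
    each allele).
    """
    if set(rp_calls.columns) != set(matrix.calls.columns):
        raise ValueError("rp_calls must cover the same markers as the matrix")
    if not 0 <= maf_threshold <= 0.5:
        raise ValueError("maf_threshold must be in [0, 0.5]")
    rp = rp_calls.loc[:, matrix.calls.columns]

    dropped: dict[str, list] = {}
    cols = np.asarray(matrix.calls.columns)

    rp_arr = rp.to_numpy()
    rule1 = (rp_arr == MISSING).all(axis=0)
    dropped["rp_missing"] = list(cols[rule1])
    alive = ~rule1

    rule2 = ((rp_arr == HET).sum(axis=0) >= rp_het_limit) & alive
    dropped["rp_het"] = list(cols[rule2])
    alive &= ~rule2

    arr = matrix.calls.to_numpy()
    miss_frac = (arr == MISSING).mean(axis=0)
    rule3 = (miss_frac > max_missing) & alive
    dropped["missingness"] = list(cols[rule3])
    alive &= ~rule3

    n_ref = 2 * (arr == RP_HOM).sum(axis=0) + (arr == HET).sum(axis=0)
    n_alt = 2 * (arr == DONOR_HOM).sum(axis=0) + (arr == HET).sum(axis=0)
    total = n_ref + n_alt
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(total > 0, np.minimum(n_ref, n_alt) / np.maximum(total, 1), 0.0)
    rule4 = (maf <= maf_threshold) & alive
    dropped["maf"] = list(cols[rule4])
    alive &= ~rule4

    keep = list(cols[alive])
    report = QCReport(
        n_input_markers=matrix.n_markers,
        n_dropped_rp_missing=len(dropped["rp_missing"]),
        n_dropped_rp_het=len(dropped["rp_het"]),
        n_dropped_missingness=len(dropped["missingness"]),
        n_dropped_maf=len(dropped["maf"]),
        n_retained=len(keep),
        dropped=dropped,
    )
    return matrix.subset_markers(keep), report


def _modal_call(column: np.ndarray) -> str:
    """Most frequent non-missing call in a marker column (ties by code order)."""
    counts = Counter(c for c in column if c != MISSING)
    if not counts:
        return MISSING
    best = max(counts.values())
    for code in CALL_CODES:
        if counts.get(code) == best:
            return code
    raise AssertionError("unreachable")


def impute_knn(matrix: MarkerMatrix, k: int = 5, window: int = 30) -> MarkerMatrix:
    """Fill missing calls by k-nearest-neighbour vote over flanking markers.

    For each missing call the ``window`` markers flanking the target
    (``window/2`` per side, within the same chromosome, padded from the
    available side near chromosome ends) define a local haplotype; the
    distance between two entries is the count of mismatching pairwise
    non-missing calls over that window.  The missing call is filled by
    majority vote among the k nearest entries (distance ties broken by
    entry order, vote ties resolved to the marker-wise modal call).  If
    all k neighbours are themselves missing at the target, the
    marker-wise modal call is used.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if matrix.n_entries < k + 1:
        raise ValueError("need at least k+1 entries")
    arr = matrix.calls.to_numpy(dtype="U1").copy()
    n, m = arr.shape
    order = matrix.markers.sort_values(["chrom", "bp"]).index
    col_of = {mk: i for i, mk in enumerate(matrix.calls.columns)}
    # marker column indices grouped by chromosome, in physical order
    by_chrom: dict = {}
    for mk in order:
        by_chrom.setdefault(matrix.markers.at[mk, "chrom"], []).append(col_of[mk])

    missing_rows, missing_cols = np.nonzero(arr == MISSING)
    if missing_rows.size == 0:
        return matrix
    half = max(window // 2, 1)
    filled = arr.copy()
    for e, j in zip(missing_rows, missing_cols):
        chrom = matrix.markers.iloc[j]["chrom"]
        chrom_cols = by_chrom[chrom]
        pos = chrom_cols.index(j)
        lo = max(pos - half, 0)
        hi = min(pos + half + 1, len(chrom_cols))
        flank = [c for c in chrom_cols[lo:hi] if c != j]
        if not flank:
            flank = [c for c in range(m) if c != j]
        block = arr[:, flank]
        target_row = block[e]
        comparable = (block != MISSING) & (target_row != MISSING)[None, :]
        dist = ((block != target_row[None, :]) & comparable).sum(axis=1)
        candidates = [i for i in range(n) if i != e]
        candidates.sort(key=lambda i: (dist[i], i))
        neighbours = candidates[:k]
        votes = Counter(arr[i, j] for i in neighbours if arr[i, j] != MISSING)
        if not votes:
            filled[e, j] = _modal_call(arr[:, j])
            continue
        best = max(votes.values())
        winners = [c for c in CALL_CODES if votes.get(c) == best]
        filled[e, j] = winners[0] if len(winners) == 1 else _modal_call(arr[:, j])
    calls = pd.DataFrame(filled, index=matrix.calls.index, columns=matrix.calls.columns)
    return MarkerMatrix(calls=calls, markers=matrix.markers, meta=matrix.meta)


def _state_percent(matrix: MarkerMatrix, code: str) -> pd.Series:
    arr = matrix.calls.to_numpy()
    non_missing = (arr != MISSING).sum(axis=1)
    empty = non_missing == 0
    if empty.any():
        bad = list(matrix.calls.index[empty])
        warnings.warn(f"entries with all calls missing excluded: {bad}")
    hits = (arr == code).sum(axis=1)
    with np.errstate(invalid="ignore"):
        pct = 100.0 * hits / non_missing
    out = pd.Series(pct, index=matrix.calls.index, name=f"{code}_pct")
    return out[~empty]


def heterozygosity(matrix: MarkerMatrix) -> pd.Series:
    """Per-entry heterozygosity: 100 x het calls / non-missing calls."""
    return _state_percent(matrix, HET).rename("heterozygosity_pct")


def donor_homozygosity(matrix: MarkerMatrix) -> pd.Series:
    """Per-entry donor-homozygous percentage of non-missing calls."""
    return _state_percent(matrix, DONOR_HOM).rename("donor_hom_pct")


def donor_genome_proportion(heterozygosity_pct, donor_hom_pct=0.0):
    """DGP = heterozygosity/2 + donor-homozygous percentage.

    Each heterozygous locus carries one donor allele, so it contributes
    half; each donor-homozygous locus (doubled haploids) contributes
    fully.  Accepts scalars or aligned Series, returns percentages.
    """
    het = np.asarray(heterozygosity_pct, dtype=float)
    hom = np.asarray(donor_hom_pct, dtype=float)
    if ((het < 0) | (het > 100)).any() or ((hom < 0) | (hom > 100)).any():
        raise ValueError("percentages must be in [0, 100]")
    dgp = het / 2.0 + hom
    if isinstance(heterozygosity_pct, pd.Series):
        return pd.Series(dgp, index=heterozygosity_pct.index, name="dgp_pct")
    return float(dgp) if dgp.ndim == 0 else dgp


def expected_dgp(t: int, dh_from_bc1: bool = False) -> float:
    """Neutral expected donor genome proportion (percent).

    After t backcrosses to the recurrent parent without selection the
    expected donor fraction is (1/2)^(t+1): the F1 carries 50% donor
    genome and each backcross halves it.  A doubled haploid made from a
    random BC1 gamete fixes the BC1 donor expectation at 25%.
    """
    if dh_from_bc1:
        return 25.0
    if t < 1:
        raise ValueError("backcross generation t must be >= 1")
    return 100.0 * 0.5 ** (t + 1)
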