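"""Synthetic backcross-introgression populations and their phenotypes.

The generator emulates the study design the downstream statistics
assume: backcross (BC) families carried to BC3-BC6 under truncation
selection for plant height versus unselected BC1-derived doubled
haploid (DH) lines, a recursive structural model linking marker
heterozygosity, gibberellin (GA) and brassinosteroid (BR) levels, and
plant height (PHT), seedling mesocotyl assays under water / Pcz / Ucz
inhibitor treatment, and candidate-gene maps with controllable
enrichment near causal loci.

Genomes are tracked at marker resolution only.  Meiosis follows a
Haldane no-interference model: the recombination fraction between
adjacent markers at map distance d Morgans is (1 - exp(-2 d)) / 2, and
a gamete is a Markov chain of parental-origin states along each
chromosome.  All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotype_core import (
    DONOR_HOM,
    HET,
    MarkerMatrix,
    RP_HOM,
)

VARIABLES = ("heterozygosity", "GA", "BR", "PHT")

#: Pairwise Pearson correlations reported for the taller-background
#: introgression library (PHT, BR, GA, heterozygosity); the default
#: structural parameters are calibrated so the model implies them.
PIF_TARGET_CORRELATIONS = {
    ("PHT", "BR"): 0.46,
    ("PHT", "GA"): 0.59,
    ("PHT", "heterozygosity"): 0.72,
    ("BR", "GA"): 0.52,
    ("BR", "heterozygosity"): 0.34,
    ("GA", "heterozygosity"): 0.53,
}

__all__ = [
    "MarkerMap",
    "StructuralParams",
    "PedigreeSpec",
    "simulate_genome_map",
    "simulate_bc_population",
    "simulate_dh_population",
    "simulate_phenotypes",
    "simulate_hormone_assay",
    "simulate_candidate_genes",
    "simulate_rp_controls",
    "structural_sample",
    "implied_correlation",
    "default_structural_params",
    "PIF_TARGET_CORRELATIONS",
    "VARIABLES",
]


@dataclass(frozen=True)
class MarkerMap:
    """Marker positions on a set of chromosomes.

    ``cm_per_mb`` converts physical to genetic distance (default
    1 cM/Mb, a genome-wide average rate).
    """

    chrom_length_bp: tuple
    positions: tuple  # per chromosome, sorted 1-based bp arrays
    cm_per_mb: float = 1.0

    def __post_init__(self) -> None:
        if len(self.chrom_length_bp) != len(self.positions):
            raise ValueError("one position array per chromosome required")
        for L, pos in zip(self.chrom_length_bp, self.positions):
            pos = np.asarray(pos)
            if L <= 0:
                raise ValueError("chromosome lengths must be positive")
            if pos.size < 1:
                raise ValueError("every chromosome needs at least one marker")
            if (np.diff(pos) <= 0).any():
                raise ValueError("positions must be strictly increasing")
            if pos[0] < 1 or pos[-1] > L:
                raise ValueError("positions must lie in [1, chrom_length]")

    @property
    def n_chromosomes(self) -> int:
        return len(self.chrom_length_bp)

    @property
    def n_markers(self) -> int:
        return int(sum(len(p) for p in self.positions))

    def annotations(self) -> pd.DataFrame:
        """Marker annotation table (marker id, chrom, bp), genome order."""
        rows = []
        for c, pos in enumerate(self.positions, start=1):
            for bp in pos:
                rows.append((f"M{c:02d}_{int(bp):09d}", c, int(bp)))
        return pd.DataFrame(rows, columns=["marker", "chrom", "bp"]).set_index("marker")

    def recombination_fractions(self, chrom_idx: int) -> np.ndarray:
        """Haldane recombination fraction between adjacent markers."""
        pos = np.asarray(self.positions[chrom_idx], dtype=float)
        d_morgan = np.diff(pos) / 1e6 * self.cm_per_mb / 100.0
        return 0.5 * (1.0 - np.exp(-2.0 * d_morgan))


@dataclass(frozen=True)
class StructuralParams:
    """Recursive structural model over (heterozygosity, GA, BR, PHT).

    ``edges`` maps directed edges to standardized path coefficients;
    ``residual_sd`` gives residual standard deviations of the
    endogenous variables; ``exo_variance`` the variance of the
    exogenous heterozygosity score.  With the defaults all variables
    have unit model-implied variance, so coefficients are path
    correlations.
    """

    edges: dict
    residual_sd: dict
    exo_variance: dict = field(default_factory=lambda: {"heterozygosity": 1.0})

    def __post_init__(self) -> None:
        # singular (noiseless-limit) models are allowed; negative
        # eigenvalues would mean an inadmissible covariance
        sigma = self.implied_covariance()
        if np.linalg.eigvalsh(sigma).min() < -1e-10:
            raise ValueError("implied covariance matrix is not positive definite")

    def coefficient_matrix(self) -> np.ndarray:
        """B[i, j] = coefficient on variable j in the equation for variable i."""
        idx = {v: i for i, v in enumerate(VARIABLES)}
        B = np.zeros((len(VARIABLES), len(VARIABLES)))
        for (src, dst), coef in self.edges.items():
            B[idx[dst], idx[src]] = coef
        return B

    def implied_covariance(self) -> np.ndarray:
        B = self.coefficient_matrix()
        p = len(VARIABLES)
        P = np.zeros((p, p))
        for i, v in enumerate(VARIABLES):
            if v in self.exo_variance:
                P[i, i] = self.exo_variance[v]
            else:
                P[i, i] = self.residual_sd.get(v, 0.0) ** 2
        inv = np.linalg.inv(np.eye(p) - B)
        return inv @ P @ inv.T


def default_structural_params() -> StructuralParams:
    """Structural parameters calibrated to the observed PIF correlations.

    The final-model topology has edges Het->GA, GA->BR, GA->PHT,
    BR->PHT and Het->PHT.  Coefficients are obtained by solving the
    standardized path equations against :data:`PIF_TARGET_CORRELATIONS`
    (per-equation least squares on the correlation matrix), and
    residual variances are set so every variable has unit variance.
    """
    r = PIF_TARGET_CORRELATIONS
    a = r[("GA", "heterozygosity")]
    b = r[("BR", "GA")]
    # PHT equation: regress PHT on (Het, GA, BR) under the model-implied
    # predictor correlations corr(Het,GA)=a, corr(GA,BR)=b, corr(Het,BR)=a*b.
    pred_corr = np.array([[1.0, a, a * b], [a, 1.0, b], [a * b, b, 1.0]])
    rhs = np.array(
        [r[("PHT", "heterozygosity")], r[("PHT", "GA")], r[("PHT", "BR")]]
    )
    c, d, f = np.linalg.solve(pred_corr, rhs)
    pht_var = rhs @ np.linalg.solve(pred_corr, rhs)
    edges = {
        ("heterozygosity", "GA"): float(a),
        ("GA", "BR"): float(b),
        ("heterozygosity", "PHT"): float(c),
        ("GA", "PHT"): float(d),
        ("BR", "PHT"): float(f),
    }
    residual_sd = {
        "GA": float(np.sqrt(1.0 - a**2)),
        "BR": float(np.sqrt(1.0 - b**2)),
        "PHT": float(np.sqrt(1.0 - pht_var)),
    }
    return StructuralParams(edges=edges, residual_sd=residual_sd)


def implied_correlation(params: StructuralParams) -> pd.DataFrame:
    """Model-implied correlation matrix over the four observed variables."""
    sigma = params.implied_covariance()
    sd = np.sqrt(np.diag(sigma))
    corr = sigma / np.outer(sd, sd)
    return pd.DataFrame(corr, index=VARIABLES, columns=VARIABLES)


def structural_sample(
    params: StructuralParams, het_score: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw (GA, BR, PHT) given standardized heterozygosity scores.

    Applies the recursive equations in topological order with fresh
    Gaussian residuals; returns a DataFrame over all four variables.
    """
    het_score = np.asarray(het_score, dtype=float)
    n = het_score.size
    values = {"heterozygosity": het_score}
    for v in VARIABLES[1:]:
        total = np.zeros(n)
        for (src, dst), coef in params.edges.items():
            if dst == v:
                total = total + coef * values[src]
        total = total + params.residual_sd.get(v, 0.0) * rng.standard_normal(n)
        values[v] = total
    return pd.DataFrame(values)


@dataclass(frozen=True)
class PedigreeSpec:
    """Backcross pedigree description.

    ``target_generation`` is the number of backcrosses t (BC_t);
    ``selection_mode`` either ``"none"`` (neutral expectations hold) or
    ``"truncation-pht"`` (the tallest of ``candidates_per_cross``
    candidate sibs on latent PHT is advanced each generation).
    """

    n_families: int
    target_generation: int = 6
    selection_mode: str = "none"
    candidates_per_cross: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.target_generation <= 8:
            raise ValueError("target_generation must be in 1..8")
        if self.candidates_per_cross < 1:
            raise ValueError("candidates_per_cross must be >= 1")
        if self.selection_mode not in ("none", "truncation-pht"):
            raise ValueError(f"unknown selection_mode {self.selection_mode!r}")
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")


def simulate_genome_map(
    n_chrom: int, chrom_length_bp: int, n_markers: int, seed: int
) -> MarkerMap:
    """Place markers uniformly at random on equal-length chromosomes.

    Marker counts are split as evenly as possible across chromosomes;
    positions are drawn without replacement and sorted.
    """
    if n_chrom < 1 or n_markers < n_chrom or chrom_length_bp < 1:
        raise ValueError("need n_chrom >= 1, n_markers >= n_chrom, positive length")
    rng = np.random.default_rng(seed)
    base, extra = divmod(n_markers, n_chrom)
    positions = []
    for c in range(n_chrom):
        count = base + (1 if c < extra else 0)
        pos = set()
        while len(pos) < count:
            need = count - len(pos)
            pos.update(rng.integers(1, chrom_length_bp + 1, size=need).tolist())
        positions.append(np.array(sorted(pos), dtype=np.int64))
    return MarkerMap(
        chrom_length_bp=tuple([chrom_length_bp] * n_chrom),
        positions=tuple(positions),
    )


def _meiosis_batch(
    gmap: MarkerMap, hap_donor: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Gametes from individuals with haplotype pair (hap_donor, all-RP).

    ``hap_donor`` is an (n, M) boolean donor-origin indicator for the
    non-recurrent haplotype, markers in genome order.  The returned
    gamete carries the donor allele where the parental-origin chain is
    on the non-recurrent haplotype and that haplotype carries donor.
    """
    n, m = hap_donor.shape
    out = np.empty((n, m), dtype=bool)
    offset = 0
    for ci in range(gmap.n_chromosomes):
        mc = len(gmap.positions[ci])
        r = gmap.recombination_fractions(ci)
        start = rng.random(n) < 0.5
        switches = rng.random((n, mc - 1)) < r[None, :]
        # parental-origin state along the chromosome: 0 = non-recurrent hap
        state = np.concatenate(
            [start[:, None], switches], axis=1
        ).cumsum(axis=1) % 2
        out[:, offset : offset + mc] = hap_donor[:, offset : offset + mc] & (
            state == 0
        )
        offset += mc
    return out


def simulate_bc_population(
    gmap: MarkerMap, spec: PedigreeSpec, params: StructuralParams | None = None
) -> tuple[MarkerMatrix, pd.DataFrame]:
    """Backcross families with optional truncation selection on latent PHT.

    Each family starts from an F1 (one full donor haplotype, one
    recurrent haplotype).  Every generation the current individual is
    crossed to the recurrent parent; under ``truncation-pht`` the
    tallest of ``candidates_per_cross`` candidate offspring on latent
    PHT is advanced, where latent PHT follows the structural equations
    applied to heterozygosity standardized within the candidate batch
    (selection only uses within-family ranking).  Returns the final
    BC_t marker matrix and a per-entry latent trait table drawn from
    the structural model with heterozygosity standardized across the
    population.
    """
    params = params or default_structural_params()
    rng = np.random.default_rng(spec.seed)
    n_fam = spec.n_families
    m = gmap.n_markers
    k = spec.candidates_per_cross if spec.selection_mode == "truncation-pht" else 1

    hap = np.ones((n_fam, m), dtype=bool)  # F1 non-recurrent haplotype: all donor
    for _ in range(spec.target_generation):
        parents = np.repeat(hap, k, axis=0)
        gametes = _meiosis_batch(gmap, parents, rng)
        if k == 1:
            hap = gametes
            continue
        het = gametes.mean(axis=1).reshape(n_fam, k)
        mu = het.mean(axis=1, keepdims=True)
        sd = het.std(axis=1, keepdims=True)
        z = np.where(sd > 0, (het - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        latent = structural_sample(params, z.ravel(), rng)
        pick = latent["PHT"].to_numpy().reshape(n_fam, k).argmax(axis=1)
        hap = gametes.reshape(n_fam, k, m)[np.arange(n_fam), pick]

    annotations = gmap.annotations()
    calls = np.where(hap, HET, RP_HOM)
    entries = [f"BC{spec.target_generation}_{i:04d}" for i in range(n_fam)]
    matrix = MarkerMatrix(
        calls=pd.DataFrame(calls, index=entries, columns=annotations.index),
        markers=annotations,
        meta=pd.DataFrame(
            {"generation": spec.target_generation, "selection": spec.selection_mode},
            index=entries,
        ),
    )
    het_frac = hap.mean(axis=1)
    sd = het_frac.std()
    z = (het_frac - het_frac.mean()) / (sd if sd > 0 else 1.0)
    latent = structural_sample(params, z, rng)
    latent.index = pd.Index(entries, name="entry")
    latent.insert(0, "heterozygosity_pct", 100.0 * het_frac)
    return matrix, latent


def simulate_dh_population(
    gmap: MarkerMap, n_lines: int, seed: int
) -> MarkerMatrix:
    """Doubled haploids from random unselected BC1 individuals.

    Each line doubles one random gamete of a random BC1 individual, so
    every call is homozygous and the expected donor genome proportion
    is 25%.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    rng = np.random.default_rng(seed)
    m = gmap.n_markers
    f1 = np.ones((n_lines, m), dtype=bool)
    bc1 = _meiosis_batch(gmap, f1, rng)  # BC1 non-recurrent haplotypes
    doubled = _meiosis_batch(gmap, bc1, rng)  # gamete of BC1, then doubled
    annotations = gmap.annotations()
    calls = np.where(doubled, DONOR_HOM, RP_HOM)
    entries = [f"DH_{i:04d}" for i in range(n_lines)]
    return MarkerMatrix(
        calls=pd.DataFrame(calls, index=entries, columns=annotations.index),
        markers=annotations,
        meta=pd.DataFrame({"generation": "BC1-DH", "selection": "none"}, index=entries),
    )


#: Field-trial scale defaults for observable traits: mean, genetic SD,
#: emulating plant height in cm and the two inhibitor-response ratios.
TRAIT_SCALES = {
    "PHT": (180.0, 25.0),
    "GA": (0.20, 0.06),
    "BR": (0.30, 0.07),
}

#: Default variance components for PHT field observations (cm^2):
#: chosen so entry-mean heritability over 5 locations x 2 replicates is
#: about 0.81, matching multi-environment maize height trials.
DEFAULT_VC = {"sigma2_env": 100.0, "sigma2_ge": 400.0, "sigma2_e": 650.0}


def simulate_phenotypes(
    entries: MarkerMatrix,
    params: StructuralParams | None = None,
    n_env: int = 5,
    n_rep: int = 2,
    vc: dict | None = None,
    seed: int = 0,
    latent: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Long-format multi-environment phenotype records for the entries.

    Genotypic values come from the structural model applied to the
    entries' standardized heterozygosity (or a precomputed ``latent``
    table); field observations add environment, genotype x environment
    and residual effects with the given variance components, scaled per
    trait relative to the PHT scale.  Columns: entry, environment,
    replicate, trait, value.
    """
    from .genotype_core import heterozygosity  # local to avoid cycle at import

    params = params or default_structural_params()
    vc = dict(DEFAULT_VC, **(vc or {}))
    if n_env < 1 or n_rep < 1:
        raise ValueError("n_env and n_rep must be >= 1")
    if any(v < 0 for v in vc.values()):
        raise ValueError("variance components must be non-negative")
    rng = np.random.default_rng(seed)
    if latent is None:
        het = heterozygosity(entries)
        sd = het.std(ddof=0)
        z = (het - het.mean()) / (sd if sd > 0 else 1.0)
        latent = structural_sample(params, z.to_numpy(), rng)
        latent.index = het.index
    n = len(latent)
    records = []
    pht_sd = TRAIT_SCALES["PHT"][1]
    for trait, (mu, sd_g) in TRAIT_SCALES.items():
        scale2 = (sd_g / pht_sd) ** 2
        g = mu + sd_g * latent[trait].to_numpy()
        env_eff = rng.normal(0.0, np.sqrt(vc["sigma2_env"] * scale2), size=n_env)
        ge = rng.normal(0.0, np.sqrt(vc["sigma2_ge"] * scale2), size=(n, n_env))
        for j in range(n_env):
            for r in range(n_rep):
                eps = rng.normal(0.0, np.sqrt(vc["sigma2_e"] * scale2), size=n)
                vals = g + env_eff[j] + ge[:, j] + eps
                records.append(
                    pd.DataFrame(
                        {
                            "entry": latent.index,
                            "environment": f"env{j + 1}",
                            "replicate": r + 1,
                            "trait": trait,
                            "value": vals,
                        }
                    )
                )
    return pd.concat(records, ignore_index=True)


@dataclass(frozen=True)
class InhibitorLink:
    """Monotone logistic map from a hormone score to a length ratio.

    ``g(z) = lo + (hi - lo) * sigmoid(slope * z + center)`` stays in
    (0, 1]; higher hormone level (more inhibitor-tolerant genotype)
    gives a larger ratio, i.e. less mesocotyl shortening.
    """

    lo: float
    hi: float
    slope: float
    center: float

    def __call__(self, z: np.ndarray) -> np.ndarray:
        return self.lo + (self.hi - self.lo) / (1.0 + np.exp(-(self.slope * np.asarray(z, float) + self.center)))

    @classmethod
    def from_mean_ratio(cls, mean_ratio: float, lo: float = 0.03, hi: float = 0.95, slope: float = 0.5):
        frac = (mean_ratio - lo) / (hi - lo)
        if not 0 < frac < 1:
            raise ValueError("mean_ratio outside the (lo, hi) band")
        return cls(lo=lo, hi=hi, slope=slope, center=float(np.log(frac / (1 - frac))))


# Ucz (GA inhibitor) shortens mesocotyls more than Pcz (BR inhibitor),
# so the GA link has the lower central ratio.
DEFAULT_BR_LINK = InhibitorLink.from_mean_ratio(0.30)
DEFAULT_GA_LINK = InhibitorLink.from_mean_ratio(0.18)


def simulate_hormone_assay(
    entries: MarkerMatrix,
    params: StructuralParams | None = None,
    n_seedlings: int = 12,
    n_replicates: int = 3,
    seed: int = 0,
    latent: pd.DataFrame | None = None,
    br_link: InhibitorLink | None = None,
    ga_link: InhibitorLink | None = None,
    baseline_mw_mm: float = 40.0,
) -> pd.DataFrame:
    """Mesocotyl-length assays under water, Pcz and Ucz treatment.

    Per entry and replicate the water-control mean length MW is drawn
    around a common baseline; MP = MW * g_BR(BR score) and
    MU = MW * g_GA(GA score) with monotone increasing link functions
    bounded in (0, 1].  Replicate means average ``n_seedlings``
    seedlings, so their noise shrinks with 1/sqrt(n_seedlings).
    Columns: entry, replicate, MW, MP, MU (mm).
    """
    from .genotype_core import heterozygosity

    if n_seedlings < 1:
        raise ValueError("n_seedlings must be >= 1")
    params = params or default_structural_params()
    br_link = br_link or DEFAULT_BR_LINK
    ga_link = ga_link or DEFAULT_GA_LINK
    rng = np.random.default_rng(seed)
    if latent is None:
        het = heterozygosity(entries)
        sd = het.std(ddof=0)
        z = (het - het.mean()) / (sd if sd > 0 else 1.0)
        latent = structural_sample(params, z.to_numpy(), rng)
        latent.index = het.index
    n = len(latent)
    g_br = br_link(latent["BR"].to_numpy())
    g_ga = ga_link(latent["GA"].to_numpy())
    seedling_sd = 6.0 / np.sqrt(n_seedlings)
    frames = []
    for rep in range(1, n_replicates + 1):
        mw = rng.normal(baseline_mw_mm, 3.0, size=n) + rng.normal(0, seedling_sd, n)
        mw = np.clip(mw, 5.0, None)
        mp = mw * g_br + rng.normal(0, seedling_sd, n)
        mu = mw * g_ga + rng.normal(0, seedling_sd, n)
        frames.append(
            pd.DataFrame(
                {
                    "entry": latent.index,
                    "replicate": rep,
                    "MW": mw,
                    "MP": np.clip(mp, 0.5, None),
                    "MU": np.clip(mu, 0.5, None),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_candidate_genes(
    gmap: MarkerMap,
    n_genes: int,
    causal_snps: pd.DataFrame | None = None,
    enrichment: float = 0.0,
    seed: int = 0,
    window_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Candidate-gene intervals, optionally enriched near causal SNPs.

    A fraction ``enrichment`` of genes is placed within ``window_bp``
    of a randomly chosen causal SNP; the remainder are uniform over the
    genome.  ``causal_snps`` needs columns chrom, bp.  Returns a
    DataFrame (gene, chrom, start, end, pathway) with 1-based inclusive
    coordinates and random BR/GA pathway labels.
    """
    if not 0.0 <= enrichment <= 1.0:
        raise ValueError("enrichment must be in [0, 1]")
    if enrichment > 0 and (causal_snps is None or len(causal_snps) == 0):
        raise ValueError("enrichment > 0 requires causal SNPs")
    rng = np.random.default_rng(seed)
    lengths = np.asarray(gmap.chrom_length_bp, dtype=float)
    n_enriched = int(round(enrichment * n_genes))
    rows = []
    for i in range(n_genes):
        size = int(rng.integers(2_000, 8_000))
        if i < n_enriched:
            snp = causal_snps.iloc[int(rng.integers(len(causal_snps)))]
            chrom = int(snp["chrom"])
            L = gmap.chrom_length_bp[chrom - 1]
            lo = max(1, int(snp["bp"]) - window_bp)
            hi = min(L - size, int(snp["bp"]) + window_bp)
            start = int(rng.integers(lo, max(hi, lo + 1)))
        else:
            chrom = int(rng.choice(gmap.n_chromosomes, p=lengths / lengths.sum()) + 1)
            start = int(rng.integers(1, gmap.chrom_length_bp[chrom - 1] - size))
        pathway = "BR" if rng.random() < 0.5 else "GA"
        rows.append((f"gene{i:04d}", chrom, start, start + size, pathway))
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "pathway"])


def simulate_rp_controls(
    gmap: MarkerMap,
    n_individuals: int = 6,
    missing_rate: float = 0.01,
    residual_het_rate: float = 0.002,
    seed: int = 0,
) -> pd.DataFrame:
    """Recurrent-parent control genotypes for marker quality control.

    An inbred recurrent parent is homozygous reference everywhere, with
    sparse random missing calls and rare residual heterozygosity.
    """
    rng = np.random.default_rng(seed)
    ann = gmap.annotations()
    m = len(ann)
    arr = np.full((n_individuals, m), RP_HOM, dtype="U1")
    arr[rng.random((n_individuals, m)) < residual_het_rate] = HET
    arr[rng.random((n_individuals, m)) < missing_rate] = "N"
    return pd.DataFrame(
        arr, index=[f"RP_{i + 1}" for i in range(n_individuals)], columns=ann.index
    )
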