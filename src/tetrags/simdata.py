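"""Synthetic autotetraploid GBS populations with known truth.

Emulates a panmictic half-sib evaluation: ~154 tetraploid genotypes
scored at ~10^4 biallelic markers through GBS-style read counts, with
replicated progeny-mean phenotypes observed in several growing
conditions.  Marker dosages are binomial(4, allele frequency) draws per
sample (no subpopulation structure, no linkage disequilibrium by
default), read depths are negative-binomial around a configurable mean,
and phenotypes follow the two-way random model

    y_icr = mu_c + g_i + (ge)_ic + e_icr

with the additive genetic value g_i = sum_m dosage(i, m) * beta_m over a
sparse-to-polygenic set of QTL.  Noise variances are calibrated
analytically from the realized variance of g so that the broad-sense
heritability on a progeny-mean basis matches ``target_h2`` in
expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calling import ReadCountMatrix


@dataclass
class SimConfig:
    """Study design and genetic architecture of a simulated population.

    Defaults mirror a half-sib progeny trial of 154 parent genotypes
    evaluated in 3 growing conditions x 3 replicates, genotyped at
    11,450 polymorphic GBS markers with a mean depth of 30 reads per
    sample and marker.  ``n_qtl=None`` means fully polygenic (every
    marker carries an effect).  ``target_h2`` is the broad-sense
    heritability on a progeny-mean basis; ``var_ratio_gc_over_g`` is
    the ratio of genotype-by-condition to genotypic variance.
    """

    n_genotypes: int = 154
    n_markers: int = 11450
    maf_range: tuple[float, float] = (0.05, 0.5)
    mean_depth: float = 30.0
    depth_dispersion: float | None = 2.0  # None -> Poisson depths
    n_qtl: int | None = None
    target_h2: float = 0.5
    var_ratio_gc_over_g: float = 0.3
    n_conditions: int = 3
    n_reps: int = 3
    condition_means: tuple[float, ...] | None = None
    ld_blocks: int | None = None  # None -> markers fully independent
    ld_rho: float = 0.95
    seed: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("maf_range must satisfy 0 <= lo <= hi <= 1")
        if self.n_genotypes < 1 or self.n_conditions < 1 or self.n_reps < 1:
            raise ValueError("counts must be >= 1")
        if self.n_markers < 0:
            raise ValueError("n_markers must be >= 0")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if not 0.0 <= self.target_h2 <= 1.0:
            raise ValueError("target_h2 must be in [0, 1]")
        if self.var_ratio_gc_over_g < 0:
            raise ValueError("var_ratio_gc_over_g must be >= 0")
        if self.n_qtl is not None and self.n_qtl > self.n_markers:
            raise ValueError("n_qtl cannot exceed n_markers")
        if self.condition_means is not None and len(self.condition_means) != self.n_conditions:
            raise ValueError("condition_means length must equal n_conditions")
        if self.ld_blocks is not None and self.ld_blocks < 1:
            raise ValueError("ld_blocks must be >= 1")
        if not 0.0 <= self.ld_rho <= 1.0:
            raise ValueError("ld_rho must be in [0, 1]")


@dataclass
class TetraploidGenotypeMatrix:
    """Samples x markers major-allele dosage in {0..4}, no missing data."""

    dosage: np.ndarray
    sample_ids: list[str]
    marker_ids: list[str]
    allele_freq: np.ndarray = field(default=None)  # per-marker major-allele frequency

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.size and ((self.dosage < 0) | (self.dosage > 4)).any():
            raise ValueError("dosage must be in {0..4}")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]


@dataclass
class SimTruth:
    """Ground truth saved alongside a simulated phenotype set."""

    beta: np.ndarray  # per-marker additive effect (trait units per dosage unit)
    breeding_values: np.ndarray  # per-genotype g_i, centered
    sigma2_g: float
    sigma2_ge: float
    sigma2_e: float


def simulate_population(config: SimConfig) -> TetraploidGenotypeMatrix:
    """Draw a panmictic tetraploid population of dosage genotypes.

    Per marker a minor-allele frequency is drawn uniformly from
    ``config.maf_range``; dosages are then independent
    binomial(4, major frequency) draws per sample.

    With ``ld_blocks`` set, markers are partitioned into contiguous
    blocks sharing a latent dosage: each marker copies the block latent
    with probability ``ld_rho`` per sample (fresh binomial draw
    otherwise), emulating the strong local linkage disequilibrium of a
    reduced-representation marker panel whose effective dimensionality
    is far below the marker count.
    """
    rng = np.random.default_rng(config.seed)
    q = rng.uniform(config.maf_range[0], config.maf_range[1], size=config.n_markers)
    p_major = 1.0 - q
    if config.ld_blocks is None or config.n_markers == 0:
        dosage = rng.binomial(4, p_major, size=(config.n_genotypes, config.n_markers))
    else:
        n_blocks = min(config.ld_blocks, config.n_markers)
        block_of = np.minimum(
            np.arange(config.n_markers) * n_blocks // config.n_markers, n_blocks - 1
        )
        # one frequency per block, shared by its markers
        p_block = 1.0 - rng.uniform(
            config.maf_range[0], config.maf_range[1], size=n_blocks
        )
        p_major = p_block[block_of]
        latent = rng.binomial(
            4, p_block, size=(config.n_genotypes, n_blocks)
        )
        fresh = rng.binomial(4, p_major, size=(config.n_genotypes, config.n_markers))
        copy = rng.random((config.n_genotypes, config.n_markers)) < config.ld_rho
        dosage = np.where(copy, latent[:, block_of], fresh)
    sample_ids = [f"G{i + 1:03d}" for i in range(config.n_genotypes)]
    marker_ids = [f"M{j + 1:05d}" for j in range(config.n_markers)]
    return TetraploidGenotypeMatrix(dosage, sample_ids, marker_ids, allele_freq=p_major)


def simulate_read_counts(
    genos: TetraploidGenotypeMatrix,
    mean_depth: float = 30.0,
    depth_dispersion: float | None = 2.0,
    seed: int | None = None,
) -> ReadCountMatrix:
    """GBS-style allele read counts given true dosages.

    Total depth per cell is negative binomial with the given mean and
    dispersion (``None`` or ``inf`` collapses to Poisson); major-allele
    reads are binomial(depth, dosage/4).  Zero-depth cells are allowed.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    rng = np.random.default_rng(seed)
    shape = genos.dosage.shape
    if depth_dispersion is None or not np.isfinite(depth_dispersion):
        depth = rng.poisson(mean_depth, size=shape)
    else:
        if depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be > 0")
        p = depth_dispersion / (depth_dispersion + mean_depth)
        depth = rng.negative_binomial(depth_dispersion, p, size=shape)
    major = rng.binomial(depth, genos.dosage / 4.0)
    minor = depth - major
    return ReadCountMatrix(major, minor, list(genos.sample_ids), list(genos.marker_ids))


def simulate_phenotypes(
    genos: TetraploidGenotypeMatrix, config: SimConfig
) -> tuple[pd.DataFrame, SimTruth]:
    """Replicated multi-condition phenotypes with additive genetics.

    Returns a long-format phenotype table (progeny, condition,
    replicate, trait, value) and the generating truth.  QTL effects are
    standard-normal draws on ``n_qtl`` randomly chosen markers (all
    markers when ``n_qtl`` is None); noise variances are set analytically
    from the realized variance of the breeding values so that

        h2_B = s2g / (s2g + s2ge/c + s2e/(c*k))

    equals ``target_h2`` in expectation.
    """
    rng = np.random.default_rng(None if config.seed is None else config.seed + 1)
    n, p = genos.n_samples, genos.n_markers
    n_qtl = p if config.n_qtl is None else config.n_qtl
    if n_qtl > p:
        raise ValueError("n_qtl cannot exceed n_markers")

    beta = np.zeros(p)
    if n_qtl > 0 and p > 0:
        qtl_idx = rng.choice(p, size=n_qtl, replace=False)
        # scale per-QTL effects so sigma2_g stays O(1) as architecture densifies
        beta[qtl_idx] = rng.normal(0.0, 1.0 / np.sqrt(max(n_qtl, 1)), size=n_qtl)
    g = genos.dosage.astype(float) @ beta
    g -= g.mean()
    sigma2_g = float(np.var(g, ddof=1)) if n > 1 else 0.0

    c, k = config.n_conditions, config.n_reps
    sigma2_ge = config.var_ratio_gc_over_g * sigma2_g
    h2 = config.target_h2
    if h2 >= 1.0:
        if sigma2_ge > 0:
            raise ValueError("target_h2 = 1 requires var_ratio_gc_over_g = 0")
        sigma2_e = 0.0
    elif sigma2_g == 0.0:
        sigma2_e, sigma2_ge = 1.0, 0.0  # pure-noise trait (null architecture)
    elif h2 <= 0.0:
        raise ValueError("target_h2 = 0 requires a null architecture (n_qtl = 0)")
    else:
        sigma2_e = c * k * (sigma2_g * (1.0 - h2) / h2 - sigma2_ge / c)
        if sigma2_e < 0:
            raise ValueError(
                "target_h2 unattainable: genotype-by-condition variance alone "
                "already caps h2 below the target"
            )

    mu = (
        np.asarray(config.condition_means, dtype=float)
        if config.condition_means is not None
        else np.zeros(c)
    )
    ge = rng.normal(0.0, np.sqrt(sigma2_ge), size=(n, c)) if sigma2_ge > 0 else np.zeros((n, c))
    e = rng.normal(0.0, np.sqrt(sigma2_e), size=(n, c, k)) if sigma2_e > 0 else np.zeros((n, c, k))
    y = mu[None, :, None] + g[:, None, None] + ge[:, :, None] + e

    records = pd.DataFrame(
        {
            "progeny": np.repeat(genos.sample_ids, c * k),
            "condition": np.tile(np.repeat([f"C{j + 1}" for j in range(c)], k), n),
            "replicate": np.tile([f"R{r + 1}" for r in range(k)], n * c),
            "trait": "trait",
            "value": y.ravel(),
        }
    )
    truth = SimTruth(beta, g, sigma2_g, sigma2_ge, sigma2_e)
    return records, truth


def simulate_dataset(config: SimConfig):
    """Convenience: population, read counts and phenotypes in one call."""
    genos = simulate_population(config)
    rc_seed = None if config.seed is None else config.seed + 2
    rc = simulate_read_counts(genos, config.mean_depth, config.depth_dispersion, seed=rc_seed)
    phenos, truth = simulate_phenotypes(genos, config)
    return genos, rc, phenos, truth
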