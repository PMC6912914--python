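"""Synthetic-data generators with known ground truth.

Every input the analysis chain needs can be generated here: fractal
elevation surfaces, population sites, pairwise genetic-differentiation
matrices built from a known monotone function of a landscape distance
(the generative twin of the MLPE regression), neutral-coalescent
haplotype alignments, and multi-locus diploid microsatellite genotypes.

All generators are deterministic for a fixed integer seed; sub-streams
are derived from the config seed with ``numpy.random.default_rng``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import PairwiseMatrix, Raster, SiteSet
from .landscape import TransformSpec
from .seqstats import SequenceAlignment
from .msat import GenotypeTable

__all__ = [
    "LandscapeSimConfig",
    "GeneticSimConfig",
    "CoalescentSimConfig",
    "MsatSimConfig",
    "gen_elevation",
    "gen_sites",
    "simulate_differentiation",
    "simulate_haplotypes",
    "simulate_genotypes",
]


# ---------------------------------------------------------------------------
# elevation

@dataclass
class LandscapeSimConfig:
    """Fractal elevation surface via spectral synthesis.

    ``roughness_exponent`` is the power-spectrum slope beta: the surface
    is filtered Gaussian noise with P(f) ~ f^-beta.  beta around 3 gives
    terrain-like surfaces.  Values are rescaled to [0, elevation_range].
    """

    nrows: int = 64
    ncols: int = 64
    cellsize: float = 5000.0          # metres; the study grid was 5 km
    roughness_exponent: float = 3.0
    elevation_range: float = 3000.0   # metres, sea level to high ranges
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nrows < 8 or self.ncols < 8:
            raise ValueError("nrows and ncols must be >= 8")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")
        if self.elevation_range < 0:
            raise ValueError("elevation_range must be >= 0")


def gen_elevation(cfg: LandscapeSimConfig) -> Raster:
    """Generate a seeded fractal elevation raster (no nodata cells)."""
    rng = np.random.default_rng(cfg.seed)
    nr, nc = cfg.nrows, cfg.ncols
    white = rng.standard_normal((nr, nc))
    spec = np.fft.fft2(white)
    fr = np.fft.fftfreq(nr)[:, None]
    fc = np.fft.fftfreq(nc)[None, :]
    f = np.sqrt(fr ** 2 + fc ** 2)
    amp = np.zeros_like(f)
    nz = f > 0
    amp[nz] = f[nz] ** (-cfg.roughness_exponent / 2.0)
    surf = np.real(np.fft.ifft2(spec * amp))
    lo, hi = surf.min(), surf.max()
    if hi > lo and cfg.elevation_range > 0:
        surf = (surf - lo) / (hi - lo) * cfg.elevation_range
    else:
        surf = np.zeros_like(surf)
    return Raster(values=surf, cellsize=cfg.cellsize,
                  origin=(0.0, nr * cfg.cellsize),
                  nodata_mask=np.zeros((nr, nc), dtype=bool),
                  crs_note="synthetic projected grid")


# ---------------------------------------------------------------------------
# sites

def gen_sites(raster: Raster, n_sites: int, min_separation: float = 1.0,
              seed: int = 0, max_retries: int = 10_000) -> SiteSet:
    """Place sites uniformly on valid cells with a minimum separation.

    Separation is Euclidean distance in cell units.  Placement rejects
    nodata and duplicate cells and errors out after ``max_retries``
    rejections (infeasible packing).
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    valid = np.argwhere(~raster.nodata_mask)
    if len(valid) < n_sites:
        raise ValueError("not enough valid cells")
    chosen: list[np.ndarray] = []
    tries = 0
    while len(chosen) < n_sites:
        cand = valid[rng.integers(len(valid))]
        if all(np.hypot(*(cand - c)) >= min_separation for c in chosen) and \
                not any((cand == c).all() for c in chosen):
            chosen.append(cand)
        else:
            tries += 1
            if tries > max_retries:
                raise ValueError(
                    f"could not place {n_sites} sites with separation "
                    f"{min_separation} after {max_retries} retries"
                )
    rc = np.array(chosen, dtype=int)
    sites = SiteSet(site_ids=[f"P{i + 1}" for i in range(n_sites)], rowcol=rc)
    sites.snap_to(raster)
    return sites


# ---------------------------------------------------------------------------
# differentiation matrices (MLPE generative model)

@dataclass
class GeneticSimConfig:
    """Generative twin of the MLPE model.

    y_ij = intercept + slope * z(d_ij) + u_i + u_j + eps_ij, with z the
    centered/scaled distance, u ~ N(0, sigma_pop^2) per site and
    eps ~ N(0, sigma_resid^2) per pair.  ``clamp01`` truncates into
    [0, 1] after noise (differentiation is bounded but the linear model
    is not); off by default so recovery tests are exact.
    """

    true_transform: TransformSpec = field(default_factory=TransformSpec)
    distance_model: str = "least_cost"
    intercept: float = 0.3
    slope: float = 0.8
    sigma_pop: float = 0.1
    sigma_resid: float = 0.05
    clamp01: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.distance_model not in {"least_cost", "commute", "geographic"}:
            raise ValueError(f"unknown distance model {self.distance_model!r}")
        if self.sigma_pop < 0 or self.sigma_resid < 0:
            raise ValueError("noise SDs must be >= 0")


def simulate_differentiation(dist: PairwiseMatrix, cfg: GeneticSimConfig) -> PairwiseMatrix:
    """Draw a differentiation matrix from the MLPE generative model."""
    rng = np.random.default_rng(cfg.seed)
    iu, ju, d = dist.condensed()
    sd = d.std(ddof=0)
    z = (d - d.mean()) / sd if sd > 0 else np.zeros_like(d)
    u = rng.normal(0.0, cfg.sigma_pop, size=dist.n)
    eps = rng.normal(0.0, cfg.sigma_resid, size=len(d))
    y = cfg.intercept + cfg.slope * z + u[iu] + u[ju] + eps
    if cfg.clamp01:
        y = np.clip(y, 0.0, 1.0)
    vals = np.zeros_like(dist.values)
    vals[iu, ju] = y
    vals[ju, iu] = y
    return PairwiseMatrix(labels=list(dist.labels), values=vals,
                          metric_name="simulated_differentiation",
                          meta={"config": cfg})


# ---------------------------------------------------------------------------
# coalescent haplotypes

@dataclass
class CoalescentSimConfig:
    """Neutral Kingman coalescent with infinite-sites mutations.

    theta is the population mutation rate per locus (4*N*mu*L); the
    expected number of segregating sites is theta * sum_{i<n} 1/i.
    """

    n_samples: int = 20
    theta: float = 5.0
    seq_len: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.seq_len < 1:
            raise ValueError("seq_len must be >= 1")


_BASES = np.array(list("ACGT"))


def simulate_haplotypes(cfg: CoalescentSimConfig) -> SequenceAlignment:
    """Simulate one locus under the neutral coalescent.

    Kingman tree (exponential waiting times with rate C(k,2) in units of
    2N generations... coalescent time units), Poisson(theta/2 x branch
    length) mutations dropped on branches, each hitting a fresh site.
    Raises if the mutation count exceeds seq_len (theta too large for
    the infinite-sites mapping).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    # track, per active lineage, the set of leaves below and its start time
    branches: list[tuple[list[int], float]] = []  # (leaf set, branch length)
    leafsets: list[list[int]] = [[i] for i in range(n)]
    starts: list[float] = [0.0] * n
    t = 0.0
    while len(leafsets) > 1:
        k = len(leafsets)
        t += rng.exponential(2.0 / (k * (k - 1)))
        a, b = rng.choice(k, size=2, replace=False)
        a, b = (int(a), int(b)) if a < b else (int(b), int(a))
        branches.append((leafsets[a], t - starts[a]))
        branches.append((leafsets[b], t - starts[b]))
        merged = leafsets[a] + leafsets[b]
        leafsets = [s for i, s in enumerate(leafsets) if i not in (a, b)] + [merged]
        starts = [s for i, s in enumerate(starts) if i not in (a, b)] + [t]
    lengths = np.array([bl for _, bl in branches])
    total = lengths.sum()
    n_mut = rng.poisson(cfg.theta / 2.0 * total) if cfg.theta > 0 else 0
    if n_mut > cfg.seq_len:
        raise ValueError(
            f"{n_mut} mutations exceed seq_len={cfg.seq_len}; theta too large "
            "for infinite-sites placement"
        )
    seqs = np.zeros((n, cfg.seq_len), dtype=int)  # 0 = ancestral 'A'
    if n_mut > 0:
        which = rng.choice(len(branches), size=n_mut, p=lengths / total)
        sites = rng.choice(cfg.seq_len, size=n_mut, replace=False)
        for b_idx, site in zip(which, sites):
            derived = rng.integers(1, 4)  # any non-ancestral base
            for leaf in branches[b_idx][0]:
                seqs[leaf, site] = derived
    seq_strs = ["".join(_BASES[row]) for row in seqs]
    return SequenceAlignment(ids=[f"s{i + 1}" for i in range(n)], seqs=seq_strs)


# ---------------------------------------------------------------------------
# microsatellite genotypes

@dataclass
class MsatSimConfig:
    """Diploid microsatellite genotypes for discrete populations.

    Either give explicit per-pop per-locus allele frequencies, or an
    ``fst_target`` in (0, 1): per-locus population frequencies are then
    drawn around common ancestral frequencies with a Balding-Nichols
    (island-model drift) Dirichlet, whose concentration (1-F)/F sets the
    expected differentiation.  Genotypes are two independent allele
    draws (HWE within populations); calls go missing independently at
    ``missing_rate``.
    """

    n_pops: int = 4
    n_per_pop: int = 20
    n_loci: int = 11                      # the study's panel size
    n_alleles: int = 6
    allele_freqs: list | None = None      # [pop][locus] -> frequency vector
    fst_target: float | None = 0.1
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pops < 1 or self.n_per_pop < 1 or self.n_loci < 1:
            raise ValueError("population, sample and locus counts must be >= 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.allele_freqs is None and self.fst_target is None:
            raise ValueError("need allele_freqs or fst_target")
        if self.allele_freqs is not None:
            for pop_freqs in self.allele_freqs:
                for f in pop_freqs:
                    if abs(float(np.sum(f)) - 1.0) > 1e-9:
                        raise ValueError("allele frequencies must sum to 1")
        if self.fst_target is not None and not 0 < self.fst_target < 1:
            raise ValueError("fst_target must be in (0, 1)")


def simulate_genotypes(cfg: MsatSimConfig) -> GenotypeTable:
    """Draw a genotype table under within-population HWE."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.allele_freqs is not None:
        freqs = [[np.asarray(f, dtype=float) for f in pop] for pop in cfg.allele_freqs]
        n_pops = len(freqs)
        n_loci = len(freqs[0])
    else:
        n_pops, n_loci = cfg.n_pops, cfg.n_loci
        conc = (1 - cfg.fst_target) / cfg.fst_target
        freqs = []
        ancestral = [rng.dirichlet(np.full(cfg.n_alleles, 1.5)) for _ in range(n_loci)]
        for _ in range(n_pops):
            freqs.append([rng.dirichlet(np.maximum(a * conc, 1e-6))
                          for a in ancestral])
    n_ind = cfg.n_per_pop * n_pops
    calls = np.zeros((n_ind, n_loci, 2), dtype=int)
    individuals, pop_labels = [], []
    row = 0
    for p in range(n_pops):
        for i in range(cfg.n_per_pop):
            individuals.append(f"P{p + 1}_{i + 1}")
            pop_labels.append(f"P{p + 1}")
            for l in range(n_loci):
                f = freqs[p][l]
                # allele codes start at 1; 0 is the missing sentinel
                calls[row, l, :] = rng.choice(len(f), size=2, p=f) + 1
            row += 1
    if cfg.missing_rate > 0:
        miss = rng.random((n_ind, n_loci)) < cfg.missing_rate
        calls[miss] = 0
    return GenotypeTable(individuals=individuals, pop_labels=pop_labels,
                         loci=[f"L{l + 1}" for l in range(n_loci)], calls=calls)
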