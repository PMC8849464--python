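"""Synthetic landscapes, site layouts and genotype matrices with known
isolation-by-resistance structure and known outlier loci.

The generator emulates the sampling design of a triatomine landscape-genomics
survey: ~25 collection sites on a projected grid, a subset of sites carrying
both domestic and wild ecotope groups, ~10 diploid samples per group, and a
few thousand biallelic SNPs. Site allele frequencies follow a Gaussian-copula
Beta model: each locus draws an ancestral frequency p0 ~ Beta(2, 2); a latent
multivariate-normal site vector with correlation exp(-d_eff / lambda) is
mapped through the standard-normal CDF into quantiles of the Balding-Nichols
marginal Beta(p0 (1-F)/F, (1-p0)(1-F)/F), giving F-model marginals (expected
multilocus F_ST ~ F) with spatial correlation that decays with effective
(resistance) distance. Outlier loci add a logit-scale shift to every domestic
group. Genotypes are Binomial(2, p) per individual; missingness is completely
at random.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from scipy.stats import norm

from .datatypes import (
    MISSING,
    AnalysisError,
    ConfigurationError,
    DistanceMatrix,
    GenotypeMatrix,
    RasterSurface,
)
from .resistance import (
    TransformParams,
    build_conductance_graph,
    commute_distance,
    monomolecular,
    rescale_surface,
)
from .rng import substream

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "PlacementError",
    "SimulationError",
    "generate_elevation_field",
    "place_sites",
    "simulate_genotypes",
    "simulate_dataset",
]


class PlacementError(AnalysisError):
    pass


class SimulationError(AnalysisError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic generator.

    Defaults emulate the survey design this package targets: 25 sites, 7 of
    them with both domestic and wild groups, 10 diploids per group, 2,500
    biallelic SNPs on a 250 m grid, baseline differentiation F = 0.1, and a
    handful of domestically-shifted outlier loci (delta on the logit scale is
    a free knob, not an estimate). covariance_scale None means "median
    effective distance between sites", a scale at which spatial correlation
    is informative for any commute-time magnitude.
    """

    n_sites: int = 25
    n_dual_sites: int = 7
    samples_per_site: int = 10
    n_loci: int = 2500
    n_outlier_loci: int = 5
    grid_shape: tuple[int, int] = (60, 60)
    cell_size: float = 250.0
    gaussian_field_range: float = 3000.0
    true_transform: TransformParams = field(
        default_factory=lambda: TransformParams(variant=0, shape=0.5, maximum=50.0)
    )
    covariance_scale: float | None = None
    baseline_fst: float = 0.1
    ecotope_shift: float = 2.0
    missing_rate: float = 0.005
    min_separation: float = 1000.0
    years: tuple[int, ...] = (2016, 2017)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_outlier_loci < self.n_loci:
            raise ConfigurationError("need n_outlier_loci < n_loci")
        if not 0.0 < self.baseline_fst < 1.0:
            raise ConfigurationError("baseline F_ST must lie in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        if self.grid_shape[0] * self.grid_shape[1] < self.n_sites:
            raise ConfigurationError("grid too small for the requested sites")
        if self.n_dual_sites > self.n_sites:
            raise ConfigurationError("n_dual_sites cannot exceed n_sites")


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside a synthetic genotype matrix."""

    true_resistance: RasterSurface | None
    true_effective_distances: DistanceMatrix
    outlier_locus_ids: list[str]
    p0: np.ndarray
    group_freqs: pd.DataFrame  # groups x loci realised allele frequencies
    covariance_scale: float


def generate_elevation_field(
    grid_shape: tuple[int, int],
    cell_size: float,
    range_m: float,
    seed: int = 0,
) -> RasterSurface:
    """Gaussian random field with exponential covariance exp(-h/range).

    Simulated by circulant embedding on a doubled torus (negative embedding
    eigenvalues, which the exponential kernel can produce on small grids, are
    clipped to zero). The unit-variance field z is mapped to elevation as
    1500 + 500 z, clipped to [0, 3000] m a.s.l., so a long-range (flat)
    field stays flat instead of being stretched to the full range.
    Deterministic given the seed.
    """
    nrows, ncols = int(grid_shape[0]), int(grid_shape[1])
    if nrows < 1 or ncols < 1 or cell_size <= 0:
        raise ConfigurationError("grid dimensions and cell size must be positive")
    if range_m <= 0:
        raise ConfigurationError("correlation range must be positive")
    rng = substream(seed, "elevation_field")
    er, ec = 2 * nrows, 2 * ncols
    ii = np.minimum(np.arange(er), er - np.arange(er))
    jj = np.minimum(np.arange(ec), ec - np.arange(ec))
    h = np.hypot.outer(ii, jj) * cell_size
    cov = np.exp(-h / range_m)
    lam = np.clip(np.fft.fft2(cov).real, 0.0, None)
    # real white noise keeps Hermitian symmetry, so the filtered field is real
    # with covariance equal to the (clipped) circulant embedding of cov
    w = rng.normal(size=(er, ec))
    z = np.fft.ifft2(np.sqrt(lam) * np.fft.fft2(w)).real[:nrows, :ncols]
    elev = 1500.0 + 500.0 * z
    return RasterSurface(np.clip(elev, 0.0, 3000.0), cell_size=cell_size, kind="continuous")


def place_sites(
    raster: RasterSurface,
    n_sites: int,
    min_separation: float,
    seed: int = 0,
    n_dual: int = 0,
    max_restarts: int = 50,
) -> pd.DataFrame:
    """Random site layout on valid cell centres with pairwise separation
    >= min_separation; `n_dual` sites carry both ecotopes, the rest alternate
    between domestic-only and wild-only. Raises PlacementError when the
    separation constraint cannot be met within bounded retries."""
    if n_sites < 2:
        raise ConfigurationError("need at least 2 sites")
    valid_cells = np.argwhere(raster.valid())
    if len(valid_cells) < n_sites:
        raise PlacementError("not enough valid cells for the requested sites")
    rng = substream(seed, "place_sites")
    for _ in range(max_restarts):
        order = rng.permutation(len(valid_cells))
        chosen: list[np.ndarray] = []
        coords: list[tuple[float, float]] = []
        for idx in order:
            r, c = valid_cells[idx]
            x, y = raster.cell_center(int(r), int(c))
            if all((x - x2) ** 2 + (y - y2) ** 2 >= min_separation**2 for x2, y2 in coords):
                chosen.append(valid_cells[idx])
                coords.append((x, y))
                if len(chosen) == n_sites:
                    break
        if len(chosen) == n_sites:
            break
    else:
        raise PlacementError(
            f"could not place {n_sites} sites at separation {min_separation}"
        )
    dual = rng.choice(n_sites, size=n_dual, replace=False) if n_dual else np.array([], int)
    rows = []
    single_toggle = 0
    for i, ((r, c), (x, y)) in enumerate(zip(chosen, coords)):
        if i in dual:
            eco = "both"
        else:
            eco = "domestic" if single_toggle % 2 == 0 else "wild"
            single_toggle += 1
        rows.append(
            {
                "site_id": f"S{i + 1:02d}",
                "row": int(r),
                "col": int(c),
                "x": x,
                "y": y,
                "ecotope": eco,
            }
        )
    return pd.DataFrame(rows)


def _site_groups(sites: pd.DataFrame) -> list[tuple[str, str]]:
    """(site_id, ecotope) groups; dual sites contribute both ecotopes."""
    groups = []
    for _, row in sites.iterrows():
        if row["ecotope"] == "both":
            groups.append((row["site_id"], "domestic"))
            groups.append((row["site_id"], "wild"))
        else:
            groups.append((row["site_id"], row["ecotope"]))
    return groups


def simulate_genotypes(
    effective_dm: DistanceMatrix,
    config: SimulationConfig,
    sites: pd.DataFrame,
    true_resistance: RasterSurface | None = None,
) -> tuple[GenotypeMatrix, SimulationTruth]:
    """Draw a genotype matrix from the Gaussian-copula Beta model.

    `effective_dm` must be a symmetric zero-diagonal matrix labelled by the
    site ids in `sites`. See the module docstring for the model; positive
    definiteness of the site correlation matrix is enforced by a 1e-8 diagonal
    jitter (failure after jitter raises SimulationError).
    """
    eff = effective_dm.submatrix([str(s) for s in sites["site_id"]])
    lam = config.covariance_scale
    if lam is None:
        off = eff.condensed()
        lam = float(np.median(off)) if len(off) and np.median(off) > 0 else 1.0
    corr = np.exp(-eff.values / lam)
    corr[np.diag_indices_from(corr)] = 1.0 + 1e-8
    try:
        L = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise SimulationError("site correlation matrix not positive definite") from exc

    rng = substream(config.seed, "genotypes")
    n_sites = eff.n
    n_loci = config.n_loci
    F = config.baseline_fst
    p0 = rng.beta(2.0, 2.0, size=n_loci)
    Z = rng.normal(size=(n_loci, n_sites)) @ L.T
    a = p0 * (1.0 - F) / F
    b = (1.0 - p0) * (1.0 - F) / F
    u = norm.cdf(Z)
    # guard quantiles away from 0/1 so ppf stays finite
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    p_site = beta_dist.ppf(u, a[:, None], b[:, None])
    p_site = np.clip(p_site, 1e-9, 1.0 - 1e-9)

    outlier_idx = np.sort(rng.choice(n_loci, size=config.n_outlier_loci, replace=False))
    locus_ids = [f"L{j + 1:05d}" for j in range(n_loci)]
    outlier_ids = [locus_ids[j] for j in outlier_idx]

    groups = _site_groups(sites)
    site_index = {s: i for i, s in enumerate(eff.labels)}
    group_freqs = np.empty((len(groups), n_loci))
    for gi, (site, eco) in enumerate(groups):
        p = p_site[:, site_index[site]].copy()
        if eco == "domestic" and len(outlier_idx):
            logit = np.log(p[outlier_idx] / (1.0 - p[outlier_idx]))
            p[outlier_idx] = 1.0 / (1.0 + np.exp(-(logit + config.ecotope_shift)))
        group_freqs[gi] = p

    n_per = config.samples_per_site
    sample_ids, meta_rows, blocks = [], [], []
    for gi, (site, eco) in enumerate(groups):
        g = rng.binomial(2, group_freqs[gi][None, :].repeat(n_per, axis=0))
        blocks.append(g)
        srow = sites.loc[sites["site_id"] == site].iloc[0]
        for s in range(n_per):
            sid = f"{site}_{eco[0]}_{s + 1:02d}"
            sample_ids.append(sid)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "site_id": site,
                    "ecotope": eco,
                    "year": int(rng.choice(config.years)),
                    "x": float(srow["x"]),
                    "y": float(srow["y"]),
                }
            )
    genotypes = np.concatenate(blocks, axis=0).astype(np.int8)
    if config.missing_rate > 0:
        drop = rng.random(genotypes.shape) < config.missing_rate
        genotypes[drop] = MISSING
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    gm = GenotypeMatrix(genotypes, sample_ids, locus_ids, meta)
    truth = SimulationTruth(
        true_resistance=true_resistance,
        true_effective_distances=eff,
        outlier_locus_ids=outlier_ids,
        p0=p0,
        group_freqs=pd.DataFrame(
            group_freqs, index=[f"{s}:{e}" for s, e in groups], columns=locus_ids
        ),
        covariance_scale=float(lam),
    )
    return gm, truth


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, SimulationTruth, pd.DataFrame, RasterSurface]:
    """End-to-end synthetic dataset: elevation field -> true resistance ->
    commute-time effective distances -> sites -> genotypes.

    Returns (genotypes, truth, site table, elevation raster).
    """
    elev = generate_elevation_field(
        config.grid_shape, config.cell_size, config.gaussian_field_range, config.seed
    )
    resistance = monomolecular(rescale_surface(elev), config.true_transform)
    sites = place_sites(
        resistance,
        config.n_sites,
        config.min_separation,
        seed=config.seed,
        n_dual=config.n_dual_sites,
    )
    focal_cells = [(int(r), int(c)) for r, c in sites[["row", "col"]].to_numpy()]
    graph = build_conductance_graph(resistance, 8, focal_cells)
    eff = commute_distance(graph, sites, resistance)
    gm, truth = simulate_genotypes(eff, config, sites, true_resistance=resistance)
    return gm, truth, sites, elev
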