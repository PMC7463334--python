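"""Synthetic seascapes with known planted structure.

Every downstream stage is exercised against data whose truth is known by
construction: daily currents with a dominant direction plus smooth noise;
daily SST with a seasonal cycle, a latitudinal gradient and localized
heatwave events; reef cells of varying area; neutral loci whose expected
pairwise F_ST grows linearly with least-cost sea distance (isolation by
sea distance); and adaptive loci whose genotype presence follows a
logistic function of an environmental variable.

Neutral structure is a correlated Balding-Nichols-style scheme: per locus,
an ancestral frequency p is drawn and site frequencies are
p_i = p + sqrt(2 F p (1-p)) z_i with z a zero-mean Gaussian vector whose
variogram tracks the sea distances, E[(z_i - z_j)^2] ~= d_ij / d_max, and
F = beta_sim * d_max.  The expected pairwise Weir-Cockerham theta is then
approximately F * d_ij / d_max = beta_sim * d_ij.  Least-cost graph
distances are generally not conditionally negative definite, so no
Gaussian field can realise that variogram exactly; the generator builds
the classical-MDS (Gower-centered, eigenvalue-clipped) embedding and then
rescales the covariance so that the REGRESSION SLOPE of the planted
expected theta on distance equals beta_sim exactly — the linear trend is
the planted quantity, pairwise deviations are structured residuals.  The
realized-vs-target relation is a tested property, not an assumption.

All randomness derives from one root seed through named substreams
(currents / sst / genotypes / aux), so stages can be regenerated
independently and identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from reefscape.genotypes import GenotypeMatrix
from reefscape.grids import GridSpec, RasterSeries, ReefGrid

_STREAMS = {"currents": 1, "sst": 2, "genotypes": 3, "aux": 4}


def substream(seed: int, name: str) -> np.random.Generator:
    """Named child RNG of the root seed."""
    return np.random.default_rng([int(seed), _STREAMS[name]])


@dataclass(frozen=True)
class HeatwaveEvent:
    """Localized SST boost: +intensity degC within radius cells of the
    center, from start_day for duration_days.  Overlapping events sum."""

    row: int
    col: int
    radius_cells: float
    start_day: int
    duration_days: int
    intensity: float


@dataclass
class SeascapeConfig:
    rows: int = 30
    cols: int = 30
    cell_size_km: float = 5.0
    origin_lon: float = 127.0
    origin_lat: float = 28.0
    land_blocks: tuple = ((12, 18, 13, 17),)  # (r0, r1, c0, c1), half-open
    n_days: int = 1825  # five years: anomalies stay rare relative to the climatology
    start_date: str = "2001-01-01"
    seed: int = 0
    # currents
    current_direction: tuple[float, float] = (1.0, 0.35)  # (east, north), normalised
    current_mean_speed: float = 0.15  # m/s
    current_noise_sd: float = 0.15  # mesoscale variability comparable to the mean
    current_noise_smooth: float = 2.0  # gaussian sigma, pixels
    # SST
    sst_baseline: float = 26.0
    sst_seasonal_amplitude: float = 3.0
    sst_gradient_per_cell: float = -0.02  # degC per row southward (row 0 north)
    heatwaves: tuple[HeatwaveEvent, ...] = ()
    # sites: (row, col, n_colonies)
    sites: tuple = ()
    # loci
    n_neutral_loci: int = 2000
    n_adaptive_loci: int = 3
    adaptive_intercept: float = -4.0
    adaptive_slope: float = 8.0
    beta_sim: float | None = None  # target FST per unit sea distance
    target_max_fst: float = 0.08  # sets beta_sim from the distance range when beta_sim is None

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        for (_, _, n) in self.sites:
            if n < 1:
                raise ValueError("each site needs at least one colony")
        if np.hypot(*self.current_direction) == 0:
            raise ValueError("current direction must be a nonzero vector")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.origin_lon, self.origin_lat, self.cell_size_km,
                        self.rows, self.cols)

    def sea_mask(self) -> np.ndarray:
        mask = np.ones((self.rows, self.cols), bool)
        for (r0, r1, c0, c1) in self.land_blocks:
            mask[r0:r1, c0:c1] = False
        return mask

    def times(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_date, periods=self.n_days, freq="D")

    def site_table(self) -> pd.DataFrame:
        sites = self.sites if self.sites else default_sites(self)
        grid = self.grid
        rows = []
        for i, (r, c, n) in enumerate(sites):
            if not self.sea_mask()[r, c]:
                raise ValueError(f"site pixel ({r}, {c}) is on land")
            lat, lon = grid.lats()[r], grid.lons()[c]
            rows.append((f"S{i + 1:02d}", int(r), int(c), lon, lat, int(n)))
        return pd.DataFrame(rows, columns=["site", "row", "col", "lon", "lat", "n_colonies"])


def default_sites(config: SeascapeConfig, n_sites: int = 12, n_colonies: int = 15) -> tuple:
    """Spread sites over sea pixels on a jittered regular lattice."""
    rng = np.random.default_rng([config.seed, 9])
    mask = config.sea_mask()
    sea = np.argwhere(mask)
    k = int(np.ceil(np.sqrt(n_sites)))
    rr = np.linspace(2, config.rows - 3, k)
    cc = np.linspace(2, config.cols - 3, k)
    anchors = [(r, c) for r in rr for c in cc]
    rng.shuffle(anchors)
    chosen, used = [], set()
    for (r, c) in anchors:
        d = np.abs(sea[:, 0] - r) + np.abs(sea[:, 1] - c)
        j = int(np.argmin(d))
        pix = tuple(sea[j])
        if pix not in used:
            used.add(pix)
            chosen.append((int(pix[0]), int(pix[1]), n_colonies))
        if len(chosen) == n_sites:
            break
    return tuple(chosen)


# ------------------------------------------------------------- currents
def generate_currents(config: SeascapeConfig) -> tuple[RasterSeries, RasterSeries]:
    """Daily (u, v) current fields, m/s: dominant vector plus spatially
    smooth zero-mean noise; land pixels masked."""
    grid = config.grid
    mask = config.sea_mask()
    rng = substream(config.seed, "currents")
    ex, ey = config.current_direction
    norm = np.hypot(ex, ey)
    u0 = config.current_mean_speed * ex / norm
    v0 = config.current_mean_speed * ey / norm
    shape = (config.n_days, config.rows, config.cols)
    u = np.full(shape, u0)
    v = np.full(shape, v0)
    if config.current_noise_sd > 0:
        # smoothed white noise has theoretical per-pixel sd (sum w^2) for a
        # separable Gaussian kernel of weights w; rescale to the target sd
        sigma = config.current_noise_smooth
        radius = int(4.0 * sigma + 0.5)
        w = np.exp(-0.5 * (np.arange(-radius, radius + 1) / sigma) ** 2)
        w /= w.sum()
        scale = config.current_noise_sd / (w**2).sum()
        for comp in (u, v):
            noise = rng.standard_normal(shape)
            for t in range(config.n_days):
                comp[t] += scale * gaussian_filter(noise[t], sigma)
    times = config.times()
    return (
        RasterSeries(grid, times, u, mask, name="u", units="m/s"),
        RasterSeries(grid, times, v, mask, name="v", units="m/s"),
    )


# ------------------------------------------------------------------ SST
def generate_sst(config: SeascapeConfig) -> RasterSeries:
    """Daily SST: baseline + seasonal sinusoid + latitudinal gradient +
    heatwave boosts (overlapping events sum)."""
    grid = config.grid
    mask = config.sea_mask()
    times = config.times()
    doy = times.dayofyear.to_numpy()
    seasonal = config.sst_baseline + config.sst_seasonal_amplitude * np.cos(
        2 * np.pi * (doy - 212) / 365.25  # peak around end of July
    )
    rowgrad = config.sst_gradient_per_cell * np.arange(config.rows)
    values = seasonal[:, None, None] + rowgrad[None, :, None] + np.zeros(
        (1, 1, config.cols)
    )
    rr, cc = np.mgrid[0:config.rows, 0:config.cols]
    for ev in config.heatwaves:
        foot = np.hypot(rr - ev.row, cc - ev.col) <= ev.radius_cells
        t0, t1 = ev.start_day, min(ev.start_day + ev.duration_days, config.n_days)
        values[t0:t1, foot] += ev.intensity
    return RasterSeries(grid, times, values, mask, name="SST", units="degC")


def generate_auxiliary(config: SeascapeConfig) -> dict[str, RasterSeries]:
    """Companion environmental series for the full descriptor scheme:
    daily salinity and chlorophyll, monthly suspended particulate matter
    and photosynthetically available radiation.  Weak seasonal cycles plus
    noise; not used for planted signal."""
    grid = config.grid
    mask = config.sea_mask()
    rng = substream(config.seed, "aux")
    times = config.times()
    doy = times.dayofyear.to_numpy()
    out: dict[str, RasterSeries] = {}
    for name, base, amp, sd, units in (
        ("SSS", 34.5, 0.4, 0.1, "psu"),
        ("CHL", 0.25, 0.08, 0.03, "mg/m3"),
    ):
        vals = (
            base
            + amp * np.cos(2 * np.pi * (doy - 30) / 365.25)[:, None, None]
            + sd * rng.standard_normal((config.n_days, config.rows, config.cols))
        )
        out[name] = RasterSeries(grid, times, vals, mask, name=name, units=units)
    m_times = pd.date_range(config.start_date, periods=max(config.n_days // 30, 2), freq="MS")
    month = m_times.month.to_numpy()
    for name, base, amp, sd, units in (
        ("SPM", 2.0, 0.5, 0.2, "g/m3"),
        ("PAR", 40.0, 12.0, 2.0, "E/m2/day"),
    ):
        vals = (
            base
            + amp * np.cos(2 * np.pi * (month - 7) / 12)[:, None, None]
            + sd * rng.standard_normal((len(m_times), config.rows, config.cols))
        )
        out[name] = RasterSeries(grid, m_times, vals, mask, name=name, units=units)
    return out


# ------------------------------------------------------------ genotypes
def variogram_covariance(gamma: np.ndarray) -> tuple[np.ndarray, float]:
    """Covariance of a Gaussian vector approximating a target variogram.

    ``gamma``: symmetric matrix of target squared increments,
    E[(z_i - z_j)^2] = gamma_ij.  Returns the classical-MDS (Gower-
    centered, eigenvalue-clipped) covariance C, rescaled so the OLS
    regression slope of the realised variogram on the target is exactly 1,
    together with the raw (pre-rescale) slope for diagnostics.  When gamma
    is conditionally negative definite the embedding is exact.
    """
    n = len(gamma)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -J @ gamma @ J / 2
    w, v = np.linalg.eigh((B + B.T) / 2)
    C = (v * np.maximum(w, 0)) @ v.T
    diag = np.diag(C)
    realised = diag[:, None] + diag[None, :] - 2 * C
    iu = np.triu_indices(n, 1)
    x, y = gamma[iu], realised[iu]
    denom = ((x - x.mean()) ** 2).sum()
    slope = float(((x - x.mean()) * (y - y.mean())).sum() / denom) if denom > 0 else 1.0
    if slope <= 0:
        slope = 1.0
    return C / slope, slope


def generate_genotypes(
    config: SeascapeConfig,
    sea_distance_matrix: np.ndarray,
    env_at_sites: np.ndarray,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Genotypes with planted neutral isolation-by-sea-distance and
    adaptive genotype-environment signal.

    ``sea_distance_matrix``: square site-by-site matrix (asymmetric input
    is collapsed by the per-pair minimum).  ``env_at_sites``: the
    environmental variable driving the adaptive loci, one value per site.
    Returns the genotype matrix and a truth ledger (one row per locus:
    type, planted parameters).
    """
    if rng is None:
        rng = substream(config.seed, "genotypes")
    site_tab = config.site_table()
    n_sites = len(site_tab)
    D = np.asarray(sea_distance_matrix, float)
    if D.shape != (n_sites, n_sites):
        raise ValueError("sea distance matrix must be n_sites x n_sites")
    D = np.minimum(D, D.T)
    env = np.asarray(env_at_sites, float)
    if env.shape != (n_sites,):
        raise ValueError("env_at_sites must have one value per site")

    d_max = D.max()
    beta = config.beta_sim
    if beta is None:
        beta = config.target_max_fst / d_max if d_max > 0 else 0.0
    if d_max > 0 and beta * d_max > 1:
        raise ValueError("beta_sim * max distance exceeds 1: unattainable FST")
    F = beta * d_max

    if d_max > 0:
        C, _ = variogram_covariance(D / d_max)
        w, v = np.linalg.eigh(C + 1e-12 * np.eye(n_sites))
        L = v * np.sqrt(np.maximum(w, 0))
    else:
        L = np.zeros((n_sites, n_sites))

    n_col = site_tab["n_colonies"].to_numpy()
    n_ind = int(n_col.sum())
    site_of_ind = np.repeat(np.arange(n_sites), n_col)

    Ln, La = config.n_neutral_loci, config.n_adaptive_loci
    codes = np.empty((n_ind, Ln + La), dtype=np.int8)

    # neutral: correlated Balding-Nichols-style site frequencies;
    # E[(p_i - p_j)^2] = 2 F p q * gamma_ij with gamma ~ d/d_max, hence
    # expected pairwise WC theta ~ beta_sim * d_ij (trend-exact)
    p_anc = rng.uniform(0.1, 0.9, size=Ln)
    z = (L @ rng.standard_normal((n_sites, Ln)))
    p_site = p_anc[None, :] + np.sqrt(2 * F * p_anc * (1 - p_anc))[None, :] * z
    p_site = np.clip(p_site, 0.001, 0.999)
    codes[:, :Ln] = rng.binomial(2, p_site[site_of_ind, :]).astype(np.int8)

    # adaptive: focal genotype (hom-alt) presence ~ Bernoulli(logistic(a + b env))
    a, b = config.adaptive_intercept, config.adaptive_slope
    p_carry = 1.0 / (1.0 + np.exp(-(a + b * env)))
    for j in range(La):
        carrier = rng.random(n_ind) < p_carry[site_of_ind]
        other = rng.integers(0, 2, size=n_ind)  # non-carriers split 0/1
        codes[:, Ln + j] = np.where(carrier, 2, other).astype(np.int8)

    individuals = pd.DataFrame({
        "id": [f"{s}_{k:03d}" for s, n in zip(site_tab["site"], n_col) for k in range(n)],
        "site": np.repeat(site_tab["site"].to_numpy(), n_col),
        "lon": np.repeat(site_tab["lon"].to_numpy(), n_col),
        "lat": np.repeat(site_tab["lat"].to_numpy(), n_col),
    })
    loci_per_scaffold = 100
    idx = np.arange(Ln + La)
    snps = pd.DataFrame({
        "scaffold": ["scaffold_%d" % (i // loci_per_scaffold + 1) for i in idx],
        "pos": (idx % loci_per_scaffold + 1) * 10_000,
        "ref": "A",
        "alt": "T",
    })
    truth = pd.DataFrame({
        "locus": idx,
        "snp": snps["scaffold"] + ":" + snps["pos"].astype(str),
        "kind": ["neutral"] * Ln + ["adaptive"] * La,
        "intercept": [np.nan] * Ln + [a] * La,
        "slope": [np.nan] * Ln + [b] * La,
        "beta_sim": beta,
    })
    matrix = GenotypeMatrix(codes=codes, individuals=individuals, snps=snps)
    return matrix, truth


# ------------------------------------------------------------ reef grid
def reef_grid_from_mask(config: SeascapeConfig, coverage_rng_seed: int | None = None) -> ReefGrid:
    """One reef cell per sea pixel, with areas varying below the nominal
    cell area (partially covered cells)."""
    rng = np.random.default_rng(
        [config.seed, 8] if coverage_rng_seed is None else coverage_rng_seed
    )
    grid = config.grid
    mask = config.sea_mask()
    nominal = config.cell_size_km**2
    sea = np.argwhere(mask)
    cover = rng.uniform(0.2, 1.0, size=len(sea))
    cells = pd.DataFrame({
        "cell_id": [f"R{r:03d}C{c:03d}" for r, c in sea],
        "row": sea[:, 0],
        "col": sea[:, 1],
        "lon": grid.lons()[sea[:, 1]],
        "lat": grid.lats()[sea[:, 0]],
        "area_km2": cover * nominal,
    })
    return ReefGrid(cells=cells, nominal_cell_area_km2=nominal)


def default_heatwaves(config: SeascapeConfig, n_events: int = 8) -> tuple[HeatwaveEvent, ...]:
    """Summer heatwaves of graded intensity placed along the grid diagonal,
    so bleaching alert frequency spans a broad range across sites.

    Each event center is hit in a random subset of years with jittered
    start days, keeping anomalies rare relative to the monthly climatology
    (a heatwave recurring in the same calendar month of every year would
    simply inflate the MMM baseline and erase its own heat-stress signal).
    """
    rng = np.random.default_rng([config.seed, 7])
    sites = config.site_table()
    centers = list(zip(sites["row"], sites["col"]))
    # a couple of off-site events add spatial texture beyond the samples
    sea = np.argwhere(config.sea_mask())
    for _ in range(2):
        centers.append(tuple(sea[rng.integers(len(sea))]))
    events = []
    n_years = max(config.n_days // 365, 1)
    n_events = len(centers)
    for i, (r, c) in enumerate(centers):
        frac = i / max(n_events - 1, 1)
        radius = float(rng.uniform(3, 5))
        for y in range(n_years):
            if rng.random() > 0.6:
                continue
            t0 = int(365 * y + rng.integers(175, 225))  # near the seasonal peak
            if t0 + 35 >= config.n_days:
                continue
            events.append(HeatwaveEvent(
                row=int(r), col=int(c), radius_cells=radius,
                start_day=t0, duration_days=35,
                intensity=float(1.0 + 3.5 * frac),
            ))
    return tuple(events)


def generate_seascape(config: SeascapeConfig) -> dict:
    """Run the full generator: currents, SST (+ default heatwaves when the
    config lists none), auxiliary series, reef grid, site table.  Genotype
    generation needs sea distances and is done by the pipeline after the
    connectivity stage; see :func:`generate_genotypes`."""
    cfg = config
    if not cfg.heatwaves:
        from dataclasses import replace

        cfg = replace(cfg, heatwaves=default_heatwaves(cfg))
    u, v = generate_currents(cfg)
    sst = generate_sst(cfg)
    aux = generate_auxiliary(cfg)
    return {
        "config": cfg,
        "u": u,
        "v": v,
        "sst": sst,
        "aux": aux,
        "reef_grid": reef_grid_from_mask(cfg),
        "sites": cfg.site_table(),
    }
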