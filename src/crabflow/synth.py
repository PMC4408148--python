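"""Synthetic genotype, spatial, landscape, and flower-visitor data with known truth.

Gene pools follow an F-model: per locus, ancestral allele frequencies are drawn
from a flat Dirichlet and each pool's frequencies from a Dirichlet centred on
the ancestral vector with concentration (1-F)/F, so F acts as a drift/divergence
parameter. Downstream modules are exercised on these datasets because the real
field genotypes are not public.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import (
    GenotypeMatrix,
    INSECT_ORDERS,
    _default_metadata,
)

#: reference point for mapping planar km coordinates to lat/lon
ORIGIN_LAT = 47.0
ORIGIN_LON = 2.0
KM_PER_DEG_LAT = 111.19
KM_PER_DEG_LON = KM_PER_DEG_LAT * math.cos(math.radians(ORIGIN_LAT))


@dataclass
class DispersalConfig:
    pollen_sigma: float = 2.0  # km
    seed_sigma: float = 1.0  # km
    n_generations: int = 20


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study design; see module docstring."""

    n_wild_clusters: int = 5
    n_loci: int = 26
    alleles_per_locus: tuple[int, int] = (5, 15)
    divergence_f: float = 0.15
    crop_divergence_f: float = 0.30
    n_per_cluster: int = 50
    n_crop: int = 50
    # each entry: (ancestry vector over [wild_1..wild_K, crop], count, label)
    hybrid_spec: list = field(default_factory=list)
    missing_rate: float = 0.0
    dispersal: DispersalConfig = field(default_factory=DispersalConfig)
    landscape_effects: tuple[float, float, float] = (0.0, 0.0, 0.0)
    sites_per_cluster: int = 1
    extent_km: tuple[float, float] = (50.0, 50.0)
    seed: int = 0

    def validate(self):
        if self.n_wild_clusters < 1:
            raise ValueError("need at least one wild cluster")
        if self.n_loci < 1:
            raise ValueError("need at least one locus")
        lo, hi = self.alleles_per_locus
        if lo < 2 or hi < lo:
            raise ValueError("alleles_per_locus must be a range with min >= 2")
        for f in (self.divergence_f, self.crop_divergence_f):
            if not 0.0 < f < 1.0:
                raise ValueError("divergence F must lie strictly in (0, 1)")
        if not 0.0 <= self.missing_rate < 0.2:
            raise ValueError("missing_rate must lie in [0, 0.2)")
        for vec, count, *_ in self.hybrid_spec:
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (self.n_wild_clusters + 1,):
                raise ValueError("hybrid ancestry vector has wrong length")
            if abs(vec.sum() - 1.0) > 1e-9 or (vec < 0).any():
                raise ValueError("hybrid ancestry vector must be a simplex point")
            if count < 0:
                raise ValueError("negative hybrid count")
        return self

    @property
    def n_pools(self) -> int:
        return self.n_wild_clusters + 1

    @property
    def pool_names(self) -> list[str]:
        return [f"wild_{k + 1}" for k in range(self.n_wild_clusters)] + ["crop"]


@dataclass
class AlleleFrequencyTable:
    """Per-pool, per-locus allele frequencies on integer allele codes."""

    pool_names: list[str]
    locus_ids: list[str]
    allele_codes: list[np.ndarray]  # per locus, sorted integer codes
    freqs: list[np.ndarray]  # per locus, (n_pools, n_alleles), rows sum to 1

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for l, locus in enumerate(self.locus_ids):
            for k, pool in enumerate(self.pool_names):
                for a, code in enumerate(self.allele_codes[l]):
                    rows.append((pool, locus, int(code), self.freqs[l][k, a]))
        return pd.DataFrame(rows, columns=["pool", "locus", "allele", "freq"])


def sample_cluster_frequencies(config: SimulationConfig, rng=None) -> AlleleFrequencyTable:
    """Draw F-model allele frequencies for K wild pools plus one crop pool."""
    config.validate()
    rng = np.random.default_rng(config.seed if rng is None else rng)
    lo, hi = config.alleles_per_locus
    codes, freqs = [], []
    conc_wild = (1.0 - config.divergence_f) / config.divergence_f
    conc_crop = (1.0 - config.crop_divergence_f) / config.crop_divergence_f
    for l in range(config.n_loci):
        n_alleles = int(rng.integers(lo, hi + 1))
        ancestral = rng.dirichlet(np.ones(n_alleles))
        pool_freqs = np.empty((config.n_pools, n_alleles))
        for k in range(config.n_wild_clusters):
            pool_freqs[k] = rng.dirichlet(ancestral * conc_wild)
        pool_freqs[-1] = rng.dirichlet(ancestral * conc_crop)
        # microsatellite-style codes: even steps from a base repeat size
        codes.append(np.arange(100, 100 + 2 * n_alleles, 2, dtype=np.int32))
        freqs.append(pool_freqs)
    return AlleleFrequencyTable(
        config.pool_names,
        [f"L{l + 1:02d}" for l in range(config.n_loci)],
        codes,
        freqs,
    )


def _draw_copies(rng, freqs_l, codes_l, source_pools):
    """Draw one allele code per entry of ``source_pools`` from its pool."""
    cum = np.cumsum(freqs_l, axis=1)
    u = rng.random(len(source_pools))
    idx = (u[:, None] > cum[source_pools]).sum(axis=1)
    return codes_l[np.minimum(idx, len(codes_l) - 1)]


def _site_grid(config, rng):
    """Site centres on the simulation rectangle, one block per wild cluster."""
    n_sites = config.n_wild_clusters * config.sites_per_cluster
    w, h = config.extent_km
    xs = rng.uniform(0, w, n_sites)
    ys = rng.uniform(0, h, n_sites)
    return xs, ys


def _gamete_vectors(ancestry):
    """Split 2 x ancestry into two unit-mass gamete source distributions,
    concentrating each gamete on as few pools as possible.

    This makes an exact (0.5, 0.5) spec behave like a true F1 (one gamete per
    parental pool, heterozygous at fixed differences) and (0.75, 0.25) like a
    BC1 (one pure gamete, one 50/50 gamete), while preserving the expected
    ancestry for any vector.
    """
    mass = 2.0 * np.asarray(ancestry, dtype=float)
    order = np.argsort(-mass, kind="stable")
    m = np.zeros_like(mass)
    f = np.zeros_like(mass)
    room = 1.0
    for k in order:
        take = min(room, mass[k])
        m[k] = take
        room -= take
        f[k] = mass[k] - take
    return m, f


def sample_genotypes(freqs: AlleleFrequencyTable, config: SimulationConfig, rng=None):
    """Sample pure-pool and hybrid individuals under within-pool Hardy-Weinberg.

    Each individual's two gene copies are drawn from maternal/paternal gamete
    source distributions derived from its ancestry vector (see
    :func:`_gamete_vectors`), then the allele from the chosen pool's
    frequencies. Returns ``(GenotypeMatrix, TruthTable)`` where the truth table
    is a DataFrame with true ancestry vectors (columns ``q_<pool>``), hybrid
    class labels, site ids, and coordinates.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1 if rng is None else rng)
    K = config.n_wild_clusters

    ancestries, labels, classes, sites = [], [], [], []
    for k in range(K):
        vec = np.zeros(config.n_pools)
        vec[k] = 1.0
        for i in range(config.n_per_cluster):
            ancestries.append(vec)
            labels.append(f"w{k + 1}_{i + 1}")
            classes.append("pure_wild")
            sites.append(f"site_{k * config.sites_per_cluster + i % config.sites_per_cluster + 1}")
    for i in range(config.n_crop):
        vec = np.zeros(config.n_pools)
        vec[-1] = 1.0
        ancestries.append(vec)
        labels.append(f"c_{i + 1}")
        classes.append("crop")
        sites.append("orchard")
    for spec in config.hybrid_spec:
        vec, count = np.asarray(spec[0], dtype=float), spec[1]
        name = spec[2] if len(spec) > 2 else "hybrid"
        home = int(np.argmax(vec[:K]))
        for i in range(count):
            ancestries.append(vec)
            labels.append(f"{name}{home + 1}_{i + 1}")
            classes.append(name)
            sites.append(f"site_{home * config.sites_per_cluster + i % config.sites_per_cluster + 1}")
    if not ancestries:
        raise ValueError("empty design: no individuals requested")

    A = np.vstack(ancestries)
    n = len(labels)
    gametes = np.array([_gamete_vectors(a) for a in A])  # (n, 2, n_pools)
    cum_gam = np.cumsum(gametes, axis=2)
    calls = np.zeros((n, config.n_loci, 2), dtype=np.int32)
    for l in range(config.n_loci):
        for copy in range(2):
            cum = cum_gam[:, copy, :]
            src = np.minimum(
                (rng.random(n)[:, None] > cum).sum(axis=1), config.n_pools - 1
            )
            calls[:, l, copy] = _draw_copies(rng, freqs.freqs[l], freqs.allele_codes[l], src)
    if config.missing_rate > 0:
        mask = rng.random((n, config.n_loci)) < config.missing_rate
        calls[mask] = 0

    xs, ys = _site_grid(config, rng)
    site_names = [f"site_{j + 1}" for j in range(len(xs))]
    site_xy = dict(zip(site_names, zip(xs, ys)))
    w, h = config.extent_km
    site_xy["orchard"] = (w / 2, h / 2)
    jit = rng.normal(0, 0.2, (n, 2))
    x_km = np.array([site_xy[s][0] for s in sites]) + jit[:, 0]
    y_km = np.array([site_xy[s][1] for s in sites]) + jit[:, 1]

    meta = _default_metadata(labels)
    meta["site_id"] = sites
    meta["species_label"] = ["crop" if c == "crop" else "wild" for c in classes]
    meta["latitude"] = ORIGIN_LAT + y_km / KM_PER_DEG_LAT
    meta["longitude"] = ORIGIN_LON + x_km / KM_PER_DEG_LON
    G = GenotypeMatrix(labels, list(freqs.locus_ids), calls, meta)

    truth = pd.DataFrame(
        {"individual_id": labels, "hybrid_class": classes, "site_id": sites,
         "x_km": x_km, "y_km": y_km}
    )
    for j, pool in enumerate(freqs.pool_names):
        truth[f"q_{pool}"] = A[:, j]
    return G, truth


# -- spatially explicit pedigree --------------------------------------------


def simulate_spatial_pedigree(
    freqs: AlleleFrequencyTable,
    config: SimulationConfig,
    n_individuals: int | None = None,
    pool: int = 0,
    rng=None,
):
    """Constant-size pedigree with Gaussian pollen/seed dispersal on a rectangle.

    Founders are placed uniformly; each generation an offspring takes a uniform
    mother, a father weighted by a Gaussian pollen kernel of distance, and a
    position displaced from the mother by a Gaussian seed kernel (reflecting
    boundaries). Smaller sigmas yield stronger isolation by distance.
    Returns ``(GenotypeMatrix, TruthTable)`` for the final generation.
    """
    config.validate()
    disp = config.dispersal
    if disp.pollen_sigma <= 0 or disp.seed_sigma <= 0:
        raise ValueError("dispersal sigmas must be positive")
    if disp.n_generations < 0:
        raise ValueError("n_generations must be >= 0")
    rng = np.random.default_rng(config.seed + 2 if rng is None else rng)
    n = n_individuals if n_individuals is not None else config.n_per_cluster
    if n < 2:
        raise ValueError("need at least two individuals")
    L = len(freqs.locus_ids)
    w, h = config.extent_km

    calls = np.zeros((n, L, 2), dtype=np.int32)
    src = np.full(n, pool)
    for l in range(L):
        for copy in range(2):
            calls[:, l, copy] = _draw_copies(rng, freqs.freqs[l], freqs.allele_codes[l], src)
    pos = np.column_stack([rng.uniform(0, w, n), rng.uniform(0, h, n)])

    for _ in range(disp.n_generations):
        mothers = rng.integers(0, n, n)
        d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
        kern = np.exp(-d2 / (2.0 * disp.pollen_sigma**2))
        cumk = np.cumsum(kern[mothers], axis=1)
        u = rng.random(n) * cumk[:, -1]
        fathers = (u[:, None] > cumk).sum(axis=1)
        pick_m = rng.integers(0, 2, (n, L))
        pick_f = rng.integers(0, 2, (n, L))
        new_calls = np.empty_like(calls)
        new_calls[:, :, 0] = np.take_along_axis(
            calls[mothers], pick_m[:, :, None], axis=2
        )[:, :, 0]
        new_calls[:, :, 1] = np.take_along_axis(
            calls[fathers], pick_f[:, :, None], axis=2
        )[:, :, 0]
        new_pos = pos[mothers] + rng.normal(0, disp.seed_sigma, (n, 2))
        # reflect into the rectangle
        for dim, lim in enumerate((w, h)):
            x = np.abs(new_pos[:, dim]) % (2 * lim)
            new_pos[:, dim] = np.where(x > lim, 2 * lim - x, x)
        calls, pos = new_calls, new_pos

    labels = [f"p_{i + 1}" for i in range(n)]
    meta = _default_metadata(labels)
    meta["site_id"] = "pedigree"
    meta["species_label"] = "wild"
    meta["latitude"] = ORIGIN_LAT + pos[:, 1] / KM_PER_DEG_LAT
    meta["longitude"] = ORIGIN_LON + pos[:, 0] / KM_PER_DEG_LON
    G = GenotypeMatrix(labels, list(freqs.locus_ids), np.sort(calls, axis=2), meta)
    truth = pd.DataFrame(
        {
            "individual_id": labels,
            "hybrid_class": "pure_wild",
            "site_id": "pedigree",
            "x_km": pos[:, 0],
            "y_km": pos[:, 1],
        }
    )
    for j, pname in enumerate(freqs.pool_names):
        truth[f"q_{pname}"] = 1.0 if j == pool else 0.0
    return G, truth


# -- landscape covariates -----------------------------------------------------


def attach_landscape_covariates(
    site_ids,
    landscape_effects=(0.0, 0.0, 0.0),
    seed: int = 0,
    target_corr: float = 0.9,
    base_rate: float = 0.15,
):
    """Draw correlated landscape covariates per site and the implied expected
    introgression probability.

    Orchard count and area are drawn log-normally with Pearson correlation
    ``target_corr`` on the log scale. The expected per-site introgression
    probability is ``exp(b0 + bd*z_d + bn*z_n + bdn*z_d*z_n)`` mapped into
    (0, 1) through r/(1+r); betas act on z-scored covariates.

    Returns ``(landscape_table, probs)`` with ``probs`` a Series indexed by site.
    """
    site_ids = list(site_ids)
    if len(site_ids) < 2:
        raise ValueError("need at least two sites")
    if len(set(site_ids)) != len(site_ids):
        raise ValueError("duplicate site ids")
    beta_d, beta_n, beta_dn = landscape_effects
    rng = np.random.default_rng(seed)
    m = len(site_ids)
    density = rng.lognormal(mean=1.0, sigma=0.6, size=m)
    z = rng.multivariate_normal(
        [2.0, 3.0],
        [[0.5, target_corr * 0.5], [target_corr * 0.5, 0.5]],
        size=m,
    )
    n_orchards = np.maximum(1, np.round(np.exp(z[:, 0]))).astype(int)
    orchard_area = np.exp(z[:, 1])
    management = np.where(rng.random(m) < 0.5, "intensive", "extensive")

    def zscore(v):
        s = v.std()
        return (v - v.mean()) / s if s > 0 else np.zeros_like(v)

    zd, zn = zscore(density), zscore(n_orchards.astype(float))
    raw = np.exp(np.log(base_rate / (1 - base_rate)) + beta_d * zd + beta_n * zn + beta_dn * zd * zn)
    probs = raw / (1.0 + raw)

    tab = pd.DataFrame(
        {
            "site_id": site_ids,
            "apple_density": density,
            "n_orchards": n_orchards,
            "orchard_area": orchard_area,
            "management_class": management,
        }
    )
    return tab, pd.Series(probs, index=site_ids, name="p_hybrid")


def assign_hybrid_status(site_of_individual, probs: pd.Series, seed: int = 0) -> pd.Series:
    """Bernoulli hybrid indicator per individual from its site's probability."""
    rng = np.random.default_rng(seed)
    p = probs.reindex(site_of_individual).to_numpy()
    if np.isnan(p).any():
        raise ValueError("individual site missing from probability table")
    return pd.Series(
        rng.random(len(p)) < p, index=getattr(site_of_individual, "index", None)
    )


# -- flower visitors ----------------------------------------------------------


def simulate_visitor_observations(
    rates_by_order=None,
    management_effect: float = 0.0,
    n_obs: int = 306,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate flower-visitor records across six insect orders and two
    management classes; the intensive class carries multiplicatively fewer
    distinct taxa (factor exp(-management_effect), floor one taxon).
    """
    if rates_by_order is None:
        rates_by_order = {o: 12.0 for o in INSECT_ORDERS}
    if set(rates_by_order) - set(INSECT_ORDERS):
        raise ValueError("unknown insect order in rates_by_order")
    if n_obs < 1:
        raise ValueError("n_obs must be positive")
    rng = np.random.default_rng(seed)
    records = []
    for order in INSECT_ORDERS:
        rate = rates_by_order.get(order, 0.0)
        for mclass, factor in (("extensive", 1.0), ("intensive", math.exp(-management_effect))):
            k = max(1, int(rng.poisson(rate * factor)))
            for t in range(k):
                records.append((f"{order[:3]}_t{t + 1}", order, mclass))
    cells = pd.DataFrame(records, columns=["taxon_id", "insect_order", "management_class"])
    # one record per generated taxon, remaining observations multinomial
    if n_obs < len(cells):
        cells = cells.sample(n=n_obs, random_state=int(rng.integers(2**31)))
        reps = np.ones(len(cells), dtype=int)
    else:
        extra = rng.multinomial(n_obs - len(cells), np.ones(len(cells)) / len(cells))
        reps = 1 + extra
    out = cells.loc[cells.index.repeat(reps)].reset_index(drop=True)
    out.insert(0, "record_id", [f"r{i + 1}" for i in range(len(out))])
    return out


# -- serialization -------------------------------------------------------------


def write_dataset(outdir, G: GenotypeMatrix, truth: pd.DataFrame,
                  landscape: pd.DataFrame | None = None,
                  visitors: pd.DataFrame | None = None):
    """Write GENEPOP + metadata/truth CSVs (and optional covariate tables)."""
    from pathlib import Path
    from .genio import write_genepop

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genepop(G, outdir / "genotypes.gen")
    meta = G.metadata.reset_index()
    meta.to_csv(outdir / "metadata.csv", index=False)
    truth.to_csv(outdir / "truth.csv", index=False)
    if landscape is not None:
        landscape.to_csv(outdir / "landscape.csv", index=False)
    if visitors is not None:
        visitors.to_csv(outdir / "visitors.csv", index=False)
    return outdir
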