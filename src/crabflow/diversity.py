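"""Within-species diversity statistics.

Observed/unbiased expected heterozygosity, Weir-Cockerham variance-component
F-statistics (ratio-of-sums over loci and alleles), permutation tests for
pairwise differentiation and heterozygote deficit, and rarefaction-standardized
allelic and private allelic richness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genio import GenotypeMatrix


def _allele_stats(G: GenotypeMatrix, idx, locus: int):
    """Allele counts and heterozygote indicator per individual subset ``idx``."""
    calls = G.calls[idx, locus, :]
    typed = calls[:, 0] > 0
    calls = calls[typed]
    return calls, typed


def heterozygosities(G: GenotypeMatrix, individuals=None) -> pd.DataFrame:
    """Per-locus H_O (fraction heterozygous among typed individuals) and
    Nei-unbiased H_E = (2n/(2n-1)) * (1 - sum p^2). Returns one row per locus
    plus columns for n typed; use :func:`multilocus_means` for the summary."""
    idx = np.arange(G.n_individuals) if individuals is None else np.asarray(individuals)
    rows = []
    for l, locus in enumerate(G.locus_ids):
        calls, _ = _allele_stats(G, idx, l)
        n = len(calls)
        if n == 0:
            rows.append((locus, 0, np.nan, np.nan))
            continue
        ho = float((calls[:, 0] != calls[:, 1]).mean())
        _, counts = np.unique(calls.ravel(), return_counts=True)
        p = counts / (2 * n)
        he_raw = 1.0 - float((p**2).sum())
        he = (2 * n / (2 * n - 1)) * he_raw if n > 0 and 2 * n > 1 else np.nan
        rows.append((locus, n, ho, he))
    return pd.DataFrame(rows, columns=["locus", "n_typed", "H_O", "H_E"])


def multilocus_means(het: pd.DataFrame) -> dict:
    """Unweighted means over polymorphic, typed loci."""
    ok = (het["n_typed"] > 0) & (het["H_E"] > 0)
    sub = het[ok]
    return {
        "H_O": float(sub["H_O"].mean()) if len(sub) else np.nan,
        "H_E": float(sub["H_E"].mean()) if len(sub) else np.nan,
        "n_loci_used": int(len(sub)),
    }


# -- Weir & Cockerham variance components ------------------------------------


def _wc_components_locus(G: GenotypeMatrix, unit_indices, locus: int):
    """Per-allele (a, b, c) variance components at one locus.

    ``unit_indices`` is a list of integer index arrays, one per unit. Units with
    no typed individual at the locus are dropped; with a single remaining unit
    only (b, c) are returned (a = NaN), matching the one-population F_IS
    estimator.
    """
    pops = []
    for idx in unit_indices:
        calls, _ = _allele_stats(G, np.asarray(idx), locus)
        if len(calls):
            pops.append(calls)
    r = len(pops)
    if r == 0:
        return None
    alleles = np.unique(np.concatenate([c.ravel() for c in pops]))
    if alleles.size < 2:
        return None  # monomorphic overall
    n_i = np.array([len(c) for c in pops], dtype=float)
    p_i = np.zeros((r, alleles.size))
    h_i = np.zeros((r, alleles.size))
    for j, calls in enumerate(pops):
        for a, allele in enumerate(alleles):
            hits = calls == allele
            p_i[j, a] = hits.sum() / (2 * n_i[j])
            h_i[j, a] = (hits.sum(axis=1) == 1).mean()
    nsum = n_i.sum()
    nbar = nsum / r
    pbar = (n_i[:, None] * p_i).sum(axis=0) / nsum
    hbar = (n_i[:, None] * h_i).sum(axis=0) / nsum
    if r >= 2:
        nc = (nsum - (n_i**2).sum() / nsum) / (r - 1)
        s2 = (n_i[:, None] * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        if nbar <= 1 or nc <= 0:
            return None
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
    else:
        if nbar <= 1:
            return None
        a = np.full(alleles.size, np.nan)
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (2 * nbar - 1) / (4 * nbar) * hbar
        )
    c = hbar / 2
    return a, b, c


def wc_f_statistics(G: GenotypeMatrix, units: dict | None = None) -> dict:
    """Multilocus Weir-Cockerham F_ST and F_IS as ratios of summed components.

    ``units`` maps unit name -> individual index array; default groups by
    ``site_id``. With a single unit F_ST is NaN (flagged) while F_IS is the
    one-population estimator.
    """
    if units is None:
        units = {
            s: np.nonzero((G.sites() == s).to_numpy())[0]
            for s in pd.unique(G.sites())
        }
    unit_indices = list(units.values())
    single = len(unit_indices) == 1
    A = B = C = 0.0
    per_locus = []
    for l, locus in enumerate(G.locus_ids):
        comp = _wc_components_locus(G, unit_indices, l)
        if comp is None:
            per_locus.append((locus, np.nan, np.nan))
            continue
        a, b, c = comp
        with np.errstate(invalid="ignore"):
            fst_l = np.nansum(a) / (np.nansum(a) + b.sum() + c.sum()) if not single else np.nan
            denom = b.sum() + c.sum()
            fis_l = b.sum() / denom if denom != 0 else np.nan
        per_locus.append((locus, fst_l, fis_l))
        if not single and np.isfinite(a).all():
            A += a.sum()
        B += b.sum()
        C += c.sum()
    fst = A / (A + B + C) if not single and (A + B + C) != 0 else np.nan
    fis = B / (B + C) if (B + C) != 0 else np.nan
    return {
        "F_ST": float(fst) if fst == fst else np.nan,
        "F_IS": float(fis) if fis == fis else np.nan,
        "per_locus": pd.DataFrame(per_locus, columns=["locus", "F_ST", "F_IS"]),
        "single_unit": single,
    }


def pairwise_fst_permutation(
    G: GenotypeMatrix, units: dict, n_perm: int = 999, seed: int = 0
) -> dict:
    """Pairwise multilocus theta with permutation p-values.

    p = (1 + #{theta_perm >= theta_obs}) / (n_perm + 1), permuting individuals
    between the two units.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    names = list(units)
    m = len(names)
    theta = np.zeros((m, m))
    pval = np.full((m, m), np.nan)
    for i in range(m):
        for j in range(i + 1, m):
            ia = np.asarray(units[names[i]])
            ib = np.asarray(units[names[j]])
            obs = wc_f_statistics(G, {"a": ia, "b": ib})["F_ST"]
            theta[i, j] = theta[j, i] = obs
            pool = np.concatenate([ia, ib])
            hits = 0
            for _ in range(n_perm):
                perm = rng.permutation(pool)
                t = wc_f_statistics(
                    G, {"a": perm[: len(ia)], "b": perm[len(ia):]}
                )["F_ST"]
                if t >= obs:
                    hits += 1
            p = (1 + hits) / (n_perm + 1)
            pval[i, j] = pval[j, i] = p
    return {
        "theta": pd.DataFrame(theta, index=names, columns=names),
        "p": pd.DataFrame(pval, index=names, columns=names),
    }


def hwe_deficit_test(
    G: GenotypeMatrix, individuals=None, n_perm: int = 9999, seed: int = 0
) -> dict:
    """One-sided heterozygote-deficit test.

    Observed multilocus F_IS is compared with its null distribution obtained by
    re-pairing the observed gene copies into diploids at random within the unit
    and locus (allele counts preserved);
    p = (1 + #{F_IS_perm >= F_IS_obs}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    idx = np.arange(G.n_individuals) if individuals is None else np.asarray(individuals)
    copies = []
    for l in range(G.n_loci):
        calls, _ = _allele_stats(G, idx, l)
        if len(calls) >= 2 and np.unique(calls.ravel()).size >= 2:
            copies.append(calls.ravel())
    if not copies:
        return {"F_IS": np.nan, "p": np.nan, "flag": "monomorphic or untyped unit"}

    def fis_of(copy_lists):
        b = c = 0.0
        for arr in copy_lists:
            calls = arr.reshape(-1, 2)
            n = len(calls)
            alleles, counts = np.unique(arr, return_counts=True)
            p = counts / (2 * n)
            h = np.array([((calls == al).sum(axis=1) == 1).mean() for al in alleles])
            bb = (n / (n - 1)) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)
            b += bb.sum()
            c += (h / 2).sum()
        return b / (b + c) if (b + c) != 0 else np.nan

    obs = fis_of(copies)
    hits = 0
    for _ in range(n_perm):
        permed = [rng.permutation(arr) for arr in copies]
        if fis_of(permed) >= obs:
            hits += 1
    return {"F_IS": float(obs), "p": (1 + hits) / (n_perm + 1), "flag": None}


# -- rarefaction ---------------------------------------------------------------


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _presence_prob(counts: np.ndarray, g: int) -> np.ndarray:
    """Q_a(g) = 1 - C(N - N_a, g) / C(N, g) per allele."""
    N = counts.sum()
    q = np.ones(len(counts))
    keep = N - counts >= g
    if keep.any():
        q[keep] = 1.0 - np.exp(_log_comb(N - counts[keep], g) - _log_comb(N, g))
    return q


def allele_counts(G: GenotypeMatrix, individuals, locus: int):
    calls, _ = _allele_stats(G, np.asarray(individuals), locus)
    alleles, counts = np.unique(calls.ravel(), return_counts=True)
    return alleles, counts


def rarefied_allelic_richness(G: GenotypeMatrix, individuals, g: int = 2) -> pd.DataFrame:
    """Expected number of distinct alleles in a random subsample of g gene
    copies, per locus; loci with fewer than g typed copies are excluded and
    flagged (included = False)."""
    if g < 1:
        raise ValueError("g must be >= 1")
    rows = []
    for l, locus in enumerate(G.locus_ids):
        _, counts = allele_counts(G, individuals, l)
        N = counts.sum()
        if N < g:
            rows.append((locus, int(N), np.nan, False))
            continue
        rows.append((locus, int(N), float(_presence_prob(counts, g).sum()), True))
    return pd.DataFrame(rows, columns=["locus", "n_copies", "A_R", "included"])


def private_allelic_richness(G: GenotypeMatrix, units: dict, g: int = 2) -> pd.DataFrame:
    """Rarefied private allelic richness per unit.

    A_P,j(g) = sum over alleles of Q_ja(g) * prod_{j' != j} (1 - Q_j'a(g)),
    averaged over loci where every unit has at least g typed copies.
    """
    if g < 1:
        raise ValueError("g must be >= 1")
    names = list(units)
    per_locus = {name: [] for name in names}
    used_loci = []
    for l, locus in enumerate(G.locus_ids):
        all_alleles = []
        counts_by_unit = {}
        ok = True
        for name in names:
            alleles, counts = allele_counts(G, units[name], l)
            if counts.sum() < g:
                ok = False
                break
            counts_by_unit[name] = dict(zip(alleles, counts))
            all_alleles.append(alleles)
        if not ok:
            continue
        used_loci.append(locus)
        alleles = np.unique(np.concatenate(all_alleles))
        Qmat = np.zeros((len(names), alleles.size))
        for j, name in enumerate(names):
            cnt = np.array([counts_by_unit[name].get(a, 0) for a in alleles], dtype=float)
            N = int(sum(counts_by_unit[name].values()))
            q = np.ones(alleles.size)
            keepn = N - cnt >= g
            q[keepn] = 1.0 - np.exp(_log_comb(N - cnt[keepn], g) - _log_comb(N, g))
            q[cnt == 0] = 0.0
            Qmat[j] = q
        for j, name in enumerate(names):
            others = np.prod(1.0 - np.delete(Qmat, j, axis=0), axis=0)
            per_locus[name].append(float((Qmat[j] * others).sum()))
    rows = []
    for name in names:
        vals = per_locus[name]
        rows.append((name, len(vals), float(np.mean(vals)) if vals else np.nan))
    return pd.DataFrame(rows, columns=["unit", "n_loci_used", "A_P"])


# -- site filters --------------------------------------------------------------


def site_filters(G: GenotypeMatrix, min_individuals: int = 4, min_per_marker: int = 2) -> dict:
    """The two analysis sets used downstream.

    ``diversity_sites``: sites with >= ``min_individuals`` genotyped
    individuals. ``richness_sites``: the subset where additionally every marker
    is typed in >= ``min_per_marker`` individuals. Exclusion reasons reported.
    """
    sites = G.sites()
    diversity_sites, richness_sites, excluded = [], [], {}
    for site in pd.unique(sites):
        idx = np.nonzero((sites == site).to_numpy())[0]
        if len(idx) < min_individuals:
            excluded[site] = f"fewer than {min_individuals} individuals"
            continue
        diversity_sites.append(site)
        typed = (G.calls[idx, :, 0] > 0).sum(axis=0)
        if (typed >= min_per_marker).all():
            richness_sites.append(site)
        else:
            bad = G.locus_ids[int(np.argmin(typed))]
            excluded[site] = f"locus {bad} typed in fewer than {min_per_marker} individuals"
    return {
        "diversity_sites": diversity_sites,
        "richness_sites": richness_sites,
        "excluded": excluded,
    }


# -- inverse-distance-weighted export (in lieu of kriged maps) -----------------


def idw_grid(values, lats, lons, n_grid: int = 25, power: float = 2.0) -> pd.DataFrame:
    """Inverse-distance-weighted interpolation of per-site values onto a
    lat/lon grid spanning the sites; simple map export, not kriging."""
    values = np.asarray(values, dtype=float)
    lats, lons = np.asarray(lats, dtype=float), np.asarray(lons, dtype=float)
    glat = np.linspace(lats.min(), lats.max(), n_grid)
    glon = np.linspace(lons.min(), lons.max(), n_grid)
    rows = []
    for la in glat:
        for lo in glon:
            d = np.hypot(lats - la, lons - lo)
            if (d < 1e-9).any():
                v = values[d < 1e-9][0]
            else:
                wgt = d**-power
                v = float((wgt * values).sum() / wgt.sum())
            rows.append((la, lo, v))
    return pd.DataFrame(rows, columns=["latitude", "longitude", "value"])
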