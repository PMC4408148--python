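"""Fine-scale spatial genetic structure.

Pairwise Loiselle kinship, isolation-by-distance regression of kinship on
ln(distance) with a coordinate-permutation test, and the Sp statistic
Sp = -b_L / (1 - F_N), where b_L is the slope restricted to pairs within L km
and F_N the mean kinship in the first distance class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_KM = 6371.0088


def haversine_matrix(lat, lon) -> np.ndarray:
    """Great-circle distance matrix in km."""
    lat = np.radians(np.asarray(lat, dtype=float))
    lon = np.radians(np.asarray(lon, dtype=float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def _dosage_matrix(G):
    """Per locus: (X, typed, alleles) with X the allele-dosage/2 matrix
    (NaN rows for untyped individuals)."""
    out = []
    for l in range(G.n_loci):
        calls = G.calls[:, l, :]
        typed = calls[:, 0] > 0
        alleles = np.unique(calls[typed])
        if alleles.size == 0:
            out.append(None)
            continue
        X = np.full((G.n_individuals, alleles.size), np.nan)
        sub = np.zeros((typed.sum(), alleles.size))
        tcalls = calls[typed]
        for a, allele in enumerate(alleles):
            sub[:, a] = (tcalls == allele).sum(axis=1) / 2.0
        X[typed] = sub
        out.append((X, typed, alleles))
    return out


def loiselle_kinship(G, reference=None) -> np.ndarray:
    """Pairwise Loiselle/Nason kinship matrix.

    Reference allele frequencies and the small-sample bias correction use the
    ``reference`` individual subset (default: everyone in ``G``). Per pair,
    only loci typed in both individuals contribute; multilocus F_ij is the
    ratio of summed per-locus numerators to summed denominators. Pairs sharing
    no typed polymorphic locus are NaN.
    """
    N = G.n_individuals
    ref = np.arange(N) if reference is None else np.asarray(reference)
    num = np.zeros((N, N))
    den = np.zeros((N, N))
    any_poly = False
    for block in _dosage_matrix(G):
        if block is None:
            continue
        X, typed, _ = block
        ref_typed = typed.copy()
        mask_ref = np.zeros(N, dtype=bool)
        mask_ref[ref] = True
        ref_typed &= mask_ref
        n_l = int(ref_typed.sum())
        if n_l < 2:
            continue
        p = X[ref_typed].mean(axis=0)
        d_l = float((p * (1 - p)).sum())
        if d_l <= 0:
            continue  # monomorphic in the reference
        any_poly = True
        Xc = X - p
        Xc0 = np.nan_to_num(Xc)
        cross = Xc0 @ Xc0.T + d_l / (n_l - 1)
        both = np.outer(typed, typed)
        num += np.where(both, cross, 0.0)
        den += np.where(both, d_l, 0.0)
    if not any_poly:
        raise ValueError("no polymorphic locus in the reference set")
    with np.errstate(invalid="ignore", divide="ignore"):
        F = num / den
    F[den == 0] = np.nan
    np.fill_diagonal(F, np.nan)  # self-pairs excluded
    return F


@dataclass
class IbdResult:
    b: float
    f1: float
    r2: float
    p: float
    n_pairs: int
    max_d: float | None
    first_class_edge: float


def _slope(f, x):
    xm, fm = x.mean(), f.mean()
    vx = ((x - xm) ** 2).mean()
    if vx == 0:
        return np.nan, np.nan
    cov = ((x - xm) * (f - fm)).mean()
    b = cov / vx
    vf = ((f - fm) ** 2).mean()
    r2 = cov**2 / (vx * vf) if vf > 0 else np.nan
    return b, r2


def kinship_ibd_regression(
    F,
    d,
    max_d: float | None = None,
    first_class_edge: float = 1.0,
    n_perm: int = 9999,
    seed: int = 0,
) -> IbdResult:
    """OLS slope of F_ij on ln(d_ij) with a coordinate-permutation test.

    Pairs retained: i < j, finite F, d > 0 (and d <= max_d if set). F_1 is the
    mean kinship over pairs with d <= first_class_edge. The permutation test
    shuffles individual positions (rows/columns of d jointly) and recomputes
    the slope; two-sided p = (1 + #{|b_perm| >= |b_obs|}) / (n_perm + 1).
    """
    F = np.asarray(F, dtype=float)
    d = np.asarray(d, dtype=float)
    n = F.shape[0]
    iu = np.triu_indices(n, 1)
    fv = F[iu]

    def stats_for(dm):
        dv = dm[iu]
        keep = np.isfinite(fv) & (dv > 0)
        if max_d is not None:
            keep &= dv <= max_d
        if keep.sum() < 3:
            return None
        return _slope(fv[keep], np.log(dv[keep])), int(keep.sum())

    obs = stats_for(d)
    if obs is None:
        raise ValueError("fewer than 3 usable pairs for the IBD regression")
    (b, r2), n_pairs = obs

    first = np.isfinite(fv) & (d[iu] <= first_class_edge)
    f1 = float(fv[first].mean()) if first.any() else np.nan

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        res = stats_for(d[np.ix_(perm, perm)])
        if res is None:
            continue
        (bp, _), _ = res
        if abs(bp) >= abs(b):
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return IbdResult(float(b), f1, float(r2), p, n_pairs, max_d, first_class_edge)


def sp_statistic(b_ld: float, f_n: float) -> float:
    """Sp = -b_L / (1 - F_N); requires F_N < 1."""
    if not np.isfinite(f_n) or f_n >= 1.0:
        raise ValueError("F_N must be finite and < 1")
    if not np.isfinite(b_ld):
        raise ValueError("slope must be finite")
    return -b_ld / (1.0 - f_n)


def sgs_analysis(
    G,
    individuals=None,
    max_d: float = 10.0,
    first_class_edge: float = 1.0,
    n_perm: int = 9999,
    seed: int = 0,
) -> dict:
    """Kinship + IBD regression + Sp for one analysis population.

    Reference allele frequencies are taken over the analysis set itself. The
    restricted slope b_Ld (d <= max_d) feeds Sp; when no pairs survive the
    restriction the overall slope is used and flagged.
    """
    if individuals is not None:
        G = G.subset_individuals(individuals)
    coords = G.coordinates()
    if np.isnan(coords).any():
        raise ValueError("individuals without coordinates in SGS analysis")
    F = loiselle_kinship(G)
    d = haversine_matrix(coords[:, 0], coords[:, 1])
    fallback = False
    try:
        res = kinship_ibd_regression(
            F, d, max_d=max_d, first_class_edge=first_class_edge,
            n_perm=n_perm, seed=seed,
        )
    except ValueError:
        res = kinship_ibd_regression(
            F, d, max_d=None, first_class_edge=first_class_edge,
            n_perm=n_perm, seed=seed,
        )
        fallback = True
    sp = sp_statistic(res.b, res.f1) if np.isfinite(res.f1) and res.f1 < 1 else np.nan
    return {
        "b": res.b,
        "F_1": res.f1,
        "r2": res.r2,
        "p": res.p,
        "Sp": sp,
        "n_pairs": res.n_pairs,
        "used_overall_slope": fallback,
        "kinship": F,
        "distances": d,
    }
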