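"""Quasi-Poisson GLMs linking introgression and visitor diversity to landscape.

Log-link IRLS fits whose point estimates equal Poisson maximum likelihood; the
dispersion parameter (Pearson chi-square over residual df) only rescales
inference. Terms are tested sequentially with analysis-of-deviance F-tests
using the dispersion of the fullest model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genio import INSECT_ORDERS


class GlmError(RuntimeError):
    pass


@dataclass
class GlmFit:
    response: str
    terms: list
    coefficients: np.ndarray
    dispersion: float
    deviance: float
    df_resid: int
    n: int
    mu: np.ndarray = field(repr=False, default=None)
    iterations: int = 0
    dispersion_floored: bool = False

    def coef_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"term": self.terms, "estimate": self.coefficients})


def _deviance_poisson(y, mu):
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * (term - (y - mu)).sum())


def fit_quasipoisson(y, X, terms=None, response: str = "y",
                     max_iter: int = 100, tol: float = 1e-8) -> GlmFit:
    """Fit a log-link quasi-Poisson GLM by IRLS.

    ``y`` must be non-negative (not necessarily integer); ``X`` is a dense
    design matrix including the intercept column. Convergence is a relative
    deviance change below ``tol``; rank deficiency and non-convergence raise
    :class:`GlmError`.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if (y < 0).any():
        raise GlmError("negative response values")
    n, p = X.shape
    if terms is None:
        terms = [f"x{j}" for j in range(p)]
    if n <= p:
        raise GlmError("residual df would be non-positive")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        _, R = np.linalg.qr(X)
        aliased = int(np.argmin(np.abs(np.diag(R))))
        raise GlmError(f"design is rank deficient; aliased term: {terms[aliased]}")

    mu = np.clip(y + 0.5, 1e-8, None)
    eta = np.log(mu)
    dev = _deviance_poisson(y, mu)
    beta = None
    trace = [dev]
    for it in range(1, max_iter + 1):
        w = mu
        z = eta + (y - mu) / mu
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        eta = X @ beta
        if (eta > 700).any():
            raise GlmError(f"divergence (separation?) at iteration {it}; trace={trace}")
        mu = np.exp(eta)
        new_dev = _deviance_poisson(y, mu)
        trace.append(new_dev)
        if abs(new_dev - dev) < tol * (abs(dev) + 0.1):
            dev = new_dev
            break
        dev = new_dev
    else:
        raise GlmError(f"IRLS did not converge in {max_iter} iterations; trace={trace}")

    pearson = float(((y - mu) ** 2 / mu).sum())
    df_resid = n - p
    phi = pearson / df_resid
    floored = False
    if phi <= np.finfo(float).eps:
        phi = np.finfo(float).eps
        floored = True
    return GlmFit(
        response=response,
        terms=list(terms),
        coefficients=beta,
        dispersion=phi,
        deviance=dev,
        df_resid=df_resid,
        n=n,
        mu=mu,
        iterations=it,
        dispersion_floored=floored,
    )


def anova_f(fit_nested: GlmFit, fit_full: GlmFit, phi: float | None = None) -> dict:
    """Analysis-of-deviance F-test between two nested quasi-Poisson fits.

    F = (delta deviance / delta df) / phi, with phi the full-model Pearson
    dispersion unless supplied; p from F(delta df, df_resid of the full model).
    """
    ddf = fit_nested.df_resid - fit_full.df_resid
    ddev = fit_nested.deviance - fit_full.deviance
    phi = fit_full.dispersion if phi is None else phi
    if ddf == 0:
        return {"F": 0.0, "df_term": 0, "df_resid": fit_full.df_resid, "p": 1.0}
    if ddf < 0:
        raise GlmError("models are not nested (nested model has more parameters)")
    F = max(ddev, 0.0) / ddf / phi
    p = float(stats.f.sf(F, ddf, fit_full.df_resid)) if F > 0 else 1.0
    return {"F": float(F), "df_term": int(ddf), "df_resid": fit_full.df_resid, "p": p}


def sequential_anova(y, blocks, response: str = "y") -> pd.DataFrame:
    """Sequential (type-I) F-tests.

    ``blocks`` is an ordered list of (term_name, columns) added on top of an
    intercept; every term is tested against the dispersion of the fullest model.
    """
    n = len(y)
    X = np.ones((n, 1))
    terms = ["(intercept)"]
    fits = [fit_quasipoisson(y, X, terms, response)]
    for name, cols in blocks:
        cols = np.atleast_2d(np.asarray(cols, dtype=float))
        if cols.shape[0] != n:
            cols = cols.T
        X = np.hstack([X, cols])
        terms = terms + [name] * cols.shape[1]
        fits.append(fit_quasipoisson(y, X, terms, response))
    full = fits[-1]
    rows = []
    for i, (name, _) in enumerate(blocks):
        res = anova_f(fits[i], fits[i + 1], phi=full.dispersion)
        rows.append({"term": name, **res})
    out = pd.DataFrame(rows)
    out.attrs["fit"] = full
    return out


# -- the three study models ------------------------------------------------------


def _join_landscape(classified: pd.DataFrame, landscape: pd.DataFrame):
    import warnings

    merged = classified.merge(landscape, on="site_id", how="left")
    missing = merged["apple_density"].isna()
    if missing.any():
        warnings.warn(
            f"dropping {int(missing.sum())} individual(s) from sites without "
            "landscape covariates",
            stacklevel=3,
        )
        merged = merged[~missing]
    if len(merged) == 0:
        raise GlmError("no individuals with landscape covariates")
    return merged.reset_index(drop=True)


def run_model_1_2(
    classified: pd.DataFrame,
    landscape: pd.DataFrame,
    response: str = "mean_crop_ancestry",
) -> dict:
    """Models 1 and 2: introgression vs apple density crossed with orchard
    number (model 1) or orchard area (model 2).

    ``classified`` needs columns ``site_id`` and ``crop_ancestry`` (per
    individual, 1 - w); covariates are site-level. Also reports the Pearson
    correlation between orchard number and area.
    """
    merged = _join_landscape(classified, landscape)
    y = merged["crop_ancestry"].to_numpy(dtype=float)
    density = merged["apple_density"].to_numpy(dtype=float)
    out = {}
    for model, covariate in (("model_1", "n_orchards"), ("model_2", "orchard_area")):
        cov = merged[covariate].to_numpy(dtype=float)
        blocks = [
            ("apple_density", density),
            (covariate, cov),
            (f"{covariate}*apple_density", density * cov),
        ]
        out[model] = sequential_anova(y, blocks, response=f"crop_ancestry ({response})")
    out["covariate_correlation"] = float(
        np.corrcoef(merged["n_orchards"], merged["orchard_area"])[0, 1]
    )
    out["n_individuals"] = len(merged)
    return out


def visitor_summary(visitors: pd.DataFrame) -> pd.DataFrame:
    """Observation and distinct-taxon bookkeeping per management class."""
    rows = []
    for mclass, sub in visitors.groupby("management_class", sort=True):
        rows.append(
            {
                "management_class": mclass,
                "n_observations": len(sub),
                "n_taxa": sub["taxon_id"].nunique(),
                "n_orders": sub["insect_order"].nunique(),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["total_observations"] = int(len(visitors))
    out.attrs["total_taxa"] = int(visitors["taxon_id"].nunique())
    return out


def run_model_3(visitors: pd.DataFrame, granularity: str) -> pd.DataFrame:
    """Model 3: visitor diversity vs management intensity, controlling for
    insect order.

    ``granularity`` is required (no silent default): "taxa" fits the distinct-
    taxon count on one row per order x management-class cell; "observations"
    fits one row per observation record carrying its cell's distinct-taxon
    count (observation-level degrees of freedom).
    """
    import warnings

    if granularity not in ("taxa", "observations"):
        raise ValueError("granularity must be 'taxa' or 'observations'")
    cells = (
        visitors.groupby(["insect_order", "management_class"], sort=True)
        .agg(n_taxa=("taxon_id", "nunique"), n_observations=("record_id", "size"))
        .reset_index()
    )
    if granularity == "taxa":
        rows = cells
    else:
        rows = cells.loc[cells.index.repeat(cells["n_observations"])].reset_index(drop=True)
    orders = [o for o in INSECT_ORDERS if o in set(rows["insect_order"])]
    y = rows["n_taxa"].to_numpy(dtype=float)
    intensive = (rows["management_class"] == "intensive").to_numpy(dtype=float)
    blocks = [("management_class[intensive]", intensive)]
    if len(orders) > 1:
        dummies = np.column_stack(
            [(rows["insect_order"] == o).to_numpy(dtype=float) for o in orders[1:]]
        )
        blocks.append(("insect_order", dummies))
    else:
        warnings.warn("single insect order present; order term dropped", stacklevel=2)
    out = sequential_anova(y, blocks, response=f"visitor diversity ({granularity})")
    out.attrs["granularity"] = granularity
    out.attrs["cells"] = cells
    return out
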