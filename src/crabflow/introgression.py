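"""Threshold classification of crop-wild admixture and introgression rates.

Individuals sampled as wild are classified from their cumulative membership w
in the wild clusters: pure wild (w > 0.9), misidentified crop (w < 0.1), hybrid
otherwise (boundary values fall to hybrid). Group-level introgression is
reported in two variants because "proportion admixture" is ambiguous:
``hybrid_fraction`` and ``mean_crop_ancestry``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CATEGORIES = ("pure_wild", "hybrid", "misidentified_crop")


def cumulative_wild_membership(Q, wild_cluster_ids) -> np.ndarray:
    """w_i = sum of individual i's memberships over the wild clusters.

    ``Q`` is (N, K); ``wild_cluster_ids`` are column indices. The complement is
    treated as the crop pool, so crop membership is 1 - w.
    """
    Q = np.asarray(Q, dtype=float)
    wild = list(wild_cluster_ids)
    if any(k < 0 or k >= Q.shape[1] for k in wild):
        raise ValueError("wild cluster index out of range")
    if len(set(wild)) != len(wild):
        raise ValueError("duplicate wild cluster index")
    if not wild:
        return np.zeros(Q.shape[0])
    return Q[:, wild].sum(axis=1)


def classify_individuals(
    w, pure_threshold: float = 0.9, crop_threshold: float = 0.1
) -> np.ndarray:
    """Categorize each individual from its cumulative wild membership.

    pure_wild iff w > pure_threshold (strict); misidentified_crop iff
    w < crop_threshold (strict); hybrid for crop_threshold <= w <=
    pure_threshold (both boundaries inclusive to hybrid, by convention).
    """
    if crop_threshold >= pure_threshold:
        raise ValueError("crop_threshold must be below pure_threshold")
    w = np.asarray(w, dtype=float)
    if ((w < -1e-9) | (w > 1 + 1e-9)).any():
        raise ValueError("membership outside [0, 1]")
    out = np.full(w.shape, "hybrid", dtype=object)
    out[w > pure_threshold] = "pure_wild"
    out[w < crop_threshold] = "misidentified_crop"
    return out


@dataclass
class IntrogressionClassification:
    table: pd.DataFrame  # individual_id, w, category (+ grouping columns)

    def counts(self) -> pd.Series:
        return self.table["category"].value_counts().reindex(CATEGORIES, fill_value=0)


def classification_table(
    individual_ids, w, categories, groups: pd.DataFrame | None = None
) -> IntrogressionClassification:
    tab = pd.DataFrame(
        {"individual_id": list(individual_ids), "w": np.asarray(w, dtype=float),
         "category": categories}
    )
    if groups is not None:
        tab = tab.join(groups.reset_index(drop=True))
    return IntrogressionClassification(tab)


def introgression_rate(cls: IntrogressionClassification, group_by: str | None = None) -> pd.DataFrame:
    """Per-group crop-to-wild introgression rates, both variants.

    - ``hybrid_fraction``: n_hybrid / n_non_misidentified
    - ``hybrid_fraction_total``: n_hybrid / n_total (misidentified included)
    - ``mean_crop_ancestry``: mean(1 - w) over non-misidentified individuals
    """
    tab = cls.table
    if group_by is None:
        groups = [("all", tab)]
    else:
        if group_by not in tab.columns:
            raise ValueError(f"unknown grouping column {group_by!r}")
        groups = list(tab.groupby(group_by, sort=True))
    rows = []
    for key, sub in groups:
        n_total = len(sub)
        keep = sub[sub["category"] != "misidentified_crop"]
        n_hyb = int((sub["category"] == "hybrid").sum())
        n_mis = n_total - len(keep)
        rows.append(
            {
                "group": key,
                "n_total": n_total,
                "n_hybrids": n_hyb,
                "n_misidentified": n_mis,
                "hybrid_fraction": n_hyb / len(keep) if len(keep) else np.nan,
                "hybrid_fraction_total": n_hyb / n_total if n_total else np.nan,
                "mean_crop_ancestry": float((1.0 - keep["w"]).mean()) if len(keep) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def assign_wild_populations(Q_wild, threshold: float = 0.55, cluster_names=None) -> pd.DataFrame:
    """Assign each (nonintrogressed) individual to its argmax wild cluster when
    that membership strictly exceeds ``threshold``, else "unassigned"."""
    Q_wild = np.asarray(Q_wild, dtype=float)
    K = Q_wild.shape[1]
    names = list(cluster_names) if cluster_names is not None else [
        f"pop_{k + 1}" for k in range(K)
    ]
    best = Q_wild.argmax(axis=1)
    best_q = Q_wild[np.arange(len(Q_wild)), best]
    assigned = np.where(
        best_q > threshold, np.array(names, dtype=object)[best], "unassigned"
    )
    return pd.DataFrame(
        {"population": assigned, "max_membership": best_q, "threshold": threshold}
    )


def infer_crop_clusters(Q, species_labels) -> list[int]:
    """Identify crop-pool cluster columns from a-priori species labels: a
    cluster is 'crop' when its mean membership among crop-labelled individuals
    exceeds its mean among wild-labelled ones."""
    Q = np.asarray(Q, dtype=float)
    labels = np.asarray(species_labels)
    crop = labels == "crop"
    wild = labels == "wild"
    if not crop.any() or not wild.any():
        raise ValueError("need both crop- and wild-labelled individuals")
    crop_mean = Q[crop].mean(axis=0)
    wild_mean = Q[wild].mean(axis=0)
    out = [int(k) for k in np.nonzero(crop_mean > wild_mean)[0]]
    if not out or len(out) == Q.shape[1]:
        raise ValueError("could not separate crop from wild clusters")
    return out
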