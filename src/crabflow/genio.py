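"""Genotype, metadata, and covariate table I/O.

Diploid multilocus genotypes are carried in :class:`GenotypeMatrix`, read and
written as GENEPOP text files (2- or 3-digit allele encoding, ``0`` = missing).
Per-individual metadata (site, a-priori species label, coordinates) is joined
from a CSV; landscape and flower-visitor tables are plain CSV with controlled
vocabularies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

SPECIES_LABELS = ("wild", "crop", "unknown")
INSECT_ORDERS = (
    "Hymenoptera",
    "Diptera",
    "Coleoptera",
    "Lepidoptera",
    "Hemiptera",
    "Neuroptera",
)
MANAGEMENT_CLASSES = ("intensive", "extensive")

METADATA_COLUMNS = ("site_id", "species_label", "latitude", "longitude")


class GenepopParseError(ValueError):
    """GENEPOP syntax error, carrying the 1-based offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def _default_metadata(individual_ids) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site_id": pd.Series(["unknown"] * len(individual_ids), dtype=object),
            "species_label": pd.Series(["unknown"] * len(individual_ids), dtype=object),
            "latitude": np.full(len(individual_ids), np.nan),
            "longitude": np.full(len(individual_ids), np.nan),
        },
        index=pd.Index(individual_ids, name="individual_id"),
    )


@dataclass
class GenotypeMatrix:
    """Diploid genotypes for N individuals at L codominant loci.

    ``calls`` has shape (N, L, 2) with positive integer allele codes; a missing
    call is stored as ``(0, 0)`` (GENEPOP convention). Pairs are kept
    order-normalized ``(low, high)``.
    """

    individual_ids: list[str]
    locus_ids: list[str]
    calls: np.ndarray
    metadata: pd.DataFrame | None = None

    def __post_init__(self):
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.locus_ids = [str(l) for l in self.locus_ids]
        self.calls = np.asarray(self.calls, dtype=np.int32)
        if self.calls.shape != (len(self.individual_ids), len(self.locus_ids), 2):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.individual_ids)} individuals x {len(self.locus_ids)} loci"
            )
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("duplicate individual ids")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValueError("duplicate locus ids")
        if (self.calls < 0).any():
            raise ValueError("negative allele codes")
        # a half-missing call is treated as fully missing
        half = (self.calls == 0).any(axis=2) & (self.calls != 0).any(axis=2)
        if half.any():
            self.calls = self.calls.copy()
            self.calls[half] = 0
        self.calls = np.sort(self.calls, axis=2)
        if self.metadata is None:
            self.metadata = _default_metadata(self.individual_ids)
        else:
            self.metadata = self.metadata.reindex(self.individual_ids)
            for col in METADATA_COLUMNS:
                if col not in self.metadata.columns:
                    self.metadata[col] = (
                        np.nan if col in ("latitude", "longitude") else "unknown"
                    )

    # -- basic accessors ---------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def missing_mask(self) -> np.ndarray:
        """Boolean (N, L): True where the diploid call is missing."""
        return self.calls[:, :, 0] == 0

    def missing_fraction(self) -> np.ndarray:
        """Per-individual fraction of missing diploid calls."""
        if self.n_loci == 0:
            return np.zeros(self.n_individuals)
        return self.missing_mask().mean(axis=1)

    def subset_individuals(self, keep) -> "GenotypeMatrix":
        """Return a copy restricted to individuals in ``keep`` (ids or indices)."""
        if len(keep) and isinstance(next(iter(keep)), str):
            index = {iid: i for i, iid in enumerate(self.individual_ids)}
            idx = [index[k] for k in keep]
        else:
            idx = list(keep)
        ids = [self.individual_ids[i] for i in idx]
        return GenotypeMatrix(
            ids, list(self.locus_ids), self.calls[idx], self.metadata.loc[ids].copy()
        )

    def sites(self) -> pd.Series:
        return self.metadata["site_id"]

    def coordinates(self) -> np.ndarray:
        """(N, 2) array of (latitude, longitude)."""
        return self.metadata[["latitude", "longitude"]].to_numpy(dtype=float)

    def __eq__(self, other):
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.individual_ids == other.individual_ids
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.calls, other.calls)
        )


# -- GENEPOP ---------------------------------------------------------------


def read_genepop(path) -> GenotypeMatrix:
    """Parse a GENEPOP file.

    Accepts comma- or newline-separated locus headers and 2- or 3-digit allele
    encoding (auto-detected, mixing widths is an error). POP block index is
    recorded as ``site_id`` ("pop1", "pop2", ...) unless metadata later
    overrides it.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise GenepopParseError("empty file", 1)

    locus_ids: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        chunk = lines[i].strip()
        if chunk:
            locus_ids.extend(s.strip() for s in chunk.split(",") if s.strip())
        i += 1

    individual_ids: list[str] = []
    site_of: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    digit_width: int | None = None
    pop_index = 0
    pop_size = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if line.upper() == "POP":
            if pop_index > 0 and pop_size == 0:
                raise GenepopParseError("empty POP block", i)
            pop_index += 1
            pop_size = 0
            i += 1
            continue
        if pop_index == 0:
            raise GenepopParseError("individual record before first POP", i + 1)
        if "," not in line:
            raise GenepopParseError("expected 'name , genotypes'", i + 1)
        name, _, geno = line.partition(",")
        tokens = geno.split()
        if locus_ids and len(tokens) != len(locus_ids):
            raise GenepopParseError(
                f"{len(tokens)} genotype fields for {len(locus_ids)} loci", i + 1
            )
        calls = []
        for tok in tokens:
            if len(tok) not in (4, 6) or not tok.isdigit():
                raise GenepopParseError(f"bad genotype field {tok!r}", i + 1)
            w = len(tok) // 2
            if digit_width is None:
                digit_width = w
            elif digit_width != w:
                raise GenepopParseError(
                    f"mixed allele digit widths ({digit_width} then {w})", i + 1
                )
            a1, a2 = int(tok[:w]), int(tok[w:])
            if a1 == 0 or a2 == 0:
                a1 = a2 = 0
            calls.append((min(a1, a2), max(a1, a2)))
        individual_ids.append(name.strip())
        site_of.append(f"pop{pop_index}")
        rows.append(calls)
        pop_size += 1
        i += 1

    if pop_index > 0 and pop_size == 0:
        raise GenepopParseError("empty POP block", len(lines))
    calls_arr = (
        np.array(rows, dtype=np.int32)
        if rows
        else np.zeros((0, len(locus_ids), 2), dtype=np.int32)
    )
    meta = _default_metadata(individual_ids)
    meta["site_id"] = site_of
    return GenotypeMatrix(individual_ids, locus_ids, calls_arr, meta)


def write_genepop(G: GenotypeMatrix, path, digit_width: int = 3, title: str = "crabflow export"):
    """Write ``G`` in GENEPOP format; missing calls become all-zero fields.

    A new POP block starts whenever ``site_id`` changes along the input order,
    so site-contiguous matrices round-trip their block structure.
    """
    limit = 10 ** digit_width
    over = np.nonzero((G.calls >= limit).any(axis=(0, 2)))[0]
    if over.size:
        raise ValueError(
            f"allele code exceeds digit width {digit_width} at locus "
            f"{G.locus_ids[over[0]]}"
        )
    sites = list(G.metadata["site_id"].fillna("unknown"))
    out = [title]
    out.extend(G.locus_ids)
    prev_site = object()
    for i, iid in enumerate(G.individual_ids):
        if sites[i] != prev_site:
            out.append("POP")
            prev_site = sites[i]
        fields = [
            f"{a1:0{digit_width}d}{a2:0{digit_width}d}" for a1, a2 in G.calls[i]
        ]
        out.append(f"{iid} , " + " ".join(fields))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(out) + "\n")


# -- metadata / tables -----------------------------------------------------


def read_metadata(G: GenotypeMatrix, path) -> GenotypeMatrix:
    """Left-join a metadata CSV (individual_id, site_id, species_label, latitude,
    longitude) onto ``G``; unmatched genotype ids keep label "unknown" and raise
    a warning."""
    meta = pd.read_csv(path, dtype={"individual_id": str, "site_id": str})
    if "individual_id" not in meta.columns:
        raise ValueError("metadata CSV needs an 'individual_id' column")
    if meta["individual_id"].duplicated().any():
        dup = meta.loc[meta["individual_id"].duplicated(), "individual_id"].iloc[0]
        raise ValueError(f"duplicate individual id in metadata: {dup}")
    meta = meta.set_index("individual_id")
    if "latitude" in meta.columns and (meta["latitude"].abs() > 90).any():
        raise ValueError("latitude out of range [-90, 90]")
    if "longitude" in meta.columns and (meta["longitude"].abs() > 180).any():
        raise ValueError("longitude out of range [-180, 180]")
    if "species_label" in meta.columns:
        bad = set(meta["species_label"].dropna()) - set(SPECIES_LABELS)
        if bad:
            raise ValueError(f"unknown species labels: {sorted(bad)}")

    joined = G.metadata.copy()
    matched = meta.index.intersection(joined.index)
    unmatched = [i for i in G.individual_ids if i not in set(meta.index)]
    for col in METADATA_COLUMNS:
        if col in meta.columns:
            joined.loc[matched, col] = meta.loc[matched, col]
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} genotype id(s) missing from metadata "
            f"(species_label left 'unknown'): {unmatched[:5]}",
            stacklevel=2,
        )
        joined.loc[unmatched, "species_label"] = "unknown"
    return replace(G, metadata=joined)


def read_landscape(path) -> pd.DataFrame:
    tab = pd.read_csv(path, dtype={"site_id": str})
    required = {"site_id", "apple_density", "n_orchards", "orchard_area", "management_class"}
    missing = required - set(tab.columns)
    if missing:
        raise ValueError(f"landscape CSV missing columns {sorted(missing)}")
    if tab["site_id"].duplicated().any():
        raise ValueError("duplicate site_id in landscape table")
    for col in ("apple_density", "n_orchards", "orchard_area"):
        if (tab[col] < 0).any():
            raise ValueError(f"negative values in landscape column {col}")
    bad = set(tab["management_class"]) - set(MANAGEMENT_CLASSES)
    if bad:
        raise ValueError(f"unknown management classes: {sorted(bad)}")
    return tab


def read_visitors(path) -> pd.DataFrame:
    tab = pd.read_csv(path, dtype=str)
    required = {"record_id", "taxon_id", "insect_order", "management_class"}
    missing = required - set(tab.columns)
    if missing:
        raise ValueError(f"visitor CSV missing columns {sorted(missing)}")
    bad = set(tab["insect_order"]) - set(INSECT_ORDERS)
    if bad:
        raise ValueError(f"unknown insect orders: {sorted(bad)}")
    bad = set(tab["management_class"]) - set(MANAGEMENT_CLASSES)
    if bad:
        raise ValueError(f"unknown management classes: {sorted(bad)}")
    return tab


# -- filtering ---------------------------------------------------------------


def filter_missingness(G: GenotypeMatrix, max_missing: float = 0.20):
    """Drop individuals whose missing-call fraction is >= ``max_missing``
    (strictly-below-threshold individuals are retained). Never removes loci.

    Returns ``(filtered, removed_ids)``.
    """
    frac = G.missing_fraction()
    keep = frac < max_missing if max_missing < 1.0 else np.ones(len(frac), bool)
    removed = [iid for iid, k in zip(G.individual_ids, keep) if not k]
    return G.subset_individuals(np.nonzero(keep)[0]), removed
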