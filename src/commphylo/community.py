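"""Community matrix, trait table and stem table containers, file readers,
and the rarefaction step that standardizes plots to a common stem count."""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "CommunityError",
    "CommunityMatrix",
    "TraitTable",
    "StemTable",
    "read_community_table",
    "read_trait_table",
    "read_stem_table",
    "rarefy_counts",
    "default_rarefaction_target",
    "normalize_name",
    "match_tree_names",
]

METADATA_COLUMNS = ("forest_type", "stratum", "area_m2")


class CommunityError(ValueError):
    """Invalid community matrix, metadata, trait or stem input."""


def normalize_name(name: str) -> str:
    """Trim and collapse space/underscore variants of a species name."""
    return re.sub(r"[\s_]+", "_", str(name).strip())


@dataclass
class CommunityMatrix:
    """Plot-by-species abundance counts with per-plot metadata.

    ``counts`` is an integer DataFrame (plots as rows, species as columns);
    ``metadata`` is indexed by plot id with columns ``forest_type``,
    ``stratum`` and ``area_m2``.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            bad = [
                (p, s)
                for p in self.counts.index
                for s in self.counts.columns
                if self.counts.at[p, s] < 0
            ]
            raise CommunityError(f"negative abundances at {bad[:10]}")
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise CommunityError(f"duplicate plot ids: {dups}")
        missing_meta = [p for p in self.counts.index if p not in self.metadata.index]
        if missing_meta:
            raise CommunityError(f"plots missing from metadata: {missing_meta}")
        for col in METADATA_COLUMNS:
            if col not in self.metadata.columns:
                raise CommunityError(f"metadata lacks required column {col!r}")
        self.metadata = self.metadata.loc[self.counts.index]

    # -- accessors --------------------------------------------------------

    @property
    def plots(self) -> list[str]:
        return list(self.counts.index)

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)

    def plot_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def richness(self) -> pd.Series:
        return (self.counts > 0).sum(axis=1)

    def species_set(self, plot: str) -> list[str]:
        row = self.counts.loc[plot]
        return list(row.index[row > 0])

    def subset_stratum(self, stratum: str) -> "CommunityMatrix":
        keep = self.metadata.index[self.metadata["stratum"] == stratum]
        if len(keep) == 0:
            raise CommunityError(f"no plots in stratum {stratum!r}")
        counts = self.counts.loc[keep]
        counts = counts.loc[:, counts.sum(axis=0) > 0]
        return CommunityMatrix(counts, self.metadata.loc[keep])

    def pooled_counts(self, group_by: str) -> pd.DataFrame:
        """Summed abundances per group (``plot`` or a metadata column)."""
        if group_by == "plot":
            return self.counts.copy()
        if group_by not in self.metadata.columns:
            raise CommunityError(f"unknown grouping column {group_by!r}")
        return self.counts.groupby(self.metadata[group_by]).sum()

    def write(self, counts_path, metadata_path) -> None:
        self.counts.to_csv(counts_path, index_label="plot")
        self.metadata.to_csv(metadata_path, index_label="plot")


@dataclass
class TraitTable:
    """Species wood densities (g/cm³) with the resolution actually used.

    ``table`` is indexed by species with columns ``wood_density`` and
    ``resolution`` (``species`` or ``genus-mean``).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        wd = self.table["wood_density"].astype(float)
        bad = self.table.index[(wd <= 0) | (wd >= 1.5) | ~np.isfinite(wd)]
        if len(bad):
            raise CommunityError(
                f"wood densities outside (0, 1.5) for: {list(bad)[:10]}"
            )
        ok = self.table["resolution"].isin(["species", "genus-mean"])
        if not ok.all():
            raise CommunityError(
                f"unknown resolution flags: "
                f"{self.table['resolution'][~ok].unique().tolist()}"
            )

    def density(self, species: str) -> float:
        return float(self.table.at[species, "wood_density"])

    def __contains__(self, species: str) -> bool:
        return species in self.table.index

    def write(self, path) -> None:
        self.table.to_csv(path, index_label="species")

    @classmethod
    def from_measurements(
        cls,
        measured: Mapping[str, float],
        species: list[str],
        genus_of: Mapping[str, str] | None = None,
    ) -> "TraitTable":
        """Resolve densities for *species*, falling back to the genus mean.

        A species absent from *measured* receives the mean density of its
        congeners that do have measurements, flagged ``genus-mean``.  The
        genus defaults to the substring before the first underscore.
        """
        if genus_of is None:
            genus_of = {s: s.split("_", 1)[0] for s in species}
        genus_pool: dict[str, list[float]] = {}
        for s, v in measured.items():
            genus_pool.setdefault(genus_of.get(s, s.split("_", 1)[0]), []).append(v)

        rows, unresolved = [], []
        for s in species:
            if s in measured:
                rows.append((s, float(measured[s]), "species"))
            else:
                pool = genus_pool.get(genus_of.get(s, ""), [])
                if pool:
                    rows.append((s, float(np.mean(pool)), "genus-mean"))
                else:
                    unresolved.append(s)
        if unresolved:
            raise CommunityError(
                f"no species- or genus-level wood density for: {unresolved}"
            )
        table = pd.DataFrame(
            rows, columns=["species", "wood_density", "resolution"]
        ).set_index("species")
        return cls(table)


@dataclass
class StemTable:
    """Per-stem records: plot, species, dbh (cm)."""

    table: pd.DataFrame  # columns: plot, species, dbh

    def __post_init__(self) -> None:
        for col in ("plot", "species", "dbh"):
            if col not in self.table.columns:
                raise CommunityError(f"stem table lacks column {col!r}")
        dbh = self.table["dbh"].astype(float)
        if (dbh <= 0).any() or not np.isfinite(dbh).all():
            raise CommunityError("stem dbh values must be positive and finite")

    def for_plot(self, plot: str) -> pd.DataFrame:
        return self.table[self.table["plot"] == plot]

    def write(self, path) -> None:
        self.table.to_csv(path, index=False)


# -- readers ---------------------------------------------------------------


def _read_delimited(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", **kwargs)


def read_community_table(path, metadata_path) -> CommunityMatrix:
    """Read a plot × species count table and its plot metadata.

    Counts must be non-negative integers; every plot in the matrix must have
    a metadata row.  Violations are reported with the offending plot /
    species / value.
    """
    raw = _read_delimited(path, index_col=0)
    raw.index = raw.index.astype(str)

    if raw.index.duplicated().any():
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise CommunityError(f"duplicate plot ids: {dups}")

    offenders = []
    for plot in raw.index:
        for sp in raw.columns:
            v = raw.at[plot, sp]
            try:
                fv = float(v)
            except (TypeError, ValueError):
                offenders.append((plot, sp, v))
                continue
            if not float(fv).is_integer():
                offenders.append((plot, sp, v))
    if offenders:
        raise CommunityError(
            f"non-integer abundances (plot, species, value): {offenders[:10]}"
        )
    counts = raw.astype(np.int64)

    if counts.index.duplicated().any():
        dups = counts.index[counts.index.duplicated()].unique().tolist()
        raise CommunityError(f"duplicate plot ids: {dups}")

    meta = _read_delimited(metadata_path)
    if "plot" not in meta.columns:
        raise CommunityError("metadata table lacks a 'plot' column")
    meta["plot"] = meta["plot"].astype(str)
    if meta["plot"].duplicated().any():
        raise CommunityError(
            f"duplicate metadata rows for plots: "
            f"{meta['plot'][meta['plot'].duplicated()].tolist()}"
        )
    meta = meta.set_index("plot")
    missing = [p for p in counts.index if p not in meta.index]
    if missing:
        raise CommunityError(f"plots missing from metadata: {missing}")
    extra = [p for p in meta.index if p not in counts.index]
    if extra:
        log.warning("metadata rows for plots absent from matrix: %s", extra)

    return CommunityMatrix(counts, meta.loc[counts.index])


def read_trait_table(path) -> TraitTable:
    df = _read_delimited(path)
    if "species" not in df.columns:
        raise CommunityError("trait table lacks a 'species' column")
    return TraitTable(df.set_index("species"))


def read_stem_table(path) -> StemTable:
    return StemTable(_read_delimited(path))


# -- name matching ---------------------------------------------------------


def match_tree_names(
    comm: CommunityMatrix, tip_labels: list[str]
) -> tuple[CommunityMatrix, list[str]]:
    """Align matrix species to tree tips; drop and report the unmatched.

    Matching is exact after trimming and underscore/space normalization.
    Returns the aligned matrix (columns renamed to the tree's spelling) and
    the list of dropped species names.
    """
    tip_norm = {normalize_name(t): t for t in tip_labels}
    rename, dropped = {}, []
    for sp in comm.species:
        key = normalize_name(sp)
        if key in tip_norm:
            rename[sp] = tip_norm[key]
        else:
            dropped.append(sp)
    if dropped:
        log.warning(
            "%d species absent from the tree were dropped: %s",
            len(dropped), dropped,
        )
    counts = comm.counts.drop(columns=dropped).rename(columns=rename)
    if counts.shape[1] == 0:
        raise CommunityError("no species shared between matrix and tree")
    return CommunityMatrix(counts, comm.metadata), dropped


# -- rarefaction -----------------------------------------------------------


def default_rarefaction_target(comm: CommunityMatrix) -> int:
    """Stem count of the plot with the fewest stems."""
    totals = comm.plot_totals()
    if len(totals) == 0:
        raise CommunityError("empty community matrix")
    return int(totals.min())


def rarefy_counts(
    comm: CommunityMatrix,
    target: int,
    seed: int | np.random.Generator | None = None,
) -> CommunityMatrix:
    """Subsample every plot to exactly *target* stems without replacement.

    Each plot's rarefied counts are a multivariate-hypergeometric draw from
    its observed counts, so no absent species can appear and a plot already
    at *target* stems is returned unchanged.
    """
    if target < 1:
        raise CommunityError(f"rarefaction target must be >= 1, got {target}")
    totals = comm.plot_totals()
    limiting = totals.idxmin()
    if target > totals[limiting]:
        raise CommunityError(
            f"rarefaction target {target} exceeds the smallest plot total "
            f"({totals[limiting]} stems in plot {limiting!r})"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.empty_like(comm.counts.to_numpy())
    for r, (_, row) in enumerate(comm.counts.iterrows()):
        out[r] = rng.multivariate_hypergeometric(row.to_numpy(), target)
    counts = pd.DataFrame(out, index=comm.counts.index, columns=comm.counts.columns)
    return CommunityMatrix(counts, comm.metadata)
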