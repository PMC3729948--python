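"""Per-plot phylogenetic alpha-diversity.

Implements Faith's PD (rooted convention), the Helmus family of indices
(PSV, PSR, PSE), the abundance-weighted raw distance statistics MPD and
MNTD, and basal-area-weighted plot wood density.  Metrics that are
undefined for a plot (fewer than two species) raise
:class:`UndefinedMetricError`; the table builder converts those into
missing values with a reason code rather than silent zeros.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .community import CommunityMatrix, StemTable, TraitTable, rarefy_counts
from .phylo import Phylogeny, PhyloError, cophenetic_distances, phylo_correlation

__all__ = [
    "UndefinedMetricError",
    "faith_pd",
    "psv",
    "pse",
    "psr",
    "mpd_abund",
    "mntd_abund",
    "plot_wood_density",
    "plot_metrics_table",
]


class UndefinedMetricError(ValueError):
    """Metric undefined for the given input (e.g. a monospecific plot)."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


def faith_pd(tree: Phylogeny, species_set: Iterable[str], rooted: bool = True) -> float:
    """Faith's phylogenetic diversity of a species set (Myr).

    Sum of branch lengths of the minimal subtree connecting the species;
    by default the subtree includes the path down to the root, so a single
    species contributes its full tip depth.  With ``rooted=False`` branches
    above the set's MRCA are excluded.
    """
    wanted = set(species_set)
    if not wanted:
        raise UndefinedMetricError("empty species set")
    tips = {t: n for t, n in zip(tree.tip_labels, tree.dendropy_tree.leaf_node_iter())}
    unknown = sorted(wanted - set(tips))
    if unknown:
        raise PhyloError(f"species not in tree: {unknown}")

    root = tree.root
    visited = set()
    total = 0.0
    for sp in wanted:
        node = tips[sp]
        while node is not root and node not in visited:
            if node.edge.length is None:
                raise PhyloError(f"missing branch length on path above {sp!r}")
            total += node.edge.length
            visited.add(node)
            node = node.parent_node

    if not rooted:
        # subtract the root-to-MRCA path
        depths = tree.node_depths()
        paths = []
        for sp in wanted:
            chain, node = [], tips[sp]
            while node is not None:
                chain.append(node)
                node = node.parent_node
            paths.append(chain[::-1])
        mrca = root
        for level in zip(*paths):
            if all(n is level[0] for n in level):
                mrca = level[0]
            else:
                break
        total -= depths[mrca]
    return total


def _square(df: pd.DataFrame, species: list[str]) -> np.ndarray:
    missing = [s for s in species if s not in df.index]
    if missing:
        raise PhyloError(f"species not in matrix: {missing}")
    return df.loc[species, species].to_numpy(dtype=float)


def psv(corr: pd.DataFrame, species_set: Iterable[str]) -> float:
    """Phylogenetic species variability: 1 − mean off-diagonal correlation."""
    species = list(species_set)
    n = len(species)
    if n < 2:
        raise UndefinedMetricError("PSV undefined for fewer than 2 species")
    C = _square(corr, species)
    return float(1.0 - (C.sum() - np.trace(C)) / (n * (n - 1)))


def pse(
    corr: pd.DataFrame,
    abundances: Mapping[str, int] | pd.Series,
    method: str = "helmus",
) -> float:
    """Phylogenetic species evenness: abundance-weighted PSV.

    ``helmus`` (default) is the published definition, as implemented in
    picante: PSE = Σ_{i≠j} M_i M_j (1 − c_ij) / (N²·(S−1)/S), which
    penalizes both phylogenetic clumping and abundance unevenness (a star
    phylogeny with uneven abundances scores below 1).  ``pairs`` is the
    abundance-weighted mean correlation over heterospecific individual
    pairs subtracted from 1, i.e. Σ M_i M_j (1 − c_ij) / (N² − ΣM_i²),
    which measures relatedness only.  Both reduce to PSV when abundances
    are equal.
    """
    ab = pd.Series(abundances, dtype=float)
    ab = ab[ab > 0]
    if len(ab) < 2:
        raise UndefinedMetricError("PSE undefined for fewer than 2 species")
    species = list(ab.index)
    C = _square(corr, species)
    m = ab.to_numpy()
    N = m.sum()
    hetero_weight = N**2 - m @ m               # sum_{i != j} m_i m_j
    hetero_corr = m @ C @ m - m @ m            # sum_{i != j} m_i m_j c_ij
    num = hetero_weight - hetero_corr          # sum_{i != j} m_i m_j (1 - c_ij)
    if method == "helmus":
        den = N**2 * (len(m) - 1) / len(m)
    elif method == "pairs":
        den = hetero_weight
    else:
        raise ValueError(f"method must be 'helmus' or 'pairs', got {method!r}")
    return float(num / den)


def psr(psv_value: float, richness: int) -> float:
    """Phylogenetic species richness: S × PSV (effective species)."""
    if richness < 2:
        raise UndefinedMetricError("PSR undefined for fewer than 2 species")
    return float(richness * psv_value)


def mpd_abund(
    coph: pd.DataFrame,
    abundances: Mapping[str, int] | pd.Series,
    include_conspecific: bool = False,
) -> float:
    """Abundance-weighted mean pairwise phylogenetic distance (Myr).

    By default averages over heterospecific pairs only, each species pair
    weighted by the product of its abundances.  ``include_conspecific=True``
    also counts zero-distance conspecific pairs (picante's convention for
    abundance-weighted MPD), which shrinks the value toward zero.
    """
    ab = pd.Series(abundances, dtype=float)
    ab = ab[ab > 0]
    if len(ab) < 2:
        raise UndefinedMetricError("MPD undefined for fewer than 2 species")
    D = _square(coph, list(ab.index))
    m = ab.to_numpy()
    num = m @ D @ m                  # d_ii = 0, so conspecific pairs drop out
    den = m.sum() ** 2
    if not include_conspecific:
        den -= m @ m
    return float(num / den)


def mntd_abund(coph: pd.DataFrame, abundances: Mapping[str, int] | pd.Series) -> float:
    """Abundance-weighted mean nearest-taxon distance (Myr).

    Each individual contributes the distance to its nearest heterospecific
    relative; individuals are weighted by species abundance.
    """
    ab = pd.Series(abundances, dtype=float)
    ab = ab[ab > 0]
    if len(ab) < 2:
        raise UndefinedMetricError("MNTD undefined for fewer than 2 species")
    D = _square(coph, list(ab.index)).copy()
    np.fill_diagonal(D, np.inf)
    nn = D.min(axis=1)
    m = ab.to_numpy()
    return float((m * nn).sum() / m.sum())


def plot_wood_density(
    stems: StemTable,
    traits: TraitTable,
    plot: str,
    min_dbh: float = 5.0,
) -> float:
    """Basal-area-weighted mean wood density of one plot (g/cm³).

    Basal area per species is Σ π(dbh/2)² over its stems; only stems with
    dbh ≥ *min_dbh* (default 5 cm, the overstorey census threshold) enter
    the weighting.
    """
    sub = stems.for_plot(plot)
    sub = sub[sub["dbh"].astype(float) >= min_dbh]
    if len(sub) == 0:
        raise UndefinedMetricError(f"no stems with dbh >= {min_dbh} in plot {plot!r}")
    unresolved = sorted(set(sub["species"]) - set(traits.table.index))
    if unresolved:
        raise PhyloError(f"no wood density for species: {unresolved}")
    ba = sub.groupby("species")["dbh"].apply(
        lambda d: float((math.pi * (d.astype(float) / 2.0) ** 2).sum())
    )
    wd = np.array([traits.density(s) for s in ba.index])
    return float((ba.to_numpy() * wd).sum() / ba.sum())


def plot_metrics_table(
    tree: Phylogeny,
    comm: CommunityMatrix,
    r_draws: int = 100,
    target: int | None = None,
    seed: int | np.random.Generator | None = None,
    stems: StemTable | None = None,
    traits: TraitTable | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rarefied per-plot alpha-diversity table.

    Each of *r_draws* independent rarefaction draws (to *target* stems,
    default the smallest plot total) yields S, PD, PSV, PSR, PSE, MPD and
    MNTD per plot; wood density, which is not rarefied, is appended to the
    summary when stem and trait tables are given.

    Returns ``(long, summary)``: a tidy long table with one row per plot ×
    draw × metric (undefined values carry a reason), and the per-plot mean
    across draws in wide form.
    """
    from .community import default_rarefaction_target

    if target is None:
        target = default_rarefaction_target(comm)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    coph = cophenetic_distances(tree)
    corr = phylo_correlation(tree)

    records = []
    for draw in range(r_draws):
        rare = rarefy_counts(comm, target, rng)
        for plot in rare.plots:
            row = rare.counts.loc[plot]
            ab = row[row > 0]
            sp = list(ab.index)
            S = len(sp)
            values: dict[str, float] = {"S": float(S)}
            reason = None
            try:
                values["PD"] = faith_pd(tree, sp)
                p = psv(corr, sp)
                values["PSV"] = p
                values["PSR"] = psr(p, S)
                values["PSE"] = pse(corr, ab)
                values["MPD"] = mpd_abund(coph, ab)
                values["MNTD"] = mntd_abund(coph, ab)
            except UndefinedMetricError as exc:
                reason = exc.reason
            for metric, value in values.items():
                records.append((plot, draw, metric, value, None))
            if reason is not None:
                for metric in ("PSV", "PSR", "PSE", "MPD", "MNTD"):
                    records.append((plot, draw, metric, np.nan, reason))

    long = pd.DataFrame(
        records, columns=["plot", "rarefaction_draw", "metric", "value", "reason"]
    )
    summary = (
        long.pivot_table(index="plot", columns="metric", values="value", aggfunc="mean")
        .reindex(comm.plots)
    )
    summary.columns.name = None

    if stems is not None and traits is not None:
        wd = {}
        for plot in comm.plots:
            try:
                wd[plot] = plot_wood_density(stems, traits, plot)
            except UndefinedMetricError:
                wd[plot] = np.nan
        summary["WD"] = pd.Series(wd)

    summary = summary.join(comm.metadata)
    return long, summary
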