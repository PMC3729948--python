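"""Synthetic phylogenies, traits and plot communities with known assembly
regimes.

The generator emulates a successional forest-plot study: 4 forest types ×
5 plots × 2 strata sampled from a shared regional species pool on a dated
pure-birth phylogeny.  Plots are assembled under one of three regimes:

* ``filtering`` — a multidimensional niche (independent Brownian-motion
  axes on the tree; 3 by default) and a per-plot optimum; species are
  sampled with weight exp(−strength · ‖trait − optimum‖²/d), so close
  relatives co-occur (phylogenetic clustering, the young-secondary
  signature).  A single axis is supported but lets convergent distant
  lineages into the niche window and weakens the clustering signal;
* ``repulsion`` — species are accepted sequentially only when their nearest
  phylogenetic distance to the already-accepted set exceeds a quantile of
  the pool's pairwise distances that rises with strength, so distant
  relatives co-occur (overdispersion, the old-secondary signature);
* ``neutral`` — a uniform draw from the pool (old-growth).

At strength 0 both structured regimes reduce exactly to the neutral draw.
Abundances are log-series distributed and assigned independently of the
phylogeny.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .community import CommunityMatrix, StemTable, TraitTable
from .phylo import AgeConstraints, Phylogeny

__all__ = [
    "ScenarioConfig",
    "simulate_tree",
    "brownian_trait",
    "niche_traits",
    "assemble_community",
    "simulate_succession_dataset",
    "SuccessionDataset",
    "make_fixture",
    "FIXTURE_EXPECTED",
]

FOREST_TYPES = ("YS", "OS", "UPOG", "OG")
REGIME_OF_TYPE = {
    "YS": "filtering",   # young secondary: environmental filtering
    "OS": "repulsion",   # old secondary: competitive repulsion
    "UPOG": "neutral",   # underplanted old growth
    "OG": "neutral",     # old growth
}


@dataclass
class ScenarioConfig:
    """Study-design parameters for the synthetic successional dataset.

    Defaults mirror the emulated design: a regional pool of 240 species,
    4 forest types × 5 plots, two strata per plot (overstorey censused at
    dbh ≥ 5 cm, understorey below), 60 overstorey and 100 understorey stems
    per 500 m² plot.
    """

    pool_size: int = 240
    birth_rate: float = 1.0
    root_age: float = 100.0          # Myr
    plots_per_type: int = 5
    overstorey_stems: int = 60
    understorey_stems: int = 100
    overstorey_richness: int = 20
    understorey_richness: int = 25
    filter_strength: float = 10.0
    repulsion_strength: float = 4.0
    niche_axes: int = 3
    logseries_theta: float = 0.95
    plot_area_m2: float = 500.0
    genus_cut_age: float = 15.0      # Myr: clades younger than this = genus
    missing_density_frac: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pool_size < 10:
            raise ValueError("pool size must be >= 10")
        if self.filter_strength < 0 or self.repulsion_strength < 0:
            raise ValueError("regime strengths must be >= 0")
        for stems, rich in (
            (self.overstorey_stems, self.overstorey_richness),
            (self.understorey_stems, self.understorey_richness),
        ):
            if stems < rich:
                raise ValueError("stems per plot must be >= plot richness")


def simulate_tree(
    n_tips: int,
    birth_rate: float = 1.0,
    seed: int | np.random.Generator | None = None,
    root_age: float | None = 100.0,
) -> Phylogeny:
    """Pure-birth (Yule) tree with *n_tips*, ultrametric and dated.

    Speciation events fall on a random lineage after Exp(k·λ) waiting times;
    after the pool reaches *n_tips* lineages one further Exp(n·λ) interval
    is appended so terminal branches have positive length.  Depths are
    rescaled so the root sits at *root_age* (Myr) unless ``root_age`` is
    None.  Tips are labelled sp0001…, internal nodes n0001… (root: "root").
    """
    if n_tips < 2:
        raise ValueError("a tree needs at least 2 tips")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    root = tree.seed_node
    birth = {root: 0.0}
    c1, c2 = dendropy.Node(), dendropy.Node()
    t = 0.0
    active = [c1, c2]
    for c in active:
        root.add_child(c)
        birth[c] = 0.0

    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        idx = int(rng.integers(k))
        parent = active.pop(idx)
        parent.edge.length = t - birth[parent]
        a, b = dendropy.Node(), dendropy.Node()
        for c in (a, b):
            parent.add_child(c)
            birth[c] = t
            active.append(c)
    t += rng.exponential(1.0 / (birth_rate * n_tips))
    for leaf in active:
        leaf.edge.length = t - birth[leaf]

    scale = 1.0 if root_age is None or t == 0 else root_age / t
    tip_i = inner_i = 0
    for node in tree.preorder_node_iter():
        if node.edge.length is not None:
            node.edge.length *= scale
        if node.is_leaf():
            tip_i += 1
            node.taxon = taxon_ns.new_taxon(f"sp{tip_i:04d}")
        elif node is root:
            node.label = "root"
        else:
            inner_i += 1
            node.label = f"n{inner_i:04d}"
    return Phylogeny(tree)


def brownian_trait(
    tree: Phylogeny,
    rate: float = 1.0,
    seed: int | np.random.Generator | None = None,
) -> pd.Series:
    """Brownian-motion trait on the tree: independent Normal(0, rate·len)
    increments along every branch, root value 0.  Returns tip values."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    value = {tree.root: 0.0}
    out = {}
    for node in tree.dendropy_tree.preorder_node_iter():
        if node is tree.root:
            continue
        length = node.edge.length or 0.0
        value[node] = value[node.parent_node] + rng.normal(0.0, np.sqrt(rate * length))
        if node.is_leaf():
            out[node.taxon.label if node.taxon else node.label] = value[node]
    return pd.Series(out, dtype=float)


def _logseries_abundances(
    rng: np.random.Generator, n_species: int, total: int, theta: float
) -> np.ndarray:
    """Allocate *total* stems to species: one each, remainder multinomial
    with log-series-distributed weights."""
    weights = stats.logser(theta).rvs(size=n_species, random_state=rng).astype(float)
    counts = np.ones(n_species, dtype=np.int64)
    rest = total - n_species
    if rest > 0:
        counts += rng.multinomial(rest, weights / weights.sum())
    return counts


def niche_traits(
    tree: Phylogeny,
    n_axes: int = 3,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Standardized multidimensional niche: *n_axes* independent Brownian
    traits on the tree, each centred and scaled to unit variance across
    tips.  Rows are tips, columns niche axes."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cols = {}
    for d in range(n_axes):
        t = brownian_trait(tree, rate=1.0, seed=rng)
        cols[f"axis{d + 1}"] = (t - t.mean()) / t.std(ddof=0)
    return pd.DataFrame(cols)


def assemble_community(
    tree: Phylogeny,
    regime: str,
    strength: float,
    richness: int,
    stems: int,
    seed: int | np.random.Generator | None = None,
    trait: pd.Series | pd.DataFrame | None = None,
    coph: pd.DataFrame | None = None,
    logseries_theta: float = 0.95,
    n_niche_axes: int = 3,
) -> pd.Series:
    """Species abundances for one plot under an assembly regime.

    Returns a Series (species → stem count) with exactly *richness* species
    and *stems* total stems.  ``trait`` (filtering; a Series for one niche
    axis or a DataFrame of axes from :func:`niche_traits`) and ``coph``
    (repulsion) may be precomputed and shared across plots.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = tree.tip_labels
    if richness > len(labels):
        raise ValueError("richness exceeds pool size")
    if stems < richness:
        raise ValueError("stems must be >= richness")

    if regime == "neutral" or strength == 0:
        chosen = list(rng.choice(labels, size=richness, replace=False))
    elif regime == "filtering":
        if trait is None:
            Z = niche_traits(tree, n_niche_axes, rng)
        elif isinstance(trait, pd.Series):
            z = (trait - trait.mean()) / trait.std(ddof=0)
            Z = z.to_frame("axis1")
        else:
            Z = trait
        Zm = Z.reindex(labels).to_numpy()
        optimum = Zm[int(rng.integers(len(labels)))]
        w = np.exp(-strength * ((Zm - optimum) ** 2).sum(axis=1) / Zm.shape[1])
        w = w / w.sum()
        chosen = list(rng.choice(labels, size=richness, replace=False, p=w))
    elif regime == "repulsion":
        if coph is None:
            from .phylo import cophenetic_distances

            coph = cophenetic_distances(tree)
        D = coph.loc[labels, labels].to_numpy()
        off = D[np.triu_indices_from(D, k=1)]
        q = strength / (1.0 + strength)
        threshold = float(np.quantile(off, q))
        chosen_idx = [int(rng.integers(len(labels)))]
        candidates = [i for i in range(len(labels)) if i != chosen_idx[0]]
        n_relaxed = 0
        while len(chosen_idx) < richness:
            rng.shuffle(candidates)
            pick = None
            for c in candidates:
                if D[c, chosen_idx].min() >= threshold:
                    pick = c
                    break
            if pick is None:
                threshold *= 0.9
                n_relaxed += 1
                continue
            chosen_idx.append(pick)
            candidates.remove(pick)
        if n_relaxed:
            warnings.warn(
                f"repulsion constraint infeasible at the requested quantile; "
                f"distance threshold relaxed {n_relaxed} time(s)",
                stacklevel=2,
            )
        chosen = [labels[i] for i in chosen_idx]
    else:
        raise ValueError(f"unknown regime {regime!r}")

    counts = _logseries_abundances(rng, richness, stems, logseries_theta)
    return pd.Series(counts, index=chosen, dtype=np.int64)


def _genus_groups(tree: Phylogeny, cut_age: float) -> dict[str, str]:
    """Assign tips to genera: maximal clades whose crown is younger than
    *cut_age* Myr (singletons form their own genus)."""
    depths = tree.node_depths()
    root_age = max(depths[l] for l in tree.dendropy_tree.leaf_node_iter())
    genus_of: dict[str, str] = {}
    gi = 0

    def tips_of(node) -> list[str]:
        return [
            (l.taxon.label if l.taxon else l.label)
            for l in (node.leaf_iter() if not node.is_leaf() else [node])
        ]

    def walk(node) -> None:
        nonlocal gi
        age = root_age - depths[node]
        if node.is_leaf() or age <= cut_age:
            gi += 1
            for t in tips_of(node):
                genus_of[t] = f"gen{gi:03d}"
            return
        for c in node.child_nodes():
            walk(c)

    walk(tree.root)
    return genus_of


@dataclass
class SuccessionDataset:
    """Complete synthetic bundle: dated tree, undated topology with its age
    file, community matrix (both strata), traits and stems."""

    tree: Phylogeny
    topology: Phylogeny            # same tree, branch lengths stripped
    ages: AgeConstraints
    community: CommunityMatrix
    traits: TraitTable
    stems: StemTable
    config: ScenarioConfig
    genus_of: dict[str, str] = field(default_factory=dict)

    def write(self, outdir) -> dict[str, str]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "tree": outdir / "tree.nwk",
            "topology": outdir / "tree_topology.nwk",
            "ages": outdir / "node_ages.tsv",
            "community": outdir / "community.csv",
            "metadata": outdir / "plots.csv",
            "traits": outdir / "traits.csv",
            "stems": outdir / "stems.csv",
        }
        self.tree.write(paths["tree"])
        self.topology.write(paths["topology"])
        self.ages.to_file(paths["ages"])
        self.community.write(paths["community"], paths["metadata"])
        self.traits.write(paths["traits"])
        self.stems.write(paths["stems"])
        return {k: str(v) for k, v in paths.items()}


def _strip_lengths(tree: Phylogeny) -> Phylogeny:
    clone = tree.copy()
    for node in clone.dendropy_tree.preorder_node_iter():
        node.edge.length = None
    return clone


def _all_node_ages(tree: Phylogeny) -> AgeConstraints:
    depths = tree.node_depths()
    root_age = max(
        depths[l] for l in tree.dendropy_tree.leaf_node_iter()
    )
    ages = {}
    for node in tree.dendropy_tree.preorder_internal_node_iter():
        if node.label:
            ages[node.label] = root_age - depths[node]
    return AgeConstraints(ages)


def simulate_succession_dataset(config: ScenarioConfig | None = None) -> SuccessionDataset:
    """Synthetic 4-type × 5-plot × 2-strata dataset with known regimes.

    Young-secondary plots assemble under filtering (clustered), old
    secondary under repulsion (overdispersed), underplanted and old growth
    neutrally — the successional gradient from clustering through
    overdispersion to random.  Wood densities carry Brownian phylogenetic
    signal, with a fraction of species-level values withheld so the
    genus-mean fallback is exercised; stem diameters are log-normal.
    """
    cfg = config or ScenarioConfig()
    rng = np.random.default_rng(cfg.seed)

    tree = simulate_tree(cfg.pool_size, cfg.birth_rate, rng, cfg.root_age)
    genus_of = _genus_groups(tree, cfg.genus_cut_age)
    # relabel tips to Genus_species form so the genus fallback has structure
    rename = {}
    for tip in tree.dendropy_tree.leaf_node_iter():
        old = tip.taxon.label
        new = f"{genus_of[old]}_{old}"
        tip.taxon.label = new
        rename[old] = new
    genus_of = {rename[t]: g for t, g in genus_of.items()}
    labels = tree.tip_labels

    from .phylo import cophenetic_distances

    trait = niche_traits(tree, cfg.niche_axes, rng)
    coph = cophenetic_distances(tree)

    rows, meta_rows = [], []
    stem_rows = []
    for ftype in FOREST_TYPES:
        regime = REGIME_OF_TYPE[ftype]
        strength = {
            "filtering": cfg.filter_strength,
            "repulsion": cfg.repulsion_strength,
            "neutral": 0.0,
        }[regime]
        for p in range(1, cfg.plots_per_type + 1):
            for stratum, stems_n, rich in (
                ("overstorey", cfg.overstorey_stems, cfg.overstorey_richness),
                ("understorey", cfg.understorey_stems, cfg.understorey_richness),
            ):
                plot_id = f"{ftype}{p:02d}_{stratum[:4]}"
                ab = assemble_community(
                    tree, regime, strength, rich, stems_n,
                    seed=rng, trait=trait, coph=coph,
                    logseries_theta=cfg.logseries_theta,
                )
                rows.append(ab.reindex(labels).fillna(0).rename(plot_id))
                meta_rows.append(
                    (plot_id, ftype, stratum, cfg.plot_area_m2)
                )
                for sp, n in ab.items():
                    if stratum == "overstorey":
                        dbh = 5.0 + rng.lognormal(1.8, 0.7, size=int(n))
                    else:
                        dbh = rng.uniform(1.0, 4.99, size=int(n))
                    stem_rows.extend((plot_id, sp, float(d)) for d in dbh)

    counts = pd.DataFrame(rows).astype(np.int64)
    metadata = pd.DataFrame(
        meta_rows, columns=["plot", "forest_type", "stratum", "area_m2"]
    ).set_index("plot")
    community = CommunityMatrix(counts, metadata)

    # wood density: bounded transform of a Brownian trait -> (0.25, 1.25)
    wd_trait = brownian_trait(tree, rate=1.0, seed=rng)
    z = (wd_trait - wd_trait.mean()) / wd_trait.std(ddof=0)
    density = 0.25 + 1.0 / (1.0 + np.exp(-z))
    measured = dict(zip(density.index, density.to_numpy()))
    # withhold species-level values where a congener can stand in, leaving
    # at least one measured species per genus
    by_genus: dict[str, list[str]] = {}
    for s in labels:
        by_genus.setdefault(genus_of[s], []).append(s)
    for members in by_genus.values():
        if len(members) < 2:
            continue
        n_drop = min(rng.binomial(len(members), cfg.missing_density_frac),
                     len(members) - 1)
        for s in rng.choice(members, size=n_drop, replace=False):
            del measured[s]
    traits = TraitTable.from_measurements(measured, labels, genus_of)

    stems = StemTable(pd.DataFrame(stem_rows, columns=["plot", "species", "dbh"]))

    return SuccessionDataset(
        tree=tree,
        topology=_strip_lengths(tree),
        ages=_all_node_ages(tree),
        community=community,
        traits=traits,
        stems=stems,
        config=cfg,
        genus_of=genus_of,
    )


# ---------------------------------------------------------------------------
# Tiny hand-checkable fixture
# ---------------------------------------------------------------------------

FIXTURE_NEWICK = "(((A:1,B:1)n1:1,C:2)n2:2,(D:3,E:3)n3:1)root;"

# Hand-derived constants for the fixture tree and plots below.
# Tip depths all 4 (ultrametric, root age 4).
# Correlations (shared depth / 4): c(A,B)=3/4, c(A,C)=c(B,C)=1/2,
#   c(D,E)=1/4, cross-root pairs 0.
# Distances: d(A,B)=2, d(A,C)=d(B,C)=4, d(D,E)=6, cross-root pairs 8.
# P1 = {A:2, B:1, C:1}; P2 = {C:1, D:2, E:1}.
FIXTURE_EXPECTED = {
    "PD_P1": 7.0,            # A1+B1+n1:1+C2+n2:2
    "PD_P2": 11.0,           # C2+n2:2+D3+E3+n3:1
    "PD_all": 14.0,          # total branch length
    "PSV_P1": 5.0 / 12.0,    # 1 - (3/4+1/2+1/2)/3
    "PSV_P2": 11.0 / 12.0,   # 1 - (0+0+1/4)/3
    # Helmus PSE: (N^2 - M'CM) / (N^2 (S-1)/S) = (16-12)/(32/3)
    "PSE_P1": 0.375,
    # pair-averaged variant: 1 - 6/10 (heterospecific pair weights, M=2,1,1)
    "PSE_P1_pairs": 0.4,
    "MPD_P1": 3.2,           # 32/10
    "MNTD_P1": 2.5,          # (2*2 + 1*2 + 1*4)/4
    "UniFrac_P1_P2": 5.0 / 7.0,  # unique 10 / (10 + shared 4)
}


def make_fixture() -> SuccessionDataset:
    """Five-species, two-plot worked example with hand-derived expected
    metric values (see :data:`FIXTURE_EXPECTED`)."""
    tree = Phylogeny.from_newick(FIXTURE_NEWICK)
    counts = pd.DataFrame(
        [[2, 1, 1, 0, 0], [0, 0, 1, 2, 1]],
        index=["P1", "P2"],
        columns=["A", "B", "C", "D", "E"],
    )
    metadata = pd.DataFrame(
        {
            "plot": ["P1", "P2"],
            "forest_type": ["YS", "OG"],
            "stratum": ["overstorey", "overstorey"],
            "area_m2": [500.0, 500.0],
        }
    ).set_index("plot")
    community = CommunityMatrix(counts, metadata)
    traits = TraitTable.from_measurements(
        {"A": 0.4, "B": 0.5, "C": 0.6, "D": 0.7, "E": 0.8},
        ["A", "B", "C", "D", "E"],
        genus_of={s: s for s in "ABCDE"},
    )
    stems = StemTable(
        pd.DataFrame(
            {
                "plot": ["P1"] * 4 + ["P2"] * 4,
                "species": ["A", "A", "B", "C", "C", "D", "D", "E"],
                "dbh": [10.0, 10.0, 20.0, 10.0, 10.0, 20.0, 10.0, 10.0],
            }
        )
    )
    return SuccessionDataset(
        tree=tree,
        topology=_strip_lengths(tree),
        ages=AgeConstraints({"root": 4.0, "n1": 1.0, "n2": 2.0, "n3": 3.0}),
        community=community,
        traits=traits,
        stems=stems,
        config=ScenarioConfig(),
        genus_of={s: s for s in "ABCDE"},
    )
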