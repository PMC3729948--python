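"""Individual-based accumulation (rarefaction) curves for species richness,
Faith's PD, and PSR.

Species and PD curves have hypergeometric closed forms (the probability
that a species, or a branch, survives a draw of m individuals); the
resampling estimators average over random orderings or subsamples and are
cross-checked against the closed forms.  PSR has no closed form and is
estimated by resampling only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .phylo import Phylogeny, PhyloError

__all__ = [
    "AccumulationCurve",
    "species_accum_resample",
    "species_accum_analytic",
    "pd_accum",
    "psr_accum",
]


@dataclass
class AccumulationCurve:
    """Mean metric value (with resampling sd where applicable) versus the
    number of individuals drawn."""

    metric: str
    m: np.ndarray
    mean: np.ndarray
    sd: np.ndarray | None = None
    n_resamples: int | None = None
    n_dropped: int = 0  # subsamples where the metric was undefined

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"metric": self.metric, "m": self.m, "mean": self.mean})
        out["sd"] = self.sd if self.sd is not None else np.nan
        out["n_resamples"] = self.n_resamples
        return out


def _pool_series(pool) -> pd.Series:
    s = pd.Series(pool, dtype=np.int64)
    s = s[s > 0]
    if s.empty:
        raise ValueError("empty individual pool")
    return s


def _log_choose(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _absence_prob(N: int, counts: np.ndarray, m: np.ndarray) -> np.ndarray:
    """P(none of a class with `counts` members in a draw of m), shape
    (len(counts), len(m)); C(N-N_s, m)/C(N, m) with the convention 0 when
    m > N - N_s."""
    Ns = counts[:, None].astype(float)
    mm = m[None, :].astype(float)
    with np.errstate(invalid="ignore"):
        logp = _log_choose(N - Ns, mm) - _log_choose(N, mm)
    p = np.exp(logp)
    p[mm > N - Ns] = 0.0
    return p


def species_accum_resample(
    pool, n_orders: int = 50, seed=None
) -> AccumulationCurve:
    """Species-individual curve by averaging over random orderings.

    Individuals are randomly ordered *n_orders* times and the cumulative
    species count tallied at every m from 1 to the pool total.
    """
    s = _pool_series(pool)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    individuals = np.repeat(np.arange(len(s)), s.to_numpy())
    N = individuals.size
    curves = np.empty((n_orders, N))
    for r in range(n_orders):
        order = rng.permutation(individuals)
        seen = np.zeros(len(s), dtype=bool)
        newsp = np.empty(N)
        for k, sp in enumerate(order):
            newsp[k] = 0.0 if seen[sp] else 1.0
            seen[sp] = True
        curves[r] = np.cumsum(newsp)
    return AccumulationCurve(
        metric="species",
        m=np.arange(1, N + 1),
        mean=curves.mean(axis=0),
        sd=curves.std(axis=0, ddof=1) if n_orders > 1 else np.zeros(N),
        n_resamples=n_orders,
    )


def species_accum_analytic(pool) -> AccumulationCurve:
    """Exact expected species count: E[S(m)] = Σ_s [1 − C(N−N_s, m)/C(N, m)]."""
    s = _pool_series(pool)
    N = int(s.sum())
    m = np.arange(1, N + 1)
    absent = _absence_prob(N, s.to_numpy(), m)
    return AccumulationCurve(metric="species", m=m, mean=(1.0 - absent).sum(axis=0))


def _branch_table(tree: Phylogeny, pool: pd.Series):
    """(lengths, per-branch pooled individual counts) for rooted PD."""
    labels = tree.tip_labels
    unknown = sorted(set(pool.index) - set(labels))
    if unknown:
        raise PhyloError(f"pool species not in tree: {unknown}")
    index = {l: i for i, l in enumerate(labels)}
    abund = np.zeros(len(labels))
    for sp, n in pool.items():
        abund[index[sp]] = n

    lengths, counts, masks = [], [], {}
    root = tree.root
    for nd in tree.dendropy_tree.postorder_node_iter():
        if nd.is_leaf():
            m = np.zeros(len(labels), dtype=bool)
            m[index[nd.taxon.label if nd.taxon else nd.label]] = True
        else:
            m = np.zeros(len(labels), dtype=bool)
            for c in nd.child_nodes():
                m |= masks[c]
        masks[nd] = m
        if nd is not root:
            if nd.edge.length is None:
                raise PhyloError("PD accumulation requires branch lengths")
            lengths.append(nd.edge.length)
            counts.append(abund[m].sum())
    return np.array(lengths), np.array(counts), masks, index


def pd_accum(
    pool,
    tree: Phylogeny,
    mode: str = "analytic",
    n_resamples: int = 50,
    seed=None,
) -> AccumulationCurve:
    """PD-individual curve (rooted PD of m randomly drawn individuals).

    ``analytic`` mode uses the per-branch hypergeometric survival form
    E[PD(m)] = Σ_b L_b · [1 − C(N−N_b, m)/C(N, m)], where N_b counts the
    pooled individuals descending from branch b; ``resample`` mode averages
    rooted PD over *n_resamples* draws without replacement.
    """
    s = _pool_series(pool)
    N = int(s.sum())
    lengths, counts, masks, index = _branch_table(tree, s)
    m = np.arange(1, N + 1)

    if mode == "analytic":
        keep = counts > 0
        absent = _absence_prob(N, counts[keep], m)
        mean = (lengths[keep][:, None] * (1.0 - absent)).sum(axis=0)
        return AccumulationCurve(metric="PD", m=m, mean=mean)
    if mode != "resample":
        raise ValueError(f"mode must be 'analytic' or 'resample', got {mode!r}")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sp_of_ind = np.repeat(np.arange(len(s)), s.to_numpy())
    col = np.array([index[sp] for sp in s.index])
    # per-branch tip masks in the same postorder as `lengths`
    branch_masks = []
    root = tree.root
    for nd in tree.dendropy_tree.postorder_node_iter():
        if nd is not root:
            branch_masks.append(masks[nd])
    B = np.array(branch_masks)  # (edges, tips)

    curves = np.empty((n_resamples, N))
    for r in range(n_resamples):
        order = rng.permutation(sp_of_ind)
        present = np.zeros(B.shape[1], dtype=bool)
        pd_now = 0.0
        covered = np.zeros(B.shape[0], dtype=bool)
        for k, local_sp in enumerate(order):
            tip = col[local_sp]
            if not present[tip]:
                present[tip] = True
                newly = ~covered & B[:, tip]
                pd_now += lengths[newly].sum()
                covered |= newly
            curves[r, k] = pd_now
    return AccumulationCurve(
        metric="PD",
        m=m,
        mean=curves.mean(axis=0),
        sd=curves.std(axis=0, ddof=1) if n_resamples > 1 else np.zeros(N),
        n_resamples=n_resamples,
    )


def default_grid(N: int, max_points: int = 100) -> np.ndarray:
    """Grid of individual counts 1..N, thinned to at most *max_points*
    (always including 1 and N)."""
    if N <= max_points:
        return np.arange(1, N + 1)
    grid = np.unique(np.round(np.linspace(1, N, max_points)).astype(int))
    return grid


def psr_accum(
    pool,
    tree: Phylogeny,
    corr: pd.DataFrame | None = None,
    n_resamples: int = 50,
    grid: np.ndarray | None = None,
    seed=None,
) -> AccumulationCurve:
    """PSR accumulation by rarefaction: mean S·PSV of m-individual draws.

    Monospecific subsamples, where PSV is undefined, are dropped and
    counted in ``n_dropped``.
    """
    from .phylo import phylo_correlation

    s = _pool_series(pool)
    if len(s) < 2:
        raise ValueError("PSR accumulation needs a pool with >= 2 species")
    if corr is None:
        corr = phylo_correlation(tree)
    N = int(s.sum())
    if grid is None:
        grid = default_grid(N)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    Csub = corr.loc[list(s.index), list(s.index)].to_numpy()
    counts = s.to_numpy()
    mean = np.empty(len(grid))
    sd = np.empty(len(grid))
    dropped = 0
    for gi, m in enumerate(grid):
        vals = []
        for _ in range(n_resamples):
            sub = rng.multivariate_hypergeometric(counts, int(m))
            present = np.flatnonzero(sub)
            k = present.size
            if k < 2:
                dropped += 1
                continue
            C = Csub[np.ix_(present, present)]
            p = 1.0 - (C.sum() - k) / (k * (k - 1))
            vals.append(k * p)
        if vals:
            mean[gi] = float(np.mean(vals))
            sd[gi] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        else:
            mean[gi] = np.nan
            sd[gi] = np.nan
    return AccumulationCurve(
        metric="PSR", m=np.asarray(grid), mean=mean, sd=sd,
        n_resamples=n_resamples, n_dropped=dropped,
    )


def accum_by_level(
    comm, tree: Phylogeny, n_resamples: int = 50, seed=None
) -> pd.DataFrame:
    """Species, PD and PSR curves per plot, per forest type, and pooled.

    Returns a tidy long table with columns level, id, metric, m, mean, sd,
    n_resamples.
    """
    from .phylo import phylo_correlation

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    corr = phylo_correlation(tree)
    frames = []

    def add(level: str, ident: str, pool: pd.Series) -> None:
        pool = pool[pool > 0]
        grid = default_grid(int(pool.sum()))
        sp = species_accum_analytic(pool)
        keep = np.isin(sp.m, grid)
        frames.append(
            pd.DataFrame({"level": level, "id": ident, "metric": "species",
                          "m": sp.m[keep], "mean": sp.mean[keep], "sd": np.nan,
                          "n_resamples": np.nan})
        )
        pdc = pd_accum(pool, tree, mode="analytic")
        frames.append(
            pd.DataFrame({"level": level, "id": ident, "metric": "PD",
                          "m": pdc.m[keep], "mean": pdc.mean[keep], "sd": np.nan,
                          "n_resamples": np.nan})
        )
        if (pool > 0).sum() >= 2:
            psrc = psr_accum(pool, tree, corr=corr, n_resamples=n_resamples,
                             grid=grid, seed=rng)
            frames.append(
                pd.DataFrame({"level": level, "id": ident, "metric": "PSR",
                              "m": psrc.m, "mean": psrc.mean, "sd": psrc.sd,
                              "n_resamples": psrc.n_resamples})
            )

    for plot in comm.plots:
        add("plot", plot, comm.counts.loc[plot])
    pooled_type = comm.pooled_counts("forest_type")
    for ftype in pooled_type.index:
        add("type", str(ftype), pooled_type.loc[ftype])
    add("landscape", "all", comm.counts.sum(axis=0))
    return pd.concat(frames, ignore_index=True)
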