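"""Independent-swap matrix randomization and the standardized effect sizes
NRI and NTI.

The null model repeatedly proposes a random 2×2 submatrix and, when it has
a checkerboard occupancy pattern, swaps it.  Row (plot richness) and column
(species occurrence frequency) totals of the presence–absence matrix are
preserved exactly, and abundance values travel with their presence cells.
Proposals are uniform and rejected proposals count as steps, which makes
the chain doubly stochastic: its stationary distribution is uniform over
the reachable margin-preserving configurations.

NRI = −(MPD − mean MPD_null) / sd MPD_null, and NTI likewise for MNTD,
against 999 independently randomized matrices by default.  Positive values
indicate phylogenetic clustering, negative values overdispersion.
"""

from __future__ import annotations

import warnings
from typing import Literal

import numpy as np
import pandas as pd
from numba import njit

from .community import CommunityMatrix, rarefy_counts, default_rarefaction_target
from .phylo import Phylogeny, cophenetic_distances

__all__ = [
    "independent_swap",
    "default_swap_attempts",
    "ses_metric",
    "nri_nti_table",
]

_MAX_ATTEMPTS = 5_000_000


@njit(cache=True)
def _swap_kernel(M, n_attempts, seed):  # pragma: no cover - exercised via wrapper
    np.random.seed(seed)
    n_rows, n_cols = M.shape
    successes = 0
    for _ in range(n_attempts):
        i = np.random.randint(0, n_rows)
        j = np.random.randint(0, n_rows)
        a = np.random.randint(0, n_cols)
        b = np.random.randint(0, n_cols)
        if i == j or a == b:
            continue
        ia = M[i, a]
        ib = M[i, b]
        ja = M[j, a]
        jb = M[j, b]
        if ia > 0 and jb > 0 and ib == 0 and ja == 0:
            M[i, a] = 0
            M[i, b] = ia
            M[j, a] = jb
            M[j, b] = 0
            successes += 1
        elif ib > 0 and ja > 0 and ia == 0 and jb == 0:
            M[i, b] = 0
            M[i, a] = ib
            M[j, b] = ja
            M[j, a] = 0
            successes += 1
    return successes


def default_swap_attempts(counts: np.ndarray, swaps_per_cell: float = 3.0) -> int:
    """Burn-in length sized to the matrix, as attempted swaps.

    A uniform 2×2 proposal hits a checkerboard with probability about
    2f²(1−f)² at fill fraction f, so the attempt count is chosen so that the
    expected number of realized swaps is *swaps_per_cell* per presence cell
    (capped at 5·10⁶ attempts).
    """
    presence = counts > 0
    cells = int(presence.sum())
    if cells == 0:
        return 0
    f = cells / presence.size
    rate = 2.0 * f * f * (1.0 - f) * (1.0 - f)
    if rate <= 0:
        return _MAX_ATTEMPTS
    return int(min(_MAX_ATTEMPTS, max(20_000, swaps_per_cell * cells / rate)))


def _swap_array(
    counts: np.ndarray, n_swaps: int, seed: int
) -> tuple[np.ndarray, int]:
    M = np.ascontiguousarray(counts, dtype=np.int64).copy()
    successes = _swap_kernel(M, np.int64(n_swaps), np.uint32(seed))
    return M, int(successes)


def independent_swap(
    comm: CommunityMatrix,
    n_swaps: int | None = None,
    seed: int | None = None,
) -> CommunityMatrix:
    """One swap-randomized copy of the community matrix.

    *n_swaps* counts attempted swaps; ``None`` sizes the burn-in to the
    matrix via :func:`default_swap_attempts`.  Emits a warning when no
    checkerboard was found (the null then equals the observed matrix).
    """
    counts = comm.counts.to_numpy()
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("independent swap needs >= 2 plots and >= 2 species")
    if n_swaps is None:
        n_swaps = default_swap_attempts(counts)
    if n_swaps < 1:
        raise ValueError(f"n_swaps must be >= 1, got {n_swaps}")
    rng = np.random.default_rng(seed)
    M, successes = _swap_array(counts, n_swaps, int(rng.integers(2**32)))
    if successes == 0:
        warnings.warn(
            "no checkerboard submatrix was swapped; null equals observed",
            stacklevel=2,
        )
    out = pd.DataFrame(M, index=comm.counts.index, columns=comm.counts.columns)
    return CommunityMatrix(out, comm.metadata)


# -- vectorized per-plot metrics on raw arrays -----------------------------


def _mpd_all_plots(A: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Abundance-weighted MPD for every row of A (nan where undefined)."""
    Af = A.astype(float)
    num = np.einsum("ps,ps->p", Af @ D, Af)
    tot = Af.sum(axis=1)
    den = tot**2 - np.einsum("ps,ps->p", Af, Af)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den <= 0] = np.nan
    return out


def _mntd_all_plots(A: np.ndarray, D: np.ndarray) -> np.ndarray:
    n_plots = A.shape[0]
    out = np.full(n_plots, np.nan)
    for p in range(n_plots):
        idx = np.flatnonzero(A[p])
        if idx.size < 2:
            continue
        sub = D[np.ix_(idx, idx)].copy()
        np.fill_diagonal(sub, np.inf)
        nn = sub.min(axis=1)
        m = A[p, idx].astype(float)
        out[p] = (m * nn).sum() / m.sum()
    return out


_METRIC_FUNCS = {"MPD": _mpd_all_plots, "MNTD": _mntd_all_plots}


def _ses_one_matrix(
    counts: np.ndarray,
    D: np.ndarray,
    metrics: tuple[str, ...],
    n_null: int,
    n_swaps: int | None,
    rng: np.random.Generator,
) -> dict[str, dict[str, np.ndarray]]:
    """Observed and null metric distributions for each plot row.

    All requested metrics are read off the same stream of null matrices.
    """
    if n_swaps is None:
        n_swaps = default_swap_attempts(counts)
    obs = {m: _METRIC_FUNCS[m](counts, D) for m in metrics}
    nulls = {m: np.empty((n_null, counts.shape[0])) for m in metrics}
    seeds = rng.integers(2**32, size=n_null)
    for k in range(n_null):
        M, _ = _swap_array(counts, n_swaps, int(seeds[k]))
        for m in metrics:
            nulls[m][k] = _METRIC_FUNCS[m](M, D)
    return {
        m: {"obs": obs[m], "null": nulls[m]} for m in metrics
    }


_INDEX_NAME = {"MPD": "NRI", "MNTD": "NTI"}


def _ses_frame(
    plots: list[str],
    metric: str,
    obs: np.ndarray,
    null: np.ndarray,
    n_swaps: int,
    draw: int | None = None,
) -> pd.DataFrame:
    n_null = null.shape[0]
    null_mean = np.nanmean(null, axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        null_sd = np.nanstd(null, axis=0, ddof=1)
    z = np.full_like(obs, np.nan)
    reason = np.array([None] * len(plots), dtype=object)
    undefined = np.isnan(obs)
    reason[undefined] = "metric undefined (fewer than 2 species)"
    degenerate = (~undefined) & ((null_sd == 0) | np.isnan(null_sd))
    reason[degenerate] = "null sd is zero (plot invariant under swaps)"
    ok = ~undefined & ~degenerate
    z[ok] = (obs[ok] - null_mean[ok]) / null_sd[ok]

    # one-sided lower quantile of the observed value among the nulls, and
    # the two-sided rank p with add-one correction
    q = np.full_like(obs, np.nan)
    p2 = np.full_like(obs, np.nan)
    for i in np.flatnonzero(ok):
        n_le = int((null[:, i] <= obs[i]).sum())
        n_ge = int((null[:, i] >= obs[i]).sum())
        q[i] = (n_le + 1) / (n_null + 1)
        p2[i] = min(1.0, 2.0 * min(n_le + 1, n_ge + 1) / (n_null + 1))

    frame = pd.DataFrame(
        {
            "plot": plots,
            "metric": metric,
            "obs": obs,
            "null_mean": np.where(undefined, np.nan, null_mean),
            "null_sd": np.where(undefined, np.nan, null_sd),
            "z": z,
            "index": -z,
            "index_name": _INDEX_NAME[metric],
            "quantile": q,
            "p_rank": p2,
            "n_null": n_null,
            "n_swaps": n_swaps,
            "reason": reason,
        }
    )
    if draw is not None:
        frame.insert(1, "rarefaction_draw", draw)
    return frame


def ses_metric(
    comm: CommunityMatrix,
    tree: Phylogeny,
    metric: Literal["MPD", "MNTD"],
    n_null: int = 999,
    n_swaps: int | None = None,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Standardized effect size of MPD or MNTD per plot.

    Returns one row per plot with the observed value, null mean/sd over
    *n_null* swap-randomized matrices, z, the signed index (NRI for MPD,
    NTI for MNTD), the two-sided rank p, and a reason code where undefined.
    """
    if metric not in _METRIC_FUNCS:
        raise ValueError(f"metric must be 'MPD' or 'MNTD', got {metric!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    coph = cophenetic_distances(tree)
    missing = [s for s in comm.species if s not in coph.index]
    if missing:
        raise ValueError(f"species not in tree: {missing}")
    D = coph.loc[comm.species, comm.species].to_numpy()
    counts = comm.counts.to_numpy()
    attempts = n_swaps if n_swaps is not None else default_swap_attempts(counts)
    res = _ses_one_matrix(counts, D, (metric,), n_null, attempts, rng)[metric]
    return _ses_frame(comm.plots, metric, res["obs"], res["null"], attempts)


def nri_nti_table(
    comm: CommunityMatrix,
    tree: Phylogeny,
    r_draws: int = 10,
    target: int | None = None,
    n_null: int = 999,
    n_swaps: int | None = None,
    seed: int | np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """NRI and NTI per plot across rarefaction draws.

    Every draw rarefies the matrix to *target* stems (default the smallest
    plot total) and computes both indices against its own stream of
    *n_null* swap-randomized matrices; NRI and NTI share the stream.

    Returns ``(long, summary)``: one row per plot × draw × metric, and the
    per-plot mean of each index across draws.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if target is None:
        target = default_rarefaction_target(comm)
    coph = cophenetic_distances(tree)
    missing = [s for s in comm.species if s not in coph.index]
    if missing:
        raise ValueError(f"species not in tree: {missing}")
    D = coph.loc[comm.species, comm.species].to_numpy()

    frames = []
    for draw in range(r_draws):
        rare = rarefy_counts(comm, target, rng)
        counts = rare.counts.to_numpy()
        attempts = n_swaps if n_swaps is not None else default_swap_attempts(counts)
        res = _ses_one_matrix(counts, D, ("MPD", "MNTD"), n_null, attempts, rng)
        for metric in ("MPD", "MNTD"):
            frames.append(
                _ses_frame(
                    comm.plots, metric,
                    res[metric]["obs"], res[metric]["null"],
                    attempts, draw=draw,
                )
            )
    long = pd.concat(frames, ignore_index=True)
    summary = (
        long.pivot_table(index="plot", columns="index_name", values="index",
                         aggfunc="mean")
        .reindex(comm.plots)
        .join(comm.metadata)
    )
    summary.columns.name = None
    return long, summary
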