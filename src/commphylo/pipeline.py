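"""End-to-end analysis driver.

Runs the full plan on any conforming dataset: validate and align inputs,
rarefy, per-plot alpha metrics, NRI/NTI against the independent-swap null,
UniFrac + jackknifed UPGMA per forest type, accumulation curves, and group
comparisons — each stratum analysed separately — and writes a manifest of
every stochastic choice so a re-run with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .accumulation import accum_by_level
from .alpha import plot_metrics_table
from .beta import jackknife_support, unifrac_matrix
from .community import (
    default_rarefaction_target,
    match_tree_names,
    read_community_table,
    read_stem_table,
    read_trait_table,
)
from .groupstats import compare_groups
from .nulls import nri_nti_table
from .phylo import AgeConstraints, Phylogeny, bladj_date

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "validate_inputs"]


@dataclass
class RunConfig:
    """Inputs and knobs for one pipeline run."""

    tree_path: str
    community_path: str
    metadata_path: str
    ages_path: str | None = None
    traits_path: str | None = None
    stems_path: str | None = None
    out_dir: str = "commphylo_out"
    rarefaction_target: int | None = None   # None = smallest plot total
    r_draws: int = 100                      # rarefaction draws for alpha
    ses_draws: int = 10                     # rarefaction draws for NRI/NTI
    n_null: int = 999
    n_swaps: int | None = None              # None = auto burn-in
    jackknife_reps: int = 100
    accum_resamples: int = 50
    strata: tuple[str, ...] = ("overstorey", "understorey")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("r_draws", "ses_draws", "n_null", "jackknife_reps",
                     "accum_resamples"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def _load_tree(config: RunConfig) -> tuple[Phylogeny, list[str]]:
    notes = []
    tree = Phylogeny.from_newick(Path(config.tree_path).read_text())
    if not tree.has_branch_lengths():
        if config.ages_path is None:
            raise ValueError(
                "tree lacks branch lengths and no ages file was given"
            )
        ages = AgeConstraints.from_file(config.ages_path)
        tree = bladj_date(tree, ages)
        notes.append("tree dated with bladj from the ages file")
    return tree, notes


def validate_inputs(config: RunConfig) -> list[dict]:
    """Cross-validation report: one issue dict per problem found.

    ``severity`` is ``fatal`` (the pipeline would abort) or ``warning``
    (the pipeline proceeds after a logged adjustment, e.g. dropping a
    species absent from the tree).
    """
    issues: list[dict] = []
    try:
        tree, _ = _load_tree(config)
    except Exception as exc:
        issues.append({"stage": "tree", "severity": "fatal", "detail": str(exc)})
        return issues

    try:
        comm = read_community_table(config.community_path, config.metadata_path)
    except Exception as exc:
        issues.append({"stage": "community", "severity": "fatal", "detail": str(exc)})
        return issues

    tips = set(tree.tip_labels)
    from .community import normalize_name

    norm_tips = {normalize_name(t) for t in tips}
    unmatched = [s for s in comm.species if normalize_name(s) not in norm_tips]
    for s in unmatched:
        issues.append({
            "stage": "name-matching", "severity": "warning",
            "detail": f"species {s!r} absent from tree; will be dropped",
        })
    mono = comm.richness()[comm.richness() < 2]
    for plot in mono.index:
        issues.append({
            "stage": "community", "severity": "warning",
            "detail": f"plot {plot!r} is monospecific; SES metrics undefined",
        })
    empty = comm.plot_totals()[comm.plot_totals() == 0]
    for plot in empty.index:
        issues.append({
            "stage": "community", "severity": "fatal",
            "detail": f"plot {plot!r} has no stems",
        })
    return issues


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the output bundle to ``config.out_dir``.

    Returns the manifest (also written as ``manifest.json``).  Stage seeds
    are independent spawns of the master seed, so any stage is reproducible
    in isolation.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    issues = validate_inputs(config)
    fatal = [i for i in issues if i["severity"] == "fatal"]
    if fatal:
        raise ValueError(f"validation failed: {fatal}")

    tree, tree_notes = _load_tree(config)
    comm_all = read_community_table(config.community_path, config.metadata_path)
    comm_all, dropped = match_tree_names(comm_all, tree.tip_labels)
    traits = read_trait_table(config.traits_path) if config.traits_path else None
    stems = read_stem_table(config.stems_path) if config.stems_path else None

    ss = np.random.SeedSequence(config.seed)
    stage_seeds = {
        name: int(child.generate_state(1, dtype=np.uint32)[0])
        for name, child in zip(
            ("alpha", "ses", "jackknife", "accum"), ss.spawn(4)
        )
    }

    manifest = {
        "package": "commphylo",
        "version": __version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "stage_seeds": stage_seeds,
        "species_dropped_from_tree": dropped,
        "notes": tree_notes,
        "validation_warnings": [i for i in issues if i["severity"] == "warning"],
        "strata": {},
        "outputs": [],
    }

    def save(df: pd.DataFrame, name: str, index=False) -> None:
        path = out / name
        df.to_csv(path, index=index)
        manifest["outputs"].append(name)

    strata_present = [
        s for s in config.strata
        if (comm_all.metadata["stratum"] == s).any()
    ]
    if not strata_present:
        strata_present = [None]  # single unlabelled stratum

    for stratum in strata_present:
        comm = comm_all.subset_stratum(stratum) if stratum else comm_all
        tag = stratum or "all"
        target = config.rarefaction_target or default_rarefaction_target(comm)
        log.info("stratum %s: %d plots, %d species, rarefaction target %d",
                 tag, len(comm.plots), len(comm.species), target)

        alpha_long, alpha_summary = plot_metrics_table(
            tree, comm, r_draws=config.r_draws, target=target,
            seed=stage_seeds["alpha"], stems=stems, traits=traits,
        )
        save(alpha_long, f"alpha_{tag}_long.csv")
        save(alpha_summary.reset_index(names="plot"), f"alpha_{tag}_summary.csv")

        ses_long, ses_summary = nri_nti_table(
            comm, tree, r_draws=config.ses_draws, target=target,
            n_null=config.n_null, n_swaps=config.n_swaps,
            seed=stage_seeds["ses"],
        )
        save(ses_long, f"ses_{tag}_long.csv")
        save(ses_summary.reset_index(names="plot"), f"ses_{tag}_summary.csv")

        dist = unifrac_matrix(tree, comm, group_by="forest_type")
        save(dist, f"unifrac_types_{tag}.csv", index=True)
        dendro = jackknife_support(
            tree, comm, group_by="forest_type",
            n_reps=config.jackknife_reps, seed=stage_seeds["jackknife"],
        )
        (out / f"upgma_types_{tag}.nwk").write_text(dendro.to_newick() + "\n")
        manifest["outputs"].append(f"upgma_types_{tag}.nwk")

        curves = accum_by_level(
            comm, tree, n_resamples=config.accum_resamples,
            seed=stage_seeds["accum"],
        )
        save(curves, f"accum_{tag}.csv")

        responses = [c for c in ("S", "PD", "PSV", "PSR", "PSE", "WD")
                     if c in alpha_summary.columns]
        comparisons = compare_groups(alpha_summary, responses)
        rows = []
        for resp, res in comparisons.items():
            for _, r in res.group_table.iterrows():
                rows.append({
                    "response": resp, "test": res.test,
                    "statistic": res.statistic, "p_value": res.p_value,
                    "transform": res.transform, "group": r["group"],
                    "n": r["n"], "mean": r["mean"], "se": r["se"],
                    "letter": r["letter"],
                })
        save(pd.DataFrame(rows), f"group_stats_{tag}.csv")

        manifest["strata"][tag] = {
            "n_plots": len(comm.plots),
            "n_species": len(comm.species),
            "rarefaction_target": target,
        }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
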