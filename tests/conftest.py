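import numpy as np
import pandas as pd
import pytest

import commphylo as cp


@pytest.fixture(scope="session")
def fixture_dataset():
    """Tiny hand-checkable 5-species, 2-plot dataset."""
    return cp.make_fixture()


@pytest.fixture(scope="session")
def small_tree():
    return cp.parse_newick("((A:1,B:1)n1:1,C:2)root;")


def random_tree(rng: np.random.Generator, n_tips: int, ultrametric: bool = True):
    """Random tree for oracle comparisons (pure-birth topology; optionally
    with independently perturbed branch lengths)."""
    tree = cp.simulate_tree(n_tips, seed=rng, root_age=10.0 if ultrametric else None)
    if not ultrametric:
        for node in tree.dendropy_tree.preorder_node_iter():
            if node.edge.length is not None:
                node.edge.length = float(rng.uniform(0.1, 3.0))
    return tree


def random_community(rng: np.random.Generator, tree, n_plots: int,
                     richness: int, stems: int, forest_types=("YS", "OG")):
    labels = tree.tip_labels
    rows = []
    for p in range(n_plots):
        k = min(richness, len(labels))
        chosen = rng.choice(labels, size=k, replace=False)
        counts = np.ones(k, dtype=np.int64)
        counts += rng.multinomial(stems - k, np.full(k, 1.0 / k))
        rows.append(pd.Series(counts, index=chosen).reindex(labels)
                    .fillna(0).rename(f"p{p:03d}"))
    counts = pd.DataFrame(rows).astype(np.int64)
    meta = pd.DataFrame({
        "plot": counts.index,
        "forest_type": [forest_types[i % len(forest_types)] for i in range(n_plots)],
        "stratum": "overstorey",
        "area_m2": 500.0,
    }).set_index("plot")
    return cp.CommunityMatrix(counts, meta)
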