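import numpy as np
import pytest

from apoclone import bruvo, synth
from apoclone.genotype_io import Genotype, GenotypeSet, LocusDef

STUDY_SEED = 1


@pytest.fixture(scope="session")
def study():
    """Full synthetic study at a fixed seed: (config, GenotypeSet, fcm, truth)."""
    cfg = synth.study_config(seed=STUDY_SEED)
    gs, fcm, truth = synth.simulate_study(cfg)
    return cfg, gs, fcm, truth


@pytest.fixture(scope="session")
def polyploid_dm(study):
    """Bruvo distance matrix over the polyploid samples, full 13-locus panel."""
    _, gs, _, truth = study
    poly_ids = [s for s, p in truth.ploidy_of.items() if p > 2]
    return bruvo.distance_matrix(gs.subset_samples(poly_ids))


@pytest.fixture()
def tiny_panel():
    return [
        LocusDef("L1", repeat_len=2),
        LocusDef("L2", repeat_len=2),
        LocusDef("GA", repeat_len=2, genome_tag="genomeA"),
    ]


def make_genotype(sample_id, alleles, taxon="t", ploidy=None):
    return Genotype(
        sample_id,
        taxon=taxon,
        ploidy=ploidy,
        alleles={k: frozenset(v) for k, v in alleles.items()},
    )


@pytest.fixture()
def clone_set(tiny_panel):
    """3 identical genotypes + 1 single-step mutant + 1 unrelated."""
    base = {"L1": {10, 12}, "L2": {15}, "GA": {20, 22}}
    mut = {"L1": {10, 13}, "L2": {15}, "GA": {20, 22}}
    far = {"L1": {20, 24}, "L2": {30}, "GA": {40, 44}}
    gts = [
        make_genotype("a1", base),
        make_genotype("a2", base),
        make_genotype("a3", base),
        make_genotype("b1", mut),
        make_genotype("c1", far),
    ]
    return GenotypeSet(tiny_panel, gts)


def random_additive_tree(n_leaves, rng):
    """Random additive tree as an edge dict; returns (names, distance matrix).

    Built by attaching leaves to random edges; path lengths computed by
    breadth-first search over the edge graph — independent of the package's
    tree code.
    """
    # nodes: 0..; adjacency {u: {v: w}}
    adj = {0: {}, 1: {}, 2: {}, 3: {}}
    nxt = 4

    def connect(u, v, w):
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w

    def bl():
        return float(rng.uniform(0.01, 0.05))

    leaves = [0, 1, 2]
    for leaf in leaves:
        connect(leaf, 3, bl())
    while len(leaves) < n_leaves:
        # pick a random edge, subdivide, hang a new leaf
        u = int(rng.choice([k for k in adj if adj[k]]))
        v = int(rng.choice(list(adj[u])))
        w = adj[u][v]
        mid, new_leaf = nxt, nxt + 1
        nxt += 2
        del adj[u][v]
        del adj[v][u]
        t = float(rng.uniform(0.2, 0.8))
        connect(u, mid, w * t)
        connect(mid, v, w * (1 - t))
        connect(mid, new_leaf, bl())
        leaves.append(new_leaf)

    names = [f"t{i}" for i in range(len(leaves))]
    dmat = np.zeros((len(leaves), len(leaves)))
    for i, src in enumerate(leaves):
        # Dijkstra-lite (tree, so BFS with accumulated weights)
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for j, dst in enumerate(leaves):
            dmat[i, j] = dist[dst]
    dmat = (dmat + dmat.T) / 2  # remove float-summation asymmetry
    return names, dmat
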