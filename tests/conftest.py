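import numpy as np
import pytest

from phylocompare import DistanceMatrix, PhyloTree, random_topology


def random_tree(m: int, seed, lengths: bool = True) -> PhyloTree:
    """Random binary unrooted tree with exponential branch lengths."""
    if lengths:
        return random_topology(
            [f"t{i:03d}" for i in range(m)],
            seed=seed,
            branch_length=lambda rng: float(rng.exponential(1.0)) + 1e-6,
        )
    return random_topology([f"t{i:03d}" for i in range(m)], seed=seed)


def brute_force_bipartitions(tree: PhyloTree) -> set:
    """Independent bipartition enumeration working directly on the adjacency.

    For every edge, floods the graph from one endpoint with the edge removed
    and collects the tip labels reached; non-trivial splits are canonicalized
    as frozensets-of-frozensets.  Deliberately avoids PhyloTree.bipartitions.
    """
    adj = tree._adj
    tips = tree._tips
    all_tips = frozenset(tips.values())
    out = set()
    for u in adj:
        for v in adj[u]:
            if u > v:
                continue
            seen = {u, v}
            work = [v]
            side = set()
            while work:
                x = work.pop()
                if x in tips:
                    side.add(tips[x])
                for y in adj[x]:
                    if y not in seen:
                        seen.add(y)
                        work.append(y)
            side = frozenset(side)
            if 1 < len(side) < len(all_tips) - 1:
                out.add(frozenset((side, all_tips - side)))
    return out


def brute_force_rf(t1: PhyloTree, t2: PhyloTree) -> int:
    return len(brute_force_bipartitions(t1) ^ brute_force_bipartitions(t2))


@pytest.fixture(scope="session")
def small_benchmark(tmp_path_factory):
    """A small but fully structured benchmark shared across tests."""
    from phylocompare import BenchmarkParams, make_benchmark

    params = BenchmarkParams(
        n_clades=3,
        clade_sizes=(5, 5, 5),
        n_genes=4,
        L=800,
        mu=0.03,
        discordance=0,
        seed=20,
    )
    return make_benchmark(params, tmp_path_factory.mktemp("bench"))
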