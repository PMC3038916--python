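import itertools

import numpy as np
import pytest

from semkit.align_io import MafRow, QualityAlignmentBlock
from semkit.phylo_error import BASES, PhyloModel, SubstitutionModel, parse_newick

_BASE_IDX = {b: i for i, b in enumerate(BASES)}


@pytest.fixture
def two_species_block():
    """Small hand-written pairwise block with qualities."""
    return QualityAlignmentBlock(
        rows=[
            MafRow("ref.chr1", 10, 8, "+", 1000, "ACGTACGT", quality="FFFFFFFF"),
            MafRow("draft.scaf1", 5, 7, "+", 500, "ACGTAC-T", quality="993399-1"),
        ]
    )


@pytest.fixture
def quartet_model():
    tree = parse_newick("((A:0.05,B:0.07):0.02,(C:0.06,D:0.09):0.03);")
    return PhyloModel(tree, SubstitutionModel.jukes_cantor())


def brute_force_prune(column, model, rho=1.0):
    """Independent pruning oracle: explicit sum over internal-node labelings.

    P(X) = sum over assignments of bases to internal nodes of
    pi(root) * prod over branches P(parent -> child), with observed leaves
    fixed and missing leaves summed out (probability one).
    """
    tree = model.tree
    internal = [n for n in tree.postorder() if not n.is_leaf]
    parents = tree.parent_map()
    total = 0.0
    P = {id(n): model.subst.transition_matrix(rho * n.length) for n in tree.postorder()}
    for assign in itertools.product(range(4), repeat=len(internal)):
        states = {id(n): s for n, s in zip(internal, assign)}
        prob = model.subst.pi[states[id(tree)]]
        for node in tree.postorder():
            par = parents[id(node)]
            if par is None:
                continue
            ps = states[id(par)]
            if node.is_leaf:
                b = column.get(node.name, "N")
                if b in ("N", "-", None):
                    continue  # missing data sums to 1
                prob *= P[id(node)][ps, _BASE_IDX[b]]
            else:
                prob *= P[id(node)][ps, states[id(node)]]
        total += prob
    return total


def brute_force_parsimony(leaf_entries, tree, W):
    """Independent Sankoff oracle: exhaustive minimization over labelings.

    leaf_entries maps leaf name to a string over {0,1,?} (compressed
    columns); every node, leaves included, ranges over its compatible
    states. Returns (min_cost, {node_name: set of optimal states}).
    """
    n = len(next(iter(leaf_entries.values())))
    size = 1 << n

    def compatible(entries):
        out = []
        for s in range(size):
            ok = all(
                c == "?" or (s >> k & 1) == int(c) for k, c in enumerate(entries)
            )
            if ok:
                out.append(s)
        return out

    nodes = list(tree.preorder())
    names = {}
    counter = 0
    for node in nodes:
        names[id(node)] = node.name if (node.is_leaf or node.name) else f"node{counter}"
        counter += 1
    choices = []
    for node in nodes:
        if node.is_leaf:
            choices.append(compatible(leaf_entries.get(node.name, "?" * n)))
        else:
            choices.append(list(range(size)))
    parents = tree.parent_map()
    best = None
    optimal: dict[str, set] = {names[id(node)]: set() for node in nodes}
    for assign in itertools.product(*choices):
        states = {id(node): s for node, s in zip(nodes, assign)}
        cost = 0
        for node in nodes:
            par = parents[id(node)]
            if par is not None:
                cost += int(W[states[id(par)], states[id(node)]])
        if best is None or cost < best:
            best = cost
            optimal = {names[id(node)]: set() for node in nodes}
        if cost == best:
            for node in nodes:
                optimal[names[id(node)]].add(states[id(node)])
    return best, optimal
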