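"""Phylogenetic machinery for sequencing-error detection.

Implements Felsenstein's pruning algorithm for alignment-column likelihoods
under a reversible nucleotide substitution model, a per-species 4x4 error
transition matrix (the distribution of the observed base given that an
error occurred at a true base), and a log-odds score comparing

* an *error model*, in which the focal species' observed base arose by a
  single sequencing error on top of an otherwise correctly evolved column,
  against
* a *substitution-only model*, in which the observed base is genuine.

Both models carry a column-specific branch-length scaling factor ``rho``
that is optimized independently for each, so that rate variation across
columns is absorbed before the comparison: an apparent substitution at a
highly conserved column scores as a likely error, while the same base in a
fast-evolving column does not. The error-model likelihood is the
unnormalized sum over candidate true bases; only the ordering of scores
matters downstream (the score feeds a logistic regression or a sign check),
so no proportionality constant is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "BASES",
    "TreeNode",
    "parse_newick",
    "SubstitutionModel",
    "PhyloModel",
    "ErrorMatrix",
    "prune_likelihood",
    "estimate_error_matrix",
    "error_logodds",
    "UNDEFINED",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_MISSING = frozenset("N-?")

#: Sentinel returned when the log-odds score is undefined (no aligned
#: partners); callers fall back to quality-only masking.
UNDEFINED = None


# ---------------------------------------------------------------------------
# trees


@dataclass
class TreeNode:
    """Rooted tree node; ``length`` is the branch above it (subs/site)."""

    name: str = ""
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterable["TreeNode"]:
        for c in self.children:
            yield from c.postorder()
        yield self

    def preorder(self) -> Iterable["TreeNode"]:
        yield self
        for c in self.children:
            yield from c.preorder()

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def parent_map(self) -> dict[int, Optional["TreeNode"]]:
        parents: dict[int, Optional[TreeNode]] = {id(self): None}
        for node in self.preorder():
            for c in node.children:
                parents[id(c)] = node
        return parents


def parse_newick(newick: str) -> TreeNode:
    """Parse a Newick string (via dendropy) into a :class:`TreeNode` tree.

    Unrooted trees are rooted at dendropy's seed node; all algorithms in
    this package are invariant to that choice (symmetric cost/rate models).
    """
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")

    def build(dnode) -> TreeNode:
        name = ""
        if dnode.taxon is not None:
            name = dnode.taxon.label.replace(" ", "_")
        elif dnode.label:
            name = str(dnode.label)
        node = TreeNode(
            name=name,
            length=float(dnode.edge.length) if dnode.edge.length is not None else 0.0,
        )
        node.children = [build(c) for c in dnode.child_nodes()]
        return node

    return build(tree.seed_node)


# ---------------------------------------------------------------------------
# substitution model


class SubstitutionModel:
    """Reversible nucleotide rate matrix with precomputed eigensystem."""

    def __init__(self, rate_matrix: np.ndarray, frequencies: np.ndarray):
        Q = np.asarray(rate_matrix, dtype=float)
        pi = np.asarray(frequencies, dtype=float)
        if Q.shape != (4, 4):
            raise ValueError("rate matrix must be 4x4")
        if not np.allclose(Q.sum(axis=1), 0.0, atol=1e-8):
            raise ValueError("rate matrix rows must sum to 0")
        if not np.isclose(pi.sum(), 1.0, atol=1e-8) or np.any(pi <= 0):
            raise ValueError("frequencies must be positive and sum to 1")
        self.Q = Q
        self.pi = pi
        # eigendecomposition once; P(t) = U diag(exp(d t)) U^-1
        d, U = np.linalg.eig(Q)
        self._d = d
        self._U = U
        self._Uinv = np.linalg.inv(U)

    def transition_matrix(self, t: float) -> np.ndarray:
        """``P(t) = expm(Q t)``, clipped to [0, 1] against round-off."""
        if t < 0:
            raise ValueError("negative branch length")
        P = (self._U * np.exp(self._d * t)) @ self._Uinv
        P = np.real(P)
        np.clip(P, 0.0, 1.0, out=P)
        return P

    @classmethod
    def jukes_cantor(cls) -> "SubstitutionModel":
        Q = np.full((4, 4), 1.0 / 3.0)
        np.fill_diagonal(Q, -1.0)
        return cls(Q, np.full(4, 0.25))

    @classmethod
    def hky(cls, kappa: float, frequencies: Sequence[float]) -> "SubstitutionModel":
        pi = np.asarray(frequencies, dtype=float)
        Q = np.zeros((4, 4))
        transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                Q[i, j] = pi[j] * (kappa if (i, j) in transitions else 1.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        # normalize to one expected substitution per unit branch length
        rate = -np.dot(pi, np.diag(Q))
        return cls(Q / rate, pi)

    @classmethod
    def gtr(
        cls, exchangeabilities: Sequence[float], frequencies: Sequence[float]
    ) -> "SubstitutionModel":
        """GTR from 6 exchangeabilities (AC, AG, AT, CG, CT, GT) and freqs."""
        s = list(exchangeabilities)
        pi = np.asarray(frequencies, dtype=float)
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        Q = np.zeros((4, 4))
        for (i, j), x in zip(pairs, s):
            Q[i, j] = x * pi[j]
            Q[j, i] = x * pi[i]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        rate = -np.dot(pi, np.diag(Q))
        return cls(Q / rate, pi)


@dataclass
class PhyloModel:
    """A tree plus substitution model; ``rho`` scales all branch lengths."""

    tree: TreeNode
    subst: SubstitutionModel
    rho: float = 1.0

    def leaf_names(self) -> list[str]:
        return self.tree.leaf_names()


# ---------------------------------------------------------------------------
# pruning likelihood


def _base_index(b: str) -> Optional[int]:
    if b in _MISSING:
        return None
    try:
        return _BASE_INDEX[b]
    except KeyError:
        raise ValueError(f"invalid base {b!r}")


def prune_likelihood(
    column: Mapping[str, str], model: PhyloModel, rho: Optional[float] = None
) -> float:
    """P(column | tree, model) by Felsenstein's pruning algorithm.

    *column* maps leaf names to bases; ``N``/``-`` (and leaves absent from
    the mapping) are missing data, contributing all-ones partial
    likelihoods. Raises if a column species is not on the tree or if no
    species carries an observed base.
    """
    if rho is None:
        rho = model.rho
    leaf_set = set(model.leaf_names())
    unknown = set(column) - leaf_set
    if unknown:
        raise ValueError(f"species not on tree: {sorted(unknown)}")
    observed = sum(
        1 for sp, b in column.items() if _base_index(b) is not None
    )
    if observed == 0:
        raise ValueError("all-missing column")

    partials: dict[int, np.ndarray] = {}
    for node in model.tree.postorder():
        if node.is_leaf:
            idx = _base_index(column.get(node.name, "N"))
            L = np.ones(4)
            if idx is not None:
                L = np.zeros(4)
                L[idx] = 1.0
        else:
            L = np.ones(4)
            for c in node.children:
                P = model.subst.transition_matrix(rho * c.length)
                L = L * (P @ partials[id(c)])
        partials[id(node)] = L
    like = float(np.dot(model.subst.pi, partials[id(model.tree)]))
    return like


# ---------------------------------------------------------------------------
# error transition matrix


class ErrorMatrix:
    """Per-species error spectrum: M[i, j] = P(observed j | true i, error).

    The diagonal is zero by construction — an "error" means the observed
    base differs from the true one — and each row sums to 1.
    """

    def __init__(self, matrix: np.ndarray):
        M = np.asarray(matrix, dtype=float)
        if M.shape != (4, 4):
            raise ValueError("error matrix must be 4x4")
        if not np.allclose(np.diag(M), 0.0):
            raise ValueError("error matrix diagonal must be 0")
        if not np.allclose(M.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("error matrix rows must sum to 1")
        self.M = M

    def __getitem__(self, ij: tuple[int, int]) -> float:
        return float(self.M[ij])

    @classmethod
    def uniform(cls) -> "ErrorMatrix":
        M = np.full((4, 4), 1.0 / 3.0)
        np.fill_diagonal(M, 0.0)
        return cls(M)


def estimate_error_matrix(
    substitution_counts: Mapping[tuple[str, str], float]
) -> ErrorMatrix:
    """Row-normalize observed (true base -> draft base) mismatch counts.

    Counts should come from low-quality bins of a draft-vs-finished
    tabulation (see :func:`semkit.error_assessment.tabulate_differences`,
    which retains them). Rows without data fall back to uniform 1/3.
    """
    M = np.zeros((4, 4))
    for (i, j), c in substitution_counts.items():
        if i == j:
            continue
        if i in _BASE_INDEX and j in _BASE_INDEX:
            M[_BASE_INDEX[i], _BASE_INDEX[j]] += c
    for r in range(4):
        total = M[r].sum()
        if total > 0:
            M[r] /= total
        else:
            M[r] = 1.0 / 3.0
            M[r, r] = 0.0
    return ErrorMatrix(M)


# ---------------------------------------------------------------------------
# log-odds score


_RHO_BOUNDS = (0.01, 20.0)
_RHO_TOL = 1e-4


def _optimize_rho(loglike, bounds=_RHO_BOUNDS) -> tuple[float, float]:
    """Maximize a scalar log-likelihood over rho; deterministic bounded search."""
    res = minimize_scalar(
        lambda r: -loglike(r),
        bounds=bounds,
        method="bounded",
        options={"xatol": _RHO_TOL},
    )
    rho_hat = float(res.x)
    best = -float(res.fun)
    # guard against a flat/edge optimum missing rho = 1
    base = loglike(1.0)
    if base > best:
        return 1.0, base
    return rho_hat, best


def error_logodds(
    column: Mapping[str, str],
    species: str,
    model: PhyloModel,
    M: ErrorMatrix,
    optimize_rho: bool = True,
) -> Optional[float]:
    """Log-odds that *species*' base in *column* is a sequencing error.

    The no-error likelihood is the pruning likelihood of the observed
    column; the error likelihood sums, over candidate true bases ``i``
    different from the observed ``x_s``, the likelihood of the column with
    ``x_s`` replaced by ``i``, weighted by ``M[i, x_s]`` (single-error
    assumption: at most one error per column). The branch-scaling factor is
    optimized separately under each model; with ``optimize_rho=False`` both
    use ``model.rho``.

    Returns ``UNDEFINED`` (None) when no other species has an observed base.
    """
    x_s = column.get(species)
    if x_s is None or _base_index(x_s) is None:
        raise ValueError(f"species {species!r} missing from column")
    partners = sum(
        1
        for sp, b in column.items()
        if sp != species and _base_index(b) is not None
    )
    if partners == 0:
        return UNDEFINED

    xi = _BASE_INDEX[x_s]

    def loglike_noerror(rho: float) -> float:
        return math.log(max(prune_likelihood(column, model, rho), 1e-300))

    def error_likelihood(rho: float) -> float:
        total = 0.0
        for i, base in enumerate(BASES):
            if i == xi:
                continue
            m = M[i, xi]
            if m == 0.0:
                continue
            swapped = dict(column)
            swapped[species] = base
            total += prune_likelihood(swapped, model, rho) * m
        return total

    def loglike_error(rho: float) -> float:
        return math.log(max(error_likelihood(rho), 1e-300))

    if optimize_rho:
        _, ll0 = _optimize_rho(loglike_noerror)
        _, ll1 = _optimize_rho(loglike_error)
    else:
        ll0 = loglike_noerror(model.rho)
        ll1 = loglike_error(model.rho)
    return ll1 - ll0
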