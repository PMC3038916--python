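"""Lineage-specific indel detection and quality-gated imputation.

An *indel region* (IR) is a maximal run of alignment columns that each
contain at least one gap, flanked by gapless columns. Within an IR each
species is reduced to a presence/absence string (1 = base, 0 = gap,
? = missing), adjacent identical columns are compressed (events cost the
same regardless of length, so identical columns carry no extra signal),
and each species' pattern becomes one of ``2**n`` *indel states* over the
``n`` compressed columns.

Ancestral states are reconstructed by Sankoff parsimony (min-sum message
passing, the log-domain twin of max-product) with a state-transition cost
matrix ``W`` in which ``w[i, j]`` is the minimum number of indel events
needed to turn state ``i`` into state ``j``. A single event inserts or
deletes one *contiguous run in sequence coordinates*: a legal move between
nested states flips a set of columns that is consecutive among the
1-columns of the larger state, so a deletion spanning an interior gap
column still counts as one event. ``W`` is computed by breadth-first
search over states and cached per width.

All states achieving the global minimum cost are enumerated at every node.
A leaf whose observed column entry disagrees with *every* optimal state of
its parent is a lineage-specific (LS) event: leaf 1 under an all-0 parent
is an LS insertion, leaf 0 under an all-1 parent an LS deletion. LS calls
supported only by low-quality sequence are then reverted to the ancestral
state: spurious insertions are excised, spurious deletions filled with
``N`` (quality bin 0 so downstream tabulation ignores the filled bases).
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .align_io import (
    GAP,
    QualityAlignmentBlock,
    bin_representative,
    encode_quality_char,
)
from .error_assessment import indel_quality
from .phylo_error import TreeNode

__all__ = [
    "IndelRegion",
    "LSIndelCall",
    "extract_indel_regions",
    "compress_columns",
    "event_cost_matrix",
    "parsimony_states",
    "call_ls_indels",
    "impute",
    "MAX_GAP",
    "MAX_WIDTH",
]

MAX_GAP = 10  # gap runs longer than this become missing data
MAX_WIDTH = 10  # IRs wider than this (compressed) are skipped

_INF = np.int64(10**9)


# ---------------------------------------------------------------------------
# indel regions


@dataclass
class IndelRegion:
    """A maximal gap-containing column run reduced to presence/absence."""

    block_index: int
    col_start: int
    col_end: int  # half-open span of original alignment columns
    species: list[str]  # row order of the matrix
    matrix: list[str]  # per species: string over {0,1,?}, one char per column
    skipped: bool = False
    # set by compress_columns:
    compressed: Optional[list[tuple[str, ...]]] = None  # distinct columns
    multiplicity: Optional[list[int]] = None
    col_map: Optional[list[int]] = None  # original column -> compressed index

    @property
    def width(self) -> int:
        return self.col_end - self.col_start

    @property
    def n(self) -> Optional[int]:
        return len(self.compressed) if self.compressed is not None else None

    def column(self, j: int) -> tuple[str, ...]:
        """Presence entries of original column *j* (relative), per species."""
        return tuple(self.matrix[s][j] for s in range(len(self.species)))


def _presence_string(text: str, start: int, end: int, max_gap: int) -> str:
    """Presence/absence over a column span; long gap runs become '?'."""
    out = []
    for i in range(start, end):
        c = text[i]
        out.append("0" if c == GAP else "1")
    s = "".join(out)
    # a maximal gap run longer than max_gap is treated as missing data;
    # runs are maximal within the full row, so check the flanks too
    res = list(s)
    i = 0
    while i < len(s):
        if s[i] == "0":
            j = i
            while j < len(s) and s[j] == "0":
                j += 1
            run_len = j - i
            # extend run length into the flanking context
            k = start + i - 1
            while k >= 0 and text[k] == GAP:
                run_len += 1
                k -= 1
            k = start + j
            while k < len(text) and text[k] == GAP:
                run_len += 1
                k += 1
            if run_len > max_gap:
                for t in range(i, j):
                    res[t] = "?"
            i = j
        else:
            i += 1
    return "".join(res)


def extract_indel_regions(
    blocks: Iterable[QualityAlignmentBlock],
    leaves: Sequence[str],
    max_gap: int = MAX_GAP,
    max_width: int = MAX_WIDTH,
) -> Iterator[IndelRegion]:
    """Find indel regions in a stream of blocks.

    Species in *leaves* but absent from a block are all-``?``; gap runs
    longer than *max_gap* are masked to ``?``. Regions whose compressed
    width exceeds *max_width* are emitted with ``skipped=True`` (no calls
    will be made for them). Gap runs abutting a block edge have no gapless
    flank and are not emitted.
    """
    leaves = list(leaves)
    for bi, block in enumerate(blocks):
        texts = []
        for sp in leaves:
            texts.append(block.row(sp).text if block.has_species(sp) else None)
        ncols = block.ncols

        def has_gap(col: int) -> bool:
            return any(t is not None and t[col] == GAP for t in texts)

        col = 0
        while col < ncols:
            if not has_gap(col):
                col += 1
                continue
            start = col
            while col < ncols and has_gap(col):
                col += 1
            end = col
            # require gapless flanking columns inside the block
            if start == 0 or end == ncols:
                continue
            matrix = []
            for t in texts:
                if t is None:
                    matrix.append("?" * (end - start))
                else:
                    matrix.append(_presence_string(t, start, end, max_gap))
            region = IndelRegion(
                block_index=bi,
                col_start=start,
                col_end=end,
                species=leaves,
                matrix=matrix,
            )
            compress_columns(region)
            if region.n is not None and region.n > max_width:
                region.skipped = True
            yield region


def compress_columns(region: IndelRegion) -> IndelRegion:
    """Merge adjacent identical columns, recording multiplicities.

    Columns are identical when every species (including ``?`` entries)
    agrees. Sets ``compressed``, ``multiplicity`` and ``col_map`` in place
    and returns the region.
    """
    cols = [region.column(j) for j in range(region.width)]
    compressed: list[tuple[str, ...]] = []
    multiplicity: list[int] = []
    col_map: list[int] = []
    for c in cols:
        if compressed and compressed[-1] == c:
            multiplicity[-1] += 1
        else:
            compressed.append(c)
            multiplicity.append(1)
        col_map.append(len(compressed) - 1)
    region.compressed = compressed
    region.multiplicity = multiplicity
    region.col_map = col_map
    return region


# ---------------------------------------------------------------------------
# cost matrix


def _neighbors(state: int, n: int) -> Iterator[int]:
    """States one indel event away from *state* (symmetric relation).

    One event flips a set of columns that is consecutive among the
    1-columns of the larger state; enumerating deletions from every state
    generates each edge in both directions.
    """
    ones = [k for k in range(n) if state >> k & 1]
    m = len(ones)
    for a in range(m):
        for b in range(a, m):
            mask = 0
            for k in ones[a : b + 1]:
                mask |= 1 << k
            yield state ^ mask  # deletion from state's perspective


@lru_cache(maxsize=None)
def event_cost_matrix(n: int) -> np.ndarray:
    """Minimum indel events between all pairs of states of width *n*.

    Computed by breadth-first search from each state over single-event
    moves. The result is symmetric with zero diagonal and satisfies the
    triangle inequality (it is a graph metric). Cached per width.
    """
    if not 1 <= n <= MAX_WIDTH:
        raise ValueError(f"width must be in 1..{MAX_WIDTH}, got {n}")
    size = 1 << n
    W = np.full((size, size), -1, dtype=np.int64)
    # adjacency (small: <= 1024 states, <= ~30 edges each)
    adj: list[set[int]] = [set() for _ in range(size)]
    for s in range(size):
        for t in _neighbors(s, n):
            adj[s].add(t)
            adj[t].add(s)
    for src in range(size):
        W[src, src] = 0
        queue = deque([src])
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if W[src, v] < 0:
                    W[src, v] = W[src, u] + 1
                    queue.append(v)
    return W


def event_cost_matrix_columnwise(n: int) -> np.ndarray:
    """Naive alternative cost: one event per maximal differing column run.

    Counts, for states i and j, the number of maximal runs of compressed
    columns at which they differ. Ignores sequence-coordinate contiguity
    across interior columns (e.g. rates 101 -> 010 as 3 events where the
    BFS metric gives 2). Provided for comparison only.
    """
    size = 1 << n
    W = np.zeros((size, size), dtype=np.int64)
    for i in range(size):
        for j in range(size):
            runs = 0
            for direction in (i & ~j, j & ~i):  # deletions, then insertions
                prev = 0
                for k in range(n):
                    cur = direction >> k & 1
                    if cur and not prev:
                        runs += 1
                    prev = cur
            W[i, j] = runs
    return W


# ---------------------------------------------------------------------------
# parsimony


def _leaf_cost_vector(entries: str, compressed_n: int) -> np.ndarray:
    """Zero/inf cost vector over states compatible with a leaf's entries."""
    size = 1 << compressed_n
    cost = np.zeros(size, dtype=np.int64)
    for k, c in enumerate(entries):
        if c == "?":
            continue
        bit = int(c)
        mask = np.array([(s >> k & 1) != bit for s in range(size)])
        cost[mask] = _INF
    return cost


def parsimony_states(
    region: IndelRegion,
    tree: TreeNode,
    W: Optional[np.ndarray] = None,
) -> tuple[dict[str, set[int]], int]:
    """Enumerate all node states consistent with minimum-cost labelings.

    Exact min-sum (Sankoff) message passing up and down the tree; leaves
    with observed entries are constrained to compatible states, fully
    missing leaves are free. Returns a mapping from node id (leaf name, or
    ``"node<k>"`` preorder index for unnamed internal nodes) to the set of
    integer-encoded states attaining the global minimum, plus that minimum
    cost. Refuses regions wider than :data:`MAX_WIDTH` or flagged skipped.
    """
    if region.compressed is None:
        compress_columns(region)
    n = region.n
    assert n is not None
    if region.skipped or n > MAX_WIDTH:
        raise ValueError(f"region of compressed width {n} refused (limit {MAX_WIDTH})")
    if W is None:
        W = event_cost_matrix(n)
    size = 1 << n
    leaf_entries = {}
    for sp, row in zip(region.species, region.matrix):
        # leaf entries over compressed columns: representative original column
        assert region.col_map is not None
        comp_entries = []
        seen = -1
        for j, ci in enumerate(region.col_map):
            if ci != seen:
                comp_entries.append(row[j])
                seen = ci
        leaf_entries[sp] = "".join(comp_entries)

    # assign ids
    names: dict[int, str] = {}
    counter = 0
    for node in tree.preorder():
        if node.is_leaf:
            names[id(node)] = node.name
        else:
            names[id(node)] = node.name or f"node{counter}"
        counter += 1

    # upward (post-order) Sankoff costs and per-child messages
    up: dict[int, np.ndarray] = {}
    msg: dict[int, np.ndarray] = {}  # message from child c to its parent
    for node in tree.postorder():
        if node.is_leaf:
            entries = leaf_entries.get(node.name, "?" * n)
            up[id(node)] = _leaf_cost_vector(entries, n)
        else:
            total = np.zeros(size, dtype=np.int64)
            for c in node.children:
                child_cost = np.minimum(up[id(c)], _INF)
                m = (W + child_cost[None, :]).min(axis=1)
                msg[id(c)] = m
                total = total + m
            up[id(node)] = total

    root = tree
    min_cost = int(up[id(root)].min())

    # downward pass: outside costs
    down: dict[int, np.ndarray] = {id(root): np.zeros(size, dtype=np.int64)}
    for node in tree.preorder():
        for c in node.children:
            # cost at parent excluding c's subtree
            excl = down[id(node)] + up[id(node)] - msg[id(c)]
            down[id(c)] = (excl[:, None] + W).min(axis=0)

    result: dict[str, set[int]] = {}
    for node in tree.preorder():
        total = up[id(node)] + down[id(node)]
        best = np.nonzero(total == min_cost)[0]
        result[names[id(node)]] = set(int(s) for s in best)
    return result, min_cost


# ---------------------------------------------------------------------------
# LS calls


@dataclass
class LSIndelCall:
    """A lineage-specific indel attributed to one terminal branch."""

    species: str
    block_index: int
    col_start: int
    col_end: int  # half-open original-column span
    kind: str  # insertion | deletion
    length: int
    quality: int  # quality bin
    eligible: bool = True
    corrected: bool = False


def call_ls_indels(
    region: IndelRegion,
    state_sets: dict[str, set[int]],
    tree: TreeNode,
    block: QualityAlignmentBlock,
) -> list[LSIndelCall]:
    """Extract lineage-specific calls column-by-column from optimal states.

    A leaf present (1) at a compressed column whose parent's optimal states
    are unanimously 0 there is an LS insertion; a leaf absent (0) under a
    unanimous parent 1 is an LS deletion. Parent ambiguity (both 0 and 1
    among optimal states) or a ``?`` leaf entry yields no call. Calls are
    expanded to original columns and adjacent same-type columns merged.
    """
    if region.compressed is None or region.col_map is None:
        raise ValueError("region must be compressed")
    parents = tree.parent_map()
    node_by_id = {id(node): node for node in tree.preorder()}
    # map leaf name -> parent name key used in state_sets
    names: dict[int, str] = {}
    counter = 0
    for node in tree.preorder():
        names[id(node)] = node.name if (node.is_leaf or node.name) else f"node{counter}"
        counter += 1

    calls: list[LSIndelCall] = []
    for si, sp in enumerate(region.species):
        leaf = next((l for l in tree.leaves() if l.name == sp), None)
        if leaf is None:
            continue
        parent = parents[id(leaf)]
        if parent is None:
            continue
        pstates = state_sets[names[id(parent)]]
        row = region.matrix[si]
        # per-compressed-column LS verdicts
        verdict: list[Optional[str]] = []
        seen = -1
        for j, ci in enumerate(region.col_map):
            if ci == seen:
                continue
            seen = ci
            c = row[j]
            if c == "?":
                verdict.append(None)
                continue
            bits = {s >> ci & 1 for s in pstates}
            if c == "1" and bits == {0}:
                verdict.append("insertion")
            elif c == "0" and bits == {1}:
                verdict.append("deletion")
            else:
                verdict.append(None)
        # expand to original columns, merge adjacent same-type
        j = 0
        while j < region.width:
            kind = verdict[region.col_map[j]]
            if kind is None:
                j += 1
                continue
            k = j
            while k < region.width and verdict[region.col_map[k]] == kind:
                k += 1
            c0 = region.col_start + j
            c1 = region.col_start + k
            # finished-grade rows carry no quality track: top bin, never corrected
            if block.row(sp).quality is None:
                q = 9
            else:
                q = indel_quality(block, sp, c0, c1, kind)
            calls.append(
                LSIndelCall(
                    species=sp,
                    block_index=region.block_index,
                    col_start=c0,
                    col_end=c1,
                    kind=kind,
                    length=k - j,
                    quality=q,
                )
            )
            j = k
    return calls


# ---------------------------------------------------------------------------
# imputation


def impute(
    blocks: Sequence[QualityAlignmentBlock],
    calls: Sequence[LSIndelCall],
    threshold: int = 25,
) -> tuple[list[QualityAlignmentBlock], list[dict]]:
    """Revert low-quality lineage-specific indels to the ancestral state.

    Calls whose quality-bin representative is below *threshold* (raw phred
    units) are corrected: LS insertions have their bases excised (columns
    made all-gap are dropped), LS deletions are filled with ``N`` at
    quality bin 0. Row ``size``/``start`` fields and the start coordinates
    of downstream blocks on the same source are updated. Overlapping
    contradictory calls are resolved first-wins with a warning.

    Returns edited copies of the blocks and an edit log (one dict per
    corrected call, with original coordinates enabling reversal).
    """
    edited = [b.copy() for b in blocks]
    log: list[dict] = []
    # per-source cumulative size change, applied to later blocks' starts
    offset: dict[str, int] = {}

    by_block: dict[int, list[LSIndelCall]] = {}
    for call in calls:
        by_block.setdefault(call.block_index, []).append(call)

    for bi, block in enumerate(edited):
        # shift starts by edits made in earlier blocks
        for row in block.rows:
            if row.src in offset and offset[row.src] != 0:
                row.start += offset[row.src]

        todo = sorted(
            (c for c in by_block.get(bi, [])
             if bin_representative(c.quality) < threshold),
            key=lambda c: (c.col_start, c.col_end),
        )
        claimed: list[tuple[int, int, str]] = []
        for call in todo:
            clash = [
                (s, e, sp) for s, e, sp in claimed
                if sp == call.species and s < call.col_end and call.col_start < e
            ]
            if clash:
                warnings.warn(
                    f"block {bi}: overlapping calls for {call.species} at "
                    f"{call.col_start}-{call.col_end}; first wins"
                )
                continue
            claimed.append((call.col_start, call.col_end, call.species))
            row = block.row(call.species)
            text = list(row.text)
            qual = list(row.quality) if row.quality is not None else None
            src_pos = row.start + sum(
                1 for i in range(call.col_start) if row.text[i] != GAP
            )
            if call.kind == "insertion":
                removed = "".join(
                    text[i] for i in range(call.col_start, call.col_end)
                    if text[i] != GAP
                )
                for i in range(call.col_start, call.col_end):
                    if text[i] != GAP:
                        text[i] = GAP
                        if qual is not None:
                            qual[i] = GAP
                row.size -= len(removed)
                offset[row.src] = offset.get(row.src, 0) - len(removed)
                action = "excise"
                detail = removed
            else:  # deletion: fill with N at quality bin 0
                filled = 0
                for i in range(call.col_start, call.col_end):
                    if text[i] == GAP:
                        text[i] = "N"
                        if qual is not None:
                            qual[i] = encode_quality_char(0)
                        filled += 1
                row.size += filled
                offset[row.src] = offset.get(row.src, 0) + filled
                action = "fill"
                detail = "N" * filled
            row.text = "".join(text)
            if qual is not None:
                row.quality = "".join(qual)
            call.corrected = True
            log.append(
                {
                    "src": row.src,
                    "start": src_pos,
                    "end": src_pos + call.length,
                    "species": call.species,
                    "block": bi,
                    "col_start": call.col_start,
                    "col_end": call.col_end,
                    "type": call.kind,
                    "length": call.length,
                    "quality": bin_representative(call.quality),
                    "action": action,
                    "detail": detail,
                }
            )
        _drop_allgap_columns(block)
    return edited, log


def _drop_allgap_columns(block: QualityAlignmentBlock) -> None:
    ncols = block.ncols
    keep = [
        i for i in range(ncols)
        if any(r.text[i] != GAP for r in block.rows)
    ]
    if len(keep) == ncols:
        return
    for r in block.rows:
        r.text = "".join(r.text[i] for i in keep)
        if r.quality is not None:
            r.quality = "".join(r.quality[i] for i in keep)
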