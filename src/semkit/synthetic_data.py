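"""Truth-tracked synthetic inputs embodying the error-model assumptions.

Three generators cover the toolkit's input space:

* :func:`simulate_assembly` — a pairwise draft-vs-finished alignment. Read
  depth at each position is Poisson with mean ``coverage`` conditioned on
  being >= 1, the assembled quality is the sum of that many independent
  draws from the single-read quality distribution ``p1``, and basecall
  errors strike with probability ``10**(-q/10)`` at the (uncapped) summed
  quality ``q``. Indel errors strike at a configurable multiple of the
  basecall error probability, reflecting the shared quality dependence of
  the two error classes. Polymorphism between the sequenced individuals is
  injected independently of quality.

* :func:`simulate_alignment` — a gapless-rooted multi-species alignment
  evolved down a phylogeny under a reversible substitution model with
  short (<= 10 bp) true indels; the alignment is the true homology, no
  aligner is involved. A coding mode biases true indel lengths toward
  multiples of three.

* :func:`inject_errors` — corrupts designated rows of an existing
  alignment with simulated quality tracks and quality-dependent basecall
  and indel errors, recording a truth table from which
  :func:`replay_truth` reconstructs the clean input exactly.

All randomness flows through one :class:`numpy.random.Generator` seeded
from the config, so every output is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .align_io import (
    GAP,
    MafRow,
    QualityAlignmentBlock,
    bin_quality,
    encode_quality_char,
)
from .coverage_model import QualityDistribution
from .phylo_error import BASES, SubstitutionModel, TreeNode, parse_newick

__all__ = [
    "SimulationConfig",
    "AssemblySimulation",
    "AlignmentSimulation",
    "InjectionResult",
    "default_single_read_profile",
    "default_tree_newick",
    "simulate_assembly",
    "simulate_alignment",
    "inject_errors",
    "replay_truth",
]

_BASE_IDX = {b: i for i, b in enumerate(BASES)}


def default_single_read_profile() -> QualityDistribution:
    """A capillary-like single-read quality distribution.

    Emulates reads whose ends degrade: 13.7% of bases fall below phred 20
    (the heavy lower tail produced by read ends), a small mid-range shelf,
    and ~80% of bases at finished-grade scores (>= 45). Defined at raw
    phred resolution.
    """
    pairs = [
        # low-quality tail, 13.7% total
        (8, 0.0152), (10, 0.0228), (12, 0.0305), (14, 0.0305),
        (16, 0.0228), (18, 0.0152),
        # mid-range shelf, 6.3%
        (22, 0.018), (27, 0.015), (32, 0.012), (37, 0.010), (42, 0.008),
        # finished-grade bulk, 80%
        (45, 0.30), (48, 0.25), (50, 0.25),
    ]
    return QualityDistribution.from_pairs(pairs)


def default_tree_newick() -> str:
    """Six-taxon tree with mammal-like branch lengths (subs/site)."""
    return (
        "((speciesA:0.10,speciesB:0.12):0.05,"
        "((speciesC:0.08,speciesD:0.11):0.06,"
        "(speciesE:0.14,speciesF:0.09):0.04):0.03);"
    )


@dataclass
class SimulationConfig:
    """Knobs for all three generators; the defaults are the study conditions.

    Coverage 2x, nucleotide diversity ``pi = 5e-3`` (typical mammalian
    nuclear diversity), basecall error probability ``10**(-q/10)`` at the
    true summed quality, indel errors at a quarter of the basecall error
    probability (split between insertions and deletions — indel error
    rates run a factor ~4-5 below basecall rates), and true indels ~20-fold
    rarer than substitutions with a deletion bias.
    """

    seed: int = 0
    # assembly-level simulation
    genome_length: int = 20_000
    gc: float = 0.41
    coverage: float = 2.0
    p1: QualityDistribution = field(default_factory=default_single_read_profile)
    polymorphism_rate: float = 5e-3
    insertion_error_ratio: float = 0.125  # x basecall error probability
    deletion_error_ratio: float = 0.125
    error_indel_length_p: float = 0.7  # geometric, truncated at 10
    quality_cap: int = 50  # applied only when encoding scores for output
    error_spectrum: Optional[np.ndarray] = None  # 4x4, rows sum to 1 off-diag
    # alignment simulation
    tree_newick: str = field(default_factory=default_tree_newick)
    alignment_length: int = 5_000
    subst_model: SubstitutionModel = field(
        default_factory=SubstitutionModel.jukes_cantor
    )
    indel_sub_ratio: float = 0.05  # indel events per expected substitution
    deletion_fraction: float = 0.6
    true_indel_length_p: float = 0.5  # geometric, truncated at 10
    coding_mode: bool = False
    frame_fraction: float = 0.9  # coding mode: P(length in {3,6,9})

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def spectrum(self) -> np.ndarray:
        if self.error_spectrum is not None:
            M = np.asarray(self.error_spectrum, dtype=float)
        else:
            M = np.full((4, 4), 1.0 / 3.0)
            np.fill_diagonal(M, 0.0)
        return M


def _random_bases(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p)


def _truncated_poisson(lam: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Poisson(lam) conditioned on >= 1."""
    x = rng.poisson(lam, n)
    while True:
        zero = x == 0
        if not zero.any():
            return x
        x[zero] = rng.poisson(lam, int(zero.sum()))


def _summed_qualities(
    depths: np.ndarray, p1: QualityDistribution, rng: np.random.Generator
) -> np.ndarray:
    draws = p1.sample(int(depths.sum()), rng)
    offsets = np.concatenate([[0], np.cumsum(depths)[:-1]])
    return np.add.reduceat(draws, offsets)


def _geometric_length(p: float, rng: np.random.Generator, cap: int = 10) -> int:
    return int(min(rng.geometric(p), cap))


def _substitute(base_idx: int, M: np.ndarray, rng: np.random.Generator) -> int:
    return int(rng.choice(4, p=M[base_idx]))


# ---------------------------------------------------------------------------
# assembly simulation


@dataclass
class AssemblySimulation:
    """Pairwise draft-vs-reference block plus full truth."""

    block: QualityAlignmentBlock
    truth: pd.DataFrame
    raw_qualities: np.ndarray  # uncapped summed quality per surviving draft base
    depths: np.ndarray  # read depth per reference position


def simulate_assembly(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> AssemblySimulation:
    """Simulate a draft assembly aligned to its finished reference.

    The returned block has two rows, ``REF`` (finished, quality ``F``) and
    ``DRAFT`` (binned qualities, scores capped at ``quality_cap`` for
    encoding only). The truth table records every polymorphism, basecall
    error, insertion error and deletion error with alignment-column and
    source coordinates.
    """
    if config.coverage <= 0:
        raise ValueError("coverage must be positive")
    if rng is None:
        rng = config.rng()
    L = config.genome_length
    M = config.spectrum()

    ref = _random_bases(L, config.gc, rng)
    draft_true = ref.copy()
    poly = rng.random(L) < config.polymorphism_rate
    for i in np.nonzero(poly)[0]:
        draft_true[i] = _substitute(draft_true[i], M * 0 + (1 - np.eye(4)) / 3.0, rng)

    depths = _truncated_poisson(config.coverage, L, rng)
    q = _summed_qualities(depths, config.p1, rng)
    perr = 10.0 ** (-q / 10.0)

    observed = draft_true.copy()
    base_err = rng.random(L) < perr
    for i in np.nonzero(base_err)[0]:
        observed[i] = _substitute(draft_true[i], M, rng)

    ins_mask = rng.random(L) < config.insertion_error_ratio * perr
    del_mask = rng.random(L) < config.deletion_error_ratio * perr

    # deletion errors: mark runs of deleted reference positions
    deleted = np.zeros(L, dtype=bool)
    del_events = []  # (start_pos, length)
    for i in np.nonzero(del_mask)[0]:
        if deleted[i]:
            continue
        length = _geometric_length(config.error_indel_length_p, rng)
        length = min(length, L - i)
        if deleted[i : i + length].any():
            continue
        deleted[i : i + length] = True
        del_events.append((int(i), length))
    del_starts = {s: l for s, l in del_events}

    ins_events = {}  # anchor position -> list of inserted base indices
    for i in np.nonzero(ins_mask)[0]:
        if deleted[i]:
            continue
        length = _geometric_length(config.error_indel_length_p, rng)
        ins_events[int(i)] = list(_random_bases(length, config.gc, rng))

    # materialize the alignment
    ref_text: list[str] = []
    draft_text: list[str] = []
    draft_qual: list[str] = []
    raw_q: list[int] = []
    truth_rows: list[dict] = []
    col = 0
    draft_pos = 0
    for i in range(L):
        qc = encode_quality_char(bin_quality(min(int(q[i]), config.quality_cap)))
        if deleted[i]:
            ref_text.append(BASES[ref[i]])
            draft_text.append(GAP)
            draft_qual.append(GAP)
            if i in del_starts:
                truth_rows.append(
                    {
                        "kind": "deletion_error",
                        "column": col,
                        "ref_pos": i,
                        "draft_pos": draft_pos,
                        "length": del_starts[i],
                        "true": "".join(
                            BASES[draft_true[j]] for j in range(i, i + del_starts[i])
                        ),
                        "q_raw": int(q[i]),
                        "bin": bin_quality(min(int(q[i]), config.quality_cap)),
                    }
                )
            col += 1
            continue
        ref_text.append(BASES[ref[i]])
        draft_text.append(BASES[observed[i]])
        draft_qual.append(qc)
        raw_q.append(int(q[i]))
        if poly[i]:
            truth_rows.append(
                {
                    "kind": "polymorphism",
                    "column": col,
                    "ref_pos": i,
                    "draft_pos": draft_pos,
                    "length": 1,
                    "true": BASES[draft_true[i]],
                    "q_raw": int(q[i]),
                    "bin": bin_quality(min(int(q[i]), config.quality_cap)),
                }
            )
        if base_err[i]:
            truth_rows.append(
                {
                    "kind": "basecall_error",
                    "column": col,
                    "ref_pos": i,
                    "draft_pos": draft_pos,
                    "length": 1,
                    "true": BASES[draft_true[i]],
                    "q_raw": int(q[i]),
                    "bin": bin_quality(min(int(q[i]), config.quality_cap)),
                }
            )
        col += 1
        draft_pos += 1
        if i in ins_events:
            bases = ins_events[i]
            truth_rows.append(
                {
                    "kind": "insertion_error",
                    "column": col,
                    "ref_pos": i,
                    "draft_pos": draft_pos,
                    "length": len(bases),
                    "true": "",
                    "q_raw": int(q[i]),
                    "bin": bin_quality(min(int(q[i]), config.quality_cap)),
                }
            )
            for b in bases:
                ref_text.append(GAP)
                draft_text.append(BASES[b])
                draft_qual.append(qc)
                raw_q.append(int(q[i]))
                col += 1
                draft_pos += 1

    draft_size = sum(1 for c in draft_text if c != GAP)
    block = QualityAlignmentBlock(
        rows=[
            MafRow("REF.chr1", 0, L, "+", L, "".join(ref_text),
                   quality="".join("F" if c != GAP else GAP for c in ref_text)),
            MafRow("DRAFT.chr1", 0, draft_size, "+", draft_size,
                   "".join(draft_text), quality="".join(draft_qual)),
        ]
    )
    block.validate()
    truth = pd.DataFrame(
        truth_rows,
        columns=["kind", "column", "ref_pos", "draft_pos", "length", "true",
                 "q_raw", "bin"],
    )
    return AssemblySimulation(
        block=block, truth=truth, raw_qualities=np.array(raw_q), depths=depths
    )


# ---------------------------------------------------------------------------
# alignment simulation


@dataclass
class AlignmentSimulation:
    """Multi-species true-homology alignment plus true-indel truth."""

    block: QualityAlignmentBlock
    truth: pd.DataFrame
    tree: TreeNode


def _true_indel_length(config: SimulationConfig, rng: np.random.Generator) -> int:
    if config.coding_mode and rng.random() < config.frame_fraction:
        return int(rng.choice([3, 6, 9], p=[0.5, 0.3, 0.2]))
    return _geometric_length(config.true_indel_length_p, rng)


def simulate_alignment(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> AlignmentSimulation:
    """Evolve sequences down the tree with substitutions and short indels.

    The alignment is the true homology: insertion events open fresh
    columns (gap in every other lineage), deletions leave gaps. Events per
    branch are Poisson with mean ``indel_sub_ratio * branch_length *
    current_sites``. Truth records one row per indel event with its final
    alignment-column span and the branch (child node) it occurred on.
    """
    if rng is None:
        rng = config.rng()
    tree = parse_newick(config.tree_newick)
    L = config.alignment_length

    # name internal nodes deterministically (preorder), as parsimony does
    counter = 0
    names: dict[int, str] = {}
    for node in tree.preorder():
        names[id(node)] = node.name if (node.is_leaf or node.name) else f"node{counter}"
        counter += 1

    seqs: dict[int, list[int]] = {}  # node id -> list of base idx, -1 for gap
    col_ids: list[int] = list(range(L))
    next_col_id = L
    truth_rows: list[dict] = []

    root_seq = list(_random_bases(L, config.gc, rng))
    seqs[id(tree)] = root_seq

    def evolve(parent: TreeNode, child: TreeNode) -> None:
        nonlocal next_col_id
        t = child.length
        seq = list(seqs[id(parent)])
        # substitutions at non-gap sites
        P = config.subst_model.transition_matrix(t)
        nongap = [i for i, b in enumerate(seq) if b >= 0]
        if nongap:
            cur = np.array([seq[i] for i in nongap])
            new = cur.copy()
            for b in range(4):
                sel = cur == b
                if sel.any():
                    new[sel] = rng.choice(4, size=int(sel.sum()), p=P[b])
            for i, b in zip(nongap, new):
                seq[i] = int(b)
        seqs[id(child)] = seq
        # indel events
        n_sites = len([i for i in seq if i >= 0])
        mean_events = config.indel_sub_ratio * t * n_sites
        n_events = int(rng.poisson(mean_events))
        for _ in range(n_events):
            length = _true_indel_length(config, rng)
            if rng.random() < config.deletion_fraction:
                nongap = [i for i, b in enumerate(seq) if b >= 0]
                if len(nongap) <= length:
                    continue
                k = int(rng.integers(0, len(nongap) - length + 1))
                cols = nongap[k : k + length]
                for i in cols:
                    seq[i] = -1
                truth_rows.append(
                    {
                        "branch": names[id(child)],
                        "leaf": child.is_leaf,
                        "kind": "true_deletion",
                        "length": length,
                        "col_id_start": col_ids[cols[0]],
                        "col_id_end": col_ids[cols[-1]],
                    }
                )
            else:
                pos = int(rng.integers(0, len(seq) + 1))
                new_bases = list(_random_bases(length, config.gc, rng))
                new_ids = list(range(next_col_id, next_col_id + length))
                next_col_id += length
                col_ids[pos:pos] = new_ids
                for nid, s in seqs.items():
                    s[pos:pos] = [-1] * length
                seq[pos : pos + length] = new_bases
                truth_rows.append(
                    {
                        "branch": names[id(child)],
                        "leaf": child.is_leaf,
                        "kind": "true_insertion",
                        "length": length,
                        "col_id_start": new_ids[0],
                        "col_id_end": new_ids[-1],
                    }
                )
        # recurse after this branch is settled
        for g in child.children:
            evolve(child, g)

    for c in tree.children:
        evolve(tree, c)

    # map column ids to final indices
    id_to_col = {cid: i for i, cid in enumerate(col_ids)}
    for row in truth_rows:
        row["col_start"] = id_to_col.get(row.pop("col_id_start"), -1)
        row["col_end"] = id_to_col.get(row.pop("col_id_end"), -1) + 1

    rows = []
    for leaf in tree.leaves():
        seq = seqs[id(leaf)]
        text = "".join(BASES[b] if b >= 0 else GAP for b in seq)
        size = sum(1 for b in seq if b >= 0)
        rows.append(MafRow(f"{leaf.name}.chr1", 0, size, "+", size, text))
    block = QualityAlignmentBlock(rows=rows)
    _strip_allgap(block)
    block.validate()
    truth = pd.DataFrame(
        truth_rows,
        columns=["branch", "leaf", "kind", "length", "col_start", "col_end"],
    )
    return AlignmentSimulation(block=block, truth=truth, tree=tree)


def _strip_allgap(block: QualityAlignmentBlock) -> None:
    keep = [
        i for i in range(block.ncols)
        if any(r.text[i] != GAP for r in block.rows)
    ]
    if len(keep) == block.ncols:
        return
    for r in block.rows:
        r.text = "".join(r.text[i] for i in keep)
        if r.quality is not None:
            r.quality = "".join(r.quality[i] for i in keep)


# ---------------------------------------------------------------------------
# error injection


@dataclass
class InjectionResult:
    """Corrupted alignment plus the truth needed to undo every edit."""

    block: QualityAlignmentBlock
    truth: pd.DataFrame


def inject_errors(
    block: QualityAlignmentBlock,
    species: Sequence[str],
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> InjectionResult:
    """Corrupt designated rows with quality tracks and simulated errors.

    Each designated row receives a per-base quality track (Poisson depth,
    summed single-read draws) and then quality-dependent basecall errors,
    deletion errors (bases turned to gaps) and insertion errors (fresh
    columns, gap in all other rows). Truth rows carry final alignment
    columns, the species coordinate, and the true content, sufficient for
    :func:`replay_truth` to reconstruct the input block exactly.
    """
    if rng is None:
        rng = config.rng()
    M = config.spectrum()
    texts = {r.src: list(r.text) for r in block.rows}
    quals = {r.src: (list(r.quality) if r.quality else None) for r in block.rows}
    order = [r.src for r in block.rows]
    truth_rows: list[dict] = []

    for sp in species:
        row = block.row(sp)
        src = row.src
        text = texts[src]
        positions = [i for i, c in enumerate(text) if c != GAP]
        nb = len(positions)
        depths = _truncated_poisson(config.coverage, nb, rng)
        q = _summed_qualities(depths, config.p1, rng)
        perr = 10.0 ** (-q / 10.0)
        qchars = [
            encode_quality_char(bin_quality(min(int(x), config.quality_cap)))
            for x in q
        ]
        qual = [GAP] * len(text)
        for k, i in enumerate(positions):
            qual[i] = qchars[k]
        quals[src] = qual

        poly = rng.random(nb) < config.polymorphism_rate
        base_err = rng.random(nb) < perr
        del_mask = rng.random(nb) < config.deletion_error_ratio * perr
        ins_mask = rng.random(nb) < config.insertion_error_ratio * perr

        def bin_of(k: int) -> int:
            return bin_quality(min(int(q[k]), config.quality_cap))

        for k in np.nonzero(poly)[0]:
            i = positions[k]
            old = text[i]
            if old == "N":
                continue
            new = BASES[_substitute(_BASE_IDX[old], (1 - np.eye(4)) / 3.0, rng)]
            text[i] = new
            truth_rows.append(
                {"species": sp, "kind": "polymorphism", "col_start": i,
                 "col_end": i + 1, "base_pos": k, "length": 1, "true": old,
                 "q_raw": int(q[k]), "bin": bin_of(k)}
            )
        for k in np.nonzero(base_err)[0]:
            i = positions[k]
            old = text[i]
            if old == "N":
                continue
            new = BASES[_substitute(_BASE_IDX[old], M, rng)]
            text[i] = new
            truth_rows.append(
                {"species": sp, "kind": "basecall_error", "col_start": i,
                 "col_end": i + 1, "base_pos": k, "length": 1, "true": old,
                 "q_raw": int(q[k]), "bin": bin_of(k)}
            )
        # deletion errors
        deleted = np.zeros(nb, dtype=bool)
        for k in np.nonzero(del_mask)[0]:
            length = _geometric_length(config.error_indel_length_p, rng)
            length = min(length, nb - k)
            if deleted[k : k + length].any():
                continue
            deleted[k : k + length] = True
            cols = positions[k : k + length]
            removed = "".join(text[i] for i in cols)
            rq = "".join(qual[i] for i in cols)
            for i in cols:
                text[i] = GAP
                qual[i] = GAP
            truth_rows.append(
                {"species": sp, "kind": "deletion_error", "col_start": cols[0],
                 "col_end": cols[-1] + 1, "base_pos": k, "length": length,
                 "true": removed, "qual_chars": rq, "cols": list(cols),
                 "q_raw": int(q[k]), "bin": bin_of(k)}
            )
        # insertion errors: collect, then splice right-to-left
        insertions = []  # (column after which to insert, bases, qchar, base_pos, q_raw, bin)
        for k in np.nonzero(ins_mask)[0]:
            if deleted[k]:
                continue
            length = _geometric_length(config.error_indel_length_p, rng)
            bases = [BASES[b] for b in _random_bases(length, config.gc, rng)]
            insertions.append((positions[k], bases, qchars[k], int(k), int(q[k]), bin_of(k)))
        for at_col, bases, qc, k, qr, b in sorted(insertions, reverse=True):
            ins_at = at_col + 1
            length = len(bases)
            for osrc in order:
                if osrc == src:
                    texts[osrc][ins_at:ins_at] = bases
                    if quals[osrc] is not None:
                        quals[osrc][ins_at:ins_at] = [qc] * length
                else:
                    texts[osrc][ins_at:ins_at] = [GAP] * length
                    if quals[osrc] is not None:
                        quals[osrc][ins_at:ins_at] = [GAP] * length
            # shift previously recorded truth columns
            for trow in truth_rows:
                if trow["col_start"] >= ins_at:
                    trow["col_start"] += length
                    trow["col_end"] += length
                if "cols" in trow and trow["cols"] is not None:
                    trow["cols"] = [
                        c + length if c >= ins_at else c for c in trow["cols"]
                    ]
            truth_rows.append(
                {"species": sp, "kind": "insertion_error", "col_start": ins_at,
                 "col_end": ins_at + length, "base_pos": k + 1, "length": length,
                 "true": "", "q_raw": qr, "bin": b}
            )

    new_rows = []
    for r in block.rows:
        text = "".join(texts[r.src])
        qual = quals[r.src]
        size = sum(1 for c in text if c != GAP)
        new_rows.append(
            MafRow(r.src, r.start, size, r.strand, size,
                   text, quality="".join(qual) if qual is not None else None)
        )
    out = QualityAlignmentBlock(rows=new_rows, score=block.score)
    out.validate()
    truth = pd.DataFrame(
        truth_rows,
        columns=["species", "kind", "col_start", "col_end", "base_pos",
                 "length", "true", "qual_chars", "cols", "q_raw", "bin"],
    )
    return InjectionResult(block=out, truth=truth)


def replay_truth(
    result: InjectionResult, original_species: Sequence[str]
) -> QualityAlignmentBlock:
    """Reconstruct the pre-injection block from a truth table.

    Substitutions and deletion errors are reverted in place; all
    insertion-error columns are then dropped in one pass. Quality tracks of
    the corrupted species are removed (the clean input carried none).
    """
    block = result.block.copy()
    texts = {r.src: list(r.text) for r in block.rows}
    truth = result.truth
    src_of = {block.row(sp).src: sp for sp in original_species}

    # undo in reverse application order so stacked edits unwind correctly
    for _, t in truth.iloc[::-1].iterrows():
        src = block.row(t["species"]).src
        if t["kind"] in ("polymorphism", "basecall_error"):
            texts[src][t["col_start"]] = t["true"]
        elif t["kind"] == "deletion_error":
            for c, ch in zip(t["cols"], t["true"]):
                texts[src][c] = ch

    drop = set()
    for _, t in truth[truth["kind"] == "insertion_error"].iterrows():
        drop.update(range(t["col_start"], t["col_end"]))
    keep = [i for i in range(block.ncols) if i not in drop]

    for r in block.rows:
        r.text = "".join(texts[r.src][i] for i in keep)
        r.size = sum(1 for c in r.text if c != GAP)
        r.src_size = r.size
        if r.src in src_of:
            r.quality = None
    block.validate()
    return block
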