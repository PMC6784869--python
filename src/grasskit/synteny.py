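"""Collinear block chaining and multi-outgroup gene indel calling.

Synteny blocks are runs of homologous genes in conserved order between two
genomes, found here by sparse dynamic programming over homology anchors
(score = anchor count; a gap of more than ``max_gap_genes`` genes in either
genome breaks the chain; both orientations are searched; blocks below the
minimum anchor count are dropped and each anchor is used at most once).

Presence/absence calls then use outgroup triangulation between two focal
genomes (e.g. a diploid wheat chromosome vs its hexaploid homoeologue) and
three outgrass genomes: a gene of genome B inside a block but missing from
genome A is a deletion in A when at least two outgroups retain it in
collinear position; a gene of A absent everywhere else, with both flanking
anchors supported by at least two outgroups, is an insertion in A.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .assemblystats import round_half_up

__all__ = [
    "SyntenyBlock",
    "IndelCall",
    "chain_collinear",
    "chain_genomes",
    "call_gene_indels",
    "alignment_coverage",
]


@dataclass
class SyntenyBlock:
    block_id: str
    genome_a: str
    genome_b: str
    orientation: str  # '+' or '-'
    anchors: list  # (order_a, order_b, gene_a, gene_b), monotonic in a

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    @property
    def range_a(self) -> tuple[int, int]:
        ia = [a[0] for a in self.anchors]
        return min(ia), max(ia)

    @property
    def range_b(self) -> tuple[int, int]:
        ib = [a[1] for a in self.anchors]
        return min(ib), max(ib)


@dataclass(frozen=True)
class IndelCall:
    gene_id: str
    focal_genome: str
    call: str  # deleted_in_<genome> semantics carried by `call` + focal_genome
    supporting_outgroups: tuple
    block_id: str


# ---------------------------------------------------------------------------
# chaining
# ---------------------------------------------------------------------------

def _best_chain(anchors: Sequence[tuple], max_gap: int, sign: int) -> list[int]:
    """Indices of the best monotonic chain (sign=+1 rising b, -1 falling b).

    Ties broken by smaller total gap length, then earliest start. O(n^2) DP —
    adequate for desk-scale gene counts.
    """
    n = len(anchors)
    order = sorted(range(n), key=lambda i: (anchors[i][0], sign * anchors[i][1]))
    score = [1] * n
    gaps = [0] * n
    prev = [-1] * n
    for oi in range(n):
        i = order[oi]
        ai, bi = anchors[i][0], anchors[i][1]
        for oj in range(oi):
            j = order[oj]
            aj, bj = anchors[j][0], anchors[j][1]
            da = ai - aj
            db = (bi - bj) * sign
            if da <= 0 or db <= 0:
                continue
            if da - 1 > max_gap or db - 1 > max_gap:
                continue
            cand = (score[j] + 1, -(gaps[j] + (da - 1) + (db - 1)))
            if cand > (score[i], -gaps[i]) or (
                cand == (score[i], -gaps[i])
                and prev[i] >= 0
                and (anchors[j][0], sign * anchors[j][1])
                < (anchors[prev[i]][0], sign * anchors[prev[i]][1])
            ):
                score[i] = score[j] + 1
                gaps[i] = gaps[j] + (da - 1) + (db - 1)
                prev[i] = j
    if n == 0:
        return []
    best = max(
        range(n),
        key=lambda i: (score[i], -gaps[i], (-anchors[i][0], -sign * anchors[i][1])),
    )
    chain = []
    at = best
    while at >= 0:
        chain.append(at)
        at = prev[at]
    chain.reverse()
    return chain


def chain_collinear(
    order_a: Mapping[str, int],
    order_b: Mapping[str, int],
    pairs: Iterable[tuple[str, str]],
    min_anchors: int = 3,
    max_gap_genes: int = 10,
    genome_a: str = "A",
    genome_b: str = "B",
) -> list[SyntenyBlock]:
    """Maximal-scoring monotonic anchor chains between two gene orders.

    ``order_a``/``order_b`` map gene id -> order index (unique per genome);
    ``pairs`` are homologous (gene_a, gene_b). Blocks are extracted greedily:
    best chain first (score, then smaller total gap, then earliest start),
    anchors removed, repeat; chains shorter than ``min_anchors`` are dropped.
    """
    for name, order in (("A", order_a), ("B", order_b)):
        vals = list(order.values())
        if len(set(vals)) != len(vals):
            raise ValueError(f"duplicate order indices in genome {name}")
    anchors = [
        (order_a[ga], order_b[gb], ga, gb)
        for ga, gb in pairs
        if ga in order_a and gb in order_b
    ]
    anchors = sorted(set(anchors))
    blocks: list[SyntenyBlock] = []
    counter = 0
    while anchors:
        plus = _best_chain(anchors, max_gap_genes, +1)
        minus = _best_chain(anchors, max_gap_genes, -1)

        def chain_key(chain: list[int], sign: int):
            if not chain:
                return (0, 0, ())
            gap = sum(
                (anchors[chain[t + 1]][0] - anchors[chain[t]][0] - 1)
                + abs(anchors[chain[t + 1]][1] - anchors[chain[t]][1]) - 1
                for t in range(len(chain) - 1)
            )
            return (len(chain), -gap, tuple(-anchors[chain[0]][k] for k in (0, 1)))

        use_plus = chain_key(plus, +1) >= chain_key(minus, -1)
        chain, orient = (plus, "+") if use_plus else (minus, "-")
        if len(chain) < min_anchors:
            break
        counter += 1
        chosen = [anchors[i] for i in chain]
        blocks.append(
            SyntenyBlock(
                block_id=f"{genome_a}-{genome_b}.{counter:03d}",
                genome_a=genome_a,
                genome_b=genome_b,
                orientation=orient,
                anchors=chosen,
            )
        )
        used = set(chain)
        anchors = [a for i, a in enumerate(anchors) if i not in used]
    return blocks


def chain_genomes(
    orders: Mapping[str, pd.DataFrame],
    pairs: pd.DataFrame,
    genome_a: str,
    genome_b: str,
    min_anchors: int = 3,
    max_gap_genes: int = 10,
) -> list[SyntenyBlock]:
    """Convenience wrapper over per-species order tables and a homology table
    (columns species_a, gene_a, species_b, gene_b)."""
    oa = dict(zip(orders[genome_a]["gene"], orders[genome_a]["order"]))
    ob = dict(zip(orders[genome_b]["gene"], orders[genome_b]["order"]))
    sel = pairs[
        ((pairs["species_a"] == genome_a) & (pairs["species_b"] == genome_b))
    ]
    swapped = pairs[
        ((pairs["species_a"] == genome_b) & (pairs["species_b"] == genome_a))
    ]
    pair_list = list(zip(sel["gene_a"], sel["gene_b"])) + list(
        zip(swapped["gene_b"], swapped["gene_a"])
    )
    return chain_collinear(
        oa, ob, pair_list, min_anchors=min_anchors, max_gap_genes=max_gap_genes,
        genome_a=genome_a, genome_b=genome_b,
    )


# ---------------------------------------------------------------------------
# indel calling
# ---------------------------------------------------------------------------

def _anchor_members(blocks: Iterable[SyntenyBlock]) -> tuple[set, set]:
    """Genes of genome_a / genome_b that are anchors in any given block."""
    in_a: set = set()
    in_b: set = set()
    for blk in blocks:
        for _, _, ga, gb in blk.anchors:
            in_a.add(ga)
            in_b.add(gb)
    return in_a, in_b


def call_gene_indels(
    focal_other_blocks: Sequence[SyntenyBlock],
    orders: Mapping[str, pd.DataFrame],
    outgroup_blocks: Mapping[tuple, Sequence[SyntenyBlock]],
    focal: str,
    other: str,
    outgroups: Sequence[str],
    min_outgroup_support: int = 2,
) -> list[IndelCall]:
    """Deletion/insertion calls inside focal-vs-other blocks.

    ``outgroup_blocks`` maps (genome, outgroup) -> that pair's block list, for
    genome in {focal, other}. A gene of ``other`` inside a block but not
    anchored to ``focal`` anywhere is ``deleted_in_focal`` when >= 2 outgroups
    hold it in collinear position; a gene of ``focal`` inside a block,
    anchored nowhere else, is ``inserted_in_focal`` when its flanking anchors
    are supported by >= 2 outgroups. Collinear support means anchor
    membership in a genome-vs-outgroup block, not mere homology presence.
    """
    focal_anchored, other_anchored = _anchor_members(focal_other_blocks)

    support: dict[str, dict[str, set]] = {focal: {}, other: {}}
    for genome in (focal, other):
        for out in outgroups:
            blocks = outgroup_blocks.get((genome, out), [])
            genes, _ = _anchor_members(blocks)
            for g in genes:
                support[genome].setdefault(g, set()).add(out)

    order_focal = orders[focal].sort_values("order")
    order_other = orders[other].sort_values("order")
    genes_focal = order_focal["gene"].tolist()
    genes_other = order_other["gene"].tolist()
    idx_focal = dict(zip(order_focal["gene"], order_focal["order"]))

    calls: list[IndelCall] = []
    seen: set = set()
    for blk in focal_other_blocks:
        a_lo, a_hi = blk.range_a
        b_lo, b_hi = blk.range_b
        block_anchor_a = sorted(a[0] for a in blk.anchors)

        # deletions in focal: `other` genes inside the block range, unmatched
        for gb in genes_other[b_lo : b_hi + 1]:
            if gb in other_anchored or gb in seen:
                continue
            outs = tuple(sorted(support[other].get(gb, ())))
            if len(outs) >= min_outgroup_support:
                seen.add(gb)
                calls.append(
                    IndelCall(gb, focal, f"deleted_in_{focal}", outs, blk.block_id)
                )

        # insertions in focal: focal genes inside the block range, anchored
        # nowhere (neither to `other` nor to any outgroup)
        for ga in genes_focal[a_lo : a_hi + 1]:
            if ga in focal_anchored or ga in seen:
                continue
            if support[focal].get(ga):
                continue  # collinear in some outgroup -> not a novel insertion
            pos = idx_focal[ga]
            left = [a for a in block_anchor_a if a < pos]
            right = [a for a in block_anchor_a if a > pos]
            if not left or not right:
                continue
            flank_genes = (
                genes_focal[max(left)],
                genes_focal[min(right)],
            )
            flank_support = [support[focal].get(g, set()) for g in flank_genes]
            if all(len(s) >= min_outgroup_support for s in flank_support):
                outs = tuple(sorted(flank_support[0] & flank_support[1]))
                seen.add(ga)
                calls.append(
                    IndelCall(ga, focal, f"inserted_in_{focal}", outs, blk.block_id)
                )
    return calls


# ---------------------------------------------------------------------------
# coverage arithmetic
# ---------------------------------------------------------------------------

def alignment_coverage(
    intervals: Iterable[tuple[int, int]], chromosome_length: int, decimals: int = 1
) -> tuple[int, float]:
    """Union of aligned intervals and its percentage of the chromosome."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if s < 0 or e > chromosome_length or s > e:
            raise ValueError(f"interval ({s}, {e}) outside chromosome")
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    covered = sum(e - s for s, e in merged)
    pct = round_half_up(Fraction(covered * 100, chromosome_length), decimals)
    return covered, pct
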