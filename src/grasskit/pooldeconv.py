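"""Read deconvolution for 2D-pooled BAC libraries.

Clones are arrayed in a row x column grid and sequenced as row pools and
column pools; a read is attributed to the clone at the intersection of the
single row pool and single column pool it aligns into. The assignment rule:
a read qualifies for a pool when its best alignment there reaches >= 90%
read coverage and >= 99% identity (both inclusive, both configurable); it is
assigned if and only if its qualifying hits are confined to exactly one row
pool and exactly one column pool and that cell holds a clone. Anything else
is rejected with the first applicable reason among no_hit, row_ambiguous,
col_ambiguous, empty_cell.

The bundled matcher is a k-mer-seeded (k=21) gapless comparator adequate for
substitution-only reads; precomputed PAF hits can be ingested instead, so any
production aligner can stand in front of the same assignment rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "PoolLayout",
    "AlignmentHit",
    "ReadAssignment",
    "match_reads",
    "assign_reads",
    "hits_from_paf",
    "summarize_assignments",
]

REJECT_REASONS = ("no_hit", "row_ambiguous", "col_ambiguous", "empty_cell")


class LayoutError(ValueError):
    """A hit references a pool the layout does not know."""


@dataclass
class PoolLayout:
    rows: list
    cols: list
    cell_to_bac: dict  # (row, col) -> bac id; absent cells are empty

    def __post_init__(self) -> None:
        seen: dict[str, tuple] = {}
        for cell, bac in self.cell_to_bac.items():
            if bac in seen:
                raise ValueError(f"BAC {bac} occupies two cells: {seen[bac]}, {cell}")
            seen[bac] = cell

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PoolLayout":
        rows: list = []
        cols: list = []
        cell_to_bac: dict = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                bac, row, col = line.split("\t")[:3]
                if row not in rows:
                    rows.append(row)
                if col not in cols:
                    cols.append(col)
                cell_to_bac[(row, col)] = bac
        return cls(rows=rows, cols=cols, cell_to_bac=cell_to_bac)


@dataclass(frozen=True)
class AlignmentHit:
    read_id: str
    contig_id: str
    pool_id: str
    coverage: float  # aligned fraction of the read
    identity: float  # matches / aligned columns

    def __post_init__(self) -> None:
        if not (0.0 <= self.coverage <= 1.0 and 0.0 <= self.identity <= 1.0):
            raise ValueError("coverage and identity must lie in [0, 1]")


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    bac_id: str | None  # None when rejected
    reason: str | None  # one of REJECT_REASONS when rejected


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def _best_gapless_hit(read: str, contig: str, index: dict, k: int) -> tuple[float, float] | None:
    """Best (coverage, identity) of the read against one contig.

    Seeds anchor candidate gapless placements (contig_pos - read_pos); each
    distinct placement is scored by comparing the read to the overlapping
    contig window. Substitution-only reads make this exact.
    """
    n, m = len(read), len(contig)
    offsets = set()
    for i in range(0, n - k + 1, max(1, k // 2)):
        for pos in index.get(read[i : i + k], ()):
            offsets.add(pos - i)
    best = None
    for off in offsets:
        a0 = max(0, -off)  # first read position that lands on the contig
        a1 = min(n, m - off)
        if a1 <= a0:
            continue
        aligned = a1 - a0
        matches = sum(
            1 for t in range(a0, a1) if read[t] == contig[t + off]
        )
        cov = aligned / n
        ident = matches / aligned
        if best is None or (cov, ident) > best:
            best = (cov, ident)
    return best


def match_reads(
    reads: Mapping[str, str],
    pool_contigs: Mapping[str, Mapping[str, str]],
    min_identity: float = 0.99,
    min_coverage: float = 0.90,
    k: int = 21,
    pool_membership: Mapping[str, Sequence[str]] | None = None,
) -> list[AlignmentHit]:
    """One best hit per (read, pool) meeting both thresholds (inclusive >=).

    ``pool_membership`` optionally restricts which reads are searched against
    which pools (a read is only aligned to *crossing* pools, i.e. those of the
    other axis than the pool it was sequenced in); by default every read is
    searched against every pool.
    """
    if not (0.0 < min_identity <= 1.0 and 0.0 < min_coverage <= 1.0):
        raise ValueError("thresholds must lie in (0, 1]")
    hits: list[AlignmentHit] = []
    for pool_id in pool_contigs:
        contigs = pool_contigs[pool_id]
        indexes = {}
        for cid, cseq in contigs.items():
            idx: dict[str, list[int]] = {}
            for pos in range(0, len(cseq) - k + 1):
                idx.setdefault(cseq[pos : pos + k], []).append(pos)
            indexes[cid] = idx
        read_ids: Iterable[str]
        if pool_membership is not None:
            read_ids = pool_membership.get(pool_id, ())
        else:
            read_ids = reads.keys()
        for rid in read_ids:
            read = reads[rid]
            best: tuple[float, float, str] | None = None
            for cid, cseq in contigs.items():
                res = _best_gapless_hit(read, cseq, indexes[cid], k)
                if res is None:
                    continue
                cov, ident = res
                if best is None or (cov, ident) > best[:2]:
                    best = (cov, ident, cid)
            if best is not None and best[0] >= min_coverage and best[1] >= min_identity:
                hits.append(
                    AlignmentHit(read_id=rid, contig_id=best[2], pool_id=pool_id,
                                 coverage=best[0], identity=best[1])
                )
    return hits


def hits_from_paf(
    path: str | Path,
    contig_to_pool: Mapping[str, str],
    min_identity: float = 0.99,
    min_coverage: float = 0.90,
) -> list[AlignmentHit]:
    """Ingest PAF alignments; coverage = aligned query fraction, identity =
    residue matches / alignment block length. Keeps the best hit per
    (read, pool) meeting both thresholds."""
    best: dict[tuple, AlignmentHit] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 11:
                continue
            qname, qlen, qstart, qend = parts[0], int(parts[1]), int(parts[2]), int(parts[3])
            tname, matches, blocklen = parts[5], int(parts[9]), int(parts[10])
            if tname not in contig_to_pool:
                raise LayoutError(f"PAF target {tname} maps to no known pool")
            pool = contig_to_pool[tname]
            cov = (qend - qstart) / qlen if qlen else 0.0
            ident = matches / blocklen if blocklen else 0.0
            if cov < min_coverage or ident < min_identity:
                continue
            key = (qname, pool)
            hit = AlignmentHit(qname, tname, pool, cov, ident)
            if key not in best or (hit.coverage, hit.identity) > (
                best[key].coverage, best[key].identity
            ):
                best[key] = hit
    return list(best.values())


# ---------------------------------------------------------------------------
# assignment rule
# ---------------------------------------------------------------------------

def assign_reads(
    hits: Iterable[AlignmentHit],
    layout: PoolLayout,
    read_ids: Iterable[str] | None = None,
) -> list[ReadAssignment]:
    """Apply the cross-point rule: unique row pool + unique column pool.

    ``read_ids``, when given, enumerates the full read set so reads with no
    hits at all still receive an explicit ``no_hit`` rejection; otherwise only
    reads present in ``hits`` are reported.
    """
    rowset, colset = set(layout.rows), set(layout.cols)
    per_read: dict[str, tuple[set, set]] = {}
    if read_ids is not None:
        per_read = {rid: (set(), set()) for rid in read_ids}
    for hit in hits:
        rows, cols = per_read.setdefault(hit.read_id, (set(), set()))
        if hit.pool_id in rowset:
            rows.add(hit.pool_id)
        elif hit.pool_id in colset:
            cols.add(hit.pool_id)
        else:
            raise LayoutError(f"hit pool {hit.pool_id} not in layout")

    out: list[ReadAssignment] = []
    for rid in per_read:
        rows, cols = per_read[rid]
        if not rows and not cols:
            out.append(ReadAssignment(rid, None, "no_hit"))
        elif len(rows) != 1:
            out.append(ReadAssignment(rid, None, "row_ambiguous"))
        elif len(cols) != 1:
            out.append(ReadAssignment(rid, None, "col_ambiguous"))
        else:
            cell = (next(iter(rows)), next(iter(cols)))
            bac = layout.cell_to_bac.get(cell)
            if bac is None:
                out.append(ReadAssignment(rid, None, "empty_cell"))
            else:
                out.append(ReadAssignment(rid, bac, None))
    return out


def summarize_assignments(assignments: Sequence[ReadAssignment]) -> dict:
    summary = {"total": len(assignments), "assigned": 0}
    for reason in REJECT_REASONS:
        summary[reason] = 0
    per_bac: dict[str, int] = {}
    for a in assignments:
        if a.bac_id is not None:
            summary["assigned"] += 1
            per_bac[a.bac_id] = per_bac.get(a.bac_id, 0) + 1
        else:
            summary[a.reason] += 1
    summary["per_bac"] = per_bac
    return summary


def write_assignments_tsv(assignments: Sequence[ReadAssignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tbac_id\treason\n")
        for a in assignments:
            fh.write(f"{a.read_id}\t{a.bac_id or 'REJECTED'}\t{a.reason or ''}\n")
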