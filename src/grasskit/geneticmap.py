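"""Bin-based F2 genetic map construction and pseudomolecule anchoring.

The pipeline mirrors how chromosome-scale plant assemblies are anchored with
a dense F2 map: SNP calls are filtered (depth >= 2, MAF >= 0.1), collapsed
into 50-SNP bins with a majority-consensus genotype, grouped into linkage
groups, ordered, cleaned of spurious double crossovers (adjacent crossovers
closer than 1 Mb, or more than 10 events per chromosome, are set to missing),
merged across <= 100 kb gaps, and converted to centimorgans with the Kosambi
mapping function

    d = 25 * ln((1 + 2r) / (1 - 2r)).

Grouping (single-linkage components at r <= 0.25) and ordering (greedy
nearest-neighbour chaining + 2-opt) are deliberately simple, reproducible
stand-ins for interactive mapping software; what is validated is recovery of
the true marker order and map length on simulated crosses, not algorithm
identity.

Genotype codes: 0 = A (parent-1 homozygote), 1 = H, 2 = B, -1 = missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SnpBin",
    "filter_snps",
    "make_bins",
    "estimate_rf",
    "rf_matrix",
    "group_markers",
    "order_markers",
    "correct_crossovers",
    "merge_bins",
    "kosambi",
    "map_positions",
    "build_map",
    "build_pseudomolecules",
    "GeneticMap",
    "PseudomoleculeBuild",
]

MISSING = -1


class UndefinedRecombinationError(ValueError):
    """No informative individual shared by the two bins."""


class ContigConflictError(ValueError):
    """A contig's bins land in more than one linkage group."""


# ---------------------------------------------------------------------------
# SNP filtering and binning
# ---------------------------------------------------------------------------

def filter_snps(
    calls: pd.DataFrame, min_depth: int = 2, min_maf: float = 0.1
) -> pd.DataFrame:
    """Keep calls with depth >= min_depth and MAF >= min_maf (both inclusive)."""
    if not {"depth", "maf"} <= set(calls.columns):
        raise ValueError("calls need 'depth' and 'maf' columns")
    mask = (calls["depth"] >= min_depth) & (calls["maf"] >= min_maf)
    return calls.loc[mask].reset_index(drop=True)


@dataclass
class SnpBin:
    bin_id: str
    contig: str
    start: int  # bp of first member SNP (1-based)
    end: int  # bp of last member SNP
    n_snps: int
    genotypes: np.ndarray  # per-individual consensus codes
    members: list = field(default_factory=list)

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


def _consensus(codes: np.ndarray, min_agreement: float = 0.6) -> int:
    """Majority genotype among non-missing member SNPs; ties or <60% -> missing."""
    called = codes[codes >= 0]
    if called.size == 0:
        return MISSING
    counts = np.bincount(called, minlength=3)
    top = int(np.argmax(counts))
    if counts[top] / called.size < min_agreement:
        return MISSING
    if (counts == counts[top]).sum() > 1:  # tie
        return MISSING
    return top


def make_bins(
    markers: pd.DataFrame,
    genotypes: np.ndarray,
    window: int = 50,
    step: int = 50,
    min_agreement: float = 0.6,
) -> list[SnpBin]:
    """Collapse consecutive SNPs into bins of <= ``window`` per contig.

    ``markers`` must be sorted by position within each contig and carry
    'marker', 'chrom'(or 'contig') and 'pos'; ``genotypes`` is the matching
    markers x individuals code matrix.
    """
    chrom_col = "contig" if "contig" in markers.columns else "chrom"
    bins: list[SnpBin] = []
    for contig, sub in markers.groupby(chrom_col, sort=False):
        idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        if not np.all(np.diff(pos) >= 0):
            raise ValueError(f"SNPs on {contig} are not position-sorted")
        for w0 in range(0, len(idx), step):
            sel = idx[w0 : w0 + window]
            if sel.size == 0:
                continue
            block = genotypes[sel]
            cons = np.array(
                [_consensus(block[:, j], min_agreement) for j in range(block.shape[1])],
                dtype=np.int8,
            )
            bins.append(
                SnpBin(
                    bin_id=f"{contig}:{w0 // step:04d}",
                    contig=str(contig),
                    start=int(pos[w0]),
                    end=int(pos[min(w0 + window, len(pos)) - 1]),
                    n_snps=int(sel.size),
                    genotypes=cons,
                    members=list(sub.loc[sel, "marker"]),
                )
            )
    return bins


# ---------------------------------------------------------------------------
# recombination fractions
# ---------------------------------------------------------------------------

def estimate_rf(g_i: np.ndarray, g_j: np.ndarray, cap: float = 0.499) -> float:
    """r = recombination events / (2 x informative individuals).

    A<->H and H<->B transitions count one event, A<->B counts two; pairs with
    a missing code are skipped. H<->H pairs are counted as zero events (their
    two-recombinant resolution is invisible without flanking information).
    """
    valid = (g_i >= 0) & (g_j >= 0)
    n = int(valid.sum())
    if n == 0:
        raise UndefinedRecombinationError("no informative individuals")
    events = int(np.abs(g_i[valid].astype(int) - g_j[valid].astype(int)).sum())
    return min(events / (2.0 * n), cap)


def rf_matrix(bins: Sequence[SnpBin], cap: float = 0.499) -> np.ndarray:
    geno = np.stack([b.genotypes for b in bins]).astype(np.int16)
    n = geno.shape[0]
    valid = geno >= 0
    out = np.zeros((n, n))
    for i in range(n):
        vi = valid[i]
        shared = valid & vi  # rows: j, broadcast over individuals
        counts = shared.sum(axis=1)
        diffs = np.abs(geno - geno[i])
        diffs[~shared] = 0
        events = diffs.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(counts > 0, events / (2.0 * np.maximum(counts, 1)), np.nan)
        out[i] = np.minimum(r, cap)
    np.fill_diagonal(out, 0.0)
    return out


def group_markers(rf: np.ndarray, max_r: float = 0.25) -> list[list[int]]:
    """Single-linkage connected components under r <= max_r."""
    n = rf.shape[0]
    if rf.shape != (n, n):
        raise ValueError("rf matrix must be square")
    g = nx.Graph()
    g.add_nodes_from(range(n))
    ii, jj = np.where(np.triu(rf <= max_r, k=1) & ~np.isnan(np.triu(rf, k=1)))
    g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


# ---------------------------------------------------------------------------
# ordering
# ---------------------------------------------------------------------------

def _greedy_chain(sub_rf: np.ndarray) -> list[int]:
    """Grow a path by repeatedly appending the nearest unused bin to an end."""
    n = sub_rf.shape[0]
    if n == 1:
        return [0]
    start = int(np.unravel_index(np.nanargmin(np.where(np.eye(n, dtype=bool), np.nan, sub_rf)), (n, n))[0])
    path = [start]
    used = {start}
    while len(path) < n:
        best = None
        for end, side in ((path[0], "left"), (path[-1], "right")):
            for cand in range(n):
                if cand in used:
                    continue
                r = sub_rf[end, cand]
                if np.isnan(r):
                    continue
                if best is None or r < best[0]:
                    best = (r, cand, side)
        if best is None:  # disconnected remainder: append arbitrarily
            cand = next(c for c in range(n) if c not in used)
            best = (0.5, cand, "right")
        _, cand, side = best
        used.add(cand)
        if side == "left":
            path.insert(0, cand)
        else:
            path.append(cand)
    return path


def _two_opt(path: list[int], sub_rf: np.ndarray, max_rounds: int = 20) -> list[int]:
    """2-opt segment reversals minimizing the sum of adjacent r."""
    def cost(p: Sequence[int]) -> float:
        return float(sum(sub_rf[p[t], p[t + 1]] for t in range(len(p) - 1)))

    n = len(path)
    best = list(path)
    for _ in range(max_rounds):
        improved = False
        for a in range(n - 1):
            for b in range(a + 1, n):
                left = best[a - 1] if a > 0 else None
                right = best[b + 1] if b + 1 < n else None
                old = 0.0
                new = 0.0
                if left is not None:
                    old += sub_rf[left, best[a]]
                    new += sub_rf[left, best[b]]
                if right is not None:
                    old += sub_rf[best[b], right]
                    new += sub_rf[best[a], right]
                if new < old - 1e-12:
                    best[a : b + 1] = best[a : b + 1][::-1]
                    improved = True
        if not improved:
            break
    return best


def order_markers(
    group: Sequence[int], rf: np.ndarray, bins: Sequence[SnpBin] | None = None
) -> list[int]:
    """Seriation of one linkage group: greedy chaining then 2-opt.

    When ``bins`` is given, the group is oriented so the bins of its first
    contig run in ascending physical position.
    """
    group = list(group)
    if len(group) < 2:
        return group
    sub = rf[np.ix_(group, group)]
    path = _two_opt(_greedy_chain(sub), sub)
    ordered = [group[i] for i in path]
    if bins is not None:
        first_contig = bins[ordered[0]].contig
        phys = [bins[i].midpoint for i in ordered if bins[i].contig == first_contig]
        ranks = list(range(len(phys)))
        if len(phys) >= 2:
            corr = np.corrcoef(ranks, phys)[0, 1]
            if np.isfinite(corr) and corr < 0:
                ordered.reverse()
    return ordered


# ---------------------------------------------------------------------------
# crossover sanitation
# ---------------------------------------------------------------------------

def _runs(genos: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of equal non-missing codes: (first idx, last idx, code)."""
    runs = []
    cur = None
    for t, g in enumerate(genos):
        if g < 0:
            continue
        if cur is None or g != cur[2]:
            if cur is not None:
                runs.append(cur)
            cur = (t, t, int(g))
        else:
            cur = (cur[0], t, cur[2])
    if cur is not None:
        runs.append(cur)
    return runs


def correct_crossovers(
    genotypes: np.ndarray,
    bin_positions: Sequence[float],
    min_cross_distance: float = 1e6,
    max_events: int = 10,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Remove implausible double crossovers along one ordered chromosome.

    For each individual: (1) any genotype segment whose two bounding
    crossovers lie closer than ``min_cross_distance`` is set to missing
    (killing spurious double crossovers); (2) if more than ``max_events``
    crossovers remain, the physically shortest interior segments are set to
    missing until the count is within bounds. Crossover positions are taken
    as midpoints between the flanking bins. Returns the corrected matrix and
    a change log; the operation never adds crossovers and is idempotent.
    """
    pos = np.asarray(bin_positions, dtype=float)
    out = genotypes.copy()
    log_rows = []
    n_ind = out.shape[1]
    for j in range(n_ind):
        col = out[:, j]

        def crossover_positions(runs):
            xpos = []
            for a in range(len(runs) - 1):
                left_end = runs[a][1]
                right_start = runs[a + 1][0]
                xpos.append(0.5 * (pos[left_end] + pos[right_start]))
            return xpos

        changed = True
        while changed:  # rule 1 until stable (merging runs can expose new pairs)
            changed = False
            runs = _runs(col)
            if len(runs) < 3:
                break
            xpos = crossover_positions(runs)
            for a in range(1, len(runs) - 1):
                if xpos[a] - xpos[a - 1] < min_cross_distance:
                    first, last, code = runs[a]
                    col[first : last + 1] = np.where(
                        col[first : last + 1] >= 0, MISSING, col[first : last + 1]
                    )
                    log_rows.append(
                        {"individual": j, "rule": "close_double_crossover",
                         "first_bin": first, "last_bin": last, "code": code}
                    )
                    changed = True
                    break

        # rule 2: cap the number of crossovers
        while True:
            runs = _runs(col)
            if len(runs) - 1 <= max_events or len(runs) < 3:
                break
            xpos = crossover_positions(runs)
            spans = [(xpos[a] - xpos[a - 1], a) for a in range(1, len(runs) - 1)]
            _, a = min(spans)
            first, last, code = runs[a]
            col[first : last + 1] = np.where(
                col[first : last + 1] >= 0, MISSING, col[first : last + 1]
            )
            log_rows.append(
                {"individual": j, "rule": "event_cap",
                 "first_bin": first, "last_bin": last, "code": code}
            )
    log = pd.DataFrame(
        log_rows, columns=["individual", "rule", "first_bin", "last_bin", "code"]
    )
    return out, log


def count_crossovers(genotypes: np.ndarray) -> np.ndarray:
    """Crossover (run-boundary) count per individual along the ordered bins."""
    return np.array(
        [max(0, len(_runs(genotypes[:, j])) - 1) for j in range(genotypes.shape[1])]
    )


# ---------------------------------------------------------------------------
# bin merging and distances
# ---------------------------------------------------------------------------

def _vectors_compatible(a: np.ndarray, b: np.ndarray) -> bool:
    both = (a >= 0) & (b >= 0)
    return bool(np.all(a[both] == b[both]))


def merge_bins(bins: Sequence[SnpBin], max_gap: float = 1e5) -> list[SnpBin]:
    """Merge physically adjacent bins with compatible genotypes.

    Adjacent bins on the same contig merge when the gap between their spans
    is <= ``max_gap`` and their genotype vectors agree wherever both are
    called (missing matches anything); merged vectors take the called value.
    """
    merged: list[SnpBin] = []
    for b in bins:
        if merged:
            prev = merged[-1]
            gap = b.start - prev.end
            if (
                b.contig == prev.contig
                and 0 <= gap <= max_gap
                and _vectors_compatible(prev.genotypes, b.genotypes)
            ):
                geno = prev.genotypes.copy()
                take = (geno < 0) & (b.genotypes >= 0)
                geno[take] = b.genotypes[take]
                merged[-1] = replace(
                    prev,
                    end=max(prev.end, b.end),
                    n_snps=prev.n_snps + b.n_snps,
                    genotypes=geno,
                    members=prev.members + b.members,
                )
                continue
        merged.append(replace(b, genotypes=b.genotypes.copy(),
                              members=list(b.members)))
    return merged


def kosambi(r: float) -> float:
    """Kosambi map distance 25*ln((1+2r)/(1-2r)) in centimorgans."""
    if not (0.0 <= r < 0.5):
        raise ValueError(f"recombination fraction {r} outside [0, 0.5)")
    return 25.0 * math.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


def map_positions(
    ordered_bins: Sequence[SnpBin], group_name: str = "LG1"
) -> pd.DataFrame:
    """Cumulative Kosambi cM along one ordered group."""
    rows = []
    cm = 0.0
    for t, b in enumerate(ordered_bins):
        r_next = np.nan
        if t + 1 < len(ordered_bins):
            try:
                r_next = estimate_rf(b.genotypes, ordered_bins[t + 1].genotypes)
            except UndefinedRecombinationError:
                r_next = np.nan
        rows.append(
            {"group": group_name, "order": t, "bin": b.bin_id, "contig": b.contig,
             "start": b.start, "end": b.end, "n_snps": b.n_snps,
             "cM": cm, "r_to_next": r_next}
        )
        if np.isfinite(r_next):
            cm += kosambi(float(r_next))
    return pd.DataFrame(rows)


@dataclass
class GeneticMap:
    table: pd.DataFrame  # group, order, bin, contig, start, end, cM, r_to_next
    bins: list
    bin_order: dict  # group -> list of bin indices
    change_log: pd.DataFrame

    @property
    def total_length_cm(self) -> float:
        return float(
            self.table.groupby("group")["cM"].max().sum()
        )


def build_map(
    markers: pd.DataFrame,
    genotypes: np.ndarray,
    window: int = 50,
    step: int | None = None,
    min_depth: int = 2,
    min_maf: float = 0.1,
    max_r_group: float = 0.25,
    min_cross_distance: float = 1e6,
    max_events: int = 10,
    merge_gap: float = 1e5,
) -> GeneticMap:
    """Full pipeline: filter -> bin -> group -> order -> merge -> correct ->
    Kosambi distances. Marker table columns: marker, chrom/contig, pos, depth,
    maf; genotype rows must align with the marker table."""
    step = window if step is None else step
    markers = markers.reset_index(drop=True)
    mask = (
        (markers["depth"] >= min_depth) & (markers["maf"] >= min_maf)
    ).to_numpy()
    kept = markers.loc[mask].reset_index(drop=True)
    geno = genotypes[mask]
    bins = make_bins(kept, geno, window=window, step=step)
    rf = rf_matrix(bins)
    groups = group_markers(rf, max_r=max_r_group)

    tables = []
    bin_order: dict[str, list[int]] = {}
    logs = []
    for gi, group in enumerate(groups):
        name = f"LG{gi + 1}"
        ordered_idx = order_markers(group, rf, bins)
        ordered = [bins[i] for i in ordered_idx]
        ordered = merge_bins(ordered, max_gap=merge_gap)
        geno_mat = np.stack([b.genotypes for b in ordered])
        corrected, log = correct_crossovers(
            geno_mat, [b.midpoint for b in ordered],
            min_cross_distance=min_cross_distance, max_events=max_events,
        )
        for b, row in zip(ordered, corrected):
            b.genotypes = row
        log["group"] = name
        logs.append(log)
        tables.append(map_positions(ordered, group_name=name))
        bin_order[name] = ordered_idx
    table = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    change_log = pd.concat(logs, ignore_index=True) if logs else pd.DataFrame()
    return GeneticMap(table, bins, bin_order, change_log)


# ---------------------------------------------------------------------------
# pseudomolecule construction
# ---------------------------------------------------------------------------

@dataclass
class PseudomoleculeBuild:
    chromosome: str
    placements: pd.DataFrame  # contig, start, end, strand, gap_after
    sequence: str
    unanchored: list


def build_pseudomolecules(
    contigs: Mapping[str, str],
    anchored: pd.DataFrame,
    gap_size: int = 100,
) -> list[PseudomoleculeBuild]:
    """Order and orient contigs along the map into chromosome sequences.

    ``anchored`` rows: contig, group, bin physical midpoint ('pos') and 'cM'.
    Contigs are ordered by mean cM of their bins (ties by physical order),
    oriented by the correlation between within-contig bin position and cM
    (single-bin or indeterminate -> forward), and joined with ``gap_size`` N
    gaps. A contig anchored to two groups raises ContigConflictError.
    """
    conflicts = anchored.groupby("contig")["group"].nunique()
    bad = conflicts[conflicts > 1]
    if len(bad):
        raise ContigConflictError(
            f"contigs in multiple groups: {sorted(bad.index.tolist())}"
        )
    builds = []
    anchored_set = set(anchored["contig"])
    unanchored = sorted(set(contigs) - anchored_set)
    for group, sub in anchored.groupby("group"):
        stats = []
        for contig, rows in sub.groupby("contig"):
            mean_cm = rows["cM"].mean()
            strand = "+"
            if len(rows) >= 2:
                corr = np.corrcoef(rows["pos"], rows["cM"])[0, 1]
                if np.isfinite(corr) and corr < 0:
                    strand = "-"
            stats.append((mean_cm, rows["pos"].min(), contig, strand))
        stats.sort()
        pieces = []
        rows_out = []
        cursor = 0
        for t, (_, _, contig, strand) in enumerate(stats):
            seq = contigs[contig]
            if strand == "-":
                seq = seq[::-1].translate(str.maketrans("ACGTacgt", "TGCAtgca"))
            start = cursor
            end = start + len(seq)
            gap_after = gap_size if t + 1 < len(stats) else 0
            rows_out.append(
                {"contig": contig, "start": start, "end": end,
                 "strand": strand, "gap_after": gap_after}
            )
            pieces.append(seq)
            if gap_after:
                pieces.append("N" * gap_after)
            cursor = end + gap_after
        builds.append(
            PseudomoleculeBuild(
                chromosome=str(group),
                placements=pd.DataFrame(rows_out),
                sequence="".join(pieces),
                unanchored=unanchored,
            )
        )
    return builds
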