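"""LTR retrotransposon detection, divergence estimation and insertion dating.

An LTR retrotransposon inserts with two identical long terminal repeats; the
repeats then accumulate substitutions independently, so their divergence K
clocks the insertion: T = K / (2r) with r the substitution rate per site per
year (default 1.3e-8, the rate commonly used for grass transposons).
Divergence is estimated with the Kimura two-parameter model, which corrects
transitions (P) and transversions (Q) separately:

    K = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

Intact elements (two LTRs flanking an internal domain) are found by a
k-mer-seeded self-comparison with gapless x-drop extension and target-site
duplication (TSD) boundary refinement; solo-LTRs — single repeats left by
intra-element recombination — are found by library matching at >85% identity,
excluding anything overlapping an intact element. The solo/intact ratio per
superfamily (Gypsy, Copia) indexes element turnover.
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from .assemblystats import round_half_up

__all__ = [
    "LTRElement",
    "DivergenceEstimate",
    "k2p_from_counts",
    "k2p_distance",
    "insertion_age",
    "solo_intact_ratio",
    "age_histogram",
    "find_intact_ltr",
    "find_solo_ltr",
    "date_elements",
]

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")

DEFAULT_RATE = 1.3e-8  # substitutions per site per year


class SaturationError(ValueError):
    """K2P log argument non-positive: divergence beyond what the model can invert."""


@dataclass
class LTRElement:
    element_id: str
    family: str  # Gypsy / Copia / other
    kind: str  # intact / solo
    chrom: str
    ltr5: tuple[int, int]  # 0-based half-open
    ltr3: tuple[int, int] | None = None
    internal: tuple[int, int] | None = None
    tsd_len: int = 0
    identity: float | None = None

    @property
    def span(self) -> tuple[int, int]:
        if self.kind == "intact":
            assert self.ltr3 is not None
            return (self.ltr5[0], self.ltr3[1])
        return self.ltr5


@dataclass
class DivergenceEstimate:
    element_id: str
    sites: int
    p: float  # transition fraction
    q: float  # transversion fraction
    k: float  # K2P distance
    age_years: float
    rate: float
    family: str = "other"


# ---------------------------------------------------------------------------
# divergence and dating
# ---------------------------------------------------------------------------

def k2p_from_counts(n_sites: int, n_transitions: int, n_transversions: int) -> float:
    if n_sites <= 0:
        raise ValueError("need at least one compared site")
    p = n_transitions / n_sites
    q = n_transversions / n_sites
    a = 1.0 - 2.0 * p - q
    b = 1.0 - 2.0 * q
    if a <= 0.0 or b <= 0.0:
        raise SaturationError(f"saturated divergence (P={p:.3f}, Q={q:.3f})")
    return -0.5 * math.log(a * math.sqrt(b))


def _aligned_columns(seq_a: str, seq_b: str) -> tuple[str, str]:
    """Global alignment returning the two gapped rows.

    Gap penalties are set so two substitutions are never re-written as an
    insertion/deletion pair (which would silently drop divergent columns
    from the K2P counts and bias distances downward).
    """
    from Bio import Align

    aligner = Align.PairwiseAligner(
        match_score=2, mismatch_score=-1, open_gap_score=-6,
        extend_gap_score=-2, mode="global",
    )
    aln = aligner.align(seq_a, seq_b)[0]
    return str(aln[0]), str(aln[1])


def k2p_distance(
    seq_a: str,
    seq_b: str,
    element_id: str = "",
    rate: float = DEFAULT_RATE,
    family: str = "other",
    aligned: bool = False,
) -> DivergenceEstimate:
    """K2P divergence between two LTR copies.

    With ``aligned=True`` the inputs are treated as alignment rows (equal
    length, may contain '-'); otherwise a global alignment is computed first.
    Gap columns are excluded from P, Q and the site count.
    """
    a, b = (seq_a.upper(), seq_b.upper())
    if not aligned:
        a, b = _aligned_columns(a, b)
    elif len(a) != len(b):
        raise ValueError("aligned=True requires equal-length rows")
    sites = ts = tv = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-" or x not in "ACGT" or y not in "ACGT":
            continue
        sites += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            ts += 1
        else:
            tv += 1
    k = k2p_from_counts(sites, ts, tv)
    return DivergenceEstimate(
        element_id=element_id,
        sites=sites,
        p=ts / sites,
        q=tv / sites,
        k=k,
        age_years=insertion_age(k, rate),
        rate=rate,
        family=family,
    )


def insertion_age(k: float, rate: float = DEFAULT_RATE) -> float:
    """T = K / (2r) years; the two LTRs diverge along two branches."""
    if k < 0:
        raise ValueError("K must be non-negative")
    if rate <= 0:
        raise ValueError("rate must be positive")
    return k / (2.0 * rate)


def solo_intact_ratio(n_solo: int, n_intact: int, decimals: int = 1) -> float:
    if n_intact <= 0:
        raise ZeroDivisionError("solo/intact ratio undefined with no intact elements")
    from fractions import Fraction

    return round_half_up(Fraction(n_solo, n_intact), decimals)


def age_histogram(
    estimates: Iterable[DivergenceEstimate],
    bin_width_years: float = 2.5e5,
    max_age_years: float = 5e6,
) -> pd.DataFrame:
    """Counts per (family, age bin); the per-family mode bin carries ``is_mode``."""
    rows = [(e.family, e.age_years) for e in estimates]
    n_bins = int(math.ceil(max_age_years / bin_width_years))
    edges = np.arange(n_bins + 1) * bin_width_years
    out = []
    frame = pd.DataFrame(rows, columns=["family", "age"])
    for family, sub in frame.groupby("family"):
        counts, _ = np.histogram(sub["age"].clip(upper=max_age_years - 1e-9), bins=edges)
        mode = int(np.argmax(counts)) if counts.sum() else -1
        for i, c in enumerate(counts):
            out.append(
                {
                    "family": family,
                    "bin_start_years": edges[i],
                    "bin_end_years": edges[i + 1],
                    "count": int(c),
                    "is_mode": i == mode and c > 0,
                }
            )
    return pd.DataFrame(
        out, columns=["family", "bin_start_years", "bin_end_years", "count", "is_mode"]
    )


# ---------------------------------------------------------------------------
# intact-element detection
# ---------------------------------------------------------------------------

def _xdrop_extend(
    seq: str, i: int, j: int, k: int, xdrop: int = 25
) -> tuple[int, int, int, int]:
    """Gapless extension of an exact k-mer seed at positions i and j (i < j).

    Scores +1/match, -2/mismatch; keeps the best-scoring endpoints. Returns
    (start_offset_left, end_offset_right, matches, length) relative to the seed.
    """
    n = len(seq)
    # right extension (beyond the seed)
    best_r, score, best_score = 0, 0, 0
    a, b = i + k, j + k
    off = 0
    while b + off < n and j + k + off < j + 20000:
        score += 1 if seq[a + off] == seq[b + off] else -2
        off += 1
        if score > best_score:
            best_score, best_r = score, off
        if best_score - score > xdrop:
            break
    # left extension
    best_l, score, best_score = 0, 0, 0
    off = 0
    while i - off - 1 >= 0 and j - off - 1 >= i + k:
        score += 1 if seq[i - off - 1] == seq[j - off - 1] else -2
        off += 1
        if score > best_score:
            best_score, best_l = score, off
        if best_score - score > xdrop:
            break
    s1, e1 = i - best_l, i + k + best_r
    matches = sum(1 for t in range(s1, e1) if seq[t] == seq[t + (j - i)])
    return best_l, best_r, matches, e1 - s1


def _refine_with_tsd(
    seq: str,
    s1: int,
    e1: int,
    d: int,
    tsd_range: tuple[int, int] = (4, 6),
    max_shift: int = 4,
) -> tuple[int, int, int]:
    """Adjust repeat boundaries so a target-site duplication flanks the element.

    Extension over identical copies can overrun the true boundary wherever the
    flanking bases happen to agree; the TSD (the short host duplication created
    at insertion) pins it down. Prefers the longest exactly-matching TSD, then
    the smallest boundary shift. Returns (start_shift, end_shift, tsd_len);
    (0, 0, 0) when no TSD is found.
    """
    n = len(seq)
    # score 2*t - shift: a longer duplication is stronger evidence, but a
    # chance match far from the extension boundary should not outrank a
    # shorter duplication sitting exactly where the extension stopped
    candidates = []  # (-(2t - shift), shift, a, b)
    for t in range(tsd_range[0], tsd_range[1] + 1):
        for a in range(-max_shift, max_shift + 1):
            left = seq[s1 + a - t : s1 + a]
            if len(left) < t:
                continue
            for b in range(-max_shift, max_shift + 1):
                right_start = e1 + d + b
                if right_start + t > n:
                    continue
                if seq[right_start : right_start + t] == left:
                    shift = abs(a) + abs(b)
                    candidates.append((-(2 * t - shift), shift, a, b, t))
    if not candidates:
        return (0, 0, 0)
    _, _, a, b, t = min(candidates)
    return (a, b, t)


@dataclass
class _Candidate:
    s1: int
    e1: int
    d: int
    identity: float
    tsd_len: int
    tsd_score: int = 0


def find_intact_ltr(
    genome: Mapping[str, str],
    min_ltr_len: int = 100,
    max_ltr_len: int = 3000,
    min_identity: float = 0.85,
    internal_range: tuple[int, int] = (1000, 15000),
    family_library: Mapping[str, str] | None = None,
    k: int = 13,
    max_kmer_hits: int = 200,
    require_tsd: bool = False,
) -> list[LTRElement]:
    """Self-comparison scan for [5'LTR][internal][3'LTR] structures.

    Two same-strand repeats within the length and spacing bounds, aligning at
    >= ``min_identity``, form a candidate; boundaries are refined by TSD
    search; overlapping candidates are resolved greedily (TSD-confirmed
    first, then identity, then shorter span). ``require_tsd=True`` keeps only
    TSD-confirmed elements, which suppresses chimeric pairings of distinct
    nearby elements of one family at the cost of missing elements whose TSD
    has decayed. Family is the best library match of the 5'LTR when a
    library is supplied.
    """
    elements: list[LTRElement] = []
    counter = 0
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        index: dict[str, list[int]] = {}
        for pos in range(0, len(seq) - k + 1):
            index.setdefault(seq[pos : pos + k], []).append(pos)
        min_span = internal_range[0] + min_ltr_len
        max_span = internal_range[1] + max_ltr_len
        seen_diag: set[tuple[int, int]] = set()
        cands: list[_Candidate] = []
        for positions in index.values():
            if len(positions) < 2 or len(positions) > max_kmer_hits:
                continue
            for ai, i in enumerate(positions):
                lo = bisect_left(positions, i + min_span, ai + 1)
                hi = bisect_right(positions, i + max_span, ai + 1)
                for j in positions[lo:hi]:
                    d = j - i
                    bucket = ((i // 50), d)
                    if bucket in seen_diag:
                        continue
                    seen_diag.add(bucket)
                    bl, br, matches, length = _xdrop_extend(seq, i, j, k)
                    if not (min_ltr_len <= length <= max_ltr_len):
                        continue
                    identity = matches / length
                    if identity < min_identity:
                        continue
                    s1, e1 = i - bl, i + k + br
                    internal_len = d - length
                    if not (internal_range[0] <= internal_len <= internal_range[1]):
                        continue
                    a, b, tsd = _refine_with_tsd(seq, s1, e1, d)
                    score = 0
                    if tsd:
                        s1, e1 = s1 + a, e1 + b
                        length = e1 - s1
                        matches = sum(
                            1 for t in range(s1, e1) if seq[t] == seq[t + d]
                        )
                        identity = matches / length
                        score = 2 * tsd - (abs(a) + abs(b))
                    cands.append(_Candidate(s1, e1, d, identity, tsd, score))
        # Non-overlapping selection by maximum total weight (weighted interval
        # scheduling). Weight is dominated by TSD strength (2*len - boundary
        # shift): a chimeric pairing of two neighbouring same-family elements
        # carries at best a weak chance TSD, so the two true elements it
        # would cover always outweigh it.
        if require_tsd:
            cands = [c for c in cands if c.tsd_len]
        cands = [c for c in cands if c.identity >= min_identity]
        cands.sort(key=lambda c: (c.e1 + c.d, c.s1))
        ends = [c.e1 + c.d for c in cands]
        weights = [c.tsd_score * 1000 + int(c.identity * 100) for c in cands]
        n_c = len(cands)
        best_w = [0] * (n_c + 1)
        choose = [False] * n_c
        prev_idx = [0] * n_c
        for t in range(n_c):
            # last candidate ending at or before this one's start
            prev_idx[t] = bisect_right(ends, cands[t].s1, 0, t)
        for t in range(n_c):
            with_t = weights[t] + best_w[prev_idx[t]]
            if with_t > best_w[t]:
                best_w[t + 1] = with_t
                choose[t] = True
            else:
                best_w[t + 1] = best_w[t]
        selected: list[_Candidate] = []
        t = n_c
        while t > 0:
            if choose[t - 1]:
                selected.append(cands[t - 1])
                t = prev_idx[t - 1]
            else:
                t -= 1
        selected.sort(key=lambda c: c.s1)
        for c in selected:
            counter += 1
            ltr5 = (c.s1, c.e1)
            ltr3 = (c.s1 + c.d, c.e1 + c.d)
            family = "other"
            if family_library:
                family = _classify_family(seq[ltr5[0] : ltr5[1]], family_library)
            elements.append(
                LTRElement(
                    element_id=f"intact_{counter:05d}",
                    family=family,
                    kind="intact",
                    chrom=chrom,
                    ltr5=ltr5,
                    ltr3=ltr3,
                    internal=(ltr5[1], ltr3[0]),
                    tsd_len=c.tsd_len,
                    identity=c.identity,
                )
            )
    elements.sort(key=lambda e: (e.chrom, e.ltr5[0]))
    return elements


def _classify_family(ltr_seq: str, library: Mapping[str, str], min_match: float = 0.6) -> str:
    best_fam, best_id = "other", min_match
    for name, lib_seq in library.items():
        res = edlib.align(ltr_seq, lib_seq, mode="NW", task="distance")
        ident = 1.0 - res["editDistance"] / max(len(ltr_seq), len(lib_seq))
        if ident > best_id:
            best_id = ident
            best_fam = name.split("_")[0]
    return best_fam


# ---------------------------------------------------------------------------
# solo-LTR detection
# ---------------------------------------------------------------------------

def find_solo_ltr(
    genome: Mapping[str, str],
    ltr_library: Mapping[str, str],
    intact_elements: Sequence[LTRElement],
    min_identity: float = 0.85,
    k: int = 13,
) -> list[LTRElement]:
    """Single LTR copies matching a library LTR at identity strictly > threshold.

    Anything overlapping an intact element is excluded first, so the two LTRs
    of an intact element are never double-counted as solos.
    """
    if not ltr_library:
        raise ValueError("solo-LTR search requires a non-empty LTR library")
    intact_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for el in intact_elements:
        intact_by_chrom.setdefault(el.chrom, []).append(el.span)

    solos: list[LTRElement] = []
    counter = 0
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        index: dict[str, list[int]] = {}
        for pos in range(0, len(seq) - k + 1):
            index.setdefault(seq[pos : pos + k], []).append(pos)
        accepted: list[tuple[float, int, int, str]] = []
        for name, lib in ltr_library.items():
            lib = lib.upper()
            # candidate loci from seed clusters (genome position minus library offset)
            starts: list[int] = []
            for off in range(0, len(lib) - k + 1, max(1, k // 2)):
                for pos in index.get(lib[off : off + k], ()):
                    starts.append(pos - off)
            if not starts:
                continue
            starts.sort()
            clusters: list[list[int]] = [[starts[0]]]
            for s in starts[1:]:
                if s - clusters[-1][-1] <= len(lib) // 2:
                    clusters[-1].append(s)
                else:
                    clusters.append([s])
            max_ed = int(len(lib) * (1.0 - min_identity)) + 1
            for cl in clusters:
                lo = max(0, cl[0] - 20)
                hi = min(len(seq), cl[-1] + len(lib) + 20)
                res = edlib.align(lib, seq[lo:hi], mode="HW", task="locations", k=max_ed)
                if res["editDistance"] < 0:
                    continue
                ident = 1.0 - res["editDistance"] / len(lib)
                if ident <= min_identity:  # strict >
                    continue
                loc = res["locations"][0]
                accepted.append((ident, lo + loc[0], lo + loc[1] + 1, name.split("_")[0]))
        # resolve overlaps: best identity wins; drop hits inside intact elements
        accepted.sort(key=lambda t: (-t[0], t[1]))
        spans_taken: list[tuple[int, int]] = []
        intact_spans = intact_by_chrom.get(chrom, [])
        for ident, s, e, family in accepted:
            if any(s < t1 and t0 < e for t0, t1 in intact_spans):
                continue
            if any(s < t1 and t0 < e for t0, t1 in spans_taken):
                continue
            spans_taken.append((s, e))
            counter += 1
            solos.append(
                LTRElement(
                    element_id=f"solo_{counter:05d}",
                    family=family,
                    kind="solo",
                    chrom=chrom,
                    ltr5=(s, e),
                    identity=ident,
                )
            )
    solos.sort(key=lambda e: (e.chrom, e.ltr5[0]))
    return solos


def date_elements(
    genome: Mapping[str, str],
    elements: Iterable[LTRElement],
    rate: float = DEFAULT_RATE,
) -> list[DivergenceEstimate]:
    """Date intact elements from the divergence of their own 5'/3' LTR pair."""
    out = []
    for el in elements:
        if el.kind != "intact" or el.ltr3 is None:
            continue
        seq = genome[el.chrom]
        a = seq[el.ltr5[0] : el.ltr5[1]]
        b = seq[el.ltr3[0] : el.ltr3[1]]
        out.append(k2p_distance(a, b, element_id=el.element_id, rate=rate, family=el.family))
    return out
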