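"""Windowed diversity statistics and π-ratio selective-sweep scanning.

For a structured population genotyped at biallelic SNPs, sliding windows
(default 100 kb, 10 kb step) carry per-group nucleotide diversity π (mean
pairwise difference per site, missing-aware), Watterson's θ_W = S / (a_{n-1}
L) with a_{n-1} = Σ_{i=1}^{n-1} 1/i, and the Hudson two-population FST
(ratio of window-summed numerators and denominators). A selective sweep in
one group shows up as an elevated π ratio against that group; windows above
the ratio threshold are merged into candidate signals and annotated with
overlapping genes. Haplotypes over a gene region (homozygous-majority
coding) are cross-tabulated against a binary phenotype with Fisher's exact
test.

π is normalized by window length, not callable length, matching the common
windowed convention; the per-SNP estimator is the unbiased allele-count form
2c(n-c)/(n(n-1)) summed over SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

__all__ = [
    "filter_pop_snps",
    "window_stats",
    "hudson_fst_snp",
    "sweep_scan",
    "SweepSignal",
    "haplotype_association",
    "watterson_a",
]


def watterson_a(n: int) -> float:
    """Harmonic number a_{n-1} = sum_{i=1}^{n-1} 1/i for n haplotypes."""
    if n < 2:
        raise ValueError("Watterson's constant needs >= 2 haplotypes")
    return float(sum(1.0 / i for i in range(1, n)))


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_pop_snps(
    genotypes: np.ndarray, positions: np.ndarray, min_maf: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Exclude SNPs with minor allele frequency LOWER than ``min_maf``.

    The boundary (MAF exactly equal to the threshold) is kept. MAF comes from
    non-missing alleles; monomorphic or all-missing SNPs are removed.
    """
    geno = np.asarray(genotypes)
    called = geno >= 0
    n_alleles = 2 * called.sum(axis=0)
    alt = np.where(called, geno, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), 0.0)
    maf = np.minimum(p, 1.0 - p)
    keep = (n_alleles > 0) & (maf >= min_maf) & (maf > 0)
    return geno[:, keep], np.asarray(positions)[keep]


# ---------------------------------------------------------------------------
# windowed statistics
# ---------------------------------------------------------------------------

def _group_counts(geno: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(alt allele count, called allele count) per SNP for one group."""
    called = geno >= 0
    n = 2 * called.sum(axis=0)
    alt = np.where(called, geno, 0).sum(axis=0)
    return alt.astype(float), n.astype(float)


def _pi_sum(alt: np.ndarray, n: np.ndarray) -> float:
    """Sum over SNPs of the unbiased per-site heterozygosity 2c(n-c)/(n(n-1))."""
    ok = n >= 2
    c, m = alt[ok], n[ok]
    return float(np.sum(2.0 * c * (m - c) / (m * (m - 1.0))))


def hudson_fst_snp(
    alt1: np.ndarray, n1: np.ndarray, alt2: np.ndarray, n2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP Hudson FST numerator and denominator (nan where undefined)."""
    ok = (n1 >= 2) & (n2 >= 2)
    p1 = np.where(ok, alt1 / np.maximum(n1, 1), np.nan)
    p2 = np.where(ok, alt2 / np.maximum(n2, 1), np.nan)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / np.maximum(n1 - 1, 1) - p2 * (
        1 - p2
    ) / np.maximum(n2 - 1, 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return np.where(ok, num, np.nan), np.where(ok, den, np.nan)


def window_stats(
    genotypes: np.ndarray,
    positions: np.ndarray,
    groups: Sequence[int],
    chrom_length: int,
    window: int = 100_000,
    step: int = 10_000,
    chrom: str = "chr1",
    fst_pairs: Sequence[tuple[int, int]] = (),
) -> pd.DataFrame:
    """Per-window, per-group π, θ_W and segregating sites; optional FST pairs.

    Rows: chrom, start, end, truncated, group, n_haplotypes, segregating,
    pi, theta_w, plus one ``fst_<a>_<b>`` column per requested pair (raw
    value in ``fst_<a>_<b>_raw``, reported value clipped below at 0).
    Windows run [start, start+window) at ``step`` offsets; a final window
    truncated by the chromosome end is flagged.
    """
    geno = np.asarray(genotypes)
    pos = np.asarray(positions)
    groups = np.asarray(groups)
    order = np.argsort(pos, kind="stable")
    geno, pos = geno[:, order], pos[order]
    group_ids = sorted(set(int(g) for g in groups))

    counts = {}
    for g in group_ids:
        counts[g] = _group_counts(geno[groups == g])

    rows = []
    start = 0
    while start < chrom_length:
        end = min(start + window, chrom_length)
        truncated = end - start < window
        length = end - start
        lo = np.searchsorted(pos, start + 1, side="left")  # positions are 1-based
        hi = np.searchsorted(pos, end, side="right")
        sel = slice(lo, hi)
        fst_vals = {}
        for a, b in fst_pairs:
            num, den = hudson_fst_snp(
                counts[a][0][sel], counts[a][1][sel],
                counts[b][0][sel], counts[b][1][sel],
            )
            den_sum = np.nansum(den)
            if hi > lo and den_sum > 0:
                raw = float(np.nansum(num) / den_sum)
            else:
                raw = np.nan
            fst_vals[f"fst_{a}_{b}_raw"] = raw
            fst_vals[f"fst_{a}_{b}"] = max(raw, 0.0) if np.isfinite(raw) else np.nan
        for g in group_ids:
            alt, n = counts[g][0][sel], counts[g][1][sel]
            n_hap = int(2 * (groups == g).sum())
            seg = int(np.sum((alt > 0) & (alt < n)))
            pi = _pi_sum(alt, n) / length
            theta = seg / (watterson_a(n_hap) * length) if n_hap >= 2 else np.nan
            rows.append(
                {"chrom": chrom, "start": start, "end": end,
                 "truncated": truncated, "group": g, "n_haplotypes": n_hap,
                 "segregating": seg, "pi": pi, "theta_w": theta, **fst_vals}
            )
        if end >= chrom_length:
            break
        start += step
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sweep scan
# ---------------------------------------------------------------------------

@dataclass
class SweepSignal:
    chrom: str
    start: int
    end: int
    group_num: int
    group_den: int
    max_ratio: float
    n_windows: int
    genes: list


def sweep_scan(
    stats: pd.DataFrame,
    group_num: int,
    group_den: int,
    ratio_threshold: float,
    genes: pd.DataFrame | None = None,
) -> list[SweepSignal]:
    """Windows with π_num/π_den above the threshold, merged into signals.

    π_den = 0 with π_num > 0 also flags the window (infinite ratio); windows
    where both are 0 are skipped. Overlapping flagged windows merge into
    maximal intervals carrying the largest finite ratio observed. ``genes``
    (columns chrom, start, end, id) attaches overlapping gene ids.
    """
    num = stats[stats["group"] == group_num][["chrom", "start", "end", "pi"]]
    den = stats[stats["group"] == group_den][["chrom", "start", "end", "pi"]]
    merged = num.merge(
        den, on=["chrom", "start", "end"], suffixes=("_num", "_den"), how="outer",
        indicator=True,
    )
    if (merged["_merge"] != "both").any():
        raise ValueError("window grids differ between the two groups")

    flagged = []
    for row in merged.itertuples():
        if row.pi_den > 0:
            ratio = row.pi_num / row.pi_den
            if ratio > ratio_threshold:
                flagged.append((row.chrom, row.start, row.end, ratio))
        elif row.pi_num > 0:
            flagged.append((row.chrom, row.start, row.end, np.inf))

    signals: list[SweepSignal] = []
    for chrom in sorted({f[0] for f in flagged}):
        windows = sorted(f for f in flagged if f[0] == chrom)
        current = None
        for _, s, e, ratio in windows:
            if current is None or s > current[1]:
                if current is not None:
                    signals.append(_make_signal(chrom, current, group_num,
                                                group_den, genes))
                current = [s, e, ratio, 1]
            else:
                current[1] = max(current[1], e)
                current[2] = max(current[2], ratio)
                current[3] += 1
        if current is not None:
            signals.append(_make_signal(chrom, current, group_num, group_den, genes))
    return signals


def _make_signal(chrom, current, group_num, group_den, genes) -> SweepSignal:
    s, e, ratio, n = current
    overlapping: list = []
    if genes is not None:
        hit = genes[
            (genes["chrom"] == chrom) & (genes["start"] < e) & (genes["end"] > s)
        ]
        overlapping = hit["id"].tolist()
    return SweepSignal(chrom, int(s), int(e), group_num, group_den,
                       float(ratio), int(n), overlapping)


# ---------------------------------------------------------------------------
# haplotype-phenotype association
# ---------------------------------------------------------------------------

def haplotype_association(
    region_genotypes: np.ndarray,
    phenotype: Sequence[int],
    groups: Sequence[int] | None = None,
) -> tuple[pd.DataFrame, float | None]:
    """Enumerate homozygous haplotypes over a region and test the top two.

    ``region_genotypes`` is accessions x SNPs dosage (0/1/2, -1 missing); an
    accession contributes a haplotype only if homozygous at every region SNP
    (heterozygous or missing -> excluded). Returns a per-haplotype table
    (counts overall, by phenotype class and by group) and the two-sided
    Fisher exact p for the top-2 haplotypes x phenotype 2x2 table (None when
    fewer than two haplotype classes, or a degenerate table).
    """
    geno = np.asarray(region_genotypes)
    phen = np.asarray(phenotype)
    grp = np.asarray(groups) if groups is not None else np.zeros(len(phen), int)

    haps: dict[str, list[int]] = {}
    for a in range(geno.shape[0]):
        row = geno[a]
        if np.any(row == 1) or np.any(row < 0):
            continue
        key = "".join("1" if d == 2 else "0" for d in row)
        haps.setdefault(key, []).append(a)

    rows = []
    for key, members in sorted(haps.items(), key=lambda kv: (-len(kv[1]), kv[0])):
        members = np.array(members)
        row = {
            "haplotype": key,
            "count": len(members),
            "phenotype_1": int((phen[members] == 1).sum()),
            "phenotype_0": int((phen[members] == 0).sum()),
        }
        for g in sorted(set(int(x) for x in grp)):
            row[f"group_{g}"] = int((grp[members] == g).sum())
        rows.append(row)
    table = pd.DataFrame(rows)

    p_value = None
    if len(table) >= 2:
        top = table.iloc[:2]
        cont = np.array(
            [[top.iloc[0]["phenotype_1"], top.iloc[0]["phenotype_0"]],
             [top.iloc[1]["phenotype_1"], top.iloc[1]["phenotype_0"]]]
        )
        # a haplotype class with a single member still appears in the table,
        # but an all-zero margin makes the test meaningless
        if cont.sum() > 0 and cont.sum(axis=1).min() > 0:
            p_value = float(fisher_exact(cont, alternative="two-sided")[1])
    return table, p_value
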