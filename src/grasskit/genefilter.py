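"""Gene-set cleaning rules: TE-related genes, pseudogenes, low-support models,
confidence classes, lncRNA criteria and duplicate-gene classification.

A raw evidence-based gene set is reduced to a core protein-coding set by
deterministic rules applied in a fixed precedence:

1. transposon-related: > 50 aa or > 50% of the protein aligned to annotated
   transposons (both strict);
2. non-coding: no protein evidence and protein < 50 aa;
3. pseudogene: a single-exon gene whose protein is fully covered by a
   multi-exon gene; or a multi-exon gene fully covered by another gene with
   length < 70% of the coverer and expression < half the mean of all genes;
4. low support: single-exon, only EST/RNA-seq evidence, protein < 100 aa and
   expression < half the mean;
5. survivors: >= 2 distinct evidence types -> high confidence, exactly 1 ->
   low confidence.

The mean expression is computed once over the full input, so verdicts do not
depend on input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "GeneModel",
    "FilterVerdict",
    "flag_te_genes",
    "flag_pseudogenes",
    "filter_low_support",
    "classify_confidence",
    "classify_genes",
    "classify_lncrna",
    "find_duplicates",
]

EVIDENCE_TYPES = frozenset(
    {"same_species_cDNA", "same_species_EST", "cross_species", "protein", "rnaseq"}
)
_TRANSCRIPT_ONLY = frozenset({"same_species_EST", "rnaseq"})

LABELS = (
    "kept_HC",
    "kept_LC",
    "removed_TE",
    "removed_pseudo",
    "removed_low_support",
    "removed_noncoding",
)


@dataclass
class GeneModel:
    gene_id: str
    n_exons: int
    protein_length: int  # aa
    evidence: frozenset  # subset of EVIDENCE_TYPES
    expression: float  # abundance units (FPKM-like)
    te_aligned_aa: int = 0
    te_aligned_fraction: float = 0.0
    covered_by: str | None = None  # gene that fully covers this protein
    coverer_is_multi_exon: bool = False
    coverer_protein_length: int = 0

    def __post_init__(self) -> None:
        self.evidence = frozenset(self.evidence)
        unknown = self.evidence - EVIDENCE_TYPES
        if unknown:
            raise ValueError(f"unknown evidence types: {sorted(unknown)}")
        if not 0.0 <= self.te_aligned_fraction <= 1.0:
            raise ValueError("te_aligned_fraction outside [0, 1]")


@dataclass(frozen=True)
class FilterVerdict:
    gene_id: str
    label: str
    rule: str


class EmptyEvidenceError(ValueError):
    """A surviving gene carries no evidence at all."""


# individual rules ----------------------------------------------------------

def flag_te_genes(gene: GeneModel) -> FilterVerdict | None:
    if gene.te_aligned_aa > 50:
        return FilterVerdict(gene.gene_id, "removed_TE", "te_aa_gt_50")
    if gene.te_aligned_fraction > 0.5:
        return FilterVerdict(gene.gene_id, "removed_TE", "te_fraction_gt_half")
    return None


def _flag_noncoding(gene: GeneModel) -> FilterVerdict | None:
    if "protein" not in gene.evidence and gene.protein_length < 50:
        return FilterVerdict(gene.gene_id, "removed_noncoding", "no_protein_lt_50aa")
    return None


def flag_pseudogenes(gene: GeneModel, mean_expression: float) -> FilterVerdict | None:
    if gene.covered_by is None:
        return None
    if gene.n_exons == 1:
        if gene.coverer_is_multi_exon:
            return FilterVerdict(
                gene.gene_id, "removed_pseudo", "single_exon_covered_by_multi"
            )
        return None
    short = (
        gene.coverer_protein_length > 0
        and gene.protein_length < 0.7 * gene.coverer_protein_length
    )
    weak = gene.expression < 0.5 * mean_expression
    if short and weak:
        return FilterVerdict(
            gene.gene_id, "removed_pseudo", "multi_exon_covered_short_weak"
        )
    return None


def filter_low_support(gene: GeneModel, mean_expression: float) -> FilterVerdict | None:
    if (
        gene.n_exons == 1
        and gene.evidence
        and gene.evidence <= _TRANSCRIPT_ONLY
        and gene.protein_length < 100
        and gene.expression < 0.5 * mean_expression
    ):
        return FilterVerdict(
            gene.gene_id, "removed_low_support", "single_exon_transcript_only"
        )
    return None


def classify_confidence(gene: GeneModel) -> FilterVerdict:
    if not gene.evidence:
        raise EmptyEvidenceError(f"{gene.gene_id} survived filtering with no evidence")
    if len(gene.evidence) >= 2:
        return FilterVerdict(gene.gene_id, "kept_HC", "multi_evidence")
    return FilterVerdict(gene.gene_id, "kept_LC", "single_evidence")


# full pipeline -------------------------------------------------------------

def classify_genes(genes: Sequence[GeneModel]) -> list[FilterVerdict]:
    """One verdict per gene; precedence TE -> noncoding -> pseudogene ->
    low-support -> confidence. The mean expression over ALL input genes is
    computed once, up front."""
    if not genes:
        return []
    mean_expr = sum(g.expression for g in genes) / len(genes)
    verdicts: list[FilterVerdict] = []
    for gene in genes:
        verdict = (
            flag_te_genes(gene)
            or _flag_noncoding(gene)
            or flag_pseudogenes(gene, mean_expr)
            or filter_low_support(gene, mean_expr)
            or classify_confidence(gene)
        )
        verdicts.append(verdict)
    return verdicts


def verdicts_frame(verdicts: Iterable[FilterVerdict]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"gene_id": v.gene_id, "label": v.label, "rule": v.rule} for v in verdicts]
    )


# lncRNA --------------------------------------------------------------------

def classify_lncrna(
    length_bp: int, longest_orf_aa: int, coding_score: float
) -> bool:
    """lncRNA iff length > 200 bp, no ORF longer than 50 aa, and the external
    coding-potential score is <= 0 (positive scores mark coding transcripts)."""
    return length_bp > 200 and longest_orf_aa <= 50 and coding_score <= 0


# duplicated genes ----------------------------------------------------------

def find_duplicates(
    gene_order: Mapping[str, Sequence[str]],
    paralog_pairs: Iterable[tuple[str, str]],
    max_intervening: int = 2,
    min_collinear_pairs: int = 2,
) -> dict:
    """Label tandem and segmental duplicates from paralogy and gene order.

    ``gene_order`` maps chromosome -> ordered gene ids. A paralog pair on one
    chromosome separated by <= ``max_intervening`` genes is tandem. Collinear
    chains of >= ``min_collinear_pairs`` paralog pairs, with gaps of <=
    ``max_intervening`` non-collinear genes on both sides, mark their member
    genes segmental.
    """
    index: dict[str, tuple[str, int]] = {}
    for chrom, order in gene_order.items():
        for i, g in enumerate(order):
            index[g] = (chrom, i)

    tandem: set[str] = set()
    located: list[tuple] = []
    for a, b in paralog_pairs:
        if a not in index or b not in index:
            continue
        ca, ia = index[a]
        cb, ib = index[b]
        if ca == cb and abs(ia - ib) - 1 <= max_intervening and a != b:
            tandem.add(a)
            tandem.add(b)
        located.append((ca, ia, cb, ib, a, b))

    # chain pairs that advance by <= max_intervening + 1 in both genomes
    located.sort(key=lambda t: (t[0], t[2], t[1], t[3]))
    segmental: set[str] = set()
    i = 0
    while i < len(located):
        chain = [located[i]]
        j = i + 1
        while j < len(located):
            prev, cand = chain[-1], located[j]
            if (
                cand[0] == prev[0]
                and cand[2] == prev[2]
                and 0 < cand[1] - prev[1] <= max_intervening + 1
                and 0 < cand[3] - prev[3] <= max_intervening + 1
            ):
                chain.append(cand)
                j += 1
            elif cand[0] == prev[0] and cand[2] == prev[2] and cand[1] <= prev[1]:
                j += 1
            else:
                break
        if len(chain) >= min_collinear_pairs:
            for rec in chain:
                segmental.add(rec[4])
                segmental.add(rec[5])
        i = max(i + 1, j if len(chain) >= min_collinear_pairs else i + 1)

    return {"tandem": sorted(tandem), "segmental": sorted(segmental)}
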