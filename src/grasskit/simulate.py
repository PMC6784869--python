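"""Synthetic data with recorded ground truth for every pipeline stage.

Everything downstream (pool deconvolution, bin-map construction, LTR dating,
synteny indel calling, sweep scanning) is exercised on data generated here, so
each generator records the truth it plants: read-to-BAC origins, crossover
positions, LTR insertion ages, planted gene indels, sweep window coordinates.

Generators are pure functions of (config, seed): one `numpy` Generator is
derived per generator from ``SeedSequence([seed, tag])``, never global state.

Model choices (see docs/methods.md for rationale):

* crossovers: Poisson count per chromosome per gamete, uniform placement, no
  interference;
* LTR divergence: Kimura two-parameter process with transition/transversion
  ratio 2.0, each LTR copy evolved K/2 = r*T from the family consensus so the
  pair diverges by K = 2 r T;
* reads: uniform starts, fixed length, independent substitutions, no indels;
* population: Balding–Nichols group frequencies around shared ancestral
  frequencies, with heterozygosity in the swept group divided by the
  configured factor inside the sweep window.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm

__all__ = [
    "SimConfig",
    "LtrFamilySpec",
    "SsrSpec",
    "F2Spec",
    "BacSpec",
    "PopSpec",
    "OrthoSpec",
    "PlacementError",
    "Genome",
    "simulate_genome",
    "simulate_bac_pools",
    "simulate_f2",
    "simulate_population",
    "simulate_ortholog_tables",
    "simulate_neutral_haplotypes",
    "k2p_mutate",
    "write_fasta",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class PlacementError(ValueError):
    """Planted features do not fit in the configured genome."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class LtrFamilySpec:
    family: str = "Gypsy"
    n_intact: int = 10
    n_solo: int = 10
    age_mean_years: float = 1.0e6
    age_sd_years: float = 2.0e5
    ltr_length: int = 400
    internal_length: int = 3000


@dataclass
class SsrSpec:
    # motif length -> number of SSR loci
    counts: dict = field(default_factory=lambda: {1: 10, 2: 10, 3: 6, 6: 2})
    copies: tuple[int, int] = (8, 30)


@dataclass
class F2Spec:
    n_individuals: int = 200
    n_markers: int = 500
    crossover_rate: float = 2.0  # expected crossovers per chromosome per gamete
    genotype_error_rate: float = 0.01
    missing_rate: float = 0.05
    mean_depth: float = 20.0


@dataclass
class BacSpec:
    n_bacs: int = 24
    insert_length: tuple[int, int] = (20_000, 40_000)
    pool_rows: int = 4
    pool_cols: int = 6
    read_length: int = 150
    reads_per_bac: int = 30
    read_error_rate: float = 0.0
    shared_segment_bp: int = 0  # planted duplication between two BACs


@dataclass
class PopSpec:
    group_sizes: tuple[int, ...] = (30, 64, 53)
    n_snps: int = 2000
    chrom_length: int = 10_000_000
    background_diversity: float = 0.3  # target mean heterozygosity at ancestral SNPs
    fst: float = 0.05  # Balding–Nichols drift of group frequencies
    sweep_window: tuple[int, int] = (4_000_000, 4_500_000)
    swept_group: int = 1
    sweep_reduction: float = 10.0
    phenotype_linkage: float = 1.0
    missing_rate: float = 0.0


@dataclass
class OrthoSpec:
    species: tuple[str, ...] = ("Tu3", "Ta3B", "Bd", "Os", "Sb")
    n_core: int = 200
    n_insertions: int = 5
    n_deletions: int = 5
    homology_noise: float = 0.0
    similarity: tuple[float, float] = (0.85, 0.99)


@dataclass
class SimConfig:
    seed: int = 0
    genome_length: int = 1_400_000
    n_chromosomes: int = 7
    n_genes: int = 70
    ltr_spec: list = field(
        default_factory=lambda: [
            LtrFamilySpec("Gypsy", 10, 10, 1.2e6, 2.0e5),
            LtrFamilySpec("Copia", 10, 10, 0.6e6, 2.0e5),
        ]
    )
    ssr_spec: SsrSpec = field(default_factory=SsrSpec)
    f2_spec: F2Spec = field(default_factory=F2Spec)
    bac_spec: BacSpec = field(default_factory=BacSpec)
    pop_spec: PopSpec = field(default_factory=PopSpec)
    ortho_spec: OrthoSpec = field(default_factory=OrthoSpec)
    substitution_rate: float = 1.3e-8  # per site per year
    ts_tv_ratio: float = 2.0
    emit_sequence: bool = True

    def __post_init__(self) -> None:
        if self.genome_length < 10_000:
            raise ValueError("genome_length must be at least 10 kb")
        pop = self.pop_spec
        if any(g < 0 for g in pop.group_sizes):
            raise ValueError("group sizes must be non-negative")

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimConfig":
        data = dict(data)
        sub = {
            "ltr_spec": lambda v: [LtrFamilySpec(**x) for x in v],
            "ssr_spec": lambda v: SsrSpec(**v),
            "f2_spec": lambda v: F2Spec(**v),
            "bac_spec": lambda v: BacSpec(**v),
            "pop_spec": lambda v: PopSpec(**v),
            "ortho_spec": lambda v: OrthoSpec(**v),
        }
        for key, conv in sub.items():
            if key in data and not isinstance(data[key], (LtrFamilySpec, SsrSpec)):
                data[key] = conv(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _rng(config: SimConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), tag]))


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def str_to_codes(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.zeros(arr.size, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        out[arr == b] = i
    return out


def _k2p_transition_matrix(distance: float, kappa: float = 2.0) -> np.ndarray:
    """Base-substitution probabilities after ``distance`` expected subs/site."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    q = np.full((4, 4), beta)
    # order A C G T; transitions A<->G (0,2) and C<->T (1,3)
    q[0, 2] = q[2, 0] = alpha
    q[1, 3] = q[3, 1] = alpha
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return expm(q * distance)


def k2p_mutate(
    codes: np.ndarray, distance: float, rng: np.random.Generator, kappa: float = 2.0
) -> np.ndarray:
    """Evolve a coded sequence along a branch of the given K2P length."""
    if distance <= 0:
        return codes.copy()
    pmat = _k2p_transition_matrix(distance, kappa)
    cum = np.cumsum(pmat, axis=1)
    u = rng.random(codes.size)
    return (u[:, None] > cum[codes]).sum(axis=1).astype(np.int8)


def write_fasta(path: str | Path, records: Mapping[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in records:
            fh.write(f">{name}\n")
            seq = records[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# genome with planted genes, LTR elements and SSRs
# ---------------------------------------------------------------------------

@dataclass
class GenomeTruth:
    chrom_lengths: dict
    elements: list  # dicts: id, chrom, start, end, ltr5, ltr3, family, kind, age, k
    genes: list
    ssrs: list
    ltr_library: dict  # family -> consensus LTR sequence

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


@dataclass
class Genome:
    sequences: dict
    chrom_lengths: dict
    annotation: pd.DataFrame
    truth: GenomeTruth


def simulate_genome(config: SimConfig) -> Genome:
    """Random diploid-genome substrate carrying genes, LTR elements and SSRs.

    Intact elements are emitted as TSD + 5'LTR + internal + 3'LTR + TSD with
    both LTR copies evolved r*T from the family consensus, so the realized
    5'/3' divergence is K = 2 r T in expectation. Coordinates in the truth and
    annotation are 0-based half-open internally; the annotation table also
    carries 1-based inclusive columns for GFF-style export.
    """
    rng = _rng(config, 0)
    n_chrom = config.n_chromosomes
    base_len = config.genome_length // n_chrom
    chrom_lengths = {f"chr{i + 1}": base_len for i in range(n_chrom)}
    chroms = list(chrom_lengths)

    truth = GenomeTruth(dict(chrom_lengths), [], [], [], {})
    if not config.emit_sequence:
        # map/population-scale runs need only coordinates, never bases
        ann = pd.DataFrame(columns=["chrom", "type", "start", "end", "strand", "id"])
        return Genome({}, dict(chrom_lengths), ann, truth)

    # family consensus LTR sequences (the "library")
    for spec in config.ltr_spec:
        if spec.family not in truth.ltr_library and (spec.n_intact or spec.n_solo):
            truth.ltr_library[spec.family] = codes_to_str(
                rng.integers(0, 4, spec.ltr_length).astype(np.int8)
            )

    # build the feature payloads first, then pack them
    features: list[dict] = []
    for spec in config.ltr_spec:
        lib = truth.ltr_library.get(spec.family)
        lib_codes = str_to_codes(lib) if lib else None
        for i in range(spec.n_intact):
            age = max(0.0, rng.normal(spec.age_mean_years, spec.age_sd_years))
            k_true = 2.0 * config.substitution_rate * age
            ltr_a = k2p_mutate(lib_codes, k_true / 2.0, rng, config.ts_tv_ratio)
            ltr_b = k2p_mutate(lib_codes, k_true / 2.0, rng, config.ts_tv_ratio)
            internal = rng.integers(0, 4, spec.internal_length).astype(np.int8)
            tsd = rng.integers(0, 4, int(rng.integers(4, 7))).astype(np.int8)

            def _avoid(forbidden: int) -> np.ndarray:
                return np.array(
                    [(forbidden + 1 + rng.integers(3)) % 4], dtype=np.int8
                )

            # guard against boundary ambiguity: if the base flanking a TSD
            # equalled the adjacent LTR base (or the internal boundary bases
            # mirrored the TSD ends), the element would admit an equally valid
            # alternative [TSD][LTR] decomposition and the planted coordinates
            # would not be a well-defined truth
            internal[0] = _avoid(int(tsd[0]))[0]
            internal[-1] = _avoid(int(tsd[-1]))[0]
            left_guard = _avoid(int(ltr_b[-1]))
            right_guard = _avoid(int(ltr_a[0]))
            payload = np.concatenate(
                [left_guard, tsd, ltr_a, internal, ltr_b, tsd, right_guard]
            )
            features.append(
                {
                    "kind": "intact",
                    "family": spec.family,
                    "seq": payload,
                    "tsd": tsd.size,
                    "guard": 1,
                    "ltr_len": lib_codes.size,
                    "internal_len": spec.internal_length,
                    "age": age,
                    "k": k_true,
                }
            )
        for i in range(spec.n_solo):
            age = max(0.0, rng.normal(spec.age_mean_years, spec.age_sd_years))
            solo = k2p_mutate(lib_codes, config.substitution_rate * age, rng,
                              config.ts_tv_ratio)
            features.append(
                {"kind": "solo", "family": spec.family, "seq": solo, "age": age}
            )
    for _ in range(config.n_genes):
        glen = int(rng.integers(600, 3000))
        features.append(
            {"kind": "gene", "seq": rng.integers(0, 4, glen).astype(np.int8)}
        )
    for motif_len, count in config.ssr_spec.counts.items():
        for _ in range(count):
            motif = rng.integers(0, 4, motif_len).astype(np.int8)
            copies = int(rng.integers(*config.ssr_spec.copies))
            features.append(
                {"kind": "ssr", "seq": np.tile(motif, copies),
                 "motif": codes_to_str(motif)}
            )

    rng.shuffle(features)
    # round-robin assignment to chromosomes, then per-chromosome random packing
    per_chrom: dict[str, list[dict]] = {c: [] for c in chroms}
    for idx, feat in enumerate(features):
        per_chrom[chroms[idx % n_chrom]].append(feat)

    sequences: dict[str, str] = {}
    ann_rows: list[dict] = []
    counters = {"intact": 0, "solo": 0, "gene": 0, "ssr": 0}
    # mild AT bias, as in grass genomes
    base_p = np.array([0.28, 0.22, 0.22, 0.28])
    for chrom in chroms:
        length = chrom_lengths[chrom]
        feats = per_chrom[chrom]
        total = sum(f["seq"].size for f in feats)
        free = length - total
        if free < (len(feats) + 1):
            raise PlacementError(
                f"{chrom}: features need {total} bp of {length} bp available"
            )
        gaps = rng.dirichlet(np.ones(len(feats) + 1)) * free
        gaps = np.floor(gaps).astype(int)
        seq = rng.choice(4, size=length, p=base_p).astype(np.int8)
        cursor = 0
        for gap, feat in zip(gaps, feats):
            cursor += int(gap)
            start = cursor
            payload = feat["seq"]
            seq[start : start + payload.size] = payload
            end = start + payload.size
            cursor = end
            kind = feat["kind"]
            counters[kind] += 1
            fid = f"{kind}_{counters[kind]:05d}"
            if kind == "intact":
                t = feat["tsd"]
                g_off = feat["guard"]
                ltr_len = feat["ltr_len"]
                ltr5 = (start + g_off + t, start + g_off + t + ltr_len)
                ltr3 = (end - g_off - t - ltr_len, end - g_off - t)
                truth.elements.append(
                    {
                        "id": fid,
                        "chrom": chrom,
                        "start": ltr5[0],
                        "end": ltr3[1],
                        "ltr5": list(ltr5),
                        "ltr3": list(ltr3),
                        "tsd_len": t,
                        "family": feat["family"],
                        "kind": "intact",
                        "age_years": feat["age"],
                        "k_true": feat["k"],
                    }
                )
                ann_rows.append(
                    {"chrom": chrom, "type": "LTR_retrotransposon",
                     "start": ltr5[0] + 1, "end": ltr3[1], "strand": "+",
                     "id": fid, "family": feat["family"]}
                )
            elif kind == "solo":
                truth.elements.append(
                    {
                        "id": fid,
                        "chrom": chrom,
                        "start": start,
                        "end": end,
                        "ltr5": [start, end],
                        "ltr3": None,
                        "tsd_len": 0,
                        "family": feat["family"],
                        "kind": "solo",
                        "age_years": feat["age"],
                        "k_true": None,
                    }
                )
                ann_rows.append(
                    {"chrom": chrom, "type": "solo_LTR", "start": start + 1,
                     "end": end, "strand": "+", "id": fid,
                     "family": feat["family"]}
                )
            elif kind == "gene":
                truth.genes.append(
                    {"id": fid, "chrom": chrom, "start": start, "end": end}
                )
                ann_rows.append(
                    {"chrom": chrom, "type": "gene", "start": start + 1,
                     "end": end, "strand": "+" if rng.random() < 0.5 else "-",
                     "id": fid, "family": ""}
                )
            else:
                truth.ssrs.append(
                    {"id": fid, "chrom": chrom, "start": start, "end": end,
                     "motif": feat["motif"]}
                )
                ann_rows.append(
                    {"chrom": chrom, "type": "SSR", "start": start + 1,
                     "end": end, "strand": "+", "id": fid, "family": ""}
                )
        sequences[chrom] = codes_to_str(seq)

    annotation = pd.DataFrame(
        ann_rows, columns=["chrom", "type", "start", "end", "strand", "id", "family"]
    ).sort_values(["chrom", "start"], ignore_index=True)
    return Genome(sequences, dict(chrom_lengths), annotation, truth)


# ---------------------------------------------------------------------------
# 2D-pooled BAC library
# ---------------------------------------------------------------------------

@dataclass
class PoolTruth:
    read_to_bac: dict
    ambiguous_reads: list
    bac_cells: dict  # bac -> (row_pool, col_pool)
    bac_intervals: dict  # bac -> (chrom, start, end)
    shared_segment: dict | None


@dataclass
class PoolSim:
    layout: "object"  # pooldeconv.PoolLayout
    reads: dict  # read id -> sequence
    pool_reads: dict  # pool id -> list of read ids
    pool_contigs: dict  # pool id -> {contig id: sequence}
    truth: PoolTruth


def simulate_bac_pools(config: SimConfig, genome: Genome) -> PoolSim:
    """Row/column pooled BAC library with reads of known origin.

    Each BAC occupies one (row, col) cell; every read drawn from a BAC appears
    in exactly that BAC's row pool and column pool. An optional duplicated
    segment copied between two BACs in different rows and columns plants
    genuinely ambiguous reads (recorded in the truth).
    """
    from .pooldeconv import PoolLayout

    spec = config.bac_spec
    if spec.pool_rows * spec.pool_cols < spec.n_bacs:
        raise ValueError("pool grid smaller than the number of BACs")
    if not genome.sequences:
        raise ValueError("BAC simulation needs genome sequences (emit_sequence=True)")
    rng = _rng(config, 1)

    rows = [f"R{i + 1:02d}" for i in range(spec.pool_rows)]
    cols = [f"C{j + 1:02d}" for j in range(spec.pool_cols)]
    cells = [(r, c) for r in rows for c in cols]
    order = rng.permutation(len(cells))
    bac_ids = [f"BAC{i + 1:04d}" for i in range(spec.n_bacs)]
    cell_to_bac = {cells[order[i]]: bac_ids[i] for i in range(spec.n_bacs)}
    layout = PoolLayout(rows=rows, cols=cols, cell_to_bac=cell_to_bac)
    bac_cells = {b: cell for cell, b in cell_to_bac.items()}

    # BAC inserts emulate a minimal tiling path: non-overlapping intervals,
    # so ambiguity arises only from repeats or planted duplications
    chroms = [c for c, L in genome.chrom_lengths.items()
              if L >= spec.insert_length[1]]
    if not chroms:
        raise ValueError("no chromosome long enough for the configured inserts")
    lengths = {b: int(rng.integers(spec.insert_length[0], spec.insert_length[1] + 1))
               for b in bac_ids}
    capacity = {c: int(genome.chrom_lengths[c] * 0.95) for c in chroms}
    per_chrom: dict[str, list[str]] = {c: [] for c in chroms}
    filled = {c: 0 for c in chroms}
    for bac in bac_ids:
        # least-filled chromosome that still has room
        chrom = min(chroms, key=lambda c: filled[c] / capacity[c])
        if filled[chrom] + lengths[bac] > capacity[chrom]:
            raise PlacementError("BAC inserts exceed the available genome")
        per_chrom[chrom].append(bac)
        filled[chrom] += lengths[bac]
    bac_seqs: dict[str, np.ndarray] = {}
    bac_intervals: dict[str, tuple] = {}
    for chrom in chroms:
        members = per_chrom[chrom]
        if not members:
            continue
        free = genome.chrom_lengths[chrom] - filled[chrom]
        gaps = np.floor(rng.dirichlet(np.ones(len(members) + 1)) * free).astype(int)
        cursor = 0
        for gap, bac in zip(gaps, members):
            cursor += int(gap)
            start, end = cursor, cursor + lengths[bac]
            bac_seqs[bac] = str_to_codes(genome.sequences[chrom][start:end])
            bac_intervals[bac] = (chrom, start, end)
            cursor = end

    shared = None
    if spec.shared_segment_bp > 0 and spec.n_bacs >= 2:
        # pick two BACs in different rows AND columns so the duplication is
        # irresolvable by the 2D rule
        donor, acceptor = None, None
        for a in bac_ids:
            for b in bac_ids:
                ra, ca = bac_cells[a]
                rb, cb = bac_cells[b]
                if ra != rb and ca != cb:
                    donor, acceptor = a, b
                    break
            if donor:
                break
        seg = spec.shared_segment_bp
        off_a = int(rng.integers(0, bac_seqs[donor].size - seg + 1))
        off_b = int(rng.integers(0, bac_seqs[acceptor].size - seg + 1))
        bac_seqs[acceptor][off_b : off_b + seg] = bac_seqs[donor][off_a : off_a + seg]
        shared = {"donor": donor, "acceptor": acceptor,
                  "donor_offset": off_a, "acceptor_offset": off_b, "length": seg}

    reads: dict[str, str] = {}
    pool_reads: dict[str, list] = {p: [] for p in rows + cols}
    read_to_bac: dict[str, str] = {}
    ambiguous: list[str] = []
    for bac in bac_ids:
        seq = bac_seqs[bac]
        row, col = bac_cells[bac]
        for ri in range(spec.reads_per_bac):
            start = int(rng.integers(0, seq.size - spec.read_length + 1))
            read = seq[start : start + spec.read_length].copy()
            if spec.read_error_rate > 0:
                mask = rng.random(read.size) < spec.read_error_rate
                shift = rng.integers(1, 4, int(mask.sum()))
                read[mask] = (read[mask] + shift) % 4
            rid = f"{bac}_r{ri:04d}"
            reads[rid] = codes_to_str(read)
            read_to_bac[rid] = bac
            pool_reads[row].append(rid)
            pool_reads[col].append(rid)
            if shared is not None:
                for who, off_key in (("donor", "donor_offset"),
                                     ("acceptor", "acceptor_offset")):
                    if bac == shared[who]:
                        off = shared[off_key]
                        if off <= start and start + spec.read_length <= off + shared["length"]:
                            ambiguous.append(rid)

    pool_contigs: dict[str, dict] = {p: {} for p in rows + cols}
    for bac in bac_ids:
        row, col = bac_cells[bac]
        contig = codes_to_str(bac_seqs[bac])
        pool_contigs[row][f"{bac}_ctg"] = contig
        pool_contigs[col][f"{bac}_ctg"] = contig

    truth = PoolTruth(read_to_bac, ambiguous, bac_cells, bac_intervals, shared)
    return PoolSim(layout, reads, pool_reads, pool_contigs, truth)


# ---------------------------------------------------------------------------
# F2 mapping population
# ---------------------------------------------------------------------------

@dataclass
class F2Truth:
    markers: pd.DataFrame  # marker, chrom, pos, order, cM_true
    crossovers: dict  # individual -> chrom -> [gamete1 breaks, gamete2 breaks]
    phases: dict  # individual -> chrom -> (gamete1 start phase, gamete2 start phase)
    clean_genotypes: np.ndarray


@dataclass
class F2Sim:
    genotypes: np.ndarray  # markers x individuals, codes 0=A 1=H 2=B, -1 missing
    markers: pd.DataFrame  # marker, chrom, pos, depth, maf
    individuals: list
    truth: F2Truth

    def to_frame(self) -> pd.DataFrame:
        codes = np.array(["A", "H", "B"])
        cells = np.where(self.genotypes >= 0,
                         codes[np.clip(self.genotypes, 0, 2)], "-")
        frame = self.markers.copy()
        for j, ind in enumerate(self.individuals):
            frame[ind] = cells[:, j]
        return frame


def simulate_f2(config: SimConfig, genome: Genome) -> F2Sim:
    """F2 cross between two inbred parents (AA x BB) with known crossovers.

    Each gamete receives a Poisson number of crossovers per chromosome placed
    uniformly; genotypes are the sum of two gametes (A/H/B), then corrupted by
    the configured error and missing rates. The truth keeps marker order, true
    genetic positions (cM = 100 * rate * pos / L) and every breakpoint.
    """
    spec = config.f2_spec
    rng = _rng(config, 2)
    chroms = list(genome.chrom_lengths)
    total_len = sum(genome.chrom_lengths.values())
    # allocate markers proportionally, at least 2 per chromosome
    alloc = {c: max(2, int(round(spec.n_markers * genome.chrom_lengths[c] / total_len)))
             for c in chroms}

    marker_rows = []
    positions: dict[str, np.ndarray] = {}
    order = 0
    for chrom in chroms:
        L = genome.chrom_lengths[chrom]
        pos = np.sort(rng.choice(np.arange(1, L + 1), size=alloc[chrom], replace=False))
        positions[chrom] = pos
        for p in pos:
            marker_rows.append(
                {"marker": f"m{order:05d}", "chrom": chrom, "pos": int(p),
                 "order": order,
                 "cM_true": 100.0 * spec.crossover_rate * p / L}
            )
            order += 1
    markers = pd.DataFrame(marker_rows)
    n_markers = len(markers)
    n_ind = spec.n_individuals

    genotypes = np.zeros((n_markers, n_ind), dtype=np.int8)
    crossovers: dict[str, dict] = {}
    individuals = [f"F2_{i + 1:04d}" for i in range(n_ind)]
    row_offset = {}
    off = 0
    for chrom in chroms:
        row_offset[chrom] = off
        off += alloc[chrom]

    phases: dict[str, dict] = {}
    for i, ind in enumerate(individuals):
        crossovers[ind] = {}
        phases[ind] = {}
        for chrom in chroms:
            L = genome.chrom_lengths[chrom]
            pos = positions[chrom]
            geno = np.zeros(pos.size, dtype=np.int8)
            breaks_all = []
            phase_all = []
            for _gamete in range(2):
                n_x = int(rng.poisson(spec.crossover_rate))
                breaks = np.sort(rng.integers(1, L, size=n_x))
                phase0 = int(rng.integers(2))
                hap = (phase0 + np.searchsorted(breaks, pos, side="left")) % 2
                geno += hap.astype(np.int8)
                breaks_all.append([int(b) for b in breaks])
                phase_all.append(phase0)
            sl = slice(row_offset[chrom], row_offset[chrom] + pos.size)
            genotypes[sl, i] = geno
            crossovers[ind][chrom] = breaks_all
            phases[ind][chrom] = tuple(phase_all)

    clean = genotypes.copy()
    if spec.genotype_error_rate > 0:
        mask = rng.random(genotypes.shape) < spec.genotype_error_rate
        shift = rng.integers(1, 3, size=int(mask.sum()))
        genotypes[mask] = (genotypes[mask] + shift) % 3
    if spec.missing_rate > 0:
        genotypes[rng.random(genotypes.shape) < spec.missing_rate] = -1

    # observed depth / MAF annotations used by the SNP filter
    depth = rng.poisson(spec.mean_depth, size=n_markers).astype(int)
    maf = np.empty(n_markers)
    for r in range(n_markers):
        g = genotypes[r]
        called = g[g >= 0]
        if called.size == 0:
            maf[r] = 0.0
        else:
            alt = (called.sum()) / (2.0 * called.size)
            maf[r] = min(alt, 1.0 - alt)
    markers["depth"] = depth
    markers["maf"] = maf

    truth = F2Truth(markers[["marker", "chrom", "pos", "order", "cM_true"]].copy(),
                    crossovers, phases, clean)
    return F2Sim(genotypes, markers, individuals, truth)


# ---------------------------------------------------------------------------
# structured population with a planted sweep
# ---------------------------------------------------------------------------

@dataclass
class PopTruth:
    sweep_window: tuple
    swept_group: int
    causal_snp: int
    group_freqs: np.ndarray


@dataclass
class PopSim:
    genotypes: np.ndarray  # accessions x snps, alt-allele dosage 0/1/2, -1 missing
    positions: np.ndarray
    chrom: str
    accessions: list
    groups: list  # group index per accession
    phenotype: np.ndarray  # 1 = resistant
    truth: PopTruth


def simulate_population(config: SimConfig) -> PopSim:
    """Three-group population with a low-diversity sweep and a linked phenotype.

    Group allele frequencies follow a Balding–Nichols draw around shared
    ancestral frequencies; inside the sweep window the swept group's expected
    heterozygosity is divided by ``sweep_reduction``. A binary phenotype tracks
    the swept group's major allele at the window-central SNP with probability
    ``phenotype_linkage``.
    """
    spec = config.pop_spec
    if not (0 <= spec.sweep_window[0] < spec.sweep_window[1] <= spec.chrom_length):
        raise ValueError("sweep window outside the chromosome")
    if any(g < 2 for g in spec.group_sizes):
        raise ValueError("each group needs at least 2 accessions")
    rng = _rng(config, 3)
    n_acc = sum(spec.group_sizes)
    n_groups = len(spec.group_sizes)

    positions = np.sort(
        rng.choice(np.arange(1, spec.chrom_length + 1), size=spec.n_snps,
                   replace=False)
    )
    # Beta(c, c) ancestral frequencies with mean heterozygosity c/(2c+1)
    h = min(spec.background_diversity, 0.45)
    c = h / (1.0 - 2.0 * h)
    anc = rng.beta(c, c, size=spec.n_snps)
    anc = np.clip(anc, 0.01, 0.99)

    f = max(spec.fst, 1e-4)
    scale = (1.0 - f) / f
    freqs = np.empty((n_groups, spec.n_snps))
    for g in range(n_groups):
        freqs[g] = rng.beta(anc * scale, (1.0 - anc) * scale)
    freqs = np.clip(freqs, 1e-4, 1.0 - 1e-4)

    in_window = (positions >= spec.sweep_window[0]) & (positions < spec.sweep_window[1])
    if spec.sweep_reduction > 1.0:
        g = spec.swept_group
        p = freqs[g, in_window]
        het = 2.0 * p * (1.0 - p) / spec.sweep_reduction
        root = np.sqrt(np.clip(1.0 - 2.0 * het, 0.0, 1.0))
        freqs[g, in_window] = np.where(p < 0.5, 0.5 * (1 - root), 0.5 * (1 + root))

    group_of = np.repeat(np.arange(n_groups), spec.group_sizes)
    genotypes = np.empty((n_acc, spec.n_snps), dtype=np.int8)
    for a in range(n_acc):
        genotypes[a] = rng.binomial(2, freqs[group_of[a]])
    if spec.missing_rate > 0:
        genotypes[rng.random(genotypes.shape) < spec.missing_rate] = -1

    center = (spec.sweep_window[0] + spec.sweep_window[1]) // 2
    causal = int(np.argmin(np.abs(positions - center)))
    major_is_alt = freqs[spec.swept_group, causal] >= 0.5
    dosage = genotypes[:, causal]
    carrier = (dosage == 2) if major_is_alt else (dosage == 0)
    linked = rng.random(n_acc) < spec.phenotype_linkage
    noise = rng.integers(0, 2, n_acc).astype(bool)
    phenotype = np.where(linked, carrier, noise).astype(np.int8)

    accessions = [f"acc{a + 1:03d}" for a in range(n_acc)]
    truth = PopTruth(tuple(spec.sweep_window), spec.swept_group, causal, freqs)
    return PopSim(genotypes, positions, "chr1", accessions,
                  [int(g) for g in group_of], phenotype, truth)


# ---------------------------------------------------------------------------
# multi-species gene orders with planted indels
# ---------------------------------------------------------------------------

@dataclass
class OrthoTruth:
    deleted_core: list  # core indices removed from the focal genome
    inserted_genes: list  # gene ids present only in the focal genome
    focal: str
    other: str


@dataclass
class OrthoSim:
    orders: dict  # species -> DataFrame(gene, chrom, order)
    pairs: pd.DataFrame  # species_a, gene_a, species_b, gene_b, similarity
    truth: OrthoTruth


def simulate_ortholog_tables(config: SimConfig) -> OrthoSim:
    """Shared collinear gene order with planted focal-genome indels.

    Deletions remove core genes from the focal genome (first species) while
    every other genome keeps them; insertions add focal-only genes. Optional
    spurious homology pairs emulate annotation noise.
    """
    spec = config.ortho_spec
    if len(spec.species) < 5:
        raise ValueError("need the two focal genomes plus at least 3 outgroups")
    rng = _rng(config, 4)
    focal, other = spec.species[0], spec.species[1]
    n = spec.n_core

    eligible = np.arange(2, n - 2)
    chosen = rng.choice(eligible, size=spec.n_deletions + spec.n_insertions,
                        replace=False)
    deleted = sorted(int(x) for x in chosen[: spec.n_deletions])
    insert_after = sorted(int(x) for x in chosen[spec.n_deletions :])

    gene_name = lambda sp, core: f"{sp}_g{core:04d}"
    orders: dict[str, pd.DataFrame] = {}
    for sp in spec.species:
        genes = []
        for core in range(n):
            if sp == focal and core in deleted:
                continue
            genes.append((gene_name(sp, core), core))
            if sp == focal and core in insert_after:
                genes.append((f"{focal}_ins{core:04d}", None))
        orders[sp] = pd.DataFrame(
            {"gene": [g for g, _ in genes], "chrom": "chr3",
             "order": np.arange(len(genes))}
        )

    pair_rows = []
    lo, hi = spec.similarity
    species = list(spec.species)
    for ai in range(len(species)):
        for bi in range(ai + 1, len(species)):
            sa, sb = species[ai], species[bi]
            for core in range(n):
                if focal in (sa, sb) and core in deleted:
                    continue
                pair_rows.append(
                    {"species_a": sa, "gene_a": gene_name(sa, core),
                     "species_b": sb, "gene_b": gene_name(sb, core),
                     "similarity": float(rng.uniform(lo, hi))}
                )
    if spec.homology_noise > 0:
        n_noise = int(round(spec.homology_noise * n))
        for _ in range(n_noise):
            sa, sb = rng.choice(len(species), size=2, replace=False)
            sa, sb = species[int(sa)], species[int(sb)]
            ga = orders[sa]["gene"].iloc[int(rng.integers(len(orders[sa])))]
            gb = orders[sb]["gene"].iloc[int(rng.integers(len(orders[sb])))]
            pair_rows.append(
                {"species_a": sa, "gene_a": ga, "species_b": sb, "gene_b": gb,
                 "similarity": float(rng.uniform(lo, hi))}
            )
    pairs = pd.DataFrame(pair_rows)
    truth = OrthoTruth(deleted, [f"{focal}_ins{c:04d}" for c in insert_after],
                       focal, other)
    return OrthoSim(orders, pairs, truth)


# ---------------------------------------------------------------------------
# neutral coalescent haplotypes (π / θ_W calibration)
# ---------------------------------------------------------------------------

def simulate_neutral_haplotypes(
    n_haplotypes: int,
    sequence_length: float,
    mutation_rate: float,
    ne: float,
    seed: int,
):
    """Neutral constant-size coalescent haplotypes via msprime (no recombination).

    Returns (positions, haplotype matrix of 0/1 with shape snps x haplotypes).
    Under this model E[π] = E[θ_W] = 4·Ne·μ per site, which calibrates the
    diversity estimators.
    """
    import msprime

    ts = msprime.sim_ancestry(
        samples=n_haplotypes, ploidy=1, population_size=ne,
        sequence_length=sequence_length, random_seed=max(1, seed % (2**31 - 1)),
    )
    mts = msprime.sim_mutations(
        ts, rate=mutation_rate, random_seed=max(1, (seed + 1) % (2**31 - 1)),
        model=msprime.BinaryMutationModel(),
    )
    genotypes = mts.genotype_matrix()
    positions = np.array([s.position for s in mts.sites()])
    return positions, genotypes
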