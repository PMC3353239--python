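"""Synthetic genomes, haplotypes, reads and truth tables.

The generator emulates the study design the downstream analysis assumes: an
inbred, nearly homozygous female sample carrying two neo-X copies, and an
outbred male pool carrying clonal, diverged neo-Y copies alongside neo-X
copies with low-frequency segregating polymorphism.  Planted neo-Y lesions
(premature stops, frameshifts, tandem duplications) and a male-limited
supernumerary (B) fragment mosaicked from subcentromeric sequence are all
recorded in a truth table so every stage can be validated offline.

All coordinates in truth tables are 0-based on the reference genome.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._seq import A, C, G, T, Genome, decode, encode, revcomp

STOP_CODONS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = [
    "".join(c) for c in itertools.product("TCAG", repeat=3) if "".join(c) not in STOP_CODONS
]


class SimulationError(ValueError):
    """Raised when a plan cannot be realised (e.g. infeasible gene packing)."""


# ---------------------------------------------------------------------------
# plans
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChromSpec:
    label: str
    muller: str
    length: int
    gene_count: int


@dataclass(frozen=True)
class GenomePlan:
    """Layout of the ancestral (reference) genome."""

    chrom_specs: tuple[ChromSpec, ...]
    gc_content: float = 0.42
    seed: int = 0
    mean_cds_codons: int = 300
    cds_codon_sd: int = 40
    gene_flank: int = 300  # non-coding genic flank on each side; the "intron" class

    def __post_init__(self):
        if not 0 < self.gc_content < 1:
            raise SimulationError("gc_content must be in (0, 1)")
        for cs in self.chrom_specs:
            if cs.length <= 0:
                raise SimulationError(f"{cs.label}: length must be > 0")
            mean_gene = 3 * self.mean_cds_codons + 2 * self.gene_flank
            if cs.gene_count * mean_gene >= cs.length:
                raise SimulationError(
                    f"{cs.label}: {cs.gene_count} genes of mean span {mean_gene} bp "
                    f"cannot fit in {cs.length} bp"
                )


def default_genome_plan(seed: int = 0, scale: float = 1.0) -> GenomePlan:
    """2 Mb four-chromosome demo karyotype: ancestral X, fused neo element
    (~40% of the genome), a large autosome and the dot chromosome."""

    def s(x):
        return int(round(x * scale))

    def g(n):
        return n if scale >= 1 else max(2, int(round(n * scale)))

    return GenomePlan(
        chrom_specs=(
            ChromSpec("chrX", "A", s(500_000), g(30)),
            ChromSpec("neo", "C+D", s(800_000), g(50)),
            ChromSpec("chr2", "B+E", s(500_000), g(35)),
            ChromSpec("chr4", "F", s(200_000), g(5)),
        ),
        seed=seed,
    )


@dataclass(frozen=True)
class DivergencePlan:
    """Between-haplotype divergence and planted neo-Y lesions.

    Rates are per bp.  ``female_het_rate`` is the residual heterozygosity of
    the inbred female (a free parameter; real value unknown), kept well below
    ``snp_rate``.  ``male_het_rate`` models segregating variation in the
    outbred male pool, distributed at low counts over ``male_haplotype_pairs``
    neo-X-side haplotypes so that male polymorphisms sit at read ratios far
    from the fixed-difference 1:1 band.
    """

    snp_rate: float = 2e-3
    indel_rate: float = 2e-4
    indel_len_range: tuple[int, int] = (1, 6)
    pseudogene_fraction: float = 0.2
    ancestral_disruption_count: int = 5
    tandem_dup_count: int = 10
    tandem_dup_len_range: tuple[int, int] = (500, 2000)
    b_slice_len: int = 2000
    b_private_len: int = 20000
    b_snp_count: int = 10
    female_het_rate: float = 5e-4
    male_het_rate: float = 3e-3
    male_haplotype_pairs: int = 4

    def __post_init__(self):
        for name in ("snp_rate", "indel_rate", "female_het_rate", "male_het_rate"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        if not 0 <= self.pseudogene_fraction <= 1:
            raise SimulationError("pseudogene_fraction must be in [0, 1]")
        lo, hi = self.indel_len_range
        if not (1 <= lo <= hi <= 6):
            raise SimulationError("indel_len_range must lie within [1, 6]")
        if self.male_haplotype_pairs < 1:
            raise SimulationError("male_haplotype_pairs must be >= 1")

    @property
    def b_fragment_len(self) -> int:
        return 2 * self.b_slice_len + self.b_private_len


@dataclass(frozen=True)
class InsertSpec:
    """Paired-end library geometry (insert = outer fragment length)."""

    mean: int = 500
    sd: int = 50
    read_len: int = 100

    def __post_init__(self):
        if self.mean <= 2 * self.read_len:
            raise SimulationError("insert mean must exceed 2 x read_len")
        if self.sd <= 0:
            raise SimulationError("insert sd must be > 0")


# ---------------------------------------------------------------------------
# truth table
# ---------------------------------------------------------------------------

#: ``freq`` is the expected allele frequency in the male read pool
#: (0.5 for fixed neo-X/neo-Y differences, count/(2H) for male segregating
#: polymorphism, NaN where not applicable)
SNP_COLS = ["chrom", "pos", "ref", "alt", "carrier", "freq"]
INDEL_COLS = ["chrom", "pos", "ref", "alt", "length", "kind", "carrier"]
DISRUPT_COLS = ["gene_id", "chrom", "kind", "allele", "pos"]
SV_COLS = ["chrom", "start", "end", "type", "haplotype"]


@dataclass
class TruthTable:
    """Every planted event, in reference coordinates (0-based)."""

    planted_snps: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=SNP_COLS))
    planted_indels: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=INDEL_COLS))
    planted_disruptions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=DISRUPT_COLS)
    )
    planted_svs: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=SV_COLS))

    def write(self, prefix) -> None:
        self.planted_snps.to_csv(f"{prefix}.snps.tsv", sep="\t", index=False)
        self.planted_indels.to_csv(f"{prefix}.indels.tsv", sep="\t", index=False)
        self.planted_disruptions.to_csv(f"{prefix}.disruptions.tsv", sep="\t", index=False)
        self.planted_svs.to_csv(f"{prefix}.svs.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, prefix) -> "TruthTable":
        return cls(
            pd.read_csv(f"{prefix}.snps.tsv", sep="\t"),
            pd.read_csv(f"{prefix}.indels.tsv", sep="\t"),
            pd.read_csv(f"{prefix}.disruptions.tsv", sep="\t"),
            pd.read_csv(f"{prefix}.svs.tsv", sep="\t"),
        )


# ---------------------------------------------------------------------------
# ancestral genome
# ---------------------------------------------------------------------------


def _random_orf(rng: np.random.Generator, n_codons: int) -> np.ndarray:
    """ATG + stop-free internal codons + exactly one terminal stop."""
    internal = rng.integers(0, len(_SENSE_CODONS), size=n_codons - 2)
    parts = ["ATG"] + [_SENSE_CODONS[i] for i in internal] + ["TAA"]
    return encode("".join(parts))


def build_ancestral_genome(plan: GenomePlan) -> tuple[Genome, pd.DataFrame]:
    """Generate the reference genome and its single-exon gene models.

    Each chromosome is random sequence at the planned GC content with
    ``gene_count`` non-overlapping ORFs planted on random strands.  Returns
    the genome and a gene table (gene span = CDS plus the non-coding flank).
    """
    root = np.random.SeedSequence(plan.seed)
    chrom_seeds = root.spawn(len(plan.chrom_specs))
    seqs: dict[str, np.ndarray] = {}
    rows = []
    base_p = np.array(
        [
            (1 - plan.gc_content) / 2,
            plan.gc_content / 2,
            plan.gc_content / 2,
            (1 - plan.gc_content) / 2,
        ]
    )
    for cs, css in zip(plan.chrom_specs, chrom_seeds):
        rng = np.random.default_rng(css)
        codes = rng.choice(4, size=cs.length, p=base_p).astype(np.uint8)
        if cs.gene_count > 0:
            slot = cs.length // cs.gene_count
            for gi in range(cs.gene_count):
                n_codons = max(20, int(round(rng.normal(plan.mean_cds_codons, plan.cds_codon_sd))))
                cds_len = 3 * n_codons
                if cds_len + 2 * plan.gene_flank + 2 > slot:
                    raise SimulationError(
                        f"cannot pack gene of {cds_len} bp plus flanks into a "
                        f"{slot} bp slot on {cs.label}"
                    )
                off = int(rng.integers(plan.gene_flank, slot - cds_len - plan.gene_flank))
                cds_start = gi * slot + off
                cds_end = cds_start + cds_len
                strand = "+" if rng.random() < 0.5 else "-"
                orf = _random_orf(rng, n_codons)
                codes[cds_start:cds_end] = orf if strand == "+" else revcomp(orf)
                rows.append(
                    {
                        "gene_id": f"{cs.label}_g{gi:04d}",
                        "chrom": cs.label,
                        "start": cds_start - plan.gene_flank,
                        "end": cds_end + plan.gene_flank,
                        "strand": strand,
                        "cds_start": cds_start,
                        "cds_end": cds_end,
                        "expression": float(rng.random()),
                    }
                )
        seqs[cs.label] = codes
    genes = pd.DataFrame(rows, columns=[
        "gene_id", "chrom", "start", "end", "strand", "cds_start", "cds_end", "expression"
    ])
    return Genome(seqs, [cs.label for cs in plan.chrom_specs]), genes


# -- GFF3 (1-based inclusive) ------------------------------------------------


def write_gff3(genes: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in genes.itertuples():
            attrs = f"ID={r.gene_id};expression={r.expression:.6f}"
            fh.write(
                f"{r.chrom}\tneosex_sim\tgene\t{r.start + 1}\t{r.end}\t.\t{r.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{r.chrom}\tneosex_sim\tCDS\t{r.cds_start + 1}\t{r.cds_end}\t.\t{r.strand}\t0"
                f"\tID={r.gene_id}.cds;Parent={r.gene_id}\n"
            )


def read_gff3(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "source", "type", "start", "end", "score", "strand", "phase", "attrs"],
    )
    genes = df[df["type"] == "gene"].copy()
    cds = df[df["type"] == "CDS"].copy()
    genes["gene_id"] = genes["attrs"].str.extract(r"ID=([^;]+)")
    genes["expression"] = genes["attrs"].str.extract(r"expression=([0-9.eE+-]+)").astype(float)
    cds["gene_id"] = cds["attrs"].str.extract(r"Parent=([^;]+)")
    cds = cds.set_index("gene_id")
    genes["cds_start"] = genes["gene_id"].map(cds["start"]).astype(int) - 1
    genes["cds_end"] = genes["gene_id"].map(cds["end"]).astype(int)
    genes["start"] = genes["start"] - 1
    out = genes[
        ["gene_id", "chrom", "start", "end", "strand", "cds_start", "cds_end", "expression"]
    ].reset_index(drop=True)
    out["end"] = out["end"].astype(int)
    return out


# ---------------------------------------------------------------------------
# haplotype derivation
# ---------------------------------------------------------------------------


@dataclass
class Haplotype:
    """One haploid sequence set with its share of the sample ('weight':
    fraction of the diploid sample this haplotype represents)."""

    name: str
    seqs: dict[str, np.ndarray]
    weight: float


@dataclass
class SexedSample:
    """The simulated study material for both sexes plus the truth table."""

    female: list[Haplotype]
    male: list[Haplotype]
    b_fragment: np.ndarray | None
    truth: TruthTable


Edit = tuple[int, int, np.ndarray]  # (pos, ref_len, alt codes)


def apply_edits(base: np.ndarray, edits: list[Edit]) -> np.ndarray:
    """Apply non-overlapping edits; safe in any order (applied right-to-left)."""
    if not edits:
        return base.copy()
    parts = []
    prev = 0
    for pos, ref_len, alt in sorted(edits, key=lambda e: e[0]):
        parts.append(base[prev:pos])
        parts.append(alt)
        prev = pos + ref_len
    parts.append(base[prev:])
    return np.concatenate(parts)


class _Reserver:
    """Tracks reserved (disjoint) reference intervals so planted events never
    collide; bisect keeps reservation O(log n)."""

    def __init__(self):
        self._starts: list[int] = []
        self._ends: list[int] = []

    def try_reserve(self, start: int, end: int, pad: int = 8) -> bool:
        import bisect

        i = bisect.bisect_left(self._starts, start - pad)
        # neighbour on the left may still overlap via its end
        if i > 0 and self._ends[i - 1] > start - pad:
            return False
        if i < len(self._starts) and self._starts[i] < end + pad:
            return False
        self._starts.insert(i, start)
        self._ends.insert(i, end)
        return True


def _codon_genome_span(gene, codon_idx: int) -> tuple[int, int]:
    """Reference interval of codon ``codon_idx`` (CDS-space) of a gene."""
    if gene.strand == "+":
        s = gene.cds_start + 3 * codon_idx
    else:
        s = gene.cds_end - 3 * (codon_idx + 1)
    return s, s + 3


def _plant_premature_stop(rng, gene, ref_codes, reserver, snp_rows, allele):
    """Introduce a nonsense mutation: a single substitution turning one
    internal codon into a stop.  Returns (edit list, codon index), or
    (None, None) when no codon of the gene is one substitution from a stop
    or every such locus is already reserved."""
    n_codons = (gene.cds_end - gene.cds_start) // 3
    order = rng.permutation(np.arange(2, n_codons - 2))
    for codon_idx in order:
        s, e = _codon_genome_span(gene, int(codon_idx))
        old = ref_codes[s:e]
        codon = decode(old if gene.strand == "+" else revcomp(old))
        hits = [
            (i, stop)
            for stop in STOP_CODONS
            for i in range(3)
            if sum(a != b for a, b in zip(codon, stop)) == 1 and codon[i] != stop[i]
        ]
        if not hits:
            continue
        if not reserver.try_reserve(s, e):
            continue
        i, stop = hits[int(rng.integers(len(hits)))]
        mutant = codon[:i] + stop[i] + codon[i + 1 :]
        new = encode(mutant) if gene.strand == "+" else revcomp(encode(mutant))
        off = int(np.nonzero(old != new)[0][0])
        snp_rows.append(
            {
                "chrom": gene.chrom,
                "pos": s + off,
                "ref": decode(old[off : off + 1]),
                "alt": decode(new[off : off + 1]),
                "carrier": allele,
                "freq": 0.5 if allele == "neoY" else 1.0,
            }
        )
        return [(s + off, 1, new[off : off + 1].copy())], int(codon_idx)
    return None, None


def derive_haplotypes(
    genome: Genome, genes: pd.DataFrame, dp: DivergencePlan, seed: int
) -> SexedSample:
    """Derive female and male haplotype sets, the B fragment and the truth.

    Female: two near-identical copies of the reference (residual
    heterozygosity only).  Male: ``male_haplotype_pairs`` neo-X-side copies
    with low-count polymorphism plus as many clonal neo-Y-side copies
    carrying the planted divergence, disruptions and tandem duplications.
    All haplotypes inherit the planted ancestral disruptions.
    """
    if "neo" not in genome:
        raise SimulationError("genome must contain a 'neo' chromosome")
    neo_genes = genes[genes["chrom"] == "neo"]
    if dp.pseudogene_fraction > 0 and len(neo_genes) == 0:
        raise SimulationError("pseudogene_fraction > 0 but the neo element carries no genes")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 20120322]))
    H = dp.male_haplotype_pairs
    reserver = _Reserver()
    snp_rows: list[dict] = []
    indel_rows: list[dict] = []
    disrupt_rows: list[dict] = []
    sv_rows: list[dict] = []

    # per-chromosome edit lists
    ancestral: dict[str, list[Edit]] = {c: [] for c in genome.names}
    neoy: list[Edit] = []  # neo-Y-only edits, reference coordinates
    female_het: dict[str, list[Edit]] = {c: [] for c in genome.names}
    male_poly: dict[str, list[list[Edit]]] = {c: [[] for _ in range(2 * H)] for c in genome.names}

    # 1. ancestral disruptions (all haplotypes, recorded for the filter test)
    if dp.ancestral_disruption_count > 0:
        if len(neo_genes) < dp.ancestral_disruption_count:
            raise SimulationError("not enough neo genes for ancestral disruptions")
        anc_idx = rng.choice(len(neo_genes), dp.ancestral_disruption_count, replace=False)
        anc_genes = neo_genes.iloc[np.sort(anc_idx)]
        for gene in anc_genes.itertuples():
            edits, codon = _plant_premature_stop(rng, gene, genome.seqs["neo"], reserver,
                                                 snp_rows, "ancestral")
            if edits is None:
                continue
            ancestral["neo"].extend(edits)
            disrupt_rows.append(
                {"gene_id": gene.gene_id, "chrom": "neo", "kind": "premature_stop",
                 "allele": "ancestral", "pos": 3 * codon}
            )
    else:
        anc_genes = neo_genes.iloc[:0]

    # 2. neo-Y lesions: chosen genes get a premature stop or a frameshift
    eligible = neo_genes[~neo_genes["gene_id"].isin(anc_genes["gene_id"])]
    n_dis = int(round(dp.pseudogene_fraction * len(neo_genes)))
    if n_dis > len(eligible):
        raise SimulationError("pseudogene_fraction too high for the available neo genes")
    if n_dis > 0:
        dis_idx = rng.choice(len(eligible), n_dis, replace=False)
        for gene in eligible.iloc[np.sort(dis_idx)].itertuples():
            kind = "premature_stop" if rng.random() < 0.5 else "frameshift"
            if kind == "premature_stop":
                edits, codon = _plant_premature_stop(rng, gene, genome.seqs["neo"], reserver,
                                                     snp_rows, "neoY")
                if edits is None:
                    continue
                neoy.extend(edits)
                disrupt_rows.append(
                    {"gene_id": gene.gene_id, "chrom": "neo", "kind": "premature_stop",
                     "allele": "neoY", "pos": 3 * codon}
                )
            else:
                length = int(rng.choice([1, 2, 4, 5]))
                lo = gene.cds_start + 9
                hi = gene.cds_end - 9 - length
                for _ in range(20):
                    pos = int(rng.integers(lo, hi))
                    if reserver.try_reserve(pos, pos + length + 1):
                        break
                else:
                    continue
                if rng.random() < 0.5:  # deletion from the neo-Y
                    ref_s = genome.seqs["neo"][pos : pos + length]
                    neoy.append((pos, length, np.empty(0, dtype=np.uint8)))
                    indel_rows.append(
                        {"chrom": "neo", "pos": pos, "ref": decode(ref_s), "alt": "",
                         "length": -length, "kind": "del", "carrier": "neoY"}
                    )
                else:  # insertion on the neo-Y
                    ins = rng.integers(0, 4, size=length).astype(np.uint8)
                    neoy.append((pos, 0, ins))
                    indel_rows.append(
                        {"chrom": "neo", "pos": pos, "ref": "", "alt": decode(ins),
                         "length": length, "kind": "ins", "carrier": "neoY"}
                    )
                disrupt_rows.append(
                    {"gene_id": gene.gene_id, "chrom": "neo", "kind": "frameshift",
                     "allele": "neoY", "pos": pos - gene.cds_start}
                )

    # 3. neo-Y tandem duplications (placed before point divergence so that
    #    large intervals can still find collision-free space)
    neo_len = genome.length("neo")
    dlo, dhi = dp.tandem_dup_len_range
    dup_edits: list[Edit] = []
    for _ in range(dp.tandem_dup_count):
        for _try in range(50):
            length = int(rng.integers(dlo, dhi + 1))
            start = int(rng.integers(0, neo_len - length))
            if reserver.try_reserve(start, start + length, pad=dp.indel_len_range[1] + 8):
                break
        else:
            continue
        # duplication realised as insertion of the unit after its own end
        unit = genome.seqs["neo"][start : start + length].copy()
        dup_edits.append((start + length, 0, unit))
        sv_rows.append(
            {"chrom": "neo", "start": start, "end": start + length,
             "type": "tandem_duplication", "haplotype": "neoY"}
        )

    # 4. neo-Y divergence SNPs and short indels
    n_snp = rng.binomial(neo_len, dp.snp_rate)
    for pos in np.sort(rng.choice(neo_len, size=n_snp, replace=False)):
        pos = int(pos)
        if not reserver.try_reserve(pos, pos + 1, pad=2):
            continue
        ref_b = int(genome.seqs["neo"][pos])
        if ref_b > 3:
            continue
        alt_b = int((ref_b + rng.integers(1, 4)) % 4)
        neoy.append((pos, 1, np.array([alt_b], dtype=np.uint8)))
        snp_rows.append(
            {"chrom": "neo", "pos": pos, "ref": "ACGT"[ref_b], "alt": "ACGT"[alt_b],
             "carrier": "neoY", "freq": 0.5}
        )
    lo_len, hi_len = dp.indel_len_range
    n_ind = rng.binomial(neo_len, dp.indel_rate)
    for pos in np.sort(rng.choice(neo_len - 10, size=n_ind, replace=False)):
        pos = int(pos)
        length = int(rng.integers(lo_len, hi_len + 1))
        if not reserver.try_reserve(pos, pos + length):
            continue
        if rng.random() < 0.5:
            ref_s = genome.seqs["neo"][pos : pos + length]
            neoy.append((pos, length, np.empty(0, dtype=np.uint8)))
            indel_rows.append(
                {"chrom": "neo", "pos": pos, "ref": decode(ref_s), "alt": "",
                 "length": -length, "kind": "del", "carrier": "neoY"}
            )
        else:
            ins = rng.integers(0, 4, size=length).astype(np.uint8)
            neoy.append((pos, 0, ins))
            indel_rows.append(
                {"chrom": "neo", "pos": pos, "ref": "", "alt": decode(ins),
                 "length": length, "kind": "ins", "carrier": "neoY"}
            )

    # 5. female residual heterozygosity (on haplotype 2 only)
    for chrom in genome.names:
        clen = genome.length(chrom)
        n = rng.binomial(clen, dp.female_het_rate)
        for pos in np.sort(rng.choice(clen, size=n, replace=False)):
            pos = int(pos)
            if chrom == "neo" and not reserver.try_reserve(pos, pos + 1, pad=2):
                continue
            ref_b = int(genome.seqs[chrom][pos])
            alt_b = int((ref_b + rng.integers(1, 4)) % 4)
            female_het[chrom].append((pos, 1, np.array([alt_b], dtype=np.uint8)))
            carrier = "neoX_polymorphism" if chrom == "neo" else "female_polymorphism"
            snp_rows.append(
                {"chrom": chrom, "pos": pos, "ref": "ACGT"[ref_b], "alt": "ACGT"[alt_b],
                 "carrier": carrier, "freq": float("nan")}
            )

    # 6. male segregating polymorphism at low haplotype counts
    for chrom in genome.names:
        clen = genome.length(chrom)
        n = rng.binomial(clen, dp.male_het_rate)
        # on the neo element only neo-X-side copies segregate (the neo-Y is clonal)
        hap_pool = np.arange(H) if chrom == "neo" else np.arange(2 * H)
        for pos in np.sort(rng.choice(clen, size=n, replace=False)):
            pos = int(pos)
            if chrom == "neo" and not reserver.try_reserve(pos, pos + 1, pad=2):
                continue
            ref_b = int(genome.seqs[chrom][pos])
            alt_b = int((ref_b + rng.integers(1, 4)) % 4)
            count = int(rng.choice([1, 2, 3], p=[0.7, 0.2, 0.1]))
            count = min(count, len(hap_pool))
            for h in rng.choice(hap_pool, size=count, replace=False):
                male_poly[chrom][int(h)].append((pos, 1, np.array([alt_b], dtype=np.uint8)))
            snp_rows.append(
                {"chrom": chrom, "pos": pos, "ref": "ACGT"[ref_b], "alt": "ACGT"[alt_b],
                 "carrier": "male_polymorphism", "freq": count / (2 * H)}
            )

    # -- assemble haplotypes ----------------------------------------------
    base = {c: apply_edits(genome.seqs[c], ancestral[c]) for c in genome.names}
    neoy_seq = apply_edits(genome.seqs["neo"], ancestral["neo"] + neoy + dup_edits)

    female = [
        Haplotype("female_h1", dict(base), 0.5),
        Haplotype(
            "female_h2",
            {c: apply_edits(base[c], female_het[c]) for c in genome.names},
            0.5,
        ),
    ]
    male: list[Haplotype] = []
    for h in range(2 * H):
        seqs = {}
        for c in genome.names:
            if c == "neo" and h >= H:
                seqs[c] = neoy_seq  # clonal neo-Y, shared array
            else:
                seqs[c] = apply_edits(base[c], male_poly[c][h])
        side = "x" if h < H else "y"
        male.append(Haplotype(f"male_{side}{h % H + 1}", seqs, 1.0 / (2 * H)))

    # -- B fragment --------------------------------------------------------
    b_fragment = None
    if dp.b_fragment_len > 0 and dp.b_slice_len > 0:
        sl = dp.b_slice_len
        x_slice = genome.seqs["chrX"][1000 : 1000 + sl].copy() if "chrX" in genome else \
            genome.seqs[genome.names[0]][1000 : 1000 + sl].copy()
        neo_slice = genome.seqs["neo"][neo_len - 1000 - sl : neo_len - 1000].copy()
        private = rng.integers(0, 4, size=dp.b_private_len).astype(np.uint8)
        b_fragment = np.concatenate([x_slice, private, neo_slice])
        for pos in np.sort(rng.choice(len(b_fragment), size=dp.b_snp_count, replace=False)):
            pos = int(pos)
            ref_b = int(b_fragment[pos])
            alt_b = int((ref_b + rng.integers(1, 4)) % 4)
            b_fragment[pos] = alt_b
            snp_rows.append(
                {"chrom": "B", "pos": pos, "ref": "ACGT"[ref_b], "alt": "ACGT"[alt_b],
                 "carrier": "B", "freq": float("nan")}
            )
        male.append(Haplotype("B", {"B": b_fragment}, 0.5))

    truth = TruthTable(
        pd.DataFrame(snp_rows, columns=SNP_COLS),
        pd.DataFrame(indel_rows, columns=INDEL_COLS),
        pd.DataFrame(disrupt_rows, columns=DISRUPT_COLS),
        pd.DataFrame(sv_rows, columns=SV_COLS),
    )
    for df in (truth.planted_snps, truth.planted_indels):
        if len(df):
            lens = df["chrom"].map({**genome.lengths, "B": dp.b_fragment_len})
            assert (df["pos"] >= 0).all() and (df["pos"] < lens).all()
    return SexedSample(female, male, b_fragment, truth)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


@dataclass
class ReadSet:
    """A simulated (or parsed) set of read pairs, codes as sequenced."""

    r1: np.ndarray  # (n, L) uint8
    r2: np.ndarray
    hap: np.ndarray  # source haplotype index (or -1)
    chrom: np.ndarray  # source chromosome as pandas-category codes
    chrom_names: list[str]
    start: np.ndarray  # fragment start on the source haplotype
    insert: np.ndarray
    hap_names: list[str] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.r1)

    @property
    def read_len(self) -> int:
        return self.r1.shape[1]

    def name(self, i: int) -> str:
        hap = self.hap_names[self.hap[i]] if self.hap[i] >= 0 else "na"
        chrom = self.chrom_names[self.chrom[i]] if self.chrom[i] >= 0 else "na"
        return f"p{i:07d}|{hap}|{chrom}|{self.start[i]}|{self.insert[i]}"

    def to_fastq(self, path1, path2) -> None:
        qual = "?" * self.read_len  # constant Q30, Sanger +33
        for path, reads, mate in ((path1, self.r1, 1), (path2, self.r2, 2)):
            with open(path, "w") as fh:
                txt = decode(reads.reshape(-1))
                L = self.read_len
                fh.writelines(
                    f"@{self.name(i)}/{mate}\n{txt[i * L:(i + 1) * L]}\n+\n{qual}\n"
                    for i in range(len(reads))
                )

    @classmethod
    def from_fastq(cls, path1, path2) -> "ReadSet":
        import pysam

        def load(path):
            seqs, names = [], []
            with pysam.FastxFile(str(path)) as fh:
                for rec in fh:
                    seqs.append(encode(rec.sequence))
                    names.append(rec.name)
            return np.stack(seqs), names

        r1, names = load(path1)
        r2, _ = load(path2)
        haps, chroms, starts, inserts = [], [], [], []
        hap_names: list[str] = []
        chrom_names: list[str] = []
        for nm in names:
            if nm.endswith("/1") or nm.endswith("/2"):
                nm = nm[:-2]
            fields = nm.split("|")
            if len(fields) == 5:
                _, hap, chrom, s, ins = fields
                if hap not in hap_names:
                    hap_names.append(hap)
                if chrom not in chrom_names:
                    chrom_names.append(chrom)
                haps.append(hap_names.index(hap))
                chroms.append(chrom_names.index(chrom))
                starts.append(int(s))
                inserts.append(int(ins))
            else:
                haps.append(-1)
                chroms.append(-1)
                starts.append(-1)
                inserts.append(-1)
        return cls(
            r1, r2, np.asarray(haps), np.asarray(chroms), chrom_names,
            np.asarray(starts), np.asarray(inserts), hap_names,
        )


def _allocate(weights: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder allocation of ``total`` into integer counts."""
    if total == 0 or weights.sum() == 0:
        return np.zeros(len(weights), dtype=np.int64)
    quota = weights / weights.sum() * total
    counts = np.floor(quota).astype(np.int64)
    rem = total - counts.sum()
    if rem > 0:
        order = np.argsort(-(quota - counts), kind="stable")
        counts[order[:rem]] += 1
    return counts


def simulate_reads(
    haplotypes: list[Haplotype],
    ins: InsertSpec,
    coverage: float,
    err_rate: float,
    seed: int,
) -> ReadSet:
    """Draw inward-facing (FR) read pairs uniformly from each haplotype.

    Total pair count is ``round(C * G / (2L))`` with G the weighted haploid
    genome size (sum over haplotypes of weight x length), so the expected
    depth at a reference position is the requested coverage.  Insert lengths
    are Normal(mean, sd) truncated at 2 x read_len; a per-base error rate
    substitutes uniformly among the three other bases.
    """
    if coverage <= 0:
        raise SimulationError("coverage must be > 0")
    L = ins.read_len
    units = []  # (hap_idx, chrom_idx_global, codes, weighted_len)
    chrom_names: list[str] = []
    for hi, hap in enumerate(haplotypes):
        for chrom, codes in hap.seqs.items():
            if L > len(codes):
                raise SimulationError(f"read_len {L} exceeds {chrom} length on {hap.name}")
            if chrom not in chrom_names:
                chrom_names.append(chrom)
            units.append((hi, chrom_names.index(chrom), codes, hap.weight * len(codes)))
    wlen = np.array([u[3] for u in units])
    total_pairs = int(round(coverage * wlen.sum() / (2 * L)))
    counts = _allocate(wlen, total_pairs)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 6502]))
    r1p, r2p, happ, chromp, startp, insp = [], [], [], [], [], []
    for (hi, ci, codes, _w), n in zip(units, counts):
        if n == 0:
            continue
        clen = len(codes)
        max_ins = min(clen, ins.mean + 6 * ins.sd)
        lens = np.rint(rng.normal(ins.mean, ins.sd, size=n)).astype(np.int64)
        for _ in range(100):
            bad = (lens < 2 * L) | (lens > max_ins)
            if not bad.any():
                break
            lens[bad] = np.rint(rng.normal(ins.mean, ins.sd, size=bad.sum())).astype(np.int64)
        np.clip(lens, 2 * L, max_ins, out=lens)
        starts = rng.integers(0, clen - lens + 1)
        cols = np.arange(L)
        f1 = codes[starts[:, None] + cols]
        f2 = codes[(starts + lens - L)[:, None] + cols]
        # reverse-complement each row (mate 2 is sequenced off the far end)
        r2 = np.ascontiguousarray(np.flip(f2, axis=1))
        r2 = np.array([3, 2, 1, 0, 4], dtype=np.uint8)[r2]
        if err_rate > 0:
            for arr in (f1, r2):
                mask = rng.random(arr.shape) < err_rate
                shift = rng.integers(1, 4, size=int(mask.sum()))
                arr[mask] = ((arr[mask] + shift) % 4).astype(np.uint8)
        r1p.append(f1)
        r2p.append(r2)
        happ.append(np.full(n, hi))
        chromp.append(np.full(n, ci))
        startp.append(starts)
        insp.append(lens)
    cat = lambda ps, dt=np.int64: (
        np.concatenate(ps).astype(dt) if ps else np.empty(0, dtype=dt)
    )
    return ReadSet(
        np.concatenate(r1p) if r1p else np.empty((0, L), dtype=np.uint8),
        np.concatenate(r2p) if r2p else np.empty((0, L), dtype=np.uint8),
        cat(happ), cat(chromp), chrom_names, cat(startp), cat(insp),
        [h.name for h in haplotypes],
    )


# ---------------------------------------------------------------------------
# derived inputs for the scaffolding and subtraction stages
# ---------------------------------------------------------------------------


def haplotype_to_scaffolds(
    hap: Haplotype, chunk: int, prefix: str
) -> dict[str, np.ndarray]:
    """Split a haplotype into fixed-size scaffold chunks (assembly stand-in)."""
    out: dict[str, np.ndarray] = {}
    i = 0
    for chrom in hap.seqs:
        codes = hap.seqs[chrom]
        for s in range(0, len(codes), chunk):
            out[f"{prefix}_{i:05d}"] = codes[s : s + chunk]
            i += 1
    return out


def fragment_assembly(
    genome: Genome,
    genes: pd.DataFrame,
    seed: int,
    mean_piece: int = 40_000,
    spurious_rate: float = 0.1,
    flip_rate: float = 0.3,
):
    """Fragment the genome into scaffold pieces and emit protein-hit and
    conserved-adjacency tables, mimicking a draft assembly aligned to a
    reference proteome with conserved gene order.

    Returns (scaffolds, hits, adjacency, truth) where ``truth`` records each
    scaffold's source interval and orientation.  Roughly half the breakpoints
    fall inside genes so that order-along-the-gene merging has work to do.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1433]))
    scaffolds: dict[str, np.ndarray] = {}
    truth_rows = []
    hit_rows = []
    prot_chrom = dict(zip(genes["gene_id"], genes["chrom"]))
    sid = 0
    for chrom in genome.names:
        clen = genome.length(chrom)
        n_pieces = max(1, int(round(clen / mean_piece)))
        cuts = np.sort(rng.choice(np.arange(1000, clen - 1000), size=n_pieces - 1, replace=False)) \
            if n_pieces > 1 else np.empty(0, dtype=np.int64)
        bounds = np.concatenate([[0], cuts, [clen]])
        cgenes = genes[genes["chrom"] == chrom]
        for s, e in zip(bounds[:-1], bounds[1:]):
            s, e = int(s), int(e)
            name = f"scf{sid:05d}"
            sid += 1
            flipped = rng.random() < flip_rate
            piece = genome.seqs[chrom][s:e]
            scaffolds[name] = revcomp(piece) if flipped else piece
            truth_rows.append(
                {"scaffold": name, "chrom": chrom, "start": s, "end": e,
                 "flipped": flipped}
            )
            has_real_hit = False
            for g in cgenes.itertuples():
                ov_s = max(s, g.cds_start)
                ov_e = min(e, g.cds_end)
                if ov_e - ov_s < 30:
                    continue
                has_real_hit = True
                # protein (aa) interval of the overlap, in CDS orientation
                if g.strand == "+":
                    p_start = (ov_s - g.cds_start) // 3
                    p_end = (ov_e - g.cds_start) // 3
                else:
                    p_start = (g.cds_end - ov_e) // 3
                    p_end = (g.cds_end - ov_s) // 3
                rel = 1 if g.strand == "+" else -1
                if flipped:
                    rel, ss, se = -rel, e - ov_e, e - ov_s
                else:
                    ss, se = ov_s - s, ov_e - s
                hit_rows.append(
                    {"scaffold": name, "protein": g.gene_id,
                     "score": float(ov_e - ov_s),
                     "identity": float(rng.uniform(0.92, 1.0)),
                     "s_start": ss, "s_end": se,
                     "p_start": int(p_start), "p_end": int(p_end),
                     "orientation": "+" if rel > 0 else "-",
                     "chrom": chrom}
                )
            # spurious off-target hits accompany genuine homology, the way
            # secondary alignments do; hit-free scaffolds stay unassigned
            if has_real_hit and rng.random() < spurious_rate and len(genes):
                g = genes.iloc[int(rng.integers(len(genes)))]
                if g["chrom"] != chrom:
                    span = int(rng.integers(30, 90))
                    hit_rows.append(
                        {"scaffold": name, "protein": g["gene_id"],
                         "score": float(span), "identity": float(rng.uniform(0.3, 0.7)),
                         "s_start": 0, "s_end": span, "p_start": 0, "p_end": span // 3,
                         "orientation": "+", "chrom": g["chrom"]}
                    )
    adj_rows = []
    for chrom in genome.names:
        ids = genes.loc[genes["chrom"] == chrom, "gene_id"].tolist()
        strands = genes.loc[genes["chrom"] == chrom, "strand"].tolist()
        for (a, sa), (b, sb) in zip(zip(ids, strands), zip(ids[1:], strands[1:])):
            adj_rows.append({"protein_a": a, "protein_b": b, "chrom": chrom,
                             "orient_a": sa, "orient_b": sb})
    hits = pd.DataFrame(hit_rows)
    adjacency = pd.DataFrame(adj_rows)
    truth = pd.DataFrame(truth_rows)
    return scaffolds, hits, adjacency, truth
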