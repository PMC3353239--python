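"""Neo-X / neo-Y allele reconstruction and degeneration statistics.

From sex-partitioned variant calls, each gene's neo-X allele is the
reference CDS with female-derived (near-fixed) alleles applied, and the
neo-Y allele adds the male-only alleles whose male read ratio is consistent
with a fixed neo-X/neo-Y difference (~1:1 in the male pool).  Alleles are
scanned for coding disruptions (premature stop, frameshift, start loss);
genes already disrupted in the female-derived allele are ancestral
pseudogenes and are excluded.  Enrichment of the surviving pseudogene set
on the neo element is tested with Fisher's exact test, and coding
divergence/constraint is summarised by Nei–Gojobori (1986) Ka/Ks and codon
usage indices (ENC, CAI, FOP, CBI).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from scipy import stats

from ._seq import Genome, decode, encode, revcomp

STOPS = set(standard_dna_table.stop_codons)
CODON_TO_AA = dict(standard_dna_table.forward_table)
SENSE_CODONS = sorted(CODON_TO_AA)


# ---------------------------------------------------------------------------
# allele reconstruction
# ---------------------------------------------------------------------------


@dataclass
class AllelePair:
    gene_id: str
    neoX_cds: str
    neoY_cds: str
    applied_neoX: list = field(default_factory=list)
    applied_neoY: list = field(default_factory=list)


class UnresolvableGene(ValueError):
    pass


def _apply_variants_to_region(seq: np.ndarray, region_start: int, variants) -> np.ndarray:
    """Apply VCF-like variants (position-descending) to a region copy.

    ``variants`` rows need chrom-local ``pos``, ``kind``, ``ref``, ``alt``.
    Overlapping edits raise :class:`UnresolvableGene`.
    """
    seq = seq.copy()
    edits = []
    for v in variants:
        pos = v["pos"] - region_start
        if v["kind"] == "snp":
            edits.append((pos, 1, encode(v["alt"])))
        elif v["kind"] == "ins":
            edits.append((pos, 0, encode(v["alt"])))
        else:  # del
            edits.append((pos, len(v["ref"]), np.empty(0, dtype=np.uint8)))
    edits.sort(key=lambda e: -e[0])
    last_start = None
    out = seq
    for pos, ref_len, alt in edits:
        if last_start is not None and pos + ref_len > last_start:
            raise UnresolvableGene("overlapping variants")
        last_start = pos
        out = np.concatenate([out[:pos], alt, out[pos + ref_len :]])
    return out


def reconstruct_alleles(
    gene,
    genome: Genome,
    female_calls: pd.DataFrame,
    male_only_calls: pd.DataFrame,
    female_fixed_min_ratio: float = 0.75,
    male_ratio_band: tuple[float, float] = (0.25, 0.75),
) -> AllelePair | None:
    """Rebuild the two neo alleles of one gene from partitioned calls.

    Female calls applied to the reference are restricted to near-fixed
    sites (alt fraction >= ``female_fixed_min_ratio``): residual
    heterozygous sites do not represent the sampled neo-X consensus.
    Male-only calls additionally require a male alt ratio inside
    ``male_ratio_band`` (heterozygous-like, candidate fixed neo-X/neo-Y
    difference).  Returns None when overlapping indels make the gene
    unresolvable.
    """
    s, e = int(gene.cds_start), int(gene.cds_end)
    region = genome.seqs[gene.chrom][s:e]

    def select(calls, lo=None, hi=None, fixed_min=None):
        sub = calls[(calls["chrom"] == gene.chrom) & (calls["pos"] >= s) & (calls["pos"] < e)]
        out = []
        for r in sub.itertuples():
            if fixed_min is not None:
                tot = r.female_ref + r.female_alt
                if tot > 0 and r.female_alt / tot < fixed_min:
                    continue
            if lo is not None and not (lo <= r.alt_ratio_male <= hi):
                continue
            out.append(
                {"pos": int(r.pos), "kind": r.kind, "ref": r.ref, "alt": r.alt}
            )
        return out

    fem = select(female_calls, fixed_min=female_fixed_min_ratio)
    mal = select(male_only_calls, lo=male_ratio_band[0], hi=male_ratio_band[1])
    try:
        neox_region = _apply_variants_to_region(region, s, fem)
        neoy_region = _apply_variants_to_region(neox_region, s, _shift_onto(fem, mal, s))
    except UnresolvableGene:
        return None
    if gene.strand == "-":
        neox_region = revcomp(neox_region)
        neoy_region = revcomp(neoy_region)
    return AllelePair(gene.gene_id, decode(neox_region), decode(neoy_region), fem, mal)


def _shift_onto(applied, variants, region_start):
    """Shift male-only variant coordinates onto the female-edited frame
    (female indels upstream of a site change its offset)."""
    if not applied:
        return variants
    shifts = sorted(
        (v["pos"], (len(v["alt"]) if v["kind"] == "ins" else 0) - (len(v["ref"]) if v["kind"] == "del" else 0))
        for v in applied
        if v["kind"] != "snp"
    )
    out = []
    for v in variants:
        delta = sum(d for p, d in shifts if p < v["pos"])
        out.append({**v, "pos": v["pos"] + delta})
    return out


# ---------------------------------------------------------------------------
# disruption scan
# ---------------------------------------------------------------------------


@dataclass
class DisruptionFlag:
    gene_id: str
    kind: str  # premature_stop | frameshift | start_loss
    cds_offset: int
    allele: str


def scan_disruptions(cds: str, gene_id: str, allele: str, ref_cds_len: int | None = None):
    """Flag coding lesions in one reconstructed allele.

    * premature_stop: an internal stop codon strictly before the terminal one
    * frameshift: CDS length not a multiple of 3 (net intra-CDS indel != 0 mod 3)
    * start_loss: the first codon is no longer ATG

    Genes shorter than 6 bp are skipped (returns None).
    """
    if len(cds) < 6:
        import warnings

        warnings.warn(f"{gene_id}: CDS shorter than 6 bp, skipped")
        return None
    flags: list[DisruptionFlag] = []
    if cds[:3] != "ATG":
        flags.append(DisruptionFlag(gene_id, "start_loss", 0, allele))
    if len(cds) % 3 != 0:
        flags.append(DisruptionFlag(gene_id, "frameshift", len(cds) % 3, allele))
    n_codons = len(cds) // 3
    for i in range(1, n_codons - 1):
        codon = cds[3 * i : 3 * i + 3]
        if codon in STOPS:
            flags.append(DisruptionFlag(gene_id, "premature_stop", 3 * i, allele))
            break
    return flags


def scan_gene_set(pairs: list[AllelePair]) -> pd.DataFrame:
    rows = []
    for ap in pairs:
        for allele, cds in (("neoX", ap.neoX_cds), ("neoY", ap.neoY_cds)):
            flags = scan_disruptions(cds, ap.gene_id, allele)
            for f in flags or []:
                rows.append(
                    {"gene_id": f.gene_id, "allele": f.allele, "kind": f.kind,
                     "cds_offset": f.cds_offset}
                )
    return pd.DataFrame(rows, columns=["gene_id", "allele", "kind", "cds_offset"])


def filter_ancestral(flags: pd.DataFrame) -> tuple[set, set]:
    """Split disrupted genes into (derived pseudogenes, ancestral set).

    A gene disrupted on the female-derived allele (neoX / reference-side) is
    ancestral and removed; only genes disrupted exclusively on the male-
    derived allele survive.
    """
    anc = set(flags.loc[flags["allele"] == "neoX", "gene_id"])
    der = set(flags.loc[flags["allele"] == "neoY", "gene_id"]) - anc
    return der, anc


def pseudogene_enrichment(counts: dict[str, tuple[int, int]], focal: str = "neo") -> pd.DataFrame:
    """Two-sided Fisher's exact test of the focal chromosome's pseudogene
    fraction against every other chromosome (no multiple-testing
    correction).  ``counts`` maps chromosome -> (pseudogenes, total genes).
    """
    k1, n1 = counts[focal]
    rows = []
    for chrom, (k2, n2) in counts.items():
        if chrom == focal:
            continue
        if n1 == 0 or n2 == 0:
            continue
        table = [[k1, n1 - k1], [k2, n2 - k2]]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append(
            {"chrom": chrom, "focal_pseudo": k1, "focal_total": n1,
             "other_pseudo": k2, "other_total": n2, "p_value": float(p)}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Nei–Gojobori Ka/Ks
# ---------------------------------------------------------------------------


@dataclass
class KaKsResult:
    Ka: float
    Ks: float
    Na: float
    Ns: float
    Sa: float
    Ss: float


def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon: at each
    position the 3 possible substitutions are classified; mutations to stop
    codons count as nonsynonymous."""
    aa = CODON_TO_AA[codon]
    syn = 0.0
    for i in range(3):
        for b in "ACGT":
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1 :]
            if alt not in STOPS and CODON_TO_AA[alt] == aa:
                syn += 1 / 3
    return syn, 3.0 - syn


_SITES_CACHE = {c: _codon_sites(c) for c in SENSE_CODONS}


def _codon_path_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) difference counts
    between two codons; paths through stop codons are discarded (all-stop
    path sets fall back to including them)."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0

    def walk(allow_stops):
        tot_s = tot_n = 0.0
        n_paths = 0
        for order in itertools.permutations(diff):
            cur = c1
            s = n = 0.0
            ok = True
            for i in order:
                nxt = cur[:i] + c2[i] + cur[i + 1 :]
                if nxt in STOPS and not allow_stops:
                    ok = False
                    break
                if cur in STOPS or nxt in STOPS:
                    n += 1
                elif CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                    s += 1
                else:
                    n += 1
                cur = nxt
            if ok:
                tot_s += s
                tot_n += n
                n_paths += 1
        return tot_s, tot_n, n_paths

    ts, tn, k = walk(False)
    if k == 0:
        ts, tn, k = walk(True)
    return ts / k, tn / k


def kaks(pair: AllelePair) -> KaKsResult | None:
    """Nei–Gojobori Ka/Ks with Jukes–Cantor correction for one allele pair.

    Requires equal-length, frame-intact CDSs (frameshifted genes are
    excluded upstream); returns None when the pair cannot be scored.
    Symmetric in its two sequences.
    """
    s1, s2 = pair.neoX_cds, pair.neoY_cds
    if len(s1) != len(s2) or len(s1) % 3 != 0:
        return None
    if "N" in s1 or "N" in s2:
        return None
    Sa = Ss = Na = Ns = 0.0
    for i in range(0, len(s1), 3):
        c1, c2 = s1[i : i + 3], s2[i : i + 3]
        if c1 in STOPS or c2 in STOPS:
            continue  # terminal / aberrant stops carry no rate information
        syn1, non1 = _SITES_CACHE[c1]
        syn2, non2 = _SITES_CACHE[c2]
        Ss += (syn1 + syn2) / 2
        Sa += (non1 + non2) / 2
        ds, dn = _codon_path_diffs(c1, c2)
        Ns += ds
        Na += dn

    def jc(p):
        if p <= 0:
            return 0.0
        x = 1 - 4 * p / 3
        if x <= 0:
            return float("nan")
        return -0.75 * float(np.log(x))

    ka = jc(Na / Sa) if Sa > 0 else 0.0
    ks = jc(Ns / Ss) if Ss > 0 else 0.0
    return KaKsResult(ka, ks, Na, Ns, Sa, Ss)


# ---------------------------------------------------------------------------
# codon-usage bias
# ---------------------------------------------------------------------------

# synonymous families (stop codons excluded); single-codon families (M, W)
# carry no bias signal
_FAMILIES: dict[str, list[str]] = {}
for _c, _aa in CODON_TO_AA.items():
    _FAMILIES.setdefault(_aa, []).append(_c)
_DEGENERATE = {aa: sorted(cs) for aa, cs in _FAMILIES.items() if len(cs) > 1}


@dataclass
class CodonBiasResult:
    ENC: float
    CAI: float
    FOP: float
    CBI: float


def _codon_counts(cds: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(0, len(cds) - len(cds) % 3, 3):
        c = cds[i : i + 3]
        if c in CODON_TO_AA:
            counts[c] = counts.get(c, 0) + 1
    return counts


def enc(cds: str) -> float:
    """Wright's effective number of codons, capped to the [20, 61] range.

    Family homozygosity F = (n * sum p_i^2 - 1) / (n - 1), averaged within
    each degeneracy class; a missing 3-fold class borrows the mean of the
    2- and 4-fold classes.
    """
    counts = _codon_counts(cds)
    by_deg: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, codons in _DEGENERATE.items():
        n = sum(counts.get(c, 0) for c in codons)
        if n < 2:
            continue
        ps = [counts.get(c, 0) / n for c in codons]
        F = (n * sum(p * p for p in ps) - 1) / (n - 1)
        by_deg[len(codons)].append(F)

    def mean(xs):
        return sum(xs) / len(xs) if xs else None

    F2, F3, F4, F6 = (mean(by_deg[d]) for d in (2, 3, 4, 6))
    if F3 is None and F2 is not None and F4 is not None:
        F3 = (F2 + F4) / 2
    if None in (F2, F3, F4, F6) or 0 in (F2, F3, F4, F6):
        return float("nan")
    val = 2 + 9 / F2 + 1 / F3 + 5 / F4 + 3 / F6
    return float(min(max(val, 20.0), 61.0))


def cai_weights(reference_cds: list[str]) -> dict[str, float]:
    """Relative-adaptiveness weights from a reference (highly expressed)
    gene set: w = codon frequency / max frequency in its family."""
    counts: dict[str, int] = {}
    for cds in reference_cds:
        for c, n in _codon_counts(cds).items():
            counts[c] = counts.get(c, 0) + n
    weights: dict[str, float] = {}
    for aa, codons in _DEGENERATE.items():
        mx = max(counts.get(c, 0) for c in codons)
        for c in codons:
            weights[c] = (counts.get(c, 0) / mx) if mx > 0 else 1.0
    return weights


def optimal_codons(weights: dict[str, float]) -> set[str]:
    opt = set()
    for aa, codons in _DEGENERATE.items():
        best = max(codons, key=lambda c: (weights.get(c, 0.0), c))
        opt.add(best)
    return opt


def codon_bias(cds: str, weights: dict[str, float]) -> CodonBiasResult:
    """ENC, CAI, FOP and CBI of one CDS against reference weights.

    CAI: geometric mean of weights over codons of degenerate families
    (w=0 codons are floored at 0.01 as usual).  FOP: optimal / total
    synonymously variable codons.  CBI (Bennetzen–Hall):
    (Nopt - Nrand) / (Ntot - Nrand) with Nrand the expectation under
    uniform usage.
    """
    counts = _codon_counts(cds)
    opt = optimal_codons(weights)
    logw = 0.0
    n_tot = 0
    n_opt = 0
    n_rand = 0.0
    for aa, codons in _DEGENERATE.items():
        fam_n = sum(counts.get(c, 0) for c in codons)
        if fam_n == 0:
            continue
        n_tot += fam_n
        n_rand += fam_n * sum(1 for c in codons if c in opt) / len(codons)
        for c in codons:
            k = counts.get(c, 0)
            if k == 0:
                continue
            w = max(weights.get(c, 0.0), 0.01)
            logw += k * float(np.log(w))
            if c in opt:
                n_opt += k
    cai = float(np.exp(logw / n_tot)) if n_tot else float("nan")
    fop = n_opt / n_tot if n_tot else float("nan")
    cbi = (n_opt - n_rand) / (n_tot - n_rand) if n_tot > n_rand else float("nan")
    return CodonBiasResult(enc(cds), cai, fop, cbi)


def codon_bias_table(
    pairs: list[AllelePair], genes: pd.DataFrame, top_fraction: float = 0.1
) -> pd.DataFrame:
    """Codon-usage indices per allele; the CAI reference set is the
    ``top_fraction`` of genes by expression label."""
    expr = genes.set_index("gene_id")["expression"]
    ranked = expr.sort_values(ascending=False)
    n_ref = max(1, int(round(top_fraction * len(ranked))))
    ref_ids = set(ranked.index[:n_ref])
    ref_cds = [ap.neoX_cds for ap in pairs if ap.gene_id in ref_ids]
    if not ref_cds:
        ref_cds = [ap.neoX_cds for ap in pairs]
    weights = cai_weights(ref_cds)
    rows = []
    for ap in pairs:
        for allele, cds in (("neoX", ap.neoX_cds), ("neoY", ap.neoY_cds)):
            if len(cds) % 3 != 0 or "N" in cds:
                continue
            cb = codon_bias(cds, weights)
            rows.append(
                {"gene_id": ap.gene_id, "allele": allele, "ENC": cb.ENC,
                 "CAI": cb.CAI, "FOP": cb.FOP, "CBI": cb.CBI}
            )
    return pd.DataFrame(rows, columns=["gene_id", "allele", "ENC", "CAI", "FOP", "CBI"])
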