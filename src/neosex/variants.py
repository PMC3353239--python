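"""Pileup construction, SNP/short-indel calling and sex-comparison reports.

The caller is a count-threshold caller: a site is called in one sex when
depth >= min_depth, alt reads >= min_alt_reads and alt fraction >= f_min.
Qualities are synthetic constants upstream, so a Bayesian genotype model
would only re-weight counts; what the downstream statistics need — recall
of planted divergence and a low false-positive floor — is enforced directly
on counts.  Sex partitions:

* ``male_only``        called in males, alt essentially absent in females —
                       the signature of a fixed neo-X/neo-Y difference
                       (expected alt ratio ~0.5 in the male read pool);
* ``female_segregating`` called in females only;
* ``shared``           called in both sexes.

Densities are reported per callable kb (positions with depth >= min_depth in
that sex), avoiding coverage confounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import Genome

BASES = "ACGT"


@dataclass(frozen=True)
class CallerParams:
    min_depth: int = 8
    min_alt_reads: int = 3
    f_min: float = 0.2

    def __post_init__(self):
        if self.min_depth < 2:
            raise ValueError("min_depth must be >= 2")


@dataclass(frozen=True)
class DensityParams:
    window: int = 1_000_000
    step: int = 100_000
    min_depth: int = 8
    min_alt_reads: int = 3
    region_class: str = "all"  # all | exonic | intronic

    def __post_init__(self):
        if self.step > self.window:
            raise ValueError("step must be <= window")


@dataclass
class PileupColumn:
    chrom: str
    pos: int
    ref: str
    counts: np.ndarray  # (2 strands, 4 bases)
    gap_opens: int = 0

    @property
    def depth(self) -> int:
        return int(self.counts.sum())


@dataclass
class Pileup:
    """Per-position, per-strand base counts over the whole genome.

    ``counts`` has shape (total_length, 2, 4) in chromosome concatenation
    order (no padding); ``chrom_bounds`` maps chromosomes to row slices.
    """

    genome: Genome
    counts: np.ndarray
    gap_opens: np.ndarray  # (total_length,) read count opening a gap here
    chrom_bounds: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.chrom_bounds:
            off = 0
            for n in self.genome.names:
                ln = self.genome.length(n)
                self.chrom_bounds[n] = (off, off + ln)
                off += ln

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=(1, 2))

    def column(self, chrom: str, pos: int) -> PileupColumn:
        s, _ = self.chrom_bounds[chrom]
        return PileupColumn(
            chrom, pos, self.genome.fetch(chrom, pos, pos + 1),
            self.counts[s + pos], int(self.gap_opens[s + pos]),
        )

    def columns(self, chrom: str):
        """Yield one column per covered position (small-data convenience)."""
        s, e = self.chrom_bounds[chrom]
        depth = self.counts[s:e].sum(axis=(1, 2))
        for pos in np.nonzero(depth)[0]:
            yield self.column(chrom, int(pos))


def build_pileup(pairs: pd.DataFrame, rs, genome: Genome, gapped: pd.DataFrame | None = None) -> Pileup:
    """Accumulate per-strand base counts from uniquely mapped pairs.

    CIGAR I/D events from gapped realignments contribute their matched
    segments to the counts and one gap-opening event at the left-aligned
    gap position.
    """
    for name in pairs["chrom1"].unique():
        if name and name not in genome:
            raise ValueError(f"alignment reference {name!r} absent from genome")
    total = genome.total_length
    flat = np.zeros(total * 8, dtype=np.int64)
    starts_by_chrom = {}
    off = 0
    for n in genome.names:
        starts_by_chrom[n] = off
        off += genome.length(n)
    L = rs.read_len
    cols = np.arange(L)
    m = pairs[pairs["status"] == "mapped"]
    chrom_off = m["chrom1"].map(starts_by_chrom).to_numpy(dtype=np.int64)
    chrom_off2 = m["chrom2"].map(starts_by_chrom).to_numpy(dtype=np.int64)
    pid = m["pair_id"].to_numpy()
    chrom_len_map = {n: genome.length(n) for n in genome.names}
    ends1 = chrom_off + m["chrom1"].map(chrom_len_map).to_numpy(dtype=np.int64)
    ends2 = chrom_off2 + m["chrom2"].map(chrom_len_map).to_numpy(dtype=np.int64)
    for reads, offs, ends, poss, strands in (
        (rs.r1, chrom_off, ends1, m["pos1"].to_numpy(), m["strand1"].to_numpy()),
        (rs.r2, chrom_off2, ends2, m["pos2"].to_numpy(), m["strand2"].to_numpy()),
    ):
        if len(poss) == 0:
            continue
        seq = reads[pid]
        rev = strands == "-"
        if rev.any():
            rc = np.ascontiguousarray(np.flip(seq[rev], axis=1))
            rc = np.array([3, 2, 1, 0, 4], dtype=np.uint8)[rc]
            seq = seq.copy()
            seq[rev] = rc
        gpos = (offs + poss)[:, None] + cols  # (n, L)
        strand_bit = rev.astype(np.int64) * 4
        idx = gpos * 8 + strand_bit[:, None] + seq
        # a placement may overhang the chromosome end by up to max_mm bases
        ok = (seq < 4) & (gpos < ends[:, None])
        flat += np.bincount(idx[ok].ravel(), minlength=total * 8)
    gap_opens = np.zeros(total, dtype=np.int64)
    if gapped is not None and len(gapped):
        gap_idx: list[np.ndarray] = []
        for r in gapped.itertuples():
            o = starts_by_chrom[r.chrom]
            j = r.gap_pos - r.pos
            reads = rs.r1 if r.mate == 1 else rs.r2
            seq = reads[r.pair_id]
            if r.strand == "-":
                seq = np.array([3, 2, 1, 0, 4], dtype=np.uint8)[seq[::-1]]
            sb = 4 if r.strand == "-" else 0
            clen = genome.length(r.chrom)
            # left matched block
            left = seq[:j]
            lpos = r.pos + np.arange(j)
            okl = (left < 4) & (lpos < clen)
            gap_idx.append((o + lpos[okl]) * 8 + sb + left[okl])
            # right matched block
            if r.kind == "del":
                right = seq[j:]
                rstart = r.pos + j + r.length
            else:
                right = seq[j + r.length :]
                rstart = r.pos + j
            rpos = rstart + np.arange(len(right))
            okr = (right < 4) & (rpos < clen)
            gap_idx.append((o + rpos[okr]) * 8 + sb + right[okr])
            gap_opens[o + r.gap_pos] += 1
        if gap_idx:
            flat += np.bincount(np.concatenate(gap_idx), minlength=total * 8)
    counts = flat.reshape(total, 2, 4)
    return Pileup(genome, counts, gap_opens)


def _ref_codes_flat(genome: Genome) -> np.ndarray:
    return np.concatenate([genome.seqs[n] for n in genome.names])


def _per_sex_site_stats(pileup: Pileup, ref: np.ndarray, params: CallerParams):
    """Vectorised per-site calling in one sex.

    Returns (called mask, alt base codes, ref counts, alt counts,
    alt fwd-strand counts, alt rev-strand counts, depth).
    """
    tot = pileup.counts.sum(axis=1)  # (G, 4) summed over strands
    depth = tot.sum(axis=1)
    pos_idx = np.arange(len(ref))
    safe_ref = np.clip(ref, 0, 3)
    ref_counts = tot[pos_idx, safe_ref]
    masked = tot.copy()
    masked[pos_idx, safe_ref] = -1
    alt = masked.argmax(axis=1)
    alt_counts = tot[pos_idx, alt]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(depth > 0, alt_counts / np.maximum(depth, 1), 0.0)
    called = (
        (depth >= params.min_depth)
        & (alt_counts >= params.min_alt_reads)
        & (frac >= params.f_min)
        & (ref < 4)
    )
    alt_f = pileup.counts[pos_idx, 0, alt]
    alt_r = pileup.counts[pos_idx, 1, alt]
    return called, alt, ref_counts, alt_counts, alt_f, alt_r, depth


def call_snps(
    pileup_male: Pileup,
    pileup_female: Pileup,
    genome: Genome,
    params: CallerParams = CallerParams(),
) -> pd.DataFrame:
    """Joint male/female SNP calls with sex-partition labels."""
    ref = _ref_codes_flat(genome)
    cm, am, rm, xm, fm, rvm, dm = _per_sex_site_stats(pileup_male, ref, params)
    cf, af, rf_, xf, ff, rvf, df_ = _per_sex_site_stats(pileup_female, ref, params)
    any_called = cm | cf
    idx = np.nonzero(any_called)[0]
    bounds = np.array([pileup_male.chrom_bounds[n][0] for n in genome.names])
    ci = np.searchsorted(bounds, idx, side="right") - 1
    names = np.asarray(genome.names, dtype=object)
    pos = idx - bounds[ci]
    alt = np.where(cm[idx], am[idx], af[idx])
    partition = np.where(
        cm[idx] & cf[idx],
        "shared",
        np.where(
            cm[idx] & (xf[idx] < params.min_alt_reads),
            "male_only",
            np.where(
                cf[idx] & ~cm[idx] & (xm[idx] < params.min_alt_reads),
                "female_segregating",
                "unassigned",
            ),
        ),
    )
    male_alt = pileup_male.counts.sum(axis=1)[idx, alt]
    female_alt = pileup_female.counts.sum(axis=1)[idx, alt]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_m = np.where(dm[idx] > 0, male_alt / np.maximum(dm[idx], 1), 0.0)
    calling_male = cm[idx]
    df = pd.DataFrame(
        {
            "kind": "snp",
            "chrom": names[ci],
            "pos": pos,
            "ref": [BASES[b] for b in ref[idx]],
            "alt": [BASES[b] for b in alt],
            "male_ref": rm[idx],
            "male_alt": male_alt,
            "female_ref": rf_[idx],
            "female_alt": female_alt,
            "alt_fwd": np.where(calling_male, fm[idx], ff[idx]),
            "alt_rev": np.where(calling_male, rvm[idx], rvf[idx]),
            "partition": partition,
            "alt_ratio_male": ratio_m,
        }
    )
    return df


def call_indels(
    gapped_male: pd.DataFrame,
    gapped_female: pd.DataFrame,
    params: CallerParams = CallerParams(),
) -> pd.DataFrame:
    """Short-indel calls: an indel is retained in a sex iff it has at least
    one supporting read on each strand and length in [1, 6]."""

    def per_sex(gapped):
        if len(gapped) == 0:
            return pd.DataFrame(
                columns=["chrom", "gap_pos", "kind", "length", "seq", "fwd", "rev", "support"]
            )
        g = gapped[(gapped["length"] >= 1) & (gapped["length"] <= 6)]
        grp = g.groupby(["chrom", "gap_pos", "kind", "length", "seq"], as_index=False).agg(
            fwd=("strand", lambda s: int((s == "+").sum())),
            rev=("strand", lambda s: int((s == "-").sum())),
        )
        grp["support"] = grp["fwd"] + grp["rev"]
        return grp[(grp["fwd"] >= 1) & (grp["rev"] >= 1)]

    m = per_sex(gapped_male)
    f = per_sex(gapped_female)
    key = ["chrom", "gap_pos", "kind", "length", "seq"]
    merged = m.merge(f, on=key, how="outer", suffixes=("_m", "_f"))
    num_cols = [c for c in merged.columns if c not in key]
    for c in num_cols:
        merged[c] = pd.to_numeric(merged[c], errors="coerce").fillna(0)
    in_m = merged["support_m"] > 0
    in_f = merged["support_f"] > 0
    merged["partition"] = np.where(
        in_m & in_f, "shared", np.where(in_m, "male_only", "female_segregating")
    )
    out = pd.DataFrame(
        {
            "kind": merged["kind"],
            "chrom": merged["chrom"],
            "pos": merged["gap_pos"].astype(int),
            "ref": np.where(merged["kind"] == "del", merged["seq"], ""),
            "alt": np.where(merged["kind"] == "ins", merged["seq"], ""),
            "male_ref": 0,
            "male_alt": merged["support_m"].astype(int),
            "female_ref": 0,
            "female_alt": merged["support_f"].astype(int),
            "alt_fwd": (merged.get("fwd_m", 0) + merged.get("fwd_f", 0)).astype(int),
            "alt_rev": (merged.get("rev_m", 0) + merged.get("rev_f", 0)).astype(int),
            "partition": merged["partition"],
            "alt_ratio_male": 0.5,
            "length": merged["length"].astype(int),
        }
    )
    return out.sort_values(["chrom", "pos"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# densities and reports
# ---------------------------------------------------------------------------


def window_density(
    calls: pd.DataFrame, chrom_lengths: dict[str, int], params: DensityParams
) -> pd.DataFrame:
    """Sliding-window call density (sites/kb); trailing partial window kept
    with its true length."""
    rows = []
    for chrom, clen in chrom_lengths.items():
        pos = np.sort(calls.loc[calls["chrom"] == chrom, "pos"].to_numpy())
        starts = list(range(0, max(clen - params.window, 0) + 1, params.step))
        if not starts or starts[-1] + params.window < clen:
            starts.append(starts[-1] + params.step if starts else 0)
        for s in starts:
            e = min(s + params.window, clen)
            if e <= s:
                continue
            n = np.searchsorted(pos, e) - np.searchsorted(pos, s)
            rows.append(
                {"chrom": chrom, "start": s, "end": e,
                 "density": 1000.0 * n / (e - s), "n_calls": int(n)}
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "density", "n_calls"])


def write_bedgraph(track: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write('track type=bedGraph name="snp_density"\n')
        for r in track.itertuples():
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.density:.6g}\n")


def format_ratio(male: float, female: float) -> str:
    """Table-style ratio: 2 decimals, printed as an integer once >= 10;
    'NA' when the female density is 0."""
    if female == 0:
        return "NA" if male == 0 else "Inf"
    r = male / female
    return f"{round(r)}" if r >= 10 else f"{r:.2f}"


def region_masks(genes: pd.DataFrame, chrom_lengths: dict[str, int]):
    """Boolean exonic (CDS) and intronic (genic non-CDS flank) masks."""
    exonic = {c: np.zeros(l, dtype=bool) for c, l in chrom_lengths.items()}
    genic = {c: np.zeros(l, dtype=bool) for c, l in chrom_lengths.items()}
    for g in genes.itertuples():
        genic[g.chrom][max(0, g.start) : g.end] = True
        exonic[g.chrom][g.cds_start : g.cds_end] = True
    intronic = {c: genic[c] & ~exonic[c] for c in genic}
    return exonic, intronic


def density_ratio_table(
    calls_male: pd.DataFrame,
    calls_female: pd.DataFrame,
    genes: pd.DataFrame,
    genome: Genome,
    pileup_male: Pileup | None = None,
    pileup_female: Pileup | None = None,
    params: CallerParams = CallerParams(),
) -> pd.DataFrame:
    """Per-chromosome exonic/intronic SNP densities with male/female ratios.

    Densities are per callable kb of the region class when pileups are
    given, else per region kb.
    """
    lengths = genome.lengths
    exonic, intronic = region_masks(genes, lengths)
    rows = []
    for chrom in genome.names:
        row = {"chrom": chrom}
        s = None
        if pileup_male is not None:
            s, e = pileup_male.chrom_bounds[chrom]
        for cls_name, mask in (("exonic", exonic[chrom]), ("intronic", intronic[chrom])):
            for sex, calls, pileup in (
                ("male", calls_male, pileup_male),
                ("female", calls_female, pileup_female),
            ):
                pos = calls.loc[
                    (calls["chrom"] == chrom) & (calls["kind"] == "snp"), "pos"
                ].to_numpy()
                pos = pos[pos < len(mask)]
                n = int(mask[pos].sum()) if len(pos) else 0
                if pileup is not None:
                    callable_bp = int(
                        (mask & (pileup.depth[s:e] >= params.min_depth)).sum()
                    )
                else:
                    callable_bp = int(mask.sum())
                row[f"{cls_name}_{sex}"] = 1000.0 * n / callable_bp if callable_bp else 0.0
            row[f"{cls_name}_ratio"] = format_ratio(
                row[f"{cls_name}_male"], row[f"{cls_name}_female"]
            )
        rows.append(row)
    return pd.DataFrame(rows)


def allele_ratio_spectrum(
    calls_male: pd.DataFrame,
    genome: Genome,
    pileup_male: Pileup | None = None,
    ratio_band: tuple[float, float] = (0.4, 0.6),
    params: CallerParams = CallerParams(),
) -> pd.DataFrame:
    """Fraction and per-kb density of male calls whose alt-read ratio sits in
    the 'around 1:1' band — the signature of fixed neo-X/neo-Y differences."""
    lo, hi = ratio_band
    rows = []
    for chrom in genome.names:
        sub = calls_male[
            (calls_male["chrom"] == chrom)
            & (calls_male["kind"] == "snp")
            & (calls_male["partition"].isin(["male_only", "shared"]))
        ]
        in_band = sub["alt_ratio_male"].between(lo, hi)
        n = len(sub)
        if pileup_male is not None:
            s, e = pileup_male.chrom_bounds[chrom]
            callable_bp = int((pileup_male.depth[s:e] >= params.min_depth).sum())
        else:
            callable_bp = genome.length(chrom)
        rows.append(
            {
                "chrom": chrom,
                "n_calls": n,
                "fraction_in_band": float(in_band.mean()) if n else 0.0,
                "density_in_band": 1000.0 * int(in_band.sum()) / callable_bp
                if callable_bp
                else 0.0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# VCF output
# ---------------------------------------------------------------------------


def write_vcf(calls: pd.DataFrame, genome: Genome, path, sample: str = "joint") -> None:
    """Minimal VCF 4.2 with per-sex counts and the partition in INFO."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=neosex\n")
        for n in genome.names:
            fh.write(f"##contig=<ID={n},length={genome.length(n)}>\n")
        fh.write('##INFO=<ID=PART,Number=1,Type=String,Description="Sex partition">\n')
        fh.write('##INFO=<ID=MC,Number=2,Type=Integer,Description="Male ref,alt counts">\n')
        fh.write('##INFO=<ID=FC,Number=2,Type=Integer,Description="Female ref,alt counts">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        order = {n: i for i, n in enumerate(genome.names)}
        calls = calls.sort_values(
            ["chrom", "pos"], key=lambda s: s.map(order) if s.name == "chrom" else s
        )
        for r in calls.itertuples():
            if r.kind == "snp":
                pos1, ref, alt = r.pos + 1, r.ref, r.alt
            else:
                # anchor base convention for indels
                anchor_pos = max(0, r.pos - 1)
                anchor = genome.fetch(r.chrom, anchor_pos, anchor_pos + 1)
                if r.kind == "ins":
                    pos1, ref, alt = anchor_pos + 1, anchor, anchor + r.alt
                else:
                    pos1, ref, alt = anchor_pos + 1, anchor + r.ref, anchor
            info = (
                f"PART={r.partition};MC={int(r.male_ref)},{int(r.male_alt)};"
                f"FC={int(r.female_ref)},{int(r.female_alt)}"
            )
            fh.write(f"{r.chrom}\t{pos1}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\n")
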