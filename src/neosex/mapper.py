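"""Minimal paired-end seed-and-extend read aligner.

Contract: each mate maps with at most ``max_mm`` mismatches (default 2);
in paired mode the reported placement is the best co-placement, but pair
orientation and span are *recorded, never used to reject* — anomalous
geometry is exactly the evidence the SV scanner consumes.  Reads that fail
ungapped placement are realigned single-end with one contiguous 1-6 bp gap
(left-aligned), feeding the short-indel caller.

Because orientation and span never veto a placement, the best co-placement
of a pair factorises into the independently best placement of each mate;
a mate with tied best placements makes the pair ambiguous and it is
excluded from all downstream evidence.  Seeds of length k=13 at three
disjoint read offsets guarantee (pigeonhole) an exact seed for any <=2
mismatch placement of reads >= 39 bp.

The whole path is vectorised with numpy over flat (concatenated-genome)
coordinates; SAM import/export goes through pysam.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from ._seq import Genome, decode, encode, kmer_codes_at, revcomp, sliding_kmer_codes
from .simdata import InsertSpec, ReadSet

DEFAULT_K = 13

PAIR_COLS = [
    "pair_id", "status", "chrom1", "pos1", "strand1", "mm1",
    "chrom2", "pos2", "strand2", "mm2", "span", "orientation", "unique",
]


@dataclass
class PairAlignment:
    """A mapped pair: 0-based leftmost positions, strands as '+'/'-'."""

    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str
    span: int  # outer distance when co-located, else -1
    mismatches: tuple[int, int]
    orientation_class: str  # FR | RF | FF | interlocus
    unique: bool = True
    indel: tuple | None = None


@dataclass
class GappedAlignment:
    """Single-end realignment with exactly one 1-6 bp gap."""

    chrom: str
    pos: int  # alignment start on the reference
    strand: str
    mismatches: int
    kind: str  # 'del' (read lacks reference bases) or 'ins' (read has extra)
    gap_pos: int  # reference position of the gap, left-aligned
    length: int
    seq: str  # deleted reference bases or inserted read bases


class SeedIndex:
    """Sorted-array k-mer index over the forward strand of a genome."""

    def __init__(self, genome: Genome, k: int = DEFAULT_K):
        if k < 11:
            raise ValueError("k must be >= 11")
        self.genome = genome
        self.k = k
        skipped = [n for n in genome.names if genome.length(n) < k]
        if skipped:
            import warnings

            warnings.warn(f"chromosomes shorter than k={k} skipped: {skipped}")
        concat = genome.concat
        codes, valid = sliding_kmer_codes(concat, k)
        pos = np.nonzero(valid)[0].astype(np.int64)
        vals = codes[pos]
        order = np.argsort(vals, kind="stable")
        self.sorted_codes = vals[order]
        self.sorted_pos = pos[order]

    @classmethod
    def build(cls, genome: Genome, k: int = DEFAULT_K) -> "SeedIndex":
        return cls(genome, k)

    def lookup(self, kmer: str) -> list[tuple[str, int, str]]:
        """All forward-strand occurrences of a length-k substring."""
        if len(kmer) != self.k:
            raise ValueError(f"kmer must have length {self.k}")
        q, valid = sliding_kmer_codes(encode(kmer), self.k)
        if not valid[0]:
            return []
        lo = np.searchsorted(self.sorted_codes, q[0], "left")
        hi = np.searchsorted(self.sorted_codes, q[0], "right")
        out = []
        for flat in np.sort(self.sorted_pos[lo:hi]):
            ci, p = self.genome.from_flat(np.array([flat]))
            out.append((self.genome.names[ci[0]], int(p[0]), "+"))
        return out

    def _ranges(self, queries: np.ndarray):
        lo = np.searchsorted(self.sorted_codes, queries, "left")
        hi = np.searchsorted(self.sorted_codes, queries, "right")
        return lo, hi


def index_reference(genome: Genome, k: int = DEFAULT_K) -> SeedIndex:
    return SeedIndex(genome, k)


def _expand_ranges(lo: np.ndarray, hi: np.ndarray):
    """Flatten [lo, hi) ranges; returns (owner row index, flat index)."""
    counts = hi - lo
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    owner = np.repeat(np.arange(len(lo)), counts)
    idx = np.repeat(hi - np.cumsum(counts), counts) + np.arange(total)
    return owner, idx


def _candidates(reads: np.ndarray, index: SeedIndex):
    """Unique candidate flat start positions per read (one orientation)."""
    n, L = reads.shape
    k = index.k
    if L < 3 * k:
        offs = list(range(0, L - k + 1, k))[:3] or [0]
    else:
        offs = [0, (L - k) // 2, L - k]
    q = kmer_codes_at(reads, offs, k)  # (n, n_off)
    owners, poss = [], []
    for j, off in enumerate(offs):
        lo, hi = index._ranges(q[:, j])
        owner, idx = _expand_ranges(lo, hi)
        owners.append(owner)
        poss.append(index.sorted_pos[idx] - off)
    owner = np.concatenate(owners)
    pos = np.concatenate(poss)
    ok = (pos >= 0) & (pos + L <= len(index.genome.concat))
    owner, pos = owner[ok], pos[ok]
    key = owner * np.int64(1 << 40) + pos
    key = np.unique(key)
    return key >> 40, key & np.int64((1 << 40) - 1)


def _count_mismatches(reads, owner, pos, concat, chunk=400_000):
    L = reads.shape[1]
    mm = np.empty(len(owner), dtype=np.int32)
    cols = np.arange(L)
    for s in range(0, len(owner), chunk):
        e = min(s + chunk, len(owner))
        seg = concat[pos[s:e, None] + cols]
        mm[s:e] = (seg != reads[owner[s:e]]).sum(axis=1)
    return mm


def _best_per_read(n_reads, owner, pos, strand, mm, max_mm):
    """Best placement per read over pooled candidates.

    Returns arrays (mapped, best_pos, best_strand, best_mm, tied).
    """
    keep = mm <= max_mm
    owner, pos, strand, mm = owner[keep], pos[keep], strand[keep], mm[keep]
    best_pos = np.full(n_reads, -1, dtype=np.int64)
    best_strand = np.zeros(n_reads, dtype=np.int8)
    best_mm = np.full(n_reads, 127, dtype=np.int32)
    tied = np.zeros(n_reads, dtype=bool)
    if len(owner) == 0:
        return best_pos, best_strand, best_mm, tied
    order = np.lexsort((strand, pos, mm, owner))
    owner, pos, strand, mm = owner[order], pos[order], strand[order], mm[order]
    first = np.ones(len(owner), dtype=bool)
    first[1:] = owner[1:] != owner[:-1]
    fi = np.nonzero(first)[0]
    rows = owner[fi]
    best_pos[rows] = pos[fi]
    best_strand[rows] = strand[fi]
    best_mm[rows] = mm[fi]
    # tie: the next candidate of the same read has the same mismatch count
    nxt = fi + 1
    has_next = nxt < len(owner)
    same = np.zeros(len(fi), dtype=bool)
    same[has_next] = (owner[nxt[has_next]] == rows[has_next]) & (
        mm[nxt[has_next]] == mm[fi[has_next]]
    )
    tied[rows[same]] = True
    return best_pos, best_strand, best_mm, tied


def align_single_reads(reads: np.ndarray, index: SeedIndex, max_mm: int = 2):
    """Ungapped best placement of each read on either strand.

    Returns (flat_pos, strand(0 fwd/1 rev), mm, tied); flat_pos == -1 when
    unmapped.
    """
    n = len(reads)
    rc = np.ascontiguousarray(np.flip(reads, axis=1))
    rc = np.array([3, 2, 1, 0, 4], dtype=np.uint8)[rc]
    owners, poss, strands, mms = [], [], [], []
    for s, arr in ((0, reads), (1, rc)):
        owner, pos = _candidates(arr, index)
        mm = _count_mismatches(arr, owner, pos, index.genome.concat)
        owners.append(owner)
        poss.append(pos)
        strands.append(np.full(len(owner), s, dtype=np.int8))
        mms.append(mm)
    return _best_per_read(
        n,
        np.concatenate(owners),
        np.concatenate(poss),
        np.concatenate(strands),
        np.concatenate(mms),
        max_mm,
    )


def align_pairs(rs: ReadSet, index: SeedIndex, ins: InsertSpec, max_mm: int = 2) -> pd.DataFrame:
    """Align every pair; returns one row per pair (see PAIR_COLS).

    status: 'mapped' | 'ambiguous' | 'unmapped'.  Orientation classes:
    FR (proper), RF (tandem-duplication signature), FF (same strand),
    interlocus (mates on different chromosomes).
    """
    L = rs.read_len
    g = index.genome
    p1, s1, m1, t1 = align_single_reads(rs.r1, index, max_mm)
    p2, s2, m2, t2 = align_single_reads(rs.r2, index, max_mm)
    n = rs.n_pairs
    mapped = (p1 >= 0) & (p2 >= 0)
    amb = mapped & (t1 | t2)
    ok = mapped & ~amb
    ci1, cp1 = g.from_flat(np.where(p1 >= 0, p1, 0))
    ci2, cp2 = g.from_flat(np.where(p2 >= 0, p2, 0))
    left_is_1 = p1 <= p2
    lstrand = np.where(left_is_1, s1, s2)
    rstrand = np.where(left_is_1, s2, s1)
    same_chrom = ci1 == ci2
    orientation = np.full(n, "unmapped", dtype=object)
    orientation[ok & ~same_chrom] = "interlocus"
    sc = ok & same_chrom
    orientation[sc & (lstrand == 0) & (rstrand == 1)] = "FR"
    orientation[sc & (lstrand == 1) & (rstrand == 0)] = "RF"
    orientation[sc & (lstrand == rstrand)] = "FF"
    span = np.where(sc, np.maximum(p1, p2) + L - np.minimum(p1, p2), -1)
    status = np.full(n, "unmapped", dtype=object)
    status[ok] = "mapped"
    status[amb] = "ambiguous"
    names = np.asarray(g.names, dtype=object)
    df = pd.DataFrame(
        {
            "pair_id": np.arange(n),
            "status": status,
            "chrom1": np.where(p1 >= 0, names[ci1], ""),
            "pos1": np.where(p1 >= 0, cp1, -1),
            "strand1": np.where(s1 == 0, "+", "-"),
            "mm1": np.where(p1 >= 0, m1, -1),
            "chrom2": np.where(p2 >= 0, names[ci2], ""),
            "pos2": np.where(p2 >= 0, cp2, -1),
            "strand2": np.where(s2 == 0, "+", "-"),
            "mm2": np.where(p2 >= 0, m2, -1),
            "span": span,
            "orientation": orientation,
            "unique": ok,
        }
    )
    df.attrs["read_len"] = L
    df.attrs["insert"] = (ins.mean, ins.sd, ins.read_len)
    return df


def align_pair(
    seq1: str, seq2: str, index: SeedIndex, ins: InsertSpec, max_mm: int = 2
) -> PairAlignment | None:
    """Single-pair convenience wrapper; None when unmapped/ambiguous."""
    rs = ReadSet(
        encode(seq1)[None, :], encode(seq2)[None, :],
        np.array([-1]), np.array([-1]), [], np.array([-1]), np.array([-1]), [],
    )
    df = align_pairs(rs, index, ins, max_mm)
    r = df.iloc[0]
    if r["status"] != "mapped":
        return None
    return PairAlignment(
        r["chrom1"], int(r["pos1"]), r["strand1"],
        r["chrom2"], int(r["pos2"]), r["strand2"],
        int(r["span"]), (int(r["mm1"]), int(r["mm2"])),
        r["orientation"], bool(r["unique"]),
    )


# ---------------------------------------------------------------------------
# gapped single-end realignment
# ---------------------------------------------------------------------------


def _left_align_gap(concat, p, j, d, kind, read):
    """Shift a gap at read offset j left while the flanking base repeats."""
    if kind == "del":
        # deleted reference bases are concat[p+j : p+j+d]
        while j > 0 and concat[p + j - 1] == concat[p + j + d - 1] and read[j - 1] == concat[p + j - 1]:
            j -= 1
    else:
        while j > 0 and read[j - 1] == read[j + d - 1] and read[j - 1] == concat[p + j - 1]:
            j -= 1
    return j


def _eval_gapped(read, concat, p, max_mm, max_indel):
    """Best single-gap alignment of ``read`` starting at flat position p.

    Returns (mm, j, d, kind) or None.  'del': read lacks d reference bases
    (CIGAR D); 'ins': read carries d extra bases (CIGAR I).
    """
    L = len(read)
    if p < 0 or p + L + max_indel > len(concat):
        return None
    best = None
    base_ref = concat[p : p + L + max_indel]
    neq0 = read != base_ref[:L]
    pre = np.concatenate([[0], np.cumsum(neq0)])
    for d in range(1, max_indel + 1):
        # deletion: read[j:] matches ref shifted right by d
        neq_d = read != base_ref[d : d + L]
        suf = np.concatenate([np.cumsum(neq_d[::-1])[::-1], [0]])
        tot = pre[1:L] + suf[1:L]  # gap strictly inside the read
        jj = int(np.argmin(tot))
        if tot[jj] <= max_mm:
            cand = (int(tot[jj]), jj + 1, d, "del")
            if best is None or cand[0] < best[0]:
                best = cand
        # insertion: read[j+d:] matches ref continuing at j
        m = L - d
        neq_i = read[d:] != base_ref[:m]
        sufi = np.concatenate([np.cumsum(neq_i[::-1])[::-1], [0]])
        tot = pre[1 : m + 1] + sufi[1 : m + 1]
        if len(tot):
            jj = int(np.argmin(tot))
            if tot[jj] <= max_mm:
                cand = (int(tot[jj]), jj + 1, d, "ins")
                if best is None or cand[0] < best[0]:
                    best = cand
    return best


def realign_single(
    read, index: SeedIndex, max_mm: int = 2, max_indel: int = 6
) -> GappedAlignment | None:
    """Realign one previously unmapped read allowing one 1-6 bp gap.

    Seeds anchor the read by its first and last k-mer on both strands; every
    implied start position is scored exhaustively over gap length and
    placement, and the winning gap is left-aligned.
    """
    if isinstance(read, str):
        read = encode(read)
    g = index.genome
    concat = g.concat
    k = index.k
    L = len(read)
    rc = revcomp(read)
    best = None
    for strand, r in ((0, read), (1, rc)):
        q = kmer_codes_at(r[None, :], [0, L - k], k)
        starts = set()
        for j, off in enumerate((0, L - k)):
            lo, hi = index._ranges(q[:, j : j + 1].ravel())
            for flat in index.sorted_pos[lo[0] : hi[0]]:
                if off == 0:
                    starts.add(int(flat))
                else:
                    # right-anchored: try all gap lengths for both gap kinds
                    for d in range(1, max_indel + 1):
                        starts.add(int(flat) + k - L - d)  # del
                        starts.add(int(flat) + k - L + d)  # ins
                    starts.add(int(flat) + k - L)
        for p in sorted(starts):
            res = _eval_gapped(r, concat, p, max_mm, max_indel)
            if res is None:
                continue
            mm, j, d, kind = res
            cand = (mm, p, j, d, kind, strand)
            if best is None or cand[:2] < best[:2]:
                best = cand
    if best is None:
        return None
    mm, p, j, d, kind, strand = best
    r = read if strand == 0 else rc
    j = _left_align_gap(concat, p, j, d, kind, r)
    ci, cp = g.from_flat(np.array([p]))
    chrom = g.names[int(ci[0])]
    if kind == "del":
        seq = decode(concat[p + j : p + j + d])
    else:
        seq = decode(r[j : j + d])
    return GappedAlignment(
        chrom, int(cp[0]), "+" if strand == 0 else "-", mm, kind,
        int(cp[0]) + j, d, seq,
    )


def realign_unmapped(
    rs: ReadSet, pairs: pd.DataFrame, index: SeedIndex, max_mm: int = 2, max_indel: int = 6
) -> pd.DataFrame:
    """Gapped realignment of every mate that failed ungapped pairing."""
    rows = []
    for mate, reads, pcol in ((1, rs.r1, "pos1"), (2, rs.r2, "pos2")):
        unmapped = pairs.index[(pairs["status"] == "unmapped") & (pairs[pcol] < 0)]
        for i in unmapped:
            ga = realign_single(reads[i], index, max_mm, max_indel)
            if ga is None:
                continue
            rows.append(
                {
                    "pair_id": int(pairs.at[i, "pair_id"]), "mate": mate,
                    "chrom": ga.chrom, "pos": ga.pos, "strand": ga.strand,
                    "mm": ga.mismatches, "kind": ga.kind, "gap_pos": ga.gap_pos,
                    "length": ga.length, "seq": ga.seq,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["pair_id", "mate", "chrom", "pos", "strand", "mm", "kind",
                 "gap_pos", "length", "seq"],
    )


# ---------------------------------------------------------------------------
# SAM I/O
# ---------------------------------------------------------------------------


def write_sam(path, rs: ReadSet, pairs: pd.DataFrame, gapped: pd.DataFrame, genome: Genome):
    """Emit a coordinate-unsorted SAM with @SQ lines via pysam."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": genome.length(n)} for n in genome.names],
    }
    L = rs.read_len
    gap_by_pair: dict[tuple[int, int], tuple] = {}
    for r in gapped.itertuples():
        gap_by_pair[(r.pair_id, r.mate)] = r
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        tid = {n: i for i, n in enumerate(genome.names)}
        for row in pairs.itertuples():
            for mate, reads, chrom, pos, strand, mm in (
                (1, rs.r1, row.chrom1, row.pos1, row.strand1, row.mm1),
                (2, rs.r2, row.chrom2, row.pos2, row.strand2, row.mm2),
            ):
                a = pysam.AlignedSegment()
                a.query_name = f"p{row.pair_id:07d}"
                seq = reads[row.pair_id]
                rev = strand == "-"
                flag = 0x1 | (0x40 if mate == 1 else 0x80)
                g = gap_by_pair.get((row.pair_id, mate))
                if row.status == "mapped":
                    if rev:
                        flag |= 0x10
                        seq = revcomp(seq)
                    a.reference_id = tid[chrom]
                    a.reference_start = int(pos)
                    a.cigarstring = f"{L}M"
                    a.set_tag("NM", int(mm))
                elif g is not None:
                    if g.strand == "-":
                        flag |= 0x10
                        seq = revcomp(seq)
                    a.reference_id = tid[g.chrom]
                    a.reference_start = int(g.pos)
                    j = g.gap_pos - g.pos
                    op = "D" if g.kind == "del" else "I"
                    rest = L - j - (g.length if g.kind == "ins" else 0)
                    a.cigarstring = f"{j}M{g.length}{op}{rest}M"
                    a.set_tag("NM", int(g.mm + g.length))
                else:
                    flag |= 0x4
                a.flag = flag
                a.query_sequence = decode(seq)
                a.query_qualities = pysam.qualitystring_to_array("?" * L)
                out.write(a)


def read_sam(path, genome: Genome):
    """Parse an external SAM into the pair table + gapped table.

    Accepts any name-grouped SAM whose reference names match the genome.
    """
    pairs: dict[str, dict] = {}
    gap_rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for sn in fh.references:
            if sn not in genome:
                raise ValueError(f"SAM reference {sn!r} absent from genome")
        reads1, reads2 = {}, {}
        for a in fh:
            mate = 1 if a.is_read1 or not a.is_paired else 2
            store = reads1 if mate == 1 else reads2
            name = a.query_name
            seq = a.query_sequence or ""
            codes = encode(seq)
            if a.is_reverse:
                codes = revcomp(codes)
            store.setdefault(name, codes)
            rec = pairs.setdefault(
                name,
                {"status": "unmapped", "chrom1": "", "pos1": -1, "strand1": "+",
                 "mm1": -1, "chrom2": "", "pos2": -1, "strand2": "+", "mm2": -1},
            )
            if a.is_unmapped:
                continue
            cig = a.cigartuples or []
            gaps = [(i, op, ln) for i, (op, ln) in enumerate(cig) if op in (1, 2)]
            sfx = str(mate)
            rec[f"chrom{sfx}"] = a.reference_name
            rec[f"pos{sfx}"] = a.reference_start
            rec[f"strand{sfx}"] = "-" if a.is_reverse else "+"
            rec[f"mm{sfx}"] = int(a.get_tag("NM")) if a.has_tag("NM") else 0
            if gaps:
                qoff = cig[0][1]
                op = "ins" if gaps[0][1] == 1 else "del"
                ln = gaps[0][2]
                gseq = (seq[qoff : qoff + ln] if op == "ins" else "")
                gap_rows.append(
                    {"pair_id": name, "mate": mate, "chrom": a.reference_name,
                     "pos": a.reference_start, "strand": "-" if a.is_reverse else "+",
                     "mm": max(0, rec[f"mm{sfx}"] - ln),
                     "kind": op, "gap_pos": a.reference_start + qoff,
                     "length": ln, "seq": gseq}
                )
    names = sorted(pairs)
    rows = []
    r1_list, r2_list = [], []
    L = max((len(v) for v in list(reads1.values()) + list(reads2.values())), default=0)
    for i, name in enumerate(names):
        rec = pairs[name]
        mapped = rec["pos1"] >= 0 and rec["pos2"] >= 0
        span = -1
        orientation = "unmapped"
        if mapped and rec["chrom1"] == rec["chrom2"]:
            lo = min(rec["pos1"], rec["pos2"])
            hi = max(rec["pos1"], rec["pos2"])
            span = hi + L - lo
            ls = rec["strand1"] if rec["pos1"] <= rec["pos2"] else rec["strand2"]
            rs_ = rec["strand2"] if rec["pos1"] <= rec["pos2"] else rec["strand1"]
            orientation = {("+", "-"): "FR", ("-", "+"): "RF"}.get((ls, rs_), "FF")
        elif mapped:
            orientation = "interlocus"
        rows.append(
            {"pair_id": i, "status": "mapped" if mapped else "unmapped",
             **{k: rec[k] for k in ("chrom1", "pos1", "strand1", "mm1",
                                     "chrom2", "pos2", "strand2", "mm2")},
             "span": span, "orientation": orientation, "unique": mapped}
        )
        for store, lst in ((reads1, r1_list), (reads2, r2_list)):
            codes = store.get(name, np.full(L, 4, dtype=np.uint8))
            if len(codes) < L:
                codes = np.concatenate([codes, np.full(L - len(codes), 4, np.uint8)])
            lst.append(codes)
    name_to_idx = {name: i for i, name in enumerate(names)}
    for g in gap_rows:
        g["pair_id"] = name_to_idx[g["pair_id"]]
    df = pd.DataFrame(rows, columns=PAIR_COLS)
    df.attrs["read_len"] = L
    rs_out = ReadSet(
        np.stack(r1_list) if r1_list else np.empty((0, L), np.uint8),
        np.stack(r2_list) if r2_list else np.empty((0, L), np.uint8),
        np.full(len(names), -1), np.full(len(names), -1), [],
        np.full(len(names), -1), np.full(len(names), -1), [],
    )
    return df, pd.DataFrame(gap_rows, columns=[
        "pair_id", "mate", "chrom", "pos", "strand", "mm", "kind", "gap_pos", "length", "seq"
    ]), rs_out
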