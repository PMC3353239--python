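"""B-chromosome candidate detection by male-vs-female assembly subtraction.

A male scaffold is a candidate B (or otherwise male-limited) sequence when
less than 20% of its length is alignable to the female assembly.  Alignable
coverage is measured by shared-k-mer chaining: every position covered by a
k-mer present in the female assembly counts as aligned.  Candidates whose
annotated proteins match any known published sequence are removed, a
B-derived probe ranks the survivors by local alignment score, and per-sex
fractions of reads aligning to (sub)centromeric sequence provide the
read-level corroboration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align

from ._seq import Genome, decode, encode, sliding_kmer_codes
from .mapper import SeedIndex, align_single_reads


@dataclass
class BCandidate:
    scaffold_id: str
    length: int
    aligned_fraction: float
    known_homology: bool = False
    probe_score: float | None = None

    @property
    def is_candidate(self) -> bool:
        return not self.known_homology


def _kmer_set(seqs: dict[str, np.ndarray], k: int) -> np.ndarray:
    vals = []
    for codes in seqs.values():
        v, ok = sliding_kmer_codes(codes, k)
        vals.append(v[ok])
    if not vals:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(vals))


def subtract_assemblies(
    male: dict[str, np.ndarray],
    female: dict[str, np.ndarray],
    cov_threshold: float = 0.20,
    k: int = 21,
) -> pd.DataFrame:
    """Alignable fraction of every male scaffold against the female
    assembly; candidates have aligned_fraction < cov_threshold.

    Coverage: the union of [i, i+k) for every male position i whose k-mer
    occurs anywhere in the female assembly (either strand).  k=21 keeps the
    chance of a spurious shared k-mer on megabase assemblies negligible
    while 1% diverged homologous sequence still covers.
    """
    if not male or not female:
        raise ValueError("both assemblies must be non-empty")
    fset = _kmer_set(female, k)
    # include reverse-complement k-mers of the female assembly
    rc = {n + "_rc": np.array([3, 2, 1, 0, 4], dtype=np.uint8)[codes[::-1]]
          for n, codes in female.items()}
    fset = np.union1d(fset, _kmer_set(rc, k))
    rows = []
    for name in sorted(male):
        codes = male[name]
        L = len(codes)
        vals, ok = sliding_kmer_codes(codes, k)
        covered = np.zeros(L + k, dtype=bool)
        if len(vals) and len(fset):
            pos = np.nonzero(ok)[0]
            q = vals[ok]
            j = np.searchsorted(fset, q)  # fset is sorted (np.unique)
            member = (j < len(fset)) & (fset[np.minimum(j, len(fset) - 1)] == q)
            hit = pos[member]
            # cover [i, i+k) for each hit via difference array
            diff = np.zeros(L + k + 1, dtype=np.int32)
            np.add.at(diff, hit, 1)
            np.add.at(diff, hit + k, -1)
            covered[: L + k] = np.cumsum(diff[:-1]) > 0
        frac = float(covered[:L].mean()) if L else 0.0
        rows.append(
            {"scaffold": name, "length": L, "aligned_fraction": frac,
             "candidate": frac < cov_threshold}
        )
    return pd.DataFrame(rows, columns=["scaffold", "length", "aligned_fraction", "candidate"])


def filter_known(
    candidates: pd.DataFrame,
    annotations: dict[str, list[str]] | None = None,
    known_hits: set[str] | None = None,
) -> pd.DataFrame:
    """Drop candidates carrying an annotated protein with homology to the
    known set.  ``annotations``: scaffold -> protein ids;
    ``known_hits``: protein ids matching published sequences."""
    annotations = annotations or {}
    known_hits = known_hits or set()
    out = candidates.copy()
    flags = [
        any(p in known_hits for p in annotations.get(s, []))
        for s in out["scaffold"]
    ]
    out["known_homology"] = flags
    return out[out["candidate"] & ~out["known_homology"]].reset_index(drop=True)


def probe_bait(
    probe: str,
    scaffolds: dict[str, np.ndarray],
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
    k: int = 13,
) -> pd.DataFrame:
    """Rank scaffolds by best local alignment score against a probe.

    Scaffolds sharing no k-mer with the probe (either strand) are skipped
    entirely, so an unrelated probe yields an empty ranking.  Ties are
    broken by scaffold id.
    """
    if len(probe) < 50:
        raise ValueError("probe must be >= 50 bp")
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    pcodes = encode(probe)
    prc = np.array([3, 2, 1, 0, 4], dtype=np.uint8)[pcodes[::-1]]
    pk = np.unique(np.concatenate([
        sliding_kmer_codes(pcodes, k)[0], sliding_kmer_codes(prc, k)[0]
    ]))
    rows = []
    for name in sorted(scaffolds):
        codes = scaffolds[name]
        vals, ok = sliding_kmer_codes(codes, k)
        if not np.isin(vals[ok], pk).any():
            continue
        seq = decode(codes)
        score = max(aligner.score(seq, probe), aligner.score(seq, decode(prc)))
        rows.append({"scaffold": name, "probe_score": float(score)})
    df = pd.DataFrame(rows, columns=["scaffold", "probe_score"])
    return df.sort_values(
        ["probe_score", "scaffold"], ascending=[False, True]
    ).reset_index(drop=True)


def centromeric_read_fraction(
    reads: np.ndarray, centromeric: dict[str, np.ndarray], max_mm: int = 2
) -> float:
    """Fraction of reads aligning (<= max_mm mismatches) to any sequence of
    the centromeric set."""
    if not centromeric:
        raise ValueError("centromeric sequence set must be non-empty")
    genome = Genome({n: c for n, c in centromeric.items()})
    idx = SeedIndex(genome)
    pos, _strand, _mm, _tied = align_single_reads(reads, idx, max_mm)
    if len(reads) == 0:
        return 0.0
    return float((pos >= 0).mean())
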