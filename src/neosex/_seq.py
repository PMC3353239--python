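"""Low-level sequence machinery shared by every stage.

Sequences are held as numpy ``uint8`` code arrays (A=0, C=1, G=2, T=3, N=4),
which keeps the mapper, pileup and simulator fully vectorisable.  The
:class:`Genome` container also maintains a single concatenated code array
(chromosomes separated by runs of N) so that alignment coordinates can be
handled as flat int64 offsets and converted back at the edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam

A, C, G, T, N = 0, 1, 2, 3, 4

_ENCODE = np.full(256, N, dtype=np.uint8)
for _i, _ch in enumerate(b"ACGT"):
    _ENCODE[_ch] = _i
    _ENCODE[_ch + 32] = _i  # lower case

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)
_RC = np.array([T, G, C, A, N], dtype=np.uint8)

#: spacer length between chromosomes in the concatenated array; longer than
#: any read so a candidate placement can never bridge two chromosomes.
PAD = 256


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _ENCODE[np.frombuffer(seq, dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode uint8 codes back to an upper-case string."""
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp(codes: np.ndarray) -> np.ndarray:
    """Reverse-complement a code array (N maps to N)."""
    return _RC[codes[::-1]]


def revcomp_str(seq: str) -> str:
    return decode(revcomp(encode(seq)))


@dataclass
class Genome:
    """Ordered collection of chromosome/scaffold code arrays.

    ``names`` fixes iteration order; all downstream coordinate frames are
    0-based half-open on these sequences.
    """

    seqs: dict[str, np.ndarray]
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.names:
            self.names = list(self.seqs)
        self._concat: np.ndarray | None = None
        self._offsets: np.ndarray | None = None

    # -- basic accessors ---------------------------------------------------
    def __contains__(self, name: str) -> bool:
        return name in self.seqs

    def __len__(self) -> int:
        return len(self.names)

    def length(self, name: str) -> int:
        return len(self.seqs[name])

    @property
    def lengths(self) -> dict[str, int]:
        return {n: len(self.seqs[n]) for n in self.names}

    @property
    def total_length(self) -> int:
        return sum(len(self.seqs[n]) for n in self.names)

    def fetch(self, name: str, start: int = 0, end: int | None = None) -> str:
        return decode(self.seqs[name][start:end])

    # -- flat coordinate frame --------------------------------------------
    def _build_concat(self) -> None:
        parts: list[np.ndarray] = []
        offsets = []
        pad = np.full(PAD, N, dtype=np.uint8)
        pos = PAD
        parts.append(pad)
        for n in self.names:
            offsets.append(pos)
            parts.append(self.seqs[n])
            parts.append(pad)
            pos += len(self.seqs[n]) + PAD
        self._concat = np.concatenate(parts)
        self._offsets = np.asarray(offsets, dtype=np.int64)

    @property
    def concat(self) -> np.ndarray:
        if self._concat is None:
            self._build_concat()
        return self._concat

    @property
    def offsets(self) -> np.ndarray:
        """Flat start offset of each chromosome, in ``names`` order."""
        if self._offsets is None:
            self._build_concat()
        return self._offsets

    def to_flat(self, name: str, pos) -> np.ndarray | int:
        return self.offsets[self.names.index(name)] + pos

    def from_flat(self, flat: np.ndarray):
        """Map flat positions to (chrom_index, position) arrays."""
        flat = np.asarray(flat, dtype=np.int64)
        idx = np.searchsorted(self.offsets, flat, side="right") - 1
        idx = np.clip(idx, 0, len(self.names) - 1)
        return idx, flat - self.offsets[idx]

    # -- FASTA I/O ---------------------------------------------------------
    @classmethod
    def from_fasta(cls, path) -> "Genome":
        seqs: dict[str, np.ndarray] = {}
        names: list[str] = []
        with pysam.FastxFile(str(path)) as fh:
            for rec in fh:
                names.append(rec.name)
                seqs[rec.name] = encode(rec.sequence)
        return cls(seqs, names)

    def to_fasta(self, path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for n in self.names:
                fh.write(f">{n}\n")
                s = decode(self.seqs[n])
                for i in range(0, len(s), width):
                    fh.write(s[i : i + width] + "\n")


def write_fasta(path, seqs: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, s in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def sliding_kmer_codes(codes: np.ndarray, k: int):
    """Return (kmer integer codes, validity mask) for every window start.

    A window is valid when it contains no N.  Uses the base-4 polynomial
    code so k is limited to 31 (int64); the mapper uses k=13.
    """
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    pow4 = (4 ** np.arange(k, dtype=np.int64))[::-1]
    valid = (win < 4).all(axis=1)
    vals = win.astype(np.int64) @ pow4
    return vals, valid


def kmer_codes_at(reads: np.ndarray, offsets, k: int) -> np.ndarray:
    """Kmer codes of 2-D read array at given column offsets -> (n_reads, n_off)."""
    pow4 = (4 ** np.arange(k, dtype=np.int64))[::-1]
    cols = [reads[:, o : o + k].astype(np.int64) @ pow4 for o in offsets]
    return np.stack(cols, axis=1)
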