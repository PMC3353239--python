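"""Synteny-guided super-scaffolding and chromosome assignment.

Draft scaffolds are merged in two passes driven by protein alignments to a
reference species with conserved gene order:

1. order-along-the-gene: scaffolds hitting successive parts of one protein
   are concatenated in protein order (orientations harmonised);
2. conserved-adjacency: scaffolds anchored (>=50% query span) to proteins
   that are adjacent, in conserved order and orientation, across the
   reference panel are joined with a 500-N spacer.

Any ambiguity (a scaffold demanded at incompatible positions, anchors to
non-adjacent map slots) conservatively leaves scaffolds unmerged, with a
logged reason.  Hits are tabular alignments produced by any aligner; this
module does not align.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import N, revcomp

SPACER_N = 500

HIT_COLS = [
    "scaffold", "protein", "score", "identity",
    "s_start", "s_end", "p_start", "p_end", "orientation",
]


@dataclass
class AssemblyStats:
    total_length: int
    scaffold_count: int
    n50: int

    def to_dict(self):
        return {
            "total_length": self.total_length,
            "scaffold_count": self.scaffold_count,
            "n50": self.n50,
        }


def n50(lengths) -> AssemblyStats:
    """N50 = largest length L such that scaffolds >= L hold half the total."""
    lengths = np.asarray(sorted(lengths, reverse=True), dtype=np.int64)
    if len(lengths) == 0 or (lengths <= 0).any():
        raise ValueError("lengths must be non-empty and positive")
    total = int(lengths.sum())
    csum = np.cumsum(lengths)
    i = int(np.searchsorted(csum, total / 2, side="left"))
    return AssemblyStats(total, len(lengths), int(lengths[i]))


def resolve_overlapping_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Keep, per protein, only the top-scoring scaffold among scaffolds whose
    hit intervals on the protein overlap; non-overlapping hits all survive.

    Greedy by score (ties broken by scaffold id): a hit survives iff it
    overlaps no higher-priority *surviving* hit, so a region freed by a
    dropped hit can still be represented by a lower-scoring one.
    """
    keep_idx = []
    for _, grp in hits.groupby("protein", sort=True):
        grp = grp.sort_values(["score", "scaffold"], ascending=[False, True])
        kept: list = []
        for h in grp.itertuples():
            overlapped = any(
                g.p_start < h.p_end and h.p_start < g.p_end for g in kept
            )
            if not overlapped:
                kept.append(h)
                keep_idx.append(h.Index)
    return hits.loc[sorted(keep_idx)]


def merge_by_gene(
    hits: pd.DataFrame, scaffolds: dict[str, np.ndarray]
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Concatenate scaffolds hitting successive parts of one protein.

    Returns the updated scaffold dict (merged pieces removed, merged
    product added as ``merge_<protein>``) and a log table.  A scaffold
    claimed by more than one merge group is left unmerged (conflict logged);
    reverse-orientation hits contribute the reverse complement.
    """
    log_rows = []
    out = dict(scaffolds)
    claimed: dict[str, str] = {}
    groups = []
    for protein, grp in hits.groupby("protein", sort=True):
        grp = grp.sort_values("p_start")
        scf = grp["scaffold"].tolist()
        if len(set(scf)) < 2:
            continue
        groups.append((protein, grp))
    # first pass: detect conflicts
    for protein, grp in groups:
        for s in dict.fromkeys(grp["scaffold"]):
            if s in claimed:
                claimed[s] = "CONFLICT"
            else:
                claimed[s] = protein
    for protein, grp in groups:
        scf_order = list(dict.fromkeys(grp["scaffold"]))
        if any(claimed[s] == "CONFLICT" for s in scf_order):
            log_rows.append(
                {"protein": protein, "action": "skipped",
                 "reason": "scaffold required by multiple merge groups",
                 "scaffolds": ",".join(scf_order)}
            )
            continue
        if any(s not in out for s in scf_order):
            log_rows.append(
                {"protein": protein, "action": "skipped",
                 "reason": "scaffold already consumed", "scaffolds": ",".join(scf_order)}
            )
            continue
        orient = {r.scaffold: r.orientation for r in grp.itertuples()}
        parts = []
        for s in scf_order:
            seq = out.pop(s)
            parts.append(seq if orient[s] == "+" else revcomp(seq))
        out[f"merge_{protein}"] = np.concatenate(parts)
        log_rows.append(
            {"protein": protein, "action": "merged", "reason": "",
             "scaffolds": ",".join(scf_order)}
        )
    return out, pd.DataFrame(log_rows, columns=["protein", "action", "reason", "scaffolds"])


def remap_hits_after_merge(hits: pd.DataFrame, merge_log: pd.DataFrame) -> pd.DataFrame:
    """Re-address hits of merged-away scaffolds to the merge product.

    A component emitted reverse-complemented (its driving hit was '-')
    flips the orientation of all its hits in the product frame.  Scaffold-
    local coordinates are not updated (downstream anchoring only uses the
    protein interval and orientation).
    """
    name_map: dict[str, str] = {}
    flip: dict[str, bool] = {}
    merged = merge_log[merge_log["action"] == "merged"]
    for r in merged.itertuples():
        comps = r.scaffolds.split(",")
        for s in comps:
            name_map[s] = f"merge_{r.protein}"
    drivers: dict[tuple[str, str], str] = {}
    for r in hits.itertuples():
        drivers.setdefault((r.protein, r.scaffold), r.orientation)
    for r in merged.itertuples():
        for s in r.scaffolds.split(","):
            flip[s] = drivers.get((r.protein, s), "+") == "-"
    h = hits.copy()
    flipped = h["scaffold"].map(lambda s: flip.get(s, False))
    h.loc[flipped, "orientation"] = h.loc[flipped, "orientation"].map(
        {"+": "-", "-": "+"}
    )
    h["scaffold"] = h["scaffold"].map(lambda s: name_map.get(s, s))
    return h


@dataclass
class SyntenyMap:
    """Reference gene order and the conserved-adjacency relation."""

    order: dict[str, list[str]]  # chromosome -> ordered protein ids
    adjacency: set[tuple[str, str]]  # unordered conserved neighbour pairs

    @classmethod
    def from_adjacency_table(cls, adj: pd.DataFrame) -> "SyntenyMap":
        order: dict[str, list[str]] = {}
        pairs = set()
        for chrom, grp in adj.groupby("chrom", sort=True):
            ids: list[str] = []
            for r in grp.itertuples():
                if not ids:
                    ids.append(r.protein_a)
                ids.append(r.protein_b)
                pairs.add((r.protein_a, r.protein_b))
                pairs.add((r.protein_b, r.protein_a))
            order[chrom] = ids
        return cls(order, pairs)


def _anchors(
    hits: pd.DataFrame, protein_lengths: dict[str, int], min_span_fraction: float = 0.5
) -> pd.DataFrame:
    """Qualifying anchors: hits spanning over half of the query protein."""
    span = hits["p_end"] - hits["p_start"]
    plen = hits["protein"].map(protein_lengths)
    return hits[span > min_span_fraction * plen]


def merge_by_synteny(
    scaffolds: dict[str, np.ndarray],
    hits: pd.DataFrame,
    smap: SyntenyMap,
    protein_lengths: dict[str, int],
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Join scaffolds anchored to conserved-adjacent proteins with 500 Ns.

    Scaffolds are placed at their anchor protein's slot in the reference
    order; runs of consecutively anchored slots whose successive protein
    pairs are conserved-adjacent become one super-scaffold.  A scaffold
    anchored to non-adjacent slots, or a slot claimed by two scaffolds, is
    excluded (logged).
    """
    anchors = _anchors(hits[hits["scaffold"].isin(scaffolds)], protein_lengths)
    log_rows = []
    # protein -> (scaffold, orientation); ambiguous slots dropped
    slot: dict[str, tuple[str, str]] = {}
    for r in anchors.itertuples():
        if r.protein in slot and slot[r.protein][0] != r.scaffold:
            slot[r.protein] = ("AMBIG", "+")
        elif r.protein not in slot:
            slot[r.protein] = (r.scaffold, r.orientation)
    # scaffold -> anchored slots; multi-slot scaffolds must be map-adjacent
    by_scaffold: dict[str, list[str]] = {}
    for prot, (scf, _o) in slot.items():
        by_scaffold.setdefault(scf, []).append(prot)
    excluded = set()
    for scf, prots in by_scaffold.items():
        if scf == "AMBIG" or len(prots) < 2:
            continue
        for chrom, order in smap.order.items():
            idxs = sorted(order.index(p) for p in prots if p in order)
            if len(idxs) >= 2 and any(b - a > 1 for a, b in zip(idxs, idxs[1:])):
                excluded.add(scf)
                log_rows.append(
                    {"scaffold": scf, "action": "excluded",
                     "reason": "anchored to non-adjacent map positions"}
                )
    out = dict(scaffolds)
    spacer = np.full(SPACER_N, N, dtype=np.uint8)
    super_i = 0
    for chrom, order in smap.order.items():
        run: list[tuple[str, str]] = []  # (scaffold, orientation)
        run_prot: list[str] = []

        def flush():
            nonlocal super_i
            scfs = list(dict.fromkeys(s for s, _ in run))
            if len(scfs) < 2 or any(s not in out for s in scfs):
                return
            parts = []
            orient: dict[str, str] = {}
            for s, o in run:
                orient.setdefault(s, o)
            for j, s in enumerate(scfs):
                if j:
                    parts.append(spacer)
                seq = out.pop(s)
                parts.append(seq if orient[s] == "+" else revcomp(seq))
            out[f"super_{super_i:04d}"] = np.concatenate(parts)
            log_rows.append(
                {"scaffold": f"super_{super_i:04d}", "action": "joined",
                 "reason": ",".join(scfs)}
            )
            super_i += 1

        for prot in order:
            entry = slot.get(prot)
            usable = (
                entry is not None
                and entry[0] != "AMBIG"
                and entry[0] not in excluded
            )
            if usable and run_prot:
                # require conserved adjacency with the previous anchored slot
                if (run_prot[-1], prot) not in smap.adjacency:
                    flush()
                    run, run_prot = [], []
            if usable:
                if not run or run[-1][0] != entry[0]:
                    run.append(entry)
                run_prot.append(prot)
            else:
                flush()
                run, run_prot = [], []
        flush()
    return out, pd.DataFrame(log_rows, columns=["scaffold", "action", "reason"])


def assign_chromosomes(hits: pd.DataFrame) -> pd.DataFrame:
    """Assign each scaffold to the chromosome of its top hit, ranked by the
    ratio of identical bases to aligned span (= identity)."""
    if len(hits) == 0:
        return pd.DataFrame(columns=["scaffold", "chrom", "identity"])
    h = hits.copy()
    h["rank_key"] = h["identity"]
    best = (
        h.sort_values(["rank_key", "chrom"], ascending=[False, True])
        .groupby("scaffold", as_index=False)
        .first()
    )
    return best[["scaffold", "chrom", "identity"]].sort_values("scaffold").reset_index(drop=True)


def write_agp(log: pd.DataFrame, path) -> None:
    log.to_csv(path, sep="\t", index=False)
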