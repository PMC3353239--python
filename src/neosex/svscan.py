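"""Mate-pair-violation structural-variant scanning.

A uniquely mapped pair is classified by orientation and span against the
library geometry:

* different chromosomes                      -> ``interlocus``
* reverse-forward orientation                -> ``rf_orientation``
  (tandem-duplication breakpoint signature)
* span > mean + k*sd                         -> ``long_span``  (deletion)
* span < mean - k*sd                         -> ``short_span`` (insertion)
* otherwise                                  -> ``normal``

Same-strand (FF/RR) pairs are inversion evidence; they are tallied in the
violation report as ``other`` but deliberately not emitted as typed calls.
Anomalies of one class clustering within ``cluster_window`` are merged into
an SV call, and calls need ``min_support`` (default 3) supporting pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simdata import InsertSpec

SV_TYPES = {
    "long_span": "deletion",
    "short_span": "insertion",
    "rf_orientation": "tandem_duplication",
    "interlocus": "dispersed_duplication",
}


@dataclass(frozen=True)
class SvParams:
    ins: InsertSpec = field(default_factory=InsertSpec)
    sd_multiplier: float = 3.0
    min_support: int = 3
    cluster_window: int | None = None  # default mean + 3*sd

    def __post_init__(self):
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if self.sd_multiplier <= 0:
            raise ValueError("sd_multiplier must be > 0")

    @property
    def window(self) -> int:
        if self.cluster_window is not None:
            return self.cluster_window
        return int(self.ins.mean + 3 * self.ins.sd)


@dataclass
class SvCall:
    type: str
    chrom: str
    start: int
    end: int
    support: int
    sex: str = ""
    cds_overlap: bool = False


def classify_pair(pa, p: SvParams) -> str:
    """Anomaly class of one mapped, unique pair (see module docstring)."""
    if pa.chrom1 != pa.chrom2:
        return "interlocus"
    if pa.orientation_class == "RF":
        return "rf_orientation"
    if pa.orientation_class == "FF":
        return "ff_orientation"
    if pa.span > p.ins.mean + p.sd_multiplier * p.ins.sd:
        return "long_span"
    if pa.span < p.ins.mean - p.sd_multiplier * p.ins.sd:
        return "short_span"
    return "normal"


def classify_pairs(pairs: pd.DataFrame, p: SvParams) -> pd.Series:
    """Vectorised classification of the mapped-pair table."""
    m = pairs["status"] == "mapped"
    out = pd.Series("unmapped", index=pairs.index, dtype=object)
    inter = m & (pairs["orientation"] == "interlocus")
    rf = m & (pairs["orientation"] == "RF")
    ff = m & (pairs["orientation"] == "FF")
    span = pairs["span"]
    hi = p.ins.mean + p.sd_multiplier * p.ins.sd
    lo = p.ins.mean - p.sd_multiplier * p.ins.sd
    rest = m & ~inter & ~rf & ~ff
    out[rest & (span > hi)] = "long_span"
    out[rest & (span < lo)] = "short_span"
    out[rest & (span >= lo) & (span <= hi)] = "normal"
    out[rf] = "rf_orientation"
    out[ff] = "ff_orientation"
    out[inter] = "interlocus"
    return out


def _pair_geometry(pairs: pd.DataFrame, read_len: int) -> pd.DataFrame:
    """Left/right mate coordinates for same-chromosome pairs."""
    left_is_1 = pairs["pos1"] <= pairs["pos2"]
    lpos = np.where(left_is_1, pairs["pos1"], pairs["pos2"])
    rpos = np.where(left_is_1, pairs["pos2"], pairs["pos1"])
    return pd.DataFrame(
        {
            "chrom": pairs["chrom1"],
            "left_start": lpos,
            "left_end": lpos + read_len,
            "right_start": rpos,
            "right_end": rpos + read_len,
        },
        index=pairs.index,
    )


def cluster_anomalies(
    pairs: pd.DataFrame, anomalies: pd.Series, p: SvParams, sex: str = ""
) -> pd.DataFrame:
    """Merge same-class anomalous pairs into SV calls.

    Same-chromosome anomalies are swept left-to-right; a new cluster opens
    when the left-mate start jumps by more than the cluster window.
    Intervals: deletion = intersection of inner spans (the deleted reference
    segment must lie inside every supporting pair); insertion = the implied
    breakpoint interval; tandem duplication = the RF-implied duplicated unit
    [min reverse-mate start, max forward-mate end).  Interlocus pairs are
    clustered on both loci and reported as dispersed duplications anchored
    at the lexicographically first locus.
    """
    read_len = pairs.attrs.get("read_len", 100)
    rows: list[dict] = []
    geom = _pair_geometry(pairs, read_len)
    for aclass in ("long_span", "short_span", "rf_orientation"):
        sel = pairs.index[anomalies == aclass]
        if len(sel) == 0:
            continue
        sub = geom.loc[sel].sort_values(["chrom", "left_start"])
        chroms = sub["chrom"].to_numpy()
        ls = sub["left_start"].to_numpy()
        new = np.ones(len(sub), dtype=bool)
        new[1:] = (chroms[1:] != chroms[:-1]) | (np.diff(ls) > p.window)
        cluster_id = np.cumsum(new)
        sub = sub.assign(cluster=cluster_id)
        for _, grp in sub.groupby("cluster"):
            support = len(grp)
            if support < p.min_support:
                continue
            chrom = grp["chrom"].iloc[0]
            if aclass == "rf_orientation":
                # leftmost mate is the reverse one; unit spans rev-start..fwd-end
                start = int(grp["left_start"].min())
                end = int(grp["right_end"].max())
            elif aclass == "long_span":
                start = int(grp["left_end"].max())
                end = int(grp["right_start"].min())
                if end <= start:  # discordant support geometry
                    start, end = int(grp["left_end"].min()), int(grp["right_start"].max())
            else:  # short_span: implied insertion breakpoint region
                start = int(grp["left_end"].max())
                end = max(start + 1, int(grp["right_start"].min()))
            rows.append(
                {"type": SV_TYPES[aclass], "chrom": chrom, "start": start,
                 "end": end, "support": support, "sex": sex}
            )
    # dispersed duplications from interlocus pairs
    sel = pairs.index[anomalies == "interlocus"]
    if len(sel):
        sub = pairs.loc[sel, ["chrom1", "pos1", "chrom2", "pos2"]].copy()
        flip = sub["chrom1"] > sub["chrom2"]
        sub.loc[flip, ["chrom1", "pos1", "chrom2", "pos2"]] = sub.loc[
            flip, ["chrom2", "pos2", "chrom1", "pos1"]
        ].to_numpy()
        sub = sub.sort_values(["chrom1", "chrom2", "pos1"])
        c1 = sub["chrom1"].to_numpy()
        c2 = sub["chrom2"].to_numpy()
        p1 = sub["pos1"].to_numpy()
        p2 = sub["pos2"].to_numpy()
        new = np.ones(len(sub), dtype=bool)
        new[1:] = (
            (c1[1:] != c1[:-1])
            | (c2[1:] != c2[:-1])
            | (np.diff(p1) > p.window)
        )
        cluster_id = np.cumsum(new)
        for cid in np.unique(cluster_id):
            sel2 = cluster_id == cid
            # both loci must be tight
            if p2[sel2].max() - p2[sel2].min() > 2 * p.window:
                continue
            support = int(sel2.sum())
            if support < p.min_support:
                continue
            rows.append(
                {
                    "type": "dispersed_duplication",
                    "chrom": str(c1[sel2][0]),
                    "start": int(p1[sel2].min()),
                    "end": int(p1[sel2].max()) + read_len,
                    "support": support,
                    "sex": sex,
                }
            )
    out = pd.DataFrame(rows, columns=["type", "chrom", "start", "end", "support", "sex"])
    return out.sort_values(["chrom", "start", "type"]).reset_index(drop=True)


def annotate_cds_overlap(svs: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Flag SVs whose interval intersects any CDS by >= 1 bp."""
    svs = svs.copy()
    flags = np.zeros(len(svs), dtype=bool)
    for chrom, cds in genes.groupby("chrom"):
        starts = np.sort(cds["cds_start"].to_numpy())
        ends = cds.sort_values("cds_start")["cds_end"].to_numpy()
        sel = svs["chrom"] == chrom
        if not sel.any():
            continue
        s = svs.loc[sel, "start"].to_numpy()
        e = svs.loc[sel, "end"].to_numpy()
        # CDS i overlaps [s,e) iff cds_start < e and cds_end > s;
        # with sorted non-overlapping CDS, check the first CDS not ending
        # before s
        i = np.searchsorted(ends, s, side="right")
        ok = (i < len(starts)) & (starts[np.minimum(i, len(starts) - 1)] < e)
        flags[np.nonzero(sel.to_numpy())[0]] = ok
    svs["cds_overlap"] = flags
    return svs


def violation_rate(anomalies: pd.Series) -> float:
    """Fraction of mapped pairs with an anomalous geometry."""
    mapped = anomalies[anomalies != "unmapped"]
    if len(mapped) == 0:
        return 0.0
    return float((mapped != "normal").mean())


def mf_ratio_report(
    svs_male: pd.DataFrame,
    svs_female: pd.DataFrame,
    anomalies_male: pd.Series | None = None,
    anomalies_female: pd.Series | None = None,
) -> dict:
    """Per-chromosome, per-type SV counts with male/female ratios, plus the
    per-sex mate-pair violation rates.  A zero female count yields ``inf``.
    """
    cm = svs_male.groupby(["chrom", "type"]).size().rename("male")
    cf = svs_female.groupby(["chrom", "type"]).size().rename("female")
    tab = pd.concat([cm, cf], axis=1).fillna(0).astype(int).reset_index()
    with np.errstate(divide="ignore"):
        tab["ratio"] = np.where(
            tab["female"] > 0,
            tab["male"] / tab["female"].replace(0, np.nan),
            np.where(tab["male"] > 0, np.inf, np.nan),
        )
    report = {"table": tab}
    if anomalies_male is not None:
        report["violation_rate_male"] = violation_rate(anomalies_male)
    if anomalies_female is not None:
        report["violation_rate_female"] = violation_rate(anomalies_female)
    return report


def write_bedpe(pairs: pd.DataFrame, anomalies: pd.Series, path) -> None:
    """Anomalous pairs as BEDPE."""
    read_len = pairs.attrs.get("read_len", 100)
    sel = ~anomalies.isin(["normal", "unmapped"])
    with open(path, "w") as fh:
        for i in pairs.index[sel]:
            r = pairs.loc[i]
            fh.write(
                f"{r['chrom1']}\t{r['pos1']}\t{r['pos1'] + read_len}\t"
                f"{r['chrom2']}\t{r['pos2']}\t{r['pos2'] + read_len}\t"
                f"pair{r['pair_id']}\t.\t{r['strand1']}\t{r['strand2']}\t{anomalies[i]}\n"
            )


def write_sv_bed(svs: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for r in svs.itertuples():
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.type}\t{r.support}\t.\n"
            )
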