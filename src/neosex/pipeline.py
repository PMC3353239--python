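"""End-to-end orchestration: simulate -> map -> call -> scan -> report.

``run_all`` executes every stage on a :class:`PipelineConfig`, writing each
stage's artifacts before the next starts, and returns the in-memory results
(tables, call sets, truth) for programmatic use.  All randomness derives
from the single config seed, so one config yields byte-identical outputs.
Window sizes for the density tracks scale with the simulated genome
(window = genome/10, step = window/10) so chromosome-scale patterns remain
visible at desk scale.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bchrom as bc
from . import mapper as mp
from . import neoy as ny
from . import simdata as sd
from . import svscan as sv
from . import synteny as sy
from . import variants as vr
from ._seq import decode, write_fasta


@dataclass
class PipelineConfig:
    seed: int = 0
    genome_scale: float = 1.0
    coverage_female: float = 30.0
    coverage_male: float = 40.0
    err_rate: float = 0.002
    insert_mean: int = 500
    insert_sd: int = 50
    read_len: int = 100
    divergence: dict = field(default_factory=dict)  # DivergencePlan overrides
    caller: dict = field(default_factory=dict)  # CallerParams overrides
    sv_min_support: int = 3
    sv_sd_multiplier: float = 3.0
    b_cov_threshold: float = 0.20
    ratio_band: tuple = (0.4, 0.6)
    male_ratio_band: tuple = (0.25, 0.75)
    assembly_chunk: int = 50_000
    write_sam: bool = True
    write_fastq: bool = True

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "ratio_band" in data:
            data["ratio_band"] = tuple(data["ratio_band"])
        if "male_ratio_band" in data:
            data["male_ratio_band"] = tuple(data["male_ratio_band"])
        return cls(**data)

    @property
    def insert(self) -> sd.InsertSpec:
        return sd.InsertSpec(self.insert_mean, self.insert_sd, self.read_len)

    @property
    def divergence_plan(self) -> sd.DivergencePlan:
        dv = dict(self.divergence)
        for key in ("indel_len_range", "tandem_dup_len_range"):
            if key in dv:
                dv[key] = tuple(dv[key])
        return sd.DivergencePlan(**dv)

    @property
    def caller_params(self) -> vr.CallerParams:
        return vr.CallerParams(**self.caller)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _fmt2(x: float) -> float:
    return float(f"{x:.2f}")


def make_table2(
    density_table: pd.DataFrame,
    pseudo_counts: dict[str, tuple[int, int]],
    kaks_stats: pd.DataFrame,
    dup_overlap: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the per-chromosome comparison table.

    Densities at 2 decimals; ratios at 2 decimals, printed as integers once
    >= 10; missing chromosomes get null cells.
    """
    rows = []
    chroms = list(density_table["chrom"])
    kk = kaks_stats.set_index("chrom") if len(kaks_stats) else pd.DataFrame()
    dv = dup_overlap.set_index("chrom") if len(dup_overlap) else pd.DataFrame()
    for chrom in chroms:
        d = density_table[density_table["chrom"] == chrom].iloc[0]
        row = {
            "chrom": chrom,
            "exonic_snp_density_mf": f"{d['exonic_male']:.2f}/{d['exonic_female']:.2f}"
            f"({d['exonic_ratio']})",
            "intronic_snp_density_mf": f"{d['intronic_male']:.2f}/{d['intronic_female']:.2f}"
            f"({d['intronic_ratio']})",
        }
        if chrom in pseudo_counts:
            k, n = pseudo_counts[chrom]
            row["pseudogenes"] = f"{k}/{n}"
        else:
            row["pseudogenes"] = ""
        for col, src in (("ka_mean_x1000", "ka_mean"), ("ka_sd_x1000", "ka_sd")):
            if len(kk) and chrom in kk.index:
                row[col] = _fmt2(1000 * kk.loc[chrom, src])
            else:
                row[col] = None
        for sex in ("male", "female"):
            col = f"tandem_dup_cds_pct_{sex}"
            if len(dv) and chrom in dv.index and f"pct_{sex}" in dv.columns:
                row[col] = _fmt2(dv.loc[chrom, f"pct_{sex}"])
            else:
                row[col] = None
        rows.append(row)
    return pd.DataFrame(rows)


def ratio_table_from_densities(densities: dict[str, tuple[float, float, float, float]]) -> pd.DataFrame:
    """Table-2-style parenthetical ratios from given per-chromosome
    (exonic_male, exonic_female, intronic_male, intronic_female) densities."""
    rows = []
    for chrom, (em, ef, im, if_) in densities.items():
        rows.append(
            {
                "chrom": chrom,
                "exonic_ratio": vr.format_ratio(em, ef),
                "intronic_ratio": vr.format_ratio(im, if_),
            }
        )
    return pd.DataFrame(rows)


def run_all(config: PipelineConfig, outdir) -> dict:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    results: dict = {"config": config}

    def record(stage: str, files: list[Path], **info):
        log.append(
            {"stage": stage, "files": {f.name: _digest(f) for f in files if f.exists()},
             **info}
        )

    # ---------------- simdata ----------------
    try:
        plan = sd.default_genome_plan(seed=config.seed, scale=config.genome_scale)
        genome, genes = sd.build_ancestral_genome(plan)
        dp = config.divergence_plan
        sample = sd.derive_haplotypes(genome, genes, dp, seed=config.seed)
        ins = config.insert
        reads_f = sd.simulate_reads(sample.female, ins, config.coverage_female,
                                    config.err_rate, config.seed + 1)
        reads_m = sd.simulate_reads(sample.male, ins, config.coverage_male,
                                    config.err_rate, config.seed + 2)
        genome.to_fasta(out / "reference.fa")
        sd.write_gff3(genes, out / "genes.gff3")
        sample.truth.write(out / "truth")
        if sample.b_fragment is not None:
            write_fasta(out / "b_fragment.fa", {"B": decode(sample.b_fragment)})
        if config.write_fastq:
            reads_f.to_fastq(out / "female_1.fq", out / "female_2.fq")
            reads_m.to_fastq(out / "male_1.fq", out / "male_2.fq")
        config.to_yaml(out / "config.yaml")
        record("simdata", [out / "reference.fa", out / "genes.gff3"],
               seed=config.seed, n_pairs_female=reads_f.n_pairs,
               n_pairs_male=reads_m.n_pairs)
    except Exception as e:  # noqa: BLE001
        raise StageError("simdata", e) from e
    results.update(genome=genome, genes=genes, sample=sample)

    # ---------------- mapper ----------------
    try:
        index = mp.SeedIndex(genome)
        pairs_f = mp.align_pairs(reads_f, index, ins)
        pairs_m = mp.align_pairs(reads_m, index, ins)
        gapped_f = mp.realign_unmapped(reads_f, pairs_f, index)
        gapped_m = mp.realign_unmapped(reads_m, pairs_m, index)
        if config.write_sam:
            mp.write_sam(out / "female.sam", reads_f, pairs_f, gapped_f, genome)
            mp.write_sam(out / "male.sam", reads_m, pairs_m, gapped_m, genome)
        record("mapper", [out / "female.sam", out / "male.sam"],
               mapped_female=int((pairs_f["status"] == "mapped").sum()),
               mapped_male=int((pairs_m["status"] == "mapped").sum()))
    except Exception as e:  # noqa: BLE001
        raise StageError("mapper", e) from e
    results.update(pairs_f=pairs_f, pairs_m=pairs_m, gapped_f=gapped_f, gapped_m=gapped_m)

    # ---------------- variants ----------------
    try:
        params = config.caller_params
        pu_f = vr.build_pileup(pairs_f, reads_f, genome, gapped_f)
        pu_m = vr.build_pileup(pairs_m, reads_m, genome, gapped_m)
        snps = vr.call_snps(pu_m, pu_f, genome, params)
        indels = vr.call_indels(gapped_m, gapped_f, params)
        calls = pd.concat([snps, indels], ignore_index=True)
        calls_male = calls[calls["partition"].isin(["male_only", "shared"])]
        calls_female = calls[calls["partition"].isin(["female_segregating", "shared"])]
        vr.write_vcf(calls, genome, out / "joint.vcf")
        vr.write_vcf(calls_male, genome, out / "male.vcf")
        vr.write_vcf(calls_female, genome, out / "female.vcf")
        window = max(10_000, genome.total_length // 10)
        dparams = vr.DensityParams(window=window, step=window // 10,
                                   min_depth=params.min_depth)
        track_m = vr.window_density(calls_male, genome.lengths, dparams)
        track_f = vr.window_density(calls_female, genome.lengths, dparams)
        vr.write_bedgraph(track_m, out / "male_density.bedgraph")
        vr.write_bedgraph(track_f, out / "female_density.bedgraph")
        dtab = vr.density_ratio_table(calls_male, calls_female, genes, genome,
                                      pu_m, pu_f, params)
        dtab.to_csv(out / "density_ratio.tsv", sep="\t", index=False)
        spectrum = vr.allele_ratio_spectrum(snps, genome, pu_m,
                                            tuple(config.ratio_band), params)
        spectrum.to_csv(out / "allele_ratio_spectrum.tsv", sep="\t", index=False)
        record("variants", [out / "joint.vcf", out / "density_ratio.tsv"],
               n_snps=len(snps), n_indels=len(indels))
    except Exception as e:  # noqa: BLE001
        raise StageError("variants", e) from e
    results.update(snps=snps, indels=indels, calls=calls, density_table=dtab,
                   spectrum=spectrum, pileup_m=pu_m, pileup_f=pu_f,
                   track_m=track_m, track_f=track_f)

    # ---------------- svscan ----------------
    try:
        svp = sv.SvParams(ins=ins, sd_multiplier=config.sv_sd_multiplier,
                          min_support=config.sv_min_support)
        anom_m = sv.classify_pairs(pairs_m, svp)
        anom_f = sv.classify_pairs(pairs_f, svp)
        svs_m = sv.cluster_anomalies(pairs_m, anom_m, svp, sex="male")
        svs_f = sv.cluster_anomalies(pairs_f, anom_f, svp, sex="female")
        svs_m = sv.annotate_cds_overlap(svs_m, genes)
        svs_f = sv.annotate_cds_overlap(svs_f, genes)
        sv.write_bedpe(pairs_m, anom_m, out / "male_anomalies.bedpe")
        sv.write_bedpe(pairs_f, anom_f, out / "female_anomalies.bedpe")
        sv.write_sv_bed(svs_m, out / "male_svs.bed")
        sv.write_sv_bed(svs_f, out / "female_svs.bed")
        report = sv.mf_ratio_report(svs_m, svs_f, anom_m, anom_f)
        report["table"].to_csv(out / "sv_mf_ratio.tsv", sep="\t", index=False)
        record("svscan", [out / "male_svs.bed", out / "sv_mf_ratio.tsv"],
               n_svs_male=len(svs_m), n_svs_female=len(svs_f),
               violation_rate_male=report.get("violation_rate_male"),
               violation_rate_female=report.get("violation_rate_female"))
    except Exception as e:  # noqa: BLE001
        raise StageError("svscan", e) from e
    results.update(svs_m=svs_m, svs_f=svs_f, sv_report=report,
                   anom_m=anom_m, anom_f=anom_f)

    # ---------------- neoy ----------------
    try:
        female_calls = calls[calls["partition"].isin(["female_segregating", "shared"])]
        male_only = calls[calls["partition"] == "male_only"]
        allele_pairs = []
        ref_pairs = []
        for gene in genes.itertuples():
            ap = ny.reconstruct_alleles(gene, genome, female_calls, male_only,
                                        male_ratio_band=tuple(config.male_ratio_band))
            if ap is None:
                continue
            allele_pairs.append(ap)
            s, e = int(gene.cds_start), int(gene.cds_end)
            ref_cds = genome.fetch(gene.chrom, s, e)
            if gene.strand == "-":
                from ._seq import revcomp_str

                ref_cds = revcomp_str(ref_cds)
            ref_pairs.append(ny.AllelePair(gene.gene_id, ref_cds, ap.neoX_cds))
        flags = ny.scan_gene_set(allele_pairs)
        flags.to_csv(out / "disruptions.tsv", sep="\t", index=False)
        gene_chrom = genes.set_index("gene_id")["chrom"]
        derived_all, ancestral_all = ny.filter_ancestral(flags)
        pseudo_counts: dict[str, tuple[int, int]] = {}
        for chrom in genome.names:
            ids = set(genes.loc[genes["chrom"] == chrom, "gene_id"])
            pseudo_counts[chrom] = (len(derived_all & ids), len(ids))
        enr = (
            ny.pseudogene_enrichment(pseudo_counts, focal="neo")
            if pseudo_counts.get("neo", (0, 0))[1]
            else pd.DataFrame()
        )
        if len(enr):
            enr.to_csv(out / "pseudogene_enrichment.tsv", sep="\t", index=False)
        # Ka/Ks: male column = neoX vs neoY alleles; female column = reference
        # vs female-derived allele
        kaks_rows = []
        for ap, rp in zip(allele_pairs, ref_pairs):
            chrom = gene_chrom[ap.gene_id]
            for sex, pair in (("male", ap), ("female", rp)):
                r = ny.kaks(pair)
                if r is None or np.isnan(r.Ka):
                    continue
                kaks_rows.append(
                    {"gene_id": pair.gene_id, "chrom": chrom, "sex": sex,
                     "Ka": r.Ka, "Ks": r.Ks, "Na": r.Na, "Ns": r.Ns}
                )
        kaks_df = pd.DataFrame(kaks_rows, columns=["gene_id", "chrom", "sex", "Ka", "Ks", "Na", "Ns"])
        kaks_df.to_csv(out / "kaks.tsv", sep="\t", index=False)
        kk = (
            kaks_df[kaks_df["sex"] == "male"].groupby("chrom")["Ka"]
            .agg(ka_mean="mean", ka_sd="std").fillna(0.0).reset_index()
            if len(kaks_df)
            else pd.DataFrame(columns=["chrom", "ka_mean", "ka_sd"])
        )
        cbias = ny.codon_bias_table(allele_pairs, genes)
        cbias.to_csv(out / "codon_bias.tsv", sep="\t", index=False)
        write_fasta(
            out / "alleles.fa",
            {
                f"{ap.gene_id}_{al}": cds
                for ap in allele_pairs
                for al, cds in (("neoX", ap.neoX_cds), ("neoY", ap.neoY_cds))
            },
        )
        record("neoy", [out / "disruptions.tsv", out / "kaks.tsv"],
               n_genes=len(allele_pairs), n_derived_pseudo=len(derived_all),
               n_ancestral=len(ancestral_all))
    except Exception as e:  # noqa: BLE001
        raise StageError("neoy", e) from e
    results.update(allele_pairs=allele_pairs, flags=flags, derived_pseudo=derived_all,
                   ancestral_pseudo=ancestral_all, pseudo_counts=pseudo_counts,
                   enrichment=enr, kaks=kaks_df, kaks_stats=kk, codon_bias=cbias)

    # ---------------- synteny ----------------
    try:
        scaffolds, hits, adjacency, scf_truth = sd.fragment_assembly(
            genome, genes, seed=config.seed
        )
        stats_before = sy.n50([len(s) for s in scaffolds.values()])
        kept = sy.resolve_overlapping_hits(hits)
        merged, mlog = sy.merge_by_gene(kept, scaffolds)
        hits2 = sy.remap_hits_after_merge(kept, mlog)
        smap = sy.SyntenyMap.from_adjacency_table(adjacency)
        plens = {
            g.gene_id: (g.cds_end - g.cds_start) // 3 for g in genes.itertuples()
        }
        supers, slog = sy.merge_by_synteny(merged, hits2, smap, plens)
        stats_after = sy.n50([len(s) for s in supers.values()])
        assign = sy.assign_chromosomes(kept)
        assign_truth = scf_truth.set_index("scaffold")["chrom"]
        assign["true_chrom"] = assign["scaffold"].map(assign_truth)
        assign.to_csv(out / "chromosome_assignment.tsv", sep="\t", index=False)
        pd.concat([mlog.assign(pass_="gene"),
                   slog.rename(columns={"scaffold": "protein"}).assign(pass_="synteny")],
                  ignore_index=True).to_csv(out / "scaffold_joins.tsv", sep="\t", index=False)
        write_fasta(out / "superscaffolds.fa",
                    {n: decode(s) for n, s in sorted(supers.items())})
        with open(out / "assembly_stats.json", "w") as fh:
            json.dump({"before": stats_before.to_dict(),
                       "after": stats_after.to_dict()}, fh, indent=1)
        record("synteny", [out / "assembly_stats.json"],
               n50_before=stats_before.n50, n50_after=stats_after.n50)
    except Exception as e:  # noqa: BLE001
        raise StageError("synteny", e) from e
    results.update(synteny_stats=(stats_before, stats_after), assignment=assign,
                   superscaffolds=supers)

    # ---------------- bchrom ----------------
    try:
        female_asm = sd.haplotype_to_scaffolds(sample.female[0], config.assembly_chunk, "fem")
        yside = next(h for h in sample.male if h.name.startswith("male_y"))
        male_asm = sd.haplotype_to_scaffolds(yside, config.assembly_chunk, "mal")
        b_names = []
        if sample.b_fragment is not None:
            bhap = next(h for h in sample.male if h.name == "B")
            basm = sd.haplotype_to_scaffolds(bhap, config.assembly_chunk, "malB")
            b_names = sorted(basm)
            male_asm.update(basm)
        cand = bc.subtract_assemblies(male_asm, female_asm, config.b_cov_threshold)
        cand.to_csv(out / "b_candidates.tsv", sep="\t", index=False)
        retained = bc.filter_known(cand)
        # probe: a 260 bp fragment of the B private core at ~5% divergence
        probe = None
        ranking = pd.DataFrame()
        if sample.b_fragment is not None:
            dpb = config.divergence_plan
            core_start = dpb.b_slice_len + 200
            rngp = np.random.default_rng(np.random.SeedSequence([config.seed, 260]))
            pcodes = sample.b_fragment[core_start : core_start + 260].copy()
            mut = rngp.random(len(pcodes)) < 0.05
            pcodes[mut] = ((pcodes[mut] + rngp.integers(1, 4, int(mut.sum()))) % 4).astype(np.uint8)
            probe = decode(pcodes)
            ranking = bc.probe_bait(probe, male_asm)
            ranking.to_csv(out / "probe_ranking.tsv", sep="\t", index=False)
        # centromeric read fractions: subcentromeric chrX + neo-end slices
        sl = config.divergence_plan.b_slice_len
        cent = {
            "chrX_sub": genome.seqs[genome.names[0]][1000 : 1000 + sl],
            "neo_sub": genome.seqs["neo"][-1000 - sl : -1000],
        }
        # strided subsample so every source haplotype (incl. B) contributes
        nsub = 100_000
        step_m = max(1, reads_m.n_pairs // nsub)
        step_f = max(1, reads_f.n_pairs // nsub)
        frac_m = bc.centromeric_read_fraction(reads_m.r1[::step_m], cent)
        frac_f = bc.centromeric_read_fraction(reads_f.r1[::step_f], cent)
        with open(out / "centromeric_fraction.json", "w") as fh:
            json.dump({"male": frac_m, "female": frac_f}, fh, indent=1)
        record("bchrom", [out / "b_candidates.tsv"],
               n_candidates=int(cand["candidate"].sum()),
               n_retained=len(retained),
               centromeric_male=frac_m, centromeric_female=frac_f)
    except Exception as e:  # noqa: BLE001
        raise StageError("bchrom", e) from e
    results.update(b_candidates=cand, b_retained=retained, b_truth_scaffolds=b_names,
                   probe_ranking=ranking, centromeric={"male": frac_m, "female": frac_f})

    # ---------------- report ----------------
    try:
        dup_rows = []
        for chrom in genome.names:
            row = {"chrom": chrom}
            for sex, svs in (("male", svs_m), ("female", svs_f)):
                t = svs[(svs["chrom"] == chrom) & (svs["type"] == "tandem_duplication")]
                row[f"pct_{sex}"] = 100.0 * t["cds_overlap"].mean() if len(t) else 0.0
            dup_rows.append(row)
        dup_overlap = pd.DataFrame(dup_rows)
        table2 = make_table2(dtab, pseudo_counts, kk, dup_overlap)
        table2.to_csv(out / "table2_analog.tsv", sep="\t", index=False)
        with open(out / "pipeline_log.json", "w") as fh:
            json.dump(log, fh, indent=1, default=str)
        record("report", [out / "table2_analog.tsv"])
    except Exception as e:  # noqa: BLE001
        raise StageError("report", e) from e
    results.update(table2=table2, dup_overlap=dup_overlap, log=log)
    return results


# ---------------------------------------------------------------------------
# truth-based evaluation
# ---------------------------------------------------------------------------


def evaluate_against_truth(results: dict) -> dict:
    """Compare pipeline output with the simulator's truth table.

    Returns recall/contamination metrics for planted neo-Y disruptions,
    tandem duplications, SNPs and the B-candidate subtraction.
    """
    sample: sd.SexedSample = results["sample"]
    truth = sample.truth
    out: dict = {}

    planted = truth.planted_disruptions
    planted_neoy = set(planted.loc[planted["allele"] == "neoY", "gene_id"])
    planted_anc = set(planted.loc[planted["allele"] == "ancestral", "gene_id"])
    derived = results["derived_pseudo"]
    out["disruption_recall"] = (
        len(derived & planted_neoy) / len(planted_neoy) if planted_neoy else float("nan")
    )
    out["ancestral_contaminants"] = len(derived & planted_anc)
    out["n_planted_disruptions"] = len(planted_neoy)

    tsv = truth.planted_svs
    dups = tsv[tsv["type"] == "tandem_duplication"]
    called = results["svs_m"]
    called_t = called[called["type"] == "tandem_duplication"]
    hit = 0
    for r in dups.itertuples():
        ov = called_t[
            (called_t["chrom"] == r.chrom)
            & (called_t["start"] < r.end)
            & (called_t["end"] > r.start)
        ]
        if len(ov):
            hit += 1
    out["tandem_dup_recall"] = hit / len(dups) if len(dups) else float("nan")
    out["n_planted_dups"] = len(dups)

    snps = results["snps"]
    ty = truth.planted_snps
    ty = ty[ty["carrier"] == "neoY"]
    mo = snps[(snps["partition"] == "male_only") & (snps["chrom"] == "neo")]
    key_t = set(zip(ty["pos"], ty["alt"]))
    key_c = set(zip(mo["pos"], mo["alt"]))
    out["snp_recall"] = len(key_t & key_c) / len(key_t) if key_t else float("nan")

    b_truth = set(results.get("b_truth_scaffolds", []))
    retained = set(results["b_retained"]["scaffold"]) if len(results["b_retained"]) else set()
    out["b_candidates_retained"] = sorted(retained)
    out["b_recovered"] = retained == b_truth and bool(b_truth)
    if len(results.get("probe_ranking", [])):
        out["probe_top_is_b"] = results["probe_ranking"]["scaffold"].iloc[0] in b_truth
    return out
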