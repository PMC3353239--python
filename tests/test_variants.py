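"""Pileup, caller, partition and density-report contracts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from neosex import mapper as mp
from neosex import simdata as sd
from neosex import variants as vr
from neosex._seq import Genome, decode


def tiny_pileup(genome: Genome, entries) -> vr.Pileup:
    """Build a pileup directly from (chrom, pos, strand, base, count)."""
    total = genome.total_length
    counts = np.zeros((total, 2, 4), dtype=np.int64)
    pu = vr.Pileup(genome, counts, np.zeros(total, dtype=np.int64))
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    si = {"+": 0, "-": 1}
    for chrom, pos, strand, base, n in entries:
        s, _ = pu.chrom_bounds[chrom]
        counts[s + pos, si[strand], code[base]] += n
    return pu


class TestBuildPileup:
    def test_single_clean_read_columns(self, smallsim):
        rs = sd.simulate_reads([smallsim.sample.female[0]], smallsim.ins, 0.02, 0.0, seed=31)
        one = sd.ReadSet(
            rs.r1[:1], rs.r2[:1], rs.hap[:1], rs.chrom[:1], rs.chrom_names,
            rs.start[:1], rs.insert[:1], rs.hap_names,
        )
        pairs = mp.align_pairs(one, smallsim.index, smallsim.ins)
        pu = vr.build_pileup(pairs, one, smallsim.genome)
        r = pairs.iloc[0]
        assert r["status"] == "mapped"
        s, _ = pu.chrom_bounds[r["chrom1"]]
        for off in range(100):
            col = pu.counts[s + r["pos1"] + off]
            assert col.sum() == 1
        col0 = pu.column(r["chrom1"], int(r["pos1"]))
        assert col0.depth == 1
        assert col0.ref == decode(one.r1[0][:1])

    def test_disagreeing_reads_two_base_counts(self):
        rng = np.random.default_rng(3)
        genome = Genome({"c": rng.integers(0, 4, 3000).astype(np.uint8)})
        idx = mp.SeedIndex(genome)
        ins = sd.InsertSpec(500, 50, 100)
        s = 1000
        r1a = genome.seqs["c"][s : s + 100].copy()
        r1b = r1a.copy()
        r1b[50] = (r1b[50] + 1) % 4  # disagreeing site
        r2 = genome.seqs["c"][s + 400 : s + 500]
        from neosex._seq import revcomp

        rs = sd.ReadSet(
            np.stack([r1a, r1b]), np.stack([revcomp(r2), revcomp(r2)]),
            np.array([-1, -1]), np.array([-1, -1]), [],
            np.array([-1, -1]), np.array([-1, -1]),
        )
        pairs = mp.align_pairs(rs, idx, ins)
        pu = vr.build_pileup(pairs, rs, genome)
        col = pu.counts[s + 50].sum(axis=0)
        assert (col > 0).sum() == 2

    def test_depth_matches_interval_stabbing_oracle(self, smallsim):
        """Per-position depth equals an independent +1/-1 sweep over the
        alignment spans."""
        pu = smallsim.pileup_f
        genome = smallsim.genome
        pairs = smallsim.pairs_f
        L = smallsim.reads_f.read_len
        total = genome.total_length
        diff = np.zeros(total + 1, dtype=np.int64)
        m = pairs[pairs["status"] == "mapped"]
        for chrom_col, pos_col in (("chrom1", "pos1"), ("chrom2", "pos2")):
            for chrom, grp in m.groupby(chrom_col):
                s, e = pu.chrom_bounds[chrom]
                clen = e - s
                starts = grp[pos_col].to_numpy()
                ends = np.minimum(starts + L, clen)
                np.add.at(diff, s + starts, 1)
                np.add.at(diff, s + ends, -1)
        # gapped realignments also contribute matched bases
        for r in smallsim.gapped_f.itertuples():
            s, e = pu.chrom_bounds[r.chrom]
            j = r.gap_pos - r.pos
            L2 = L - (r.length if r.kind == "ins" else 0)
            diff[s + r.pos] += 1
            end = r.pos + L2 + (r.length if r.kind == "del" else 0)
            diff[s + min(end, e - s)] -= 1
            if r.kind == "del":  # the gap itself is not covered
                diff[s + r.gap_pos] -= 1
                diff[s + r.gap_pos + r.length] += 1
        expect = np.cumsum(diff[:-1])
        assert np.array_equal(pu.depth, expect)


class TestCallSnps:
    @pytest.fixture()
    def genome1(self, rng):
        return Genome({"c": rng.integers(0, 4, 200).astype(np.uint8)})

    def test_depth_below_min_no_call(self, genome1):
        ref = decode(genome1.seqs["c"][10:11])
        alt = "A" if ref != "A" else "C"
        pu_m = tiny_pileup(genome1, [("c", 10, "+", alt, 1)])
        pu_f = tiny_pileup(genome1, [])
        calls = vr.call_snps(pu_m, pu_f, genome1)
        assert calls.empty

    def test_male_het_female_ref_is_male_only(self, genome1):
        ref = decode(genome1.seqs["c"][10:11])
        alt = "A" if ref != "A" else "C"
        pu_m = tiny_pileup(
            genome1,
            [("c", 10, "+", ref, 6), ("c", 10, "-", ref, 6),
             ("c", 10, "+", alt, 6), ("c", 10, "-", alt, 5)],
        )
        pu_f = tiny_pileup(genome1, [("c", 10, "+", ref, 10), ("c", 10, "-", ref, 10)])
        calls = vr.call_snps(pu_m, pu_f, genome1)
        assert len(calls) == 1
        r = calls.iloc[0]
        assert r["partition"] == "male_only"
        assert abs(r["alt_ratio_male"] - 11 / 23) < 1e-9
        assert (r["male_ref"], r["male_alt"]) == (12, 11)

    def test_recall_and_false_positive_floor(self):
        """At 0.2% error and 30x/40x, planted neo-Y SNP recall >= 0.95 and
        false male-only calls stay below 5/Mb, across 3 seeds."""
        total_fp = 0.0
        for seed in (0, 1, 2):
            plan = sd.GenomePlan(
                chrom_specs=(
                    sd.ChromSpec("neo", "C", 300_000, 10),
                    sd.ChromSpec("chr2", "B", 100_000, 5),
                ),
                seed=seed,
            )
            genome, genes = sd.build_ancestral_genome(plan)
            dp = sd.DivergencePlan(
                snp_rate=1e-3, indel_rate=0, pseudogene_fraction=0,
                ancestral_disruption_count=0, tandem_dup_count=0,
                female_het_rate=0, male_het_rate=0,
                b_private_len=0, b_slice_len=0,
            )
            sample = sd.derive_haplotypes(genome, genes, dp, seed=seed)
            ins = sd.InsertSpec()
            index = mp.SeedIndex(genome)
            rf = sd.simulate_reads(sample.female, ins, 30, 0.002, seed + 10)
            rm = sd.simulate_reads(sample.male, ins, 40, 0.002, seed + 20)
            pf = mp.align_pairs(rf, index, ins)
            pm = mp.align_pairs(rm, index, ins)
            pu_f = vr.build_pileup(pf, rf, genome)
            pu_m = vr.build_pileup(pm, rm, genome)
            calls = vr.call_snps(pu_m, pu_f, genome)
            truth = sample.truth.planted_snps
            ty = truth[truth["carrier"] == "neoY"]
            mo = calls[calls["partition"] == "male_only"]
            key_t = set(zip(ty["pos"], ty["alt"]))
            key_c = set(zip(mo.loc[mo["chrom"] == "neo", "pos"], mo.loc[mo["chrom"] == "neo", "alt"]))
            recall = len(key_t & key_c) / len(key_t)
            assert recall >= 0.95
            # false calls: male-only SNPs anywhere that are not planted
            fp = len(key_c - key_t) + len(mo[mo["chrom"] != "neo"])
            total_fp += fp / (genome.total_length / 1e6)
        assert total_fp / 3 <= 5.0


class TestCallIndels:
    def gapped(self, rows):
        return pd.DataFrame(
            rows, columns=["pair_id", "mate", "chrom", "pos", "strand", "mm",
                           "kind", "gap_pos", "length", "seq"],
        )

    def test_single_strand_support_rejected(self):
        g = self.gapped(
            [(i, 1, "c", 100, "+", 0, "del", 120, 3, "AAA") for i in range(3)]
        )
        out = vr.call_indels(g, self.gapped([]))
        assert out.empty

    def test_both_strands_retained(self):
        g = self.gapped(
            [(0, 1, "c", 100, "+", 0, "del", 120, 3, "AAA"),
             (1, 1, "c", 105, "-", 0, "del", 120, 3, "AAA")]
        )
        out = vr.call_indels(g, self.gapped([]))
        assert len(out) == 1
        assert out.iloc[0]["partition"] == "male_only"

    def test_length_bounds(self):
        g = self.gapped(
            [(0, 1, "c", 100, "+", 0, "del", 120, 7, "AAAAAAA"),
             (1, 1, "c", 105, "-", 0, "del", 120, 7, "AAAAAAA")]
        )
        assert vr.call_indels(g, self.gapped([])).empty

    def test_planted_deletion_recovered_left_aligned(self, smallsim):
        """Planted neo-Y short indels are recovered at their coordinates."""
        out = vr.call_indels(smallsim.gapped_m, smallsim.gapped_f)
        truth = smallsim.sample.truth.planted_indels
        if truth.empty:
            pytest.skip("no indel planted at this seed")
        hits = 0
        mo = out[out["partition"] == "male_only"]
        for r in truth.itertuples():
            m = mo[
                (mo["chrom"] == r.chrom)
                & ((mo["pos"] - r.pos).abs() <= abs(r.length))
                & (mo["kind"] == r.kind)
            ]
            hits += bool(len(m))
        assert hits / len(truth) >= 0.9


class TestWindowDensity:
    def test_uniform_calls_density(self):
        calls = pd.DataFrame({"chrom": "c", "pos": np.arange(10) * 100_000, "kind": "snp"})
        params = vr.DensityParams(window=1_000_000, step=1_000_000)
        track = vr.window_density(calls, {"c": 1_000_000}, params)
        assert len(track) == 1
        assert track.iloc[0]["density"] == pytest.approx(0.01)

    def test_zero_calls_zero_track(self):
        calls = pd.DataFrame({"chrom": [], "pos": [], "kind": []})
        params = vr.DensityParams(window=100_000, step=10_000)
        track = vr.window_density(calls, {"c": 500_000}, params)
        assert (track["density"] == 0).all()

    def test_matches_naive_recount(self, rng):
        pos = np.sort(rng.integers(0, 777_000, size=400))
        calls = pd.DataFrame({"chrom": "c", "pos": pos, "kind": "snp"})
        params = vr.DensityParams(window=100_000, step=25_000)
        track = vr.window_density(calls, {"c": 777_000}, params)
        for r in track.itertuples():
            n = sum(r.start <= p < r.end for p in pos)
            assert r.n_calls == n
            assert r.density == pytest.approx(1000 * n / (r.end - r.start))
        # trailing partial window has its true length
        assert track.iloc[-1]["end"] == 777_000


class TestRatioFormatting:
    @pytest.mark.parametrize(
        "male,female,expect",
        [
            (2.04, 1.01, "2.02"),
            (4.61, 0.97, "4.75"),
            (1.0, 1.0, "1.00"),
            (0.18, 0.01, "18"),
            (0.99, 0.03, "33"),
            (1.0, 0.0, "Inf"),
            (0.0, 0.0, "NA"),
        ],
    )
    def test_format_ratio(self, male, female, expect):
        assert vr.format_ratio(male, female) == expect


class TestAlleleRatioSpectrum:
    def test_band_membership(self, smallsim):
        genome = smallsim.genome
        calls = pd.DataFrame(
            {
                "chrom": ["neo", "neo"],
                "pos": [10, 20],
                "kind": "snp",
                "partition": "male_only",
                "alt_ratio_male": [10 / 20, 2 / 20],
            }
        )
        spec = vr.allele_ratio_spectrum(calls, genome)
        row = spec[spec["chrom"] == "neo"].iloc[0]
        assert row["n_calls"] == 2
        assert row["fraction_in_band"] == pytest.approx(0.5)

    def test_fixed_differences_sit_in_band(self):
        """At deep male coverage (the study sequenced males far deeper than
        females), planted fixed neo-Y differences fall in the 1:1 band >=90%
        of the time while low-frequency male polymorphisms (pool frequency
        <= 0.25) do so <20% of the time."""
        plan = sd.GenomePlan(
            chrom_specs=(sd.ChromSpec("neo", "C", 150_000, 10),), seed=21
        )
        genome, genes = sd.build_ancestral_genome(plan)
        dp = sd.DivergencePlan(
            snp_rate=2e-3, indel_rate=0, pseudogene_fraction=0,
            ancestral_disruption_count=0, tandem_dup_count=0,
            female_het_rate=0, male_het_rate=3e-3,
            b_private_len=0, b_slice_len=0,
        )
        sample = sd.derive_haplotypes(genome, genes, dp, seed=21)
        ins = sd.InsertSpec()
        index = mp.SeedIndex(genome)
        rm = sd.simulate_reads(sample.male, ins, 100, 0.002, 5)
        rf = sd.simulate_reads(sample.female, ins, 30, 0.002, 6)
        pu_m = vr.build_pileup(mp.align_pairs(rm, index, ins), rm, genome)
        pu_f = vr.build_pileup(mp.align_pairs(rf, index, ins), rf, genome)
        calls = vr.call_snps(pu_m, pu_f, genome)
        truth = sample.truth.planted_snps
        fixed = set(truth.loc[truth["carrier"] == "neoY", "pos"])
        poly = set(
            truth.loc[
                (truth["carrier"] == "male_polymorphism") & (truth["freq"] <= 0.25),
                "pos",
            ]
        )
        sub = calls[calls["chrom"] == "neo"]
        in_band = sub["alt_ratio_male"].between(0.4, 0.6)
        fixed_mask = sub["pos"].isin(fixed)
        assert fixed_mask.sum() >= 100
        assert in_band[fixed_mask].mean() >= 0.9
        poly_mask = sub["pos"].isin(poly)
        if poly_mask.sum() >= 5:
            assert in_band[poly_mask].mean() < 0.2


class TestVcfOutput:
    def test_vcf_parses_with_pysam(self, tmp_path, smallsim):
        calls = vr.call_snps(smallsim.pileup_m, smallsim.pileup_f, smallsim.genome)
        indels = vr.call_indels(smallsim.gapped_m, smallsim.gapped_f)
        joint = pd.concat([calls, indels], ignore_index=True)
        path = tmp_path / "x.vcf"
        vr.write_vcf(joint, smallsim.genome, path)
        import pysam

        n = 0
        with pysam.VariantFile(str(path)) as fh:
            for rec in fh:
                n += 1
                assert rec.info["PART"] in (
                    "male_only", "female_segregating", "shared", "unassigned"
                )
                ref = smallsim.genome.fetch(rec.chrom, rec.start, rec.start + len(rec.ref))
                assert ref == rec.ref
        assert n == len(joint)
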