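"""Shared fixtures: a reduced-scale simulated study reused across modules.

The session-scoped ``smallsim`` bundle keeps unit tests fast; the
full-scale study conditions are exercised only by the acceptance tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from neosex import mapper as mp
from neosex import simdata as sd
from neosex import variants as vr


@dataclass
class SimBundle:
    plan: sd.GenomePlan
    genome: object
    genes: object
    dp: sd.DivergencePlan
    sample: sd.SexedSample
    ins: sd.InsertSpec
    index: mp.SeedIndex
    reads_f: sd.ReadSet
    reads_m: sd.ReadSet
    pairs_f: object
    pairs_m: object
    gapped_f: object
    gapped_m: object
    pileup_f: vr.Pileup
    pileup_m: vr.Pileup


def small_plan(seed: int = 7) -> sd.GenomePlan:
    return sd.GenomePlan(
        chrom_specs=(
            sd.ChromSpec("chrX", "A", 120_000, 8),
            sd.ChromSpec("neo", "C+D", 200_000, 14),
            sd.ChromSpec("chr2", "B+E", 120_000, 8),
            sd.ChromSpec("chr4", "F", 60_000, 2),
        ),
        seed=seed,
    )


@pytest.fixture(scope="session")
def smallsim() -> SimBundle:
    plan = small_plan()
    genome, genes = sd.build_ancestral_genome(plan)
    dp = sd.DivergencePlan(
        pseudogene_fraction=0.3,
        ancestral_disruption_count=2,
        tandem_dup_count=4,
        tandem_dup_len_range=(400, 1200),
        b_private_len=8000,
        b_slice_len=1000,
    )
    sample = sd.derive_haplotypes(genome, genes, dp, seed=7)
    ins = sd.InsertSpec()
    index = mp.SeedIndex(genome)
    reads_f = sd.simulate_reads(sample.female, ins, 30, 0.002, 71)
    reads_m = sd.simulate_reads(sample.male, ins, 40, 0.002, 72)
    pairs_f = mp.align_pairs(reads_f, index, ins)
    pairs_m = mp.align_pairs(reads_m, index, ins)
    gapped_f = mp.realign_unmapped(reads_f, pairs_f, index)
    gapped_m = mp.realign_unmapped(reads_m, pairs_m, index)
    pileup_f = vr.build_pileup(pairs_f, reads_f, genome, gapped_f)
    pileup_m = vr.build_pileup(pairs_m, reads_m, genome, gapped_m)
    return SimBundle(
        plan, genome, genes, dp, sample, ins, index,
        reads_f, reads_m, pairs_f, pairs_m, gapped_f, gapped_m,
        pileup_f, pileup_m,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20120322)
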