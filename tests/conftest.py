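"""Shared fixtures: a small synthetic community reused across tests.

Sizes here are deliberately modest (hundreds of kb, tens of x) so the
whole suite stays fast; the acceptance tests build their own larger
datasets at the documented study scales.
"""

import numpy as np
import pytest

from holopipe import binning, simulate, spectrum


@pytest.fixture(scope="session")
def small_community():
    """200 kb diploid host + two compositionally distinct symbionts."""
    hapA, hapB, host_truth = simulate.simulate_host_genome(
        200_000, het_rate=0.005, repeat_fraction=0.10, repeat_unit_length=400, seed=101, gc=0.40
    )
    symbionts = simulate.simulate_symbiont_genomes(
        2, [80_000, 60_000], [0.62, 0.30], seed=102
    )
    members = [
        simulate.CommunityMember("host", (hapA, hapB), 50.0, 0.40),
        simulate.CommunityMember(symbionts[0][0], (symbionts[0][1],), 20.0, 0.62),
        simulate.CommunityMember(symbionts[1][0], (symbionts[1][1],), 12.0, 0.30),
    ]
    reads, truth = simulate.simulate_reads(
        members, read_length=150, error_rate=0.003, paired=True, insert_size=400, seed=103
    )
    genomes = [("host", hapA)] + symbionts
    contigs, depth_table = simulate.fragment_genomes(
        genomes, target_n50=5000, min_length=2000, seed=104,
        depths={"host": 50.0, "symbiont_1": 20.0, "symbiont_2": 12.0},
    )
    return {
        "hapA": hapA,
        "hapB": hapB,
        "host_truth": host_truth,
        "symbionts": symbionts,
        "members": members,
        "reads": reads,
        "truth": truth,
        "contigs": contigs,
        "depth_table": depth_table,
    }


@pytest.fixture(scope="session")
def community_kmer_table(small_community):
    return spectrum.count_kmers([small_community["reads"].codes], 21)


@pytest.fixture(scope="session")
def community_contig_records(small_community):
    return [
        binning.ContigRecord.from_sequence(cid, seq, truth_label=gid)
        for cid, seq, gid in small_community["contigs"]
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(7)
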