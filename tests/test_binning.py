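"""Tetranucleotide features, composition+coverage binning, bin
evaluation, host selection and read recruitment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from holopipe import _dna, binning, simulate, spectrum
from holopipe.binning import (
    Bin,
    BinningResult,
    ContigRecord,
    bin_contigs,
    contig_depth_from_kmers,
    evaluate_bins,
    recruit_reads,
    select_host_bins,
    tnf_vector,
)
from holopipe.errors import ValidationError

dna_seq = st.text(alphabet="ACGT", min_size=4, max_size=80)


def _brute_force_tnf(seq):
    """Independent oracle: enumerate 4-windows, merge with reverse
    complements by string comparison."""
    counts = {}
    for i in range(len(seq) - 3):
        w = seq[i : i + 4]
        if any(ch not in "ACGT" for ch in w):
            continue
        rc = _dna.revcomp(w)
        key = min(w, rc)
        counts[key] = counts.get(key, 0) + 1
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


class TestTNF:
    def test_homopolymer(self):
        v = tnf_vector("AAAA")
        assert v.sum() == pytest.approx(1.0)
        assert v.max() == 1.0 and (v > 0).sum() == 1

    def test_brute_force_example(self):
        # ACGTACGT: windows ACGT, CGTA, GTAC, TACG, ACGT
        v = tnf_vector("ACGTACGT")
        expected = _brute_force_tnf("ACGTACGT")
        assert sorted(expected.values()) == [1 / 5, 2 / 5, 2 / 5]
        nonzero = sorted(v[v > 0])
        assert nonzero == pytest.approx([1 / 5, 2 / 5, 2 / 5])

    @given(dna_seq)
    @settings(max_examples=100, deadline=None)
    def test_reverse_complement_symmetry(self, s):
        assert np.allclose(tnf_vector(s), tnf_vector(_dna.revcomp(s)))

    @given(dna_seq)
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force(self, s):
        v = tnf_vector(s)
        oracle = _brute_force_tnf(s)
        # compare the multisets of nonzero frequencies
        assert sorted(v[v > 1e-12]) == pytest.approx(sorted(oracle.values()))

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            tnf_vector("ACG")
        with pytest.raises(ValidationError):
            tnf_vector("ANNNC")


class TestContigDepth:
    def test_uniform_multiplicity(self, rng):
        contig = _dna.decode(rng.integers(0, 4, 500).astype(np.uint8))
        table = spectrum.count_kmers([contig] * 30, 15)
        rec = ContigRecord.from_sequence("c", contig)
        assert contig_depth_from_kmers(rec, table) == 30.0

    def test_absent_contig_scores_zero(self):
        table = spectrum.count_kmers(["ACGTACGTACGTAGT"], 7)
        assert contig_depth_from_kmers("TTTTTTTTTTTTTTTT", table) == 0.0

    def test_recovers_planted_depth(self, small_community, community_kmer_table, community_contig_records):
        # error-free depth surrogate is biased low by the read-edge factor
        # (L-k+1)/L ~ 0.87 at L=150,k=21; require agreement within 15%
        # after correcting for it
        depth_table = small_community["depth_table"]
        edge = (150 - 21 + 1) / 150
        rel_errs = []
        for c in community_contig_records:
            if c.length < 5000:
                continue
            est = contig_depth_from_kmers(c, community_kmer_table)
            rel_errs.append(abs(est / edge - depth_table[c.id]) / depth_table[c.id])
        assert np.median(rel_errs) < 0.15


def _toy_contigs(rng, n, length, gc, label, prefix):
    out = []
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    for i in range(n):
        seq = _dna.decode(rng.choice(4, size=length, p=p).astype(np.uint8))
        out.append(ContigRecord.from_sequence(f"{prefix}{i}", seq, truth_label=label))
    return out


class TestBinContigs:
    def test_single_contig_single_bin(self, rng):
        contigs = _toy_contigs(rng, 1, 30_000, 0.4, "g", "c")
        res = bin_contigs(contigs, {"c0": 10.0}, min_bin_size=20_000)
        assert len(res.bins) == 1 and res.bins[0].contig_ids == ["c0"]

    def test_identical_contigs_share_a_bin(self, rng):
        base = _toy_contigs(rng, 1, 30_000, 0.5, "g", "c")[0]
        contigs = [
            ContigRecord.from_sequence(f"c{i}", base.sequence, truth_label="g")
            for i in range(4)
        ]
        res = bin_contigs(contigs, {c.id: 15.0 for c in contigs}, min_bin_size=20_000)
        assert len(res.bins) == 1
        assert sorted(res.bins[0].contig_ids) == [c.id for c in contigs]

    def test_empty_input(self):
        res = bin_contigs([], {})
        assert res.bins == [] and res.unbinned == []

    def test_partition_invariant(self, community_contig_records, small_community):
        res = bin_contigs(
            community_contig_records, small_community["depth_table"], min_bin_size=20_000
        )
        binned = [cid for b in res.bins for cid in b.contig_ids]
        all_ids = binned + res.unbinned
        assert sorted(all_ids) == sorted(c.id for c in community_contig_records)
        assert len(all_ids) == len(set(all_ids))

    def test_tau_monotonicity(self, rng):
        contigs = _toy_contigs(rng, 6, 25_000, 0.40, "a", "a") + _toy_contigs(
            rng, 6, 25_000, 0.55, "b", "b"
        )
        depths = {c.id: (30.0 if c.truth_label == "a" else 12.0) for c in contigs}
        n_components = []
        for tau in (0.01, 0.03, 0.06, 0.2, 1.0):
            res = bin_contigs(contigs, depths, tau=tau, min_bin_size=1)
            n_components.append(len(res.bins))
        assert all(a >= b for a, b in zip(n_components, n_components[1:]))

    def test_label_renaming_preserves_structure(self, rng):
        contigs = _toy_contigs(rng, 4, 25_000, 0.4, "a", "c") + _toy_contigs(
            rng, 4, 25_000, 0.6, "b", "d"
        )
        depths = {c.id: 20.0 for c in contigs}
        res1 = bin_contigs(contigs, depths, min_bin_size=1)
        renamed = [
            ContigRecord(
                id="x_" + c.id, sequence=c.sequence, length=c.length,
                gc=c.gc, tnf=c.tnf, truth_label=c.truth_label,
            )
            for c in contigs
        ]
        res2 = bin_contigs(renamed, {"x_" + c.id: 20.0 for c in contigs}, min_bin_size=1)
        structure1 = sorted(tuple(sorted(b.contig_ids)) for b in res1.bins)
        structure2 = sorted(
            tuple(sorted(cid[2:] for cid in b.contig_ids)) for b in res2.bins
        )
        assert structure1 == structure2

    def test_separation_improves_with_gc_gap(self, rng):
        # binning F1 for a two-genome community is non-decreasing as the
        # compositional gap grows (5 -> 10 -> 20 GC points)
        f1s = []
        for dgc in (0.05, 0.10, 0.20):
            host = _toy_contigs(rng, 20, 10_000, 0.40, "host", f"h{int(dgc*100)}_")
            sym = _toy_contigs(rng, 8, 10_000, 0.40 + dgc, "sym", f"s{int(dgc*100)}_")
            contigs = host + sym
            depths = {c.id: (50.0 if c.truth_label == "host" else 18.0) for c in contigs}
            res = bin_contigs(contigs, depths, min_bin_size=20_000)
            ev = evaluate_bins(res, contigs)
            host_rec = ev.best_for_label("host")
            f1s.append(host_rec.f1 if host_rec else 0.0)
        assert all(a <= b + 1e-9 for a, b in zip(f1s, f1s[1:]))
        assert f1s[-1] >= 0.95


class TestEvaluateBins:
    def test_perfect_bins(self, rng):
        contigs = _toy_contigs(rng, 3, 30_000, 0.4, "a", "a") + _toy_contigs(
            rng, 3, 30_000, 0.65, "b", "b"
        )
        depths = {c.id: (40.0 if c.truth_label == "a" else 10.0) for c in contigs}
        res = bin_contigs(contigs, depths, min_bin_size=1)
        ev = evaluate_bins(res, contigs)
        assert len(ev.records) == 2
        for r in ev.records:
            assert r.precision == r.recall == r.f1 == 1.0

    def test_mixed_bin_arithmetic(self, rng):
        # bin holds 80 kb of A and 20 kb of B; A totals 100 kb
        a = _toy_contigs(rng, 4, 20_000, 0.4, "A", "a")
        b = _toy_contigs(rng, 1, 20_000, 0.6, "B", "b")
        extra_a = _toy_contigs(rng, 1, 20_000, 0.4, "A", "xa")
        result = BinningResult(
            bins=[
                Bin("bin_001", [c.id for c in a + b], 100_000, 0.44, 10.0),
            ],
            unbinned=[c.id for c in extra_a],
        )
        ev = evaluate_bins(result, a + b + extra_a)
        rec = ev.records[0]
        assert rec.majority_label == "A"
        assert rec.precision == pytest.approx(0.8)
        assert rec.recall == pytest.approx(0.8)
        assert rec.f1 == pytest.approx(0.8)

    def test_random_assignment_has_half_precision(self):
        # two equal genomes, contigs assigned to two bins at random:
        # expected majority precision ~0.5 (+ a margin for the upward
        # bias of the majority share at finite bin size)
        precisions = []
        for seed in range(20):
            local = np.random.default_rng(seed)
            contigs = [
                ContigRecord(
                    id=f"s{seed}_{g}{i}", sequence="", length=5_000,
                    gc=0.5, tnf=np.zeros(136), truth_label=g,
                )
                for g in ("a", "b")
                for i in range(60)
            ]
            assign = local.integers(0, 2, size=len(contigs))
            bins = []
            for bid in (0, 1):
                ids = [c.id for c, g in zip(contigs, assign) if g == bid]
                if ids:
                    bins.append(Bin(f"bin_{bid}", ids, 5_000 * len(ids), 0.5, 1.0))
            result = BinningResult(bins=bins, unbinned=[])
            ev = evaluate_bins(result, contigs)
            precisions.extend(r.precision for r in ev.records)
        assert abs(float(np.mean(precisions)) - 0.5) < 0.1


class TestSelectHostBins:
    def _result(self, specs):
        bins = [
            Bin(f"bin_{i}", [f"c{i}"], spec["len"], spec["gc"], spec["depth"])
            for i, spec in enumerate(specs)
        ]
        return BinningResult(bins=bins, unbinned=[])

    def test_single_bin_selected_both_modes(self, rng):
        contigs = _toy_contigs(rng, 2, 30_000, 0.4, "host", "c")
        depths = {c.id: 50.0 for c in contigs}
        res = bin_contigs(contigs, depths, min_bin_size=1)
        ev = evaluate_bins(res, contigs)
        assert select_host_bins(res, "heuristic") == {res.bins[0].bin_id}
        assert select_host_bins(res, "truth", host_label="host", evaluation=ev) == {
            res.bins[0].bin_id
        }

    def test_heuristic_gathers_similar_bins(self):
        res = self._result(
            [
                {"len": 300_000, "gc": 0.40, "depth": 60.0},
                {"len": 150_000, "gc": 0.41, "depth": 55.0},
                {"len": 120_000, "gc": 0.39, "depth": 70.0},
                {"len": 200_000, "gc": 0.62, "depth": 15.0},
            ]
        )
        assert select_host_bins(res, "heuristic") == {"bin_0", "bin_1", "bin_2"}

    def test_empty_result(self):
        assert select_host_bins(BinningResult([], []), "heuristic") == set()


class TestRecruitReads:
    def test_verbatim_host_read_recruited(self, rng):
        host = _dna.decode(rng.integers(0, 4, 5000).astype(np.uint8))
        read = host[1000:1150]
        host_ids, other_ids, _ = recruit_reads(
            [("r1", read)], [host], k=21, theta=1.0
        )
        assert host_ids == ["r1"] and other_ids == []

    def test_foreign_read_not_recruited(self, rng):
        host = _dna.decode(rng.integers(0, 4, 5000).astype(np.uint8))
        foreign = _dna.decode(rng.integers(0, 4, 150).astype(np.uint8))
        host_ids, other_ids, _ = recruit_reads(
            [("r1", foreign)], [host], k=21, theta=0.3
        )
        assert host_ids == [] and other_ids == ["r1"]

    def test_theta_monotonicity(self, small_community, community_contig_records):
        host_seqs = [c.sequence for c in community_contig_records if c.truth_label == "host"]
        reads = small_community["reads"]
        sizes = []
        for theta in (0.2, 0.5, 0.8, 1.0):
            mask, _ = recruit_reads(reads, host_seqs, k=21, theta=theta)
            sizes.append(int(mask.sum()))
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_community_recruitment_accuracy(self, small_community, community_contig_records):
        host_seqs = [c.sequence for c in community_contig_records if c.truth_label == "host"]
        reads = small_community["reads"]
        mask, stats = recruit_reads(reads, host_seqs, k=21, theta=0.5)
        truth_host = reads.origins == reads.member_ids.index("host")
        tp = int((mask & truth_host).sum())
        assert tp / max(int(mask.sum()), 1) >= 0.9
        assert tp / int(truth_host.sum()) >= 0.9

    def test_empty_host_set_rejected(self):
        with pytest.raises(ValidationError):
            recruit_reads([("r", "ACGT" * 50)], [], k=21, theta=0.5)

    def test_bad_theta_rejected(self, rng):
        host = _dna.decode(rng.integers(0, 4, 1000).astype(np.uint8))
        with pytest.raises(ValidationError):
            recruit_reads([("r", host[:100])], [host], k=21, theta=0.0)
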