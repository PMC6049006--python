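"""End-to-end orchestration: simulate -> count -> spectrum -> bin ->
recruit -> assess, with every intermediate written in its standard
format and a JSON run report.

All randomness flows from the single config seed through per-stage
seeds derived with ``numpy.random.SeedSequence``, so a rerun with the
same config reproduces every output byte for byte.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import __version__, binning, io, simulate, spectrum
from .assessment import assembly_metrics, marker_recovery
from .config import PipelineConfig
from .errors import HolopipeError, StageError

HOST_ID = "host"


def _stage_seed(children: list[np.random.SeedSequence], index: int) -> int:
    return int(children[index].generate_state(1)[0] & 0x7FFFFFFF)


def run_pipeline(cfg: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run the configured stages in order, returning the run report dict.

    Stage failures raise :class:`StageError` naming the stage; outputs
    written before the failure are retained.
    """
    out = Path(outdir if outdir is not None else cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(cfg.seed).spawn(8)
    report: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "profile": cfg.profile,
        "params": cfg.model_dump(),
        "stages": {},
    }
    state: dict = {}
    runners = {
        "simulate": _run_simulate,
        "count": _run_count,
        "spectrum": _run_spectrum,
        "bin": _run_bin,
        "recruit": _run_recruit,
        "assess": _run_assess,
    }
    for stage in cfg.stages:
        if stage not in runners:
            raise StageError(stage, "unknown stage")
        try:
            report["stages"][stage] = runners[stage](cfg, root, out, state)
        except HolopipeError as exc:
            raise StageError(stage, str(exc)) from exc
    io.write_json(report, out / "report.json")
    return report


def _run_simulate(cfg: PipelineConfig, root, out: Path, state: dict) -> dict:
    sc = cfg.simulate
    hapA, hapB, host_truth = simulate.simulate_host_genome(
        haploid_length=sc.host_length,
        het_rate=sc.host_het_rate,
        repeat_fraction=sc.host_repeat_fraction,
        repeat_unit_length=sc.host_repeat_unit_length,
        seed=_stage_seed(root, 0),
        gc=sc.host_gc,
    )
    symbionts = simulate.simulate_symbiont_genomes(
        n=len(sc.symbiont_lengths),
        lengths=sc.symbiont_lengths,
        gc_targets=sc.symbiont_gcs,
        seed=_stage_seed(root, 1),
    )
    members = [
        simulate.CommunityMember(
            genome_id=HOST_ID, sequences=(hapA, hapB),
            mean_depth=sc.host_depth, gc_target=sc.host_gc,
        )
    ] + [
        simulate.CommunityMember(
            genome_id=gid, sequences=(seq,), mean_depth=depth, gc_target=gc
        )
        for (gid, seq), depth, gc in zip(symbionts, sc.symbiont_depths, sc.symbiont_gcs)
    ]
    reads, truth = simulate.simulate_reads(
        members,
        read_length=sc.read_length,
        error_rate=sc.error_rate,
        paired=sc.paired,
        insert_size=sc.insert_size,
        seed=_stage_seed(root, 2),
    )
    genomes = [(HOST_ID, hapA)] + symbionts
    depths_by_genome = {HOST_ID: sc.host_depth}
    depths_by_genome.update(
        {gid: d for (gid, _), d in zip(symbionts, sc.symbiont_depths)}
    )
    contigs, depth_table = simulate.fragment_genomes(
        genomes,
        target_n50=sc.contig_n50,
        min_length=sc.contig_min_length,
        seed=_stage_seed(root, 3),
        depths=depths_by_genome,
    )
    io.write_fasta([(HOST_ID + "_hapA", hapA), (HOST_ID + "_hapB", hapB)], out / "host_genome.fasta")
    io.write_fasta(symbionts, out / "symbiont_genomes.fasta")
    io.write_fastq(reads.iter_records(), out / "reads.fastq")
    io.write_truth_table(truth.read_origins, out / "read_truth.tsv")
    io.write_fasta(
        [(io.contig_header(cid, gid), seq) for cid, seq, gid in contigs],
        out / "contigs.fasta",
    )
    io.write_truth_table(
        {cid: gid for cid, _, gid in contigs}, out / "contig_truth.tsv",
        extra=depth_table,
    )
    io.write_depth_table(depth_table, out / "contig_depth.tsv")
    state.update(
        reads=reads, truth=truth, contigs=contigs, depth_table=depth_table,
        host_truth=host_truth, host_hapA=hapA, members=members,
    )
    return {
        "n_reads": len(reads),
        "n_contigs": len(contigs),
        "host_haploid_length": host_truth.haploid_length,
        "host_het_sites": int(host_truth.het_positions.size),
        "host_repeat_bases": host_truth.repeat_bases,
        "members": truth.members,
    }


def _run_count(cfg: PipelineConfig, root, out: Path, state: dict) -> dict:
    reads = state["reads"]
    table = spectrum.count_kmers([reads.codes], cfg.spectrum.k)
    hist = spectrum.build_histogram(table)
    io.write_histogram(hist, out / f"kmer_{cfg.spectrum.k}.histo")
    state.update(kmer_table=table, histogram=hist)
    return {"k": cfg.spectrum.k, "distinct_kmers": hist.D, "total_kmers": hist.T}


def _run_spectrum(cfg: PipelineConfig, root, out: Path, state: dict) -> dict:
    mask = state.get("recruit_mask")
    if mask is not None:
        # genomic features from the binned host reads (the point of the
        # whole exercise: symbiont k-mers would inflate every estimate)
        reads = state["reads"]
        table = spectrum.count_kmers([reads.codes[mask]], cfg.spectrum.k)
        hist = spectrum.build_histogram(table)
        io.write_histogram(hist, out / f"kmer_host_{cfg.spectrum.k}.histo")
    else:
        hist = state["histogram"]
    res = spectrum.analyze_spectrum(
        hist,
        error_cutoff=cfg.spectrum.error_cutoff,
        repeat_cutoff=cfg.spectrum.repeat_cutoff,
        smoothing_window=cfg.spectrum.smoothing_window,
        m_poisson=cfg.spectrum.m_poisson,
        m_nb=cfg.spectrum.m_nb,
    )
    summary = {
        "k": res["k"],
        "error_cutoff": res["error_cutoff"],
        "lambda_het": res["lambda_het"],
        "c_hom": res["c_hom"],
        "unimodal": res["unimodal"],
        "repeat_cutoff": res["repeat_cutoff"],
        "genome_size_waterman": res["waterman"],
        "genome_size_poisson_em": res["poisson_em"].genome_size,
        "genome_size_nb_mixture": res["nb_mixture"].genome_size,
        "genome_size_median": res["genome_size_median"],
        "genome_size_sd": res["genome_size_sd"],
        "het_rate_nb": res["nb_mixture"].het_rate,
        "p_het_nb": res["nb_mixture"].p_het,
        "error_fraction": res["error_fraction"],
        "repeat_fraction": res["repeat_fraction"],
    }
    io.write_json(summary, out / "spectrum.json")
    state["spectrum_summary"] = summary
    return summary


def _run_bin(cfg: PipelineConfig, root, out: Path, state: dict) -> dict:
    bc = cfg.binning
    contigs = [
        binning.ContigRecord.from_sequence(cid, seq, truth_label=gid)
        for cid, seq, gid in state["contigs"]
        if len(seq) >= binning.TNF_K
    ]
    table = state.get("kmer_table")
    if table is not None:
        depths = binning.depth_profile(
            [c for c in contigs if c.length >= table.k], table
        )
        depths.update(
            {c.id: state["depth_table"][c.id] for c in contigs if c.id not in depths}
        )
    else:
        depths = dict(state["depth_table"])
    result = binning.bin_contigs(
        contigs, depths,
        w=bc.w, tau=bc.tau,
        min_bin_size=bc.min_bin_size, min_contig_length=bc.min_contig_length,
    )
    evaluation = binning.evaluate_bins(result, contigs)
    host_bins = binning.select_host_bins(
        result,
        mode=bc.host_mode,
        host_label=HOST_ID,
        evaluation=evaluation,
        gc_window=bc.gc_window,
        depth_factor=bc.depth_factor,
    )
    by_id = {c.id: c for c in contigs}
    bins_dir = out / "bins"
    bins_dir.mkdir(exist_ok=True)
    for b in result.bins:
        io.write_fasta(
            [(cid, by_id[cid].sequence) for cid in b.contig_ids],
            bins_dir / f"{b.bin_id}.fasta",
        )
    eval_by_bin = {r.bin_id: r for r in evaluation.records}
    with open(out / "bin_summary.tsv", "w") as fh:
        fh.write(
            "bin_id\tn_contigs\ttotal_length\tmean_gc\tmean_depth\t"
            "majority_label\tprecision\trecall\tf1\tis_host\n"
        )
        for b in result.bins:
            r = eval_by_bin[b.bin_id]
            fh.write(
                f"{b.bin_id}\t{len(b.contig_ids)}\t{b.total_length}\t"
                f"{b.mean_gc:.4f}\t{b.mean_depth:.2f}\t{r.majority_label}\t"
                f"{r.precision:.4f}\t{r.recall:.4f}\t{r.f1:.4f}\t"
                f"{int(b.bin_id in host_bins)}\n"
            )
    state.update(
        contig_records=contigs, bin_result=result,
        bin_evaluation=evaluation, host_bins=host_bins,
    )
    host_rec = evaluation.best_for_label(HOST_ID)
    return {
        "n_bins": len(result.bins),
        "n_unbinned": len(result.unbinned),
        "host_bins": sorted(host_bins),
        "host_bin_f1": host_rec.f1 if host_rec else None,
        "host_bin_precision": host_rec.precision if host_rec else None,
        "host_bin_recall": host_rec.recall if host_rec else None,
    }


def _run_recruit(cfg: PipelineConfig, root, out: Path, state: dict) -> dict:
    rc = cfg.recruit
    result = state["bin_result"]
    host_bins = state["host_bins"]
    by_id = {c.id: c for c in state["contig_records"]}
    host_seqs = [
        by_id[cid].sequence
        for b in result.bins
        if b.bin_id in host_bins
        for cid in b.contig_ids
    ]
    reads = state["reads"]
    mask, stats = binning.recruit_reads(reads, host_seqs, k=rc.k, theta=rc.theta)
    recruited = (
        (rid, seq, q) for (rid, seq, q), keep in zip(reads.iter_records(), mask) if keep
    )
    others = (
        (rid, seq, q) for (rid, seq, q), keep in zip(reads.iter_records(), mask) if not keep
    )
    io.write_fastq(recruited, out / "recruited.fastq")
    io.write_fastq(others, out / "other.fastq")
    truth_host = reads.origins == reads.member_ids.index(HOST_ID)
    tp = int((mask & truth_host).sum())
    stats["precision_vs_truth"] = tp / max(int(mask.sum()), 1)
    stats["recall_vs_truth"] = tp / max(int(truth_host.sum()), 1)
    io.write_json(stats, out / "recruit_stats.json")
    state["recruit_mask"] = mask
    return stats


def _run_assess(cfg: PipelineConfig, root, out: Path, state: dict) -> dict:
    ac = cfg.assess
    result = state["bin_result"]
    host_bins = state["host_bins"]
    by_id = {c.id: c for c in state["contig_records"]}
    scaffolds = [
        (cid, by_id[cid].sequence)
        for b in result.bins
        if b.bin_id in host_bins
        for cid in b.contig_ids
    ]
    if not scaffolds:
        raise StageError("assess", "no host bins to assess")
    gsize = int(round(state["spectrum_summary"]["genome_size_median"])) if "spectrum_summary" in state else None
    metrics = assembly_metrics(
        scaffolds, genome_size_estimate=gsize, n_split=ac.n_split, name="host_draft"
    )
    rng = np.random.default_rng(_stage_seed(root, 4))
    hapA = state["host_hapA"]
    markers = []
    for i in range(ac.n_markers):
        start = int(rng.integers(0, len(hapA) - ac.marker_length + 1))
        markers.append((f"marker_{i + 1:03d}", hapA[start : start + ac.marker_length]))
    recovery = marker_recovery(
        markers, scaffolds, k=ac.marker_k, complete_threshold=ac.marker_complete_threshold
    )
    summary = {k: (v if not isinstance(v, dict) else v) for k, v in metrics.__dict__.items()}
    summary.update(
        markers_complete=recovery.n_complete,
        markers_fragmented=recovery.n_fragmented,
        markers_missing=recovery.n_missing,
    )
    io.write_json(summary, out / "assembly_metrics.json")
    return summary
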