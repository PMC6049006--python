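"""Synthetic holobiont data with known ground truth.

The generator emulates the sequencing side of a hologenomic study: a
diploid host genome with tunable heterozygosity and repeat content,
several symbiont genomes of distinct base composition and abundance,
uniform-coverage paired short reads with a flat substitution error, and
fragmented contigs with per-contig truth labels and planted depths.
Every stage is deterministic given its seed.

Model choices (documented, not inferred from any particular dataset):
uppercase ACGT alphabet only; substitutions uniform over the three
alternative bases; repeats planted as dispersed copies (default 10 per
family) of units drawn once per family, which puts repeat k-mers well
past four times the homozygous depth; constant Q40 base qualities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import Iterator, Sequence

import numpy as np

from . import _dna
from .errors import ValidationError

QUALITY_CHAR = "I"  # Q40


@dataclass
class HostGenomeTruth:
    """Planted parameters of a simulated diploid host genome."""

    haploid_length: int
    het_rate: float
    repeat_fraction: float
    repeat_unit_length: int
    het_positions: np.ndarray
    seed: int
    repeat_bases: int = 0
    n_repeat_families: int = 0
    repeats_planted: bool = False


@dataclass
class CommunityMember:
    """One genome in a simulated community, with its haplotype sequences."""

    genome_id: str
    sequences: tuple[str, ...]  # 1 (haploid) or 2 (diploid) haplotypes
    mean_depth: float
    gc_target: float | None = None

    @property
    def ploidy(self) -> int:
        return len(self.sequences)

    @property
    def haploid_length(self) -> int:
        return len(self.sequences[0])


@dataclass
class CommunityTruth:
    """Who is in the sample and where every read came from."""

    members: list[tuple[str, int, int, float, float]]  # id, ploidy, len, gc, depth
    read_origins: dict[str, str] = field(default_factory=dict)


class ReadSet:
    """Simulated reads held as a dense 2D code matrix (one row per read).

    All reads share one length, which keeps k-mer counting and
    recruitment fully vectorized; ``iter_records`` decodes to
    (id, sequence, quality) tuples for FASTQ emission.  When ``paired``
    is set, mates occupy adjacent rows (2i, 2i+1) and ids carry /1, /2
    suffixes.
    """

    def __init__(
        self,
        codes: np.ndarray,
        origins: np.ndarray,
        member_ids: list[str],
        paired: bool,
    ):
        self.codes = codes
        self.origins = origins  # int index into member_ids, per read
        self.member_ids = member_ids
        self.paired = paired

    def __len__(self) -> int:
        return self.codes.shape[0]

    @property
    def read_length(self) -> int:
        return self.codes.shape[1]

    def read_id(self, i: int) -> str:
        gid = self.member_ids[self.origins[i]]
        if self.paired:
            return f"{gid}_f{i // 2}/{i % 2 + 1}"
        return f"{gid}_r{i}"

    def iter_records(self) -> Iterator[tuple[str, str, str]]:
        qual = QUALITY_CHAR * self.read_length
        for i in range(len(self)):
            yield self.read_id(i), _dna.decode(self.codes[i]), qual

    def origin_of(self, i: int) -> str:
        return self.member_ids[self.origins[i]]

    def truth(self) -> dict[str, str]:
        return {self.read_id(i): self.origin_of(i) for i in range(len(self))}


# ---------------------------------------------------------------------------
# host genome


def _random_codes(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def simulate_host_genome(
    haploid_length: int,
    het_rate: float = 0.005,
    repeat_fraction: float = 0.15,
    repeat_unit_length: int = 500,
    seed: int = 0,
    gc: float = 0.4,
    copies_per_family: int = 10,
) -> tuple[str, str, HostGenomeTruth]:
    """Simulate a diploid host genome as two haplotype strings plus truth.

    Haplotype B is haplotype A with substitutions drawn independently per
    base at ``het_rate`` (never substituting a base for itself).  Repeats
    are planted by overwriting the random background with dispersed
    copies of per-family units until ``repeat_fraction`` of the haploid
    length is repeat sequence (within the granularity of one unit).
    """
    if not np.isfinite(het_rate) or not 0 <= het_rate < 1:
        raise ValidationError(f"het_rate must be in [0,1), got {het_rate}")
    if not np.isfinite(repeat_fraction) or not 0 <= repeat_fraction <= 0.9:
        raise ValidationError(f"repeat_fraction must be in [0,0.9], got {repeat_fraction}")
    if repeat_unit_length >= haploid_length:
        raise ValidationError("repeat_unit_length must be < haploid_length")
    if haploid_length < 1:
        raise ValidationError("haploid_length must be positive")
    rng = np.random.default_rng(seed)
    hapA = _random_codes(rng, haploid_length, gc)

    repeat_bases = 0
    n_families = 0
    if repeat_fraction > 0:
        target = int(round(repeat_fraction * haploid_length))
        u = repeat_unit_length
        n_families = ceil(target / (copies_per_family * u))
        occupied = np.zeros(haploid_length, dtype=bool)
        for _ in range(n_families):
            unit = _random_codes(rng, u, gc)
            copies = min(copies_per_family, ceil((target - repeat_bases) / u))
            placed = 0
            attempts = 0
            while placed < copies and attempts < 200 * copies:
                start = int(rng.integers(0, haploid_length - u + 1))
                attempts += 1
                if occupied[start : start + u].any():
                    continue
                hapA[start : start + u] = unit
                occupied[start : start + u] = True
                placed += 1
                repeat_bases += u
            if repeat_bases >= target:
                break

    if het_rate > 0:
        het_mask = rng.random(haploid_length) < het_rate
        het_positions = np.flatnonzero(het_mask)
    else:
        het_positions = np.empty(0, dtype=np.int64)
    hapB = hapA.copy()
    if het_positions.size:
        shift = rng.integers(1, 4, size=het_positions.size).astype(np.uint8)
        hapB[het_positions] = (hapB[het_positions] + shift) % 4

    truth = HostGenomeTruth(
        haploid_length=haploid_length,
        het_rate=het_rate,
        repeat_fraction=repeat_fraction,
        repeat_unit_length=repeat_unit_length,
        het_positions=het_positions,
        seed=seed,
        repeat_bases=repeat_bases,
        n_repeat_families=n_families,
        repeats_planted=repeat_bases > 0,
    )
    return _dna.decode(hapA), _dna.decode(hapB), truth


# ---------------------------------------------------------------------------
# symbiont genomes


def _markov_sequence(
    rng: np.random.Generator, length: int, gc_target: float
) -> np.ndarray:
    """Order-2 Markov chain with per-genome random transitions, tilted to GC.

    The transition table is drawn once (Dirichlet noise on top of
    GC-consistent base weights) so tetranucleotide profiles differ
    between genomes; a scalar GC tilt is adjusted over a few rounds
    until the realized GC is within half a point of the target.
    """
    base_w = np.array(
        [(1 - gc_target) / 2, gc_target / 2, gc_target / 2, (1 - gc_target) / 2]
    )
    noise = rng.dirichlet(np.ones(4) * 1.5, size=16)  # one row per 2-mer context
    is_gc = np.array([0.0, 1.0, 1.0, 0.0])
    tilt = 0.0
    seq = None
    for _ in range(8):
        w = noise * base_w[None, :] * np.exp(tilt * is_gc)[None, :]
        cum = np.cumsum(w / w.sum(axis=1, keepdims=True), axis=1)
        u = rng.random(length)
        out = np.empty(length, dtype=np.uint8)
        a, b = int(rng.integers(4)), int(rng.integers(4))
        out[0], out[1] = a, b
        cum_list = cum.tolist()
        uu = u.tolist()
        prev2, prev1 = a, b
        for i in range(2, length):
            row = cum_list[(prev2 << 2) | prev1]
            x = uu[i]
            nxt = 0 if x < row[0] else 1 if x < row[1] else 2 if x < row[2] else 3
            out[i] = nxt
            prev2, prev1 = prev1, nxt
        seq = out
        gc_real = _dna.gc_fraction(seq)
        if abs(gc_real - gc_target) <= 0.005:
            break
        # logit-scale correction toward the target
        tilt += np.log(
            (gc_target / (1 - gc_target)) / max(gc_real / (1 - gc_real), 1e-9)
        )
    return seq


def simulate_symbiont_genomes(
    n: int,
    lengths: Sequence[int],
    gc_targets: Sequence[float],
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Simulate ``n`` haploid symbiont genomes with distinct compositions."""
    if len(lengths) != n or len(gc_targets) != n:
        raise ValidationError("lengths and gc_targets must have n entries")
    for gc in gc_targets:
        if not 0 < gc < 1:
            raise ValidationError(f"gc_target must be in (0,1), got {gc}")
    root = np.random.SeedSequence(seed)
    out = []
    for i, child in enumerate(root.spawn(n)):
        rng = np.random.default_rng(child)
        codes = _markov_sequence(rng, int(lengths[i]), float(gc_targets[i]))
        out.append((f"symbiont_{i + 1}", _dna.decode(codes)))
    return out


# ---------------------------------------------------------------------------
# reads


def simulate_reads(
    members: Sequence[CommunityMember],
    read_length: int = 250,
    error_rate: float = 0.005,
    paired: bool = True,
    insert_size: int = 600,
    seed: int = 0,
) -> tuple[ReadSet, CommunityTruth]:
    """Uniform-coverage shotgun reads from a community of genomes.

    Per member, ``round(mean_depth * haploid_length / read_length)``
    reads are drawn (split evenly across haplotypes for diploids, so each
    haplotype sees half the nominal depth).  Errors are uniform random
    substitutions at ``error_rate`` per base; qualities are constant.
    """
    if not 0 <= error_rate <= 0.1:
        raise ValidationError(f"error_rate must be in [0, 0.1], got {error_rate}")
    if paired and insert_size < read_length:
        raise ValidationError("insert_size must be >= read_length for paired reads")
    for mb in members:
        if mb.mean_depth <= 0:
            raise ValidationError(f"mean_depth must be positive for {mb.genome_id}")
        if read_length > mb.haploid_length:
            raise ValidationError(
                f"read_length {read_length} exceeds genome {mb.genome_id}"
            )
        if paired and insert_size > mb.haploid_length:
            raise ValidationError(
                f"insert_size {insert_size} exceeds genome {mb.genome_id}"
            )
    root = np.random.SeedSequence(seed)
    blocks: list[np.ndarray] = []
    origin_blocks: list[np.ndarray] = []
    member_ids = [mb.genome_id for mb in members]
    for mi, (mb, child) in enumerate(zip(members, root.spawn(len(members)))):
        rng = np.random.default_rng(child)
        n_reads = int(round(mb.mean_depth * mb.haploid_length / read_length))
        haps = [_dna.encode(s) for s in mb.sequences]
        per_hap = _split_even(n_reads, len(haps), pair_step=2 if paired else 1)
        for hap, n_h in zip(haps, per_hap):
            if n_h == 0:
                continue
            block = _draw_reads(rng, hap, n_h, read_length, paired, insert_size)
            if error_rate > 0:
                _apply_errors(rng, block, error_rate)
            blocks.append(block)
            origin_blocks.append(np.full(block.shape[0], mi, dtype=np.int32))
    if blocks:
        codes = np.concatenate(blocks, axis=0)
        origins = np.concatenate(origin_blocks)
    else:
        codes = np.empty((0, read_length), dtype=np.uint8)
        origins = np.empty(0, dtype=np.int32)
    reads = ReadSet(codes=codes, origins=origins, member_ids=member_ids, paired=paired)
    truth = CommunityTruth(
        members=[
            (
                mb.genome_id,
                mb.ploidy,
                mb.haploid_length,
                mb.gc_target
                if mb.gc_target is not None
                else _dna.gc_fraction(_dna.encode(mb.sequences[0])),
                mb.mean_depth,
            )
            for mb in members
        ],
        read_origins=reads.truth(),
    )
    return reads, truth


def _split_even(n_reads: int, n_haps: int, pair_step: int) -> list[int]:
    """Split a read budget across haplotypes, keeping pair multiples."""
    base = n_reads // n_haps
    base -= base % pair_step
    counts = [base] * n_haps
    rem = n_reads - base * n_haps
    rem -= rem % pair_step
    i = 0
    while rem > 0:
        counts[i % n_haps] += pair_step
        rem -= pair_step
        i += 1
    return counts


def _draw_reads(
    rng: np.random.Generator,
    genome: np.ndarray,
    n_reads: int,
    read_length: int,
    paired: bool,
    insert_size: int,
) -> np.ndarray:
    L = genome.shape[0]
    if paired:
        n_frag = n_reads // 2
        starts = rng.integers(0, L - insert_size + 1, size=n_frag)
        offs = np.arange(read_length)
        r1 = genome[starts[:, None] + offs[None, :]]
        r2f = genome[(starts + insert_size - read_length)[:, None] + offs[None, :]]
        r2 = (3 - r2f[:, ::-1]).astype(np.uint8)  # reverse strand mate
        out = np.empty((n_frag * 2, read_length), dtype=np.uint8)
        out[0::2] = r1
        out[1::2] = r2
        return out
    starts = rng.integers(0, L - read_length + 1, size=n_reads)
    offs = np.arange(read_length)
    return genome[starts[:, None] + offs[None, :]]


def _apply_errors(rng: np.random.Generator, block: np.ndarray, rate: float) -> None:
    n_err = rng.binomial(block.size, rate)
    if n_err == 0:
        return
    # with-replacement draw: collision odds are ~rate^2 and a doubly hit
    # base is still a valid substitution
    flat = rng.integers(0, block.size, size=n_err)
    shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
    r, c = np.unravel_index(flat, block.shape)
    block[r, c] = (block[r, c] + shift) % 4


# ---------------------------------------------------------------------------
# contigs


# length-weighted median of an exponential with mean mu is ~1.6783*mu
# (solves (1+x)exp(-x)=1/2 for the Gamma(2) tail), so target_n50 maps to
# a mean fragment of target_n50 / 1.6783
_N50_EXP_FACTOR = 1.6783


def fragment_genomes(
    genomes: Sequence[tuple[str, str]],
    target_n50: int,
    min_length: int = 500,
    seed: int = 0,
    depths: dict[str, float] | None = None,
) -> tuple[list[tuple[str, str, str]], dict[str, float]]:
    """Cut genomes into assembly-like contigs with truth labels.

    Contigs partition each input genome exactly (no gap, no overlap);
    cut lengths are exponential with the mean chosen so the realized N50
    lands near ``target_n50``; pieces shorter than ``min_length`` are
    merged into their left neighbor.  Returns ``(contigs, depth_table)``
    where contigs are ``(contig_id, sequence, genome_id)`` and the depth
    table maps contig_id to the planted per-genome depth (1.0 when no
    depths are supplied).
    """
    if min_length < 4:
        raise ValidationError("min_length must be >= 4 (tetranucleotides)")
    if target_n50 < min_length:
        raise ValidationError("target_n50 must be >= min_length")
    rng = np.random.default_rng(seed)
    mu = target_n50 / _N50_EXP_FACTOR
    contigs: list[tuple[str, str, str]] = []
    depth_table: dict[str, float] = {}
    for gid, seq in genomes:
        L = len(seq)
        depth = depths.get(gid, 1.0) if depths else 1.0
        if target_n50 >= L:  # an N50 at/above the genome length means no cuts
            cid = f"{gid}_c00001"
            contigs.append((cid, seq, gid))
            depth_table[cid] = depth
            continue
        cuts = [0]
        while cuts[-1] < L:
            step = max(int(round(rng.exponential(mu))), 1)
            cuts.append(min(cuts[-1] + step, L))
        # merge short pieces leftward
        bounds = [0]
        for b in cuts[1:]:
            bounds.append(b)
        merged = [bounds[0]]
        for b in bounds[1:-1]:
            if b - merged[-1] >= min_length and L - b >= min_length:
                merged.append(b)
        merged.append(L)
        for i in range(len(merged) - 1):
            cid = f"{gid}_c{i + 1:05d}"
            contigs.append((cid, seq[merged[i] : merged[i + 1]], gid))
            depth_table[cid] = depth
    return contigs, depth_table
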