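"""Host/symbiont separation by composition and coverage.

Contigs are embedded in a feature space combining the canonical
tetranucleotide frequency vector (136 classes after reverse-complement
collapsing) with log-scaled per-contig depth.  Pairs closer than a
threshold are linked and connected components become bins — a
deterministic single-linkage rendering of the composition+abundance
principle behind metagenome binners such as MetaBAT, not a clone of any
of them.  Truth-label evaluation, host-bin selection and k-mer-based
read recruitment close the loop back to reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform, pdist

from . import _dna
from .errors import ValidationError
from .spectrum import KmerTable

# ---------------------------------------------------------------------------
# canonical tetranucleotide classes

TNF_K = 4
_N_TETRA = 4**TNF_K


def _rc4(code: int) -> int:
    rc = 0
    for _ in range(TNF_K):
        rc = (rc << 2) | (3 - (code & 3))
        code >>= 2
    return rc


_CANON4 = np.array([min(c, _rc4(c)) for c in range(_N_TETRA)], dtype=np.int64)
_CLASSES = np.unique(_CANON4)  # 136 canonical classes
_CLASS_INDEX = np.full(_N_TETRA, -1, dtype=np.int64)
_CLASS_INDEX[_CLASSES] = np.arange(_CLASSES.shape[0])
N_TNF_CLASSES = int(_CLASSES.shape[0])  # (256-16)/2 + 16 = 136


def tnf_vector(sequence: str | np.ndarray) -> np.ndarray:
    """Canonical tetranucleotide frequency vector (sums to 1).

    Every 4-base window containing only ACGT is counted under its
    canonical class (window merged with its reverse complement; the 16
    palindromic windows stand alone).
    """
    codes = sequence if isinstance(sequence, np.ndarray) else _dna.encode(sequence)
    raw = _dna.kmer_codes(codes, TNF_K) if codes.shape[0] >= TNF_K else np.empty(0, np.int64)
    if raw.shape[0] == 0:
        raise ValidationError("sequence too short or ambiguous for tetranucleotides")
    idx = _CLASS_INDEX[raw]
    counts = np.bincount(idx, minlength=N_TNF_CLASSES).astype(float)
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# types


@dataclass
class ContigRecord:
    """A contig plus its binning features."""

    id: str
    sequence: str
    length: int
    gc: float
    tnf: np.ndarray
    truth_label: str | None = None

    @classmethod
    def from_sequence(
        cls, contig_id: str, sequence: str, truth_label: str | None = None
    ) -> "ContigRecord":
        codes = _dna.encode(sequence)
        return cls(
            id=contig_id,
            sequence=sequence,
            length=len(sequence),
            gc=_dna.gc_fraction(codes),
            tnf=tnf_vector(codes),
            truth_label=truth_label,
        )


CoverageProfile = Mapping[str, float]


@dataclass
class Bin:
    bin_id: str
    contig_ids: list[str]
    total_length: int
    mean_gc: float
    mean_depth: float


@dataclass
class BinningResult:
    bins: list[Bin]
    unbinned: list[str]
    params: dict = field(default_factory=dict)

    def membership(self) -> dict[str, str]:
        out = {}
        for b in self.bins:
            for cid in b.contig_ids:
                out[cid] = b.bin_id
        return out


@dataclass
class BinRecord:
    bin_id: str
    majority_label: str
    precision: float
    recall: float
    f1: float
    total_length: int


@dataclass
class BinEvaluation:
    records: list[BinRecord]

    def best_for_label(self, label: str) -> BinRecord | None:
        cand = [r for r in self.records if r.majority_label == label]
        if not cand:
            return None
        return max(cand, key=lambda r: r.f1)


# ---------------------------------------------------------------------------
# depth from k-mers


def contig_depth_from_kmers(contig: ContigRecord | str, read_kmers: KmerTable) -> float:
    """Median read-set multiplicity of the contig's canonical k-mers.

    A mapping-free depth surrogate: positions whose k-mer never occurs in
    the read set contribute zeros, so an absent contig scores 0.
    """
    seq = contig.sequence if isinstance(contig, ContigRecord) else contig
    codes = _dna.encode(seq)
    if read_kmers.k > codes.shape[0]:
        raise ValidationError("k exceeds contig length")
    canon = _dna.kmer_codes(codes, read_kmers.k)
    if canon.shape[0] == 0:
        return 0.0
    counts = read_kmers.lookup_codes(canon)
    return float(np.median(counts))


def depth_profile(contigs: Iterable[ContigRecord], read_kmers: KmerTable) -> dict[str, float]:
    return {c.id: contig_depth_from_kmers(c, read_kmers) for c in contigs}


# ---------------------------------------------------------------------------
# binning


def bin_contigs(
    contigs: Sequence[ContigRecord],
    depths: CoverageProfile,
    w: float = 0.7,
    tau: float = 0.05,
    min_bin_size: int = 200_000,
    min_contig_length: int = 2000,
) -> BinningResult:
    """Single-linkage binning on combined TNF + log-depth distance.

    ``d(i,j) = w*||tnf_i - tnf_j||_2 +
    (1-w)*|log10(d_i+1) - log10(d_j+1)| / log10(max_depth+1)``; contigs
    with ``d <= tau`` are linked, connected components become bins, and
    components below ``min_bin_size`` total length are left unbinned.
    Deterministic given its inputs.
    """
    if not 0 <= w <= 1:
        raise ValidationError(f"w must be in [0,1], got {w}")
    if not contigs:
        return BinningResult(bins=[], unbinned=[], params=_bin_params(w, tau, min_bin_size, min_contig_length))
    missing = [c.id for c in contigs if c.id not in depths]
    if missing:
        raise ValidationError(f"contigs without depth: {missing[:5]}")
    eligible = [c for c in contigs if c.length >= min_contig_length]
    short_ids = [c.id for c in contigs if c.length < min_contig_length]
    if not eligible:
        return BinningResult(
            bins=[], unbinned=[c.id for c in contigs],
            params=_bin_params(w, tau, min_bin_size, min_contig_length),
        )
    tnf = np.stack([c.tnf for c in eligible])
    d = np.asarray([np.atleast_1d(np.asarray(depths[c.id], dtype=float)).mean() for c in eligible])
    logd = np.log10(d + 1.0)
    norm = max(float(logd.max()), 1e-9)
    dist = w * squareform(pdist(tnf, metric="euclidean"))
    dist += (1 - w) * np.abs(logd[:, None] - logd[None, :]) / norm
    adj = csr_matrix(dist <= tau)
    n_comp, labels = connected_components(adj, directed=False)
    bins: list[Bin] = []
    unbinned = list(short_ids)
    groups: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(i)
    comps = sorted(
        groups.values(), key=lambda idx: (-sum(eligible[i].length for i in idx), idx[0])
    )
    for idx in comps:
        total = sum(eligible[i].length for i in idx)
        if total < min_bin_size:
            unbinned.extend(eligible[i].id for i in idx)
            continue
        lengths = np.array([eligible[i].length for i in idx], dtype=float)
        gcs = np.array([eligible[i].gc for i in idx])
        bins.append(
            Bin(
                bin_id=f"bin_{len(bins) + 1:03d}",
                contig_ids=[eligible[i].id for i in idx],
                total_length=int(total),
                mean_gc=float(np.average(gcs, weights=lengths)),
                mean_depth=float(np.average(d[idx], weights=lengths)),
            )
        )
    return BinningResult(
        bins=bins, unbinned=unbinned,
        params=_bin_params(w, tau, min_bin_size, min_contig_length),
    )


def _bin_params(w, tau, min_bin_size, min_contig_length) -> dict:
    return {
        "w": w, "tau": tau,
        "min_bin_size": min_bin_size, "min_contig_length": min_contig_length,
    }


def evaluate_bins(
    result: BinningResult, contigs: Sequence[ContigRecord]
) -> BinEvaluation:
    """Length-weighted precision/recall/F1 of each bin against truth labels."""
    by_id = {c.id: c for c in contigs}
    if any(c.truth_label is None for c in contigs):
        raise ValidationError("every contig needs a truth label for evaluation")
    label_total: dict[str, int] = {}
    for c in contigs:
        label_total[c.truth_label] = label_total.get(c.truth_label, 0) + c.length
    records = []
    for b in result.bins:
        per_label: dict[str, int] = {}
        for cid in b.contig_ids:
            c = by_id[cid]
            per_label[c.truth_label] = per_label.get(c.truth_label, 0) + c.length
        majority = max(sorted(per_label), key=lambda k: per_label[k])
        prec = per_label[majority] / b.total_length
        rec = per_label[majority] / label_total[majority]
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        records.append(
            BinRecord(
                bin_id=b.bin_id, majority_label=majority,
                precision=prec, recall=rec, f1=f1, total_length=b.total_length,
            )
        )
    return BinEvaluation(records=records)


def select_host_bins(
    result: BinningResult,
    mode: str = "heuristic",
    host_label: str | None = None,
    evaluation: BinEvaluation | None = None,
    gc_window: float = 0.03,
    depth_factor: float = 2.0,
) -> set[str]:
    """Pick the bins that make up the host draft genome.

    ``truth`` mode keeps bins whose majority label is the designated
    host; ``heuristic`` mode keeps the largest bin plus every bin whose
    mean GC lies within ``gc_window`` (fraction, default ±3 points) and
    whose mean depth is within a factor ``depth_factor`` of it — the
    host of a hologenomic sample is typically its largest, most even
    signal.
    """
    if not result.bins:
        return set()
    if mode == "truth":
        if evaluation is None or host_label is None:
            raise ValidationError("truth mode needs an evaluation and host_label")
        return {
            r.bin_id for r in evaluation.records if r.majority_label == host_label
        }
    if mode != "heuristic":
        raise ValidationError(f"unknown mode {mode!r}")
    anchor = max(result.bins, key=lambda b: b.total_length)
    chosen = set()
    for b in result.bins:
        gc_ok = abs(b.mean_gc - anchor.mean_gc) <= gc_window
        lo = anchor.mean_depth / depth_factor
        hi = anchor.mean_depth * depth_factor
        depth_ok = lo <= b.mean_depth <= hi
        if b is anchor or (gc_ok and depth_ok):
            chosen.add(b.bin_id)
    return chosen


# ---------------------------------------------------------------------------
# read recruitment


def _host_kmer_set(host_sequences: Iterable[str], k: int) -> np.ndarray:
    parts = []
    for seq in host_sequences:
        canon = _dna.kmer_codes(_dna.encode(seq), k)
        if canon.shape[0]:
            parts.append(np.unique(canon))
    if not parts:
        raise ValidationError("empty host bin set")
    return np.unique(np.concatenate(parts))


def recruit_reads(
    reads,
    host_sequences: Iterable[str],
    k: int = 21,
    theta: float = 0.5,
):
    """Assign reads to the host by shared canonical k-mer fraction.

    A read is recruited when at least ``theta`` of its canonical k-mers
    occur in the host-bin k-mer set; paired mates are recruited jointly
    when either qualifies (mirroring a mapper rescuing the mate).

    ``reads`` may be a :class:`~holopipe.simulate.ReadSet` (fast path) or
    an iterable of ``(read_id, sequence)`` pairs.  Returns
    ``(host_mask_or_ids, stats)`` — for a ReadSet a boolean mask over
    reads plus a stats dict; for an iterable, (host_ids, other_ids, stats).
    """
    if not 0 < theta <= 1:
        raise ValidationError(f"theta must be in (0,1], got {theta}")
    host = _host_kmer_set(host_sequences, k)

    def frac_in_host(canon: np.ndarray) -> float:
        if canon.shape[0] == 0:
            return 0.0
        idx = np.searchsorted(host, canon)
        idx = np.minimum(idx, host.shape[0] - 1)
        return float((host[idx] == canon).mean())

    from .simulate import ReadSet  # local import to avoid a cycle

    if isinstance(reads, ReadSet):
        n, L = reads.codes.shape
        if L < k:
            raise ValidationError("reads shorter than k")
        wins = L - k + 1
        fractions = np.empty(n)
        chunk = max(1, 20_000_000 // max(L, 1))
        for s in range(0, n, chunk):
            block = reads.codes[s : s + chunk]
            flat = np.full((block.shape[0], L + k), 4, dtype=np.uint8)
            flat[:, :L] = block
            canon = _dna.kmer_codes(flat.ravel(), k)
            # simulated reads are pure ACGT: windows per read is constant
            canon = canon.reshape(block.shape[0], wins)
            idx = np.searchsorted(host, canon)
            idx = np.minimum(idx, host.shape[0] - 1)
            hit = host[idx] == canon
            fractions[s : s + chunk] = hit.mean(axis=1)
        mask = fractions >= theta
        if reads.paired:
            pair_hit = mask[0::2] | mask[1::2]
            mask = np.repeat(pair_hit, 2)
        stats = {
            "n_reads": int(n),
            "n_recruited": int(mask.sum()),
            "fraction_recruited": float(mask.mean()) if n else 0.0,
            "theta": theta,
            "k": k,
        }
        return mask, stats

    host_ids, other_ids = [], []
    for read_id, seq in reads:
        canon = _dna.kmer_codes(_dna.encode(seq), k)
        (host_ids if frac_in_host(canon) >= theta else other_ids).append(read_id)
    n = len(host_ids) + len(other_ids)
    stats = {
        "n_reads": n,
        "n_recruited": len(host_ids),
        "fraction_recruited": len(host_ids) / n if n else 0.0,
        "theta": theta,
        "k": k,
    }
    return host_ids, other_ids, stats
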