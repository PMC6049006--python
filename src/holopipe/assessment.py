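"""Assembly quality metrics and multi-assembly z-score ranking.

Computes the standard contiguity statistics (N50/NG50/L50, N content,
GC, counts of long contigs), the "usefulness" criterion — the share of
the estimated genome size held in scaffolds at least as long as an
average gene (7 kb for invertebrates, 25 kb for vertebrates) — and a
k-mer-based marker-recovery proxy for single-copy-ortholog completeness.
Assemblies are then ranked by direction-signed standardized scores
summed per criterion, with good/average/poor labels at one standard
deviation from the median cumulative score.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _dna
from .errors import ValidationError

INVERTEBRATE_GENE_LENGTH = 7_000
VERTEBRATE_GENE_LENGTH = 25_000


# ---------------------------------------------------------------------------
# contiguity


def nx_metric(lengths: Sequence[int], x: float = 50) -> tuple[int, int]:
    """(Nx, Lx): length at which the descending cumulative sum reaches x%
    of the assembly, and how many sequences that takes."""
    if len(lengths) == 0:
        raise ValidationError("empty length list")
    if any(l <= 0 for l in lengths):
        raise ValidationError("lengths must be positive")
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    threshold = arr.sum() * x / 100.0
    cum = np.cumsum(arr)
    i = int(np.searchsorted(cum, threshold))
    return int(arr[i]), i + 1


def ngx_metric(
    lengths: Sequence[int], genome_size: int, x: float = 50
) -> tuple[int | None, int | None]:
    """Like :func:`nx_metric` but against x% of the estimated genome size.

    Returns (None, None) when the assembly does not reach the threshold.
    """
    if genome_size <= 0:
        raise ValidationError("genome_size must be positive")
    if len(lengths) == 0:
        raise ValidationError("empty length list")
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    threshold = genome_size * x / 100.0
    cum = np.cumsum(arr)
    if cum[-1] < threshold:
        return None, None
    i = int(np.searchsorted(cum, threshold))
    return int(arr[i]), i + 1


# ---------------------------------------------------------------------------
# whole-assembly metrics


@dataclass
class AssemblyMetrics:
    """Per-assembly contiguity and usefulness numbers."""

    name: str
    n_scaffolds: int
    n_contigs: int
    total_scaffold_length: int
    total_contig_length: int
    longest_scaffold: int
    longest_contig: int
    n50_scaffold: int
    l50_scaffold: int
    n50_contig: int
    l50_contig: int
    ng50_scaffold: int | None
    ng50_contig: int | None
    gc_percent: float
    n_content_percent: float
    contigs_over_10kb: int
    pct_genome_in_scaffolds_ge_7kb: float | None
    pct_genome_in_scaffolds_ge_25kb: float | None
    genome_size_estimate: int | None

    def as_series(self) -> pd.Series:
        d = self.__dict__.copy()
        d.pop("name")
        return pd.Series(d, name=self.name)


_NONACGT = re.compile(r"[^ACGT]")


def _split_contigs(seq: str, n_split: int) -> list[str]:
    parts = re.split(f"N{{{n_split},}}", seq)
    return [p for p in parts if p]


def assembly_metrics(
    scaffolds: Sequence[tuple[str, str]],
    genome_size_estimate: int | None = None,
    n_split: int = 10,
    name: str = "assembly",
) -> AssemblyMetrics:
    """Compute the full metric panel for one assembly.

    Contigs are obtained by splitting scaffolds at runs of >= ``n_split``
    Ns; non-ACGTN symbols count as N; GC is taken over non-N bases.
    Usefulness percentages are relative to ``genome_size_estimate`` and
    may exceed 100 when the assembly is larger than the estimate; they
    are None when no estimate is given.
    """
    if not scaffolds:
        raise ValidationError("need at least one scaffold")
    seqs = [_NONACGT.sub("N", s.upper()) for _, s in scaffolds]
    scaffold_lengths = [len(s) for s in seqs]
    if any(l == 0 for l in scaffold_lengths):
        raise ValidationError("empty scaffold sequence")
    contig_seqs: list[str] = []
    for s in seqs:
        contig_seqs.extend(_split_contigs(s, n_split))
    contig_lengths = [len(c) for c in contig_seqs]
    total_scaffold = sum(scaffold_lengths)
    n_bases = sum(s.count("N") for s in seqs)
    gc = sum(s.count("G") + s.count("C") for s in seqs)
    acgt = total_scaffold - n_bases
    n50_s, l50_s = nx_metric(scaffold_lengths)
    n50_c, l50_c = nx_metric(contig_lengths)
    if genome_size_estimate and genome_size_estimate > 0:
        ng50_s, _ = ngx_metric(scaffold_lengths, genome_size_estimate)
        ng50_c, _ = ngx_metric(contig_lengths, genome_size_estimate)
        pct7 = 100.0 * sum(l for l in scaffold_lengths if l >= INVERTEBRATE_GENE_LENGTH) / genome_size_estimate
        pct25 = 100.0 * sum(l for l in scaffold_lengths if l >= VERTEBRATE_GENE_LENGTH) / genome_size_estimate
    else:
        ng50_s = ng50_c = None
        pct7 = pct25 = None
        genome_size_estimate = None
    return AssemblyMetrics(
        name=name,
        n_scaffolds=len(seqs),
        n_contigs=len(contig_seqs),
        total_scaffold_length=total_scaffold,
        total_contig_length=sum(contig_lengths),
        longest_scaffold=max(scaffold_lengths),
        longest_contig=max(contig_lengths),
        n50_scaffold=n50_s,
        l50_scaffold=l50_s,
        n50_contig=n50_c,
        l50_contig=l50_c,
        ng50_scaffold=ng50_s,
        ng50_contig=ng50_c,
        gc_percent=100.0 * gc / acgt if acgt else 0.0,
        n_content_percent=100.0 * n_bases / total_scaffold,
        contigs_over_10kb=sum(1 for l in contig_lengths if l > 10_000),
        pct_genome_in_scaffolds_ge_7kb=pct7,
        pct_genome_in_scaffolds_ge_25kb=pct25,
        genome_size_estimate=genome_size_estimate,
    )


# ---------------------------------------------------------------------------
# gene length from annotations


def mean_gene_length(
    annotations, feature_type: str = "gene", round_to_kb: bool = False
) -> float:
    """Mean feature length from GFF3 annotations (1-based inclusive spans).

    ``annotations`` is a GFF3 path or a pandas DataFrame with Feature /
    Start / End columns as produced by ``pyranges`` (0-based half-open,
    so the span is End - Start).
    """
    if isinstance(annotations, (str,)) or hasattr(annotations, "__fspath__"):
        import pyranges

        df = pyranges.read_gff3(str(annotations)).df
    else:
        df = annotations
    sel = df[df["Feature"] == feature_type]
    if len(sel) == 0:
        raise ValidationError(f"no features of type {feature_type!r}")
    mean = float((sel["End"] - sel["Start"]).mean())
    if round_to_kb:
        mean = round(mean / 1000.0) * 1000.0
    return mean


# ---------------------------------------------------------------------------
# marker recovery (single-copy-ortholog completeness proxy)


@dataclass
class MarkerRecovery:
    n_complete: int
    n_fragmented: int
    n_missing: int
    status: dict[str, str] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.n_complete + self.n_fragmented + self.n_missing


def marker_recovery(
    markers: Sequence[tuple[str, str]],
    scaffolds: Sequence[tuple[str, str]],
    k: int = 21,
    complete_threshold: float = 0.9,
) -> MarkerRecovery:
    """Classify marker sequences as complete / fragmented / missing.

    A marker is *complete* when a single scaffold contains at least
    ``complete_threshold`` of the marker's distinct canonical k-mers,
    *fragmented* when the union over scaffolds does but no single
    scaffold, and *missing* otherwise.  This is a sequence-level proxy
    for single-copy-ortholog census tools, which need external databases.
    """
    if not markers:
        raise ValidationError("markers must be non-empty")
    if not 0 < complete_threshold <= 1:
        raise ValidationError("complete_threshold must be in (0,1]")
    scaffold_sets = []
    for _, seq in scaffolds:
        canon = _dna.kmer_codes(_dna.encode(seq.upper()), k)
        scaffold_sets.append(np.unique(canon))
    union = (
        np.unique(np.concatenate([s for s in scaffold_sets if s.size]))
        if any(s.size for s in scaffold_sets)
        else np.empty(0, np.int64)
    )
    status = {}
    for mid, mseq in markers:
        mk = np.unique(_dna.kmer_codes(_dna.encode(mseq.upper()), k))
        if mk.size == 0:
            status[mid] = "missing"
            continue
        best = 0.0
        for ss in scaffold_sets:
            if ss.size == 0:
                continue
            best = max(best, np.isin(mk, ss, assume_unique=True).mean())
            if best >= complete_threshold:
                break
        if best >= complete_threshold:
            status[mid] = "complete"
        elif union.size and np.isin(mk, union, assume_unique=True).mean() >= complete_threshold:
            status[mid] = "fragmented"
        else:
            status[mid] = "missing"
    vals = list(status.values())
    return MarkerRecovery(
        n_complete=vals.count("complete"),
        n_fragmented=vals.count("fragmented"),
        n_missing=vals.count("missing"),
        status=status,
    )


# ---------------------------------------------------------------------------
# z-score framework


def zscore_table(
    values: pd.DataFrame,
    directions: Mapping[str, int],
    robust: bool = False,
) -> pd.DataFrame:
    """Direction-signed standardized scores per parameter row.

    ``values`` is parameters x assemblies.  Default scaling is
    (x - mean) / sample SD; ``robust=True`` switches to
    (x - median) / (1.4826 * MAD), an alternative reading of "modified
    z-score".  A zero-spread row scores 0 everywhere.  Rows sum to 0 in
    the default scaling.
    """
    if values.shape[1] < 2:
        raise ValidationError("need at least 2 assemblies")
    if not np.isfinite(values.to_numpy(dtype=float)).all():
        raise ValidationError("values must be finite")
    z = pd.DataFrame(0.0, index=values.index, columns=values.columns)
    for p in values.index:
        row = values.loc[p].astype(float)
        direction = directions.get(p, 1)
        if robust:
            center = row.median()
            scale = 1.4826 * (row - center).abs().median()
        else:
            center = row.mean()
            scale = row.std(ddof=1)
        if scale > 0:
            z.loc[p] = direction * (row - center) / scale
    return z


def classify_assemblies(scores: Sequence[float]) -> list[str]:
    """good / average / poor labels at +-1 SD of the scores from their median."""
    if len(scores) < 2:
        raise ValidationError("need at least 2 scores")
    arr = np.asarray(scores, dtype=float)
    med = float(np.median(arr))
    sd = float(np.std(arr, ddof=1))
    labels = []
    for s in arr:
        if sd > 0 and s >= med + sd:
            labels.append("good")
        elif sd > 0 and s <= med - sd:
            labels.append("poor")
        else:
            labels.append("average")
    return labels


DEFAULT_DIRECTIONS: dict[str, int] = {
    "n50_scaffold": 1,
    "n50_contig": 1,
    "ng50_scaffold": 1,
    "ng50_contig": 1,
    "n_content_percent": -1,
    "contigs_over_10kb": 1,
    "longest_scaffold": 1,
    "pct_genome_in_scaffolds_ge_7kb": 1,
    "pct_genome_in_scaffolds_ge_25kb": 1,
    "markers_complete": 1,
    "markers_fragmented": -1,
    "markers_missing": -1,
}

DEFAULT_CRITERIA: dict[str, list[str]] = {
    "completeness": ["markers_complete", "markers_fragmented", "markers_missing"],
    "contiguity": [
        "n50_scaffold",
        "n50_contig",
        "ng50_scaffold",
        "ng50_contig",
        "n_content_percent",
        "contigs_over_10kb",
        "longest_scaffold",
    ],
    "usefulness": [
        "pct_genome_in_scaffolds_ge_7kb",
        "pct_genome_in_scaffolds_ge_25kb",
    ],
}


@dataclass
class ZScoreReport:
    """Raw values, z-scores, per-criterion cumulative scores and labels."""

    values: pd.DataFrame  # parameters x assemblies
    directions: dict[str, int]
    z: pd.DataFrame
    criterion_scores: pd.DataFrame  # criteria x assemblies
    overall: pd.Series
    labels: pd.DataFrame  # criteria x assemblies, good/average/poor


def compare_assemblies(
    values: pd.DataFrame,
    directions: Mapping[str, int] | None = None,
    criteria: Mapping[str, list[str]] | None = None,
    robust: bool = False,
) -> ZScoreReport:
    """Rank assemblies: z-scores per parameter, sums per criterion, labels.

    Parameters absent from every configured criterion still get z-scores
    but do not enter any cumulative score.  Criterion membership and
    directions are configurable so alternative parameter panels can be
    swapped in.
    """
    directions = dict(DEFAULT_DIRECTIONS, **(directions or {}))
    criteria = dict(criteria) if criteria is not None else {
        crit: [p for p in plist if p in values.index]
        for crit, plist in DEFAULT_CRITERIA.items()
    }
    criteria = {c: ps for c, ps in criteria.items() if ps}
    z = zscore_table(values, directions, robust=robust)
    rows = {}
    for crit, params in criteria.items():
        missing = [p for p in params if p not in z.index]
        if missing:
            raise ValidationError(f"criterion {crit!r} uses unknown parameters {missing}")
        rows[crit] = z.loc[params].sum(axis=0)
    criterion_scores = pd.DataFrame(rows).T
    overall = criterion_scores.sum(axis=0)
    labels = pd.DataFrame(
        {
            crit: pd.Series(
                classify_assemblies(criterion_scores.loc[crit].to_numpy()),
                index=criterion_scores.columns,
            )
            for crit in criterion_scores.index
        }
    ).T
    return ZScoreReport(
        values=values,
        directions=directions,
        z=z,
        criterion_scores=criterion_scores,
        overall=overall,
        labels=labels,
    )
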