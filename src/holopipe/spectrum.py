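"""K-mer spectrum analysis: counting, coverage histograms, and genome
feature estimation.

The spectrum of a diploid genome sequenced at uniform coverage shows a
heterozygous peak at the haploid depth ``lambda`` (k-mers overlapping a
site that differs between haplotypes occur on one haplotype only), a
homozygous peak at ``2*lambda``, a low-depth error limb (k-mers created
by sequencing errors are nearly unique) and a deep repeat tail.  Three
estimators of the haploid genome size are provided:

* ``waterman_size`` — total filtered k-mer occurrences divided by the
  homozygous peak depth (Lander–Waterman relation);
* ``fit_poisson_em`` — an EM fit of the distinct-k-mer distribution as a
  mixture of Poissons with means at integer multiples of the haploid
  depth, in the spirit of coverage-bias-aware estimators such as gce;
* ``fit_nb_mixture`` — a least-squares negative-binomial mixture fit
  (GenomeScope-style) that additionally yields the heterozygous
  fraction and a per-base heterozygosity.

All estimators report the *haploid* size ``G = sum_{c>=e} c*h(c) / (2*lambda)``
(equivalently ``/ c_hom`` for Waterman) so they are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from . import _dna
from .errors import FitError, NoSignalError, ValidationError

_CHUNK_BASES = 16_000_000


@dataclass
class KmerTable:
    """Canonical k-mer occurrence counts, stored as parallel sorted arrays.

    ``codes`` holds the 2-bit packed canonical k-mers in ascending order;
    ``counts`` the occurrence count of each.  The packed layout keeps
    desk-scale counting (order 10^8 windows) tractable in memory.
    """

    k: int
    codes: np.ndarray  # int64, sorted ascending, unique
    counts: np.ndarray  # int64, same length

    @property
    def n_distinct(self) -> int:
        return int(self.codes.shape[0])

    @property
    def total_occurrences(self) -> int:
        return int(self.counts.sum())

    def get(self, kmer: str) -> int:
        """Count of a k-mer given as a string (canonicalized first)."""
        code = _dna.str_to_kmer(_dna.canonical_str(kmer.upper()))
        i = int(np.searchsorted(self.codes, code))
        if i < self.n_distinct and self.codes[i] == code:
            return int(self.counts[i])
        return 0

    def lookup_codes(self, query: np.ndarray) -> np.ndarray:
        """Vectorized counts for an array of packed canonical codes (0 if absent)."""
        idx = np.searchsorted(self.codes, query)
        idx = np.minimum(idx, self.n_distinct - 1) if self.n_distinct else idx
        if self.n_distinct == 0:
            return np.zeros(query.shape[0], dtype=np.int64)
        hit = self.codes[idx] == query
        out = np.where(hit, self.counts[idx], 0)
        return out

    def as_dict(self) -> dict[str, int]:
        """Decode to a {kmer: count} dict (small tables / tests only)."""
        return {
            _dna.kmer_to_str(int(c), self.k): int(n)
            for c, n in zip(self.codes, self.counts)
        }

    @classmethod
    def from_dict(cls, k: int, d: Mapping[str, int]) -> "KmerTable":
        codes = np.array(
            [_dna.str_to_kmer(_dna.canonical_str(s.upper())) for s in d], dtype=np.int64
        )
        counts = np.array(list(d.values()), dtype=np.int64)
        order = np.argsort(codes)
        return cls(k=k, codes=codes[order], counts=counts[order])


@dataclass
class KmerHistogram:
    """Distinct-k-mer counts per coverage depth (the Fig.-2-style spectrum)."""

    k: int
    h: dict[int, int]

    @property
    def D(self) -> int:
        """Number of distinct k-mers."""
        return int(sum(self.h.values()))

    @property
    def T(self) -> int:
        """Total k-mer occurrences."""
        return int(sum(c * n for c, n in self.h.items()))

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        depths = np.array(sorted(self.h), dtype=np.int64)
        counts = np.array([self.h[int(c)] for c in depths], dtype=np.int64)
        return depths, counts

    def dense(self, cmax: int | None = None) -> np.ndarray:
        """Counts on the contiguous depth grid 1..cmax (index 0 unused)."""
        top = max(self.h) if self.h else 0
        cmax = top if cmax is None else min(cmax, top)
        out = np.zeros(cmax + 1, dtype=float)
        for c, n in self.h.items():
            if 1 <= c <= cmax:
                out[c] = n
        return out


@dataclass
class SpectrumFit:
    """Result of one genome-feature estimation on a k-mer histogram."""

    method: str
    k: int
    error_cutoff: int
    lambda_het: float
    c_hom: float
    repeat_cutoff: float
    genome_size: float
    weights: np.ndarray | None = None
    dispersion: float | None = None
    p_het: float | None = None
    het_rate: float | None = None
    error_fraction: float | None = None
    repeat_fraction: float | None = None
    converged: bool = True
    loglik: float | None = None
    loglik_trace: list[float] | None = None
    residual_norm: float | None = None
    unimodal: bool = False


@dataclass
class GenomeFeatureEstimates:
    """Genome-size table over (k, method) with the consensus summary."""

    estimates: dict[tuple[int, str], float]
    consensus_median: float = 0.0
    consensus_sd: float = 0.0
    single_value: bool = False
    comparison_stats: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self):
        values = list(self.estimates.values())
        if values:
            self.consensus_median, self.consensus_sd = consensus_size(values)
            self.single_value = len(values) == 1


# ---------------------------------------------------------------------------
# counting


def _normalize_items(sequences: Iterable, chunk_bases: int):
    """Yield 1D uint8 code arrays, splitting 2D read matrices into
    sentinel-separated row blocks so no single item exceeds the chunk."""
    for seq in sequences:
        codes = seq if isinstance(seq, np.ndarray) else _dna.encode(seq)
        if codes.ndim == 2:  # read matrix: separate rows with sentinels
            n, length = codes.shape
            rows_per_block = max(1, chunk_bases // (length + 1))
            for s in range(0, n, rows_per_block):
                block = codes[s : s + rows_per_block]
                padded = np.full((block.shape[0], length + 1), 4, dtype=np.uint8)
                padded[:, :length] = block
                yield padded.ravel()
        else:
            yield codes.astype(np.uint8, copy=False)


def _iter_code_chunks(sequences: Iterable, chunk_bases: int):
    """Yield 1D uint8 code arrays with sentinel separators between items."""
    buf: list[np.ndarray] = []
    size = 0
    sep = np.array([4], dtype=np.uint8)
    for codes in _normalize_items(sequences, chunk_bases):
        buf.append(codes)
        buf.append(sep)
        size += codes.shape[0] + 1
        if size >= chunk_bases:
            yield np.concatenate(buf)
            buf, size = [], 0
    if buf:
        yield np.concatenate(buf)


def count_kmers(sequences: Iterable, k: int, chunk_bases: int = _CHUNK_BASES) -> KmerTable:
    """Count canonical k-mers over an iterable of DNA strings.

    Also accepts uint8 code arrays (1D, or 2D read matrices) for the fast
    path used by the simulator.  Windows containing a non-ACGT symbol are
    skipped.  Sequences shorter than ``k`` contribute nothing.
    """
    if k < 2:
        raise ValidationError(f"k must be >= 2, got {k}")
    parts: list[tuple[np.ndarray, np.ndarray]] = []
    for chunk in _iter_code_chunks(sequences, chunk_bases):
        canon = _dna.kmer_codes(chunk, k)
        if canon.shape[0]:
            codes, counts = np.unique(canon, return_counts=True)
            parts.append((codes, counts.astype(np.int64)))
    if not parts:
        return KmerTable(k=k, codes=np.empty(0, np.int64), counts=np.empty(0, np.int64))
    if len(parts) == 1:
        codes, counts = parts[0]
    else:
        allc = np.concatenate([p[0] for p in parts])
        alln = np.concatenate([p[1] for p in parts])
        order = np.argsort(allc, kind="stable")
        allc, alln = allc[order], alln[order]
        boundary = np.concatenate(([True], allc[1:] != allc[:-1]))
        codes = allc[boundary]
        counts = np.add.reduceat(alln, np.flatnonzero(boundary))
    return KmerTable(k=k, codes=codes, counts=counts)


def build_histogram(table: KmerTable) -> KmerHistogram:
    """Collapse a k-mer table into the depth -> #distinct-k-mers histogram."""
    if table.n_distinct == 0:
        return KmerHistogram(k=table.k, h={})
    depths, ndistinct = np.unique(table.counts, return_counts=True)
    return KmerHistogram(
        k=table.k, h={int(c): int(n) for c, n in zip(depths, ndistinct)}
    )


# ---------------------------------------------------------------------------
# peak structure


def _local_maxima(y: np.ndarray) -> list[int]:
    """Indices of strict-or-plateau local maxima of y[1:] (index = depth)."""
    out = []
    n = y.shape[0]
    for i in range(1, n):
        left = y[i - 1] if i - 1 >= 1 else -np.inf
        right = y[i + 1] if i + 1 < n else -np.inf
        if y[i] > left and y[i] >= right and y[i] > 0:
            out.append(i)
    return out


def detect_peaks(
    hist: KmerHistogram, smoothing_window: int = 5, max_depth: int = 10_000
) -> tuple[int, float, float, bool]:
    """Locate the error valley and the het/hom coverage peaks.

    Returns ``(e, lambda_het, c_hom, unimodal_flag)`` where ``e`` is the
    depth of the minimum between depth 1 and the first coverage peak
    (error k-mers live below it), ``lambda_het`` the haploid depth and
    ``c_hom`` the homozygous depth.  On a single-peaked (effectively
    haploid) spectrum the lone peak is reported as ``c_hom`` with
    ``lambda_het = c_hom / 2`` and the flag set.
    """
    if not hist.h:
        raise ValidationError("empty histogram")
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ValidationError("smoothing_window must be a positive odd integer")
    y = hist.dense(max_depth)
    if y.shape[0] <= 3 or sum(c * n for c, n in hist.h.items() if c >= 3) == 0:
        raise NoSignalError("all k-mer mass below depth 3; no coverage peak")
    if smoothing_window > 1:
        kern = np.ones(smoothing_window) / smoothing_window
        ys = np.convolve(y, kern, mode="same")
        ys[0] = 0.0
    else:
        ys = y.copy()
    # error valley on the *raw* counts: the limb of near-unique error
    # k-mers decays monotonically, so the first local minimum scanning up
    # from the lowest present depth separates errors from coverage signal
    lo = min(hist.h)
    top = y.shape[0] - 1
    e = lo
    for i in range(lo + 1, top):
        if y[i] > y[i - 1]:  # rising: the limb has bottomed out at i-1
            e = i - 1
            break
        if y[i] <= y[i - 1] and y[i] <= y[i + 1]:
            e = i
            break
    maxima = [i for i in _local_maxima(ys) if i > e and i >= 3]
    if not maxima:
        raise NoSignalError("no coverage peak found above the error valley")
    peak = max(maxima, key=lambda i: ys[i])
    # companion peaks must carry real mass; sparse-tail noise maxima are
    # orders of magnitude below the main peak
    floor = 0.02 * ys[peak]
    hom = [i for i in maxima if 1.6 * peak <= i <= 2.4 * peak and ys[i] >= floor]
    if hom:
        c_hom = float(max(hom, key=lambda i: ys[i]))
        lam = float(peak)
        return e, lam, c_hom, False
    half = [i for i in maxima if 0.4 * peak <= i <= 0.6 * peak and ys[i] >= floor]
    if half:
        lam = float(max(half, key=lambda i: ys[i]))
        return e, lam, float(peak), False
    # single-peaked spectrum: the peak is the homozygous depth
    return e, peak / 2.0, float(peak), True


# ---------------------------------------------------------------------------
# size estimators


def _filtered_mass(hist: KmerHistogram, e: int) -> float:
    return float(sum(c * n for c, n in hist.h.items() if c >= e))


def waterman_size(hist: KmerHistogram, e: int, c_hom: float) -> float:
    """Haploid genome size from the Lander–Waterman relation.

    ``G = sum_{c>=e} c*h(c) / c_hom`` — error-depth occurrences are
    excluded and the homozygous peak depth is the divisor, so the result
    is on the haploid scale.
    """
    if c_hom <= 0:
        raise ValidationError(f"c_hom must be positive, got {c_hom}")
    if e < 1 or e >= c_hom:
        raise ValidationError(f"need 1 <= e < c_hom, got e={e}, c_hom={c_hom}")
    return _filtered_mass(hist, e) / c_hom


def _fit_depth_range(hist: KmerHistogram, e: int, upper: float | None):
    depths, counts = hist.arrays()
    keep = depths >= e
    if upper is not None:
        keep &= depths <= upper
    depths, counts = depths[keep], counts[keep].astype(float)
    if depths.shape[0] == 0 or counts.sum() == 0:
        raise ValidationError("histogram has no mass in the fit range")
    return depths, counts


def fit_poisson_em(
    hist: KmerHistogram,
    e: int,
    m: int = 2,
    upper: float | None = None,
    lambda_init: float | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> SpectrumFit:
    """EM fit of the filtered spectrum as ``sum_i w_i Poisson(c; i*lambda)``.

    Component ``i=1`` sits at the haploid (heterozygous) depth and
    ``i=2`` at the homozygous depth; depths above ``upper`` (typically
    the repeat cutoff) are excluded from the fit but kept in the size
    numerator.  The log-likelihood is non-decreasing across iterations;
    non-convergence returns the best-so-far fit flagged unconverged.
    Because components at ``lambda`` and ``2*lambda`` are exchangeable
    under relabeling on unimodal data, initialization follows the peak
    structure unless ``lambda_init`` is given.
    """
    if m < 2:
        raise ValidationError(f"m must be >= 2, got {m}")
    depths, counts = _fit_depth_range(hist, e, upper)
    if lambda_init is None:
        _, lam0, _, _ = detect_peaks(hist)
    else:
        lam0 = float(lambda_init)
    lam = max(lam0, 1.0)
    w = np.full(m, 1.0 / m)
    comps = np.arange(1, m + 1, dtype=float)
    c = depths.astype(float)
    prev_ll = -np.inf
    ll = prev_ll
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        # E-step in log space: log w_i + log Poisson(c; i*lam)
        logp = (
            np.log(np.maximum(w, 1e-300))[None, :]
            + stats.poisson.logpmf(c[:, None], (comps * lam)[None, :])
        )
        mx = logp.max(axis=1, keepdims=True)
        post = np.exp(logp - mx)
        norm = post.sum(axis=1, keepdims=True)
        post /= norm
        ll = float((counts * (mx[:, 0] + np.log(norm[:, 0]))).sum())
        trace.append(ll)
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            converged = True
            break
        prev_ll = ll
        # M-step
        resp = post * counts[:, None]
        w = resp.sum(axis=0)
        w = w / w.sum()
        num = float((resp * c[:, None]).sum())
        den = float((resp * comps[None, :]).sum())
        lam = max(num / den, 1e-6)
    G = _filtered_mass(hist, e) / (2.0 * lam)
    return SpectrumFit(
        method="poisson_em",
        k=hist.k,
        error_cutoff=e,
        lambda_het=lam,
        c_hom=2.0 * lam,
        repeat_cutoff=upper if upper is not None else 4.0 * 2.0 * lam,
        genome_size=G,
        weights=w,
        converged=converged,
        loglik=ll,
        loglik_trace=trace,
    )


def poisson_mixture_loglik(
    hist: KmerHistogram, e: int, lam: float, w: Sequence[float], upper: float | None = None
) -> float:
    """Log-likelihood of the filtered spectrum under a Poisson mixture."""
    depths, counts = _fit_depth_range(hist, e, upper)
    comps = np.arange(1, len(w) + 1, dtype=float)
    logpmf = stats.poisson.logpmf(depths[:, None], comps[None, :] * lam)
    ll = np.log(np.maximum(np.exp(logpmf) @ np.asarray(w), 1e-300))
    return float((counts * ll).sum())


def fit_nb_mixture(
    hist: KmerHistogram,
    e: int,
    m: int = 4,
    upper: float | None = None,
    lambda_init: float | None = None,
    theta_init: float = 40.0,
) -> SpectrumFit:
    """Least-squares negative-binomial mixture fit of the spectrum.

    Models the distinct-k-mer counts for depths in ``[e, upper]`` as
    ``D' * sum_i w_i NB(c; mean=i*lambda, size=theta)`` with a shared
    dispersion.  Component 1 is heterozygous, component 2 homozygous and
    higher components duplicated sequence.  The heterozygous k-mer-locus
    fraction ``p_het = (w1/2) / (w1/2 + sum_{i>=2} w_i)`` (a heterozygous
    locus yields two distinct k-mers) converts to a per-base rate via
    ``r = 1 - (1 - p_het)^(1/k)``.
    """
    if m not in (2, 3, 4):
        raise ValidationError(f"m must be in {{2,3,4}}, got {m}")
    depths, counts = _fit_depth_range(hist, e, upper)
    if lambda_init is None:
        _, lam0, _, _ = detect_peaks(hist)
    else:
        lam0 = float(lambda_init)
    lam0 = max(lam0, 1.0)
    comps = np.arange(1, m + 1, dtype=float)
    # initial component masses: assign each depth to its nearest mean
    a0 = np.full(m, 1e-3 * counts.sum())
    nearest = np.clip(np.rint(depths / lam0), 1, m).astype(int) - 1
    for j, n in zip(nearest, counts):
        a0[j] += n
    x0 = np.concatenate(([np.log(lam0), np.log(theta_init)], np.log(a0)))
    c = depths.astype(float)

    def model(x):
        lam, theta = np.exp(x[0]), np.exp(x[1])
        a = np.exp(x[2:])
        mu = comps * lam
        p = theta / (theta + mu)
        pmf = stats.nbinom.pmf(c[:, None], theta, p[None, :])
        return pmf @ a

    def resid(x):
        return model(x) - counts

    try:
        sol = optimize.least_squares(resid, x0, method="lm", max_nfev=20000)
    except Exception as exc:  # pragma: no cover - defensive
        raise FitError(f"NB mixture optimizer raised: {exc}") from exc
    if not np.all(np.isfinite(sol.x)):
        raise FitError(
            "NB mixture fit diverged", residual_norm=float(np.linalg.norm(sol.fun))
        )
    lam, theta = float(np.exp(sol.x[0])), float(np.exp(sol.x[1]))
    a = np.exp(sol.x[2:])
    w = a / a.sum()
    p_het = (w[0] / 2.0) / (w[0] / 2.0 + w[1:].sum())
    r = 1.0 - (1.0 - p_het) ** (1.0 / hist.k)
    G = _filtered_mass(hist, e) / (2.0 * lam)
    return SpectrumFit(
        method="nb_mixture",
        k=hist.k,
        error_cutoff=e,
        lambda_het=lam,
        c_hom=2.0 * lam,
        repeat_cutoff=upper if upper is not None else 4.0 * 2.0 * lam,
        genome_size=G,
        weights=w,
        dispersion=theta,
        p_het=float(p_het),
        het_rate=float(r),
        converged=bool(sol.success),
        residual_norm=float(np.linalg.norm(sol.fun)),
    )


# ---------------------------------------------------------------------------
# fractions and consensus


def error_fraction(hist: KmerHistogram, e: int) -> float:
    """Share of total k-mer occurrences below the error cutoff."""
    if e < 1:
        raise ValidationError(f"e must be >= 1, got {e}")
    T = hist.T
    if T == 0:
        return 0.0
    return float(sum(c * n for c, n in hist.h.items() if c < e)) / T


def repeat_fraction(hist: KmerHistogram, e: int, rho: float) -> float:
    """Share of error-filtered k-mer occurrences above the repeat cutoff.

    The default cutoff used by callers is ``rho = 4 * c_hom``, which for
    a homozygous depth of 63 reproduces the conventional >250x rule.
    """
    if rho <= e:
        raise ValidationError(f"need rho > e, got rho={rho}, e={e}")
    denom = _filtered_mass(hist, e)
    if denom == 0:
        return 0.0
    num = float(sum(c * n for c, n in hist.h.items() if c > rho))
    return num / denom


def default_repeat_cutoff(c_hom: float) -> float:
    return 4.0 * c_hom


def consensus_size(estimates: Sequence[float]) -> tuple[float, float]:
    """Median and sample standard deviation of a set of size estimates.

    A single estimate yields sd 0 (callers can flag it via length)."""
    if len(estimates) == 0:
        raise ValidationError("need at least one estimate")
    arr = np.asarray(estimates, dtype=float)
    med = float(np.median(arr))
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return med, sd


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal–Wallis H with tie correction and chi-square p-value.

    ``H = [12/(N(N+1)) * sum R_i^2/n_i - 3(N+1)] / [1 - sum(t^3-t)/(N^3-N)]``
    with average ranks over the pooled sample; identical observations
    across the board give H=0, p=1.
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValidationError("need >= 2 non-empty groups")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n = pooled.shape[0]
    ranks = stats.rankdata(pooled)
    H = 0.0
    start = 0
    for g in groups:
        ni = len(g)
        Ri = ranks[start : start + ni].sum()
        H += Ri * Ri / ni
        start += ni
    H = 12.0 / (n * (n + 1)) * H - 3.0 * (n + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie = float(((tie_counts**3) - tie_counts).sum())
    denom = 1.0 - tie / (n**3 - n)
    if denom <= 0:  # every observation identical
        return 0.0, 1.0
    H /= denom
    df = len(groups) - 1
    p = float(stats.chi2.sf(H, df))
    return float(H), p


# ---------------------------------------------------------------------------
# one-call analysis


def analyze_spectrum(
    hist: KmerHistogram,
    error_cutoff: int | None = None,
    repeat_cutoff: float | None = None,
    smoothing_window: int = 5,
    m_poisson: int = 2,
    m_nb: int = 4,
) -> dict:
    """Run peak detection plus all three size estimators on one histogram.

    Returns a dict with the peak structure, the three fits, and the
    consensus (median ± sd) of the size estimates.
    """
    e_det, lam, c_hom, unimodal = detect_peaks(hist, smoothing_window)
    e = e_det if error_cutoff is None else int(error_cutoff)
    rho = default_repeat_cutoff(c_hom) if repeat_cutoff is None else float(repeat_cutoff)
    g_wat = waterman_size(hist, e, c_hom)
    fit_em = fit_poisson_em(hist, e, m=m_poisson, upper=rho, lambda_init=lam)
    fit_nb = fit_nb_mixture(hist, e, m=m_nb, upper=rho, lambda_init=lam)
    sizes = [g_wat, fit_em.genome_size, fit_nb.genome_size]
    med, sd = consensus_size(sizes)
    err = error_fraction(hist, e)
    rep = repeat_fraction(hist, e, rho)
    return {
        "k": hist.k,
        "error_cutoff": e,
        "lambda_het": lam,
        "c_hom": c_hom,
        "unimodal": unimodal,
        "repeat_cutoff": rho,
        "waterman": g_wat,
        "poisson_em": fit_em,
        "nb_mixture": fit_nb,
        "genome_size_median": med,
        "genome_size_sd": sd,
        "error_fraction": err,
        "repeat_fraction": rep,
    }
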