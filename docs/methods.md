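# Methods

`holopipe` reconstructs a host genome's reads and profile from a
taxonomically mixed (holobiont) shotgun sample, entirely in silico. This
note documents the models, the defaults and why they were chosen, the
numerical choices, and the limits of what the synthetic benchmarks show.

## The problem

A holobiont sample — a coral fragment, a lichen thallus, a sponge —
yields reads from the host plus its photosynthetic and microbial
symbionts. Host genome assembly from such data needs three in-silico
capabilities that this package provides behind one pipeline:

1. **k-mer spectrum profiling** of genome size, heterozygosity and
   repeat content, which is assembly-free and therefore usable before
   (and after) binning;
2. **contig binning** by tetranucleotide composition and coverage, plus
   recruitment of the raw reads that belong to the host bins;
3. **comparative assembly assessment** across the criteria
   completeness, contiguity and usefulness, with standardized scores.

## Synthetic holobiont generator

The generator is first-class, tested code: it plants a known truth so
every downstream stage has a parameter-recovery surface.

* **Host genome.** A uniform-i.i.d. background at a target GC (default
  0.40) of haploid length `L`. Repeats are planted by overwriting the
  background with dispersed copies of per-family units: unit length 500
  bp, 10 copies per family, family count chosen so planted repeat bases
  reach `repeat_fraction * L` (within one unit). Ten-copy families put
  repeat k-mers near 10x the homozygous depth — far beyond the 4x
  repeat cutoff — producing the deep spectrum tail repeat-rich animal
  genomes show. Haplotype B substitutes each base of haplotype A
  independently with probability `het_rate`, uniformly over the three
  alternative bases.
* **Symbionts.** Each symbiont is an order-2 Markov chain with its own
  Dirichlet-perturbed transition table tilted toward a target GC
  (realized GC within ±2 points, enforced by a few logit-scale
  correction rounds). Distinct chains give distinct tetranucleotide
  signatures even at equal GC.
* **Reads.** `round(depth * L / read_length)` reads per member, split
  evenly across haplotypes for diploids; paired reads come from
  fixed-length fragments (insert 600, 2x250 by default, mirroring
  PCR-free paired-end short-read libraries). Errors are uniform random
  substitutions at a flat per-base rate (default 0.5%); base qualities
  are constant Q40 because no downstream stage is quality-aware.
* **Contigs.** Genomes are partitioned (no gaps, no overlaps) at
  exponential spacings with mean `target_n50 / 1.6783` — the
  length-weighted median of an exponential is 1.6783 times its mean, so
  the realized N50 lands near the target — with sub-`min_length`
  pieces merged leftward. Truth labels ride in FASTA headers
  (`id|genome=<genome_id>`) and in a sidecar TSV.

What the generator does **not** emulate: indels and structural
variation, GC-biased coverage, position-dependent error profiles,
chimeric pairs, long reads. Recovery results on this data bound what
the algorithms can do under their own assumptions; they do not certify
performance on real libraries, where coverage bias and indel errors
blur the spectrum and composition signals.

## K-mer spectrum analysis

Canonical k-mers (lexicographic minimum of a window and its reverse
complement) are counted exactly in memory with 2-bit packing; the
practical ceiling is on the order of 10^8 distinct k-mers — desk scale,
deliberately not a streaming counter. The histogram `h(c)` (distinct
k-mers per depth `c`) is the object every estimator consumes; the file
dialect is the common two-column `.histo` text layout.

**Peak detection.** The error limb of near-unique k-mers decays
monotonically from depth 1, so the error cutoff `e` is the first local
minimum of the raw histogram scanning upward. Peaks are local maxima of
a moving-average-smoothed curve (window 5) above `e`; companion peaks
must reach 2% of the main peak's height to exclude sparse-tail noise.
If the tallest peak `p` has a companion in `[1.6p, 2.4p]` the pair is
(heterozygous λ, homozygous 2λ); a companion in `[0.4p, 0.6p]` means the
tallest peak is itself the homozygous one; with no companion the
spectrum is treated as effectively haploid: `c_hom = p`, `λ = p/2`,
flagged unimodal.

**Size estimators.** All three divide the error-filtered occurrence
mass `T_e = Σ_{c≥e} c·h(c)` by the homozygous depth, so all report the
*haploid* size on one scale:

* Waterman: `G = T_e / c_hom` with the detected peak;
* Poisson EM: the distinct-k-mer distribution on `e ≤ c ≤ ρ` is fit as
  `Σ_i w_i Poisson(c; i·λ)` by EM (λ shared, tolerance 1e-8, ≤500
  iterations, log-likelihood provably non-decreasing), then
  `G = T_e / (2λ̂)`;
* NB mixture: least squares of `h(c)` against
  `D'·Σ_i w_i NB(c; mean=i·λ, size=θ)` with a shared dispersion θ
  (keeping the fit identifiable on small histograms), components
  1/2/3+ read as heterozygous/homozygous/duplicated.

The mixture fits exclude depths above the repeat cutoff
`ρ = 4·c_hom` (a homozygous peak at 63x reproduces the conventional
\>250x rule); the repeat occurrence share `Σ_{c>ρ} c·h(c) / T_e` is the
repeat-content estimate, and the error share is `Σ_{c<e} c·h(c) / T`.
Both cutoffs are data-driven with manual override flags, since the
valley and the 4x rule are properties of a dataset, not constants.

A subtlety worth recording: a mixture with components at `λ` and `2λ`
is label-degenerate on unimodal data — `(λ, w=(0,1))` and
`(2λ, w=(1,0))` have identical likelihood. Initialization therefore
follows the detected peak structure (the unimodal flag halves the
initial λ), which keeps `G = T_e/(2λ)` on the haploid scale in every
case; `lambda_init` overrides it when the caller knows better.

**Heterozygosity.** A heterozygous locus contributes two distinct
k-mers at depth λ, a homozygous one a single k-mer at 2λ, so the
heterozygous *locus* fraction is `p = (w₁/2) / (w₁/2 + Σ_{i≥2} w_i)`
and the per-base rate is `r = 1 − (1 − p)^(1/k)`. Adjacent variants
closer than k bases violate the independence behind that inversion;
at r ≈ 1% and k = 21 the bias is within the tolerance the recovery
tests use.

**Consensus and comparisons.** The consensus size is the median (±
sample SD) over estimators (and optionally k sizes); group comparisons
use a tie-corrected Kruskal–Wallis H with a χ² p-value, implemented
directly and cross-checked against an independent implementation.

Sequencing errors thin both the numerator (error windows drop below
`e`) and the peak depth (a k-mer's effective coverage shrinks by
`(1−ε)^k`) by the same factor, so the size estimators remain unbiased
under the flat error model; the recovery tests confirm this at ε=0.5%.

## Binning and read recruitment

Contigs are embedded as a 136-dimensional canonical tetranucleotide
frequency vector (reverse-complement-collapsed 4-mers; 16 palindromic
classes stand alone) plus a log-scaled depth. The pairwise distance is

    d(i,j) = w·‖tnf_i − tnf_j‖₂
           + (1−w)·|log10(d_i+1) − log10(d_j+1)| / log10(max_depth+1)

with `w = 0.7`. Contig pairs with `d ≤ τ` (default 0.05) are linked and
connected components become bins; components smaller than
`min_bin_size` (200 kb at field scale, 20 kb in the test profiles,
matching the smallest host bins such projects report) stay unbinned.
This is a deterministic single-linkage rendering of the
composition+abundance principle behind metagenome binners — chosen over
an iterative medoid scheme because it is order-independent, has two
interpretable knobs, and is adequate for the pipeline's test surface.
The defaults were set from the feature-noise geometry: TNF sampling
noise of a 5 kb contig is ~0.015–0.02 in L2, while inter-genome
distances (different GC and different Markov structure) exceed 0.05, so
τ=0.05 chains same-genome contigs and leaves genome pairs unlinked.

Per-contig depth is the **median read-set multiplicity of the contig's
k-mers** rather than an alignment coverage — it needs no read mapper
and is validated against planted depths. It is biased low by the
read-edge factor `(L_read − k + 1)/L_read` and by error thinning; both
are shared across contigs and thus harmless for binning.

Host bins are selected either by truth label (evaluation mode) or by a
blind heuristic: the largest bin anchors the host, and bins within ±3
GC points and a 2x depth factor join it — the host of a hologenomic
sample being its largest, most internally consistent signal.

**Recruitment.** A read joins the host read set when at least θ
(default 0.5) of its canonical k-mers occur in the host-bin k-mer set;
mates are recruited jointly when either qualifies, mirroring a mapper
rescuing the pair. The recruited set shrinks monotonically in θ.

Bins are scored against truth labels with length-weighted precision
(majority-label share of the bin), recall (share of that genome's
total contig length captured) and F1 — an automated surrogate for the
manual reference-based bin inspection such studies perform.

## Assembly assessment

Contiguity metrics follow the standard definitions: scaffolds split
into contigs at runs of ≥10 Ns (configurable; real contig counts come
from assemblers, not a split rule), Nx/Lx by descending cumulative sum,
NGx against each assembly's *own* estimated genome size (undefined when
the assembly does not reach the threshold), GC over non-N bases,
non-ACGTN symbols counted as N.

**Usefulness** is the share of the estimated genome size held in
scaffolds at least one average gene long: 7 kb for invertebrates (the
mean protein-coding gene span measured from model-organism annotations;
`mean_gene_length` recomputes it from any GFF3) and 25 kb for
vertebrates. It can exceed 100% when an assembly outsizes the estimate.

**Completeness proxy.** Single-copy-ortholog census tools need external
databases, so completeness is proxied by marker recovery: a marker
sequence is *complete* when one scaffold contains ≥90% of its distinct
canonical k-mers, *fragmented* when only the union of scaffolds does,
*missing* otherwise. On synthetic assemblies with a known deleted
fraction the missing rate tracks the deletion within a few points.

**Ranking.** Each parameter row (parameters × assemblies) is
standardized to `direction · (x − mean)/SD` (sample SD; zero-spread
rows score 0, so every row sums to 0); per-criterion scores are the
sums over the configured parameter panels (completeness /
contiguity(7) / usefulness(2) by default, config-driven so other
panels can be swapped in). Labels per criterion: good when the
cumulative score is ≥ median + 1 SD of the scores, poor when ≤ median −
1 SD, else average. "Standardized score" has a second common reading —
median/MAD — which is available behind `robust=True`; the mean/SD
reading is the default. The classification uses the SD of the
cumulative scores (not of the pooled z values); with both readings
available the choice is explicit rather than silent.

## Pipeline order

The full run is simulate → count → bin → recruit → **spectrum** →
assess: genomic features are estimated from the *recruited host reads*,
not the whole hologenome, since symbiont k-mer mass would inflate every
size estimate. This mirrors the motivating workflow, where binning is
what makes assembly-free host genomics possible at all. All randomness
derives from one root seed through per-stage `SeedSequence` children;
reruns reproduce all outputs byte for byte.

## Problem sizes used in the test and acceptance runs

Recovery suites run at desk scale, chosen to keep the full suite in
minutes while leaving every signal (two coverage peaks, error limb,
repeat tail, six-genome community structure) well resolved:

* spectrum recovery: 2 Mb diploid host, het 0.5%, repeats 15%, 60x,
  error 0.5%, 2x250 paired reads (~480k reads);
* heterozygosity recovery: 1 Mb host at planted 1.0% and 0%;
* binning/recruitment: 1 Mb host at 70x plus five symbionts of
  100–300 kb spanning GC 30–65% at 10–40x, ~5 kb contigs.

## Known limitations

* The exact in-memory counter and the O(n²) pairwise binner are desk-
  scale tools; cluster-scale datasets need streaming counters and
  mappers, which are explicit non-goals here.
* The NB mixture is a simplified model: no k-mer duplicity linkage, no
  error component inside the fit (errors are pre-filtered at `e`),
  shared dispersion. It recovers sizes and heterozygosity on synthetic
  spectra; on real spectra with strong coverage bias the full
  GenomeScope-style model will behave better.
* The single-linkage binner has no probabilistic TNF distance table; a
  single borderline contig pair can bridge two bins if τ is set
  generously. τ and w are exposed and logged for exactly that reason.
* Marker recovery is sequence-identity-based and will call diverged
  orthologs missing; it is a proxy for, not a reimplementation of,
  database-driven ortholog censuses.
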