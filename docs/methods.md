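# Methods

This note documents the models, conventions and design choices behind
`ribolife`, and what the synthetic benchmarks do and do not establish.

## Coordinate conventions

All internal coordinates are 0-based half-open on the forward genomic
strand. GFF3 I/O converts from/to 1-based inclusive; BED/bedGraph stay
0-based half-open. Transcript models are single-exon (yeast-style): a
CDS with optional abutting 5'/3' UTRs. For minus-strand genes the
5'UTR lies to the right of the CDS in genomic coordinates, and a
footprint's "5' end" is its rightmost genomic coordinate.

## uORF prediction

A candidate uORF opens at every ATG, GTG or TTG in the 5'UTR (sense
strand) and extends codon-wise to the first in-frame TAA/TAG/TGA.
Choices where the definition is genuinely open:

* Candidates whose first in-frame stop lies beyond the UTR end (the ORF
  runs into the main CDS) are emitted with `truncated=True` and the
  interval clipped to the UTR, so that occupancy counting uses only the
  UTR portion.
* An N inside a codon terminates extension and marks the candidate
  truncated (conservative handling of ambiguity).
* Nested and overlapping candidates are all kept; counting operates on
  the per-gene union of uORF intervals, so no collapsing is needed.
* A minimum-length filter exists (`min_length`, nt) and defaults to 0.

## P-site calibration

For each read length L, the offset d_L is the candidate in 9–15 nt
(bracketing the canonical yeast 12–13 nt) maximizing the number of
reads whose 5' end + d_L equals an annotated CDS start position; ties
break to the smallest offset. A length is calibrated only when at
least 500 start-proximal footprints are available (`min_start_reads`,
config-exposed), and accepted only when the frame-0 fraction of its
in-CDS P-sites strictly exceeds frames 1 and 2.

Frame fractions exclude P-sites within the first 15 nt of each CDS.
The initiation pileup present in real (and simulated) data is uniform
across frames at the true offset, but leaks asymmetrically into
specific frames when a shifted candidate offset moves part of the
pileup out of the CDS; excluding the start-proximal margin removes that
artifact and matches the empirical observation that positional bias in
footprint data is confined to the start region.

## Region counting and normalization

Each accepted-length read contributes its count at its P-site. P-sites
in the 5'UTR increment `utr5`, in the CDS `cds`, and inside the uORF
union additionally `uorf` (so `uorf <= utr5` always). Positions covered
by two same-strand genes are discarded entirely — the region-level
analogue of counting only uniquely mapped reads. Normalized counts are
raw counts × 10^6 / (total accepted-length footprints in the library);
replicate aggregation per strain sums raw and normalized counts. The
P-site (rather than full-footprint overlap) convention for UTR counting
is a documented choice and is switchable at the cost of the offset
arithmetic only.

## Occupancy ratios

A gene enters the strain comparison only when its raw aggregated counts
exceed 50 (strictly) in both the numerator region (5'UTR or uORF union)
and the CDS, in both strains; the filter intentionally uses raw counts,
because a read-count threshold denotes reads, while the ratios
themselves use normalized counts. Distributions are compared with the
two-sided Mann–Whitney U test; the median per-gene log2(r_A/r_B) is
reported as effect direction. Note the per-gene pairing makes the rank
test conservative under the null (validated by the null-level
benchmark).

## Fold-changes, significance and TE

Normalization uses median-of-ratios size factors (geometric-mean
reference over all-nonzero rows, total-count fallback with a warning).
The fold-change estimator is deliberately simple: log2 of pseudocounted
(0.5) normalized condition means, a two-sided Welch t-test on
log2(normalized + 0.5) across replicates, BH step-up q-values over
tested genes, and a low-count gate (total raw < 10) that excludes genes
from testing. This replaces a negative-binomial shrinkage model on
purpose: downstream logic needs fold-changes and an FDR gate, not
shrinkage machinery, and the calibration benchmark bounds the realized
type-I error instead of claiming equivalence. The significance rule is
strict: up iff log2FC > 1 and q < 0.01; down symmetric. TE fold-change
is the difference of log2 fold-changes; TE classification reuses the
same gate (an assumption, flagged here).

The Mann–Whitney implementation uses exact enumeration of all rank
labelings for tie-free samples with n_a + n_b ≤ 12 and otherwise the
normal approximation with midranks, tie correction and a 0.5 continuity
correction. Integer division counts in lifespan data routinely tie, so
the approximation is the default at typical assay sizes.

## ChIP peaks, promoter targets and motif scoring

The peak caller slides 150-nt windows at 25-nt steps and keeps windows
where the ChIP count exceeds 4× the depth-scaled input expectation and
the Poisson upper-tail p-value is below 1e−5; overlapping significant
windows merge, and the summit is the argmax of the smoothed
(Gaussian, σ = 25 nt) ChIP-minus-scaled-input profile. Raw per-base
argmax would wander tens of nt under Poisson noise. Externally called
peaks can be imported (narrowPeak) and used in place of the caller.

Promoter windows are the W = 1000 nt upstream of the CDS start
(strand-aware, clipped at chromosome ends); note this span contains the
5'UTR. A summit inside exactly one window gives a unique target;
inside ≥ 2 windows (divergent promoters) the peak is ambiguous and
excluded from the target list. Summit-to-start distance is
CDS start − summit on plus, summit − CDS end on minus (positive =
upstream).

PWM site scores are Σ_i log2(f[w_i,i]/π[w_i]) with columns
pseudocount-renormalized; N bases contribute the background-weighted
mean, which is exactly 0 for normalized columns. The promoter score is
the maximum over all windows on both strands (minus-strand windows are
scored on the reverse complement); ties break leftmost, then plus
strand. A site counts as "present" when its score reaches a per-motif
threshold, default 60% of the PWM's maximum achievable score and
config-exposed — published motif-occurrence percentages depend on the
cutoff convention of the discovery tool, so no default is claimed to
reproduce them. Background π is uniform by default and can be estimated
from the promoter set. Configuration classification compares the
positions (CDS-start-relative, negative = upstream) of the best Gcn4
and Rap1 sites: the more-negative position is upstream.

## Synthetic data generator

The generator is first-class, tested code: it plants truth through
every layer so each analysis stage has an oracle.

* **Genome/annotation**: genes laid out on one chromosome as
  [promoter 1 kb][5'UTR 50–300 nt][CDS 300–1200 nt][3'UTR 100 nt][gap],
  random strand. 5'UTR backgrounds are drawn from {A,C,T} with a C
  guard base before each planted start codon, which provably makes the
  planted ATG/GTG/TTG uORFs (1–5 codon bodies, TAA stop) the only ORF
  starts in the UTR — the ground-truth record coincides with an
  exhaustive scan. Promoters are scrubbed of chance consensus matches
  before motif planting, so the planted site is its promoter's best
  hit. Motif and summit offsets are anchored at the CDS start.
* **Counts**: gene expression weights are log-normal (σ configurable);
  counts are negative-binomial via gamma–Poisson mixing with dispersion
  0.05 by default, sample means scaled to the library size, planted
  log2 fold-changes applied per gene set in the non-reference
  condition.
* **Footprints**: P-sites land on codon frame 0 with probability
  `frame_purity` (default 0.7, remainder split over frames 1/2);
  5' ends are placed at P-site − d_L (strand-aware) with lengths 28–32
  and offsets {28:12, 29:12, 30:13, 31:13, 32:13}; 8% of CDS footprints
  sit on the initiation codon, emulating the start-codon pileup of real
  footprint libraries. 5'UTR per-nt density is 0.5× the CDS density
  (a realistic sub-CDS occupancy) times a per-condition occupancy
  factor (the uORF-skipping dial, 0.4 in the long-lived condition) and
  an optional per-gene factor; 80% of UTR mass falls in the uORF union.
* **ChIP**: input is smoothed uniform Poisson noise (depth 5); ChIP is
  Poisson around input × (1 + Σ multiplier·Gaussian(σ = 75 nt)) bumps
  at planted summits.
* **Lifespan**: division counts are a rounded gamma with shape 6
  (right-skewed positive counts resembling published lifespan curves;
  the family is a free choice and config-exposed), means 19.6 / 28.48
  and 28 / 30 cells by default.

What the generator does **not** emulate: sequence-dependent ligation
and PCR biases, codon-level dwell-time variation, multimapping
ambiguity (beyond region-level overlap removal), chromatin-accessibility
structure in ChIP input, and censoring in lifespan assays. Benchmarks
passing on this generator therefore validate the statistical and
geometric logic of the pipeline, not robustness to those artifacts.

## Determinism

Every stage draws from `numpy.random.default_rng` streams keyed by
(master seed, stage name[, condition, replicate]) via CRC32 hashing, so
outputs are bit-reproducible for a fixed seed regardless of execution
order; the demo plus full pipeline run is byte-identical across runs,
which the test suite asserts.

## Benchmark problem sizes

The planted-truth benchmarks use desk-scale sizes chosen to keep the
statistical claims meaningful: 40–360 genes, 1–3 replicates,
100k–300k footprints per library, 20 seeds for power claims and 40 for
level claims, 1000 genes × 6 samples for fold-change recovery. The
uORF-skipping scenario yields ≈ 300 filter-passing genes per seed. The
lifespan worked example (mean divisions 28.48 vs 19.6 → 45.3% increase)
is computed, not hard-coded, by `percent_increase`.

## Known limitations

* The fold-change estimator has no dispersion shrinkage or outlier
  handling; at n = 3 its per-gene power is modest, and borderline
  planted effects may classify as unchanged.
* Splice-aware transcripts and 3'UTR analyses are out of scope.
* The peak caller has no local-background (λ-local) model; strong
  input artifacts would need an external caller.
* `run_pipeline` stages are independently re-runnable and
  deterministic; "resume" re-executes stages rather than loading
  partial state, which at these problem sizes is cheaper than a
  checkpointing layer.
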