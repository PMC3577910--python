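# Methods

## Model

One macronuclear chromosome is tracked at a time; a cell's state is its
copy number `x ≥ 0` and a cell with `x = 0` is dead (it never divides or
seeds a culture). Amitotic division doubles the copies and splits them
binomially: one daughter draws `a ~ Binomial(2x, 1/2)`, the other gets
`2x − a`. Daughter copies therefore sum to exactly `2x` on every
division, which has a useful consequence: **without selection the total
copy count of a culture doubles deterministically each generation**, so
a neutral culture can never lose every copy and neutral lineage
extinction is impossible. The neutral bottleneck walk (pick a uniform
cell as the next founder) is a martingale wherever zero-copy daughters
are negligible; once a lineage drifts to low copy numbers, discarding
dead daughters truncates the low tail and the conditional mean given
viability exceeds the founder value. This is a property of the process,
not an estimator bias, and it is why martingale checks in the test suite
are run either over a single transfer cycle (where conservation makes
the culture mean exact) or from a high-copy start (1000 copies, where
zero-copy daughters are unreachable in 276 generations).

Stabilizing selection uses a Gaussian fitness surface

    W(z) = exp(−z² / (2ω²)),        z = (x − θ)/θ,

applied as an independent per-cell survival probability after every
division round (including the last of a cycle), after removal of
zero-copy daughters. `θ` is the optimum and equals the starting copy
number of the experiment; `ω²` is the squared width of the surface —
the sweeps use 0.02–0.80, where 0.02 is strong selection. The deviation
`z` is *relative*: the surface width then scales with the chromosome's
abundance, and an order-1 `ω²` grid produces mortalities spanning ~0–30%
rather than instant extinction (with absolute deviations `x − θ`, a
single division's typical excursion of √(x/2) copies would be several
surface-widths and every culture would die immediately; the absolute
variant remains available as `SelectionParams(mode="absolute")` for
sensitivity checks).

## Serial-transfer protocol

Each transfer cycle grows the main and a tandem backup culture from
single founder cells through 12 synchronous, non-overlapping generations
(4096 cells when nothing dies). If the main culture dies within a cycle
the backup is promoted; if both die the lineage is extinct and stays so.
Otherwise two cells are drawn uniformly without replacement from the
surviving main culture as the next main and backup founders — the backup
is re-derived at every transfer, so stale backups never persist. The
default protocol is 23 transfers × 12 generations = 276 generations.
Trajectories record the main culture's mean copy number per transfer;
backups are bookkeeping only.

Two execution paths exist: `run_lineage` (one line at a time, the
readable reference) and `run_lineages` (all lines' cells in one flat
array with per-culture bincount bookkeeping, chunked at 1024 lines to
bound memory). They consume random numbers in different orders, so they
agree in distribution, not draw-for-draw; the suite checks their
extinction rates against each other statistically.

## Experiments

*Change in among-line variance.* Per replicate, 6 founder copy numbers
are drawn from a normal distribution matched to the measured initial
mean and variance (rounded, truncated below at 1, mirroring counts),
each run through the full protocol; the statistic is the sample variance
of surviving lines' final mean copy numbers minus that of the same
lines' starting values. Lines extinct mid-experiment are excluded (the
wet assay can only measure surviving lines); replicates with fewer than
two survivors are flagged and excluded from summaries. An optional
`transform` (e.g. natural log) is applied to line-level values before
taking variances so simulated deltas can be compared on the same scale
as variance components estimated from log-transformed measurements —
this is how the CLI's experiment-versus-simulation report is computed,
since variance components on the raw copies scale and on the log scale
are not commensurable.

*Mortality sweep.* 60 lines starting (and with optimum) at 66 copies —
the lowest-abundance chromosome in the design — across an `ω²` grid,
default 0.02–0.80 in steps of 0.02; mortality is the extinct fraction.
The measured curve falls steeply as `ω²` grows to ≈0.2 (≈30% mortality
at 0.02) and is flat within Monte-Carlo noise beyond (≈1–2%, shallow
minimum near 0.3): weak selection still loses the occasional lineage
that drifts to low copy numbers, where the fitness floor
`W(z=−1) = exp(−1/2ω²)` combines with zero-copy daughters into a
demographic vortex. Because of that flat tail, monotonicity checks on
the weak-selection side carry a 3-standard-error sampling allowance;
zero-tolerance ordering of a flat region would only test noise.

*Regulatory-model oracle.* The contrasting hypothesis — copy number is
reset to the parental state after every division unless the chromosome
is lost outright — reduces to a geometric loss time with per-generation
probability `2^(−2x)`. It is simulated generation-by-generation as a
comparison utility; with ≥ a handful of copies, loss effectively never
happens, which is the point of contrast with unregulated drift.

## Statistics

Copy numbers spanning two orders of magnitude are compared after a
natural-log transform (any base only rescales variance components
uniformly). The among-line variance component uses the balanced one-way
method-of-moments estimator

    MSB = m·Σ(ȳᵢ − ȳ)²/(k−1),   MSW = ΣΣ(yᵢⱼ − ȳᵢ)²/(k(m−1)),
    σ²_line = max(0, (MSB − MSW)/m),   σ²_resid = MSW,

with negative estimates truncated at zero (standard practice). For
balanced designs this agrees with REML whenever `MSB ≥ MSW`, and being
closed-form it is exactly testable against hand-computed fixtures.

Uncertainty comes from a nonparametric percentile bootstrap whose
resampling unit is the **cell line** (within-line replicates travel with
their line — the inference target is among-line variance). Intervals
entirely above zero are classified "increase", entirely below
"decrease", else "no change". A caveat the test suite documents
honestly: with only 6 lines the percentile interval behaves like a
z-interval with a plug-in standard error where a t(5) quantile is
needed, so its true coverage for a nominal 95% interval is ≈87%, and
calibration checks at n = 30 sit near 93%. That is an inherent
small-sample property of the percentile method, not an implementation
artifact.

Experiment-versus-simulation contrasts use a permutation Welch t-test:
pool both samples, re-split at the original sizes 10,000 times (default)
and report `p = (1 + #{|t*| ≥ |t|}) / (n_perm + 1)`, never zero; when
both groups are constant and equal the statistic is defined as 0 and
p = 1. Families of contrasts across `ω²` levels are Bonferroni-corrected
(via statsmodels; arithmetic `min(1, p·n)`).

## Synthetic qPCR generator

The generator emulates the measurement design: 6 clonal lines × 2
timepoints × 3 independent DNA extracts × 4 chromosomes (144 records).
Per gene, each line receives a lognormal "true" copies-per-cell value
around `true_mean` with relative SD `among_line_cv`; each extract
observes it with multiplicative lognormal noise (`measurement_cv`); the
final timepoint multiplies the line truth by `final_shift`. Lognormal
parameters are mean-exact (`σ² = ln(1+cv²)`, `μ = ln(mean) − σ²/2`).
Defaults: SSU 10,000 copies with `final_shift` 1.2 (emulating the
observed increase of the rRNA chromosome), α-tubP1 1345 (the ΔΔCt
reference anchor), EF1α 500 (intermediate, configurable), α-tubP2 66
(the lowest-copy chromosome and the mortality sweep's start value);
among-line CV 0.15 and measurement CV 0.05, chosen once as realistic for
extract-level qPCR of clonal lines. The ΔΔCt conversion assumes 100%
amplification efficiency: `copies = reference · 2^(−ΔΔCt)`.

What the generator deliberately does not emulate: amplification-
efficiency variation between primer pairs, well-level technical
triplicates (extract-level values are the analysis unit), plate effects,
and any real covariance between chromosomes within a line. Passing
recovery tests therefore show the pipeline is consistent with its own
generative model, not that real qPCR data meet these assumptions.

## Problem sizes and numerics

The replicated experiments default to the full design (1000 replicates);
the test suite and the acceptance script run scaled-down versions chosen
to keep total runtime at minutes on one CPU — mortality at 60 lines × 50
replicates per grid point over {0.02, 0.2, 0.4, 0.8}, variance
experiments at 200 replicates, calibration checks at 1000–2000
meta-replicates — sizes at which every qualitative contrast tested is
several standard errors wide. All stochastic APIs take an explicit
`numpy.random.Generator`; a fixed seed reproduces results bit-for-bit,
and the CLI writes a manifest sufficient to re-create any output
byte-for-byte. Counts are int64 throughout; copy numbers in realistic
regimes (≤ ~10⁴ copies, 12 doublings) sit far below overflow.
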