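# Methods

## Model

One sample per species; read counts of one-to-one orthologous genes are
independent Poisson variables with mean

    E(X_gt) = mu_gt · L_gt / S_t · N_t,     S_t = Σ_g mu_gt · L_gt,

for species t ∈ {1, 2}. `mu_gt` is the true expression level (arbitrary
units — only ratios matter), `L_gt` the transcript length in bases, `N_t`
the total orthologous read count, and `S_t` the total expression output.
The null hypothesis for gene g is mu_g1 = mu_g2. Multiple samples per
species are pooled by summation before analysis: the conditional test
consumes one count per species.

The scaling factor c = S2/S1 enters through the conditional test:
given n_g = x_g1 + x_g2, the species-1 count is Binomial(n_g, p0) with
p0 = c·L1·N1/(L2·N2 + c·L1·N1). Note the model has a gauge freedom:
multiplying every species-2 length by a constant multiplies c by the same
constant while leaving all counts unchanged. c is therefore identifiable
only *through the recorded lengths* — which is also how the synthetic data
realises a known non-trivial c (below).

## Exact test — numerical choices

* Two-sided region: absolute deviation, P(|X − n·p0| ≥ |x1 − n·p0|), not
  doubling of the smaller tail. The two differ for asymmetric p0; the
  deviation form is the published definition and is what we implement.
* Tail masses come from the binomial CDF / survival function (one call per
  tail), never from accumulating pmf terms, so totals of 10^5+ reads per
  gene stay accurate; agreement with brute-force enumeration is asserted to
  1e-12 for all n ≤ 60.
* Boundary: the qualifying-set comparison is evaluated with an absolute
  slack of 1e-9·n so that the observed outcome itself is always included
  under floating-point rounding.
* n = 0 returns p = 1: a pair with no reads carries no information and must
  contribute "no rejection" to any empirical rejection rate.
* Degenerate inputs (c ≤ 0, zero depth, p0 outside (0,1)) raise.

## Scaling-factor estimator

Objective: J(c) = |(1/m)·#{g ∈ H : p_g(c) < alpha} − alpha| over the
conserved anchor set H, with strict `<` and alpha defaulting to 0.05 (the
level is a free parameter of the method; 0.05 is the conventional choice).

Search: J is a step function of c, so we use a two-stage grid — 601
log-spaced points on [1e-3, 1e3] (log spacing respects the c ↔ 1/c species
swap symmetry), then 401 linear points across the selected coarse interval
widened by one coarse step. Both stages are evaluated as one broadcast
binomial-tail call over (grid × genes).

Selection within the grid: the test is discrete, hence conservative — at
the true c the empirical rejection rate of truly-null anchor genes sits
*below* alpha (at the default study sizes, ≈0.034–0.045 at alpha = 0.05).
J then attains its minimum on two plateaus that flank the conservatism dip,
and choosing either biases the estimate by the width of the dip (measured:
a systematic 6–10% error). We therefore treat the whole dip as the
candidate region: when the rate curve reaches alpha or below, the candidate
intervals are the maximal runs with rate ≤ alpha, and the estimate is the
geometric midpoint of the widest such run; when the rate stays above alpha
everywhere (well-powered or heavily contaminated anchor sets), the
candidates are the plain argmin plateaus. Ties in width are broken by
closeness (in log c) to the median-baseline anchor, then by smaller c.
With this rule the estimator recovers the true factor with a median error
of ~0.3% (max ~3%) over 20 clean replicates at the default study size, and
within ~1% with 40% anchor contamination.

Reported diagnostics: the selected interval (`plateau_`), the minimised
deviation (`objective_value_`), the grid description, and the median-method
anchor. In the dip regime the objective is *not* constant across the
reported interval — its edges are the argmin points; the midpoint is the
calibrated estimate.

## Median baseline

Per conserved gene, adjusted expression e_t = x_t/(L_t·N_t); genes whose
e_t lies within each species' interquartile range over the conserved set
are retained; the factor is the median of e_1/e_2 over the retained genes.
Under the mean model e_1/e_2 estimates S2/S1 gene-by-gene, so the baseline
is on exactly the same scale as the exact test's c and the two methods are
directly comparable. The published description of this baseline is not
algebraically explicit; the formula above is this package's contract for
it.

## pFDR estimator

Plug-in form with empirically estimated conditional rejection rates over a
known non-DE/DE partition (V0/V1); P(H0) defaults to the empirical
n0/(n0+n1) and may be overridden. pFDR conditions on at least one
rejection, so a zero denominator is an explicit error, never a silent 0.

## Synthetic data

The generator emulates a two-species bulk RNA-seq comparison:

* `n_orth` = 10000 regular orthologs (the published benchmark does not
  state this number; 10000 gives stable empirical rates with a 1000-gene
  anchor set).
* DE fraction `prop_de` = 0.1 at `fold` = 1.2 (base setting), direction
  drawn per gene as Bernoulli(`prop_up_sp2` = 0.9, up in species 2).
* Unique genes (orthologous, expressed in one species only): 1000 / 2000.
  They are truly DE (mu = 0 in one species) and are flagged by
  `unique_mask`.
* Unmapped genes (present in one genome only): 2000 / 4000, simulated per
  species for library realism but excluded from the ortholog table and from
  N_t, which counts orthologous reads only.
* Lengths: log-uniform on [200, 20000] bases, independently per species,
  with species-2 lengths scaled by 2.0. The scale difference is what makes
  the true c = S2/S1 ≈ 2 (see the gauge argument above); it also mirrors
  the large cross-species transcript-length differences seen in real
  human/mouse data.
* Expression rates: log-normal(0, 1.5), a stand-in for an empirical
  count-rate distribution (the benchmark's own empirical distribution is
  unpublished); an empirical rate vector can be supplied instead.
* Depths: (1e7, 2e7) expected orthologous reads. The benchmark leaves
  depth unstated; 1e7 per library is the realistic scale of a bulk RNA-seq
  experiment, and it is the regime in which the published precision values
  (which require sensitivity ≈ 0.6 at 1.5-fold) are attainable at all. At
  1e6 reads the exact test's sensitivity at 1.5-fold drops to ≈ 0.2 and no
  normalization method can reach the published precisions.
* Conserved anchor set: `m_conserved` = 1000 genes, `round(noise_rate·m)`
  drawn from the DE genes and the rest from non-DE genes. Infeasible
  compositions raise before any data are drawn.
* Everything is reproducible bit-exactly from the seed; the true c is
  recorded exactly as S2/S1 from the drawn (mu, L).

What the generator does **not** emulate: biological overdispersion
(negative-binomial noise), replicate correlation structure, mapping
artefacts, and the heavy, spiky tail of real empirical expression
distributions. Passing benchmarks on this generator therefore demonstrate
correctness and calibration of the machinery under the stated Poisson
model, not performance on real overdispersed data.

## Evaluation conventions

* Rejection is strict `p < cutoff` everywhere.
* Precision with zero predicted positives is recorded as missing (NaN) and
  excluded from means — 0/0 must not average as 0.
* Unique genes are excluded from precision / sensitivity / false-discovery
  accounting in the study runner: they are structural presence/absence
  differences that any method detects trivially, and counting them as true
  positives would pin precision near 1 regardless of normalization quality,
  hiding exactly the effect the benchmark measures.
* The real-data FDR proxy is (#DE calls inside an assumed-non-DE conserved
  set)/(total #DE calls).
* Adjusted M/A values: M = log2 of the ratio of length/depth-adjusted
  expressions, A = their mean log2; the normalization line sits at
  M = log2(c). Zero-count genes are excluded with a recorded count.

## Study runner and problem sizes

`study_configs()` encodes the seven benchmark parameterizations (anchor-set
size sweep; noise sweeps at fold 1.5; an 8-fold / 20%-DE variant; a cutoff
sweep at 40% DE; a DE-rate sweep at noise 0.2). The published benchmark
averages 100 replicates; this package defaults to `reps=100` in the runner
but the shipped tests and `scripts/acceptance.py` use 20 replicates per
condition, which gives Monte-Carlo standard errors on mean precision of
≈ 0.005 — ample for the comparisons made — while keeping a full run in tens
of seconds.

## Known limitations

* **Anchor contamination beyond 50%.** With noise drawn from a DE pool that
  is 90% up-regulated in species 2, the contaminated anchor genes form a
  coherent cluster at c/fold. Once they are the majority (noise rate 0.6),
  the global minimum of the type-I-deviation objective provably moves to
  that cluster — verified directly on the rejection-rate curves, which show
  the clean-c local minimum sitting strictly above the contaminant one at
  every depth tried. The estimator therefore locks onto the contaminant
  scale at noise 0.6 and its precision collapses, as does (differently) the
  median baseline's. The published benchmark reports the calibrated method
  staying flat through noise 0.6; that behaviour is not reproducible from
  the stated objective under this contamination model, and this package
  reports what the objective actually yields. Robustness up to ~40%
  contamination is real and reproduced here.
* The conditional test assumes Poisson counts; with overdispersed data its
  p-values are anti-conservative and the calibration objective inherits
  that bias.
* The median baseline's IQR filter needs enough doubly-expressed conserved
  genes; tiny anchor sets can leave it undefined (raised as errors).
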