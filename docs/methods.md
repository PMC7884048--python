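# Methods

This note records the models implemented by `txstress`, the assumptions
behind them, the defaults and why they were chosen, and the places where a
genuine design choice had to be made. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## The lesion model of transcription stress

Transcription-blocking DNA lesions are assumed to occur stochastically and
uniformly per base pair, so the lesion count on a gene of transcribed
length *L* kb in a condition with lesion rate λ (lesions/kb) is Poisson
with mean λ·L, and a transcript is produced only from lesion-free
templates. The mean expression multiplier is therefore the zero-count
probability

    E[expr] ∝ exp(−λ·L).

This is the simplest mechanism consistent with lesion likelihood being
directly proportional to gene length; it makes the log mean ratio between
two conditions *linear* in length, ln(mean_B/mean_A) = c − Δλ·L, which is
what `estimate_lesion_rate` inverts by weighted least squares (weights from
the delta-method variance of the log mean ratio; ordinary least squares in
the noiseless limit). Alternative forms (e.g. per-polymerase survival
along partially transcribed genes) would change the functional form; the
exponential choice is documented here precisely because the biology fixes
only "proportional likelihood", not the link function.

### Simulator defaults

| parameter | default | rationale |
|---|---|---|
| gene lengths | round(10^N(4.2, 0.6²)) bp, ≥ 200 | log-normal with median ≈ 16 kb and a heavy right tail, the shape of mammalian gene-span distributions |
| λ (repair-deficient) | 0.004 /kb | gives a clear but not saturated length skew: a 100 kb gene loses ~33% of expression, a 10 kb gene ~4% |
| λ (wild-type) | 0 /kb | baseline condition |
| DR λ factor | 0.5 | dietary restriction halves the lesion load in the default truth scenario; rapamycin leaves λ unchanged |
| baseline | 8.0 log2 units | arbitrary microarray-like intensity scale |
| noise | log-normal, sd 0.25 on log2 | typical between-replicate spread of normalized arrays |
| programmed DE | 5% of genes, log2FC ±1 | length-independent regulated genes, drawn independently of length so any length bias in DEG calls is attributable to λ alone |
| samples/group | 5 | matches the 4–5 animals per group of liver-array experiments |

Random streams derive from `numpy.random.SeedSequence(seed, spawn_key)`
with a fixed key per operation and a CRC-32 of the group label for
per-group streams, so adding or reordering groups never perturbs another
group's draws, and equal seeds across groups do not alias.

### What the simulator does *not* emulate

Probe-level artifacts (the simulation is at the gene-summary level),
normalization residuals, correlated gene modules, batch effects, and
length-correlated programmed regulation. Passing tests therefore show the
*statistics* behave as designed under the stated generative model — they
do not validate normalization pipelines for real arrays, where the user
must supply an already-normalized matrix.

## DEG calling

Per gene, a two-sample test on log2 intensities with empirical-Bayes
variance moderation on the Welch scale: with per-group squared standard
errors v = s²_A/n_A + s²_B/n_B and Satterthwaite df d, the moderated
variance is ṽ = (d₀·v̄ + d·v)/(d₀ + d) with prior df d₀ (default 4) and v̄
the cross-gene mean, and the reference distribution is Student t with
d + d₀ df. Setting d₀ = 0 recovers the plain Welch test exactly, which is
what the hand-arithmetic oracle tests exercise. Benjamini–Hochberg
q-values are computed over all genes; a DEG requires q < 0.05 **and**
linear |FC| ≥ 1.5. This transparent moderation is deliberately simple
enough to verify by spreadsheet; users wanting the full linear-model
machinery can swap in limma-style pipelines upstream and still use
`length_bias` downstream.

## Length-bias statistic

Up- and down-regulated DEG lengths are compared on the log10 scale:
Gaussian KDEs with Silverman bandwidth evaluated on a common 512-point
grid spanning both classes ±3 kernel SDs, and a two-sided
Wilcoxon–Mann–Whitney test (exact when both classes have ≤ 25 members,
tie-corrected normal approximation with continuity correction otherwise).
Because a Gaussian kernel centred at an extreme observation carries ~0.13%
of its mass beyond 3 SDs, the evaluated curves are renormalized to unit
trapezoid mass on the grid — the exported densities are proper relative
frequencies regardless of grid truncation. Null calibration of the test is
checked by passing *all* genes, split by fold-change sign, under a no-DE
simulation: sign is then independent of length and rejections are false
positives. The measured size of this procedure is computed by the
acceptance suite, not asserted here.

## Survival statistics

Kaplan–Meier, log-rank and hazard ratios are implemented directly (rather
than delegated) because the result objects expose the per-group observed
events O, expectations E and hypergeometric variance V that the toy-example
oracles and the hazard-ratio estimators consume; `lifelines` serves as an
independent cross-check oracle in the tests. Conventions:

- times in weeks, ≥ 0; deaths precede censorings at equal recorded times;
- two-sided p-values; χ² reference with df = 1 for two-group tests;
- stratified log-rank sums O−E and V over strata; a stratum lacking either
  group is dropped with a warning; a single stratum reproduces the
  unstratified test exactly;
- hazard ratios: Mantel–Haenszel ln((O_A/E_A)/(O_B/E_B)) with
  se = √(1/E_A + 1/E_B) (default), and the score estimator (O_A−E_A)/V
  with se = 1/√V; both are reported with log_hr ± 1.96·se intervals and
  the estimator is recorded in the result. Protective effects in the
  first-listed group give negative log HR.

The χ² log-rank is known to be mildly anticonservative at moderate sample
sizes (tens of events); the acceptance suite measures its size under the
null at n = 25 + 25 with enough replicates that the Monte-Carlo error of
the measurement is small compared to the tolerance band.

Onset-of-phenotype analyses (tremor, imbalance, kyphosis) reuse the same
machinery with onset as the event and death-before-onset as censoring.

## Body-weight AUC ledger

The analysis interval runs from the intervention start week through the
largest week at which *every* group retains ≥ 80% Kaplan–Meier survival
(inclusive at exactly 80%). Animals that died inside the interval are
excluded entirely. Weights are log10-transformed and shifted by the lowest
log10 baseline of the dataset — an additive shift that cannot change
between-group contrasts (property-tested). Per-animal AUCs use the
trapezoid rule with interior missing weeks bridged linearly (the
least-information-adding choice; the alternative — dropping incomplete
animals — discards data the trapezoid can use). A two-sided single-outlier
Grubbs test at α = 0.01 is applied **once** to the pooled AUCs (at most
one removal, no iteration), and group means are compared with Welch's
unequal-variances t test. Animals lacking a start-week weight are excluded
with a warning since no baseline exists for them.

## Optical fractionator

N̂ = ΣQ⁻ · (t/h) · (1/asf) · (1/ssf), with asf = frame area / grid area
and ssf = 1/section period. Nuclei are points (centroids), and the
unbiased counting rules become half-open membership: left/top frame edges
included, right/lower edges excluded, top disector plane excluded.
Systematic random sampling draws a random section-start, a random xy grid
offset, and — by default — a random depth phase for the disector band
(wrapping within the section), which makes every point's inclusion
probability exactly (h/t)·asf·ssf and the estimator unbiased conditional
on the tissue realization. A fixed guard zone (`guard_um`) is available
for matching a physical microscope protocol; with a fixed depth band the
estimator is unbiased over tissue realizations but carries a
cloud-conditional offset of order ±1/√(points in the band), which is why
the randomized depth is the default. Census designs (all fractions 1,
guard 0) recover the true count exactly. Gundersen coefficient-of-error
estimation is out of scope.

## Problem sizes in the test and acceptance suites

Simulation-based checks use: 2000 genes × 5 samples/group for length-bias
calibration (2000 replicates) and power (100 replicates); 10,000 genes for
lesion-rate recovery; 10,000 replicates for the log-rank size measurement
and 200 for hazard-ratio recovery at n = 200/group; 500 random sampling
offsets of a ~10,000-point slab for fractionator unbiasedness. Replicate
counts were set so that the binomial/Monte-Carlo standard error of each
measured rate is several times smaller than the tolerance it is compared
against.

## Known limitations

- The DEG test is a moderated Welch t, not a full linear-model fit; with
  very small groups (n = 2) its df estimate is crude.
- The exact WMW branch relies on scipy's exact null distribution, which
  ignores ties (ties push the switch toward the tie-corrected
  approximation only through class size, not tie presence).
- The lesion-rate regression assumes the programmed-DE fraction is either
  small or balanced in sign; heavy asymmetric programmed regulation biases
  the intercept, not the slope, but shortens the usable length range.
- Weight trajectories are a deterministic group curve plus iid noise; no
  per-animal random effects.
- GTF gene lengths are genomic spans (max end − min start + 1). Transcript
  lengths can be supplied via the two-column TSV instead; the choice
  matters for intron-rich genes and is deliberately left to the user.
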