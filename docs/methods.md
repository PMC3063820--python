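# Methods

`qpcrflux` implements the complete relative-quantification workflow of a
SYBR-green qPCR study of terpene metabolism in *Artemisia annua*: from
raw amplification curves to amplicon efficiencies, outlier-cleaned CT
values, reference-gene selection, efficiency-corrected expression
ratios, 2^-ΔΔCT transcript amounts, and transcript-abundance × k_cat
turnover-potential scores.  This note records the model assumptions,
the defaults that matter, and the design choices made where the
procedure was genuinely open.

## Amplification-curve model and the synthetic generator

A reaction's fluorescence at cycle *c* is modelled as

    F(c) = B + min(A·E^c, P − B) + ε,   ε ~ N(0, σ²)

with baseline *B*, plateau *P*, initial signal *A* and efficiency
*E* ∈ (1, 2] (fold-increase of product per cycle; 2 = perfect
doubling).  The pre-plateau phase is exactly exponential, so
log-fluorescence is exactly linear in cycle number there — the property
every downstream efficiency check is anchored to.  Real curves saturate
smoothly near the plateau and can show drifting baselines and
primer-dimer signal; none of that is emulated, so passing tests show
that the estimators are correct for a clean log-linear phase, not that
they are robust to every instrument artifact.

CT tables are generated from a design (genes × tissues, a control
tissue, per-gene fold-changes) through the identity
`CT(g, t) = CT(g, control) − log_E(fold)`, with:

* technical triplicates with Gaussian noise (default SD 0.15 cycles, a
  typical within-triplicate scatter for SYBR assays);
* two independent biological runs by default, mirroring the two-run
  design the pipeline is meant for — runs share the design but draw
  independent noise;
* outlier triplets (default rate 5%) in which exactly one replicate is
  displaced by +5 to +10 cycles, large enough for a Grubbs test at
  n = 3 to flag;
* a non-detect ceiling (default CT 40, the cycling protocol length):
  reactions beyond it are flagged not-detected and their CT is stored
  as missing, never as 40, to avoid biasing triplet means.

## Efficiency estimation (window of linearity)

Each trace is baseline-corrected by subtracting the mean fluorescence
over cycles 3–15, restricted to cycles still in the flat region (within
5% of the trace range above the minimum), guarding against amplicons
that leave the baseline early.  The window of linearity then bounds the
usable cycles: corrected fluorescence must be positive, at least 10×
the instrument-noise SD (estimated from the flat region or the first
eight cycles, whichever is quieter), and below 90% of the trace maximum
(saturated cycles carry no exponential signal).  All contiguous windows
of 4–6 such cycles are fitted on the log10 scale; the window with the
highest correlation wins, with ties broken toward more points and then
earlier starts, so output is deterministic.

The reported slope of the winning window comes from an
inverse-variance weighted fit: additive fluorescence noise has SD
proportional to 1/F on the log scale, so weights ∝ F² restore the
efficiency of the fit without changing the noise-free answer.  The
efficiency is E = 10^slope (the log base cancels; base 10 is used for
reporting familiarity).  Per-amplicon efficiency is the arithmetic mean
of per-reaction estimates passing a correlation filter (r ≥ 0.998,
configurable); the count of exclusions is reported.  Under these
choices, noise-free curves whose baseline window is signal-free are
recovered to ~10⁻⁷, and at 0.5% plateau noise the per-reaction mean
absolute error is ~0.015.  Bit-compatibility with any release of the
LinRegPCR program is out of scope; CT values are taken as instrument
inputs, not recomputed from curves.

## Replicate QC (Grubbs test)

Technical triplets are screened with a two-sided single-pass Grubbs
test at α = 0.05: G = max|xᵢ − x̄|/s (sample SD), compared against
G_crit(n, α) = ((n−1)/√n)·√(t²/(n−2+t²)) with t the upper α/(2n)
quantile of Student's t on n−2 degrees of freedom.  At most one value is
ever removed per triplet, none from n < 3, and zero-variance triplets
are untouched.  For n = 3 the attainable maximum of G is
(n−1)/√n ≈ 1.1547 against a critical value ≈ 1.1543, so removal occurs
only when two replicates nearly coincide — deliberately conservative.
Survivors are averaged (the tables report average CTs); one-decimal
rounding happens only at reporting.  Single-value groups (tables of
already-averaged CTs) pass through unchanged.

## Reference-gene stability

Candidates are ranked by the SD of their mean CT across samples, with a
composite per-sample index equal to the geometric mean of candidate CTs
(the BestKeeper construction) and a Pearson r of each gene against that
index.  Selection keeps genes with SD < 1 cycle (BestKeeper's published
rule of thumb) whose r clears 0.5, capped at the top k requested; genes
with any non-detected sample are ineligible, and a constant-CT gene has
undefined r, reported as NaN and treated as stable.  On the published
CT table, raw CT SD alone does not single out the three references the
study used (several targets are comparably stable), so selection
assertions are made on synthetic data where ground truth is known.

## Expression ratios and inference

The point estimate is the efficiency-corrected ratio

    ratio = E_t^(ΔCT_t) / geomean_r(E_r^(ΔCT_r)),  ΔCT = CT_control − CT_sample

normalized to one or more reference genes by the geometric mean of
their correction factors.  Significance comes from a fixed-reallocation
randomization test on the log ratio: replicate units — a target CT
paired with the reference CTs from the same well position — are pooled
and reallocated between sample and control groups (2000 iterations by
default), and p = (b+1)/(n_iter+1) counting reallocations at least as
extreme, two-sided.  Keeping units intact preserves the target-reference
pairing; with triplicates this makes the test meaningfully fine-grained
only when at least two biological runs contribute wells (6+6 units ⇒
924 allocations), which is the design default.  Intervals are percentile
bootstrap over replicate units (2000 draws, level 0.95), widened if
necessary to contain the point ratio; degenerate draws are skipped and
the count renormalized.  No multiple-testing correction is applied by
default; a Benjamini–Hochberg option exists.

## 2^-ΔΔCT amounts and turnover potential

Transcript amounts use the Livak form with the amplification factor
fixed at 2, not the measured efficiencies — the convention the source
tables follow (2^8.4 = 338 confirms it).  ΔCT is taken against the
reference gene measured in the same tissue; a calibrator cell (gene,
tissue) is 1 by construction.  The turnover-potential score is

    amount × k_cat × substrate stoichiometry

under the assumptions that active sites are proportional to transcript
level and enzymes operate at substrate saturation; K_m is stored and
reported but does not enter the score.  Squalene synthase consumes two
FDP per catalytic event, so its score counts double (k_cat assumed
≈ 1 s⁻¹, the value the competition argument uses); CYP71AV1 has no
published k_cat and is excluded with an explicit flag.

Paper-rounding mode reproduces table precision: amounts to the nearest
integer, turnover to the nearest integer at ≥ 10 and one decimal below.
One documented discrepancy: computed from the packaged CT table, the
DBR2-specific amplicon gives ΔΔCT = −11.8 in flower buds, not the
published −7.9.  The published value coincides exactly with the
combined DBR2+OPR3 amplicon's CT (23.8 − 23.8 − 7.9 = −7.9,
2^7.9 = 239), suggesting the source table used the combined primer
pair.  The pipeline reports its own computed value for the
DBR2-specific row and flags it `known_discrepancy` rather than forcing
a match.

## Numerical and reproducibility choices

* All randomness flows through `numpy.random.Generator` seeds recorded
  in the run manifest; repeated runs are byte-identical.
* Statistical calibration checks use independent replications (each
  simulated experiment has its own reference wells); sharing reference
  wells across genes correlates their tests and over-disperses
  rejection counts relative to a binomial reference.
* Calibration problem sizes: 200 independent null experiments at 1000
  randomization iterations; efficiency recovery at 100 seeds per
  efficiency value.
* Non-detects propagate as flagged missing values through every stage;
  ratios and amounts involving them are reported as undefined, never
  imputed.

## Known limitations

Plate effects, inter-run calibration drift, melt-curve analysis,
primer-dimer artifacts and absolute copy-number quantification are out
of scope.  The turnover score is a ranking device, not a flux model: it
ignores substrate concentrations, K_m, protein turnover and
translational efficiency.
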