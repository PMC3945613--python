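# Methods

This note documents the models, estimators and numerical choices behind
each `midlink` module, what the synthetic generators do and do not
emulate, and the limits of what the test suite demonstrates.

## Social space

Each chamber snapshot is a set of fly coordinates (mm, arena-centered)
inside a circular arena of radius *R* (default 45 mm, the interior of a
90 mm dish). For every fly the nearest-neighbor distance (NND) is the
minimum Euclidean distance to any other fly, computed with a k-d tree
and verified in tests against an O(n²) scan. Distances are binned into
half-open 5 mm bins `[0,5), [5,10), …` — a distance of exactly 5 mm
falls in the second bin; the convention is ours, since "0–5 mm" does
not resolve the boundary — and expressed as percentages of the
population. The Social Space Index is

    SSI = %bin1 − %bin2  ∈ [−100, 100].

Coincident coordinates are legal (particle centroids from image
analysis can coincide), land in bin 1, and log a warning.

A chamber observed five times contributes one SSI value: the five
capture histograms are averaged per bin and SSI taken from the average
(the default; `pool_distances` offers the alternative of pooling all
captures' distances, which weighs captures by fly count instead of
equally).

Under complete spatial randomness with intensity λ = n/(πR²), the NND
law P(NND ≤ d) = 1 − exp(−λπd²) gives, for n = 40 and R = 45 mm,
≈ 39% of flies in bin 1 and ≈ 47% in bin 2, hence an expected SSI near
−8; edge effects (fewer neighbors near the wall) push it lower. The
uniform generator therefore anchors the "no social structure" end of
the scale, and SSI monotonically increases with simulated aggregation.

Genotype comparison treats replicate chambers as blocks: all genotypes
of a replicate are run simultaneously in adjacent chambers, so
replicate *i* is a within-block factor level set. A one-way
repeated-measures ANOVA (block = replicate, condition = genotype) is
followed by Dunnett's many-to-one comparisons against the control.
Unequal replicate counts are rejected rather than averaged — the
blocked design requires complete blocks.

## Diurnal activity

Input is a per-fly count series on a uniform 5-minute grid, either a
Trikinetics-style monitor file (reading index, date, time, status code,
auxiliary fields, light flag, 32 channel counts; rows with invalid
status codes are rejected, not dropped) or a long `fly_id, timestamp,
count` table. The grid must be complete; a missing interval is an error
naming the gap.

Processing follows the standard reduction: flies that never move during
any 24 h period are discarded (windows aligned to consecutive days from
recording start by default; a `rolling` flag slides the window over
every bin offset, which is strictly stricter); counts are rebinned to
30 minutes by summation (totals conserved exactly); each fly's series
is folded to a 48-bin time-of-day profile by averaging over days, with
the fold aligned to clock midnight; genotype profiles are the mean ±
s.e.m. across flies.

Genotypes are compared with a mixed-design (split-plot) two-way
repeated-measures ANOVA: genotype (between subjects) tested against
subjects-within-genotype, time and genotype × time against the
residual. Per-bin genotype contrasts use an F test of the between-group
means at that bin against the pooled within-cell error
(SS<sub>subjects-within</sub> + SS<sub>residual</sub> over their summed
df — algebraically the pooled within-cell variance, so under iid noise
the per-bin F is exactly F(g−1, (N−g)·T) and the per-bin type-I rate is
α by construction; verified by simulation). Bins are flagged at
P < 0.05 without multiplicity correction, matching the per-bin-asterisk
convention; a Bonferroni option exists and is off by default.

Two summary indices are computed from a daily profile: the light/dark
ratio (total counts while lights are on over total while off) and an
anticipation index per transition — activity in the 3 h before the
transition divided by activity in the 6 h before it. The 3 h/6 h
definition is imposed by this package (anticipation is usually
discussed qualitatively); it is 0.5 for a flat profile, 0.75 for a
linear ramp, → 1 for a sharp pre-transition buildup, and the windows
are configurable. A zero denominator yields an undefined marker
(`None`), never a division error.

## Co-expression screen

Expression input is a gene × sample RPKM matrix (non-negative, no
missing cells, unique labels — violations are rejected with the cell
named). Correlations are Pearson *r* between `log10(RPKM + offset)`
profiles, offset 1 by default: the log scale matches how such data are
presented and stabilizes the right-skewed RPKM distribution. The
8-level equal-width binning of the log range (top edge inclusive,
constant data degenerate to bin 1 with a warning) is reproduced for
display purposes and available as an alternative correlation substrate
(`use_bins=True`) for sensitivity analysis, but ranking uses the
continuous log values: binning only coarsens.

Zero-variance genes make Pearson *r* undefined; they are flagged
explicitly and reported as NaN markers rather than silently dropped. A
degenerate reference gene is an error. Candidates are ranked by the
mean of their per-dataset correlations with the reference (descending;
ties broken lexicographically). With ~30 samples the two-sided α = 0.05
null threshold for |r| is ≈ 0.36, so module correlations near 0.9 are
far out of the null range — the screen's discrimination is verified by
simulation, not assumed.

## Conservation profile

Alignments are consumed, not computed. After reading (aligned FASTA,
lowercase upcased, alphabet = 20 amino acids + `X` + `-`), columns whose
gap fraction is strictly greater than 0.5 are stripped ("majority
gapped"; exactly half is retained), with a 1-based map back to original
columns. Each retained column is scored

    score = 1 − H / ln 20,   H = −Σ p_a ln p_a,

with frequencies over the observed amino acids only — gaps and `X` are
missing observations, not a 21st symbol; a column with no scorable
residues scores 0 and is flagged. The unweighted-frequency entropy
estimator is one of the standard per-column conservation estimators;
sequence weighting is a documented extension point, omitted by default.
A fully conserved column scores 1, a uniform column 0, a 50/50
two-residue column 1 − ln2/ln20 ≈ 0.7686.

Motif positions (e.g. the essential cysteines of the C1/C2 cysteine-rich
domain) are given in 1-based ungapped reference coordinates and mapped
through the reference row's gaps to alignment columns; the conserved
fraction counts sequences carrying the expected residue at that column
(`X` and gaps count as not conserved).

Whether a region out-conserves the rest of the protein is tested by the
statistic mean(region) − mean(rest) against a null built by randomly
relabeling columns; the add-one estimator p = (1 + #{perm ≥ obs})/(1 +
n_perm) guarantees p ∈ [1/(n_perm+1), 1] and counts ties conservatively.

## Statistics

The ANOVA and post-hoc machinery is implemented directly rather than
delegated, so its assumptions are explicit and its calibration is
testable:

- **One-way RM ANOVA**: subjects × conditions grid; SS split into
  condition, subject, residual; F = MS_cond/MS_resid. No sphericity
  correction by default (a Greenhouse–Geisser flag exists): the target
  designs are compared without it, and the type-I calibration of the
  uncorrected test under exchangeable noise is verified by simulation.
- **Mixed two-way RM ANOVA**: split-plot decomposition; the between
  effect is tested against subjects-within-groups, within and
  interaction against the residual. Balanced complete designs only;
  anything else is an error, never silently averaged.
- **Dunnett's test**: balanced many-to-one contrasts share the control,
  giving equicorrelation 0.5 among the k t statistics. Adjusted p =
  P(max_i |T_i| ≥ |t_j|) is evaluated by Monte-Carlo integration of the
  equicorrelated multivariate t (shared-factor construction, default
  100 000 draws, deterministic under seed), floored at the raw t
  p-value so the adjusted ≥ raw invariant holds despite Monte-Carlo
  noise. With k = 1 it reduces to the two-sided paired t (verified to
  |Δp| < 0.005); the k = 2 tail matches an independent bivariate-normal
  rectangle integration.
- **Permutation p**: add-one, one-sided "greater" by default; the
  two-sided variant doubles the smaller tail, capped at 1.
- All p-values are floored at the smallest positive float so extreme
  statistics cannot underflow to 0.

## Synthetic data

The generators define the study conditions the pipelines are validated
under; all randomness flows from one integer seed per call and outputs
are byte-reproducible.

- **Arena**: uniform placement in the disc, or a Matérn-style
  parent/offspring process — parents uniform, offspring Gaussian with
  dispersion σ = R/(1 + 1.5·c) for cluster strength c, so c = 0 is
  uniform and larger c tightens clusters; the 1.5 slope was fixed from
  a pre-build Monte-Carlo oracle so the SSI gradient over c ∈ {0, 0.5,
  1, 2, 4} is resolvable at 200 replicates. A sequential 2 mm hard core
  (≈ one fly body length) is enforced by thinning; unsatisfiable
  packings raise an explicit error naming the density. Defaults follow
  the assay geometry: 40 males, 45 mm radius.
- **Activity**: deterministic daily rate = baseline + Gaussian bumps at
  lights-on and lights-off (default 12/12 schedule, 5-min bins, 7
  days); counts are independent Poisson draws (beam crossings are event
  counts). Knockdown genotypes scale the morning bump, and the
  pre-transition part of the evening bump (the anticipation ramp), by
  the knockdown multiplier. Effect sizes are calibrated for test power,
  not to reproduce any published magnitude, since none is reported for
  these phenotypes.
- **Expression**: module genes share one latent log10 profile plus
  independent Gaussian noise, with the latent sd set to
  noise_sd·√(ρ/(1−ρ)) so every module pair has correlation ρ (ρ = 1 is
  special-cased to identical profiles); non-module genes are
  independent with matching total variance; RPKM = 10^log-value ≥ 0.
- **MSA**: row 1 is the ungapped consensus reference (so motif
  coordinates are well-defined); other rows match the column consensus
  with the motif or background conservation probability, otherwise draw
  uniformly; gaps injected per cell, never in the reference.

What the generators deliberately do **not** emulate: spatial wall
attraction or social interaction dynamics beyond static clustering;
circadian free-running (constant-darkness) behavior, activity
autocorrelation or sleep structure; expression-count mean–variance
coupling, batch effects or compositional normalization; phylogenetic
correlation among alignment rows (sequences are exchangeable given the
consensus). Passing tests therefore demonstrate correctness and
calibration of the estimators under these idealized conditions, not
robustness to every artifact of real recordings.

## Problem sizes and numerical choices

Simulation-based checks use sizes chosen to give decisive margins at
desk scale: 200 arena replicates per cluster level (SSI grid steps ≥ 4
standard errors apart), 1000 snapshots for oracle equivalence, 2000
null ANOVA simulations (rate ± 0.01 ≈ 2 binomial SE), 1000 Dunnett
familywise simulations at 20 000 Monte-Carlo draws each, 100-seed power
runs for the motif, screen and phenotype recoveries. Degenerate inputs
are handled explicitly throughout: zero within-condition variance gives
F = ∞ with the minimal positive p (or F = 0, p = 1 when the effect SS
is zero), empty alignment columns are flagged, zero denominators in
anticipation indices return an undefined marker, and histogram
normalization is asserted to 1e-9.

## Known limitations

- Dunnett adjustment assumes the balanced equicorrelated (ρ = 0.5)
  structure; unbalanced designs are rejected rather than approximated.
- The mixed ANOVA reports no sphericity correction by default; with
  heavy non-exchangeable within-subject correlation the per-bin flags
  can be anticonservative (the Bonferroni option is the blunt remedy).
- Conservation scores ignore residue similarity (a 50/50 Leu/Ile column
  scores the same as 50/50 Gly/Trp) and sequence redundancy; both are
  extension points, not defaults.
- The inactivity filter's day-aligned default can retain a fly whose
  silent 24 h straddles midnight of the recording clock; the rolling
  variant closes this gap at the cost of strictness.
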