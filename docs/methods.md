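# Methods

## Data model

A measurement is a binned size distribution on a strictly increasing grid
of diameter edges (μm). Bin midpoints are geometric means of adjacent
edges, matching the log-spaced grids of particle-sizing instruments and
log-axis plotting. Two weightings exist: raw particle counts per bin
(`number_counts`) and relative volume per bin (`relative_volume_pct`,
summing to 100 when normalised). Conversion between them treats every
granule as a sphere of its equivalent diameter (the Coulter principle
reports equivalent spherical diameter), so a bin's volume contribution is
`count · π·m³/6` at midpoint `m`; discoid A-granule geometry is not
modelled. Tables are long-format CSV/TSV with explicit
`bin_lower_um`/`bin_upper_um` columns — carrying edges rather than
midpoints removes any midpoint-convention ambiguity — with units fixed to
μm and `.` decimals only (files with `,` decimals are rejected, not
guessed).

## Mixture decomposition

The volume-weighted density is modelled as
`f(x) = (1 − w_B)·N(x; μ_A, σ_A) + w_B·LogN(x; m_B, s_B)`. The fit
minimises the unweighted sum of squared differences between observed and
model per-bin relative volume %, where each model bin mass is the integral
of the component densities between the bin edges (`Φ` differences), never
a midpoint evaluation. Because the observed curve is normalised to 100
*after* truncation to the instrument grid, the model is renormalised over
the grid inside the residual; the two scales otherwise differ by the tail
mass outside the grid (~0.07% for the default presets), which would leave
a spurious residual floor.

Fitting both components jointly (rather than per-peak) avoids the bias
that overlapping tails near the ~10 μm valley induce in sequential fits.
The optimiser (trust-region reflective least squares, gradient/step
tolerances 1e-10) works on `(w_B, gap, σ_A, m_B, s_B)` with
`μ_A = E[B] + gap` and `gap > 0`, so the identifying constraint that the
A component has the larger mean holds at every iterate and labels can
never switch between restarts. Three deterministic starts are tried (the
initial guess, and `w_B ± 0.15`); the best residual wins, and a stalled
optimiser reports `converged = False` rather than raising. Initial values
come from mode detection: μ_A from the larger-diameter mode, `m_B` from
the log of the smaller mode, `w_B` from the volume fraction below the
valley, spreads from fixed heuristics (σ_A ≈ 0.18·μ_A, s_B = 0.35).

**Mode detection.** Peaks are found on the width-corrected density
(per-bin value divided by bin width). On a log grid the raw per-bin mass
peaks ~σ²/μ above the density mode (≈0.6 μm for the A peak), and the
density scale is what instrument plots and reported peak diameters refer
to. The density is first smoothed with a 7-bin uniform filter (~2% in
diameter on the default 300-bin grid) so that counting noise cannot create
spurious one-bin maxima; a mode must have prominence ≥ 5% of the global
density maximum (configurable).

**Model selection.** The two-component model is used only when mode
detection finds ≥ 2 peaks *and* the two-component fit improves the BIC
(Gaussian-residual approximation, `n·ln(rss/n) + k·ln n`, k = 5 vs 2)
over the single-normal fit. Both gates together reproduce the behaviour
of early developing grain — only an A-type peak can be fitted — without a
subjective rule. For a one-component fit all B-type parameters and
metrics are "na"; they are genuinely inapplicable, not missing.

**Metrics.** "Mean diameter" of the B component is the log-normal mean
`exp(m_B + s_B²/2)` (not the mode or median) and of the A component the
normal mean μ_A — the one convention in which the A value also coincides
with the A mode. Because the fit target is the volume-weighted curve, all
fitted parameters describe volume-weighted components. Fits are per
replicate; genotype-level values are means over per-replicate metrics
(n = 3 by default), never fits to the mean curve. Empty tail bins are
retained with zero weight, not trimmed.

## Synthetic populations

Presets parameterise the volume-weighted mixture directly — the same
parameterisation the fit estimates — so recovery can be judged against an
exact truth; the number-weighted view needed for particle sampling is
derived by dividing the per-bin volume density by midpoint³. Defaults:
300 log-spaced bins over 2–60 μm, 10⁵ granules per measurement, starch
density 1.5 g cm⁻³ (literature value, used only to link counts to mass),
replicate jitter CV 0.03.

Preset anchors: mature wild type A mean 19 μm, B volume-mean 6 μm,
B content 40%; mature mutant 23 μm / 8.75 μm / 70% (midpoints of the
reported "circa" ranges); 12 DAF unimodal A-only at 14.0 (WT) and 14.4
(mutant) μm; 16 DAF applies the reported relative differences (A +5%,
B content +98%) to implementer-chosen wild-type bases of 16 μm and
w_B = 0.15. The 16 DAF mutant B-mean (6.5 μm vs 6.0 μm in WT) is likewise
an implementer choice — only the A-diameter and B-content ratios are
anchored. Spread defaults σ_A = 3.5 μm and s_B = 0.35 are chosen to
reproduce the visual width and valley structure of mature bimodal curves;
they are explicitly not literature-derived and are configurable.

A measurement is one multinomial draw of the total granule count over the
expected per-bin number proportions — i.e. pure counting noise at the
recorded sample size. Replicate sets add plant-to-plant variation as
independent unit-mean log-normal factors on the two location parameters
only (w_B is not jittered; minimal replicate model). Seeding is
hierarchical: each replicate's generator is spawned from
`SeedSequence((master_seed, replicate_index))`, so requesting more
replicates never perturbs earlier ones, and every stochastic operation is
a pure function of (inputs, seed) — there is no implicit global state and
the seed argument is mandatory.

What the generator emulates: log-binned volume-weighted curves with
realistic peak positions, valley structure, counting noise and replicate
scatter. What it does not: instrument coincidence correction and aperture
effects, non-spherical (discoid/lobate) granule geometry, C-type granules
or any third component, and granule growth kinetics. Passing tests
therefore demonstrate correct recovery of mixture structure from
realistic binned counting data, not robustness to instrument artefacts or
shape-induced sizing bias.

## Group statistics

Published granule-phenotype figures alternate between one-way ANOVA with
Tukey's test and Kruskal–Wallis on ranks without stating a switching
rule; `choose_test` makes the gate explicit: ANOVA is used only when
Shapiro–Wilk on pooled within-group residuals *and* Brown–Forsythe
equal-variance both fail to reject at 0.05 (configurable), otherwise the
rank route is taken. After Kruskal–Wallis, all-pairwise comparisons use
the Tukey-type (Nemenyi) procedure on mean ranks with tie correction,
mirroring the "Tukey's test" wording that common statistics packages
attach to rank-based post-hocs. Two-group time-course contrasts use the
Welch (unequal-variance) t-test — appropriate for n = 3 groups with no
variance-homogeneity guarantee. Degenerate inputs follow documented
conventions: all-identical data give H = 0, p = 1; zero within-group
variance with equal means gives p = 1, with separated means p < 1e-12
plus a degeneracy flag.

Compact letter displays use insert-and-absorb: starting from one set
containing all groups, each significant pair splits every set containing
both, and sets absorbed by supersets are dropped; letters are assigned in
group-input order starting at "a". The output satisfies, exactly, the
defining property that two groups share a letter iff their adjusted
pairwise p exceeds α (verified exhaustively in tests). Under the
single-normal null the full adaptive pipeline rejects at ≈0.05 (checked
by simulation, 2000 runs of 5 groups × n = 3).

## Pipeline

`run_pipeline` is deterministic given its configuration (plus master seed
in synthetic mode): per-preset sub-seeds derive from the master seed by
fixed arithmetic, all tables serialise floats via `repr` for byte-stable
reruns, and every output file header records the config hash, seed and
package version. Missing values serialise as the literal `na`.
Non-converged fits appear in the metrics table with empty metric fields
rather than being dropped. Plots (relative volume vs log diameter,
mean ± SE shading per genotype) are written as SVG and PNG; plotting
failures downgrade to warnings because the tables are the contract.

## Problem sizes and numerical choices

Default analyses use 300 bins, 10⁵ granules and 3 replicates — a
realistic Coulter run. The simulation studies in the test suite use
50 seeds per preset for recovery checks and 2000 null simulations for
calibration, sizes at which the Monte-Carlo error is comfortably below
the tolerances being checked. Tolerances: 1e-9 for conservation and
round-trip identities, 1e-10 optimiser gradient/step, 0.1% relative for
noiseless parameter recovery, 2% relative (component means) and
3 percentage points (B content) for stochastic recovery at 10⁵ granules.

## Known limitations

* The mixture is exactly two components; trimodal or shouldered
  distributions will be summarised, not flagged.
* B-content estimates inherit the lognormal-tail/normal-tail overlap
  ambiguity near the valley; with heavy overlap (separation < ~2σ_A) the
  decomposition is ill-conditioned and recovery guarantees do not apply.
* `granules_per_mg` assumes the analysed starch mass is known (or, for
  synthetic data, derives it from spherical volumes at the configured
  density); no instrument-specific normalisation is modelled.
* The assumption gate for test selection is a documented convention, not
  a reconstruction of any particular publication's unstated rule.
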