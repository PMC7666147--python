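# Methods

## Life-cycle model

The midge life history is collapsed to three stages (egg, larva, adult)
with one projection step per stage. Two biological facts shape the matrix:
females deposit a single egg mass and die (semelparity, so no adult
survival term `a_33`), and every egg that survives becomes a larva that
either survives to adulthood or dies (no stage stasis). The resulting
matrix is a pure 3-cycle with entries `a_13 = F`, `a_21 = s_e`,
`a_32 = s_l`. Its characteristic polynomial is `λ³ = F·s_e·s_l`, giving
the closed form `λ = (F·s_e·s_l)^(1/3)` used throughout as an independent
check on the numerical eigendecomposition (agreement required to 1e-10).

The multi-year larval period is deliberately collapsed into one step, as
the scenario comparisons are ratio-based and a uniform stretching of the
time axis cancels. For the same reason fecundity enters as eggs laid per
female without halving for sex ratio: percent reductions are invariant to
any uniform rescaling of `F` (tested), and the report metadata carries the
caveat that absolute λ values depend on this convention.

### Eigen-analysis

A 3-cycle matrix is imprimitive with index 3: its three eigenvalues are
`λ·(cube roots of unity)`, all of modulus λ. Power iteration therefore
oscillates with period 3 and never converges, so the dominant eigenvalue
comes from `numpy.linalg.eig`; the Perron root is identified as the
eigenvalue of maximal real part (for a nonnegative matrix the spectral
radius is itself a real eigenvalue, so this selection is exact). The
stable stage distribution `w` is the right eigenvector normalized to sum
1, reproductive values `v` the left eigenvector scaled so `⟨v, w⟩ = 1`.
Sensitivities use the eigenvector formula `S_ij = v_i w_j / ⟨v, w⟩` and
are verified against central finite differences (h = 1e-5, tolerance
1e-6); elasticities `(a_ij/λ)·S_ij` are masked to structural nonzeros and
each arc of the cycle has elasticity exactly 1/3. A matrix with zero
fecundity is nilpotent (λ = 0); it returns a flagged degenerate result
with NaN eigenvectors rather than raising.

## Scenarios and the growth-reduction metric

The seven scenarios take the measured vital rates as-is (control
42.9 / 0.82 / 0.78; dehydration fecundities 34.6 / 35.6 / 21.5; gel
removal `s_l = 0.5`; thermal stress `s_e = 0.63`; worst case composes the
three altered parameters simultaneously). "Percent reduction in population
growth" is ambiguous between λ and `r = ln λ`; both are computed, and the
r-based metric `100·(1 − r/r_c)` is the headline because log growth rates
compare multiplicative effects on a ratio scale. Under nearest-integer
rounding it yields 21 / 13 / 8 for the combined-dehydration, no-gel and
thermal scenarios (raw 20.86 / 13.43 / 7.96); the λ-based metric gives
20.57 / 13.78 / 8.41. Neither metric uniformly dominates the other —
`ln x / x` is not monotone around `e` — so no ordering between the two
reduction columns is asserted. When the control is not growing
(`r_c ≤ 0`) the r-based reduction is undefined and reported as NaN.

The worst-case scenario computes `λ = (21.5·0.63·0.5)^(1/3) ≈ 1.892`, a
growing population, whereas the originally reported value is a declining
λ = 0.95. No simple three-stage structure built from the tabulated rates
recovers 0.95 (halving fecundity for a 1:1 sex ratio still gives ≈ 1.50).
The package reports this discrepancy explicitly
(`worst_case_discrepancy()`, also embedded in the pipeline summary)
instead of fitting unstated parameters toward the reported number.

## Stochastic dehydration bouts

The stochastic extension draws each step's matrix from {normal, stressed}
with bout probability `p`, iid Bernoulli by default; an optional two-state
Markov mode with lag-1 autocorrelation ρ models persistent bouts (state
kept with probability ρ, otherwise redrawn from the stationary law, so the
stationary marginal stays `p`). Because each step of a cycle matrix
traverses exactly one arc, the long-run log growth rate is exactly
`r_s = (1/3)·Σ_arc E[ln rate]` — affine in `p`, with endpoints equal to
the deterministic `ln λ` of the two environments, and identical for the
iid and Markov modes (only the stationary marginal enters). The simulator
renormalizes the stage vector each step, averages post-burn-in log
increments (default burn-in 1,000 steps) and estimates Monte-Carlo error
by batch means with 100 batches. A zero vital rate realized on the path
annihilates the population vector; this returns a flagged sentinel
(`r_s = −inf`) rather than propagating silent infinities.

One numerical subtlety: for a deterministic cycle the log increments are
periodic with period 3 and any three consecutive increments sum exactly to
`ln(F·s_e·s_l)`, so the degenerate endpoints (p = 0 or 1) reproduce the
deterministic rate to 1e-9 only when the number of averaged increments is
divisible by 3; tests use such counts.

## Synthetic assay generator

The generator reproduces the study's replicate structure, not its raw
data (which are unpublished):

* **Fecundity** — per-mating-pair egg counts, 8 pairs per treatment,
  negative binomial around the treatment means (42.9 / 34.6 / 35.6 /
  21.5) with dispersion k = 10 (variance `m + m²/k`), since clutch counts
  are overdispersed relative to Poisson and only means were reported;
  Poisson is available as a config option. Viable eggs are binomial
  within each clutch at the control egg-survival rate.
* **Survival** — binomial per replicate. Larval assays use four
  replicates of 25 individuals; egg assays use three replicate clutches
  of 40 eggs (an egg mass holds 40–50), covering proportions 0.82 / 0.78 /
  0.63 / 0.5 and the dehydrated-egg viabilities 0.81 (gel) and 0.0
  (gel-less).
* **Thermal traces** — six paired in-gel/ambient series over 3 days at
  1-minute sampling: a diurnal sinusoid (mean 4 °C, amplitude 5 °C,
  plausible for austral-summer conditions near Palmer Station) plus
  Gaussian noise (sd 0.3 °C), with the in-gel amplitude multiplied by a
  damping factor of 0.5 for the gel's thermal buffering.

Every generator call derives all randomness from one seed
(`numpy` `SeedSequence` spawning per treatment), so a study bundle is
byte-reproducible. What passing recovery tests show is that the
estimation chain is unbiased and correctly scaled *under these
distributional assumptions*; they cannot validate the assumptions
themselves (real clutch-size dispersion, between-replicate
heterogeneity, non-sinusoidal field temperature) against field data.

## Assay statistics

Proportion inference follows the classical variance-stabilizing route:
per-replicate proportions are arcsine-square-root transformed, averaged on
the angular scale, and back-transformed (`sin²`) for reporting; the
pooled estimate `Σ alive / Σ start` is the default point estimate for
vital rates (whether the original analysis pooled or averaged replicates
is unknowable from the reported proportions; both are exposed).
Group comparisons use `scipy.stats.ttest_ind` (Welch by default, Student
for the classical pooled-variance form) and one-way ANOVA with Tukey HSD
adjusted p-values from the studentized-range distribution
(`scipy.stats.tukey_hsd`), cross-checked in the tests against
statsmodels' independent implementation (tolerance 1e-4). The ANOVA
entry point accepts two groups so the `F = t²` identity is directly
checkable. Thermal summaries split a trace into consecutive 24-hour
windows from the first timestamp (day boundaries are a convention, not a
measurement), report the largest within-day max−min, and the rate of
change over the absolute time gap between that day's minimum and maximum.

Originally reported test statistics (e.g. t = 3.46, F = 5.11) are not
reproduction targets: they depend on raw replicate values that were never
published, so the statistical routines are validated against analytic
identities and reference implementations instead.

## Pipeline, problem sizes, limitations

The workbench separates a deterministic surface (`reported-rates` mode:
measured rates straight into the scenario engine, seed-independent) from a
stochastic surface (`estimate-from-synthetic`: generate a bundle, estimate
rates, rebuild scenarios from the estimates). Parameter-recovery runs use
a replication multiplier of 100 (800 pairs, 300–400 survival replicates
per treatment), at which every estimate falls within 3 SE of its
generating value and scenario λ estimates land within 1% of the direct
ones. Stochastic-growth checks use 3×10⁵ steps (Monte-Carlo SE ≈ 3×10⁻⁴),
sized so the full suite runs in well under a minute per module on one CPU.

Known limitations: no density dependence, no explicit multi-year larval
stage, no spatial structure, no sex-ratio or multiple-mating dynamics, and
the bout-frequency sweep is exploratory — no field estimate of dehydration
bout frequency constrains `p`.
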