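# Methods

## Diversity and the unit of area

Diversity is quantified with Hill numbers
\(^qD = (\sum_i p_i^q)^{1/(1-q)}\) over the relative abundances
\(p_i\) of taxa present (taxa with \(p_i = 0\) are excluded from the sum
at every order, so \(^0D\) counts only observed taxa; this fixes the
\(0^0\) ambiguity at q = 0). The q = 1 case uses the analytic Shannon
limit \(\exp(-\sum p_i \ln p_i)\) whenever \(|q-1| < 10^{-9}\); no
numerical limit-taking is performed. Orders are restricted to finite
\(q \ge 0\).

One sample is one unit of area. "Accrued diversity at area A" is the
Hill number of the community formed by **summing the raw counts** of the
first A samples of an ordering and renormalizing — not the mean of
per-sample diversities, and not presence/absence for q > 0. Summing raw
counts weights samples by sequencing depth; since Hill numbers are
computed after renormalization, this is the natural pooled-community
convention. Samples with zero total count carry no community and are
dropped with a warning at table construction.

## Model fitting

PL (\(\ln D = \ln c + z \ln A\)) and PLEC
(\(\ln D = \ln c + z \ln A + dA\)) are fitted by ordinary least squares
on natural logarithms. PL needs ≥ 3 points, PLEC ≥ 4. The goodness-of-fit
R is the correlation between observed and fitted \(\ln D\) (the square
root of the OLS \(R^2\); for the simple PL regression this equals
\(|r|\)), and the p-value is the overall regression F-test (identical to
the slope t-test for PL). A curve with zero variance in \(\ln D\) — for
example identical samples, whose accumulation curve is constant — yields
a degenerate-fit flag (z = 0, R and p undefined) rather than an
exception, so permutation loops continue.

Because the ordering of samples affects c, parameters are estimated from
`n_permutations` (default 100) uniform random orderings drawn without
replacement from a seeded generator. A fit is *successful* when it is
non-degenerate, p < 0.05 and, for PLEC, d < 0 (a non-negative d has no
interior maximum, so \(A_{\max} = -z/d\) would be undefined). Reported
parameters are arithmetic means over the successful fits, on their
natural scale (c is averaged directly, not on the log scale), together
with the success count N; when N = 0 the means are NaN and a warning is
emitted. Within `build_profiles`, PL and PLEC at the same q share the
same orderings (same derived seed), so both models describe identical
curves.

## Profiles

* **PDO**: \(g = 2 - 2^z\) is always computed from the **PL** exponent
  (the transform is derived from the pure power-law form); the PLEC z is
  never fed into it. z outside [0, 1] is accepted with a warning since
  the overlap interpretation then fails.
* **MAD**: \(D_{\max} = c(-z/d)^z e^{-z}\) and \(A_{\max} = -z/d\) use
  the averaged **PLEC** parameters; they require z > 0 and d < 0 and are
  NaN otherwise. \(A_{\max}\) is reported as a real number of samples
  (rounding to an integer is presentation only). At z = 0 the curve is
  decreasing and \(D_{\max}\) degenerates to c.
* **LGD**: \(100\, c_{\mathrm{PL}} / D_{\max}\) percent, combining the
  PL one-sample diversity with the PLEC global maximum, per the
  definition of the ratio. Published tabulations of this ratio are not
  always reproducible from their own printed c and \(D_{\max}\) (e.g. a
  printed 7.26% where 37.864/606 = 6.25%); this package implements the
  definition as stated and makes no attempt to reconcile such rows, nor
  does it assume any monotonicity of LGD in q.

The default q grid is {0, 1, 2, 3}; arbitrary non-negative real orders
are accepted.

## Randomization test

`compare_groups` tests a difference in any derived parameter
(z, c, d, g, A_max, D_max, LGD) between two labelled groups. The
statistic is the difference of permutation-averaged parameters; the null
is built by shuffling group labels over the pooled samples, preserving
group sizes, and recomputing the statistic each iteration. The p-value
is two-sided with add-one correction,
\(p = (1 + \#\{|\text{null}| \ge |\text{obs}|\})/(1 + n)\), where n
counts completed iterations (iterations in which the parameter is
undefined in a shuffled group are skipped and reported). The test is run
internally in a canonical label order, making p exactly invariant to
swapping the two group labels. `inner_permutations` (orderings averaged
per fit inside each iteration) defaults to 10 as a speed/accuracy knob;
100 reproduces the full fitting protocol. No multiple-testing correction
is applied across the parameter × q grid; results are raw per-test
p-values.

## Synthetic cohorts

`generate_cohort` draws a global pool of `pool_size` species with
lognormal(μ=0, σ=1.5) abundances — the standard heavy-tailed microbial
species-abundance distribution — marks
\(\lceil \text{core\_fraction} \cdot \text{pool\_size} \rceil\) species
as core (present in every sample), gives each satellite species an
occupancy probability drawn from Beta(0.5, 2) (right-skewed: most
satellites are rare across individuals), samples per-sample presence by
Bernoulli, and draws `reads_per_sample` reads multinomially from the
renormalized abundances of the species present. Defaults (50 samples,
pool 600, 2,000 reads/sample, core fraction 0.1) echo the scale of
published tissue-microbiome cohorts — pools of a few hundred species,
thousands of reads per sample, few universally shared species — with the
read depth kept modest for desk-speed simulation. The `disjoint` flag
partitions the pool evenly across samples with no sharing: the exact
no-overlap limit, for which richness accumulates linearly and z = 1
identically.

What the generator does **not** emulate: sequencing error, chimeras and
taxonomic misassignment; depth heterogeneity between studies; phylogenetic
or co-occurrence structure among taxa; and compositional correlations
beyond the shared pool. Tests that pass on these cohorts therefore
demonstrate the correctness and calibration of the pipeline's
statistics, not robustness to those real-data artifacts.

## Numerical and design choices

* All OLS solutions come from standard linear-algebra routines
  (simple-regression closed form for PL; least squares on the
  [1, ln A, A] design for PLEC, with a rank check flagging collinear
  designs degenerate).
* All randomness flows from user-supplied seeds through NumPy
  generators; tiered runs derive one sub-seed per task from the run seed
  in a fixed task order, record it in every output row, and are
  byte-identical on rerun.
* Problem sizes used in the shipped test-suite simulations — cohorts of
  10–30 samples, pools of 80–600 species, 300–2,000 reads, 5–100
  permutations per fit, 50 randomization pairs — were chosen as the
  smallest sizes at which the examined limits and calibration properties
  are stable.
* The tiered design (`run_design`) fits per-dataset, per-group and
  pooled cohorts and runs pairwise group comparisons; group labels must
  cover every sample, and unmapped samples are reported by ID.

## Limitations

* The PLEC extrapolation of \(D_{\max}\) beyond the observed number of
  samples is a model-based extrapolation without confidence bands.
* Diversity is compared as effective numbers only; the identity of
  shared taxa (which species constitute the core) is out of scope.
* No rarefaction or coverage standardization is applied; cohorts with
  very different read depths should be standardized upstream if depth
  effects are a concern.
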