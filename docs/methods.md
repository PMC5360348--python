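# Methods

## The statistical framework

`linsel` treats single-cell *lineages* — root-to-leaf paths through binary
division trees observed over a window `[t0, t1]` of length `τ = t1 − t0` —
as the basic replicating units.  For a pooled forest with `N0` cells alive
at `t0` and `N1` at `t1`, each lineage `i` with `D_i` divisions inside the
half-open window `(t0, t1]` gets two probabilities:

- chronological: `π_i^cl = 2^(−D_i) / N0` — the probability of reaching the
  lineage by walking the tree forward in time, choosing a daughter with
  probability 1/2 at every division;
- retrospective: `π_i^rs = 1 / N1` — the probability of picking the
  lineage's terminal cell uniformly among survivors and following its
  ancestry back.

Within each tree the chronological weights are exactly normalized
(`Σ_leaves 2^(−D) = 1` for any full binary tree), and the two measures obey
the exact tilt

    π^rs = e^{τ (h̃(D) − Λ)} π^cl,   h̃(D) = D ln2 / τ,   Λ = ln(N1/N0) / τ,

which makes `h̃(D)` (the *lineage fitness*) the natural per-lineage growth
measure and `Λ` the population growth rate.  For a lineage phenotype `x`
binned on shared edges, the package estimates the *fitness landscape*

    h(x) = Λ + (1/τ) ln( P^rs(x) / P^cl(x) )

and the *selection strength*

    S[x] = ⟨h⟩_rs − ⟨h⟩_cl = (1/τ) Σ_x (P^cl − P^rs) ln(P^cl/P^rs),

the second form being `1/τ` times the Jeffreys (symmetrized KL) divergence;
the equality is algebraic on the renormalized common support and the
implementation reports the numerical residual (`jeffreys_check`, typically
< 1e−12).  `S[x]` is bounded by `S[D]`, the selection strength on the
division count itself, computed always on raw integer `D` (never on
histogram bins) because the empirical tilt makes the landscape on `D`
coincide with `h̃(D)` up to `Λ`.  The *relative selection strength*
`S_rel[x] = S[x]/S[D] ∈ [0, 1]` approximates, to second cumulants, the
squared correlation between `h̃(D)` and `h(x)`; the report carries that
correlation under both weightings for comparison.  Across an environment
change the response decomposes exactly as
`Δ⟨h⟩_rs = Δ⟨h⟩_cl + ΔS` — individual response plus change of selection.

## Lineage phenotypes

Phenotypes are time averages over a lineage's concatenated frame series:
mean concentration `(1/τ)∫c dt` (trapezoid; concentration is intensive and
integrates straight through divisions), mean elongation rate
`(1/τ)∫ d ln v/dt` and mean production rate `(1/τ)∫ (1/v) d(cv)/dt`
(midpoint `v` per increment).  A division halves the size; that jump is
bookkeeping, not growth, so the two derivative-based phenotypes drop the
frame increment straddling each division and reweight over the retained
time.  The source data's convention here is not documented; excluding the
straddling increment is this package's choice, and it makes the estimators
exact for noise-free exponential growth regardless of division timing.
When an input table samples a mother at its division time as well as the
daughter at the same frame, the mother's duplicate frame is dropped.  All
estimators are second-order accurate in the frame interval (5 min in the
reference data).  The registry (`linsel.phenotypes.PHENOTYPES`) accepts
user extractors mapping a `LineageSeries` to one scalar; `division_count`
is filled from `D` directly.

The weighted autocorrelation of a per-frame signal pools all (t, t+s)
pairs over lineages, one chronological or retrospective weight per lineage,
with plug-in weighted mean and variance over all frames, so lag 0 maps to
exactly 1.

## Binning

Histogram bin widths follow Freedman–Diaconis, `2·IQR·m^(−1/3)`, with the
IQR taken from the chronologically weighted values by inverted-CDF weighted
quantiles and `m` the lineage count; a zero IQR falls back to
`range/⌈√m⌉` with a warning.  Bins empty of lineages are trimmed and both
distributions renormalized on the retained support — this keeps `h` finite
and preserves the Jeffreys identity exactly.  Because each lineage carries
both weights, a non-empty bin is never empty in only one distribution;
probability mass is actually removed only when values fall outside
externally supplied (e.g. replicate-shared) edges, and removing more than
20% of either mass is an error unless explicitly overridden.  The
`binsweep` utility reports `S[x]` across a sweep of widths as binning QC.

## The proliferation simulator

Each cell carries a phenotype `y` whose logarithm follows a discretized
Ornstein–Uhlenbeck process,

    ln y_{t+Δt} ~ Normal( μ + e^{−γΔt}(ln y_t − μ),  σ²(1 − e^{−2γΔt}) ),

and divides during a frame with probability `f(y_t)Δt` (at most one
division per step; this reproduces the reference discrete scheme including
its O(Δt) bias — no Gillespie variant).  Defaults are the reference study
conditions: `Δt = 5 min`, `μ = −0.5 ln 1.09`, `σ² = ln 1.09` (stationary
log-normal `y` with mean 1.0 and SD 0.3), `γ = −0.6 ln r_g` per hour with
`r_g = 0.8` the autocorrelation of `ln y` after one mean generation
(`1/f0 = 1/0.6 h`), `N0 = 100` ancestors, `τ = 250 min`.  Division-rate
families: Hill `f(y) = f_max y^n/(1+y^n)` with `f_max = 1.2 h⁻¹`
(n = 0 gives the constant `f0 = 0.6 h⁻¹`), Gaussian
`f(y) = f0(1 + s^{−2} e^{−(y−1)²/2(0.3s)²})`, and constant.  Ancestors
start from the stationary law; on division the mother's last state seeds
two independent OU draws for the daughters (the wording of the source
scheme supports a full-Δt step rather than copying the state, and that is
what is implemented).  Daughters begin at the next frame; a division may
land exactly on `t1`, in which case both daughters count as (degenerate,
single-frame) surviving lineages — this keeps the chronological division
count exactly `Binomial(T, fΔt)` for constant `f`, with the retrospective
law its `2^D`-tilt, `Binomial(T, 2p/(1+p))`, and

    S[D] = (ln2/τ) · T p (1−p)/(1+p)  →  f0 ln 2   as Δt → 0.

Every cell owns an RNG stream keyed by (root seed, ancestor index,
left/right path), so seeded runs are bit-reproducible and independent of
traversal order.  The simulator has no cell-size variable (sizes are
written as 1) and no death, asymmetry, or spatial structure.

### What the generator does and does not emulate

It reproduces the reference study's data structure — ~100 trees per
replicate, 51 frames, heritable log-normal phenotype with realistic
autocorrelation, phenotype-dependent division — so passing tests
demonstrate end-to-end parameter recovery under those conditions.  It does
not emulate measurement noise, segmentation/tracking errors, cell size and
age structure, censoring, or correlated division timing beyond what the
phenotype induces, so tests bound estimator behavior on clean trees, not
robustness to instrument artifacts.

## Permutation significance

The shuffle test breaks the pairing of `(D, x)` by permuting phenotype
values across lineages while every lineage keeps its own `D` and weights;
`S[x]` is recomputed per permutation with the original bin edges frozen
(the null isolates the pairing, not the binning), and the observed value is
compared with the median and percentile 2.5/97.5 band of (by default)
10 000 permutations.  Null medians are strictly positive — the plug-in
`S` is biased upward by finite bins and finite samples — which is exactly
the bias the test is designed to expose.

### Known limitation: tree-structured dependence

The permutation null assumes exchangeable lineages.  Real (and simulated)
lineages within one tree share ancestry: with `r_g = 0.8` the phenotype
memory `1/γ ≈ 7.5 h` exceeds the `τ ≈ 4.2 h` window, so sibling lineages
share most of their time-averaged phenotype while also sharing division
history.  The effective sample size of the retrospective distribution is
then closer to the number of trees than to the number of lineages, and the
exchangeable null is anti-conservative: under a phenotype-independent
division rate the observed `S[ȳ_τ]` exceeds the 95% permutation band in a
substantial fraction of replicates even though its absolute magnitude stays
far below `S[D]`.  For i.i.d. lineages (no tree correlation) the band has
nominal coverage; the test suite checks both behaviors.  A block
(within-tree) permutation would be the natural remedy but is outside the
reference procedure and therefore not implemented.

## Numerical and design choices

- Internal time unit is hours; tabular I/O can declare minutes and is
  converted at read time.
- Half-open window `(t0, t1]` for counting divisions; a division exactly at
  `t0` belongs to the previous window.  This keeps per-tree normalization
  exact.
- Cells lost before `t1` without dividing are flagged censored, excluded
  from both measures, and counted; remaining weights are renormalized in
  the distribution estimates.
- Windows may start inside recorded trees: cells alive at `t0` become the
  window roots (`N0`); file-level roots born after `t0` are rejected.
- Replicate aggregation is an unweighted mean ± SD across replicates, at
  the CLI layer; per-replicate estimation comes first.
- Problem sizes in the test suite mirror the reference conditions
  (`N0 = 100`, `τ = 250 min`, 10 seeded replicates per condition); the
  non-monotone Gaussian-rate recovery check uses `s = 1` from the reference
  set {0.5, 1, 2}, whose peak rate (1.2 h⁻¹) matches the Hill family's
  maximum — the `s = 0.5` variant (peak 3 h⁻¹) grows populations two
  orders of magnitude larger and adds nothing qualitative.
- Degenerate inputs: an IQR of zero triggers the range-based fallback; a
  constant phenotype yields `S = 0` with a degenerate permutation null; a
  zero `S[D]` together with positive `S[x]` is rejected as inconsistent.
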