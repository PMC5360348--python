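# linsel — fitness landscapes and selection strength from single-cell lineage trees

Time-lapse microscopy of proliferating microbial microcolonies yields
*lineage trees*: every division event, plus per-frame measurements of cell
size and reporter fluorescence along every single-cell lineage.  `linsel`
turns such annotated genealogies into quantitative statements about
selection on heritable, fluctuating phenotypes — which expression states
divide more, how strongly, and whether a change in population growth comes
from individual cells' response or from selection within the population.
It is aimed at single-cell biologists analyzing agarose-pad or
mother-machine style tracking data, and at modellers who want a validated
reference implementation of lineage-based selection statistics.

## The statistic

Over a window `[t0, t1]` of length `τ`, a lineage `i` ending in a cell
alive at `t1` with `D_i` divisions has a **chronological** probability
`π_i^cl = 2^(−D_i)/N(t0)` (descend the tree forward, picking a daughter at
random at each division) and a **retrospective** probability
`π_i^rs = 1/N(t1)` (pick a survivor uniformly, follow its ancestry back).
For any lineage phenotype `x` — time-averaged expression, elongation rate,
production rate, or the division count itself — the package estimates

    h(x)   = Λ + (1/τ) ln( P^rs(x) / P^cl(x) )        (fitness landscape)
    S[x]   = ⟨h⟩_rs − ⟨h⟩_cl = (1/τ) J(P^cl, P^rs)    (selection strength)
    S_rel  = S[x] / S[D]                               (relative strength)

with `Λ = ln(N1/N0)/τ` the population growth rate and `J` the Jeffreys
divergence.  `S[D]`, the selection strength on the division count, is the
upper bound for any phenotype; `S_rel ∈ [0, 1]` approximates the squared
correlation between the lineage fitness `D ln2/τ` and `h(x)`.  A built-in
stochastic proliferation simulator (Ornstein–Uhlenbeck log-phenotype,
phenotype-dependent division probability) generates ground-truth ensembles
for end-to-end validation, and a permutation test calibrates `S[x]`
against the finite-sample null.  See `docs/methods.md` for the full model
description and estimator conventions.

## Worked example

Simulate ten replicate colonies in which cells divide with Hill-type
phenotype dependence (`f(y) = f_max y²/(1+y²)`, `f_max = 1.2 h⁻¹`), then
recover the selection statistics:

```sh
cat > hill2.yaml <<EOF
hill_n: 2
N0: 100
tau: 250
EOF
linsel simulate -c hill2.yaml -o sim_hill2 --seed 1 --replicates 10
linsel analyze --input sim_hill2 --time-unit min \
    --phenotype division_count --phenotype sim_phenotype -o ana_hill2
```

The analysis prints the replicate-aggregated table (mean ± SD over the 10
runs; abridged):

```
      phenotype  Lambda_mean    S_mean  S_D_mean  S_rel_mean  S_rel_sd
 division_count       0.6059    0.4785    0.4785      1.0000    0.0000
  sim_phenotype       0.6059    0.1023    0.4785      0.2110    0.0570
```

Reading: the population grew at `Λ ≈ 0.61 h⁻¹`; selection on the division
count itself — the hard upper bound — is `S[D] ≈ 0.48 h⁻¹`, and the
time-averaged phenotype `ȳ_τ` carries `S_rel ≈ 0.21` of that maximum, i.e.
heterogeneity in `y` explains roughly a fifth of the fitness variation
among lineages at this Hill coefficient.  Raising `hill_n` to 10 raises
`S_rel` severalfold; setting it to 0 (no phenotype dependence) drops
`S_rel` near zero while `S[D]` stays at `f0 ln 2 ≈ 0.42 h⁻¹` — division
stochasticity alone sustains selection on `D`.  Per-bin landscapes
(`bins_*.tsv`) tabulate `P^cl`, `P^rs` and `h(x)` per histogram bin; under
`hill_n: 2` the recovered `h(ȳ_τ)` tracks the assigned `f(y)` closely over
the well-populated bins.

The same `analyze` command runs on experimental tables (tab-separated
`cell_id parent_id birth_time end_time fate` plus a long-format
`cell_id time size fluorescence` samples table) with
`--phenotype elongation_rate --phenotype production_rate
--phenotype concentration`, and `linsel decompose` splits the
between-condition response `Δ⟨h⟩_rs` into `Δ⟨h⟩_cl + ΔS` per phenotype.
`linsel shuffle` reports the permutation null band for each `S[x]`;
`linsel binsweep` profiles the bin-width sensitivity.

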