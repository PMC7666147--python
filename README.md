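# midgepop

Stage-structured population demography of the Antarctic midge *Belgica
antarctica* under larval stress.

The Antarctic midge is a wingless chironomid endemic to the Antarctic
Peninsula. Larvae develop over at least two years; adults live about two
weeks, mate once, and females die shortly after depositing a single egg
mass encased in an accessory-gland gel. Experimental work shows that
dehydration of larvae lowers adult fecundity, that removing the gel lowers
egg viability and larval survival, and that thermal stress lowers egg
survivorship. `midgepop` asks what those measured effects mean for
population growth.

## The model

The life history is collapsed to three stages — egg, larva, adult — with
one matrix time step per stage and death after reproduction (semelparity).
The projection matrix is a pure 3-cycle:

```
        | 0    0    F  |
    A = | s_e  0    0  |
        | 0    s_l  0  |
```

with `F` eggs laid per female, `s_e` egg-to-larva survival and `s_l`
larva-to-adult survival. The dominant eigenvalue λ of `A` is the per-step
population growth factor; because the matrix is a cycle, the
characteristic polynomial gives the closed form `λ = (F·s_e·s_l)^(1/3)`,
and `r = ln λ` is the log growth rate. A 3-cycle matrix is imprimitive
(all three eigenvalues share the modulus λ), so λ is computed by full
eigendecomposition, never by power iteration.

Seven vital-rate scenarios encode the measured stress effects
(control `F = 42.9, s_e = 0.82, s_l = 0.78`; dehydration lowers `F` to
34.6 / 35.6 / 21.5; gel removal lowers `s_l` to 0.5; thermal stress lowers
`s_e` to 0.63; the worst case combines all three). Stress impact is
reported as `100·(1 − r/r_control)`. A stochastic extension treats each
time step as a "dehydration bout" with probability `p`, switching between
normal and stressed matrices; for cycle matrices the long-run stochastic
growth rate has the exact form
`r_s = (1/3)·Σ_arc[(1−p)·ln rate_normal + p·ln rate_stressed]`,
which serves as the oracle for the Monte-Carlo simulator.

Because the raw assay tables are not published, a synthetic-data module
regenerates them with the study's replicate structure (negative-binomial
egg counts per mating pair, binomial survival replicates, damped-sinusoid
thermal traces), so the whole estimation chain — raw tables → vital rates
→ matrices → growth rates — is testable end to end.

## Worked example

```python
from midgepop import run_scenarios, study_scenarios, report_table

table, meta = report_table(run_scenarios(study_scenarios()))
print(table[["name", "lambda", "r", "dr_pct", "dr_pct_round"]].to_string(index=False))
```

```
              name   lambda        r    dr_pct  dr_pct_round
           control 3.016166 1.103987  0.000000             0
  male_dehydration 2.807554 1.032314  6.492173             6
female_dehydration 2.834346 1.041811  5.631898             6
  both_dehydration 2.395791 0.873714 20.858313            21
            no_gel 2.600641 0.955758 13.426668            13
    thermal_stress 2.762469 1.016125  7.958567             8
        worst_case 1.891979 0.637623 42.243549            42
```

Combined male+female larval dehydration cuts log population growth by
~21%, gel removal by ~13% and thermal stress by ~8%; no single stressor
pushes λ below 1. Note the worst-case combination still yields
λ ≈ 1.89 under this matrix, not the originally reported declining value
λ = 0.95 — `midgepop.worst_case_discrepancy()` computes and reports that
gap explicitly rather than fitting hidden parameters to it.

The same results come from the command line (`midgepop scenarios`,
`midgepop sweep`, `midgepop run`) or from the numbered drivers under
`analysis/`, which also generate the synthetic assays, estimate vital
rates from them, and sweep the dehydration-bout probability.

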