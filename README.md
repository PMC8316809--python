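# picosocial

Phytoplankton are usually studied one strain at a time, yet they live in
genetically diverse populations. For the marine picoplankter
*Ostreococcus*, lineages (strains) modulate their maximum growth rate in
response to the mere presence of non-self conspecifics — even in
nutrient-replete, low-density cultures where resource competition is
absent. `picosocial` implements the full analysis pipeline for this kind
of experiment as tested, reproducible code driven by a synthetic-data
generator, so every stage can be validated without any instrument data:

1. **Synthetic experiments** — daily cell-count series from
   semi-continuous batch cultures (inoculated at 100 cells ml⁻¹,
   reaching ~10⁵ cells ml⁻¹ per transfer) for four social-milieu
   scenarios (monoculture, membrane-separated ThinCert co-culture,
   cell-free supernatant spike, direct co-culture with a
   GFP-transformed partner) × two pCO₂ environments × six lineages ×
   nested biological/technical replicates, plus cytometry-like event
   tables and per-cell O₂ evolution records.
2. **Gating** — rectangular thresholds on size (fsc) and chlorophyll
   (fl3) channels exclude debris; a green threshold splits wild-type
   from GFP populations in direct co-cultures.
3. **Growth kinetics** — the two-point estimator
   μ = (ln N_t − ln N)/t (day⁻¹), with a log-linear OLS alternative and
   per-transfer splitting of multi-transfer assays.
4. **Social response** — the response ratio
   response = μ_treatment / μ_alone (1 = no effect), with
   technical-then-biological replicate aggregation and within-/
   between-lineage variance partitioning across environments.
5. **Carbon budgets** — net photosynthesis converted from
   µmol O₂ cell⁻¹ h⁻¹ to biomass-specific carbon units via the
   photosynthetic quotient (PQ, default 1.4 mol O₂ mol C⁻¹) and the
   cellular carbon quota; the NP/growth ratio and surplus-NP percentage
   quantify photosynthate available beyond growth demand.
6. **Null model** — the regression-to-the-mean simulation: drawing
   monoculture and mixed-culture rates independently from one truncated
   normal (0.45–1.1 day⁻¹) produces an L-shaped response-vs-μ relation
   with no interaction at all; the module quantifies it (Spearman ρ,
   binned means, c/μ fit).
7. **Inference** — linear mixed-effects models (random intercept per
   biological-replicate population), likelihood-ratio tests for the
   lineage effect, AICc model selection, and per-scenario models of
   reactiveness against carbon allocation.

## Worked example

```python
from picosocial import (calibrated_design, simulate_experiment,
                        estimate_growth_table,
                        pair_treatment_with_monoculture, budget_table,
                        simulate_null, NullModelConfig)

design = calibrated_design(env="ambient", seed=1)
sim = simulate_experiment(design)
growth = estimate_growth_table(sim.counts)
print(growth.query("scenario == 'monoculture' and population == 'focal'")
      .groupby("focal")["mu"].mean().round(3))

responses = pair_treatment_with_monoculture(growth)
print(responses.groupby("scenario")["response"].mean().round(3))

budgets = budget_table(sim.photophys, growth)
print(budgets.query("scenario == 'monoculture'")["np_growth_ratio"].mean())

print(simulate_null(NullModelConfig(n_draws=1000, seed=1)).spearman_rho)
```

prints

```
focal
L01    0.475
L02    0.578
L03    0.679
L04    0.861
L05    0.897
L06    1.196
scenario
direct      1.033
spike       1.007
thincert    1.020
1.9200055464942954
-0.716978228978229
```

The six lineages span the plausible 0.45–1.1 day⁻¹ monoculture range
(replicate noise moves individual estimates slightly outside it). Mean
response ratios sit above 1 — on this calibration slow growers speed up
more than fast growers slow down — and are graded direct > ThinCert >
spike. Monoculture photosynthesis fixes 1.92× the carbon that growth
consumes, i.e. a 92% NP surplus. The null model's strongly negative
Spearman ρ is the regression-to-the-mean warning: a negative
response-vs-monoculture-growth relation arises even with no interaction,
so the L-shape alone is not evidence of growth modulation.

The same pipeline is scriptable from a shell:

```bash
picosocial all --seed 11 --outdir out/   # counts → growth → responses →
                                         # budgets → null model → inference
```

All outputs are tidy CSVs with JSON metadata sidecars (seed, version,
parameters); a fixed seed reproduces every table byte for byte.

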