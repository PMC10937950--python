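# evglyco

Simulation and analysis tools for lectin-based thermophoretic profiling of
extracellular-vesicle (EV) surface glycans in triple-negative breast cancer
(TNBC) liquid biopsy.

The assay this package models accumulates fluorescently lectin-labeled EVs at
the bottom center of a sapphire-floored microchamber by focusing an infrared
laser into the fluid: the induced temperature field drives both buoyant
convection and thermophoresis (particle drift down temperature gradients), and
their interplay concentrates EVs inside a ~100 µm detection spot where the
fluorescence is read out. Panels of lectin intensities (ConA, WGA, RCA I) are
then combined into linear discriminant signatures for diagnosis, longitudinal
treatment monitoring and progression-free-survival (PFS) prognosis.

## What is in the box

| module | contents |
|---|---|
| `evglyco.thermosim` | axisymmetric finite-volume solver for the coupled steady heat / buoyant Stokes-flow problem and the transient EV advection–drift–diffusion equation; size-weighted enrichment traces |
| `evglyco.quantify` | central-spot intensity readout, linear calibration with blank-based limit of detection, colocalization fractions with exact binomial CIs |
| `evglyco.signature` | min-max scaling, per-patient baseline normalization, pooled-covariance LDA, the two-step diagnostic classifier, monitoring and prognostic scores, drug-efficacy index η_EV |
| `evglyco.panelselect` | hierarchical clustering of glycan profiles; exhaustive 3–5 lectin subset search ranked by a PCA segregation criterion |
| `evglyco.evaluate` | accuracy with Clopper–Pearson CI, ROC AUC with DeLong CI, Mann–Whitney U, Kaplan–Meier + log-rank, Cox proportional hazards |
| `evglyco.synthdata` | seeded generators for diagnostic / longitudinal / survival cohorts, NTA-style size distributions, fluorescence spots and colocalization counts |
| `evglyco.cli` / `evglyco.io` | `evglyco` umbrella command, CSV/JSON/YAML round trips, model serialization |

## The model

**Physics.** In the axisymmetric chamber (fluid layer 400 µm × 3.5 mm radius
between a glass lid and a sapphire floor), the temperature field obeys
conjugate conduction–advection with a Beer–Lambert volumetric source from the
focused 1480 nm beam (150 mW, 160 µm spot), calibrated so the peak fluid
temperature is 65 °C at 25 °C ambient. Flow is buoyant Stokes flow
(stream function–vorticity form; Re ≪ 1). EV concentration follows

∂c/∂t + ∇·(**u** c) = ∇·(D ∇c + S_T D c ∇T),

with Stokes–Einstein diffusivity D = kT/(3πηa) and the size-dependent Soret
coefficient S_T = 0.03 (a/100 nm)² K⁻¹. Enrichment is reported as the mean
concentration over a 100-µm-diameter cylinder at the bottom center, weighted
across an NTA-style 20 nm-binned size distribution (50–290 nm).

**Statistics.** Signatures are weighted sums s(x) = wᵀx of the three scaled
lectin intensities with w ∝ Σ⁻¹(μ₁ − μ₀) from pooled-covariance LDA. The
diagnostic signature routes each sample through two discriminants (cancer vs
healthy, then TNBC vs other subtypes); the monitoring signature works on
baseline-normalized follow-ups (PD vs PR/SD); the prognostic signature
median-splits baseline scores into high/low risk for Kaplan–Meier and Cox
analysis. The drug-efficacy index is η_EV = 1/s(t_eval) − 1/s(baseline).

## Worked example

```sh
$ evglyco synth cohort --out cohort.csv --seed 1
$ evglyco signature fit --table cohort.csv --model model.json
$ evglyco signature predict --table cohort.csv --model model.json --out pred.csv
$ evglyco quantify coloc 90 349
25.8% (90/349), 95% CI 21.3%-30.7%
```

`pred.csv` carries per-sample calls and discriminant scores; on the default
synthetic three-class cohort (20 TNBC / 19 other BC / 25 healthy donors,
deliberately separable by construction) the confusion matrix is diagonal:

```
accuracy 1.000, 95% CI 0.944-1.000
```

The physics side runs from the same umbrella command:

```sh
$ evglyco simulate --out traces.csv --seed 1
peak fluid T: 65.0 C
bottom interface max T: 25.76 C
max flow speed: 394 um/s
weighted enrichment at end: 1.23
worst mass conservation error: 2.69e-14
```

The first two lines say the calibrated hot core reaches 65 °C while the
sapphire keeps the imaged floor below 28 °C; the traces file holds the
per-size-bin and size-weighted fold-enrichment versus time. See
`docs/methods.md` for why the simulated enrichment magnitude is modest under
the default Soret law and how strongly it depends on the thermophoretic
mobility.

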