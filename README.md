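# spinacarb

A mechanistic model of fasting insulin–glucose homeostasis and the SPINA
(structure parameter inference approach) biomarkers derived from it:
**SPINA-GBeta**, the secretory capacity of pancreatic beta cells (pmol/s),
and **SPINA-GR**, the insulin receptor gain — a measure of whole-body
insulin sensitivity (mol/s). Both are computed from a single pair of
fasting glucose and insulin concentrations, alongside the classical
comparators HOMA-Beta, HOMA-IR and QUICKI.

The package is aimed at metabolic researchers who want a physiologically
grounded alternative to the HOMA family for screening-scale cohorts, and at
modellers who want a small, fully solvable feedback model to simulate.

## The model

Glucose and insulin are each governed by first-order pharmacokinetics
(dilution factor α = 1/V_D, clearance rate constant β), coupled through
saturation kinetics and non-competitive inhibition:

    dG/dt = α_G·(W + P/(1 + N)) − β_G·G        N = G_E·G_R·I/(D_R + I)
    dI/dt = α_I·S − β_I·I                      S = G_β·G/(D_β + G)

Here P is constitutive hepatic glucose production, W intestinal absorption
(0 when fasting), G_β the beta-cell secretory capacity, G_R the receptor
gain, D_β and D_R the respective EC50s, and G_E a post-receptor effector
gain. With W = 0 the fasting equilibrium solves a quadratic in closed form,
and inverting the equilibrium equations gives single-sample estimators:

    SPINA-GBeta = I·(D_β + G)/(G3·G)
    SPINA-GR    = G1·P·(D_R + I)/(G_E·I·G) − D_R/(G_E·I) − 1/G_E

where G1 = α_G/β_G and G3 = α_I/β_I are the pharmacokinetic gains. These
are exact algebraic inversions: applied to the model's own equilibrium they
recover the generating G_β and G_R to machine precision. Unlike HOMA-Beta,
which is undefined for fasting glucose ≤ 3.5 mmol/L (the "HOMA-blind
zone"), the SPINA estimators are defined on the whole positive range.

The package also provides a time-domain simulator (fasting, oral and
intravenous glucose tolerance protocols), a synthetic-cohort generator that
draws subject-level (G_R, G_β) and emits model-consistent noisy fasting
records, and the validation-statistics layer used for biomarker studies
(Kruskal–Wallis + pairwise Mann–Whitney with Benjamini–Hochberg correction,
Spearman correlations with Zou's comparison CI, Bland–Altman agreement, and
the repeatability statistic e = Var_inter/(Var_intra + Var_inter)).
See `docs/methods.md` for assumptions, parameter defaults and numerics.

## Worked example

```python
import pandas as pd
import spinacarb as sc

params = sc.DEFAULT_PARAMETERS           # reference parameter set
ss = sc.equifinal_state(params)
print(f"fasting glucose: {ss.G_inf*1e3:.4f} mmol/L")
print(f"fasting insulin: {ss.I_inf*1e12:.2f} pmol/L")
print(f"SPINA-GBeta: {sc.spina_gbeta(ss.G_inf, ss.I_inf, params):.3f} pmol/s")
print(f"SPINA-GR:    {sc.spina_gr(ss.G_inf, ss.I_inf, params):.3f} mol/s")

cohort = sc.synthesize_cohort(sc.CohortSpec(
    n_subjects=500, n_repeats=2, seed=7, fractions=(0.8, 0.1, 0.1)))
panel = sc.compute_panel(cohort)
panel["group"] = cohort.frame["group"].to_numpy()
print(panel.groupby("group")[["spina_gr_mol_s", "spina_gbeta_pmol_s"]]
      .median().round(3))
report = sc.group_comparison(panel["spina_gr_mol_s"], panel["group"])
print(f"Kruskal-Wallis H = {report['H']:.1f}, p = {report['p']:.3g}")
erg = sc.ergodicity(pd.DataFrame(
    {"subject": panel["subject_id"], "value": panel["spina_gr_mol_s"]}))
print(f"repeatability e = {erg.e:.3f}")
```

prints

```
fasting glucose: 4.3377 mmol/L
fasting insulin: 63.01 pmol/L
SPINA-GBeta: 2.800 pmol/s
SPINA-GR:    2.300 mol/s
             spina_gr_mol_s  spina_gbeta_pmol_s
group
diabetes              1.023               1.788
normal                2.242               2.700
prediabetes           1.030               2.795
Kruskal-Wallis H = 301.9, p = 2.77e-66
repeatability e = 0.949
```

The reference parameters put the fasting equilibrium at normal physiological
values, and the estimators recover the generating gains exactly. In the
synthetic cohort the strata with reduced receptor gain show reduced median
SPINA-GR (the group test is decisive), and the high repeatability e means
between-subject variation dominates assay noise across repeat visits —
subjects occupy individual metabolic set points.

A command-line interface wraps the same functionality:

```sh
spinacarb steady-state
spinacarb simulate --protocol ogtt --duration 7200 --out traj.csv
spinacarb synth --n 1000 --repeats 2 --seed 1 --out cohort.csv
spinacarb indices --input cohort.csv --out panel.csv
spinacarb stats --input cohort.csv --value-cols glucose,insulin \
    --repeats-col subject_id --out report.json
```

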