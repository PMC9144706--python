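# olfrisk

Occupational risk assessment for the human assessors ("panellists") of
dynamic olfactometry, with a focus on refinery odour emissions.

Dynamic olfactometry (EN 13725) measures the odour concentration of an
emission sample by presenting it to a panel of human assessors at
decreasing dilutions — so the panellists sniff raw, source-collected
samples that may contain hazardous volatiles (BTEX, polycyclics, sulfides).
Respiratory protection and pollutant removal are both forbidden by the
measurement standard, which leaves one risk-management lever: a **minimum
dilution step** below which the sample must never be presented. `olfrisk`
computes that dilution from a per-sample chemical concentration table.

## The method

Starting from TD-GC-MS semi-quantified concentrations C_i (mg/m³
toluene-equivalent) per compound i:

**Non-carcinogenic risk** — Hazard Quotient and Hazard Index against
short-term (15-min) occupational exposure limits:

    HQ_i = C_i / OEL_i          HI = Σ_i HQ_i          acceptable: HI < 1

Because many VOCs lack a compound-specific OEL, three assignment methods of
increasing coverage are provided:

1. compound-specific OELs only, resolved through a four-tier source
   hierarchy (international OEL → national OEL → DNEL → other short-term
   limit), lowest value within a tier (precautionary);
2. method 1, then a **family/group limit** (e.g. "Hydrocarbons, aliphatic,
   C6–C8") per uncovered compound;
3. method 1, then one limit for the whole uncovered sub-mixture by the
   **reciprocal calculation procedure** (RCP):
   OEL_mix = 1 / Σ_j (f_j / OEL_j), the mass-fraction-weighted harmonic
   mean of surrogate group limits, with fractions renormalised within the
   sub-mixture.

Compounds no method can cover contribute nothing to HI and are reported as
the coverage statistic N.C.% (by count and by mass).

**Carcinogenic risk** — lifetime excess inhalation cancer risk per CLP
category 1A/1B/2 compound, summed over the mixture:

    IR = CDI × IUR,   CDI = C_air[µg/m³] × (ET·EF·ED)/(AT)

with exposure time ET (h/day), frequency EF (d/year), duration ED (years),
and lifetime averaging AT (70 years). Acceptability: IR < 10⁻⁶ per
compound, < 10⁻⁵ per mixture. The scenario collapses into one dimensionless
CDI multiplier, so risk ratios between laboratories are constant across
samples.

**Dilution policy** — every metric is linear in concentration, so

    d_min = max(HI/1, IR_mix/10⁻⁵, max_i IR_i/10⁻⁶, 1)

is the smallest dilution restoring acceptability; it is snapped upward to
the olfactometer's discrete step ladder (default 14 factor-2 steps from
1:4).

## Worked example

```python
from olfrisk import (GeneratorParams, OlfactometerLadder, assess_campaign,
                     generate_campaign, summarize)

camp = generate_campaign(GeneratorParams(n_samples=18, seed=1))
a = assess_campaign(camp.samples, camp.catalogues, camp.scenarios,
                    camp.criteria, method=2, ladder=OlfactometerLadder())
s = summarize(a.risk, ["hi", "ir_commercial", "ir_institutional"])
for metric, st in s.stats.items():
    print(f"{metric}: mean {st.mean:.3g} (sd {st.sd:.3g}), "
          f"median {st.median:.3g}, range [{st.min:.3g}, {st.max:.3g}]")
r0 = a.recommendations[0]
print("first sample:", r0.sample_id, "d_min", f"{r0.d_min:.2f}",
      "binding", r0.binding_criterion, "ladder step", r0.ladder_step)
```

prints

```
hi: mean 0.279 (sd 0.166), median 0.252, range [0.0771, 0.688]
ir_commercial: mean 2.32e-05 (sd 8.02e-06), median 2.23e-05, range [1.14e-05, 3.84e-05]
ir_institutional: mean 4.2e-06 (sd 1.45e-06), median 4.04e-06, range [2.07e-06, 6.94e-06]
first sample: S01 d_min 15.98 binding ir_single[commercial] ladder step 16.0
```

i.e. for this synthetic campaign the non-carcinogenic risk is always
acceptable (HI well below 1), the commercial-laboratory mixture cancer risk
exceeds 10⁻⁵ for most samples, and the first sample must be presented at
dilution 1:16 or higher because its dominant single carcinogen (benzene)
drives the per-compound 10⁻⁶ criterion.

The same pipeline is scriptable from the shell:

```
olfrisk simulate --n 18 --seed 1 --out-dir campaign/
olfrisk assess --samples campaign/samples.csv --oels campaign/oels.csv \
    --groups campaign/groups.csv --iur campaign/iur.csv \
    --classes campaign/classes.csv --annotations campaign/annotations.csv \
    --config src/olfrisk/data/default_config.yaml --method 2 \
    --out-prefix results/run
olfrisk dilution --risk results/run_risk.csv \
    --config src/olfrisk/data/default_config.yaml --out results/dilution.csv
```

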