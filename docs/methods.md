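# Methods

## Scope and model

`olfrisk` implements a first-tier, component-based occupational risk
assessment for olfactometric panellists. It deliberately assumes **dose
addition with no chemical interaction**: the Hazard Index is the plain sum
of hazard quotients and the mixture cancer risk is the plain sum of
per-compound lifetime excess risks. No toxicokinetic/toxicodynamic
interaction, target-organ segregation, or route-to-route extrapolation is
modelled; the intent is a conservative screening tool whose outputs (and
every intermediate decision) are auditable, with expert review expected
for borderline cases.

Concentrations are taken as given in mg/m³ toluene-equivalent —
semi-quantification against a single toluene response factor, the common
practice for untargeted TD-GC-MS screening of odour samples. All limits
are short-term (15-min) values, because a panellist's exposure consists of
brief sniffing events; no 8-h TWA variant is computed.

## OEL resolution

A compound-specific limit is searched through four source tiers in fixed
priority order: `international_oel` > `national_oel` > `dnel` >
`other_short_term`. **This ordering is an assumption** — reasonable (more
broadly vetted sources first) but not the only defensible one; it is
isolated in one place (`olfrisk.types.OEL_TIERS`) and recorded on every
assignment's `trace`. Within a tier, and whenever several group limits
match, the lowest value wins — the precautionary tie-break used
throughout.

Group matching requires structural metadata (hydrocarbon class + carbon
number) supplied explicitly via an annotation table. Names are never
parsed for chemistry, and there is no fuzzy name matching: a silent
mis-assignment is worse than a reported gap, which is exactly what the
N.C.% coverage statistics exist to expose. CAS numbers take precedence
over normalised names in every lookup.

The RCP (reciprocal calculation procedure) fallback is an adaptation of
the solvent-mixture limit OEL_mix = 1/Σ(f_i/OEL_i): it is applied **only
to the sub-mixture of compounds that have no specific limit**, with mass
fractions renormalised within that sub-mixture and component limits taken
from group matching. The sub-mixture then behaves as one pseudo-compound
(one HQ = summed concentration / OEL_mix). Compounds with no group
surrogate, and zero-concentration compounds (which carry no mass
fraction), stay unassigned. The harmonic mean guarantees
min(OEL_j) ≤ OEL_mix ≤ max(OEL_j), so the fallback can never be less
conservative than its most conservative surrogate by construction.

## Carcinogenic risk and exposure scenarios

The lifetime excess risk of a compound is IR = CDI × IUR with
CDI = C_air[µg/m³] × m and the dimensionless multiplier

    m = (ET/24) · (EF/365) · (ED·365 / AT_days),   AT_days = LT·365 by default.

The grouping — exposure factors in the numerator, averaging time in the
denominator — is the standard risk-assessment convention; continuous
lifetime exposure (ET=24, EF=365, ED=LT) gives m = 1 exactly, which the
tests pin. The per-µg/m³ basis of published IURs is the only place the
package leaves mg/m³ (×1000, inside `olfrisk.cancer` only).

Parameters (defaults): ET 3 h/day, EF 221 d/yr, ED 25 yr for the
"commercial" scenario; ET 2 h/day, EF 60 d/yr, ED 25 yr for
"institutional"; LT 70 yr for both. **These absolute values are
placeholders** — a real laboratory must characterise its own panel
workload — but their multiplier ratio, 5.525, was chosen to reproduce the
constant commercial/institutional risk ratio (≈5.52) visible row-by-row in
the published campaign table the package bundles. Cross-scenario ratio
constancy is itself an exact invariant of the model (m factors out of
every sum) and is tested both analytically and against that table.

Bundled IURs: benzene 7.8×10⁻⁶ per µg/m³ (US EPA IRIS) and naphthalene
3.4×10⁻⁵ per µg/m³ (CalEPA) — the two CLP-classified carcinogens observed
in refinery odour samples. Carcinogens lacking an IUR contribute zero and
are listed in an explicit gap list, never dropped silently.

## Dilution policy

All risk metrics are linear in concentration, so the minimum dilution is a
closed form: d_min = max of (HI/HI_max), per-scenario (IR_mix/10⁻⁵) and
(max_i IR_i/10⁻⁶), floored at 1. The term attaining the maximum is
reported as the binding criterion. Both the continuous value (2-decimal
display, full precision in machine output) and the snapped olfactometer
step are emitted, because practice differs on which one is enforced.

The single-compound 10⁻⁶ criterion is always evaluated when a per-compound
breakdown exists. When only published mixture totals are re-analysed
(`CarcRisk.from_mixture_value`, breakdown `None`) that criterion is
skipped — which reproduces published dilution tables whose values equal
IR_mix/10⁻⁵ exactly. Note the two readings genuinely differ: with benzene
dominating the carcinogenic fraction, the single-compound criterion binds
long before the mixture one on raw samples.

Default ladder: 14 factor-2 steps from 1:4 (4 … 32768). Real instruments
advertise ~14 steps between 1:4 and 1:65,000, which no integer-ratio
geometric series matches exactly; the default is therefore declared, and
fully configurable. A d_min above the top step flags the sample as
unanalysable at the available dilutions rather than raising.

## Synthetic campaigns and ground truth

The generator emulates what the pipeline consumes, not the instrument: a
28-compound refinery VOC palette (aromatics, n-/cyclo-alkanes, oxygenates,
sulfides; benzene and naphthalene as the carcinogenic fraction) with
per-compound lognormal concentrations, a per-sample lognormal
source-strength factor (σ = 0.45) that spreads sample totals over roughly
an order of magnitude, per-compound detection probabilities, and 18
area/location labels from a refinery wastewater line, vapour-recovery unit
and tank farm. Geometric means are calibrated so a default campaign lands
where real refinery campaigns do: method-1 HI ≈ 0.1–0.8 (expectation
0.335), commercial-scenario mixture IR ≈ 1–4×10⁻⁵ (expectation 2.4×10⁻⁵).
By default 3 of 28 palette compounds (≈11%) lack a specific OEL, two of
them group-matchable — mirroring the observed drop in N.C.% from method 1
to method 2; `uncovered_fraction_target` overrides this (0 forces full
method-1 coverage; carcinogens are never stripped).

It does **not** emulate chromatographic co-elution, compound-specific
response factors, detection limits, or inter-compound correlation beyond
the shared strength factor. Passing pipeline-vs-truth tests therefore
demonstrates computational correctness of the risk arithmetic, not that
the palette is a faithful emission inventory.

Every campaign carries a ground-truth table computed by an independent
plain-loop re-implementation inside the generator (tier resolution, group
matching, RCP, HI/IR sums, d_min — no shared code with the pipeline
modules). The acceptance tests require pipeline agreement within 1e-9
relative over 100 seeded campaigns. `perturb_to_boundary` rescales a
sample by one factor so its *binding* criterion sits exactly on its
threshold (d_min = 1); by linearity a further ×k rescale moves d_min to k,
which is tested for k ∈ {1.01, 1.78, 5}.

## Numerical conventions and degenerate inputs

- RCP fractions must sum to 1 within 1e-9; component limits must be > 0.
- HI equals Σ HQ and IR_mix equals Σ IR_i exactly by construction; tests
  assert them at 1e-12 relative.
- Summary statistics use the sample (n−1) standard deviation — it, not the
  population form, reproduces the published campaign's printed ±0.174 —
  with sd = 0 by convention for a single-sample campaign; an even-count
  median is the mean of the two central order statistics. Display
  precision (HI 3 decimals, IR 3 significant figures, dilution 2 decimals)
  is applied only at rendering; JSON artefacts keep full precision.
- Duplicate catalogue entries: several limits for one substance within a
  tier from different sources are legitimate (lowest wins); the same
  source stating two different values is rejected as a data error.
- An empty IUR catalogue, a sample with no carcinogens, and a fully
  uncovered sample are all valid inputs yielding zero risk plus the
  appropriate coverage/gap reporting.
- Assignment and summary results are invariant under compound and sample
  reordering; the generator is fully determined by its seed.

## Problem sizes

Default campaigns are 18 samples × ~25 detected compounds, matching the
campaign structure the package models. The test suite runs 100 seeded
campaigns for pipeline-vs-truth equivalence, 1000 random draws for
dilution-policy invariants, and 500 draws plus a hypothesis property for
RCP bounds; the whole suite completes in a few seconds on one CPU.

## Known limitations

- The four-tier OEL priority is an assumption (above); jurisdictions with
  binding national limits may legitimately invert the first two tiers.
- Absolute carcinogenic risks are only as good as the scenario parameters;
  the shipped scenarios are calibrated placeholders.
- Count-based N.C.% can understate risk when a single heavy compound is
  uncovered — which is why the mass-based figure is always reported
  alongside.
- The bundled group-limit table annotates carbon ranges for the three
  petroleum-fraction entries that their source does not print; they are
  class-gated (`petroleum_fraction`) so they never shadow the
  aliphatic/aromatic groups for ordinary compounds.
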