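# Methods

## Model and assumptions

All kinetics are strictly exponential: each observed volume segment
(`VolumePhase`, cm³ over seconds) is summarized by its signed rate
constant k = ln(V_end/V_start)/Δt, interpreted as the net
mitosis-minus-apoptosis rate per cell. No Gompertz, logistic, or other
saturating model is offered; the framework's energy map is defined on
doubling times of exponential growth, and the packaged dataset reports
only endpoint volumes, which cannot discriminate growth laws anyway.

Durations are stored in seconds throughout (1 d = 86 400 s, 1 w =
604 800 s) because the energy formula takes t_D in seconds; the tabulated
μg/ml dose column is authoritative for all energy analyses, with the
regimen text used only for scheduling.

### Virtual growth for shrinking arms

The growth-energy map is defined only for doubling times, so a shrinking
phase must first be replaced by an equivalent growing one. The equivalence
identity relating the shrunk fraction to a virtual growth fraction admits
more than one algebraic reading, so three are implemented, selectable per
call and recorded in provenance:

- `half_life_equivalence` (default): V_end' = V_start²/V_end. Chosen as
  default because it is the unique reading under which the virtual
  doubling time equals the observed half-life *exactly* (a property test
  asserts agreement to 1e-12 relative), which is what "a virtual growth
  portion of doubling time equivalent to the shrinking portion" should
  mean operationally.
- `reflection`: V_end' = 2·V_start − V_end (mirror the volume loss).
  Matches the default to first order in the shrunk fraction.
- `literal`: V_end' = V_start + V_start²/(V_start − V_end), the identity
  read at face value. Note its pathology: as the shrinkage vanishes the
  virtual end volume diverges and the virtual doubling time goes to zero,
  so it disagrees qualitatively with the other two readings for mild
  shrinkage. It is retained for comparison, never as a default.

Only four of the fourteen packaged records (3, 12, 13, 14) contain a
shrinking phase, so the choice does not touch the dose-840 analyses.

Multi-phase arms are aggregated into one effective rate as total
(virtualized) log-volume change over total duration — a time-weighted
average, consistent with reducing each arm to a single growth constant.
Static phases (no volume change) are rejected as degenerate when they are
the whole trajectory, and contribute zero log-change (but full duration)
inside a multi-phase arm.

### Energy map

E_G(t_D) = ln[(ln(ln2/t_D))²] is evaluated with the square taken before
the outer logarithm. For every biological doubling time ln2/t_D < 1, so
the inner logarithm is negative and the alternative reading
[ln(ln(ln2/t_D))]² would be complex-valued; the implemented reading is the
only real one, and it reproduces the identical-in-three clustering of the
reference table. The map is strictly increasing on t_D ≥ ln2·e s, with
E_G = 0 at the boundary; inputs below the boundary raise a domain error.
Doubling times under one hour are biologically implausible for tumors and
emit a warning (configurable constant) rather than an error, so the
mathematical domain stays usable in property tests.

The inverse used for prediction is t_D = ln2·exp(+√(exp(E_G))), the branch
with ln(ln2/t_D) < 0 — the biological branch. Round-trip identity holds to
1e-9 relative over E_G ∈ [0, 7] (≈ t_D from 1.9 s to 10⁹ d).

Energies are computed and stored in Emad; the MeV conversion
(1 Emad = 23 234.59 MeV) is applied last, purely for presentation, so the
large constant never contaminates differences or regression.

E_Dose is computed per regimen (endpoint-to-endpoint): the published
trajectories are endpoint-only, so a per-injection decomposition of the
accumulated energy is not identifiable from these data, and the regimen
total is the quantity the dose–energy model regresses.

## Regimen handling

Regimen texts are parsed from a closed set of phrasings (explicit dose
days; "every Nth day"; weekly / biweekly / twice-weekly / thrice-weekly
rates). Rate phrasings place the first injection at therapy start and
space uniformly (7/3 d for "thrice weekly"); injections beyond the
observation span are truncated with a logged warning. The *nominal* dose
count implied by the phrasing (rate × stated duration, possibly
fractional, e.g. thrice weekly for 3.5 weeks → 10.5) is kept separately
from the realized injection list: it is the basis of the cumulative-dose
audit and is unaffected by truncation.

The dose audit checks the empirical regularity dose[μg/ml] = 28 ×
cumulative mg/kg, satisfied by 13 of the 14 packaged rows within 0.5%. It
is warning-level bookkeeping: the flagged row (2100 μg/ml vs a regimen
text implying 2520) is reported, not resolved, and the tabulated dose
remains authoritative.

The efficiency criterion is stated ambiguously in the source material
(interval "to the time of dose delivery" vs "to the time of the next dose
delivery"); both are implemented as `criterion_mode` with
`to_next_dose` as default (the more operational phrasing), and pipeline
reports emit both columns so neither is silently preferred. The
comparison uses ≥, so boundary equality counts as efficient. A dose at
t = 0 has intraday doubling time 0 by linearity and is reported "not
evaluable" instead of inefficient. The steadiness check (intraday t_D
strictly increasing across dose times) is trivially true under
whole-trajectory endpoints (linearity); a `per_phase` option evaluates
each dose time against its containing phase's endpoints, which can reveal
accelerating regrowth.

Schedule classification: metronomic iff median inter-dose gap ≤ 3.5 d and
per-injection dose ≤ 1 mg/kg, else standard. The thresholds are package
choices that separate the two packaged exemplars (0.5 mg/kg thrice weekly
vs 15 mg/kg biweekly) with a wide margin, and are configurable.

## Dose–energy model

"Identical" effects are operationalized as single-linkage clustering under
a 5% relative tolerance. The observed spread of the three matching
dose-840 records is < 1%, so the conclusion is insensitive to tolerances
in [0.02, 0.10] (asserted by test). Clustering agrees with a brute-force
transitive closure on small lists (exhaustive property test).

Regression is ordinary least squares; the default fit has an intercept and
a through-origin fit is always reported alongside. With n this small no
p-values are emphasized — only r and R² (uncentered for through-origin
fits). Two-point fits and constant-dose through-origin fits are flagged
`underdetermined`; Pearson r is None when either variable is constant.

Prediction inverts the energy map: E_treated = E_G(t_D,control) +
E_Dose(dose)/C₀×h, then t_D = inverse(E_treated); a volume fold-change
2^(horizon/t_D) is reported over a caller-chosen horizon (default: the
control doubling time). Energies that overflow the inverse raise a
domain error rather than returning infinities.

## Synthetic cohorts

The generator emulates what the published records actually are —
endpoint-only volume pairs of exponential arms with known inoculum — built
backwards from a chosen linear dose–energy relation, so the analyzer run
on a noiseless cohort must return the generating parameters exactly
(closure is tested at 1e-9 relative). Defaults model a typical xenograft:
control doubling time 7 d, inoculum 10⁶ cells, 0.1 cm³ starting volume,
14-day observation, doses spanning the packaged table's range.

Measurement error is multiplicative lognormal on endpoint volumes
(volumes are positive; error scales with size). All randomness flows from
one integer seed; standard-normal draws are consumed unconditionally and
scaled by σ, so the same seed yields proportionally scaled errors across σ
and the slope-RMSE is monotone in σ by construction (also asserted
empirically over σ ∈ {0.2, 0.1, 0.05, 0}). The generator does not simulate
pharmacokinetics, immune response, inter-animal variability structure, or
non-exponential kinetics — passing tests therefore certify the analysis
machinery, not the biological adequacy of the exponential/DT-EC model on
real data.

Test problem sizes (n = 20 animals, 10 seeds for the noise-scaling check)
are the package's choices for a fast, deterministic suite; all tests and
the acceptance script complete in seconds on one CPU.

## Known limitations

- No uncertainty propagation on energies: the source data are point
  values without replicates or error bars.
- The dose–energy model is not claimed to generalize across cell lines;
  the packaged table itself shows same-dose effects differing by 30×
  between sensitive and resistant models.
- Regimen parsing covers only the packaged phrasings; anything else
  requires explicit injection times.
- One packaged record pairs non-matching control and treated observation
  windows (0.06→0.24 cm³/14 d vs 0.232→0.42 cm³/17 d); arms are analyzed
  per-arm as printed, with no alignment or rescaling, since each arm's
  energy depends only on its own endpoints and duration.
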