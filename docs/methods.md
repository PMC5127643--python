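# Methods

## Model

The package simulates a minimal feedback circuit for the yeast heat shock
response with four molecular players — the Hsp70 chaperone, the
transcription factor Hsf1, unfolded protein (UP) acting as a competing
Hsp70 client, and a YFP reporter of Hsf1 activity — tracked as six species:
free Hsp70, free Hsf1, free UP, the Hsp70·Hsf1 and Hsp70·UP complexes, and
YFP. The dynamics are mass-action binding/unbinding plus Hill-type
transcription:

* Hsp70 binds either Hsf1 or UP, never both at once;
* both clients share one on-rate constant (k₁ = k₃), enforced at
  construction unless explicitly overridden;
* free Hsf1 drives synthesis of Hsp70 and YFP through the same Hill
  function β·[Hsf1]ⁿ/(K_dⁿ+[Hsf1]ⁿ) with n = 3, a minimal representation
  of trimeric DNA binding (separate reporter overrides exist but default
  to the shared values);
* UP leaves the system only by degradation out of the Hsp70·UP complex
  (rate k₅), which simultaneously frees Hsp70 — hence Hsp70 is released
  from that complex at k₄+k₅ while free UP is returned at k₄ only;
* YFP dilution k_dil is fixed at 0: the simulated time courses (2 h) are
  shorter than a cell generation and YFP is long-lived.

These assumptions give three structural identities that the test suite
checks symbolically and along trajectories: total Hsf1 is conserved; total
Hsp70 changes only through the Hill synthesis term; total UP decays only
through k₅·[HSP·UP].

## Parameters and initial conditions

Defaults are the published selected set (arbitrary concentration units,
minutes):

| parameter | default | meaning |
|-----------|---------|---------|
| k₁ = k₃ | 166.8 min⁻¹·a.u.⁻¹ | client–Hsp70 on-rate constant |
| k₂ | 2.783 min⁻¹ | Hsp70·Hsf1 off-rate |
| k₄ | 0.0464 min⁻¹ | Hsp70·UP off-rate |
| k₅ | 4.64e-7 min⁻¹ | UP degradation out of the complex |
| β | 1.778 min⁻¹ | transcriptional activation rate |
| K_d | 0.0022 a.u. | Hsf1–DNA dissociation constant |
| k_dil | 0 (fixed) | YFP dilution |
| n | 3 (fixed) | Hill coefficient (positive integer; non-integers are rejected so screen grids stay well-defined) |

Initial conditions: free Hsp70 = 1, free Hsf1 = 0, Hsp70·Hsf1 = 1/500,
Hsp70·UP = 0, YFP = 3, and UP set by the temperature map (10.51 at 39 °C).
The tabulated free-Hsp70:complex ratio of 500 is used literally; no claim
is made about whether "500:1" was meant as free-to-total or total-to-total.
The tabulated state is used directly as t = 0 with **no pre-equilibration**
— it is in fact slightly off the binding equilibrium (zero free Hsf1), so
even without any UP the bound fraction relaxes from 1 to
k₁·HSP/(k₁·HSP+k₂) ≈ 0.984 within seconds. Tests that probe the
no-titration limit assert against that analytic floor rather than 1.

## Temperature map

The initial UP load follows UP(T) = A·e^{bT} through the anchors
(25 °C, 0.52) and (39 °C, 10.51); an exponential dependence of unfolding
on temperature is supported by calorimetry in the 25–50 °C range, which is
the enforced validity domain. An upshift is modeled purely as this jump in
initial UP — the UP equation has no production term, so there is no
continuous influx during the run.

## Numerics

* Production simulations use a stiff-capable adaptive solver (LSODA with
  the analytic Jacobian; Radau and BDF are accepted alternatives) at
  rtol 1e-6 / atol 1e-9. The system is stiff: client binding relaxes on
  the ~1/(k₁·[load]) ≈ 5e-4 min scale while the reporter accumulates over
  hours.
* Concentrations are clipped to zero inside the right-hand side before
  evaluating mass-action terms; solver undershoot below −1e-12 in an
  explicitly supplied state raises instead. The t = 0 output row is the
  initial condition itself, not the interpolant's value.
* An independent fixed-step classical RK4 integrator cross-checks the
  adaptive solution. At step 0.001 min the fastest eigenvalue
  (≈ k₁·(UP+Hsf1+HSP) ≲ 2000 min⁻¹ along the reference scenario) stays
  inside the RK4 stability region, and the two solutions agree to 1e-4
  relative error on all species.
* The parameter screen integrates at rtol 1e-5 / atol 1e-8 for throughput
  and evaluates only the output times the constraints need; production
  tolerances can be restored per call.

## Parameter screen

The three constraints are evaluated from two trajectories per candidate
set: a 120-min basal run at 25 °C and a 60-min upshift to 39 °C. The
qualitative "Hsf1 is Hsp70-bound at baseline" is quantified as the bound
fraction of total Hsf1 staying ≥ 0.5 throughout the basal run (the weakest
majority-bound reading; threshold configurable). Dissociation checks the
minimum normalized complex level over the first 5 min against 0.10;
re-association checks the 60-min value against 0.90. Thresholds are
validated independently, so vacuous settings (dissociation threshold 1,
re-association threshold 0) are legal and accept any integrable set.

The original screen's per-parameter ranges are shown only graphically in
the source material; the shipped default grid is a documented
approximation — 5 log-spaced values per free parameter spanning ±2 decades
around the selected set (5⁶ = 15 625 combinations, built so the selected
values sit on the grid exactly as floats). Reproducing the original
7×10⁵-combination screen is explicitly not claimed. Integration failures
inside a sweep are recorded per set (with the solver message) and counted
as failures rather than aborting the screen. Success frequencies are
reported per parameter value as 100 × (successful sets containing the
value)/(successful sets); with zero successes they are NaN and flagged
undefined, never 0 %.

## Perturbations

**Decoy.** Two extra species: free decoy and decoy·Hsp70, binding with the
same k₁/k₂ kinetics as Hsf1 but contributing nothing to transcription.
With zero total decoy the eight-species right-hand side reduces exactly to
the six-species one.

**Dose response.** Overexpression is parameterized directly by the initial
amount of the added species (the experimental inducer dose is not
modeled): full-length Hsf1 is added to the free-Hsf1 pool at t = 0 (the
simplest reading; binding re-equilibrates within seconds at k₁ = 166.8)
and feeds both Hsp70 binding and the Hill term, while decoy increments the
decoy pool only. The default protocol is a basal 25 °C run — activation by
overexpression requires no temperature upshift.

**Phosphorylation gain.** β evolves sigmoidally in time,
β(t) = β₀ + (β₁−β₀)/(1+e^{−s(t−t₀)}), defaults t₀ = 20 min (matching the
observed phosphorylation kinetics), s = 0.3 min⁻¹, β₁ = 2β₀; none of the
four values is published, so all are configuration-exposed. The gain is
applied **to the reporter's transcription only**, with Hsp70 synthesis
held at β₀. This was a genuinely open design point, decided by simulation:
routing the gain through Hsp70 synthesis as well lets the extra chaperone
feed back, re-repress Hsf1 faster, and largely cancel the gain — the
wild-type-minus-phospho-dead reporter difference then peaks and *declines*,
losing the sustained late-phase activity the gain exists to model. With
reporter-only routing the difference is exactly
∫(β(s)−β₀)·hill(s) ds ≥ 0: zero at t = 0, non-decreasing, and the
phospho-dead variant (β₁ = β₀) reduces to the base model identically.
`apply_to_hsp_synthesis=True` restores the shared-β variant for
exploration.

## Synthetic data

The generator emulates the *summary statistics* of the two measurement
types the model is compared against — triplicate IP/MS-style normalized
complex ratios at {0, 5, 15, 30, 60} min after a 39 °C upshift, and
flow-cytometry-style median reporter levels over time at several
temperatures. Values are the model output multiplied by independent
lognormal factors scaled to unit mean (σ² = ln(1+CV²), μ = −σ²/2), so
replicate means converge to the noiseless curve; CV defaults are 0.15
(IP/MS) and 0.10 (reporter), with 3 replicates. No instrument noise model
is published; the multiplicative lognormal is a documented stand-in
motivated only by the positivity and roughly CV-constant spread of
intensity data. The RNG (PCG64) and seed are part of the dataset record.

What the generator does **not** emulate: peptide-level quantification,
raw spectra, cytometry event distributions, biological replicate
covariance, day effects, or the slow late-phase reporter accumulation seen
in cells but absent from the pure-titration model. Passing recovery tests
therefore show the pipeline is self-consistent at the stated noise level,
not that the model fits real measurements.

**Recovery.** The data-driven screen replaces the fixed 10 %/90 %
thresholds with (mean at 5 min + 2 s.d.) and (mean at 60 min − 2 s.d.)
from the synthetic table, runs at production tolerances, and applies a
1e-6 relative slack so the zero-noise case — where the thresholds equal
the generating curve exactly — is not broken by interpolation-grid
differences between the generating and screening trajectories.

## Problem sizes

Test and reproduction runs use desk-scale settings: 120-min trajectories
on a 0.5-min output grid, the 5⁶ reduced screen, 27-combination recovery
grids across seeds 1–5, and a 0.001-min RK4 oracle on the single reference
scenario.

## Known limitations

* The base titration model deliberately lacks the slow late-phase reporter
  accumulation observed in cells; only the phospho-gain extension
  addresses it, qualitatively.
* No spatial, stochastic or delay variants; no thermodynamic unfolding
  model beyond the two-anchor exponential; no temperature ramps or
  down-shifts.
* The decoy is modeled as kinetically identical to Hsf1 toward Hsp70;
  domain-truncation variants and growth-inhibition phenotypes are outside
  the model.
* Whether overexpressed full-length Hsf1 should also raise the Hill
  saturation ceiling is ambiguous; the same Hill function on total free
  Hsf1 is used.
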