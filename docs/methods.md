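# Methods

`chemocomp` implements the quantitative analysis chain of a chemostat
competition experiment between two freshwater ciliate consumers — a
*Euplotes*-like filter feeder and clones of a *Coleps*-like raptorial feeder
— competing for two microalgae (*Cryptomonas* sp., *Navicula pelliculosa*)
and the accompanying bacteria in a nitrogen-limited flow-through system.
This note records the models, parameter choices, and design decisions.

## Units

Fixed package-wide: cell volumes in µm³, carbon in pg, concentrations per
ml, dissolved nutrients in µmol N per litre, rates per day.

## Carbon conversion (`allometry`)

Cell carbon follows a power law of biovolume, C[pg] = m·a·V^b. The bundled
organism set uses the Menden-Deuer & Lessard laws for the microalgae
(a = 0.216, b = 0.939 for the cryptophyte; a = 0.288, b = 0.811 for the
diatom), the Putt & Stoecker linear ciliate law (C = 0.14·V), and the
Loferer-Krößbacher dry-weight law for bacteria with carbon assumed half of
dry weight — the `multiplier_m` field exists precisely to house that 0.5
factor. Derived carbon densities (pg C/µm³) are stored at full precision;
rounding to the reported significant figures happens only at
formatting/comparison time, so downstream modules never compound rounding
error. Carbon-based maximum ingestion rates are cell-based rates times the
prey's mean cell carbon; diet shares are normalised carbon-based rates.

## Grazing-rate estimation (`ingestion`)

Control/grazed bottle pairs are analysed in the standard Frost form: prey
growth constant k = ln(C₂ᶜ/C₁ᶜ)/T from the control, grazing constant
g = k − ln(C₂ᵍ/C₁ᵍ)/T, time-averaged prey density
C̄ = C₁ᵍ·(e^{(k−g)T} − 1)/((k−g)T), and Heinbokel's time-averaged grazer
density as the logarithmic mean (N₂−N₁)/(ln N₂ − ln N₁) (which is exact for
exponentially changing grazers). Clearance is g/N̄ and ingestion is
clearance·C̄. Degenerate limits (k→g, N₁→N₂) switch to the analytic limit
below a 1e-9 tolerance. A negative g — a grazed bottle outgrowing its
control — is reported with a warning and excluded from functional-response
fits by default, never clamped; clamping would silently bias I_max upward.

The saturating functional response I(C) = I_max·C/(K+C) is fitted by
bounded nonlinear least squares (`scipy.optimize.curve_fit`), initialised
from a Hanes–Woolf linearisation, with K restricted to (0, 10·max density].
The fit route is the default; reporting mean ingestion at a single
saturating density remains possible by passing one-density bottles through
`clearance_and_ingestion` directly.

## Population statistics (`popmetrics`)

Net growth rate is the two-point log-linear rate r = (ln B₂ − ln B₁)/(t₂−t₁)
over a window (first/last point inside), matching how initial-phase rates
are conventionally reported; `phase_rate` instead fits an OLS slope of
ln-biomass over all uncensored points and is meant for longer decline
phases. Both are exposed because they answer different questions and agree
only for exactly exponential data. The default growth window is days 0–5
(the initial growth phase, where prey density still permits maximal
ingestion) and is configurable. The population filtration rate is
F = I_max·C̄ with C̄ the logarithmic-mean ciliate density, reported raw and
as log10.

Censoring: a count of zero in a 2-ml subsample means "below 0.5 cells/ml",
and the conventional substitute is half the detection limit — 0.25
cells/ml, which for the two ciliates corresponds to carbon detection limits
of 10^3.3 (Euplotes) and 10^2.8 (Coleps) pg C/ml. Substituted points stay
flagged `censored` and are excluded from slope fits; they are never silently
imputed.

The Coleps:Euplotes competition outcome is summarised as
log10(Coleps BM/Euplotes BM); `log_ratio_table` emits the tidy
(treatment, replicate, day, log_ratio) table ready for an external
mixed-model ANOVA — the inference itself is deliberately out of scope.

## Carbon budget (`budget`)

At late-experiment quasi-equilibrium the dominant alga's net primary
production only offsets dilution, NPP = δ·B_N. With a fraction f of gross
primary production exuded, E_A = f/(1−f)·NPP. Bacterial production obeys
the recycling balance P_B = e_B(E_A + (1−e_C)P_B − D), whose solution

    P_B = e_B (E_A − D) / (1 − e_B (1 − e_C)),   D = δ·B,

is also the limit of the geometric series implemented independently in
`bacterial_production_iterative` (ratio e_B(1−e_C); the package tests the
two routes against each other rather than collapsing them). Defaults:
e_B = e_C = 0.5 (giving P_B = ⅔(E_A−D)), δ = 0.1/d, consumer growth
efficiency 25% and maximum growth rate 0.4/d, so the consumer-side demand
terms are 1.6·B_E (ingestion sustaining maximal growth) and δ·B_E (washout).
"Maximal amount the consumer can ingest" is interpreted as μ_max/GE·B_E;
the dilution-compensating alternative δ·B_E/GE is provided as a third
`kind`. Negative P_B (exudation below bacterial washout) is returned
flagged-by-sign rather than clamped, which keeps f ↦ P_B strictly monotone
and makes `critical_exudation` an exact closed-form inverse. Dead-diatom
carbon as an extra substrate is not modelled; it would only raise P_B, so
the computed values are conservative. ln(1 + P/B) is exposed as an optional
growth-rate diagnostic without any claim attached.

## Synthetic community (`synthcommunity`)

The generator emulates the study conditions: dilution 0.1/d, 120 µmol N/l
inflow, 33 days sampled every second day, initial algal biovolume
14.4×10⁶ µm³/ml and ciliate biovolume 1.3×10⁶ µm³/ml split equally among
the inoculated taxa, lognormal observation noise (default CV 10%, a choice
typical of microscopy counts), four replicates.

Mechanisms, assembled from the system's known biology rather than fitted:

- **Algae**: Monod growth μ_max·N/(K_N+N); a fraction f (default 0.1, the
  "moderate exudation" range) of gross production goes to a dissolved
  organic carbon (DOC) pool, the rest to biomass. Default μ_max 0.9/d
  (cryptophyte) and 1.2/d (diatom) with K_N 2.0 and 0.8 µmol/l make the
  diatom the better nitrogen competitor (lower R*), reproducing the
  observed succession without tuning to trajectories.
- **Grazing**: per-prey Michaelis–Menten terms
  I_max,p·C_p/(K + ΣC) with one half-saturation per consumer
  (2×10⁵ pg C/ml, well below the initial prey stock), so saturated
  single-prey intake equals the configured I_max — the condition under
  which the bottle-assay rates were measured. The Euplotes-like consumer
  has a lag phase (default 9 d) with zero ingestion and growth, the
  simplest mechanism consistent with the observed lag, and a modest
  biomass-specific bacterivory rate (0.5/d) since its bacterial feeding
  was not quantified cell-wise. Assimilated intake converts to biomass at
  growth efficiency 0.25; egested carbon joins the DOC pool. When
  dissolved N falls below 2 µmol/l, assimilation efficiency on the diatom
  is multiplied by `nav_quality_decline` (default 0: nitrogen-starved
  diatoms support no consumer growth).
- **Bacteria**: Monod uptake of DOC, growth efficiency 0.5; respired
  carbon leaves the system.
- **Nitrogen bookkeeping**: every pool carries a fixed N:C quota (molar
  C:N 6.625 for algae, 5 for bacteria and ciliates); each carbon flux
  carries nitrogen at the source quota and transfer mismatches are
  remineralised to the dissolved pool. Total nitrogen therefore obeys
  d/dt(total) = δ(N_in − total) identically; the integrator co-integrates
  the cumulative inflow−outflow so the balance can be audited to floating-
  point precision (`nitrogen_balance_error`).

Integration is fixed-step RK4 at 0.01 d — reproducibility across platforms
is worth more here than adaptive-step speed, and at 3 300 steps per run the
cost is negligible. Observation noise is the only randomness and flows from
the single configured seed; identical config + seed gives byte-identical
output. No stochastic demography, no benthic/spatial structure, and no
mechanism for the abrupt clone crash seen in one treatment (the study
itself attributes it to unassessed factors) — the simulator is a test
harness with the *structure* of the real dataset, so estimator tests passing
on it demonstrate correctness of the estimators under the stated
assumptions, not fidelity of any particular trajectory.

Bottle factories: `generate_bottle_experiment` holds the clearance implied
by I_max at the starting prey density constant, making every estimator
assumption exact (machine-precision round-trips);
`generate_functional_response_bottles` integrates true type-II depletion
dynamics and sets each bottle's grazer density so the grazing signal g·T is
≈0.5 — large enough that 5% counting noise does not swamp the signal, small
enough that depletion stays moderate. These are a-priori design choices of
the simulated assay, mirroring how incubation experiments are planned.

### Problem sizes

Test and acceptance runs use the study-scale problem throughout: 33-day
(or, for steady-state checks, 300-day) simulations at dt = 0.01, four
replicates, and 200-replicate Monte Carlo for the I_max recovery study
(8 densities per replicate). A full suite run completes in well under a
minute on one core.

## Clone markers (`clonemarkers`)

The clone assay's computable parts: IUPAC-aware primer-site search (exact
matching by default — the primers were designed on these templates),
in-silico PCR (forward site upstream of a reverse-complemented reverse
site within 5 kb; amplicon spans both primer footprints, matching how
Sanger-verified product sizes are reported), GC-clamp attachment (the
40-nt clamp on the 21-nt forward primer gives a 61-nt DGGE primer), and
pairwise divergence as p-distance over gap-free columns of a global
alignment (match +1, mismatch −1, gap −2; no alignment method is canonical
for ITS p-distances, so the scores are exposed as parameters). Coordinates
are 0-based half-open internally and 1-based inclusive in reports.

The clone reference sequences live in a public archive and are not bundled;
tests exercise the machinery on constructed templates (labelled synthetic)
engineered to carry the real primer sites, including a trio with ITS-like
spacers yielding 510/527/515 bp products. DGGE melting behaviour is not
simulated.

## Known limitations

- The bottle estimators assume exponential dynamics within an incubation;
  strong depletion biases ingestion toward the time-average, which the
  functional-response fit absorbs only approximately.
- The equilibrium budget has no time resolution; transient bacterial
  dynamics live only in the simulator.
- Fixed N:C quotas ignore stoichiometric plasticity; the food-quality
  switch is a step function of dissolved N, the crudest possible model of
  quality decline.
- Multi-prey intake is share-weighted below saturation, so summed mixture
  intake never exceeds the single-prey saturation level; mixture I_max
  values are therefore not additive.
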