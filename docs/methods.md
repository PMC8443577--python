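# Methods

## Model overview

`dropcoop` models serial propagation of a three-member microbial consortium
(cooperator A, cooperator B, cheater) in a compartmentalized environment.
One round consists of: (1) dilute the pooled population into an emulsion so
that founder cells per droplet are Poisson(λ); (2) assign founder types
i.i.d. from the pooled fractions; (3) grow every droplet to endpoint;
(4) pool all droplets; (5) renormalize to new fractions. The deterministic
model (`propagation`) treats the emulsion as infinitely many droplets, so
only expected per-cell growth factors matter; the stochastic simulator
(`emulsion`) realizes a finite number of droplets and exhibits drift.

Assumptions worth stating explicitly:

* **Endpoint growth only.** No growth curves, lag phases or metabolite
  dynamics; a droplet's outcome is a deterministic function of its founder
  composition.
* **Monodisperse droplets.** A single droplet volume (382 pL for a 90 µm
  diameter) and hence a single λ; polydispersity is not modelled.
* **Exact re-dilution.** The between-round dilution back to the target λ is
  treated as exact; only fractions carry over.
* **No death.** Founder cells persist through an incubation, so per-cell
  growth factors are ≥ 1 (the "persistence floor").

## Founder statistics

Droplet occupancy is Poisson(λ), truncated where the upper-tail mass falls
below `tail_tol` (default 1e−12); all expectations are renormalized over the
retained support, so truncation error is far below any quantity of interest
at λ ≤ 10. Cell-type compositions given a total are multinomial. The growth
update needs the *cell-centric* view: by Poisson size-biasing, a randomly
chosen founder cell sees Poisson(λ) companions whose types are again i.i.d.
multinomial. The package computes expected growth factors both this way and
via the compartment-centric ratio E[n_i·g_i]/E[n_i]; the two routes are
mathematically identical term by term and agree to ~1e−13 in practice,
which the tests assert as a cross-check.

## Growth rule

Parameters: carrying capacity K (cells per droplet; default 750 = 382 pL ×
2·10⁹ cells/mL, rounded down as in the original parameterization), per-type
background capacities B_i (cells), cheater pool weight 1 + s_c (default
s_c = 0.40).

For a droplet with founder vector n:

1. every founded type can reach its background capacity B_i — a
   *per-droplet ceiling* for the type, independent of how many founders of
   that type are present (a lone cooperator "reaches 10% of K", not "10% per
   cell");
2. if at least one cooperator A and one cooperator B are founded, the
   cooperative pool `max(0, K − Σ_founded B_i)` is shared among all founded
   cells in proportion to n_i·w_i, with w = 1 for cooperators and 1 + s_c
   for the cheater — so within any pair-containing droplet the cheater's
   per-cell growth exceeds a cooperator's by exactly 1 + s_c when
   backgrounds are zero;
3. persistence floor: final_i = max(n_i, allocation_i);
4. capacity cap: if the summed targets exceed K (only possible when several
   background ceilings sum past K, i.e. at very low cooperation benefit),
   above-founder growth is scaled down proportionally so the droplet total
   is exactly K while growth factors stay ≥ 1.

This is the simplest rule consistent with the endpoint constraints the
scenarios specify: monoculture droplets reach their background level, pair
droplets reach K, cheaters have a per-cell advantage of 1 + s_c in shared
droplets. Background growth also occurs inside pair droplets (it is capacity
a type reaches *independently*, not an alternative mode), which keeps
outcomes continuous across the cost/benefit plane. s_c applies only to
sharing of the cooperative pool, not to background capacities, which are
parameterized separately. Final counts are real-valued (expected-value
model); the stochastic simulator pools them unrounded to avoid biasing
small-droplet results.

Scenario presets: `dependent` (B = 0 for everyone), `costless_background`
(all types reach 20% of K alone), `costly_background` (cooperators 10%,
cheater 20%). The cost/benefit mapping used by the phase diagram sets
B_cheater = (1 − benefit)·K and B_coop = (1 − cost/100)·B_cheater, so
benefit is the fraction of K only reachable with a pair (from the cheater's
standpoint) and cost is the percentage difference in independent growth.
The cheater advantage s_c = 0.40 is applied everywhere by default and is
overridable (including to 0).

## Propagation and the cooperator advantage

Fractions update multiplicatively: f_i′ ∝ f_i·G_i. Types at fraction 0 stay
at 0 but still receive a hypothetical (invasion) growth factor for
diagnostics. Fractions below 1e−15 are never clamped. The **cooperator
advantage** is the arithmetic mean of the two cooperators' expected growth
factors minus the cheater's; with symmetric cooperators it equals either
cooperator's advantage. As a function of λ it reproduces the three-regime
structure: strongly negative at λ ≪ 1 (partners rarely co-localize), maximal
at intermediate λ (≈ 1–2), and shrinking in magnitude again at large λ
(every droplet resembles the well-mixed suspension). Note the decay at large
λ is toward the suspension value, which at λ = 10 is still distinctly
negative for costly backgrounds; the advantage magnitude at λ = 10 is,
however, well below its λ → 0 magnitude, and that is what the tests assert.

`optimal_lambda` scores each candidate λ by the **one-round gain in total
cooperator fraction**. Under this criterion the optimum rises with the
initial cheater load; across cheater starts of 0.3–0.8 (cooperators split
equally) it spans λ ≈ 0.15–0.53, consistent with 0.15 being the smallest
optimum anyone would pick — the value used for the low-λ experiments. The
enrichment criterion is a genuine design choice; maximizing the one-round
relative gain gives identical optima (the denominator is fixed), while
maximizing the cooperator advantage itself would favour much larger λ
because the advantage weighs absolute growth, not fraction change.

## Stochastic emulsion simulator

Founder totals per droplet are Poisson(λ) draws; types are multinomial given
the total (consistent with Poisson thinning, so agreement with the
expectation model is an exact statistical statement). Droplets with
identical compositions are grown once and weighted, making 2·10⁵ droplets
per round cheap. Default n_droplets = 1e5 — a real 300 µL emulsion at 382 pL
per droplet contains ~8·10⁵ droplets; the default is lower for speed and
configurable. `serial_simulate` re-inoculates each round at the realized
fractions and flags extinction explicitly. `suspension_limit` models the
well-mixed control as a single compartment seeded at 1.5e−3 of capacity
(3·10⁶ cells/mL into a 2·10⁹ cells/mL medium): with both cooperators present
the compartment fills to capacity and the cheater gains factor 1 + s_c per
round, so repeated suspension transfer always fixes the cheater.

## MPN readout

The most-probable-number estimator assumes each well at effective sample
volume v is positive with probability 1 − exp(−c·v). The MLE maximizes the
binomial likelihood over ln c (coarse log-grid bracket, then bounded scalar
refinement, relative tolerance ~1e−10; the likelihood is unimodal in ln c).
The 95% CI is the standard log-normal (Wald) interval exp(ln ĉ ±
1.96/√I(ln ĉ)) with I the expected Fisher information; simulated coverage
for an 8-replicate tenfold design spanning the transition is ~93–95%.
All-negative and all-positive score patterns carry no point estimate and are
returned with one-sided 95% bounds and an explicit status.

The synthetic-observation layer measures a trajectory through three
selective media (cheater only; cooperator B only; cheater + cooperator A)
and recovers per-type concentrations by least squares — identical to the
experimental subtraction logic. Noise can make subtracted fractions
negative; they are flagged, never clamped. If the media resolve all types up
to one linear combination, the involved types are marked *confounded* (the
situation in background-growth media where cooperator A and the cheater grow
identically and only cooperator B is a usable readout); a larger deficiency
is an error.

What the simulated assay does *not* capture: plate-level contamination,
growth inhibition inside MPN wells, cross-feeding between carried-over
types in a well, or counting error in the reference total concentration.
Passing round-trip tests therefore show estimator correctness under the
Poisson-dilution model, not robustness to those artifacts.

## Problem sizes and numerical choices

* Truncation n_max from `tail_tol` = 1e−12 (n_max = 8 at λ = 0.15, 18 at
  λ = 2, 44 at λ = 10); enumeration is exact below it and vectorized.
* Composition enumeration order is fixed (lexicographically decreasing per
  total) so floating-point sums are reproducible.
* The λ-sweep defaults to 4000 parameter sets (the published scale); tests
  and the acceptance script use 100 sets, at which the regime ordering is
  already stable. The s_c sampling sd is relative (8% of 0.40 = 0.032) and
  draws are truncated at 0 to keep the cheater label semantically
  consistent; initial fractions are uniform on the simplex.
* The phase diagram defaults to a 21×21 grid, 40 rounds, λ = 2, start
  (0.50, 0.01, 0.49); reduced 11×11 grids preserve all four regimes. Near
  the zero-benefit/zero-cost corner convergence to the coexistence point is
  slow (the 1% cooperator-B start must equilibrate), so convergence checks
  use a nearby low-benefit/low-cost cell that has flattened by round 40.
* Monte-Carlo cross-checks use 2·10⁵ droplets × 20 seeds (3-standard-error
  agreement per type), and MPN coverage uses 1000 simulated assays.

## Known limitations

* The expectation model ignores drift entirely; use `serial_simulate` for
  finite-emulsion questions.
* Background ceilings shared within a type make the no-pair growth factor
  frequency-dependent (rare types get more per-cell background); this is a
  consequence of the ceiling reading of "reaches x% of capacity" and matters
  mainly in the low-benefit corner of the phase diagram.
* Only one cheater type and one cooperator pair; roles are generic in the
  data structures but the advantage summary assumes exactly one cheater.
* No polydispersity, no droplet coalescence, no within-droplet spatial
  structure.
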