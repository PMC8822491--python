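# Methods

This note documents the kinetic model, the estimators, the synthetic-data
generator and the numerical conventions used throughout `autoxkin`, and
records the reasoning behind the design choices that were genuinely open.

## 1. Reaction network

All concentrations are molar and bulk-referenced (moles per total chamber
volume); time is in seconds. The network integrated by
`autoxkin.kinetics` is

| step | rate | notes |
|---|---|---|
| initiation → LOO· | R_i | constant flux; azo decomposition and cage escape are lumped into the empirical R_i, as in the experimental analysis |
| LOO· + LH → LOOH + L· | k_p [LOO·][LH] | propagation, H abstraction |
| L· + O₂ → LOO· | k_O2 [L·][O₂] | the measured O₂ uptake; O₂ clamped (non-limiting) by default |
| LOO· + LOO· → products | 2k_t [LOO·]² | radical-removal rate convention |
| LOO· + X_g → LOOH + X_g· | k_inh,g [LOO·][X_g] | inhibition by phenol pool X_g |
| LOO· + X_g· → products | k_cross [LOO·][X_g·] | cross-termination (reaction 7) |
| 2 X_g· → inert | 2k_ArO· [X_g·]² | phenoxyl self-decay |
| 2 X_g· → 2 X_{g+1} | k_dim [X_g·]² (event rate) | phenoxyl coupling; one dimer with two recovered phenols |
| TO· + X'_g → TOH + X'_g· | k_r [TO·][X'_g] | regeneration of the tocopherol-like species by any closed-shell phenol unit of a co-antioxidant |
| X_g → inert | k_dec [X_g] | optional first-order decomposition (alkaline instability) |

**Phenol-equivalent pools.** A dimer-forming polyphenol is represented as
a cascade of *phenol-equivalent* pools X_0 (parent), X_1, … X_depth
(recovered dimer hydroxyls). One coupling event consumes two
generation-g phenoxyls and recovers two trapping-competent phenols at
generation g+1, so the phenol-unit count is conserved through coupling
while each unit can transfer one H atom per generation. Phenoxyls of the
deepest modeled generation terminate by cross-termination/self-decay like
any monophenol; with `cascade_depth = 0` the (unmodeled) dimer is an
inert sink. In the coupling-dominated limit the ideal stoichiometric
factor is `n = depth + 2`; cross-termination leakage at each generation
reduces the realized value. Regio- and stereochemistry of the coupling
are outside scope.

**Radical and O₂ ledgers.** The integrator carries cumulative counters so
that two exact identities can be tested at every output time: (i)
radicals supplied, `R_i·t`, equal radicals present (L·, LOO·, all ArO·)
plus radicals terminated through every channel; (ii) O₂ taken up (plus
initiator-derived peroxyls when those are not counted in the uptake)
resides in LOOH, in live chain carriers, or in terminated LOO-derived
products. Both hold to ~1e-18 M in the test suite.

## 2. Pseudo-phase scaling

The media are dispersions: the lipid plus surfactant occupy a volume
fraction f ≈ 0.005 (8 mM Triton X-100 micelles) or f ≈ 0.013 (20.2 mM
DMPC liposomes) of the chamber. Species confined to the lipid
pseudo-phase react at local concentrations c/f, so every bimolecular step
between two lipid-phase species proceeds, in bulk-referenced units, at
k_mol/f.

Which constants are "molecular" and which "apparent" follows from how
they are measured. k_p and k_inh are derived from rate observables in
which the two f factors cancel (e.g. R_inh = k_p[LH]·R_i/(2k_inh[ArOH])
is f-free), so the conventionally reported values are the molecular ones
and enter the simulator as k/f. The peroxyl self-termination entering
the uninhibited rate law R_ox = k_p[LH]√(R_i/2k_t) is the *apparent*
constant 2k_t,app = f·2k_t,mol; the parameter `two_kt` is that apparent
value (default 150 M⁻¹s⁻¹, a calibration reproducing R_ox ≈ 550 nM/s at
R_i = 4.6 nM/s — it is not a literature value), and the simulator uses
two_kt/f². The radical–radical steps among antioxidant-derived species
(k_dim, 2k_ArO·, k_r, k_cross) are treated as molecular (scaled 1/f).
k_O2 is left unscaled; O₂ addition is never rate-limiting.

Two consequences motivated this design. First, the closed-form oracles
above hold with the *reported* constants independent of f, so the
simulator can be verified against them exactly (the uninhibited slope
matches within 0.5%, the strong-inhibitor induction time
τ = 2[ArOH]₀/R_i within ~3%). Second, radical pools take physically
sensible values (LOO· in the tens of nM) and equilibrate within seconds;
applying the apparent 2k_t naively in mass action instead forces a ~5 µM
peroxyl pool with a ~30 min relaxation time, which smears every
breakpoint and is incompatible with the sharp experimental knees. The
medium effect on dimerization also emerges naturally: at f = 1
(homogeneous solvent) coupling cannot compete with cross-termination at
µM concentrations and the polyphenol behaves as an ordinary two-radical
trap, as observed in organic solvents.

## 3. Default parameters

| parameter | default | units | basis |
|---|---|---|---|
| k_p | 36 (micelle) / 41 (liposome) | M⁻¹s⁻¹ | methyl linoleate propagation in these media |
| k_O2 | 1e9 | M⁻¹s⁻¹ | diffusion-limited O₂ addition |
| two_kt (apparent) | 150 | M⁻¹s⁻¹ | calibration to R_ox ≈ 550 nM/s at R_i = 4.6 nM/s |
| k_rad_cross | 1e8 | M⁻¹s⁻¹ | ordinary phenoxyl + peroxyl; results insensitive provided it is large (sensitivity-tested) |
| persistent k_cross | 1e4 | M⁻¹s⁻¹ | default for dimer-forming (persistent) phenoxyls |
| two_k_AO | 15 | M⁻¹s⁻¹ | tocopheroxyl self-decay measured in cationic micelles (5.9e3 in benzene) |
| k_r | 0 (off); 20 in mixtures | M⁻¹s⁻¹ | micellar tocopherol-regeneration value |
| k_dim | 3e4 | M⁻¹s⁻¹ | calibration: coupling outruns cross-termination for persistent phenoxyls in dispersed media |
| LH₀ | 2.74e-3 | M | protocol |
| O2₀ | 1e-3 | M | O₂-saturated buffer near 37 °C; clamped by default (runs use ≤10–20% depletion) |
| R_i | 4.6e-9 | M/s | mid-range of the measured micellar fluxes |
| interface_factor | 0.005 / 0.013 | – | lipid volume fraction of each medium |
| include_initiator_O2 | off | – | initiator-derived O₂ excluded from the uptake ledger (switchable) |

Integration uses `scipy.solve_ivp` (LSODA), rtol 1e-8, atol 1e-15; a
non-finite state or a negative concentration beyond tolerance raises an
error naming the species.

## 4. Estimators

**Induction time.** A two-segment continuous piecewise-linear model is
fitted by exhaustive breakpoint search on the sampling grid (O(n) via
suffix-sum normal equations); only slope-increasing candidates compete,
since an induction period ends with an acceleration (on long records the
slow lipid depletion otherwise wins with a decelerating knee). The
breakpoint is accepted when the two-segment model beats a single line by
an F-test (α = 1e-4) — otherwise the trace is classified as retardation
or no inhibition. The accepted breakpoint is then polished by the
classical graphical rule, intersecting the induction-phase regression
line (0.15τ–0.85τ) with the post-induction line (1.1τ–2τ), iterated;
both windows are local, which makes τ independent of how far the record
runs past the break (the raw breakpoint drifts several percent with
record length). `tau_sd` comes from ≥200 residual-resampling bootstrap
replicates refitted over a candidate window around the original
breakpoint, seeded and reproducible. On soft knees (weak inhibitors,
dimer cascades) the graphical τ sits a few percent below the true
exhaustion time; this is a property of the graphical convention itself
and is shared by the truth values the generator records (Section 5).

**Phase rates.** R_inh is the least-squares slope over [0.15τ, 0.85τ]
after injection (the whole post-injection record for retarded traces,
where it is a rate of retardation); R_ox2 the slope over [1.1τ, end].
The windows skip the injection transient and the breakpoint curvature
and are configurable.

**R_i, n, ν_inh, synergy.** R_i = n_ref[ArOH]₀/τ_ref from the
tocopherol-reference run at the same medium/pH (n_ref = 2 by the field's
convention); n = R_i·τ/[ArOH]₀; ν_inh = R_inh/R_i; for an equimolar
mixture the co-antioxidant stoichiometry is
n_co = R_i(τ_mix − τ_ref)/[co], and the hyper-additivity ratio is
τ_mix/(τ_ref + τ_co).

**k_inh.** The uptake in [0.15τ, 0.85τ] is regressed through the origin
against −ln(1 − t/τ); k_inh = k_p[LH]/slope. Because a graphical τ that
undershoots the exhaustion time propagates into k_inh, the τ entering
the rate law is re-fitted by minimizing the residual of this regression
itself — the integrated law is exact for a single-phenol induction, so
the refit residual collapses there and is adopted; a modest improvement
indicates model mismatch (dimer cascade) and the graphical τ is kept.
k_inh is only computed for runs classified as inhibition; for n > 2
antioxidants the Eq.-9 value is a minimal, apparent constant and the
n/2-scaled `k_inh_corrected` is also reported.

**Classification.** "inhibition" requires a detected breakpoint and a
slow-down R_ox/R_inh ≥ 3; a slow-down ≥ 1.3 without a qualifying
breakpoint is "retardation"; otherwise "none". These thresholds are
operational conventions (configurable), chosen to reproduce the
qualitative usage in the published tables.

## 5. Synthetic data and the benchmark suite

`generate_trace` emulates the experimental protocol: the uninhibited
system runs until 10% of the dissolved O₂ is consumed, the antioxidant
roster is injected at that instant, and the record continues past the
induction period, sampled every 5 s with additive Gaussian sensor noise
(σ = 0.2 µM, zeroed first reading, optional linear drift). The real
instrument's sampling rate and noise are unpublished; these defaults are
plausible stand-ins resembling the published recordings. Everything is
bit-reproducible for a fixed seed.

The 50-trace benchmark design is 2 media × 5 pH labels × 5 settings:
uninhibited, tocopherol-analogue reference (k_inh 1.4e4), dimer-forming
stilbene (published per-pH k_inh values as inputs; cascade depth 4 with
dimer phenols trapping 5× faster than the parent — a calibration placing
the realized n at 4.2–4.8, the published polyphenol range), a weak
monophenol retarder (k_inh 500), and the reference/stilbene equimolar
mixture (k_r = 20). pH is mechanistically a label; its observed effects
are encoded empirically: the stilbene's alkaline decomposition (k_dec
1e-4 s⁻¹ at pH 8, 6e-3 s⁻¹ at pH 10, from its published half-life trend)
and tocopheroxyl persistence (k_cross lowered to ~1e3–3e3) in the pH 6–7
window — exactly where the published mixtures turn hyper-additive.

The truth table records the generating parameters (R_i, concentrations,
k_inh) plus the noise-free ground truth: τ of the noiseless twin of each
trace and the stoichiometric factor it implies *under the pipeline's own
calibration convention* (R_i from the noiseless reference run, n_ref =
2). Recovery tests therefore measure the effect of sensor noise on the
full pipeline with estimator conventions held fixed; the k_inh
comparison is against the generating parameter and so includes genuine
model mismatch. Passing them shows noise robustness and internal
consistency of the pipeline — not that the mechanistic model is the true
chemistry of any real membrane, which involves compartmentalized radical
statistics, partitioning and product chemistry the model does not
attempt.

## 6. Synergy: what regeneration can and cannot do

In any closed mass-action realization of this scheme, the total
LOO·-removal capacity of an antioxidant roster is invariant under
regeneration: every phenolic H removes exactly one LOO· (directly, or
after transfer to the tocopherol and one further HAT), and every radical
terminates pairwise. Hyper-additive induction periods therefore cannot
arise from capacity bookkeeping — a point worth stating because the
sufficiency argument "k_r ≳ 2k_TO·" is often read that way.

What regeneration does change is *suppression quality*. A persistent
tocopheroxyl radical parks part of the reference antioxidant's capacity
in an unreactive pool: alone (and in a k_r = 0 mixture — hence
additivity) the breakpoint arrives with that pool stranded. With k_r on,
the co-antioxidant's H budget continuously drains the pool back to the
active phenol, the whole mixture period runs at the strong inhibitor's
suppression, and the fitted breakpoint moves past the sum of the
individual fitted values. At the documented micellar study conditions
(R_i = 4.63 nM/s, 1 µM each, persistent tocopheroxyl k_cross = 3e2,
co-antioxidant k_inh = 2e3 with a depth-5 cascade, k_r = 20 vs
2k_ArO· = 15) the mixture is additive within 2% at k_r = 0 and exceeds
the sum by ~10% at k_r = 20; the liposomal analogue gives ~1%/7%. The
direction "k_r ≥ 2k_ArO· ⇒ hyper-additive" holds at these conditions,
not universally.

## 7. Degenerate inputs and tie-breaks

R_i = 0 yields an identically zero trace (and division errors where R_i
is a denominator, raised explicitly). two_kt = 0 makes the uninhibited
oracle undefined and is rejected for uninhibited simulations. Traces
need ≥ 20 post-injection points for τ and ≥ 5 points per rate window.
An exactly linear trace has no breakpoint by construction (the F-test
numerator vanishes). Mixture rows report no k_inh (the rate law does not
apply). Negative co-antioxidant stoichiometries are returned but
flagged with a warning. File I/O validates strict time monotonicity
(naming the first offending row) and converts legacy minute-based files
on read.

## 8. Known limitations

- The mechanism is homogeneous mass action with pseudo-phase scaling; it
  does not model per-micelle radical statistics, partitioning equilibria
  of the antioxidants, pH-dependent ionization, or dimer product
  identities.
- The graphical τ convention undershoots soft knees by a few percent;
  all internal calibrations share the convention, but absolute τ values
  for weak inhibitors carry that bias.
- two_kt, k_dim, the persistent k_cross values and the dimer trapping
  boost are calibrations, not measurements; conclusions that depend on
  their absolute values (rather than the qualitative regimes they set)
  should not be drawn from the simulator.
- The pH dependence of the fixtures is descriptive (it encodes the
  published pattern), not a mechanistic model of ionization.
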