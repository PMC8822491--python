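# autoxkin

Kinetics of antioxidant-inhibited lipid peroxidation in membrane-mimetic
dispersions — a mechanistic simulator of Clark-electrode oxygen-uptake
traces and the inference pipeline that turns such traces into the standard
kinetic descriptors of chain-breaking antioxidant activity.

The package is written for chemists and kineticists studying
radical-trapping antioxidants (tocopherols, stilbene polyphenols such as
resveratrol, simple phenols) in Triton X-100 micelles or DMPC liposomes,
where the oxidizable lipid (methyl linoleate, LH) is peroxidized by a
constant radical flux from a thermal azo initiator.

## The model

Autoxidation is the classical chain:

    initiator ->                LOO·        R_i        (constant flux)
    LOO· + LH  -> LOOH + L·                 k_p
    L·   + O2  -> LOO·                      k_O2       (~1e9 M⁻¹s⁻¹)
    LOO· + LOO· -> non-radical products     2k_t
    LOO· + ArOH -> LOOH + ArO·              k_inh      (inhibition)
    LOO· + ArO· -> non-radical products     k_cross
    ArO· + ArO· -> dimer / inert            k_dim, 2k_ArO·
    TO·  + Ar'OH -> TOH + Ar'O·             k_r        (regeneration)

A chain-breaking phenol suppresses the uptake until it is consumed; the
induction time τ obeys `τ = n·[ArOH]₀ / R_i` with stoichiometric factor
*n* (2 for tocopherols), and during the induction period the uptake
follows the integrated rate law
`Δ[O₂](t) = −(k_p[LH]/k_inh)·ln(1 − t/τ)`, which is inverted to estimate
`k_inh`. Polyphenols whose persistent phenoxyl radicals couple to dimers
with recovered, trapping-competent hydroxyl groups realize *n* > 2; a
co-antioxidant that re-reduces the tocopheroxyl radical (k_r) makes
mixture induction periods hyper-additive. All of this is implemented as a
stiff ODE network in bulk-referenced concentrations with pseudo-phase
(lipid-volume-fraction) scaling of the radical–radical steps — see
`docs/methods.md`.

From a trace the pipeline infers: τ (two-segment breakpoint + graphical
tangent intersection, bootstrap SD), the inhibited and uninhibited rates
R_inh and R_ox, R_i (calibrated from a reference antioxidant of known
*n*), *n*, k_inh (and its n/2-corrected variant), the kinetic chain
length ν_inh = R_inh/R_i, co-antioxidant stoichiometry for mixtures, and
an inhibition/retardation/none classification.

## Worked example

Generate a liposomal pH-4 benchmark condition (uninhibited blank,
tocopherol-analogue reference, resveratrol-like stilbene) and analyze the
stilbene run:

```python
from autoxkin import (InhibitionModel, NoiseModel, compute_Ri,
                      estimate_tau, generate_trace)
from autoxkin.synthetic import condition_setup

sys_b, params, _   = condition_setup("liposome", 4.0, "none")
sys_p, _, t_pmhc   = condition_setup("liposome", 4.0, "PMHC")
sys_r, _, t_rsv    = condition_setup("liposome", 4.0, "RSV")
blank = generate_trace(sys_b, params, NoiseModel(seed=1), t_end=2500.0)
ref   = generate_trace(sys_p, params, NoiseModel(seed=2), t_end=t_pmhc)
rsv   = generate_trace(sys_r, params, NoiseModel(seed=3), t_end=t_rsv)

tau_ref, _ = estimate_tau(ref, n_boot=0)
R_i = compute_Ri(tau_ref, 2.0, 1e-6)          # reference: n = 2, 1 uM
res = InhibitionModel(rsv, uninhibited=blank, R_i=R_i).fit(n_boot=200,
                                                           seed=0)
print(res.summary())
```

prints

```
Inhibited autoxidation analysis
==============================================
antioxidants:        RSV 1 uM
medium/pH:           liposome / 4.0
classification:      inhibition
tau (min):           26.26 +/- 0.14
n:                   5.12
R_inh (nM/s):        31.1
R_ox (nM/s):         405.6
R_ox/R_inh:          13.0
k_inh (M^-1 s^-1):   3.65e+03
nu_inh:              9.6
```

Read: the stilbene held the peroxidation 13× below the uninhibited rate
for 26 min; with R_i = 3.2 nM/s calibrated from the reference run, each
stilbene molecule trapped ~5 peroxyl radicals (a dimer-cascade
polyphenol, not a 2-radical monophenol), with an apparent inhibition rate
constant of 3.7 × 10³ M⁻¹s⁻¹ and ~10 propagation turnovers per radical
during inhibition.

The same machinery is scriptable from the shell:

```
autoxkin generate --seed 1 --out-dir suite/      # 50 traces + truth.csv
autoxkin analyze  --traces suite/ --out metrics.csv
autoxkin synergy  --traces suite/ --out synergy.csv
autoxkin report   --metrics metrics.csv --synergy synergy.csv
```

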