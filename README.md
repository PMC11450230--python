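# haksym

Steady-state kinetics, thermodynamics and TEVC dose-response analysis of
K⁺/H⁺ symport through HAK5-type high-affinity potassium transporters.

Plant roots facing micromolar soil K⁺ cannot use channels: at −180 mV a
channel equilibrates at best 1000-fold accumulation. HAK5-type transporters
couple each K⁺ to a proton and harvest the proton motive force instead.
This package implements the quantitative machinery used to analyse such
transporters in two-electrode voltage-clamp (TEVC) experiments on *Xenopus*
oocytes: a four-state carrier cycle solved in closed form, its reduced
Michaelis–Menten descriptions, the thermodynamic uptake limits, the
dose-response fitting layer, and a seeded synthetic-data generator so the
whole pipeline is testable without recordings.

## The model

The carrier cycle is C1 → C2 → C3 → C4 → C1: the empty outward-open carrier
(C1, net charge −2) binds external H⁺ (C2, −1) then K⁺ (C3, neutral),
converts electroneutrally to the inward-open form and releases both ions
(C4, −2), and returns through the single voltage-dependent step across a
symmetric Eyring barrier:

```
k14 = k14⁰ e^{FV/RT},   k41 = k41⁰ e^{−FV/RT},
k12 = k12⁰[H⁺]o,  k23 = k23⁰[K⁺]o,  k43 = k43⁰[H⁺]i[K⁺]i,
```

with microscopic reversibility `k41⁰k12⁰k23⁰k34 = k14⁰k21k32k43⁰` leaving
seven free rate constants. The King–Altman method gives the steady state as
sixteen directed spanning-tree products; the transport current is

```
I = 2eN (k14 C1 − k41 C4)
  = 2eN k41⁰k12⁰k23⁰k34 ([H⁺]i[K⁺]i e^{FV/RT} − [H⁺]o[K⁺]o e^{−FV/RT}) / Σᵢⱼ Cᵢⱼ ,
```

two elementary charges per cycle, negative for net uptake. Because the
denominator is affine in either external ion, the current is *exactly*
Michaelis–Menten in [K⁺]o or [H⁺]o with closed-form `I_Kmax`, `K_K`, `K_H`
— the quantities an experimenter extracts from dose-response fits. Peak
currents are fitted with `ΔI = I_max[X]/([X]+K_m)` (Hill variant for H⁺),
and post-inactivation steady-state currents with the bell-shaped

```
I_ss = ([K]/([K]+K_m)) · I_max/([K]/K_m + 1) + I_s ,
```

whose maximum falls exactly at `[K] = K_m`.

The shipped default rate constants are **calibrated, not a published
table**: deterministic log-space least squares against published oocyte
anchors (K_m[K⁺] = 23.56 µM at −120 mV/pH 4.5; K_m[H⁺] = 4.81 µM at
−120 mV/200 µM K⁺; its ~20 µM rise at −90 mV; |I_max| = 417 nA at −140 mV
fixing the transporter count N). See `docs/methods.md`.

## Worked example

```python
import haksym as hx

params = hx.default_params()
cond = hx.Conditions(V_mV=-120, K_out_M=20e-6, H_out_M=10**-4.5)
sol = hx.steady_state_current(params, cond)
print(sol.I * 1e9, hx.reversal_potential(cond))
```

prints `-169.01 nA` and `-32.5 mV`: with only 20 µM K⁺ outside (5000-fold
below the cytosolic 100 mM) the coupled cycle still carries a robust inward
current, because −120 mV lies far below the −32.5 mV reversal potential of
the H⁺-coupled reaction. The voltage scan

```python
hx.voltage_scan(params, [-150, -120, -90, -60], H_out_M=10**-4.5, K_out_M=200e-6)
```

shows `K_H` collapsing from 150.6 µM to 2.5 µM between −60 and −150 mV
while `K_K` moves less than two-fold (23.6 µM at −120 mV): the proton site
senses the membrane field, the K⁺ site does not. Dividing the K⁺ binding
constant `k23⁰` by 1000 (`hx.apply_mutant_scaling`) raises `K_K` a
thousand-fold into the millimolar range and *lowers* `K_H` — a weaker K⁺
site makes the transporter a better proton acceptor.

The `examples/` directory holds runnable scripts for each capability
(cycle solution, voltage scan, uptake limits, dose-response fitting,
inactivation ladder); a thin CLI mirrors them, e.g.

```sh
haksym limits                # channel 150 uM vs symport 1.5 nM, advantage 1e5
haksym generate-dr --out dr.csv --seed 11 && haksym fit mm --in dr.csv
haksym simulate-trace --out tr.csv --seed 2 --conc-M 0.002
```

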