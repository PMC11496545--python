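# protoflux

Simulation and analysis of proteoliposome proton-conduction assays for
dissected antiporter-like modules of respiratory Complex I.

The antiporter-like subunits of Complex I (Nqo12/Nqo13 in *T. thermophilus*;
ND4/ND5 in mitochondria) each carry a lateral proton pathway whose transfer
barrier is gated by a buried Glu–Lys ion-pair.  Reconstituted in liposomes,
these modules conduct protons when an electrochemical gradient is imposed —
by weak-acid (acetate) loading read out with the ratiometric pH dye pyranine,
or by an ATP-synthase-generated proton-motive force read out with ACMA
quenching.  `protoflux` packages the quantitative machinery for this kind of
experiment:

* **`protoflux.chem`** — acid–base speciation, buffer capacity, Nernst and
  proton-motive-force relations, and the probe models: pyranine
  (`pH = a·log10(I404/I454) + b`, a = 1.1684, b = 7.721) and a Hill-type
  ACMA quench response.
* **`protoflux.barrier`** — the ion-pair electric-field barrier-tuning model:
  `ΔG‡(d) = ΔG‡_closed − qΔx·[E∥(d) − E∥(d_closed)]`, with the exact
  two-charge Coulomb field, point-dipole far-field transfer between modules
  (`∝ (R1/R2)³`), anchor fitting (`BarrierTuningModel.fit()` →
  results object with `summary()`), and Eyring rates
  `k = (k_BT/h)·e^{−ΔG‡/RT}`.
* **`protoflux.vesicle`** — an event-driven ODE model of a representative
  vesicle: neutral-form weak-acid/base permeation, symmetric-barrier channel
  flux `J = N·k·2·sinh(Δμ̃_{H⁺}/2RT)`, valinomycin/nigericin ionophores,
  ATP-synthase pumping with a stall law, membrane capacitance, and the
  shipped construct presets (WT, ion-pair-open and proton-wire-blocked
  variants, controls).
* **`protoflux.traces`** — trace conversion and the reported estimators:
  initial linear-decay rates (`a0 + k1·t`, k1 in min⁻¹), pre-nigericin
  steady-state levels, and the vesicle orientation fraction from labelling
  ratios.
* **`protoflux.fes`** — desk-scale umbrella sampling with WHAM and MBAR on
  analytic 1-D proton-wire potentials, validated against closed forms.
* **`protoflux.synth`** — deterministic synthetic-trace generation (600 ms
  pyranine / 100 ms ACMA sampling, n = 6 replicates, 1% Gaussian noise)
  so the full pipeline runs with no external data.

A thin CLI (`protoflux simulate | make-fixtures | analyze | fit-barrier |
pmf`) binds the stages together; every run writes a provenance JSON.

## Worked example

Run the acid-driven assay for the wild-type Nqo13 module and extract the
pre-nigericin steady state:

```python
from protoflux import vesicle as vs
from protoflux.traces import steady_state_level

res = vs.acetate_assay("WT-Nqo13")   # 60 nm vesicle, 10 mM acetate at 60 s
print(res.summary())
ss = steady_state_level(res.pH_in, res.time, res.schedule)
print(f"steady-state pH: {ss.level:.3f} +/- {ss.sd:.4f}")
```

```
Proteoliposome assay (pyranine read-out)
  duration             600.0 s  (1001 samples)
  initial pH_in        7.200
  final pH_in          7.139
  min / max pH_in      6.901 /    7.200
  final dpsi           -3.77 mV
  event t=   60.0 s  add_acetate  10.0 mM
  event t=  540.0 s  add_nigericin  0.0 mM
steady-state pH: 7.113 +/- 0.0010
```

Acetate enters as the neutral acid, dissociates inside and transiently
acidifies the lumen to pH 6.90; the antiporter then exports the released
protons (K⁺ counter-flowing through valinomycin) until the trace plateaus at
pH 7.11 — between the zero-conductance control (≈ 6.93) and the Donnan
endpoint (≈ 7.14) that the fast open-ion-pair variant E123Q reaches.
Nigericin at 540 s collapses the remaining gradient.

Fitting the barrier-tuning model to the Nqo13 QM/MM anchors and transferring
it to the more distant Nqo12 ion-pair:

```python
from protoflux.barrier import BarrierTuningModel

fit = BarrierTuningModel([(3.0, 14.0), (8.0, 6.0)], pathway_distance_R=14.0).fit()
print(fit.summary())
print(f"Nqo12 open-state prediction: "
      f"{fit.transfer_anchored_prediction(R2=22.0, dg_closed_2=15.0):.2f} kcal/mol")
```

```
Barrier tuning model (Stark coupling to ion-pair Coulomb field)
  pathway distance R         14.00 A
  closed-state anchor        14.00 kcal/mol at d=3.00 A
  coupling q*dx             45.796 e*A
  effective dielectric       2.884
  open-state barrier drop     8.00 kcal/mol
  anchors (d, dG, fit, resid):
      3.00 A   14.00   14.00   +0.0000
      8.00 A    6.00    6.00   +0.0000
Nqo12 open-state prediction: 12.94 kcal/mol
```

The 8 kcal/mol barrier drop at 14 Å, diluted by the dipole far-field factor
(14/22)³, predicts a 2.1 kcal/mol drop at 22 Å — an open-state barrier of
12.94 kcal/mol for Nqo12, in line with its independently computed
≈ 13 kcal/mol.

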