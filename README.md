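# lutadose

Internal dosimetry for ¹⁷⁷Lu-DOTATATE peptide receptor radionuclide therapy
(PRRT), comparing the three imaging workflows used in clinical routine:

1. **multi-SPECT/CT** — organ activities from 3D VOIs on quantitative
   (attenuation-corrected) SPECT volumes at every imaging time point;
2. **planar** — conjugate-view (geometric-mean) whole-body scintigraphy with
   thickness-weighted background subtraction and syringe calibration, and *no*
   attenuation correction;
3. **hybrid** — planar curve *shapes* anchored in absolute terms by a single
   SPECT/CT measurement, with automatic removal and substitution of organ
   regions that overlap in projection.

The package is aimed at medical physicists and methods researchers who want
to study *why* these workflows disagree — organ overlap in projection,
uncorrected photon attenuation, the single-thickness background weighting
factor, partial-volume losses — on data where the truth is known. To that
end it ships a ground-truth digital phantom generator that emulates
mono-exponential organ washout, planar attenuation physics, Gaussian system
resolution, Poisson counting noise and a co-scanned calibration syringe.

## Model

Each organ follows a mono-exponential time–activity curve

    A(t) = A_admin · f · exp(−λ_eff t),      λ_eff = ln2/T_phys + ln2/T_bio,

and measured curves are fitted with the same (and only) model by nonlinear
least squares. The **residence time** is the cumulated activity normalised to
the administered activity,

    τ = A₀ / (λ_eff · A_admin)   [h],

and the absorbed dose uses a MIRD-style self-dose with individual organ mass
m (from CT-style volumetry × standardised density) under local electron
deposition:

    D = τ · A_admin · 3.6·10¹² · Δₑ · 1.602·10⁻¹³ / (m/1000)   [Gy],

with Δₑ = 0.1479 MeV per ¹⁷⁷Lu decay by default (full S-value tables can be
supplied as CSV). Tumours use the sphere model at liver density with a
Gaussian-PSF sphere recovery coefficient for partial-volume correction.
Planar background correction subtracts the adjacent band scaled by
wf = 1 − d_organ/d_body (anterior–posterior extents). Doses are reported in
Gy and, numerically identical for electrons (w_R = 1), Sv; dose per injected
activity (DpA) in Gy/GBq.

## Worked example

```python
from lutadose import simulate_preset_study, run_all

study = simulate_preset_study("paper_like", seed=0)   # attenuation, blur,
results = run_all(study)                              # liver over right kidney
for scenario, res in results.items():
    d = res.doses["kidney_right"]
    print(f"{scenario:12s} tau = {d.tau_h:5.2f} h   DpA = {d.dpa_gy_per_gbq:5.2f} Sv/GBq")
t = study.truth.organs["kidney_right"]
print(f"{'truth':12s} tau = {t.tau_h:5.2f} h")
```

prints

```
multi_spect  tau =  1.05 h   DpA =  1.96 Sv/GBq
planar       tau =  2.82 h   DpA =  5.28 Sv/GBq
hybrid       tau =  1.07 h   DpA =  2.01 Sv/GBq
truth        tau =  1.26 h
```

The right kidney sits behind the liver in the anterior–posterior projection:
the planar ROI therefore collects the liver column on top of the kidney
counts and overestimates the kidney dose, while the hybrid workflow removes
the overlapped pixels, substitutes the lost activity assuming uniform
concentration, and rescales to the 24 h SPECT value — landing close to the
multi-SPECT/CT result. The ordering planar > hybrid > multi-SPECT is the
headline behaviour of planar-based dosimetry for organs at risk.

The same comparison on a cohort, with paired statistics:

```python
from lutadose import simulate_cohort, run_all, compare_scenarios
comparison = compare_scenarios([run_all(s) for s in simulate_cohort(8, seed=3)])
print(comparison.organs["kidney_right"].ratio_planar_over_multi_rounded)
```

A command-line layer mirrors the library
(`lutadose simulate|quantify|run|compare|observers`, each with `--seed` and
`--out`); study directories hold NIfTI volumes plus a JSON manifest, and
reports are CSV/JSON.

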