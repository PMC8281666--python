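# imhcmr — bright- vs dark-blood T2\*-weighted CMR for intramyocardial hemorrhage, in silico

Intramyocardial hemorrhage (IMH) after reperfused myocardial infarction is
detected on T2\*-weighted cardiovascular MR as a hypointense core inside the
infarct. Two acquisition variants are used interchangeably in practice:
**bright-blood** (no preparation) and **dark-blood** (double-inversion-
recovery, DIR, preparation that nulls inflowing blood). The DIR pulses cost
longitudinal magnetization, and the standard hemorrhage quantification rule
is threshold-based — so the choice of variant is not neutral.

`imhcmr` implements the full comparison as a tested pipeline on a digital
left-ventricle phantom:

* a closed-form spoiled-GRE signal model with a lumped DIR preparation
  factor `f(TI) = 1 − (1 − κ(1−2η_ns)(1−2η_sel)) e^(−TI/T1)`, Rician noise
  and intrinsic tissue texture, at 1.5 T / 3 T and acute / chronic presets;
* the clinical quantification chain: remote reference ROI, infarct zone as
  LGE signal ≥ mean + 5 SD, hemorrhage core as T2\*w signal ≤ mean − 2 SD,
  extent as % of LV myocardial volume;
* paired signal metrics: relative SNR = 100 × (SI_remote/σ_air)_dark /
  (SI_remote/σ_air)_bright, relative CNR likewise on the IMH–remote
  contrast, COV = σ/SI;
* AHA-style segmental diagnosis (positive if hypointense area > 1% of the
  segment) of dark-blood calls against bright-blood calls: sensitivity,
  specificity, accuracy, rank-sum AUC;
* agreement statistics: ICC(2,1) with F-based CI for two synthetic readers,
  Bland–Altman bias, and OLS against a noise-free fine-grid "ex-vivo" render.

The quantification and statistics modules accept any conforming NIfTI
volumes, so the same chain can run on real data. See `docs/methods.md` for
the model, presets and design choices.

## Worked example

```python
import imhcmr as m

sim = m.simulate_subject(m.SubjectConfig(field="1.5T", phase="acute"), seed=1)
myo = sim["label_map"].myocardium_mask
bright = m.segment_subject(sim["lge"], sim["bright"], myo)
dark = m.segment_subject(sim["lge"], sim["dark"], myo)
print(f"true extent   {sim['truth'].true_imh_extent:.2f}% LV")
print(f"bright-blood  {bright.imh_extent_pct:.2f}% LV")
print(f"dark-blood    {dark.imh_extent_pct:.2f}% LV")
```

prints

```
true extent   5.48% LV
bright-blood  3.44% LV
dark-blood    2.87% LV
```

— the bright arm misses part of the weakly hypointense hemorrhage rim, and
the dark arm, whose preparation costs ~23% of the remote-myocardium signal
at 1.5 T while the noise floor is unchanged, misses more.

The numbered drivers under `analysis/` run the full study (10 subjects per
field × phase cell by default) and write every table to `results/study/`:

```bash
python analysis/01_simulate_cohort.py        # phantom + signal tables, demo NIfTIs
python analysis/02_quantify_extent.py        # extent per arm: dark underestimates
python analysis/03_signal_metrics.py         # relative SNR/CNR < 100%, COV up
python analysis/04_segmental_diagnostics.py  # dark sensitivity < 100%
python analysis/05_agreement_analysis.py     # ICC, Bland-Altman, ex-vivo OLS
```

There is also a CLI (`imhcmr simulate|run-study|quantify|agree`) for running
the pipeline from a shell on written volumes.

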