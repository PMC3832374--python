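# renogfr

Dual-modality quantification of glomerular filtration rate (GFR) in small
animals, for imaging and renal-physiology groups who want to cross-validate
MRI-based filtration measurements against transcutaneous tracer clearance:

* **DCE-MRI arm** — voxel-wise fitting of the two-compartment filtration
  model (2CFM) to dynamic contrast-enhanced renography, producing tubular
  flow maps and absolute per-kidney GFR;
* **optical arm** — one-compartment analysis of transcutaneous
  FITC-sinistrin fluorescence, producing an elimination half-life and
  absolute GFR;
* **method comparison** — group summaries, paired tests and Bland-Altman
  agreement between the two arms.

Because suitable in-vivo data cannot be regenerated at will, the package
ships a synthetic-data module (digital renography phantoms, fluorescence
traces) that emulates the statistical structure the analysis assumes, plus
the per-animal GFR table of a published 12-rat dual-modality comparison as
a bundled fixture.

## Models

**2CFM.** Each tissue voxel is a serial plasma → tubular compartment system
driven by the arterial input function c_a(t) measured in the abdominal
aorta:

    dC_P/dt = f_p · c_a(t − δ) − C_P / T_P ,    T_P = v_p / (f_p + f_t)
    dC_T/dt = (f_t / v_p) · C_P − C_T / T_T

with total tissue signal C = C_P + C_T under a linear signal-concentration
assumption (signal baseline-normalised by subtracting the mean of the
pre-contrast volumes). The tubular inflow F_T (ml/100 ml/min) is the
voxel-level surrogate of filtration; absolute single-kidney GFR is

    GFR_kidney [ml/min] = mean(F_T over cortex) × V_cortex [ml] / 100

summed over kidneys. The model is evaluated in closed form as exact
exponential-kernel convolutions of the piecewise-linear AIF and fitted by
bounded multi-start least squares; an independent high-accuracy ODE
integration of the same equations serves as a numerical cross-check.

**Clearance.** The transcutaneous signal after background subtraction is
fitted on its elimination phase by S(t) = A · 2^(−t / (60 · t½)) with t½ in
minutes, and converted to absolute GFR by the empirical single-compartment
equation GFR = (factor / t½) × BW/100 with the conversion factor in
ml/100 g body weight (default 31.26, a rat calibration constant; always an
explicit, logged configuration value).

**Agreement.** Differences optical − MRI are summarised by their mean
(bias), sample SD, and limits of agreement bias ± 2·SD, plus a two-sided
paired t-test per group.

## Worked example

Simulate a small noisy phantom, run the MRI arm, and compare the bundled
study table between methods:

```python
from renogfr import (PhantomSpec, make_phantom, baseline_normalize,
                     extract_aif, fit_map, mri_gfr,
                     load_reference_gfr_table, compare_methods)

spec = PhantomSpec(shape=(16, 12, 6), voxel_dims=(2.5, 2.5, 5.0),
                   n_volumes=200, noise_sigma=0.5, seed=1)
series, mask, truth = make_phantom(spec)
normalized = baseline_normalize(series)
aif = extract_aif(normalized, mask)
maps = fit_map(normalized, mask, aif,
               config={"delay_grid": (0.0,), "n_starts": 2},
               roles=("cortex_left", "cortex_right"))
result = mri_gfr(maps, mask, spec.voxel_dims, animal_id="phantom-01")
for role, (ft, vol, gfr) in result.per_kidney.items():
    print(f"{role}: mean F_T = {ft:.1f} ml/100 ml/min, "
          f"cortex volume = {vol:.2f} ml, GFR = {gfr:.3f} ml/min")
print(f"total MRI GFR: {result.gfr_total:.3f} ml/min")

stats = compare_methods(load_reference_gfr_table())
ba = stats["bland_altman"]
print(f"bias = {ba.bias:.2f} ml/min, SD = {ba.sd_diff:.2f}, "
      f"outside +/-2SD: {ba.n_outside}/{ba.n}")
```

prints

```
cortex_left: mean F_T = 61.7 ml/100 ml/min, cortex volume = 1.38 ml, GFR = 0.848 ml/min
cortex_right: mean F_T = 68.1 ml/100 ml/min, cortex volume = 1.38 ml, GFR = 0.937 ml/min
total MRI GFR: 1.785 ml/min
bias = 1.63 ml/min, SD = 1.39, outside +/-2SD: 1/12
```

The phantom's true tubular flows are 61 and 68 ml/100 ml/min, so the fitted
cortex means (61.7, 68.1) recover the ground truth to about 1% under this
noise level. On the bundled rat table the optical method reads on average
1.63 ml/min higher than MRI with one of twelve animals outside the ±2 SD
limits of agreement.

The same pipeline is scriptable from a shell:

```sh
renogfr simulate --out run/ --seed 42 --noise-sigma 0.5
renogfr fit-optical run/trace.csv --out run/clearance.json
renogfr compare --out run/           # bundled 12-rat table
```

The estimator layer (`TwoCompartmentFiltrationModel`,
`MonoexponentialClearanceModel`) follows scikit-learn conventions
(`fit`/`predict`, `get_params`/`set_params`, trailing-underscore fitted
attributes) and composes with sklearn tooling.

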