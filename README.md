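# csfpulse

Phase-contrast MRI (PC-MRI) quantification of cerebrospinal-fluid (CSF)
dynamics along the craniospinal axis, built for the prognostic question in
Chiari malformation type 1 (CM1): do preoperative CSF stroke volumes
predict headache relief after posterior fossa decompression?

PC-MRI encodes fluid velocity into the phase of the MR signal: a cine
acquisition gated to the cardiac cycle yields, at each of 32 cardiac
phases, a phase image wrapped to [−π, π) in which a voxel's phase φ maps to
a through-plane velocity v = venc·φ/π (venc = 10 cm/s at the aqueduct of
Sylvius, 5 cm/s elsewhere). Integrating the flow curve q(t) through a
region of interest over one cycle gives the forward and backward displaced
volumes V⁺ and V⁻; the **stroke volume** SV = (V⁺+V⁻)/2 (µL per cardiac
cycle, µL/CC) measures CSF pulsatility through that plane, and
net = V⁺−V⁻ the bulk flow. `csfpulse` measures SV at five sites — aqueduct
(`aqu`), prepontine cistern (`ppc`), foramen magnum (`fm`), cerebellar
tonsils/neuraxis (`nevrax`), C2–C3 subarachnoid space (`c2c3`) — plus the
Evans index and the narrowest aqueductal cross-sectional area, and compares
patients with vs. without postoperative headache relief (Welch t-test after
Kolmogorov–Smirnov normality screening, Mann–Whitney otherwise; exact
small-sample Mann–Whitney p-values by enumeration).

Because the underlying clinical study deposited no data, the package ships
a cine phantom simulator (pulsatile plug/Poiseuille flow through a circular
or annular lumen, with venc aliasing, phase noise and eddy-current offset)
whose stroke volume is known in closed form, and a synthetic cohort
generator parameterized by the published group summary statistics — so the
whole pipeline is testable end to end without any download.

Intended users: researchers in CSF hydrodynamics and neuroimaging methods
who need a transparent, scriptable re-implementation of the Flow-style
stroke-volume workflow, with analytic ground truth for validation.

## Worked example

A noise-free Poiseuille phantom of the aqueduct (radius 1.5 mm, mean-lumen
velocity 1 cm/s·sin(2πt/T), venc 10 cm/s) has the closed-form
SV = πR²·v·T/π ≈ 22.5 µL/CC. Quantify it end to end:

```python
from csfpulse import (PhantomSpec, WaveformTerm, generate_cine_series,
                      quantify_site, SummaryStats, t_test_summary)

spec = PhantomSpec(geometry="circle", radius_mm=1.5, profile="poiseuille",
                   waveform=(WaveformTerm(1.0, 1, 0.0),), venc_cms=10.0,
                   pixel_spacing_mm=(0.1, 0.1), grid_shape=(45, 45))
series, truth = generate_cine_series(spec)
print("analytic SV:", round(truth.sv_true_ul, 2))      # analytic SV: 22.5
res = quantify_site(series, (22, 22), "aqu")
print("measured SV:", round(res.sv_ul_per_cc, 2))      # measured SV: 21.47
```

The measured 21.47 µL/CC sits 4.6% below truth: thresholding the parabolic
profile at 20% of the centerline pulsatility excludes the slow outer ring
of the lumen, a documented −4% bias of the segmentation convention (see
`docs/methods.md`).

The prognostic comparison works from raw samples or from published summary
statistics. On the reference aqueduct row (12 relieved patients, 65±45
µL/CC, vs 29 without relief, 32±24):

```python
t = t_test_summary(SummaryStats(12, 65, 45), SummaryStats(29, 32, 24), "welch")
print(f"t={t.statistic:.2f}, df={t.df:.1f}, p={t.p_value:.3f}")
# t=2.40, df=13.7, p=0.031
```

i.e. relieved patients had significantly higher aqueductal stroke volumes.

From the shell, the same machinery:

```bash
csfpulse cohort --rng-seed 7 --out cohort.csv
csfpulse stats --cohort-csv cohort.csv --out stats.json
# sv_aqu                74.0±38.3      38.0±19.5   p=0.01* (t_welch)
# sv_ppc               428.3±297.7    399.8±182.2  p=0.76 (t_welch)
# ...
# evans_index            0.3±0.0        0.3±0.0    p=0.70 (mann_whitney)
```

One synthetic 41-patient draw from the reference distributions: the
aqueduct difference is starred, the overlapping sites and the morphometrics
are not. `csfpulse simulate` / `quantify` handle single planes (NIfTI pair
+ JSON sidecar, masks as PNG), and `csfpulse replicate-study` runs the full
replica — per-site phantom QC, cohort, Table-style comparison, and the
SV dichotomization report (e.g. SVaqu > 100 µL/CC occurring only in
relieved patients) — into one audited output directory.

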