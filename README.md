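# ectpipe

Analysis pipeline for wire-based 3D engineered cardiac tissue (ECT) assays.

ECTs are hydrogel constructs of cardiomyocytes and fibroblasts suspended
between two flexible elastomer wires.  The wires double as force sensors:
the tissue's twitch bends them, and the optical deflection, converted
through a measured displacement–force calibration, gives contractile force
in µN.  Around that central readout a study typically collects Ca²⁺ dye
videos, sharp-electrode action potentials, brightfield and confocal
images, concentration–response tables and qPCR plates.  `ectpipe`
implements the full quantitative stack for labs running such platforms —
and, because raw recordings are rarely shareable, a synthetic-data
generator that produces every input modality with exact ground truth, so
the whole pipeline is testable end to end.

## What it computes

| Stage | Model / statistic |
|---|---|
| Contractility | wire centerline tracking → deflection (px) → force (µN); per-beat double-sigmoid fit `F(t) = B + A'·σ((t−t_up)/τ_up)·σ(−(t−t_down)/τ_down)`; amplitude, FWHM, 10%→peak and peak→10% times; FFR and post-rest potentiation normalized to 1 Hz |
| Ca²⁺ transients | artifact-excluding ROI → ΔF trace → biexponential fit `B + A'(e^{−(t−t₀)/τ_d} − e^{−(t−t₀)/τ_r})`; amplitude, duration, 10–90% rise, 90–10% decay |
| Electrophysiology | RMP, amplitude, dV/dt_max (Savitzky–Golay), APD₃₀/₅₀/₉₀ from activation to the peak − x%·amplitude crossing |
| Morphometry | brightfield tissue-area segmentation (adaptive threshold pipeline, mm²); Z-disc detection (Laplacian of Gaussian), sarcomere linking, per-image median length and angle SD |
| Pharmacology | 4PL fits `y = bottom + (top−bottom)/(1+(EC₅₀/x)^hill)` with signed Hill, geometric-mean EC₅₀ across tissues, exact inverse interpolation |
| Expression | ΔΔCt with dual reference genes, RQ = 2^(−ΔΔCt), gene ratios, t-test / ANOVA + Šidák |

All models, parameters and numerical conventions are documented in
[docs/methods.md](docs/methods.md).

## Worked example

Generate a three-beat deflecting-wire video (peak sag 6 px, SNR 10), track
it, convert to force through a 10 µN/px linear calibration and fit every
twitch:

```sh
python -c "from ectpipe.contractility import ForceCalibration; \
           ForceCalibration('linear', [10.0]).to_json('cal.json')"
ect synth wire --out wv --seed 1 --duration 3 --sag 6
ect contractility --stack wv/video.tif --cal cal.json --fs 100 --out out
```

`out/twitches.csv` then contains (times in seconds):

```
 t_peak  amplitude_uN  duration_s  contraction_time_s  relaxation_time_s
 0.1241       58.4287      0.2011              0.1076             0.1911
 1.1238       58.2534      0.2013              0.1061             0.1908
 2.1238       58.2583      0.2015              0.1073             0.1917
```

The programmed pulse (scale 6 px × 10 µN/px with slightly overlapping
logistic edges) has a true realized peak of 58.7 µN and a true FWHM of
202 ms, so the recovered amplitudes are within ~0.5% and the widths within
a millisecond — at a signal-to-noise ratio of 10.  Every output directory
also carries `run_config.json` (arguments, seed, package version); reruns
with the same seed are byte-identical.

The same pattern works for each assay: `ect synth {twitch,ca,ap,
brightfield,sarcomere,doseresponse,ct}` produce inputs with ground-truth
JSON sidecars, and `ect {contractility,calcium,ap,area,sarcomere,
doseresponse,qpcr}` analyze them (or your own TIFF/CSV exports).

As a library:

```python
from ectpipe.synth import gen_ca_trace
from ectpipe.traces import fit_biexponential

ts, truth = gen_ca_trace(dict(scale=50, tau_rise=0.05, tau_decay=0.30),
                         [(1.0, 1.0)], noise_sd=0.0, fs=1000)
fit = fit_biexponential(ts)
fit.tau_decay   # 0.300
fit.peak_time   # 0.1075 = t0 + τdτr/(τd−τr)·ln(τd/τr)
```

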