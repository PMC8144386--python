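# npphen

Functional phenotyping of airway organotypic cultures from two routine
assays: **ciliary dynamics** quantified from high-speed video microscopy,
and **mitochondrial bioenergetics** from extracellular-flux (mito stress
test) plates. The package was built for studies that compare
nasopharyngeal-derived basal-cell cultures between donor cohorts (e.g.
preterm vs term neonates) as they differentiate at air–liquid interface,
but the pipelines are generic.

## What it computes

**Ciliary beat frequency (CBF) and ciliary beating surface (CBS).**
Each pixel of a video field (default acquisition: 360 frames/s, 720
frames, 1024 × 768 = 786,432 pixels) is an intensity time series
x<sub>t</sub>. After mean (DC) removal, its single-sided amplitude
spectrum is

&nbsp;&nbsp;M(f<sub>k</sub>) = 2·|X<sub>k</sub>|/N, &nbsp; f<sub>k</sub> = k·fps/N, k = 1…⌊N/2⌋,

so an on-bin sinusoid of amplitude A shows magnitude A at its bin. A
pixel is **beating** when its dominant component inside the closed
physiological band [2, 60] Hz has magnitude strictly greater than 1
intensity unit. Then, per field,

- CBF = mean dominant frequency over beating pixels (Hz),
- CBS = 100 × (beating pixels) / (total pixels) (%),

aggregated as unweighted means ± SEM over fields per well and wells per
donor.

**Mito stress-test state rates.** From per-well OCR traces over the
four-injection protocol (baseline → oligomycin → FCCP → rotenone +
antimycin A), each segment is collapsed to a rate (mean of its cycles by
default), the non-mitochondrial (rot + antA) rate is subtracted, and
rates are normalized by well protein (pmol O₂/min/µg). The respiratory
control ratio is RCR = FCCP rate / oligomycin rate. Replicate wells
falling outside Tukey 1.5 × IQR fences on any state are omitted per
plate; plate means are averaged (unweighted) per donor.

**Group statistics.** Exact Mann–Whitney U (full enumeration for group
sizes ≤ 8, tie-free), Student/Welch two-sample t, Pearson correlation,
mean ± SEM summaries.

**Synthetic data.** Simulators generate video fields (sinusoidal patches
over a static background, optional Gaussian noise) and OCR plates with
known ground truth, so every stage is testable end to end.

## Worked example

```python
import npphen as npp

# a field where 25% of the frame beats at 18 Hz, amplitude 5
spec = npp.CiliaSimSpec(height=32, width=32, frames=240, noise_sd=0.0,
                        dtype="float64",
                        patches=[npp.Patch(0, 0, 16, 16, 18.0, 5.0)])
video, truth = npp.simulate_cilia_video(spec)
m = npp.analyze_field(video)
print(f"CBS {m.cbs_percent:.1f}%  CBF {m.cbf_mean:.1f} Hz")

# a noiseless stress-test plate with true rates (100, 40, 150, 20), 10 ug protein
trace, ocr_truth = npp.simulate_ocr_plate(npp.OCRPlateSimSpec(cycle_noise_sd=0.0))
wells, plates, subjects, log = npp.analyze_trace(trace)
row = subjects.iloc[0]
print(f"baseline {row.baseline}  oligomycin {row.oligomycin}  "
      f"fccp {row.fccp}  RCR {row.rcr}")

print(npp.mann_whitney_u([1, 2, 3], [4, 5, 6]))
```

prints

```
CBS 25.0%  CBF 18.0 Hz
baseline 8.0  oligomycin 2.0  fccp 13.0  RCR 6.5
GroupComparison(method='mann-whitney-u (exact)', statistic=0.0, pvalue=0.1, n_x=3, n_y=3, notes='full enumeration')
```

CBS is exactly the designed beating fraction, CBF the designed
frequency; the corrected normalized state rates are (100−20)/10 = 8.0,
(40−20)/10 = 2.0, (150−20)/10 = 13.0 with RCR 13/2 = 6.5; and the fully
separated triplets give the smallest possible exact two-sided p at
n = 3 + 3, namely 2/20 = 0.1.

## Command line

```
npp simulate cilia --spec spec.json --out simdir
npp simulate ocr   --spec spec.json --plates 3 --out simdir
npp cbf analyze    --video field.tif --fps 360 --band 2:60 --threshold 1.0 --out outdir
npp ocr analyze    --trace ocr_trace.csv --rate-rule mean --out outdir
npp compare        --input metrics.csv --metric cbs_percent --group-col group --test mwu --out cmp
npp report         --cilia donor_summary.csv --ocr subject_rates.csv --out rep
```

Results go to files (CSV/TIFF/JSON); logs go to stderr; every output
directory records the exact run configuration and its hash.

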