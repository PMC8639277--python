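# rsnalab

Analysis of multiunit **renal sympathetic nerve activity (RSNA)** recordings
from anesthetized rats, of the kind used to study sympathetic outflow and the
arterial baroreflex in hypertension models — the spontaneously hypertensive
rat (SHR), its normotensive Wistar-Kyoto control (WKY), and SHR under chronic
low-dose L-NAME (SHRLN), a model of severe hypertension with target-organ
damage. It is written for cardiovascular physiologists who have multichannel
recordings (arterial pressure in mmHg, raw nerve signal in µV, a table of
drug administrations) and want the standard analysis chain as tested,
scriptable code rather than an interactive chart recorder.

Because no public recordings of this kind exist, the package ships a
first-class synthetic cohort generator that emulates the three phenotypes
(pressure waveforms, cardiac-locked bursting, pharmacological reflex tests),
so the entire pipeline is developed and validated end-to-end without animal
data.

## What it computes

Raw nerve signal is full-wave rectified and integrated over fixed bins
(µV/100 ms for burst analysis, per-window cumulation triggered by the
systolic peak for reflex analysis). Absolute µV values are
electrode-dependent, so after subtracting the residual electrical background
(measured after nerve blockade) every subject is expressed in **percent of
its own control-period mean**.

- **Burst metrics** — over a 60-s window of the 100-ms series: max/mean and
  min/mean bin ratios. A raised tonic floor with smaller bursts (the
  hypertensive phenotype) lowers max/mean and raises min/mean.
- **RSNA–HR coupling** — per-beat cumulated RSNA vs instantaneous heart
  rate; the peak lagged Pearson correlation classifies coupling as
  *intact* (|r| ≥ 0.3) or *altered*. This is an explicit, reproducible
  stand-in for the usual visual assessment of the beat-triggered display.
- **Baroreflex curve** — pressure is swept down with a diltiazem bolus and
  up with a phenylephrine infusion; paired per-beat (MBP, RSNA%) samples are
  averaged in 5-mmHg bins per subject, then across subjects. The descending
  limb follows the sympathoinhibition sigmoid

  RSNA(p) = L + (U − L) / (1 + exp((p − p₅₀)/k)),

  summarized by an OLS **slope** over the 10–90 % transition band (%/mmHg)
  and by the **plateau pressure** at which RSNA reaches its lower plateau.
- **Reflex responses** — baseline vs smoothed extremum for each drug
  (ΔMBP, ΔHR), and the Bezold–Jarisch transient for CPBG boluses (peak RSNA
  inhibition in %, −100 = complete nerve silence).
- **Group statistics** — one-way ANOVA with Tukey's HSD, two-way ANOVA of
  curve values on pressure bin × group, unpaired t-tests; means ± SEM.

## Worked example

```python
from rsnalab import PRESETS, RSNAModel, generate_subject, standard_protocol

preset = PRESETS["WKY"]
protocol, duration = standard_protocol(preset, "baroreflex")
record = generate_subject(preset, protocol, seed=2, duration=duration)
results = RSNAModel(record).fit()
print(results.summary())
```

prints

```
RSNA analysis -- subject WKY-2 (group WKY)
============================================================
control window        : 0-60 s
control MBP           : 126.0 mmHg
control HR            : 435.9 bpm
control RSNA          : 0.2006 uV*s per 0.5 s window (=100%)
burst max/mean        : 2.13
burst min/mean        : 0.32
RSNA-HR correlation   : r=+0.41 at lag +2 beats -> intact (|r|>=0.3 criterion)
baroreflex slope      : -10.25 %/mmHg (r2=0.985, 9 bins)
plateau pressure      : 137.5 mmHg
diltiazem     : dMBP -75 mmHg, dHR +19 bpm
phenylephrine : dMBP +108 mmHg, dHR -113 bpm
```

Reading this: during the 60-s control window the simulated animal sat at
126 mmHg / 436 bpm; its cumulated RSNA over 0.5-s systole-triggered windows
(0.2006 µV·s) defines the 100 % reference. Bursting is healthy (largest
100-ms bin is 2.1× the mean, quietest 0.32×), RSNA co-varies with heart rate
(intact coupling), and sweeping pressure with diltiazem (−75 mmHg) then
phenylephrine (+108 mmHg from the post-diltiazem baseline) traces a reflex
curve that falls at −10.3 % of control per mmHg and is fully inhibited
above ~138 mmHg. `results.curve.to_frame()` gives the binned curve, e.g.

```
 bin_low_mmHg  bin_high_mmHg  mean_rsna_pct      sem   n
        105.0          110.0         307.77     4.54  39
        110.0          115.0         230.17     3.18  34
        115.0          120.0         179.87     2.55  51
        120.0          125.0         131.42     3.25  13
        125.0          130.0          95.34     1.98  30
        130.0          135.0          67.72     1.31  21
```

Group curves come from `rsnalab.average_curves`, cohort tables from
`rsnalab.summarize_cohort`, and `results.curve.plot()` draws the curve. The
same steps are scriptable from a shell:

```bash
rsnalab simulate --group WKY --n 9 --protocol baroreflex --seed 1 --out data/
rsnalab analyze  --input data/ --window-ms 500 --out analysis/
rsnalab report   --input data/ --out cohort.csv
```

## Layout

- `src/rsnalab/synthetic.py` — phenotype presets, pressure/RSNA simulators,
  intervention kernels, cohort generation
- `src/rsnalab/processing.py` — rectification, bin integration, background
  correction, percent of control
- `src/rsnalab/cardiac.py` — systolic peak detection, per-beat MBP,
  triggered cumulation, RSNA–HR coupling
- `src/rsnalab/bursts.py` — burst amplitude ratios
- `src/rsnalab/baroreflex.py` — curve binning/averaging, slope, plateau,
  drug and Bezold–Jarisch responses
- `src/rsnalab/model.py` — `RSNAModel` / `RSNAResults` (the fitting surface)
- `src/rsnalab/stats.py` — ANOVA/Tukey/t-test and cohort reports
- `src/rsnalab/studies.py` — replicated validation studies
- `docs/methods.md` — model assumptions, parameter choices, limitations
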