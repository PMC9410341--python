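# stormquant

Quantification pipelines for studies of ventricular arrhythmia after
myocardial infarction, built around the murine "STORM" model (spontaneous
tachycardia in hypokalemic mice with MI) and its clinical translation.
The package is aimed at cardiac electrophysiology and imaging labs that
need reproducible, scriptable versions of four analyses that are usually
done by hand in LabChart, ImageJ and spreadsheet software:

1. **Telemetry ECG arrhythmia metrics** (`stormquant.ecg`).
   R peaks are detected on the rectified trace, each beat is labeled
   sinus or ventricular by QRS width and correlation with the sinus
   template, and episodes are called by rule:
   - *VT*: a maximal run of ≥ 4 consecutive ventricular beats with every
     RR interval < 75 ms (rate > 800 bpm) and no intervening sinus
     complex;
   - *Vfib*: sliding 1-s windows with peak-to-peak interval CV > 0.3,
     amplitude CV > 0.3, mean rate > 800 bpm and no sinus-like waveform,
     merged into episodes (Vfib overrides overlapping VT).

   On top of the episodes: burden (cumulative seconds and cardiac cycles
   over a horizon, with the < 1 s exclusion available for invasive EP
   studies), cohort incidence (burden statistics restricted to animals
   with burden > 0), sinus-vs-VT heart rate, rate-corrected QT
   (QTc = QT / √(RR / 100 ms), ensemble-averaged over ≥ 5 sinus cycles),
   and Bland–Altman inter-observer agreement on the percent scale.

2. **Ca²⁺ dyssynchrony mapping** (`stormquant.imaging`).
   Frames of a two-channel movie (Ca²⁺ indicator + neutrophil label) are
   gated to a fixed cardiac phase (5–30 frames), the *dyssynchrony map*
   is the per-pixel sample SD over the gated series, and Ca²⁺ *hotspots*
   are 8-connected components above μ_bg + 4·σ_bg.  Hotspot-to-neutrophil
   distances (nearest neighbour, counts within 50 µm) are compared with
   three uniformly drawn random spots per field of view by permutation
   test and t-test.

3. **Fluorescence-reflectance (FRI) scoring** (`stormquant.fri`).
   Annexin-V positive area is segmented at remote-tissue MFI + 5 × SD;
   every assay is scored as a target-to-background ratio
   TBR = MFI_target / MFI_background, with the background ROI chosen per
   assay (remote tissue for Annexin-V, off-tissue for TMRE/CellROX).

4. **Ordered-group trend testing** (`stormquant.trend`).
   The Jonckheere–Terpstra statistic
   JT = Σ_{i<j} #{x∈Gᵢ, y∈Gⱼ : x < y} + ½·#{x = y}
   over a priori ordered groups, with tie-corrected normal approximation
   (continuity-corrected) and an exact null by full enumeration for
   small samples (Monte-Carlo permutations otherwise).

Synthetic generators (`stormquant.simulate`) produce ECG traces, gated
movies and slice images with machine-readable ground truth, so every
stage is testable end to end without animal data.

## Worked example

```python
from stormquant import *
from stormquant.simulate import PlantedEpisode

spec = EcgSimSpec(
    duration_s=120.0,
    planted_episodes=[
        PlantedEpisode("VT", 30.0, 5.0, rate_bpm=1100.0),
        PlantedEpisode("VT", 80.0, 3.0, rate_bpm=950.0),
        PlantedEpisode("Vfib", 100.0, 4.0),
    ],
    noise_sd_mv=0.05,
    seed=7,
)
trace, truth = simulate_ecg(spec)

beats = classify_beat_origin(detect_r_peaks(trace))
episodes = resolve_episode_precedence(
    detect_vt_episodes(beats, trace.duration_s),
    detect_vfib_episodes(trace, beats),
)
burden = compute_burden(episodes, horizon_s=trace.duration_s)
rates = compute_heart_rate(beats, episodes)
qtc = compute_qtc(trace, beats)

print(f"VT burden   {burden['VT']['burden_s']:.2f} s "
      f"({burden['VT']['burden_cycles']} cycles in {burden['VT']['n_episodes']} episodes)")
print(f"Vfib burden {burden['Vfib']['burden_s']:.2f} s")
print(f"heart rate  {rates['sr_bpm']:.0f} bpm (sinus) vs {rates['vt_bpm']:.0f} bpm (VT)")
print(f"QTc         {1000 * qtc.qtc_s:.1f} ms over {qtc.n_cycles_used} sinus cycles")
```

Output:

```
VT burden   7.93 s (140 cycles in 2 episodes)
Vfib burden 4.00 s
heart rate  550 bpm (sinus) vs 1049 bpm (VT)
QTc         37.5 ms over 5 sinus cycles
```

The two planted VT runs (5 s at 1100 bpm, 3 s at 950 bpm) are recovered
as two episodes whose burden spans first-to-last R peak; the Vfib
segment is recovered at window resolution; the sinus and VT rates match
the planted 550/≈1050 bpm regimes; QTc equals the generator's template
QT (≈ 41 ms) corrected to the 109 ms sinus cycle length.

## Analysis scripts

`analysis/` holds numbered drivers that run the pipelines over synthetic
cohorts and write tables under `results/` (raw generated data goes to
`scratch/`):

```bash
python analysis/01_simulate_telemetry.py     # 12-mouse telemetry cohort
python analysis/02_quantify_arrhythmia.py    # burden/incidence/QTc/agreement
python analysis/03_dyssynchrony_mapping.py   # hotspots vs random spots
python analysis/04_fri_tbr.py                # TBR recovery per assay
python analysis/05_clinical_trend.py         # ordered-group trend test
```

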