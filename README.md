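# pupilscene

Analysis pipeline linking pupil size to dynamic scene statistics around the
gaze point, plus a controlled pupillary-light-response (PLR) analysis, and a
synthetic-data generator that gives every stage a parameter-recovery test.

Two analyses are implemented end to end:

1. **Gaze-contingent correlation mapping.** Raw binocular pupil traces are
   cleaned (eye selection, blink detection/repair with padded edges,
   two-pass velocity despiking), downsampled to the frame rate of a screen
   recording, and correlated pixel-by-pixel with gamma-transformed RGB
   luminance (or CIELAB channels) inside a square window centered on gaze
   (off-screen cells are NaN, blocks are mean-downsampled). Per-subject
   correlation maps are Fisher-Z transformed and tested at the group level
   with pixel-wise one-sample t tests under Benjamini–Hochberg FDR control;
   channel pairs are compared with dependent-correlation tests (Williams t
   or Steiger z), and each subject gets an above-vs-below-gaze summary test.
2. **Controlled PLR analysis.** Trial epochs (3 colors x 4 screen
   locations) are normalized to percent signal change against a 500 ms
   pre-stimulus baseline, blink-contaminated trials and under-covered
   subjects are excluded, peak constriction (PLRmin, minimum of the
   condition-mean waveform in 0–2 s) feeds a two-factor repeated-measures
   ANOVA with Greenhouse–Geisser correction and FDR-corrected one-sample
   tests on the six planned location difference scores.

The `simulate` module generates scenes (blue-dominant sky over red/green
terrain with AR(1) channel fluctuations and independently fluctuating
patches), horizon-hugging gaze walks, scene-driven pupil traces (spatially
weighted luminance drive, gamma-family impulse response, blinks with
partial-closure ramps, spike artifacts), and PLR trial sets with known
amplitude tables — all bit-reproducible given a seed.

## CLI

```sh
pupilscene simulate   --out fixtures/demo --seed 1 --frames 120
pupilscene preprocess --input fixtures/demo/eyetrack.csv --out clean.csv
pupilscene exp1       --out results/exp1 --seed 1 --subjects 8 --frames 600
pupilscene exp2       --out results/exp2 --seed 1 --subjects 15
```

`exp1` writes group t/p/FDR-mask maps per channel, channel-comparison maps,
a lag table and a manifest; `exp2` writes the QC report, the PLRmin table,
the ANOVA table and the difference-score table. All maps are CSV matrices
with JSON sidecars (`pupilscene.io_formats.read_map_bundle` reads them
back).

## Layout

| module | contents |
| --- | --- |
| `io_formats` | eye-tracking CSV/TSV reader, PNG/MP4 frame reader, map bundles, run config |
| `preprocess` | eye selection, despiking, blink detection/repair, downsampling |
| `scene_stats` | gamma fit/transform, CIELAB, gaze windows, block downsampling |
| `corrmap` | lag estimation, series alignment, pixel-wise correlation maps |
| `group_stats` | Fisher Z, t maps, BH-FDR, Williams/Steiger, upper-lower test |
| `plr` | epochs, percent signal change, QC, PLRmin, RM-ANOVA, difference scores |
| `simulate` | scene/gaze/pupil/trial generators with ground-truth records |
| `pipeline` | end-to-end orchestration and result bundles |
| `cli` | `pupilscene` command |
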