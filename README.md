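# cet — timing of convergence & extension morphogenesis

During zebrafish gastrulation, convergence & extension (C&E) movements
narrow the tissue mediolaterally and elongate the body axis, beginning
abruptly at gastrulation onset (~6 hpf shield stage for transcription,
~8 hpf for visible cell movement).  `cet` is an analysis pipeline for
asking *when* C&E starts and what shifts that timing, built for three kinds
of data:

- **Stage-resolved expression panels** (genes × stages × conditions, TPM):
  a screen for *trigger* genes — flat from sphere to 50% epiboly, sharply
  up at shield and beyond, in every condition — plus paired-gene ratio
  trajectories (e.g. the *sumf2/sumf1* antagonist/enzyme balance).
- **Explant shape series** (segmentation masks or roundness-over-time):
  roundness 4A/(πM²) per frame, Boltzmann sigmoid fits
  r(t) = Bottom + (Top−Bottom)/(1+e^{(t−V50)/slope}) giving V50 (timing)
  and slope (pace), group comparison by the extra sum-of-squares F test,
  and automated extension-onset calls.
- **Nuclear tracks** (track id, frame, x, y): signed mediolateral
  displacement toward the midline, window-4 smoothing, hinge-changepoint
  convergence onset, persistence and speed statistics.

Small Methods formulas are included: 2^−ΔΔCt relative expression,
internal-standard (20 pmol) disaccharide quantification, and pairwise
percent identity/similarity under BLOSUM62.  A synthetic-data module
generates all three input kinds with planted ground truth, so the entire
pipeline is testable without downloads.  See `docs/methods.md` for models,
assumptions and defaults.

## Worked example

Simulate a 200-gene panel (20 planted triggers, replicate CV 0.2), run the
tiered screen, then time a shape and a tracking experiment:

```sh
python analysis/01_trigger_screen.py --seed 1
python analysis/02_explant_shape.py --seed 1
python analysis/03_convergence_kinetics.py --seed 1
python analysis/04_methods_quant.py
```

prints

```
tier counts: {'tier1': 8, 'tier2': 8, 'tier3': 8}  (sensitivity 0.40, 0 false positives among 180 non-triggers)
ratio peak at 75pct, inversion at 7.401776654156129 hpf
control: V50 = 9.01 hpf, slope = 0.50 hpf (12 explants)
delayed: V50 = 9.60 hpf, slope = 0.50 hpf (12 explants)
extra sum-of-squares F(4,880) = 1084.4, p = 0.00e+00
median extension onset: control 8.00 hpf, delayed 8.33 hpf
control: planted onset 8.0 hpf -> estimated 8.00 hpf (p = 4.9e-64); median persistence 0.35, median straight-line speed 0.137 um/min
precocious: planted onset 7.5 hpf -> estimated 7.50 hpf (p = 2.1e-56); median persistence 0.38, median straight-line speed 0.156 um/min
2^-ddCt: mutant sumf2 at 0.117x the wild-type level
disaccharides: D2S6 at 3.0 pmol (5.0% of total HS)
alignment: 70.0% identity, 85.0% similarity over 20 columns
```

Reading this: the screen's hard fold thresholds keep false positives at
zero but, at this noise level, recover 8 of the 20 planted triggers (see
`docs/methods.md` on operating characteristics); the planted 0.6-hpf V50
shift between explant groups is recovered and decisively detected by the
F test; both planted convergence onsets are recovered to the frame.  Each
script writes its tables (audit TSV, fits, onsets, per-track statistics)
under `results/`.

The same stages are scriptable through the `cet` CLI
(`cet simulate|screen|shape|kinetics|quant|run --config config.yaml`), with
expression TSV (`<stage>|<condition>|<replicate>` columns plus a
stage→hpf YAML sidecar), tracker-convention CSV
(`TRACK_ID/FRAME/POSITION_X/POSITION_Y`), label-mask TIFF, and tidy CSV
outputs; every run emits a manifest with input checksums and per-stage
counts.

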