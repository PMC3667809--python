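# iftspread

Seed-based segmentation and spreading-kinetics quantification for
fluorescence time-lapse microscopy, built around the **image foresting
transform (IFT)**.

## The problem

In TIRF (total internal reflection fluorescence) microscopy only the
~100 nm of the cell closest to the coverslip is illuminated, so the
fluorescent footprint of a labelled cell reports its cell–substrate
contact area. Recording a field of cells every few seconds as they land
and spread yields a 2D+t stack from which each cell's contact area A(t)
— its *spreading kinetics* — can be read, provided every pixel of every
frame is correctly classified as background or as one specific cell.
That classification is non-trivial: cells carry widely varying dye
loads, so a single global threshold fails.

## The method

The stack is interpreted as a graph: every pixel of every frame is a
node, connected to its in-plane neighbours (4- or 8-connectivity) and
optionally to the same pixel in adjacent frames. The user marks a few
*seed* pixels per cell (each cell one unique positive label, in one or
several slices) and a few background seeds (label 0). Each arc (p, q)
weighs the local dissimilarity |I(p) − I(q)|, scaled for cross-frame
arcs. Every node then receives the label of the seed that reaches it
along the minimum-cost path,

- **max-arc** cost (default): cost(π) = max arc weight along π — the
  watershed-like rule, robust to gradual intensity ramps inside a
  footprint; or
- **additive** cost: cost(π) = Σ arc weights.

Computing all optimum paths at once is the image foresting transform: a
Dijkstra-style scan that grows a minimum-cost path forest rooted at the
seeds. Ties are broken by the deterministic lexicographic key
(cost, hop count, seed order, predecessor index), so results are exactly
reproducible and independent of traversal order. From the label volume,
per-cell areas are counted per frame, calibrated to µm², exported as
CSV, and aggregated across cells into mean ± s.e.m. spreading curves;
a pooled two-tailed Student's t-test compares groups. Small companion
numerics cover western-blot loading normalisation (actin reference lane
set to 1) and R/R₀ baseline normalisation of paired fluorescence
traces.

A synthetic-phantom generator produces spreading stacks with exact
ground truth (logistic area growth A(t) = A_max / (1 + e^(−k(t−t₀))),
per-cell intensities, rippled boundaries, Poisson + Gaussian noise), so
the whole pipeline is testable without any microscope data.

## Worked example

`examples/01_phantom_segmentation.py` simulates a two-cell stack,
seeds it, segments it and scores the result:

```
phantom: (12, 96, 96) stack, 16 seeds (2 cells + background)
Dice vs truth: min 0.9978, mean 0.9999 (1.0 = pixel-perfect overlap)
cell 1: contact area grows 57.8 -> 87.5 um^2 over 55 s (max error vs truth 0.0 um^2)
cell 2: contact area grows 51.2 -> 78.2 um^2 over 55 s (max error vs truth 0.2 um^2)
```

Dice is the overlap 2|A∩B|/(|A|+|B|) between each segmented cell and
its ground-truth region — here essentially pixel-perfect despite shot
and read noise — and the per-cell traces are the contact areas the tool
would export for a real recording. `examples/02_spreading_curves.py`
shows cohort aggregation, logistic fitting and group comparison:

```
control cohort, frame 59 (295 s): n=12, mean area 379.0 ± 10.4 um^2 (s.e.m.)
logistic fit of the mean curve: A_max=400.1 um^2, k=0.0149 /s, t0=97 s
control vs treated, mean area over the last 10 frames: t=10.93, two-tailed p=2.35e-10 (significant at p<0.05)
```

`examples/03_blot_and_ratio_numerics.py` demonstrates the blot and
R/R₀ normalisations.

## Command line

The same pipeline is scriptable from a shell:

```bash
iftspread simulate --output-dir phantom --seed 7          # synthetic bundle
iftspread segment phantom/phantom.tif phantom/seeds.csv \
    --output-dir seg --pixel-size-um 0.5                  # label TIFF + provenance
iftspread quantify seg/labels.tif --output areas.csv --pixel-size-um 0.5
iftspread curves areas.csv --output curve.csv             # mean ± s.e.m. per frame
iftspread validate phantom/phantom.tif phantom/seeds.csv  # seed-file check
```

Seeds are CSV (`t,row,col,label`) or JSON; stacks are single-channel
multi-page TIFF; calibration always comes from flags, never from TIFF
tags.

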