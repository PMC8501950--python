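# qibckit

Quantitative image-based cytometry (QIBC) in plain Python, with a synthetic
ground-truth data generator so every stage is testable offline, plus
non-overlapping degenerate DNA motif counting for genome scans.

The pipeline mirrors a standard single-cell microscopy analysis:

1. **synthetic** — generate ground-truth nuclei scenes (G1/S/G2 population
   with 2C–4C DNA content, genotoxin condition presets, planted touching
   pairs) and render them to multi-channel 16-bit images with background and
   Gaussian noise; also seeded DNA sequence generation and motif planting.
2. **segmentation** — nuclei from the DAPI channel: Gaussian smoothing,
   two-class Otsu thresholding (256-bin histogram, exact tie-breaking toward
   the lower threshold, optional log-domain split), hole filling, watershed
   on the negative distance transform seeded at distance maxima, size and
   border filtering.
3. **quantification** — per-nucleus area, centroid, integrated DAPI and raw
   per-channel mean intensities into a `CellTable` (CSV).
4. **gating** — 2C–4C interphase filter around the G1 peak of the total-DAPI
   distribution (leftmost dominant mode of the log-total histogram),
   marker-based S-phase calling (fixed or control-quantile threshold), and
   seeded equal-size subsampling across conditions.
5. **viz** — DNA-content scatter plots coloured by a third marker and
   jittered dot-bar plots with population-mean bars; every figure writes a
   CSV data sidecar so plotted values are machine-checkable.
6. **motifs** — greedy non-overlapping counting of degenerate motifs
   (A/C/G/T/N; motif `N` matches any base, sequence `N` matches nothing)
   over strings and FASTA files, with per-record and aggregate density
   reports.

## CLI

One entry point, `qibc`, with subcommands:

```bash
# synthetic field: TIFF per channel + ground-truth CSV + scene JSON
qibc simulate --config scene.yaml --out sim/ --seed 1

# nuclei label mask from the DAPI channel
qibc segment --dapi sim/scene-1_DAPI.tif --out mask.tif

# per-nucleus feature table
qibc quantify --mask mask.tif \
    --channels "DAPI=sim/scene-1_DAPI.tif,EdU=sim/scene-1_EdU.tif" \
    --condition untreated --out cells.csv

# 2C-4C interphase gate
qibc gate --cells cells.csv --out gated.csv --report gating.json

# figures (PNG + SVG + .data.csv sidecar)
qibc plot scatter --cells gated.csv --out fig.png
qibc plot dotbar  --cells gated.csv --out bars.png

# motif scan (FASTA, optionally gzipped; regex record filter)
qibc motif --fasta genome.fa --motif TNTC \
    --filter 'chr([1-9]|1[0-9]|2[0-2])$' --out report
```

`scene.yaml` mirrors `SceneConfig` field for field, e.g.:

```yaml
field_shape: [1024, 1024]
n_nuclei: 100
radius_range: [10, 14]
fraction_g1: 0.5
fraction_s: 0.3
fraction_g2: 0.2
condition: dart_wt      # untreated | dart_wt | dart_e160a | hu | cpt | mms
noise_sd: 50
seed: 1
```

Condition presets shift per-phase channel means in the direction of the
corresponding genotoxin biology (replication slowdown in S, damage markers
in S, phase-independent ADP-ribose under alkylation); their magnitudes are
qualitative emulation knobs defined in `qibckit/presets.py`, not measured
values. Synthetic background levels and dynamic range are likewise
arbitrary defaults.

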