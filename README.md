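# mechanoscape

Solid tumors stiffen as they grow: lysyl-oxidase (LOX) crosslinking packs
collagen into thick, linear, aligned fibers, and the resulting dense matrix
is a physical barrier to the T cells that immunotherapies depend on.
Quantifying that chain — macroscale stiffness, microscale fiber
architecture, nanoscale tissue mechanics, and T-cell motility — requires a
stack of measurements that are usually analyzed with ad-hoc scripts.
`mechanoscape` packages that quantification chain as a tested Python
library for researchers working on tumor mechanics and immune infiltration:

- **Stiffness maps** (shear-wave elastography): per-ROI mean/min/max/SD in
  kPa, the stiff-area fraction (pixels strictly above a 40 kPa cut-off),
  normalized stiffness time series, and caliper tumor volume
  `V = x·y²/2` (x ≥ y the perpendicular diameters).
- **Collagen fiber architecture** (SHG microscopy): a ridge/skeleton fiber
  tracer with per-fiber width, length, orientation, the curvature ratio
  `CR = A/B` (arc length A over chord B; 1 = fully linear), the per-image
  orientation coefficient of variation (SD/mean of fiber angles; smaller =
  more aligned), the Sirius-red red-orange (thick, packed fiber) area
  percentage, and crosslink autofluorescence in SHG-positive regions.
- **AFM nanoindentation**: contact-point estimation on raw approach curves
  and Young's moduli from the Hertz sphere model
  `F = (4/3)·E/(1−ν²)·√R·δ^{3/2}`, pooled into per-sample distributions.
- **T-cell tracks**: the 15 µm depth exclusion and the strict >10%-of-
  recording duration filter, then speed (µm/min), displacement (µm) and
  straightness (displacement/path length) per track, plus regional cell
  densities (cells/mm²).
- **Statistics**: Student's t / Mann–Whitney, one-way ANOVA /
  Kruskal–Wallis with Dunn's post-hoc, and per-group OLS fits of motility
  against mean tumor stiffness (slope, intercept, Pearson r).
- **Synthetic data**: seeded generators with exact ground truth for every
  stage — stiff-patch stiffness maps, rendered fiber fields, Hertzian force
  curves, persistent-random-walk tracks — so the whole chain is validated
  end to end without animal data.

## Worked example

Simulate a two-arm cohort (8 control subjects with many 60 kPa patches and
slow, tortuous T cells; 8 LOX-inhibited subjects with few soft patches and
faster cells), quantify it, and fit motility against stiffness:

```
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_quantify_cohort.py --seed 1
python analysis/03_correlate_motility.py --seed 1
```

which prints

```
         mean_stiffness_kPa  stiff_fraction  mean_speed_um_per_min
group
bapn                 11.646           0.024                  3.625
control              21.124           0.197                  2.258
pooled: slope -0.175 µm/min per kPa, r = -0.875 (n = 16)
```

The control arm is roughly twice as stiff, carries ~20% stiff-area
fraction, and its T cells move ~1.4 µm/min slower; the pooled fit recovers
the inverse stiffness–motility relation (negative slope, r = −0.88) that
the chain is designed to detect.  `analysis/04–06` benchmark the fiber
tracer, the Hertz fit and the track statistics against the generators'
ground truth (median width error ≈ 4.7%, length error ≈ 0.7%, noiseless
modulus recovery to machine precision, speed recovery within 0.4%).

The same operations are available as a CLI for real data
(`mechanoscape stiffness|fibers|siriusred|afm|tracks|correlate|simulate|run`),
reading TIFF/CSV images, two-column force-curve CSVs and track tables.

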