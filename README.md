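# aoflio

Phasor-based analysis of adaptive-optics fluorescence lifetime
ophthalmoscopy (AOFLIO) data, for researchers studying photoreceptor
function at cellular resolution.

In vivo two-photon AOFLIO records a time-correlated single-photon-counting
(TCSPC) decay histogram at every pixel of a retinal image.  Fitting those
decays with a biexponential d(t) = a₁e^(−t/τ₁) + a₂e^(−t/τ₂) and comparing
mean lifetimes τ_m = (a₁τ₁ + a₂τ₂)/(a₁ + a₂) distinguishes rods from cones
but *not* S cones from M/L cones — their τ_m distributions overlap.  The
phasor method does distinguish them: each region of interest's summed decay
is mapped to the coordinate pair

    g = Σ d[k] cos(ω t_k) / Σ d[k],   s = Σ d[k] sin(ω t_k) / Σ d[k]

at the laser repetition frequency (ω = 2π·80 MHz), corrected for the
instrument response by complex division.  Because the phasor weights decay
components by intensity (a_iτ_i) instead of amplitude, cone classes with
identical τ_m can still separate into distinct clusters: a smaller Cluster 1
(putative S cones, nearer the origin), a larger Cluster 2 (M/L cones), and
rods nearest (1, 0).

The package implements the full pipeline — decay-cube I/O and co-alignment,
ROI aggregation, IRF-deconvolved phasors, k-means-seeded Gaussian-mixture
clustering with S-cone calling, biexponential fitting (Poisson maximum
likelihood), hypofluorescent-cone detection, confusion metrics, paired
Hotelling's T² and ICC statistics — plus a synthetic photoreceptor-mosaic
simulator with complete ground truth, including a selective S-cone
photodamage mode, that stands in for in vivo data.  See
[docs/methods.md](docs/methods.md) for the model details.

## Worked example

Simulate one retinal location, image it "twice", and check that phasor
clustering finds the same S cones on both days (the repeat-imaging
paradigm), then damage the S cones and check that the baseline Cluster-1
call predicts which cones go dark (the damage paradigm):

```python
from aoflio import RunConfig, run_paradigm1, run_paradigm2

cfg = RunConfig(scene_seed=1)           # 253 x 300 px, ~330 cones, 12% S
r1 = run_paradigm1(cfg)
r2 = run_paradigm2(cfg)
```

With the default configuration this prints (via the fields shown):

```
cones matched:            333
pct Cluster 1 day1/day2:  12.01 / 12.01
repeatability sens/spec:  100.0 / 100.0
cluster means day1:       C1 (0.634, 0.376)   C2 (0.821, 0.339)
rod mean day1:            (0.903, 0.243)
P2 dark cones:            37 of 40 damaged
prediction sens/spec:     92.5 / 100.0
dark-cone delta_g:        +0.169
```

Reading this: 12% of cones fall in the smaller phasor cluster, the same
cones on both days (sensitivity/specificity of the day-2 call against day 1);
Cluster 1 sits left of Cluster 2 in the phasor plane and rods sit nearest
(1, 0).  After selective damage, 37 of the 40 true S cones turn
hypofluorescent, 92.5% of baseline Cluster-1 cones darken, no Cluster-2
cone does, and the dark cones' phasor shifts right (Δg > 0), toward shorter
lifetimes.

The same steps are available from the shell:

```bash
flio simulate --seed 3 --out scene.h5
flio phasor   --cube scene.h5 --mask scene.mask.tif --out phasors.csv
flio cluster  --phasors phasors.csv --out clusters.csv
flio paradigm1 --out-dir runs/p1 --figures
```

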