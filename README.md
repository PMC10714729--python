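# biofilmvol

Quantification of multispecies biofilm structure from multichannel confocal
z-stacks.

Mixed-species biofilms — e.g. *Stenotrophomonas maltophilia*,
*Pseudomonas aeruginosa*, *Staphylococcus aureus* and *Candida albicans*
growing together on a surface — are imaged by confocal laser scanning
microscopy with one fluorophore per species. Turning those stacks into
numbers (how much of each species is present, and where it sits in the
vertical profile of the biofilm) requires dealing with spectral
bleed-through between channels and with an objective, automatic
segmentation. `biofilmvol` implements that pipeline for microbiologists
analysing such experiments:

1. **Crosstalk calibration.** For every ordered fluorophore pair, the
   bleed-through coefficient k[i→j] is the mode of the per-voxel ratio
   I_unpopulated / I_populated over the foreground of a single-label
   control stack (an image containing only organism *i*).
2. **Crosstalk correction.** Mixed stacks are corrected subtractively,
   I'_j = max(0, I_j − Σ_{i≠j} k[i→j]·I_i), with full linear unmixing
   available behind a flag.
3. **Segmentation.** Each corrected channel is Gaussian-blurred and
   binarized at its global Li minimum-cross-entropy threshold.
4. **Quantification.** Segmented voxel volumes are summed per z-slice and
   in total, normalized to slice/stack volume, converted to species
   composition shares ("cell ratio" percentages, s_c = V_c / Σ V · 100),
   and averaged over replicate positions (mean ± sample SD). Welch's
   t-test compares total biovolumes between conditions; a layer-order
   descriptor reports bottom-to-top species ordering and sandwich-like
   arrangements.

Because such experiments rarely ship with ground truth, the package also
contains a synthetic scene generator: species occupancies built from
layers, microcolonies and hyphal tubes, rendered through a linear mixing /
PSF-blur / noise forward model with every random draw seeded. Every stage
of the pipeline can therefore be validated against exact truth.

## Worked example

A "sandwich" biofilm — species A colonizing the bottom and top bands with
species B in between — rendered with 5% noise and 5% mutual crosstalk,
then pushed through the full pipeline:

```python
import biofilmvol as bv
from biofilmvol.pipeline import analyze_stack
from biofilmvol.synthetic import calibration_controls

spec, model = bv.preset("dual_sandwich")
truth = bv.make_scene(spec)
stack, _ = bv.render(truth, model)

controls = calibration_controls(truth.labels, model, seed=3)
matrix = bv.build_crosstalk_matrix(controls)
print("estimated crosstalk k[A->B] =", round(matrix.k[0, 1], 4))

cfg = bv.ExperimentConfig(channel_labels=truth.labels)
masks, comp, profiles = analyze_stack(stack, matrix, cfg)
for lab, share, true in zip(comp.labels, comp.shares_percent, truth.shares_percent):
    print(f"{lab}: recovered {share:.1f}%  (truth {true:.1f}%)")
for s in bv.layer_order(masks):
    tag = "  <- sandwich" if s.sandwich else ""
    print(f"{s.channel}: mean z {s.mean_z:.1f}, thirds "
          f"{s.bottom_share:.2f}/{s.mid_share:.2f}/{s.top_share:.2f}{tag}")
```

prints

```
estimated crosstalk k[A->B] = 0.0469
A: recovered 52.0%  (truth 52.0%)
B: recovered 48.0%  (truth 48.0%)
A: mean z 21.7, thirds 0.62/0.12/0.27  <- sandwich
B: mean z 27.5, thirds 0.25/0.75/0.00
```

The calibrated coefficient sits a histogram-bin away from the true 0.05;
both species' volume shares are recovered to the decimal; and the
layer-order descriptor flags A — and only A — as bracketing the other
species (its bottom-third and top-third occupancy shares both exceed its
middle-third share).

The same stages are available from the shell for file-based batch work:

```sh
biofilmvol simulate --preset dual_sandwich --out-dir scene/
biofilmvol calibrate --control A=ctlA.tif --control B=ctlB.tif --config cfg.yaml --out k.csv
biofilmvol run manifest.yaml --config cfg.yaml   # full batch with CSV/JSON outputs
```

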