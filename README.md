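# tubulometry

Quantitative 3D morphometry of renal tubules and glomeruli for
nephrotoxicity studies — the image-analysis side of a
gentamicin-induced acute kidney injury read-out, from segmented label
volumes to group statistics.

## The problem

Aminoglycoside antibiotics such as gentamicin damage the proximal tubule
and the glomerulus. In larval-zebrafish and mouse models the damage is
visible in 3D imaging (synchrotron microtomography at sub-μm voxels,
confocal z-stacks of eGFP reporters) as: dilated tubular lumina, an
enlarged Bowman's space, and reduced reporter fluorescence. Turning those
images into numbers requires a reproducible measurement chain, which this
package implements:

- **Tubule morphometry** — from a binary lumen volume: topology-preserving
  3D thinning, the longest endpoint-to-endpoint geodesic through the
  26-connected skeleton graph as the centerline, a geodesic coordinate
  *s* along it (cumulative arc length, or a 1D Isomap embedding), signed
  alignment at the hairpin's turning point (TP, *s* = 0; negative toward
  the glomerulus neck, positive toward the cloaca), and spatially resolved
  caliber: inscribed-sphere diameter 2·EDT(*s*) from the Euclidean
  distance transform, and cross-section area from sub-voxel sampling of
  the plane normal to the local tangent.
- **Regional analysis** — profiles from many specimens aligned on the
  signed coordinate, split into proximal convoluted (PCT, *s* < 175 μm)
  and proximal straight (PST) segments, averaged in 25 μm bins, and
  compared control vs treated per bin with Welch's unpaired two-tailed
  t-test; whole-tubule length/diameter/volume are reported as fold change
  versus the control-group mean with box-plot five-number summaries.
- **Glomerulus metrics** — compartment ratio (Bowman's space + cellular) /
  cellular from 3D label volumes or 2D per-glomerulus area tables
  (ratio-of-means convention), plus tubular dilatation scored by an
  explicit rule: dilated ⇔ lumen area > k × control median (k = 2).
- **Fluorescence quantification** — maximum-intensity projection, mean
  signal intensity over pixels above one shared threshold (Otsu on the
  control projections by default), threshold-based glomerulus volume, and
  fold change normalized to the control mean.
- **Synthetic phantoms** — hairpin tubules with region-dependent radius,
  two-compartment glomeruli with exact voxel counts, and eGFP-like blob
  stacks, each emitting analytic ground truth; the entire pipeline is
  validated as parameter recovery against these.

## Worked example

```bash
python examples/tube_morphometry.py
```

```
ground-truth length :    401.5 um
measured length     :    402.9 um
measured mean diam  :     9.66 um (generator radius 5 um)
lumen volume        :    30989 um^3 (analytic 31536)
signed s range      : [-104.4, 298.5] um, TP at 0
mean cross-section  : PCT 76.1 um^2, PST 75.7 um^2 (circle pi*r^2 = 78.5)
```

The phantom is a hairpin lumen of radius 5 μm (neck 100 μm before the TP,
tail 300 μm after it, at 1 μm voxels). The measured geodesic length
(402.9 μm) and mean diameter (9.66 μm vs the analytic 10 μm) come from the
extracted centerline, the volume from voxel counting, and the
cross-section areas sit within a few percent of the analytic circle.

The other examples follow the same pattern: `damage_localization.py`
(binwise significance profile of a windowed radius increase — the
significant bins recover the −75…175 μm damage window and the PST region
stays non-significant), `fluorescence_si.py` (SI fold change recovering a
simulated 0.5× expression level exactly), and `glomerulus_ratios.py`
(compartment-ratio folds: 1.40 on the volume worked example, exact ratio
recovery on a phantom, 75% dilatation scoring).

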