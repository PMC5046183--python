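# nucleivote

Nuclei detection in histopathology tiles by **multi-pass adaptive symmetry
voting**, built for images with poor or uneven staining — the regime where
intensity- and model-based detectors fail because nuclei have ill-defined
boundaries and pale ("hollow") cores.

## Who this is for

Computational-pathology researchers who need nucleus *seed points* (centre
coordinates, e.g. to initialise watershed or level-set segmentation, or to
count/localise nuclei) on H&E or immunohistochemistry tiles at roughly
0.25 µm/pixel, together with a reproducible way to evaluate a detector
against manually labelled centres.

## The method

Every pixel on a nuclear edge casts votes into a fan-shaped *active voting
area* `A(x, y; r_min, r_max, α, δ)` along its inverse-gradient direction α
(for dark nuclei on a bright background, the inverse gradient points into
the nucleus). Votes are weighted by an oriented Gaussian kernel centred at
the radial midpoint of the fan, and accumulate into a vote image `V_i`
whose maxima mark putative nuclear centres. Voting runs `N` passes: after
each pass every edge pixel re-aims at the highest-vote location inside its
own fan and the angular aperture halves (`δ_i = δ_max / 2^(i−1)`), so votes
sharpen onto consistent centres. A global threshold `T_D` (Otsu) binarises
the normalised `V_N`; connected-component centroids are the detections.
Single-pass voting (SPV) is the `N = 1` special case.

The *adaptive* part targets a classic failure mode: an unevenly stained
nucleus has a pale core, so its **inner** contour carries inverse gradients
pointing *away* from the nucleus, casting spurious votes between nuclei.
Each 8-connected edge fragment `E_i` is summarised by the centroid `C_i` of
its filled convex hull; a pixel is **invalid** when the angle θ between its
inverse gradient and the pixel→`C_i` bearing exceeds π/2. Two refinement
strategies handle invalid pixels before voting:

* **GS1** — suppress them (remove from the vote);
* **GS2** — reverse them (they vote inward instead).

Detection quality is scored by greedy one-to-one matching of detections to
labelled centres within 15 px (≈ 3.68 µm at 0.2455 µm/px), precision
`P = TP/(TP+FP)`, recall `R = TP/n_GT`, `F = 2PR/(P+R)`, and the
precision-recall curve traced by sweeping `T_D` from 0 to 1 in steps of
0.05 (AUC by trapezoid).

## Worked example

```bash
# a clean phantom: 10 dark disks (radii 10-16 px) with ground truth
nucleivote phantom solid --n 10 --seed 1 --size 256 --out img.png --gt gt.csv
# detect with GS2 refinement (defaults: r_min=1, r_max=40, sigma=4, N=3)
nucleivote detect img.png --strategy gs2 --out seeds.csv
# score against the ground truth at the 15 px radius
nucleivote evaluate --det seeds.csv --gt gt.csv --radius 15
```

which prints

```
10 seeds -> seeds.csv
{
  "n_gt": 10,
  "n_det": 10,
  "n_tp": 10,
  "n_fp": 0,
  "n_fn": 0,
  "precision": 1.0,
  "recall": 1.0,
  "f_measure": 1.0
}
```

i.e. all ten nuclei found with no false detections; the seed CSV holds one
`x,y,score` row per detection (0-based pixel coordinates, mean vote value).
The same library surface is available in Python:

```python
from nucleivote import detect, RunConfig
result = detect(image_rgb, RunConfig(refine_strategy="gs2"))
result.seeds.centers   # (N, 2) array of (x, y)
```

On the hollow-**cluster** phantom — three poorly stained nuclei whose faint
outer boundaries evade the edge detector while their pale-core inner
contours vote outward — plain multi-pass voting (`--strategy none`) places
its detections in and around the void between the nuclei (8 false
positives, no true centres at the Otsu threshold), whereas `--strategy gs2`
finds exactly the 3 true centres. This is the false-positive mechanism the
gradient refinement exists to remove.

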