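# mr2sct

Tissue-segmentation-based synthetic CT (sCT) generation from a single
contrast-enhanced T1-weighted MR head volume, for MR-only radiotherapy
treatment planning of the brain.

MR voxel intensities carry no electron-density (ED) information, so an MR
scan alone cannot drive dose calculation; worse, air and cortical bone are
both signal voids on T1 images, and trabecular bone, brain, CSF, muscle
and fat overlap each other in intensity. `mr2sct` separates these tissues
with a chain of rules that use only *relative* intensity statistics,
anatomy and shape — no atlas, no registration, no training data — and then
maps each tissue's voxels into a calibrated Hounsfield-unit (HU) range.

## Method in brief

1. **Air** — the only manual input: closed air-region contours (sinuses,
   airway) on ≤ 12 axial slices. They are interpolated through the stack
   (linear interpolation of signed distance transforms), the air noise
   floor μ_Air, σ_Air is estimated robustly inside the outlined region,
   and enclosed soft tissue above μ_Air + 3σ_Air is subtracted.
2. **Brain / CSF** — a white-matter reference voxel is found as the
   maximum of the uniformity U = μ/σ in a 1 cm × 1 cm window on the middle
   coronal slice; its window mean is `wmIntensity`. The statistical brain
   range is [0.53, 1.35]·wmIntensity; initial brain is grown 3D from the
   reference within [0.7, 1.2]·wmIntensity, barred by per-slice Canny
   edges whose gaps are bridged with discrete straight segments. CSF
   statistics come from the most uniform dark 5 mm window inside the
   brain; a skull mask grown from air-dark rim seeds with
   [0, μ_CSF + 2σ_CSF] (plus everything external to it) bars CSF growing
   (μ_CSF ± 2σ_CSF) and the final brain growing.
3. **Eyes** — connected regions below 0.7·wmIntensity in an anatomical box
   anterior to the brain, filtered by midline contact, volume relative to
   a 4 cm sphere, and an axis-extent sphericity rule.
4. **Bone** — cortical bone is grown with the air window from the skull
   rim seeds; trabecular bone statistics come from cavities enclosed in
   the cortical mask and further trabecular voxels are recovered within
   5 mm of cortical bone inside μ ± 2σ.
5. **Soft tissue** — the residual is split per axial slice (with one
   adjacent slice of context each side) into muscle [min_soft, μ_soft],
   fat (μ_soft, μ_soft + 2σ_soft] and contrast artifact above.
6. **ED mapping** — per-tissue transforms to HU:

   | tissue | MR window | transform | HU |
   |---|---|---|---|
   | air / background | all | bulk | −1000 |
   | cortical bone | μ ± 2σ | inverse linear | [700, 1100] |
   | trabecular bone | μ ± 2σ | inverse linear | [500, 700] |
   | brain | μ ± 2σ | linear | [40, 75] |
   | CSF | all | bulk | 45 |
   | eye | all | bulk | 45 |
   | muscle | [min_soft, μ_soft + σ_soft] | inverse linear | [20, 80] |
   | fat | [μ_soft + σ, μ_soft + 2σ] | inverse linear | [−70, −20] |
   | contrast | all | bulk | 0 |

Evaluation against a co-registered CT: directed external-skull contour
distance (bone = HU ≥ 200) on the widest axial/coronal/sagittal slices,
Dice coefficients, and ME/MAE of HU over standard regions (body > −400 HU
in both volumes, air < −800 HU in both, soft tissue −100…200 HU).

A digital head phantom (`mr2sct.phantom`) generates paired MR-like and
ground-truth CT volumes — cortical tables with a diploic layer,
subarachnoid CSF film, ventricles, fat-socketed eyes, sinus/airway, bias
field and Rician noise — so the whole pipeline is testable end to end
without any data download.

## Worked example

```sh
mr2sct phantom make --size 128 --spacing 1.5 --seed 0 -o phantom/
mr2sct run --mr phantom/mr.nii --air phantom/air_contours.json -o out/
mr2sct evaluate --sct out/sct.nii --ct phantom/ct.nii --labels out/labels.nii -o metrics/
```

The `run` step prints the per-stage voxel counts, e.g.

```
{
  "stage_voxels": {
    "body": 565089, "air": 1194, "skull": 416215, "csf": 2031,
    "brain": 143360, "eyes": 12128, "cortical": 102813, "trabecular": 49397
  }
}
```

meaning the 128³ phantom head contains ~565k body voxels of which 143k
were labelled brain, two eyes of ~6k voxels each were found, and the
cortical/trabecular split recovered the skull. `evaluate` then reports,
for the synthetic CT against the phantom's ground-truth CT, the external
skull contour distance (here well below one voxel, since the geometry is
shared), bone Dice ≈ 0.99, and per-region mean / mean-absolute HU errors.

The same three commands work on clinical data: pass a NIfTI volume or a
DICOM series directory to `--mr`, and either the JSON contour schema
documented in `mr2sct.io_formats` or a DICOM RTSTRUCT with an ROI named
`AIR` to `--air`.

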