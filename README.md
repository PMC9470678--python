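# fibroquant

Quantification of lymphedema-induced subcutaneous fibrosis from paired-limb
axial CT slices.

## Scientific problem

Chronic extremity lymphedema remodels the subcutaneous compartment: fat is
progressively replaced by reticular fibrotic tissue. On CT this shows up as a
"honeycomb" of soft-tissue-density strands inside the subcutaneous fat of the
affected limb. Because both limbs of a patient are imaged in the same axial
slice, the healthy contralateral limb is a built-in control, and the fibrosis
burden can be expressed as affected-vs-unaffected pixel-count indices rather
than absolute densities.

`fibroquant` implements the full measurement chain:

1. **CT I/O** (`fibroquant.ct_io`) — read axial slices from DICOM, NIfTI or
   16-bit PNG (+ JSON sidecar), apply the HU calibration, center-crop/pad.
2. **Rule-based labeling** (`fibroquant.rule_label`) — label every pixel as
   one of five classes — air, muscle/water, fat, skin, fibrosis — using
   thresholds and morphology:
   - body = largest connected component per limb half of pixels > −200 HU,
     holes filled;
   - skin = body minus its erosion by a disk of radius 2 px;
   - muscle/water = interior pixels with HU in [−34, 26] (inclusive);
   - the remaining subcutaneous "donut" is split into fat vs fibrosis by an
     exact two-cluster 1-D k-means on HU values (lower-mean cluster = fat).
3. **Segmentation model** (`fibroquant.seg_model`) — a compact NumPy
   encoder–decoder network (SegNet-style max-pooling-index unpooling,
   hand-written backprop, Adam) that learns the five-class labeling from
   rule-labeled images, plus patient-grouped train/val/test splitting and the
   shift × rotation × reflection augmentation scheme (3 038 variants per
   image).
4. **Metrics** (`fibroquant.seg_metrics`) — per-class accuracy, IoU, Dice
   (DSC) and boundary-F1 from accumulated confusion matrices.
5. **Fibrosis indices** (`fibroquant.indices`) — four affected/unaffected
   indices and their 19 patient-level subindices:
   - Index 1 = (fat+fibrosis affected) / (fat+fibrosis unaffected),
   - Index 2 = (fibrosis affected − fibrosis unaffected) / (unaffected limb
     pixels),
   - Index 3 = fibrosis affected / fibrosis unaffected,
   - Index 4 = total affected-limb fibrosis pixels;
   Indices 1–3 are aggregated as Mean and Sum over all / proximal / distal
   slices.
6. **Clinical statistics** (`fibroquant.clinical_stats`) — bioimpedance ratio
   (BEI) and circumference-difference ratio (SCDR) reference measures,
   normality checking with log fallback, and partial correlation of each
   subindex with each reference measure (controlling the others), with
   significance stars.
7. **Phantom generator** (`fibroquant.phantom`) — first-class synthetic data:
   paired-limb slices with a planted, exactly-counted fibrosis fraction, and
   whole cohorts with planted index↔reference-measure correlations, used to
   validate every stage end-to-end.

## Worked example

Label a synthetic 4-slice patient, score the labeling against the generating
ground truth, and compute the fibrosis subindices:

```python
from fibroquant.phantom import PhantomSpec, make_patient
from fibroquant.rule_label import RuleParams, label_slice
from fibroquant.indices import count_limb_pair, aggregate_subindices
from fibroquant.seg_metrics import accumulate_confusion, ConfusionMatrix, class_dsc
from fibroquant._constants import FAT, FIBROSIS

# a 4-slice synthetic patient: affected limb in the image-left half
spec = PhantomSpec(image_size=64, limb_radius=13, muscle_radius=6,
                   skin_thickness=2, reticulation_period=6,
                   fibrosis_fraction_affected=0.25, hu_noise_sd=0, seed=11)
pairs, gt_counts = make_patient(spec, n_slices=4, landmark=2)

params = RuleParams(skin_erosion_radius=2)
cm = ConfusionMatrix()
counts = []
for (sl, gt), gtc in zip(pairs, gt_counts):
    lm = label_slice(sl, params)                  # rule-based 5-class labeling
    cm = accumulate_confusion(gt, lm, cm)
    # the image-left half is the patient's *right* limb (radiological view)
    counts.append(count_limb_pair(lm, affected_side="right", region=gtc.region))

print(f"fat DSC      : {class_dsc(cm, FAT):.3f}")
print(f"fibrosis DSC : {class_dsc(cm, FIBROSIS):.3f}")
table = aggregate_subindices(counts)
for name in ("Index 1 Mean", "Index 2 Mean", "Index 3 Mean", "Index 4"):
    print(f"{name:<13}: {table[name]:.4f}")
```

Output:

```text
fat DSC      : 1.000
fibrosis DSC : 1.000
Index 1 Mean : 1.0000
Index 2 Mean : 0.1045
Index 3 Mean : 4.9774
Index 4      : 324.0000
```

On this noiseless phantom the rule labeler recovers the planted fat and
fibrosis masks exactly; Index 2 > 0 and Index 3 ≈ 5 reflect the planted
25 % vs 5 % fibrosis fractions in the two limbs.

A `fibroquant` command-line interface exposes the same chain on files:
`fibroquant simulate`, `segment`, `evaluate`, `indices`, `train`
(see `fibroquant --help`).

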