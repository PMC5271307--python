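# neotemplate

Construction of a **neonatal bimodal MR–CT head template**: an unbiased CT
head template built in the stereotaxic space of an MR template, so that the
pair jointly describes both the soft tissues (from MR) and the cranial
bones, fontanels and sutures (from CT) of the newborn head.

## Why

MR templates of the neonatal brain are the standard reference for spatial
normalization, but bone gives almost no MR signal, so they cannot describe
the skull — and in neonates the skull is special: the bone plates are
unfused, separated by membranous fontanels and sutures that strongly affect
EEG/NIRS source modelling and skull development studies. CT shows bone with
excellent contrast but says little about soft tissue. A CT template *in the
same space* as an MR template gives both at once.

Registering neonatal head CT to an MR template is hard for two compounding
reasons: the modalities have inverted contrast (bone bright in CT, dark in
MR), and the extracranial tissues — thin scalp, discontinuous skull,
pillows, pacifiers, feeding tubes, a −3000 HU reconstruction rim — are far
more variable than the intracranial content. The pipeline therefore:

1. **Preprocesses** each CT: Otsu threshold + morphology extract a head
   mask; everything outside it becomes air (−1000 HU), removing the rim and
   extracranial clutter; a three-segment intensity transform maps
   `[-1000,-100]→[0,900]`, `[-99,100]→[901,3100]` (soft-tissue contrast
   expanded ~11×) and `I>100 → I+3000`, making CT intensities MR-like while
   staying exactly invertible.
2. **Extracts the intracranial region** with a pair of coupled level-set
   surfaces: an exterior surface shrinks from the head boundary, an
   interior surface grows from inside; both stop at bone edges, and where
   bone is absent (fontanels) they meet and stall without crossing, closing
   the intracranial boundary across the gaps.
3. **Registers in two steps**: the intracranial CT to an MR intracranial
   template (affine + symmetric diffeomorphic, mutual information), the
   resulting field applied to the whole CT (CT′), then a whole-head affine
   to the full MR template (CT″). Step 1 exploits the stable intracranial
   anatomy; step 2 fixes the extracranial fit.
4. **Builds the template groupwise**: all subjects are registered to the
   evolving template; its appearance is updated as the voxelwise mean of
   the warped subjects and its shape by a small diffeomorphism toward the
   population average, starting from the MR template so the result stays in
   MR space. Two iterations suffice.
5. **Validates** with mutual information
   `I(X,Y) = Σ p(x,y) log [p(x,y)/(p(x)p(y))]` against the 2 mm-FWHM
   smoothed template, and all-pairs cross-correlation of normalized test
   images.

Everything is exercised end-to-end on synthetic neonatal head phantoms —
nested ellipsoids with a bright skull shell cut by fontanel sectors, CT/MR
channels with inverted contrast, nuisance blobs and the −3000 HU rim —
generated with known ground-truth masks and deformations, so every stage is
testable without clinical data.

## Worked example

```python
import numpy as np
from neotemplate import (PhantomSpec, generate_head_phantom, generate_population,
                         extract_head_mask, clean_background, transform_ct_intensity,
                         segment_intracranial, dice, mutual_information,
                         build_mr_intracranial_template, two_step_register,
                         PipelineConfig, AffineParams, SynParams, LevelSetParams)

spec = PhantomSpec(grid_shape=(48, 48, 48), spacing=(2.5, 2.5, 2.5),
                   head_radii=(40.0, 48.0, 44.0), seed=7)
mean = generate_head_phantom(spec)

head = extract_head_mask(mean.ct)
ct_clean = clean_background(mean.ct, head)
print(f"head-mask Dice vs ground truth: {dice(head, mean.masks['head']):.4f}")
print(f"background after cleaning: min = {ct_clean.data.min():.0f} HU")

icc, pair = segment_intracranial(ct_clean, head, inner_erosion_mm=16.0)
print(f"intracranial Dice vs ground truth: "
      f"{dice(icc, mean.masks['intracranial']):.4f}"
      f"  (converged after {pair.iteration} iterations)")

mr_icc = build_mr_intracranial_template([mean.mr], [mean.masks['intracranial']])
cfg = PipelineConfig(
    affine=AffineParams(levels=(4, 2), smooth_vox=(2.0, 1.0), max_iter=(60, 40)),
    syn=SynParams(levels=(4, 2), smooth_vox=(2.0, 1.0), iterations=(40, 25)),
    levelset=LevelSetParams(max_iters=150), inner_erosion_mm=16.0)
subject = generate_population(spec, 1, seed=11)[0]
ct_pp, transform = two_step_register(subject.ct, mean.mr, mr_icc, cfg)
before = mutual_information(mean.mr, transform_ct_intensity(
    clean_background(subject.ct, extract_head_mask(subject.ct))), bins=32)
after = mutual_information(mean.mr, ct_pp, bins=32)
print(f"MI(CT, MR template): {before:.3f} before -> {after:.3f} "
      f"after two-step registration")
```

prints

```
head-mask Dice vs ground truth: 0.9995
background after cleaning: min = -1000 HU
intracranial Dice vs ground truth: 0.9495  (converged after 52 iterations)
MI(CT, MR template): 0.576 before -> 0.704 after two-step registration
```

The head mask overlaps the ground-truth head almost perfectly and the −3000
rim is gone (minimum exactly −1000 HU). The coupled level sets recover the
intracranial cavity at Dice 0.95 despite two fontanel gaps in the skull
shell. The two-step registration raises the CT–MR mutual information of a
randomly perturbed subject from 0.58 to 0.70 bits — the bimodal alignment
the template construction builds on.

For cohort-scale use, `run_template_pipeline` chains two-step registration
of every subject with groupwise template construction and evaluation, and
the `neotemplate` CLI (`preprocess`, `intracranial`, `register`,
`build-template`, `evaluate`, `phantom`, `run-all`) exposes each stage on
files.

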