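"""Compute the six evaluation metrics and the 0-100 challenge scores.

Compares a deliberately imperfect segmentation (shifted by one voxel)
against a cube ground truth, so every metric is non-trivial.
"""

import numpy as np

from tumorcut.core_types import LabelMask
from tumorcut.metrics import MANUAL_REFERENCE, evaluate_masks, ltsc08_score

truth = np.zeros((30, 30, 30), dtype=np.uint8)
truth[8:22, 8:22, 8:22] = 1
seg = np.roll(truth, 1, axis=0)  # one-voxel misregistration

rep = evaluate_masks(LabelMask(seg), LabelMask(truth), spacing=(1.0, 1.0, 1.0))
print(f"VOE  {rep.voe_pct:6.2f} %   (volumetric overlap error)")
print(f"RVD  {rep.rvd_pct:+6.2f} %   (negative would mean undersegmentation)")
print(f"ASD  {rep.asd_mm:6.2f} mm  (average surface distance)")
print(f"RMSD {rep.rmsd_mm:6.2f} mm")
print(f"MaxD {rep.maxd_mm:6.2f} mm")
print(f"DICE {rep.dice:6.3f}")
for key, score in rep.scores.items():
    print(f"  score[{key}] = {score:.1f}")
print(f"overall score {rep.overall_score:.1f}")

# the scoring anchors: zero error scores 100, average manual quality 90
manual = [ltsc08_score(v, MANUAL_REFERENCE[k]) for k, v in MANUAL_REFERENCE.items()]
print(f"manual-quality reference would score {np.mean(manual):.0f}")
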