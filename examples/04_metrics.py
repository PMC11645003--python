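"""The four segmentation metrics on simple geometry.

Computes Dice, Jaccard, 95th-percentile Hausdorff distance and average
surface distance for a predicted sphere that is slightly offset and eroded
relative to its reference.
"""

import numpy as np

from entroseg.evaluation import evaluate_masks

h = np.arange(24)
hh, ww, dd = np.meshgrid(h, h, h, indexing="ij")
gt = ((hh - 12) ** 2 + (ww - 12) ** 2 + (dd - 12) ** 2 <= 64).astype(np.uint8)
pred = ((hh - 13) ** 2 + (ww - 12) ** 2 + (dd - 12) ** 2 <= 49).astype(np.uint8)

report = evaluate_masks(pred, gt)
print(f"Dice    {report.dice:.4f}   (overlap ratio, 1 = perfect)")
print(f"Jaccard {report.jaccard:.4f}   (intersection over union; always <= Dice)")
print(f"95HD    {report.hd95:.2f} {report.units}  (95th percentile surface distance)")
print(f"ASD     {report.asd:.2f} {report.units}  (mean surface distance)")
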