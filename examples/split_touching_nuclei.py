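"""Separate two touching nuclei with the min-cut instance splitter.

Builds two disk-shaped nuclei fused by a thin neck, then splits the
binary foreground along the minimum edge cut of its pixel graph.
"""

import numpy as np

from interfish.instance_split import (
    SplitParams,
    find_instance_centers,
    l1_distance_transform,
    split_overlapping_nuclei,
)


def disk(shape, center, radius):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


mask = disk((60, 110), (30, 30), 15) | disk((60, 110), (30, 80), 15)
mask[29:32, 30:80] = True  # a 3-pixel-wide bridge between the nuclei

centers = find_instance_centers(l1_distance_transform(mask))
instances = split_overlapping_nuclei(mask, SplitParams(area_factor=0.5))

print(f"foreground pixels : {int(mask.sum())}")
print(f"centers found     : {centers}")
print(f"instances after split : {len(instances.instance_ids)}")
print(f"pixels conserved  : {bool((instances.labels > 0).sum() == mask.sum())}")
print(
    "# Deep maxima of the Manhattan distance map mark nucleus centers; the\n"
    "# 3-edge neck is the minimum cut, well under the flow limit of 60, so the\n"
    "# fused blob is relabeled as two nuclei without discarding any pixel."
)
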