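"""Classify a synthetic sample end to end: foci statistics, heuristic
image call, bootstrapped per-cell votes, and the sample-level rule.
"""

from interfish.classify_aggregate import (
    BootstrapConfig,
    bootstrap_sample_call,
    heuristic_classify,
    sample_rule_call,
)
from interfish.statfish import StatFishParams, copy_number_signal, detect_foci, image_statistics
from interfish.synthetic_fixtures import SimulationConfig, generate_field_image

config = SimulationConfig(n_nuclei=12, seed=11, class_mixture=(1.0, 0.0, 0.0))
image, mask, truth = generate_field_image(config)

params = StatFishParams()
signals = []
for nid in mask.instance_ids:
    nucleus = mask.labels == nid
    foci = detect_foci(image.channel("target"), nucleus, params)
    signals.append(copy_number_signal(foci, nucleus))

stats = image_statistics(signals)
call = heuristic_classify((stats["mean"], stats["variance"]))
print(f"copy number signal: mean={stats['mean']:.2f}%, variance={stats['variance']:.2f}")
print(f"heuristic image call: {call}  (HSR-like iff mean < 10 and variance < 64)")

# per-cell hard labels from the ground truth stand in for classifier output
labels = [t.class_label for t in truth]
fractions = bootstrap_sample_call(labels, BootstrapConfig(seed=0))
print(f"bootstrap win fractions: { {k: round(v, 2) for k, v in fractions.items()} }")
print(f"sample-level call: {sample_rule_call(fractions)}")
print(
    "# 100 majority votes over random 10-cell draws summarize the sample; the\n"
    "# fixed fraction thresholds (80%/80%/50%) then give one call per sample."
)
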