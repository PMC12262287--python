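"""Exercise the fixed distortion protocol on a synthetic field image.

Applies each of the five distortions (shrink to 0.8x, enlarge to 1.2x,
rotate 45 degrees, contrast -40%, contrast +40%) and reports how the
image-level quality score responds.
"""

from interfish.imaging_core import distortion_protocol, distort_image
from interfish.quality_control import target_quality_score
from interfish.synthetic_fixtures import SimulationConfig, generate_field_image

image, _, _ = generate_field_image(SimulationConfig(n_nuclei=10, seed=2))
base = target_quality_score(image.channel("target"))
print(f"original           : Q={base.q_score:9.1f}  shape={image.shape}")

for spec in distortion_protocol():
    distorted = distort_image(image, spec)
    report = target_quality_score(distorted.channel("target"))
    q = f"{report.q_score:9.1f}" if report.q_score is not None else "undefined"
    print(f"{spec.kind:<18} : Q={q}  shape={distorted.shape}")
print(
    "# Geometric distortions barely move the histogram statistic, while\n"
    "# contrast changes redistribute intensity mass between the background\n"
    "# and signal peaks and can push an image across the Q = 0.2 gate."
)
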