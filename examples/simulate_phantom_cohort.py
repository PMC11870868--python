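"""Generate a small multi-institute phantom cohort and inspect its geometry.

Each phantom is an anisotropic 3D volume (1.5 x 1.5 x 4.3 mm voxels)
containing five bright blobs at the pelvic landmark positions; the
printed table shows the four derived dimensions per phantom, which by
construction fall inside the configured anatomical ranges.
"""
import numpy as np

from pelvimetry import PhantomConfig, compute_dimensions, generate_cohort

cohort = generate_cohort(
    n=6,
    institute_profile=[3, 2, 1],
    config=PhantomConfig(),
    seed=11,
    observer_noise_sd=2.0,
)

print(f"{'id':<14}{'institute':<14}{'inlet':>8}{'outlet':>8}{'depth':>8}{'angle':>8}")
for rec in cohort:
    d = compute_dimensions(rec.reference)
    print(
        f"{rec.volume_id:<14}{rec.institute_id:<14}"
        f"{d.inlet_mm:8.1f}{d.outlet_mm:8.1f}{d.depth_mm:8.1f}{d.sacral_angle_deg:8.1f}"
    )

vol = cohort.records[0].volume
print(f"\nvolume grid {vol.shape} at {tuple(map(float, vol.spacing))} mm, "
      f"intensity range [{vol.data.min():.2f}, {vol.data.max():.2f}]")
print("lengths in mm, sacral angulation in degrees; a second simulated")
print("observer (2 mm jitter) is attached for inter-observer analyses")
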