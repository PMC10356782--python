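"""Register a perturbed serial stack back to its reference section.

Each section is jittered by a random affine (rotation/translation), a
smooth B-spline deformation and noise. Registration masks the AF channel
(Otsu + closing + largest component), estimates a block-matching affine
from local NCC correspondences, then refines with a mutual-information
B-spline. Quality is reported as mask DSC vs the reference and NCC between
adjacent registered sections.
"""

from mxif3d import PhantomConfig, generate_phantom, register_stack

config = PhantomConfig(
    n_sections=6,
    seed=42,
    affine_jitter=(3.0, 10.0),  # deg, px
    deform_max_px=10.0,
    cell_density_per_type={"Thelper": 20},
)
sections, truth = generate_phantom(config)
transforms, qc = register_stack(sections)

print("per-section mask DSC vs reference:",
      " ".join(f"{d:.3f}" for d in qc.dsc))
print(f"mean DSC {qc.mean_dsc:.3f}  (>= 0.95 indicates high-quality "
      "registration; the reference section itself scores 1.0)")
print(f"mean adjacent NCC {qc.mean_ncc:.3f}  (AF texture correlation "
      "between neighboring registered sections; ~0.6 is typical because "
      "tissue genuinely changes over 5 µm)")
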