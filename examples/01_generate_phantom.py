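"""Generate a synthetic 4D-flow phantom and inspect its ground truth.

The phantom is a tilted, jet-carrying chamber in a static torso-like
envelope, built so that the component label of every end-diastolic voxel is
known exactly from the closed-form flow maps.
"""

from lv4dflow.phantom import PhantomSpec, generate_phantom

spec = PhantomSpec(noise_sigma=2.0, seed=7)
field, segmentation, truth = generate_phantom(spec)

print(f"grid {field.grid_shape} @ {field.voxel_spacing[0]:.0f} mm, "
      f"{field.n_frames} frames of {field.frame_interval:.0f} ms "
      f"(cycle {field.cycle_length:.0f} ms)")
print(f"EDV {truth.edv_ml:.1f} ml, ESV {truth.esv_ml:.1f} ml, "
      f"{len(truth.seeds)} pathline seeds")
print("ground-truth component fractions (% EDV):")
for name, frac in truth.fractions.items():
    print(f"  {name:24s} {100 * frac:5.1f}  (requested {100 * truth.spec_fractions[name]:.0f})")
print(f"voxelisation gap to the requested fractions: "
      f"{100 * truth.discretisation_error:.2f} points")
print(f"velocity samples clipped at VENC: {truth.clip_count}")

# The realised fractions differ from the requested ones only by the voxel
# quantisation of the seed lattice, reported above.
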