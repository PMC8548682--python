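"""Internal void-space skeletonization on a synthetic regenerated digit.

Renders a digit phantom with tortuous internal channels of exactly known
centerline length, extracts the internal void space, thins it to a medial
skeleton, and compares the recovered total length with the ground truth.
"""

from digitbone import (
    PhantomSpec,
    generate_digit_phantom,
    internal_void_mask,
    segment_bone,
    skeleton_total_length,
    skeletonize_voids,
)

spec = PhantomSpec(seed=4, n_channels=3, channel_tortuosity=0.3)
vol, truth = generate_digit_phantom(spec)

bone = segment_bone(vol, threshold=70.0)  # between background and trabecular
voids = internal_void_mask(bone, closing_radius_voxels=5)
skeleton = skeletonize_voids(voids)
summary = skeleton_total_length(skeleton, vol.voxel_size_um)

rel_err = (summary.total_length_um - truth.channel_centerline_length_um) / (
    truth.channel_centerline_length_um
)
print(f"ground-truth centerline length : {truth.channel_centerline_length_um:8.1f} um")
print(f"recovered skeleton length      : {summary.total_length_um:8.1f} um")
print(f"relative error                 : {rel_err:+.1%}")
print(f"skeleton components            : {summary.n_components} "
      f"(channels generated: {len(truth.channel_polylines)})")

print()
print("The recovered length tracks the analytic channel length to within a")
print("few percent; lattice quantisation of diagonal steps biases slightly")
print("long while tube-end erosion during thinning biases slightly short.")
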