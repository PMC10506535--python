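"""Generate one synthetic tissue sample and inspect its pieces.

A phantom sample pairs a hyperspectral SRS cube (77 bands over the
CH-stretching window), its 7-band discrete-frequency image, fresh-frozen
and FFPE-style H&E renders, and the ground-truth label mask they were all
rendered from.
"""

from ramanstain import phantom

sample = phantom.generate_sample(seed=7, shape=(128, 128),
                                 grade_class="moderate")

print("cube:", sample.cube.shape, "bands at",
      f"{sample.cube.axis.shifts[0]:.0f}-{sample.cube.axis.shifts[-1]:.0f} cm^-1")
print("band image channels:", sample.bands.shifts)
print("grade class:", sample.grade_class)
print(f"planted lipid-droplet fraction: {sample.ld_area_fraction:.4f}")
print("mask pixel counts:", sample.mask.class_counts())

# The class counts partition the image; the droplet fraction is the share
# of the epithelial compartment occupied by planted droplets.
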