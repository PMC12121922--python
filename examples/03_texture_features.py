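"""Gray-level co-occurrence texture descriptors of a segmented lesion.

Compares a benign and a malignant phantom: the malignant interior has a
shorter-range, noisier heat texture, so its contrast/entropy rise and its
energy (uniformity) falls.
"""

from thermocad.phantoms import benign_spec, generate_phantom, malignant_spec
from thermocad.segmentation import segment_image
from thermocad.texture import roi_texture_features

for make in (benign_spec, malignant_spec):
    spec = make(seed=1)
    img = generate_phantom(spec)
    seg = segment_image(img)
    f = roi_texture_features(img.pixels, seg.roi_mask)
    print(f"{spec.label:>9}: contrast={f['contrast']:.2f} entropy={f['entropy']:.2f} "
          f"dissimilarity={f['dissimilarity']:.2f} energy={f['energy']:.3f} "
          f"homogeneity={f['homogeneity']:.3f}")
print("(descriptors are averaged over the 0/45/90/135-degree co-occurrence directions,"
      " 16 gray levels, offset 1)")
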