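"""Chaotic indices on systems with known answers, then on a phantom lesion.

The estimators are validated against closed-form invariants: the logistic map
at r=4 has largest Lyapunov exponent ln 2, a pure sine has 0, the Sierpinski
triangle has box-counting dimension log3/log2, and uniform points on a line /
in a square have correlation dimension 1 / 2.
"""

import numpy as np

from thermocad.chaos import (
    box_counting_fd, correlation_dimension, lle_jacobian, roi_chaos_features,
)
from thermocad.phantoms import generate_phantom, generate_series, malignant_spec
from thermocad.segmentation import segment_image

logistic = generate_series("logistic", {"r": 4.0}, n=5000, seed=1).values
print(f"logistic-map LLE: {lle_jacobian(logistic):.4f}  (exact: ln 2 = {np.log(2):.4f})")
sine = generate_series("sine", n=5000, seed=1).values
print(f"sine LLE:         {lle_jacobian(sine):+.4f}  (exact: 0, regular motion)")

sierp = generate_series("sierpinski", {"depth": 7}).values
print(f"Sierpinski FD:    {box_counting_fd(sierp):.4f}  (exact: log3/log2 = {np.log(3)/np.log(2):.4f})")

rng = np.random.default_rng(0)
square = rng.random((3000, 2))
print(f"uniform-square CD: {correlation_dimension(square, max_points=1500):.3f}  (exact: 2)")

spec = malignant_spec(seed=2)
img = generate_phantom(spec)
seg = segment_image(img)
f = roi_chaos_features(img.pixels, seg.roi_mask, seg.binary_image)
print(f"\nmalignant phantom ROI: FD={f['fd']:.3f} LLE={f['lle']:.3f} "
      f"KSE={f['kse']:.3f} CD={f['cd']:.3f}")
print("(FD is the lesion-boundary box dimension; LLE/KSE/CD come from the "
      "delay-embedded gray-level sequence of the ROI)")
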