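"""Brightness/contrast stress transforms around the 1.0 baseline.

Applies the multiplicative-brightness / mean-anchored-contrast transform
at factors stepped by 0.1 around 1.0 — the protocol used to probe how
image quality degradation affects a detector — and reports how the
intensity distribution moves.
"""

import numpy as np

from cxrctr.synthetic import PhantomSpec, generate_phantom, perturb_image

mask, _ = generate_phantom(PhantomSpec())
image = (mask.labels * 90 + 40).astype(np.uint8)  # grayscale stand-in

print("factor  brightness-> mean/sd      contrast-> mean/sd")
for f in (0.7, 0.8, 0.9, 1.0, 1.1, 1.2, 1.3):
    b = perturb_image(image, brightness=f)
    c = perturb_image(image, contrast=f)
    print(f"{f:4.1f}    {b.mean():7.1f} / {b.std():5.1f}     "
          f"{c.mean():7.1f} / {c.std():5.1f}")

assert np.array_equal(perturb_image(image, 1.0, 1.0), image)
print("\nBrightness scales the whole histogram (mean and spread together);")
print("contrast stretches it about the mean (spread only, until clipping).")
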