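"""The three preprocessing alternatives on a synthetic knee radiograph.

Otsu background removal zeroes everything below the between-class-variance
threshold; top/bottom-hat enhances local contrast; cartoon-texture splits
the image into a smooth component and an oscillatory residual.
"""

import numpy as np

from dicomanno import cartoon_texture, otsu_threshold, remove_background, resize_image, top_bottom_hat
from dicomanno.synthetic import PhantomSpec, generate_phantom

rng = np.random.default_rng(21)
img = generate_phantom(PhantomSpec(body_part=72696002), rng) * 255  # knee

small = resize_image(img, 224)
print(f"resize:            {img.shape} -> {small.shape}")

res = otsu_threshold(img)
cleaned = remove_background(img)
print(f"otsu threshold:    T = {res.T:.1f}  var(T) = {res.var_between:.1f} "
      f"(P0 = {res.p0:.2f}, P1 = {res.p1:.2f})")
print(f"background zeroed: {(cleaned == 0).mean():.0%} of pixels "
      f"(was {(img == 0).mean():.0%})")

enhanced = top_bottom_hat(img, radius=15)
print(f"top-bottom hat:    contrast (std) {img.std():.1f} -> {enhanced.std():.1f}")

cartoon, texture = cartoon_texture(img, scale=3.0)
print(f"cartoon-texture:   reconstruction error = "
      f"{np.abs(cartoon + texture - img).max():.2e} "
      f"(texture holds {np.square(texture).sum() / np.square(img).sum():.1%} of energy)")
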