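"""Compare the irregularity index of a clean ellipse and a star disc.

The index I = (n2 + n3) / n1 counts disagreement with the moment-fit
ellipse; discs with I > 0.14 are called irregular.
"""
from plax.scene import SceneConfig, _disc_mask, generate_scene
from plax.shape import classify_shape, fit_ellipse, irregularity

for label, kw in [("ellipse", {}),
                  ("4-lobed star", {"star_amplitude": 0.3, "star_points": 4})]:
    scene = generate_scene(SceneConfig.for_size(384, 512, **kw), seed=4)
    mask = _disc_mask(scene.truth, scene.label_map.shape)
    fit = fit_ellipse(mask)
    irr = irregularity(mask, fit)
    print(f"{label:14s}: a={fit.semi_axes[0]:.1f} b={fit.semi_axes[1]:.1f} "
          f"I={irr.index:.4f} -> {classify_shape(irr.index)}")
print("-> the star disc leaves many pixels outside its best-fit ellipse,")
print("   pushing I past the 0.14 decision threshold.")
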