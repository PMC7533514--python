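"""Count cord coils from fold crevices and compute the coilness index.

Canny edges inside the cord are filtered (length, crossing, orientation)
and deduplicated by the boundary-spacing rule; C = n * 10 / l flags
hypercoiling at C >= 4.
"""
from plax.coiling import analyze_cord
from plax.scene import CORD, SceneConfig, generate_scene

cfg = SceneConfig.for_size(384, 512, coil_count=7,
                           cord_length=(380.0, 440.0),
                           cord_halfwidth=(8.0, 9.5))
scene = generate_scene(cfg, seed=2)
res = analyze_cord(scene.image, scene.label_map == CORD,
                   scene.truth.pixels_per_cm_true)
print(f"planted coils   : {scene.truth.coil_count}")
print(f"edge segments   : {len(res.segments)}")
print(f"counted coils n : {res.n}")
print(f"cord length     : {res.length_cm:.1f} cm")
print(f"coilness C      : {res.coilness:.2f} coils / 10 cm "
      f"-> {'hypercoiled' if res.hypercoiled else 'normal'}")
print("-> n tracks the planted count; C normalizes it per 10 cm of cord.")
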