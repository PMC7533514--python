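"""Run the full two-stage pipeline in oracle mode and print the report."""
import json
import tempfile

from plax.pipeline import run_pipeline
from plax.scene import SceneConfig, generate_scene, write_scene

cfg = SceneConfig.for_size(384, 512, coil_count=5,
                           cord_length=(380.0, 440.0),
                           cord_halfwidth=(8.0, 9.5))
with tempfile.TemporaryDirectory() as d:
    paths = write_scene(generate_scene(cfg, seed=1), d, "demo")
    report = run_pipeline(paths["image"], labels_path=paths["labels"],
                          truth_path=paths["truth"])
print(json.dumps(report, indent=2))
print("-> one JSON per placenta: side, scale, shape, insertion, coiling.")
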