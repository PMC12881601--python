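"""Run several end-to-end pipelines and print the comparison table.

Normal classifies the original images; ROI classifies the mask x image
product.  Both share one segmentation stage (same training inputs and seed),
so the segmentation columns repeat — the classification columns differ.
Run:  python examples/06_compare_pipelines.py    (~30 seconds on one CPU)
"""

from papcell.phantoms import PhantomSpec, generate_dataset
from papcell.pipelines import compare_pipelines, desk_scale_config

spec = PhantomSpec(image_size=32)
samples, _ = generate_dataset(spec, {"normal": 60, "abnormal": 60}, seed=5)

cfgs = [desk_scale_config(name, seed=0, image_size=32)
        for name in ("Normal", "ROI")]
table = compare_pipelines(cfgs, samples)
print(table.to_string(index=False))
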