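"""Render the five-category observation-error heatmap for one dataset.

The image shows mutations on rows and clone-blocked cells on columns; each
pixel is colored by comparing the observed entry to the truth: true
negative (grey), true positive (light blue), false positive (dark red),
false negative (dark blue), missing (white), with a clone color bar on top.
"""

from pathlib import Path

import scclonesim as s
from scclonesim.noise import CATEGORY_NAMES

out = Path("scratch")
out.mkdir(exist_ok=True)

for fp in (0.001, 0.01, 0.05):
    cfg = s.SimConfig(fp_rate=fp, seed=2)
    ds = s.simulate_snv_dataset(cfg)
    path = out / f"heatmap_fp{fp}.png"
    cat = s.render_heatmap(ds.G.values, ds.D.values, ds.labels, path)
    counts = {name: int((cat == code).sum()) for code, name in CATEGORY_NAMES.items()}
    print(f"fp={fp}: wrote {path}; pixel counts {counts}")
# Higher FP rates visibly pepper the reference background with dark red.
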