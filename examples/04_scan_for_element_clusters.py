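"""Locate element-sized clusters of enriched guides with the window scan.

Single enriched guides can be off-target artifacts; true cis-elements enrich
*clusters* of independent guides. The scan fits a normal null to each
sample's NGG-guide enrichment scores, converts scores to upper-tail
probabilities, and reports -log10 of their product in a sliding 21-bp
window. The script compares the combined profile's peak against the planted
elements and against an effect-free control screen.
"""

import numpy as np

from chipperscan.chipper_sim import ChipperParams
from chipperscan.refmodel import random_region
from chipperscan.screen_sim import ScreenConfig, default_truth_elements
from chipperscan.workflow import run_pipeline

region = random_region(10_000, seed=11, region_id="mir_locus")
truth = default_truth_elements(region)
params = ChipperParams(n_fragments=20_000, clone_count=100_000, concatemer_length=60_000)
cfg = ScreenConfig(n_cells=500_000, read_depth=200_000)

res = run_pipeline([region], params, cfg, truth=truth, master_seed=5)
total = sum(p.values for p in res.profiles.values())
peak = int(np.argmax(total))
el = next((t.name for t in truth if t.start <= peak < t.end), "none")
print(f"combined scan peak at {peak} (-log10 p = {total[peak]:.1f}), element: {el}")

for t in truth:
    print(f"  {t.name} ({t.start}-{t.end}): max window value {total[t.start:t.end].max():.1f}")

null = run_pipeline([region], params, cfg, truth=[], master_seed=100)
null_total = sum(p.values for p in null.profiles.values())
print(f"effect-free control: max window value {null_total.max():.1f}")
print("-> planted elements stand far above anything an effect-free screen produces")
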