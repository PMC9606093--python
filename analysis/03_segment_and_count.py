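#!/usr/bin/env python
"""Segment and count hyperdense particles in the default phantom.

Runs the quantification chain (maximum-entropy threshold -> 3-D connected
components -> despeckle -> plaque exclusion -> tissue load) and compares
every output against the planted ground truth.
"""

import json
from pathlib import Path

import ichdquant as iq

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

cfg = iq.default_phantom_config(seed=1)
volume, truth = iq.generate_phantom(cfg)
res = iq.process_voi(volume, "demo-voi", min_voxels=10)

res.catalog.to_csv(OUT / "particle_catalog.csv")
res.result.to_json(OUT / "voi_result.json")
(OUT / "segmentation_log.json").write_text(json.dumps(res.log, indent=2))

true_load = truth.true_load_percent["total"]
print(f"Kapur threshold: {res.threshold:.2f} density units "
      f"(background {cfg.background_mean}, particles ~150)")
print(f"detected {len(res.catalog.retained)} particles "
      f"(planted {truth.count()}); despeckled {res.n_despeckled} noise voxels")
print(f"HD load: estimated {res.result.load_percent:.3f}% "
      f"vs planted {true_load:.3f}% "
      f"({100 * abs(res.result.load_percent - true_load) / true_load:.1f}% rel. error)")
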