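#!/usr/bin/env python
"""Decompose the particle-size distribution at fine and coarse voxel scales.

At 0.3 um voxels the equivalent-sphere diameter distribution is tri-modal
and BIC selects a 3-component Gaussian mixture (nucleoli / glia / ICHD
neurons).  Resampling the same volume to 3.0 um voxels leaves nucleoli
unresolved: detected sizes collapse toward the voxel scale and BIC selects
only two populations.
"""

import json
from pathlib import Path

import numpy as np

import ichdquant as iq

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

cfg = iq.default_phantom_config(seed=1)
volume, truth = iq.generate_phantom(cfg)

fine = iq.process_voi(volume, "fine", min_voxels=10)
coarse = iq.process_voi(iq.resample_volume(volume, 3.0), "coarse", min_voxels=1)

report = {}
for name, run in (("fine_0.3um", fine), ("coarse_3.0um", coarse)):
    fit = run.fit
    report[name] = {
        "selected_k": fit.k,
        "bic": fit.bic,
        "means_um": np.round(fit.means, 3).tolist(),
        "weights": np.round(fit.weights, 3).tolist(),
        "n_particles": len(run.catalog.retained),
    }
planted = {p: float(truth.diameters(p).mean())
           for p in ("nucleoli", "glia", "ichd")}
report["planted_mean_diameters_um"] = planted
(OUT / "population_fits.json").write_text(json.dumps(report, indent=2))

print(f"fine scale:   K={fine.fit.k}, means {np.round(fine.fit.means, 2)} um "
      f"(planted {np.round(list(planted.values()), 2)})")
print(f"coarse scale: K={coarse.fit.k}, means {np.round(coarse.fit.means, 2)} um "
      f"-> nucleoli unresolved, merged with glia")
print(f"wrote {OUT / 'population_fits.json'}")
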