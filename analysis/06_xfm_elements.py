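#!/usr/bin/env python
"""Quantify intracellular elemental density in a synthetic XFM section.

Renders calibrated P/S/Ca/Fe area-density maps with 22 normal and 11
ICHD-bearing cells (planted 3x elemental elevation in the ICHD class),
measures per-cell mean densities, and compares the classes per element with
unpaired two-sided Wilcoxon tests.
"""

import json
from pathlib import Path

import ichdquant as iq

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

maps, mask, truth = iq.generate_xfm_maps(iq.default_xfm_config(seed=5))
cell_means, comparisons = iq.run_xfm_analysis(maps, mask)

cell_means.to_csv(OUT / "xfm_cell_means.csv", index=False)
summary = {}
for element, r in comparisons.items():
    cls = cell_means[cell_means.element == element].groupby("cell_class")[
        "mean_density"].mean()
    summary[element] = {
        "ichd_mean_ng_mm2": float(cls["ichd"]),
        "normal_mean_ng_mm2": float(cls["normal"]),
        "U": r.u_statistic, "p": r.p_value, "method": r.method,
    }
(OUT / "xfm_comparisons.json").write_text(json.dumps(summary, indent=2))

print(f"{len(mask.label_ids)} cells "
      f"({list(mask.classes.values()).count('normal')} normal, "
      f"{list(mask.classes.values()).count('ichd')} ICHD)")
for e, s in summary.items():
    print(f"{e}: ICHD {s['ichd_mean_ng_mm2']:.1f} vs normal "
          f"{s['normal_mean_ng_mm2']:.1f} ng/mm2, p = {s['p']:.2e}")
print(f"wrote {OUT / 'xfm_comparisons.json'}")
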