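"""Contrast-to-noise ratio across hydration states.

Generates tibia-style phantoms in three hydration configurations and
computes the cortex-background CNR panel over three representative slices.
The CNR drop with hydration mirrors the loss of neutron contrast as tissue
takes up liquid.
"""
import bonetomo as bt
from bonetomo import contrast

for state in ("dry", "rehydrated_12h", "rehydrated_40h"):
    res = bt.generate_volume(bt.tibia_phantom(state=state, seed=4))
    idx = {p["label"]: p["index"] for p in res.phase_table}
    rois = []
    for s in (12, 24, 36):
        for lab in ("background", "cortex"):
            rois.append(
                contrast.roi_from_labels(res.volume, res.label_map,
                                         idx[lab], lab, s, erode=3)
            )
    per_slice, summary = contrast.cnr_panel(
        res.volume, rois, [("cortex", "background")]
    )
    row = summary.iloc[0]
    print(f"{state:16s} cortex:background CNR = "
          f"{row.cnr_mean:6.3f} ± {row.cnr_sd:.3f} over {row.n_slices} slices")
# CNR decreases monotonically from dry to fully rehydrated: the cortex mean
# grey approaches the background as the tissue hydrates.
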