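"""Compare membrane and cytosolic proteins in normalized cell coordinates.

Ground-truth localizations are sampled on the cell surface (a membrane
protein) and uniformly in the cell volume (a cytosolic protein), mapped
to normalized coordinates (l along the cell axis, s across it), and the
short-axis distribution is summarized after excluding the cell poles
(l in 0-0.15, 0.85-1) and mid-cell (0.35-0.65).  The enrichment score is
the fraction of localizations with |s| > 0.5; for a uniform cytosol the
analytic value is 2/3 - sqrt(3)/(2 pi) ~ 0.39.
"""

import numpy as np
import pandas as pd

import strobetrack as st
from strobetrack.segment import segment_cells

cells, mask = st.make_colony(1, rng=5)
cell = cells[0]
region = segment_cells(None, label_mask=mask)[0]
px = 65.7 / 1000
rng = np.random.default_rng(7)

for name, pts in (
    ("membrane ", cell.sample_surface(20000, rng)),
    ("cytosolic", cell.sample_volume(20000, rng)),
):
    locs = pd.DataFrame({"frame": 0, "x_px": pts[:, 0] / px, "y_px": pts[:, 1] / px, "cell": 1})
    ds = st.normalize_localizations(locs, [region])
    ds = st.subsample(ds, n=22207, rng=1)
    hist, edges, kept = st.short_axis_distribution(ds)
    score = st.membrane_enrichment(kept)
    med = np.median(np.abs(kept["s"]))
    print(f"{name}: {len(kept)} retained, median |s| = {med:.2f}, "
          f"enrichment (|s| > 0.5) = {score:.2f}")
# Membrane proteins concentrate near |s| ~ 1 (score ~ 2/3); cytosolic ones
# follow the chord-projection law (score ~ 0.39) - the separation is what
# identifies membrane localization in the imaging data.
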