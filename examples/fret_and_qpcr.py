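"""Ratiometric FRET time series and qPCR relative expression.

The Epac1 cAMP sensor is read out as the mean YFP/CFP ratio in a cell-
body ROI over 11 time points (lower ratio = more cAMP); gene expression
is compared across groups with the Livak 2^-ddCt method.
"""

import numpy as np
import pandas as pd

from flycount3d import ddct_fold_change, fret_ratio_series, make_fret_series

# simulate a cAMP rise: the true YFP/CFP ratio falls from 1.0 to 0.8
course = np.linspace(1.0, 0.8, 11)
yfp, cfp, truth = make_fret_series(course, noise_sd=2.0, rng_seed=4)
roi = np.ones(yfp[0].shape, bool)
ratios = fret_ratio_series(yfp, cfp, roi)
print("recovered YFP/CFP:", np.round(ratios, 3))

# qPCR: target Ct one cycle lower than control -> twofold up-regulation
table = pd.DataFrame({
    "sample": ["c1", "c2", "oe"],
    "group": ["control", "control", "test"],
    "ct_target": [20.1, 19.9, 19.0],
    "ct_reference": [18.0, 18.0, 18.0],
})
print(ddct_fold_change(table).to_string(index=False))
# fold_change 2.0 means the test sample expresses twice the control level.
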