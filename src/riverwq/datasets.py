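"""Small reference datasets shipped with the package.

``lpr_annual_wqi`` holds the published area-averaged annual water quality
index values for the Lower Passaic River monitoring programme (upstream
reach ULPR = monitoring locations 8-9, downstream reach DLPR = locations
10-12), 2004-2019.  The underlying station-month concentrations are not
deposited anywhere public; these annual index values are the printed
summary and serve as arithmetic inputs (class labels, reach contrasts,
range statistics), not as something the package claims to recompute from
raw data.
"""

from __future__ import annotations

import pandas as pd

_LPR_ANNUAL_WQI = [
    # (year, ulpr_wqi, dlpr_wqi)
    (2004, 54, 73), (2005, 64, 87), (2006, 52, 65), (2007, 45, 81),
    (2008, 54, 65), (2009, 46, 63), (2010, 45, 71), (2011, 39, 54),
    (2012, 51, 95), (2013, 46, 71), (2014, 49, 72), (2015, 52, 76),
    (2016, 58, 88), (2017, 52, 84), (2018, 38, 54), (2019, 34, 56),
]


def lpr_annual_wqi() -> pd.DataFrame:
    """Published annual WQI for the upstream/downstream Lower Passaic River.

    Returns a frame with columns (year, ulpr_wqi, dlpr_wqi), 16 rows
    covering 2004-2019.
    """
    return pd.DataFrame(_LPR_ANNUAL_WQI, columns=["year", "ulpr_wqi", "dlpr_wqi"])
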