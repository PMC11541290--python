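"""Pearson correlation screening between two variable blocks.

Used to relate water-column physicochemical parameters to a second block
of measurements (e.g. sediment toxic-metal concentrations) sampled on the
same occasions.  Pairs are evaluated on pairwise-complete cases; two-sided
p-values come from the t transform with n-2 degrees of freedom.  No
multiple-testing correction is applied to the primary significance flag
(raw p < alpha); a Benjamini-Hochberg flag is emitted alongside for users
who want family-wise control.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def pearson_matrix(
    block_a: pd.DataFrame,
    block_b: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All-pairs Pearson correlations between two sample-aligned blocks.

    Parameters
    ----------
    block_a, block_b
        Samples x variables frames sharing a sample index; rows are aligned
        on that index, and each pair uses its pairwise-complete cases.
    alpha
        Significance level for the raw flag (default 0.05).

    Returns a long frame with one row per (variable_a, variable_b) pair:
    r, n, p, significant, significant_bh, undefined (zero-variance pairs
    are reported as undefined rather than dropped).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    a, b = block_a.align(block_b, join="inner", axis=0)
    if len(a) == 0:
        raise ValueError("blocks share no sample ids")
    rows = []
    for va in a.columns:
        for vb in b.columns:
            x = a[va].to_numpy(float)
            y = b[vb].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            n = int(ok.sum())
            row = {"variable_a": va, "variable_b": vb, "n": n}
            if n < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                row.update({"r": np.nan, "p": np.nan, "undefined": True})
            else:
                r, p = stats.pearsonr(x[ok], y[ok])
                row.update({"r": float(r), "p": float(p), "undefined": False})
            rows.append(row)
    out = pd.DataFrame(rows)
    out["significant"] = (out["p"] < alpha).fillna(False)
    out["significant_bh"] = _bh_flags(out["p"].to_numpy(), alpha)
    return out


def _bh_flags(pvals: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejections (NaNs never rejected)."""
    flags = np.zeros(len(pvals), bool)
    ok = np.isfinite(pvals)
    p = pvals[ok]
    if p.size == 0:
        return flags
    order = np.argsort(p)
    m = p.size
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = p[order] <= thresh
    if passed.any():
        k_max = np.max(np.flatnonzero(passed))
        rej = np.zeros(m, bool)
        rej[order[:k_max + 1]] = True
        flags[np.flatnonzero(ok)] = rej
    return flags
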