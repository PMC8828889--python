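"""Published worked-example values used as fixtures and cross-checks.

These are the self-contained numbers printed in the rice RIL drought
study this toolkit operationalizes: the L53 composite-index worked
example with its pooled correlation weights, the pooled population mean
yields, and the severe-year population yields.  They document expected
behaviour; nothing here is required for analysing user data.
"""

from __future__ import annotations

import pandas as pd

from .selection import CSIWeights

__all__ = [
    "L53_INDICES",
    "l53_index_values",
    "pooled_weights",
    "POOLED_MEANS",
    "SEVERE_YEAR_YIELDS",
]

#: Printed index values of line L53 (pooled over the three trial years).
L53_INDICES = {"mp": 4.286, "gmp": 3.553, "hm": 2.945, "sti": 0.788}

#: Pooled population mean yields over all 157 entries, t ha⁻¹ (Ȳ_P, Ȳ_S).
POOLED_MEANS = {"ybar_p": 4.00, "ybar_s": 1.41}

#: Severe-year (2017) population yields, t ha⁻¹: non-stress mean and the
#: lowest stress mean, the pair behind the 89.50% reduction.
SEVERE_YEAR_YIELDS = {"yp": 4.79, "ys": 0.503}

#: Pooled correlations of the four significant indices with yield.
_POOLED_R = {
    "mp": (0.96, 0.79),
    "gmp": (0.85, 0.92),
    "hm": (0.72, 0.98),
    "sti": (0.83, 0.91),
}


def l53_index_values() -> pd.DataFrame:
    """One-row index table holding L53's printed MP/GMP/HM/STI values."""
    return pd.DataFrame(L53_INDICES, index=pd.Index(["L53"], name="genotype"))


def pooled_weights(alpha: float = 0.01) -> CSIWeights:
    """The published pooled CSI weights (MP, GMP, HM, STI)."""
    w = pd.DataFrame(_POOLED_R, index=["r_yp", "r_ys"]).T
    w.index.name = "index"
    return CSIWeights(weights=w, alpha=alpha, scope="pooled")
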