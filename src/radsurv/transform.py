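"""Rank-based inverse normal transformation.

Association structure among radiomic features is computed on normalized
scores, so each feature is mapped through the rank-based inverse normal
transform before any cross-product or model-fitting step:

    z_i = Phi^-1( (r_i - c) / (n - 2c + 1) )

with mid-ranks for ties and the Blom offset c = 3/8 by default.  The result
is monotone in the input ranks and approximately standard normal for
continuous inputs.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm, rankdata

__all__ = ["inverse_normal_transform", "BLOM_OFFSET"]

BLOM_OFFSET = 3.0 / 8.0


def inverse_normal_transform(
    values: np.ndarray, offset: float = BLOM_OFFSET
) -> np.ndarray:
    """Map a vector to normal scores by ranks.

    Parameters
    ----------
    values : array-like, length n >= 2
        Raw feature values; ties are assigned mid-ranks.
    offset : float
        Rank offset c in (r - c) / (n - 2c + 1); default Blom (3/8).

    Raises
    ------
    ValueError
        If fewer than two values, non-finite entries, or a constant vector
        (the transform is undefined; the caller must drop the feature).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-d vector")
    if x.size < 2:
        raise ValueError("inverse normal transform needs n >= 2 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    if np.ptp(x) == 0:
        raise ValueError(
            "constant vector: inverse normal transform undefined; drop the feature"
        )
    r = rankdata(x, method="average")
    n = x.size
    return norm.ppf((r - offset) / (n - 2.0 * offset + 1.0))
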