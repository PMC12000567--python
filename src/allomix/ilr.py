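"""Isometric log-ratio coordinates for a two-part composition.

With only two sources the composition ``(p_aquatic, p_terrestrial)`` lives on
a one-dimensional simplex and has a single ILR coordinate.  The convention is
aquatic-first (alphabetical, matching common mixing-model software), so

    phi = sqrt(1/2) * ln(p_aquatic / p_terrestrial)

and a *larger* phi means a *smaller* terrestrial contribution (allochthony).
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

_SQRT_HALF = np.sqrt(0.5)
_SQRT_TWO = np.sqrt(2.0)


def ilr_transform(p_aquatic):
    """Map an aquatic source proportion to its ILR coordinate.

    Parameters
    ----------
    p_aquatic : float or array-like
        Aquatic proportion, strictly inside (0, 1).

    Returns
    -------
    float or ndarray
        ILR coordinate ``sqrt(1/2) * ln(p / (1 - p))``.

    Raises
    ------
    ValueError
        If any value lies on the simplex boundary (0 or 1), where the
        coordinate is infinite.
    """
    p = np.asarray(p_aquatic, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("p_aquatic must lie strictly in (0, 1); boundary compositions have infinite ILR coordinate")
    phi = _SQRT_HALF * np.log(p / (1.0 - p))
    return phi if phi.ndim else float(phi)


def ilr_inverse(phi):
    """Map an ILR coordinate back to the aquatic proportion.

    Saturates smoothly to 0/1 for large ``|phi|``; allochthony is
    ``1 - ilr_inverse(phi)``.
    """
    phi = np.asarray(phi, dtype=float)
    p = expit(_SQRT_TWO * phi)
    return p if p.ndim else float(p)
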