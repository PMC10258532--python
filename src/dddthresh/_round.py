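"""Integer rounding shared across distance computations.

All inter-ROI distances in this package are reported in integer millimetres
using half-away-from-zero rounding (16.5 -> 17), so that distance matrices
are bit-reproducible across platforms.  numpy's default ``round`` is
banker's rounding and is deliberately not used here.
"""

from __future__ import annotations

import numpy as np


def round_half_away(x):
    """Round to nearest integer, halves away from zero.

    Works on scalars and arrays; returns int64 values.
    """
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.floor(np.abs(x) + 0.5)
    return out.astype(np.int64) if out.ndim else int(out)
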