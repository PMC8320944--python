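"""Small shared numeric helpers."""

from __future__ import annotations

import numpy as np


def minmax_normalize(arr: np.ndarray) -> np.ndarray:
    """Rescale to [0, 1]; a constant array maps to all zeros."""
    arr = np.asarray(arr, dtype=float)
    lo = arr.min()
    hi = arr.max()
    if hi - lo <= 0:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def round_half_up(x) -> np.ndarray:
    """Round with ties away from zero toward +inf (0.5 -> 1), elementwise."""
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)
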