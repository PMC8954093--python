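"""2×2 area-average downsampling shared by level synthesis and pyramidalization."""

from __future__ import annotations

import numpy as np


def downsample2x(arr: np.ndarray) -> np.ndarray:
    """Halve both spatial axes of an (H, W[, S]) image by 2×2 block averaging.

    Output dimensions are floor(H/2) × floor(W/2); a trailing odd row/column
    is dropped.  Averages round half up, so constant inputs are preserved
    exactly.
    """
    h2, w2 = arr.shape[0] // 2, arr.shape[1] // 2
    if h2 < 1 or w2 < 1:
        raise ValueError(f"downsample2x: image {arr.shape[:2]} too small to halve")
    a = arr[: h2 * 2, : w2 * 2].astype(np.uint32)
    acc = a[0::2, 0::2] + a[0::2, 1::2] + a[1::2, 0::2] + a[1::2, 1::2]
    return ((acc + 2) // 4).astype(arr.dtype)
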