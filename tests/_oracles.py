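"""Independent brute-force oracles used to cross-check the implementations.

These deliberately re-derive each quantity from its definition (explicit
window enumeration, step-up enumeration) rather than sharing any code with
the package.
"""

from __future__ import annotations

import numpy as np
from skimage.morphology import disk


def phansalkar_naive(norm: np.ndarray, radius: int, k=0.25, r=0.5, p=2.0, q=10.0) -> np.ndarray:
    """Per-pixel double-loop Phansalkar mask on an already-normalized image.

    Recomputes the circular-window mean and population std by explicit
    enumeration over the mirror-padded image.
    """
    footprint = disk(radius).astype(bool)
    padded = np.pad(norm, radius, mode="reflect")
    out = np.zeros(norm.shape, dtype=bool)
    for i in range(norm.shape[0]):
        for j in range(norm.shape[1]):
            window = padded[i : i + 2 * radius + 1, j : j + 2 * radius + 1][footprint]
            m = window.mean()
            s = window.std()
            t = m * (1.0 + p * np.exp(-q * m) + k * (s / r - 1.0))
            out[i, j] = norm[i, j] > t
    return out


def bh_naive(p_values) -> np.ndarray:
    """Step-up q-values by direct double-loop enumeration of the definition:
    q_(i) = min over j with p_(j) >= p_(i) of min(1, m * p_(j) / j).
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    q_sorted = np.empty(m)
    for i in range(m):
        candidates = [min(1.0, m * p_sorted[j] / (j + 1)) for j in range(i, m)]
        q_sorted[i] = min(candidates)
    q = np.empty(m)
    q[order] = q_sorted
    return q
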