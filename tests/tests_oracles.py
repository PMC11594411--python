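"""Independent brute-force oracles shared by test modules.

These deliberately re-derive quantities with the simplest possible code
(explicit loops, no shared helpers with the package) so they can vouch for
the vectorized implementations.
"""

import math

import numpy as np


def brute_force_mi(x, y, bins):
    """Plug-in MI in nats from an explicit joint histogram."""

    def codes(v):
        order = np.argsort(np.asarray(v, float), kind="stable")
        c = np.empty(len(v), dtype=int)
        for rank, idx in enumerate(order):
            c[idx] = rank * bins // len(v)
        return c

    cx, cy = codes(x), codes(y)
    n = len(cx)
    mi = 0.0
    for a in range(bins):
        for b in range(bins):
            pab = float(np.sum((cx == a) & (cy == b))) / n
            pa = float(np.sum(cx == a)) / n
            pb = float(np.sum(cy == b)) / n
            if pab > 0:
                mi += pab * math.log(pab / (pa * pb))
    return max(mi, 0.0)
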