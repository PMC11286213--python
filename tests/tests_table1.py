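"""Weighted-cell arrays for the simulation population cross-tabulation."""

import numpy as np

# (class, M, Y) cell counts out of n = 5,000
_CELLS = {
    0: (150, 120, 50, 80),  # EOP: (M0,Y0), (M0,Y1), (M1,Y0), (M1,Y1)
    1: (200, 125, 75, 100),  # AO
    2: (295, 180, 65, 60),  # CL
    3: (1950, 980, 325, 245),  # Low
}


def table1_arrays():
    W, M, Y, wts = [], [], [], []
    for x, cells in _CELLS.items():
        for (m, y), c in zip(((0, 0), (0, 1), (1, 0), (1, 1)), cells):
            W.append(x)
            M.append(m)
            Y.append(y)
            wts.append(c)
    return (
        np.array(W),
        np.array(M, dtype=float),
        np.array(Y, dtype=float),
        np.array(wts, dtype=float),
    )
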