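"""Independent brute-force oracles shared by the test suite.

These are deliberately written with explicit loops over the classical
cell-mean identities, independent of the package's vectorized fitting path.
"""

import itertools

import numpy as np
from scipy.stats import f as fdist


def brute_force_ss(Y: np.ndarray) -> dict:
    """Within-subject sums of squares by explicit loops (n × a × b array)."""
    n, a, b = Y.shape
    grand = Y.mean()
    m_i = [Y[i].mean() for i in range(n)]
    m_j = [Y[:, j].mean() for j in range(a)]
    m_k = [Y[:, :, k].mean() for k in range(b)]
    ss = {"A": 0.0, "B": 0.0, "AB": 0.0, "AS": 0.0, "BS": 0.0, "ABS": 0.0}
    for j in range(a):
        ss["A"] += n * b * (m_j[j] - grand) ** 2
    for k in range(b):
        ss["B"] += n * a * (m_k[k] - grand) ** 2
    for j, k in itertools.product(range(a), range(b)):
        m_jk = Y[:, j, k].mean()
        ss["AB"] += n * (m_jk - m_j[j] - m_k[k] + grand) ** 2
    for i, j in itertools.product(range(n), range(a)):
        m_ij = Y[i, j].mean()
        ss["AS"] += b * (m_ij - m_i[i] - m_j[j] + grand) ** 2
    for i, k in itertools.product(range(n), range(b)):
        m_ik = Y[i, :, k].mean()
        ss["BS"] += a * (m_ik - m_i[i] - m_k[k] + grand) ** 2
    for i, j, k in itertools.product(range(n), range(a), range(b)):
        m_ij = Y[i, j].mean()
        m_ik = Y[i, :, k].mean()
        m_jk = Y[:, j, k].mean()
        ss["ABS"] += (
            Y[i, j, k] - m_ij - m_ik - m_jk + m_i[i] + m_j[j] + m_k[k] - grand
        ) ** 2
    return ss


def brute_force_f(Y: np.ndarray) -> dict:
    """F, dfs, p and partial eta squared for every effect, from the SS oracle."""
    n, a, b = Y.shape
    ss = brute_force_ss(Y)
    out = {}
    for eff, err, df1, df2 in [
        ("A", "AS", a - 1, (a - 1) * (n - 1)),
        ("B", "BS", b - 1, (b - 1) * (n - 1)),
        ("AB", "ABS", (a - 1) * (b - 1), (a - 1) * (b - 1) * (n - 1)),
    ]:
        F = (ss[eff] / df1) / (ss[err] / df2)
        out[eff] = (F, df1, df2, fdist.sf(F, df1, df2), ss[eff] / (ss[eff] + ss[err]))
    return out
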