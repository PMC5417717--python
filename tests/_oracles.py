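"""Independent brute-force oracles used only by the test suite.

Everything here is written from first principles (explicit loops, direct
formulas, log-factorial sums) and deliberately avoids the code paths and
library calls the package itself uses, so agreement is a genuine
cross-check.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import stdtr  # Student-t CDF, used only to map t -> p


def welch_by_hand(a, b) -> tuple[float, float]:
    """Welch t statistic and two-sided p from the textbook formulas."""
    a = [float(x) for x in a]
    b = [float(x) for x in b]
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    if se2 == 0.0:
        return (0.0, 1.0) if ma == mb else (math.copysign(math.inf, ma - mb),
                                            0.0)
    t = (ma - mb) / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stdtr(df, -abs(t))
    return t, p


def trending_by_hand(matrix: np.ndarray, group_of: list[str],
                     order: tuple[str, str, str],
                     alpha: float) -> list[dict]:
    """Per-transcript trending calls via explicit loops.

    ``matrix`` is transcripts x samples; ``group_of[j]`` is the group of
    column j; ``order`` is (resistant, intermediate, vulnerable).
    """
    res_g, int_g, vul_g = order
    cols = {g: [j for j, gg in enumerate(group_of) if gg == g]
            for g in order}
    out = []
    for i in range(matrix.shape[0]):
        res = [matrix[i, j] for j in cols[res_g]]
        inter = [matrix[i, j] for j in cols[int_g]]
        vul = [matrix[i, j] for j in cols[vul_g]]
        m_res = sum(res) / len(res)
        m_int = sum(inter) / len(inter)
        m_vul = sum(vul) / len(vul)
        _, p = welch_by_hand(res, vul)
        call = "none"
        if p < alpha:
            if m_res > m_int > m_vul:
                call = "protective"
            elif m_res < m_int < m_vul:
                call = "harmful"
        out.append({"mean_res": m_res, "mean_int": m_int, "mean_vul": m_vul,
                    "log2fc": m_res - m_vul, "p": p, "call": call})
    return out


def hypergeom_tail_by_hand(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k) via a log-factorial sum."""
    if k <= 0:
        return 1.0
    lg = math.lgamma

    def log_comb(a, b):
        if b < 0 or b > a:
            return -math.inf
        return lg(a + 1) - lg(b + 1) - lg(a - b + 1)

    denom = log_comb(N, n)
    logs = []
    for j in range(k, min(K, n) + 1):
        t = log_comb(K, j) + log_comb(N - K, n - j) - denom
        if t > -math.inf:
            logs.append(t)
    if not logs:
        return 0.0
    m = max(logs)
    return math.exp(m) * sum(math.exp(t - m) for t in logs)


def bh_by_hand(p: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up, stepped through by hand.

    q for the i-th smallest p is min over ranks j >= i of p_(j) * m / j,
    capped at 1, then mapped back to input order.
    """
    m = len(p)
    idx = sorted(range(m), key=lambda i: p[i])
    q_sorted = [0.0] * m
    running = 1.0
    for pos in range(m - 1, -1, -1):
        running = min(running, p[idx[pos]] * m / (pos + 1))
        q_sorted[pos] = min(running, 1.0)
    q = [0.0] * m
    for pos, i in enumerate(idx):
        q[i] = q_sorted[pos]
    return q
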