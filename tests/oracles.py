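"""Independent reference implementations used as oracles by the tests.

Everything here is deliberately written with plain loops and
``scipy.linalg.expm`` so it shares no code path with the package's
vectorised eigensystem/pruning implementation.
"""

import numpy as np
from scipy.linalg import expm
from scipy.stats import gamma as gamma_dist

NUC = "ACGT"
PAIRS = [("A", "C"), ("A", "G"), ("A", "T"), ("C", "G"), ("C", "T"), ("G", "T")]


def classify_column(a, b, c, o):
    """Strict synapomorphy classification of one (a, b, c, O) column."""
    if a == b and c == o and a != o:
        return "x1"
    if a == c and b == o and a != b:
        return "x2"
    if b == c and a == o and b != a:
        return "x3"
    return None


def rate_matrix(model):
    Q = np.zeros((4, 4))
    for (x, y), r in zip(PAIRS, model.rates):
        i, j = NUC.index(x), NUC.index(y)
        Q[i, j] = r * model.freqs[j]
        Q[j, i] = r * model.freqs[i]
    for i in range(4):
        Q[i, i] = -sum(Q[i, j] for j in range(4) if j != i)
    mu = -sum(model.freqs[i] * Q[i, i] for i in range(4))
    return Q / mu


def category_rates(model):
    k = model.n_gamma_categories
    q = [(i + 0.5) / k for i in range(k)]
    r = gamma_dist.ppf(q, a=model.alpha, scale=1.0 / model.alpha)
    return r * k / r.sum()


def _tip_order(grouping):
    # package row order is (a, b, c, O); tree tips are (i, j, k, O)
    return {"x1": (0, 1, 2), "x2": (0, 2, 1), "x3": (1, 2, 0)}[grouping]


def pattern_probability(model, branch_lengths, grouping, pattern):
    """P(a,b,c,O pattern) by explicit summation over internal states."""
    Q = rate_matrix(model)
    ti, tj, tk, to, tint = branch_lengths
    ia, ib, ic = _tip_order(grouping)
    # map the canonical (a, b, c) states onto tree tips (i, j, k)
    tip_states = [pattern[ia], pattern[ib], pattern[ic], pattern[3]]
    si, sj, sk, so = (NUC.index(s) for s in tip_states)
    p_var = 0.0
    for r in category_rates(model):
        Pi, Pj, Pk, Po, Pint = (expm(Q * (t * r)) for t in (ti, tj, tk, to, tint))
        term = 0.0
        for v in range(4):
            for u in range(4):
                term += (
                    model.freqs[v]
                    * Pint[v, u]
                    * Pi[u, si]
                    * Pj[u, sj]
                    * Pk[v, sk]
                    * Po[v, so]
                )
        p_var += term / model.n_gamma_categories
    p_const = 0.0
    if len(set(pattern)) == 1:
        p_const = model.freqs[NUC.index(pattern[0])]
    return model.p_inv * p_const + (1 - model.p_inv) * p_var


def simulate_quartet_columns(model, branch_lengths, grouping, n_sites, rng):
    """Monte-Carlo site patterns in canonical (a, b, c, O) order."""
    Q = rate_matrix(model)
    ti, tj, tk, to, tint = branch_lengths
    rates = category_rates(model)
    pi = np.asarray(model.freqs)
    cols = []
    mats = {r: [expm(Q * (t * r)) for t in (ti, tj, tk, to, tint)] for r in rates}
    for _ in range(n_sites):
        if rng.random() < model.p_inv:
            s = rng.choice(4, p=pi)
            tip = [s, s, s, s]
        else:
            r = rates[rng.integers(len(rates))]
            Pi, Pj, Pk, Po, Pint = mats[r]
            v = rng.choice(4, p=pi)
            u = rng.choice(4, p=Pint[v])
            tip = [
                rng.choice(4, p=Pi[u]),
                rng.choice(4, p=Pj[u]),
                rng.choice(4, p=Pk[v]),
                rng.choice(4, p=Po[v]),
            ]
        ia, ib, ic = _tip_order(grouping)
        canon = [None, None, None, NUC[tip[3]]]
        canon[ia], canon[ib], canon[ic] = (NUC[tip[m]] for m in range(3))
        cols.append(tuple(canon))
    return cols
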