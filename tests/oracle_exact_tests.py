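"""Brute-force enumeration oracles for the exact nonparametric tests.

For small samples the null distributions are enumerated completely: every
C(n+m, n) group labeling for the rank-sum test, every 2^n sign pattern for
the signed-rank test. Two-sided p-values are the doubled smaller tail,
capped at 1 — the standard exact convention.
"""

import itertools
import math

import numpy as np


def _ranks(values):
    order = np.argsort(values)
    ranks = np.empty(len(values))
    ranks[order] = np.arange(1, len(values) + 1)
    return ranks


def rank_sum_exact_p(x, y):
    """Exact two-sided rank-sum p by enumerating all group labelings.

    Requires no ties across the combined sample.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    combined = np.concatenate([x, y])
    assert np.unique(combined).size == combined.size, "oracle requires no ties"
    ranks = _ranks(combined)
    n = len(x)
    observed = ranks[:n].sum()
    sums = [sum(ranks[list(ix)])
            for ix in itertools.combinations(range(len(combined)), n)]
    total = math.comb(len(combined), n)
    le = sum(1 for s in sums if s <= observed + 1e-12)
    ge = sum(1 for s in sums if s >= observed - 1e-12)
    return min(1.0, 2.0 * min(le, ge) / total)


def signed_rank_exact_p(d):
    """Exact two-sided signed-rank p by enumerating all sign patterns.

    Zero differences are dropped first; requires untied |d|.
    """
    d = np.asarray(d, float)
    d = d[d != 0]
    assert np.unique(np.abs(d)).size == d.size, "oracle requires untied |d|"
    ranks = _ranks(np.abs(d))
    observed = ranks[d > 0].sum()
    n = len(d)
    w_plus = [sum(r for r, s in zip(ranks, signs) if s)
              for signs in itertools.product([False, True], repeat=n)]
    total = 2 ** n
    le = sum(1 for w in w_plus if w <= observed + 1e-12)
    ge = sum(1 for w in w_plus if w >= observed - 1e-12)
    return min(1.0, 2.0 * min(le, ge) / total)
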