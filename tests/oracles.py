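"""Independent oracles used to check the package's statistics.

These deliberately avoid the implementation's closed forms: the LOD oracle
maximizes the Gaussian likelihood numerically, and the matching oracle
enumerates every perfect matching.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm


def gaussian_lod_oracle(y: np.ndarray, classes: np.ndarray) -> tuple[float, float, float]:
    """LOD, allele effect and pct variance by brute-force likelihood maximization.

    Full model: two class means and a common sigma; null model: one mean and
    a sigma.  Both are maximized numerically with Nelder-Mead and the LOD is
    the log10 ratio of maximized likelihoods.
    """
    y = np.asarray(y, dtype=float)
    classes = np.asarray(classes)
    in1 = classes == 1
    in2 = classes == 2

    def nll_full(p):
        m1, m2, logs = p
        s = math.exp(logs)
        mu = np.where(in1, m1, m2)
        return -norm.logpdf(y, mu, s).sum()

    def nll_null(p):
        m, logs = p
        s = math.exp(logs)
        return -norm.logpdf(y, m, s).sum()

    opts = dict(xatol=1e-12, fatol=1e-14, maxiter=20000, maxfev=20000)
    s0 = math.log(y.std() + 0.5)
    r_full = minimize(
        nll_full, [y[in1].mean() + 0.1, y[in2].mean() - 0.1, s0 + 0.2],
        method="Nelder-Mead", options=opts,
    )
    r_null = minimize(nll_null, [y.mean() + 0.1, s0 + 0.2], method="Nelder-Mead",
                      options=opts)
    lod = (r_null.fun - r_full.fun) / math.log(10.0)
    m1, m2 = r_full.x[0], r_full.x[1]
    s_full = math.exp(r_full.x[2])
    s_null = math.exp(r_null.x[1])
    pct = 100.0 * (1.0 - (s_full / s_null) ** 2)
    return float(lod), float((m1 - m2) / 2.0), float(pct)


def all_perfect_matchings(nodes: list):
    """Yield every perfect matching of an even node list."""
    if not nodes:
        yield []
        return
    a = nodes[0]
    for i in range(1, len(nodes)):
        b = nodes[i]
        rest = nodes[1:i] + nodes[i + 1 :]
        for rest_match in all_perfect_matchings(rest):
            yield [(a, b)] + rest_match


def best_matching_weight(dist: np.ndarray) -> float:
    """Maximum total weight over all perfect matchings (exhaustive)."""
    n = dist.shape[0]
    assert n % 2 == 0 and n <= 10
    best = -math.inf
    for matching in all_perfect_matchings(list(range(n))):
        w = sum(dist[a, b] for a, b in matching)
        best = max(best, w)
    return best


def mc_randomization_max_mean(
    n_items: int, n_cells: int, replicates: int, seed: int
) -> np.ndarray:
    """Monte-Carlo maxima of uniform cell counts, coded independently
    (per-item uniform draws + bincount rather than a multinomial call)."""
    rng = np.random.default_rng(seed)
    out = np.empty(replicates, dtype=int)
    for r in range(replicates):
        cells = rng.integers(0, n_cells, size=n_items)
        out[r] = np.bincount(cells, minlength=n_cells).max()
    return out
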