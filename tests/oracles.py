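"""Independent brute-force oracles used by the test suite.

These never call the simulator: outcome distributions are enumerated
exactly from the binomial law, so they can falsify the sampling paths.
"""

import numpy as np
from scipy import stats as sps


def pair_outcomes(c: int) -> dict:
    """Distribution of the viable-daughter multiset from one c-copy cell."""
    out = {}
    for a in range(2 * c + 1):
        p = sps.binom.pmf(a, 2 * c, 0.5)
        key = tuple(sorted(x for x in (a, 2 * c - a) if x > 0))
        out[key] = out.get(key, 0.0) + p
    return out


def exact_culture_distribution(founder: int, generations: int) -> dict:
    """Exact law of the viable-copies multiset after synchronous divisions."""
    dist = {(founder,): 1.0}
    for _ in range(generations):
        new = {}
        for state, p in dist.items():
            partial = {(): p}
            for c in state:
                pair = pair_outcomes(c)
                nxt = {}
                for s1, p1 in partial.items():
                    for s2, p2 in pair.items():
                        key = tuple(sorted(s1 + s2))
                        nxt[key] = nxt.get(key, 0.0) + p1 * p2
                partial = nxt
            for s, q in partial.items():
                new[s] = new.get(s, 0.0) + q
        dist = new
    return dist


def chisquare_against(expected: dict, observed: dict, n: int, min_expected=5.0) -> float:
    """Chi-square goodness-of-fit p-value, lumping rare categories."""
    keys = sorted(expected, key=expected.get, reverse=True)
    exp, obs = [], []
    tail_e = tail_o = 0.0
    for k in keys:
        e = expected[k] * n
        o = observed.get(k, 0)
        if e >= min_expected:
            exp.append(e)
            obs.append(o)
        else:
            tail_e += e
            tail_o += o
    for k in set(observed) - set(expected):
        tail_o += observed[k]
    if tail_e > 0:
        exp.append(tail_e)
        obs.append(tail_o)
    exp = np.array(exp) * (n / np.sum(exp))
    return sps.chisquare(obs, exp).pvalue
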