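"""Independent brute-force oracles used by the tests.

``ssd_distribution`` enumerates single-seed descent exactly on a small
multi-locus genome by transfer-matrix iteration over diplotype
distributions: a diplotype is an ordered pair of haplotypes (tuples of
parental-origin bits), a gamete is formed by choosing an origin path with
independent per-interval recombination (Haldane, no interference), and a
selfing generation replaces the diplotype with two independent gametes.
This is deliberately slow-and-exact and shares no code with the package's
simulators or genotype-probability machinery.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np


@lru_cache(maxsize=None)
def _gamete_probs(diplotype: tuple, rs: tuple) -> dict:
    """P(gamete | diplotype) by summing over all origin paths."""
    h0, h1 = diplotype
    m = len(h0)
    out: dict[tuple, float] = {}
    for path in itertools.product((0, 1), repeat=m):
        p = 0.5
        for k in range(m - 1):
            p *= rs[k] if path[k] != path[k + 1] else 1.0 - rs[k]
        gam = tuple(h0[k] if path[k] == 0 else h1[k] for k in range(m))
        out[gam] = out.get(gam, 0.0) + p
    return out


def ssd_distribution(rs, generations: int) -> dict:
    """Diplotype distribution of an F_g-derived line from an F1.

    ``rs`` are per-interval recombination fractions (length m-1 for an
    m-locus genome); ``generations`` is the derived generation g (g=1 is the
    F1 itself, each increment is one selfing round).  Returns a dict mapping
    ordered diplotypes (pairs of origin-bit tuples) to probability.
    """
    rs = tuple(float(r) for r in rs)
    m = len(rs) + 1
    f1 = ((0,) * m, (1,) * m)
    dist = {f1: 1.0}
    for _ in range(generations - 1):
        nxt: dict[tuple, float] = {}
        for dip, p in dist.items():
            gp = _gamete_probs(dip, rs)
            for g1, p1 in gp.items():
                for g2, p2 in gp.items():
                    key = (g1, g2)
                    nxt[key] = nxt.get(key, 0.0) + p * p1 * p2
        dist = nxt
    return dist


def genotype_distribution(rs, generations: int) -> dict:
    """Marginal distribution over multi-locus genotype codes (0/1/2 per
    locus: 0 = parent-1 hom, 1 = het, 2 = parent-2 hom)."""
    out: dict[tuple, float] = {}
    for (h0, h1), p in ssd_distribution(rs, generations).items():
        code = tuple(a + b for a, b in zip(h0, h1))
        out[code] = out.get(code, 0.0) + p
    return out


def conditional_middle_prob(r1: float, r2: float, generations: int,
                            left_code: int, right_code: int) -> np.ndarray:
    """P(middle genotype | flanking genotypes) on a 3-locus genome,
    as a vector over middle codes (0, 1, 2)."""
    dist = genotype_distribution((r1, r2), generations)
    num = np.zeros(3)
    for code, p in dist.items():
        if code[0] == left_code and code[2] == right_code:
            num[code[1]] += p
    return num / num.sum()


def haldane(d_cm: float) -> float:
    return 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))
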