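"""Brute-force reference implementations used only to check the package.

Everything here is deliberately naive — exact combinatorics with Python
integers, full enumeration, whole-protein translation — and shares no code
with the implementation paths it validates.
"""

import itertools
from math import comb

from Bio.Seq import Seq


def binom_pmf_exact(k: int, n: int, p: float) -> float:
    return comb(n, k) * p**k * (1 - p) ** (n - k)


def binom_two_sided_brute(k: int, n: int, p: float) -> float:
    """Minimum-likelihood two-sided exact binomial p by pmf summation."""
    if p == 0:
        return 1.0 if k == 0 else 0.0
    if p == 1:
        return 1.0 if k == n else 0.0
    obs = binom_pmf_exact(k, n, p)
    total = sum(
        pm
        for j in range(n + 1)
        if (pm := binom_pmf_exact(j, n, p)) <= obs * (1 + 1e-7)
    )
    return min(1.0, total)


def hypergeom_pmf_exact(k: int, N: int, K: int, n: int) -> float:
    if k < max(0, n + K - N) or k > min(K, n):
        return 0.0
    return comb(K, k) * comb(N - K, n - k) / comb(N, n)


def hypergeom_upper_brute(m: int, N: int, K: int, n: int) -> float:
    """P(X >= m) for X ~ Hypergeometric(N, K, n), exact summation."""
    return sum(hypergeom_pmf_exact(k, N, K, n) for k in range(m, min(K, n) + 1))


def mannwhitney_exact_brute(x, y) -> float:
    """Two-sided exact Mann-Whitney p by enumerating label assignments.

    U is computed by direct pair counting (wins + half-ties); the two-sided
    p is twice the smaller tail of the permutation distribution, capped at 1.
    """

    def u_stat(a, b):
        return sum(
            (1.0 if xi > yj else 0.5 if xi == yj else 0.0)
            for xi in a
            for yj in b
        )

    pooled = list(x) + list(y)
    n = len(x)
    u_obs = u_stat(x, y)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(u_stat(a, b))
    lower = sum(u <= u_obs + 1e-9 for u in us) / len(us)
    upper = sum(u >= u_obs - 1e-9 for u in us) / len(us)
    return min(1.0, 2 * min(lower, upper))


def classify_by_translation(genome, orf, pos: int, alt: str) -> str:
    """Effect of one substitution in one ORF, by translating the whole CDS
    before and after the change and comparing the proteins."""
    seq = list(genome.sequence)
    assert orf.covers(pos)
    ref_cds = _cds(seq, orf)
    seq[pos - 1] = alt
    alt_cds = _cds(seq, orf)
    ref_prot = str(Seq(ref_cds).translate())
    alt_prot = str(Seq(alt_cds).translate())
    changed = [i for i, (a, b) in enumerate(zip(ref_prot, alt_prot)) if a != b]
    if not changed:
        if alt_cds[:3] != "ATG" and ref_cds[:3] == "ATG":
            return "start_lost"
        return "synonymous"
    (i,) = changed
    a, b = ref_prot[i], alt_prot[i]
    if a == "*" and b != "*":
        return "stop_lost"
    if b == "*" and a != "*":
        return "stop_gained"
    if i == 0 and ref_cds[:3] == "ATG":
        return "start_lost"
    return "nonsynonymous"


def _cds(seq_list, orf) -> str:
    parts = [
        "".join(seq_list[start - 1 : end]) for start, end in orf.segments
    ]
    joined = "".join(parts)
    if orf.strand == "-":
        joined = str(Seq(joined).reverse_complement())
    return joined


def holm_stepdown_brute(pvals):
    """Holm adjustment exactly as defined: sort, multiply, running max."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, min(1.0, (m - rank) * pvals[i]))
        adj[i] = running
    return adj
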