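"""Independent brute-force oracles used by the test suite.

These stay deliberately naive (exact rational arithmetic, exhaustive
enumeration) and share no code with the implementation paths they
check.
"""

from fractions import Fraction
from itertools import combinations
from math import factorial


def hwe_exact_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact-rational two-sided HWE p-value by full enumeration.

    Enumerates every heterozygote count compatible with the observed
    allele counts; outcome probabilities are the Levene-Haldane
    conditional probabilities computed with Fraction factorials, and
    the p-value sums those <= the observed outcome's probability.
    """
    n = n_AA + n_Aa + n_aa
    n_a = n_Aa + 2 * n_aa
    n_A = 2 * n - n_a

    def prob(h: int) -> Fraction:
        hom_a = (n_a - h) // 2
        hom_A = (n_A - h) // 2
        return Fraction(
            factorial(n) * 2**h * factorial(n_a) * factorial(n_A),
            factorial(hom_A) * factorial(h) * factorial(hom_a) * factorial(2 * n),
        )

    h_min = min(n_a, n_A) % 2
    h_max = min(n_a, n_A)
    probs = {h: prob(h) for h in range(h_min, h_max + 1, 2)}
    p_obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= p_obs))


def greedy_prune_oracle(snp_ids, r2_lookup, threshold):
    """Replay the greedy scan naively: keep a SNP unless it exceeds the
    threshold against any already-kept SNP, in the given order."""
    kept = []
    for s in snp_ids:
        if all(r2_lookup(s, k) <= threshold for k in kept):
            kept.append(s)
    return kept


def transitive_closure_oracle(snp_ids, r2_lookup, threshold):
    """Connected components by naive repeated merging."""
    comps = [{s} for s in snp_ids]
    changed = True
    while changed:
        changed = False
        for a, b in combinations(range(len(comps)), 2):
            if any(
                r2_lookup(x, y) > threshold for x in comps[a] for y in comps[b]
            ):
                comps[a] |= comps[b]
                del comps[b]
                changed = True
                break
    return sorted([sorted(c) for c in comps], key=lambda c: (-len(c), c[0]))


def min_vertex_cover_size(edges) -> int:
    """Smallest set of vertices touching every edge, by exhaustive search."""
    verts = sorted({v for e in edges for v in e})
    for k in range(len(verts) + 1):
        for cover in combinations(verts, k):
            cset = set(cover)
            if all(cset & set(e) for e in edges):
                return k
    return len(verts)
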