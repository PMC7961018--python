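"""Exact-arithmetic enumeration oracle for the Hardy-Weinberg exact test.

Independent of the package implementation: conditional probabilities are
computed as exact integer ratios (multinomial configuration counts over
the allele-count hypergeometric denominator), the tie rule uses exact
integer comparison, and floating point enters only in the final
division.
"""

from fractions import Fraction
from math import comb


def hwe_het_weights_exact(n_total: int, n_a: int) -> tuple[list[int], list[int], int]:
    """(het counts, integer configuration weights, common denominator).

    weight(h) = C(n, n_aa) * C(n - n_aa, h) * 2^h counts the phased
    genotype configurations with h heterozygotes; the denominator is
    C(2n, n_a).  weight/denominator is the exact conditional probability.
    """
    n_b = 2 * n_total - n_a
    rare = min(n_a, n_b)
    hets, weights = [], []
    for h in range(rare % 2, rare + 1, 2):
        n_aa = (n_a - h) // 2
        weights.append(comb(n_total, n_aa) * comb(n_total - n_aa, h) * (1 << h))
        hets.append(h)
    denom = comb(2 * n_total, n_a)
    assert sum(weights) == denom
    return hets, weights, denom


def hwe_pvalues_exact(n_total: int, n_a: int) -> dict[int, float]:
    """Exact-test p-value for every feasible heterozygote count."""
    hets, weights, denom = hwe_het_weights_exact(n_total, n_a)
    order = sorted(range(len(hets)), key=weights.__getitem__)
    prefix = []
    acc = 0
    for i in order:
        acc += weights[i]
        prefix.append(acc)
    pos = {idx: k for k, idx in enumerate(order)}
    out = {}
    for i, h in enumerate(hets):
        k = pos[i]
        # include every configuration whose weight <= observed weight
        while k + 1 < len(order) and weights[order[k + 1]] <= weights[i]:
            k += 1
        out[h] = prefix[k] / denom
    return out


def hwe_het_distribution_exact(n_total: int, n_a: int) -> dict[int, Fraction]:
    hets, weights, denom = hwe_het_weights_exact(n_total, n_a)
    return {h: Fraction(w, denom) for h, w in zip(hets, weights)}


def hwe_exact_pvalue_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_AA + n_Aa
    return hwe_pvalues_exact(n, n_a)[n_Aa]
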