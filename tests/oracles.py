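"""Independent brute-force oracles kept deliberately naive.

These re-state the mapping and enrichment definitions in their most literal
form — the iterative trim-one-base-and-retry loop, and the hypergeometric
sum over binomial coefficients — so the optimized implementations can be
checked against something that cannot share their bugs.
"""

from math import comb


def iterative_trim_map(seq: str, hairpin_seqs: dict[str, str], floor: int = 18):
    """Literal 3'-trimming mapper: try the full read, trim one 3' base on
    failure, stop below the length floor.

    Returns (match_len, [(hairpin_id, 1-based start), ...]) or (0, []).
    """
    for L in range(len(seq), floor - 1, -1):
        prefix = seq[:L]
        hits = []
        for hid, hseq in hairpin_seqs.items():
            i = hseq.find(prefix)
            while i != -1:
                hits.append((hid, i + 1))
                i = hseq.find(prefix, i + 1)
        if hits:
            return L, sorted(hits)
    return 0, []


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by exhaustive enumeration of the hypergeometric pmf."""
    total = comb(N, n)
    return sum(comb(K, x) * comb(N - K, n - x) for x in range(k, min(K, n) + 1)) / total


def bh_stepup(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values, computed by hand."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        running_min = min(running_min, pvalues[idx] * m / rank)
        adjusted[idx] = running_min
    return adjusted
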