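"""Brute-force reference implementations, independent of the package.

Plain-Python double loops and exhaustive enumerations used only to verify
the vectorized estimators on short inputs.
"""

import math
from itertools import permutations


def apen_bruteforce(x, m, r):
    """Approximate entropy via the classic O(n^2) double loop.

    Self-matches included; Chebyshev distance; Phi_m = mean log match
    fraction over all m-length templates.
    """
    x = list(map(float, x))
    n = len(x)

    def phi(mm):
        templates = [x[i:i + mm] for i in range(n - mm + 1)]
        logs = []
        for ti in templates:
            cnt = sum(
                1 for tj in templates
                if max(abs(a - b) for a, b in zip(ti, tj)) <= r)
            logs.append(math.log(cnt / len(templates)))
        return sum(logs) / len(logs)

    return phi(m) - phi(m + 1)


def permen_bruteforce(x, m, tau):
    """Normalized permutation entropy by exhaustive motif counting.

    Ordinal pattern of a motif = the permutation that stably sorts it
    (ties broken by index order), counted over all motifs.
    """
    x = list(map(float, x))
    n_motifs = len(x) - (m - 1) * tau
    counts = {p: 0 for p in permutations(range(m))}
    for i in range(n_motifs):
        motif = [x[i + j * tau] for j in range(m)]
        order = tuple(sorted(range(m), key=lambda j: (motif[j], j)))
        counts[order] += 1
    H = 0.0
    for c in counts.values():
        if c:
            p = c / n_motifs
            H -= p * math.log2(p)
    return H / math.log2(math.factorial(m))


def lz76_bruteforce(bits):
    """LZ76 exhaustive-history phrase count by direct string parsing.

    A phrase ends at the first symbol that makes the current substring
    non-reproducible from the prior history; the final (possibly still
    reproducible) phrase counts as one.
    """
    s = "".join(str(int(b)) for b in bits)
    n = len(s)
    c, i = 1, 1
    while i < n:
        k = 1
        while i + k <= n and s[i:i + k] in s[:i + k - 1]:
            k += 1
        c += 1
        i += k
    return c
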