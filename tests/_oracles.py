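"""Independent brute-force oracles, kept deliberately naive.

These re-derive the estimators with explicit Python loops straight from the
formulas, sharing no code with the package, so the vectorized
implementations can be checked against them.
"""

from __future__ import annotations

import math


def brute_components(counts, delta):
    """(vS, vT) from per-region haplotype counts and a distance matrix."""
    K = len(counts)
    H = len(counts[0])
    n_k = [sum(row) for row in counts]
    v_k = []
    for k in range(K):
        x = [c / n_k[k] for c in counts[k]]
        s = 0.0
        for i in range(H):
            for j in range(H):
                s += x[i] * x[j] * delta[i][j]
        v_k.append(n_k[k] / (n_k[k] - 1.0) * s)
    v_s = sum(v_k) / K
    xbar = [sum(counts[k][i] / n_k[k] for k in range(K)) / K for i in range(H)]
    ntilde = K / sum(1.0 / n for n in n_k)
    tot = 0.0
    for i in range(H):
        for j in range(H):
            tot += xbar[i] * xbar[j] * delta[i][j]
    return v_s, tot + v_s / (K * ntilde)


def brute_gst_nst(counts, delta):
    """(Gst, Nst) raw estimates; None when the denominator vanishes."""
    H = len(counts[0])
    indicator = [[0.0 if i == j else 1.0 for j in range(H)] for i in range(H)]
    h_s, h_t = brute_components(counts, indicator)
    v_s, v_t = brute_components(counts, delta)
    gst = None if h_t <= 1e-12 else (h_t - h_s) / h_t
    nst = None if v_t <= 1e-12 else (v_t - v_s) / v_t
    return gst, nst


def brute_k2p(seq_a, seq_b):
    """K2P distance with pairwise deletion; None on saturation/no data."""
    valid = set("ACGT")
    purine = set("AG")
    n = ts = tv = 0
    for a, b in zip(seq_a, seq_b):
        if a in valid and b in valid:
            n += 1
            if a != b:
                if (a in purine) == (b in purine):
                    ts += 1
                else:
                    tv += 1
    if n == 0:
        return None
    p, q = ts / n, tv / n
    if 1 - 2 * p - q <= 0 or 1 - 2 * q <= 0:
        return None
    return -0.5 * math.log(1 - 2 * p - q) - 0.25 * math.log(1 - 2 * q)


def brute_loiselle(hap_indices_by_locus, n_haps_by_locus):
    """Pairwise kinship over individuals scored at every locus.

    hap_indices_by_locus: per locus, a list giving each individual's
    haplotype index (all individuals scored at all loci).
    Returns the full matrix as nested lists (None on the diagonal).
    """
    n = len(hap_indices_by_locus[0])
    fij = [[None] * n for _ in range(n)]
    num = [[0.0] * n for _ in range(n)]
    den = [[0.0] * n for _ in range(n)]
    for hap_idx, H in zip(hap_indices_by_locus, n_haps_by_locus):
        p = [sum(1 for h in hap_idx if h == a) / n for a in range(H)]
        d_l = sum(pa * (1 - pa) for pa in p)
        if d_l <= 0:
            continue
        for i in range(n):
            for j in range(n):
                s = 0.0
                for a in range(H):
                    xia = 1.0 if hap_idx[i] == a else 0.0
                    xja = 1.0 if hap_idx[j] == a else 0.0
                    s += (xia - p[a]) * (xja - p[a])
                num[i][j] += s + d_l / (n - 1)
                den[i][j] += d_l
    for i in range(n):
        for j in range(n):
            if i != j and den[i][j] > 0:
                fij[i][j] = num[i][j] / den[i][j]
    return fij


def brute_welch(a, b):
    """(t, df) for the unequal-variance t-test, textbook formulas."""
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, df
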