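"""Naive double-loop reference implementations used as independent oracles.

These deliberately trade speed for obviousness: every sum is an explicit
loop over the defining index ranges, with no reuse of package code.
"""

import math

import numpy as np


def ors_naive(dom_labels, D, label):
    """D is a dict (i, j) -> value over unordered domain pairs i < j."""
    other = "P" if label == "F" else "F"
    num = 0.0
    den = 0.0
    n = len(dom_labels)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = D.get((min(i, j), max(i, j)), 0.0)
            if dom_labels[i] == label and dom_labels[j] == label:
                num += d  # ordered pairs: each unordered pair hit twice
            if dom_labels[i] == label and dom_labels[j] == other and i < j:
                den += d
            if dom_labels[i] == other and dom_labels[j] == label and i < j:
                den += d
    return num / den


def drs_naive(dom_labels, D, i):
    other = "P" if dom_labels[i] == "F" else "F"
    num = 0.0
    den = 0.0
    for j in range(len(dom_labels)):
        if j == i:
            continue
        d = D.get((min(i, j), max(i, j)), 0.0)
        if dom_labels[j] == dom_labels[i]:
            num += d
        elif dom_labels[j] == other:
            den += d
    if den == 0:
        return math.nan
    return num / den


def rs_naive(C, bin_labels, label, d):
    other = "P" if label == "F" else "F"
    n = len(bin_labels)
    num = 0.0
    den = 0.0
    for i in range(n):
        if bin_labels[i] != label:
            continue
        for j in (i - d, i + d):
            if 0 <= j < n:
                if bin_labels[j] == label:
                    num += C[i, j]
                elif bin_labels[j] == other:
                    den += C[i, j]
    if den == 0:
        return math.nan
    return num / den


def tc10_naive(C, bin_labels, d, top_frac=0.1):
    """Proportion triple (pFF, pFP, pPP) for one offset."""
    n = len(bin_labels)
    entries = []
    for i in range(n - d):
        j = i + d
        if bin_labels[i] in ("F", "P") and bin_labels[j] in ("F", "P"):
            entries.append((C[i, j], i, j))
    if not entries:
        return None
    k = math.ceil(top_frac * len(entries))
    entries.sort(key=lambda t: (-t[0], t[1]))
    top = entries[:k]
    if any(v == 0 for v, _, _ in top):
        return (0.0, 0.0, 0.0)
    ff = sum(1 for _, i, j in top if bin_labels[i] == "F" and bin_labels[j] == "F")
    pp = sum(1 for _, i, j in top if bin_labels[i] == "P" and bin_labels[j] == "P")
    fp = k - ff - pp
    return (ff / k, fp / k, pp / k)


def cindex_naive(C, delta, i):
    """delta: per-bin 1 (A) / 0 (B) / nan (undefined)."""
    sa = sb = 0.0
    na = nb = 0
    for j in range(len(delta)):
        if not np.isfinite(delta[j]):
            continue
        if delta[j] == 1:
            sa += C[i, j]
            na += 1
        else:
            sb += C[i, j]
            nb += 1
    if na == 0 or nb == 0 or sa == 0 or sb == 0:
        return math.nan
    return math.log((sa / na) / (sb / nb))


def mdi_naive(q, i):
    """q: ordered per-domain means (one chromosome)."""
    if i == 0 or i == len(q) - 1:
        return math.nan
    tri = (q[i - 1], q[i], q[i + 1])
    if any(not np.isfinite(t) for t in tri):
        return math.nan
    denom = sum(tri) / 3.0
    if denom == 0:
        return math.nan
    return (tri[1] - (tri[0] + tri[2]) / 2.0) / denom


def ror_naive(d1, d2):
    nij = sum(1 for a, b in zip(d1, d2) if a > b)
    nji = sum(1 for a, b in zip(d1, d2) if a < b)
    return nij, nji, math.log(nij / nji)
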