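"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's own code paths (and the library
calls they delegate to): plain-loop sums, from-scratch BH, explicit
interval scans.  Only scipy's t-distribution tail is shared, as the
canonical special function.
"""

from __future__ import annotations

import math

from scipy import stats


def pearson_r(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def corr_pvalue(r: float, n: int) -> float:
    if abs(r) >= 1.0:
        return 5e-324
    t = r * math.sqrt((n - 2) / (1 - r * r))
    return 2.0 * stats.t.sf(abs(t), df=n - 2)


def welch_p(a, b) -> float:
    """Welch's two-sided t test P with the degenerate-variance convention
    (zero pooled variance: 0 if means differ, else 1)."""
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    if se2 == 0:
        return 1.0 if ma == mb else 0.0
    t = (ma - mb) / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2.0 * stats.t.sf(abs(t), df=df)


def bh_adjust(pvalues) -> list[float]:
    """Benjamini–Hochberg adjusted values, from scratch."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        value = min(1.0, pvalues[idx] * m / rank)
        running_min = min(running_min, value)
        adjusted[idx] = running_min
    return adjusted


def containment_scan(genes, segments) -> dict[str, set[str]]:
    """gene_id -> il_ids whose interval contains the gene start (point)."""
    out = {}
    for g in genes:
        hits = set()
        for seg in segments:
            if seg.chromosome == g.chromosome and seg.start <= g.start < seg.end:
                hits.add(seg.il_id)
        out[g.gene_id] = hits
    return out


def robust_eqtl_calls(il_log2_means: dict, parent_log2: float,
                      z_min: float, min_abs_log2: float) -> set[str]:
    """The detection rule, re-derived with plain Python statistics."""
    xs = sorted(il_log2_means.values())
    n = len(xs)
    med = (xs[n // 2] if n % 2 else (xs[n // 2 - 1] + xs[n // 2]) / 2)
    devs = sorted(abs(v - med) for v in xs)
    mad = (devs[n // 2] if n % 2 else (devs[n // 2 - 1] + devs[n // 2]) / 2)
    called = set()
    for il, x in il_log2_means.items():
        ratio = x - parent_log2
        if mad == 0:
            if abs(ratio) >= min_abs_log2:
                called.add(il)
        else:
            z = (x - med) / (1.4826 * mad)
            if abs(z) >= z_min and abs(ratio) >= min_abs_log2:
                called.add(il)
    return called
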