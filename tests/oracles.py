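"""Independent brute-force re-implementations used as test oracles.

Everything here is written as plain per-site / per-sample Python loops,
deliberately sharing no code with the vectorized package paths it checks.
"""

import math

from introscan.io import MISSING


def brute_site_stats(row):
    """(maf, missing_rate, het_rate) for one site's call list."""
    n = len(row)
    nonmiss = [int(g) for g in row if g != MISSING]
    missing_rate = (n - len(nonmiss)) / n
    if not nonmiss:
        return float("nan"), missing_rate, float("nan")
    alt = sum(g for g in nonmiss)
    p = alt / (2 * len(nonmiss))
    het = sum(1 for g in nonmiss if g == 1) / len(nonmiss)
    return min(p, 1 - p), missing_rate, het


def brute_filter(matrix, maf_min, missing_max, het_max):
    """Indices of sites passing all three strict filters."""
    keep = []
    for i in range(matrix.n_sites):
        maf, miss, het = brute_site_stats(list(matrix.calls[i]))
        if math.isnan(maf) or math.isnan(het):
            continue
        if maf > maf_min and miss < missing_max and het < het_max:
            keep.append(i)
    return keep


def brute_site_pi(row):
    """Pairwise-difference pi for one site's call list, NaN if < 2 alleles."""
    nonmiss = [int(g) for g in row if g != MISSING]
    n = 2 * len(nonmiss)
    if n < 2:
        return float("nan")
    j = sum(nonmiss)
    return 2 * j * (n - j) / (n * (n - 1))


def wc84_scalar(n1, p1, h1, n2, p2, h2):
    """Textbook two-population WC84 components (a, b, c), scalar arithmetic.

    n_i diploid sample sizes, p_i allele frequencies, h_i observed het
    proportions; r = 2 populations.
    """
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


def brute_wc_window(matrix, g1, g2, window):
    """Window Fst as ratio of per-site WC84 sums, all-loop implementation."""
    i1 = [matrix.samples.index(s) for s in g1]
    i2 = [matrix.samples.index(s) for s in g2]
    num = den = 0.0
    for i in range(matrix.n_sites):
        if matrix.chrom[i] != window.chrom:
            continue
        if not (window.start <= matrix.pos[i] - 1 < window.end):
            continue
        stats = []
        for idx in (i1, i2):
            calls = [int(matrix.calls[i, j]) for j in idx
                     if matrix.calls[i, j] != MISSING]
            n = len(calls)
            if n == 0:
                stats = None
                break
            p = sum(calls) / (2 * n)
            h = sum(1 for g in calls if g == 1) / n
            stats.append((n, p, h))
        if stats is None:
            continue
        (n1, p1, h1), (n2, p2, h2) = stats
        if n1 + n2 <= 2:
            continue
        a, b, c = wc84_scalar(n1, p1, h1, n2, p2, h2)
        num += a
        den += a + b + c
    return num / den if den != 0 else float("nan")


def brute_identity_counts(receptor_call, group_calls):
    """Site (isc, vsc) by explicit comparison loop."""
    if receptor_call == MISSING:
        return 0, 0
    isc = vsc = 0
    for g in group_calls:
        if g == MISSING:
            continue
        vsc += 1
        if g == receptor_call:
            isc += 1
    return isc, vsc


def brute_window_index(matrix, receptor, donor, acceptor, window):
    """Windowed introgressive index by site loop; NaN if a VSC is zero."""
    ri = matrix.samples.index(receptor)
    di = [matrix.samples.index(s) for s in donor]
    ai = [matrix.samples.index(s) for s in acceptor]
    isc_d = vsc_d = isc_a = vsc_a = 0
    for i in range(matrix.n_sites):
        if matrix.chrom[i] != window.chrom:
            continue
        if not (window.start <= matrix.pos[i] - 1 < window.end):
            continue
        rc = int(matrix.calls[i, ri])
        i1, v1 = brute_identity_counts(rc, [int(matrix.calls[i, j]) for j in di])
        i2, v2 = brute_identity_counts(rc, [int(matrix.calls[i, j]) for j in ai])
        isc_d += i1
        vsc_d += v1
        isc_a += i2
        vsc_a += v2
    if vsc_d == 0 or vsc_a == 0:
        return float("nan")
    return isc_d / vsc_d - isc_a / vsc_a


def brute_confusion(truths, fragments, windows):
    """Window-level TP/FP/FN by exhaustive overlap loops."""
    receptors = {t.receptor for t in truths} | {f.receptor for f in fragments}
    tp = fp = fn = 0
    for rec in receptors:
        for wi, w in enumerate(windows):
            in_truth = any(
                t.receptor == rec and t.chrom == w.chrom
                and t.start < w.end and w.start < t.end
                for t in truths)
            in_det = any(
                f.receptor == rec and f.chrom == w.chrom
                and f.start < w.end and w.start < f.end
                for f in fragments)
            if in_truth and in_det:
                tp += 1
            elif in_det:
                fp += 1
            elif in_truth:
                fn += 1
    return tp, fp, fn
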