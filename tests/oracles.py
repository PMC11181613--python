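"""Independent, deliberately slow reference implementations.

Everything here is coded directly from the textbook formulas with explicit
Python loops — no shared code with the package — so the vectorized
implementations can be checked against them to tight tolerances.
"""

from __future__ import annotations

import itertools
import math

MISSING = -1


def _pop_site_summary(doses):
    """(diploid count, ALT freq, observed het freq) for one site, one pop."""
    called = [d for d in doses if d != MISSING]
    n = len(called)
    if n == 0:
        return 0, None, None
    p = sum(called) / (2.0 * n)
    h = sum(1 for d in called if d == 1) / n
    return n, p, h


def wc_fst_site(doses1, doses2):
    """Weir & Cockerham (1984) variance components (a, b, c) for one site and
    two populations, or None when either population has no called genotype."""
    n1, p1, h1 = _pop_site_summary(doses1)
    n2, p2, h2 = _pop_site_summary(doses2)
    if n1 == 0 or n2 == 0:
        return None
    r = 2
    nbar = (n1 + n2) / r
    if nbar <= 1:
        return None
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    if nc == 0:
        return None
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


def wc_fst_window(window_doses1, window_doses2):
    """Ratio-of-sums window F_ST; window_doses* are lists of per-site dose
    lists."""
    num = den = 0.0
    for d1, d2 in zip(window_doses1, window_doses2):
        comp = wc_fst_site(d1, d2)
        if comp is None:
            continue
        a, b, c = comp
        num += a
        den += a + b + c
    return num / den if den != 0 else float("nan")


def pi_site(doses):
    """Per-site mean pairwise difference via allele-pair counting:
    n_alt * n_ref / C(m, 2) over the m called chromosomes."""
    called = [d for d in doses if d != MISSING]
    m = 2 * len(called)
    if m < 2:
        return 0.0
    n_alt = sum(called)
    n_ref = m - n_alt
    return n_alt * n_ref / (m * (m - 1) / 2.0)


def pi_window(window_doses, window_length):
    return sum(pi_site(d) for d in window_doses) / window_length


def tajimas_d(window_doses):
    """Tajima's D with constants recomputed by direct summation; n is the
    median called-chromosome count over segregating sites. NaN when S = 0 or
    n < 4."""
    seg = []
    for doses in window_doses:
        called = [d for d in doses if d != MISSING]
        m = 2 * len(called)
        if m < 2:
            continue
        n_alt = sum(called)
        if 0 < n_alt < m:
            seg.append((m, n_alt))
    S = len(seg)
    if S == 0:
        return float("nan")
    ms = sorted(m for m, _ in seg)
    mid = len(ms) // 2
    n = ms[mid] if len(ms) % 2 == 1 else (ms[mid - 1] + ms[mid]) / 2.0
    if n < 4:
        return float("nan")
    theta_pi = sum(na * (m - na) / (m * (m - 1) / 2.0) for m, na in seg)
    a1 = sum(1.0 / i for i in range(1, int(n)))
    a2 = sum(1.0 / i**2 for i in range(1, int(n)))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return float("nan")
    return (theta_pi - S / a1) / math.sqrt(var)


def ld_prune_bruteforce(dosage_cols, chroms, mafs, window, step, r2_max):
    """All-pairs reimplementation of the greedy sliding-window pruning rule.

    dosage_cols: list of per-site dose lists; returns retained indices.
    """

    def r2(x, y):
        pairs = [(a, b) for a, b in zip(x, y) if a != MISSING and b != MISSING]
        if len(pairs) < 2:
            return 0.0
        xs = [p[0] for p in pairs]
        ys = [p[1] for p in pairs]
        mx = sum(xs) / len(xs)
        my = sum(ys) / len(ys)
        vx = sum((a - mx) ** 2 for a in xs)
        vy = sum((b - my) ** 2 for b in ys)
        if vx == 0 or vy == 0:
            return 0.0
        cov = sum((a - mx) * (b - my) for a, b in zip(xs, ys))
        return cov * cov / (vx * vy)

    removed = set()
    seen = []
    for ch in chroms:
        if ch not in seen:
            seen.append(ch)
    for ch in seen:
        idx = [i for i, c in enumerate(chroms) if c == ch]
        start = 0
        while start < len(idx):
            win = [i for i in idx[start:start + window] if i not in removed]
            while True:
                best = None
                best_r2 = r2_max
                for a in range(len(win)):
                    for b in range(a + 1, len(win)):
                        v = r2(dosage_cols[win[a]], dosage_cols[win[b]])
                        if v > best_r2:
                            best_r2 = v
                            best = (win[a], win[b])
                if best is None:
                    break
                i, j = best
                if mafs[j] < mafs[i]:
                    drop = j
                elif mafs[i] < mafs[j]:
                    drop = i
                else:
                    drop = max(i, j)
                removed.add(drop)
                win.remove(drop)
            start += step
    return [i for i in range(len(dosage_cols)) if i not in removed]


def allele_sharing_distance(dose_i, dose_j):
    vals = [
        (2 - abs(a - b)) / 2.0
        for a, b in zip(dose_i, dose_j)
        if a != MISSING and b != MISSING
    ]
    return 1.0 - sum(vals) / len(vals)


def hypergeom_p_enumeration(k, set_members, candidate_size, universe):
    """P(|draw ∩ set| >= k) over all candidate_size-subsets of the universe,
    by exhaustive enumeration. Feasible for |universe| ~ 20."""
    hits = total = 0
    sset = set(set_members)
    for draw in itertools.combinations(universe, candidate_size):
        total += 1
        if len(sset.intersection(draw)) >= k:
            hits += 1
    return hits / total


def region_gene_overlaps(regions, genes, min_overlap=1):
    """Quadratic all-pairs overlap: regions (chrom, start0, end0) half-open,
    genes (gene_id, chrom, start1, end1) 1-based inclusive."""
    out = set()
    for gid, gch, gs, ge in genes:
        g0, g1 = gs - 1, ge
        for rch, rs, re in regions:
            if rch != gch:
                continue
            if min(g1, re) - max(g0, rs) >= min_overlap:
                out.add(gid)
    return sorted(out)


def bh_adjust(pvals):
    """Benjamini-Hochberg step-up, coded from the definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        val = min(prev, pvals[i] * m / rank)
        adj[i] = val
        prev = val
    return adj
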