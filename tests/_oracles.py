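"""Independent brute-force oracles used by the test suite.

Each oracle re-derives the quantity it checks from first principles with a
deliberately naive algorithm, staying independent of the library code paths
it validates.
"""

from __future__ import annotations

import itertools
import math


def sampen_bruteforce(x, m: int = 2, r_fraction: float = 0.2) -> float:
    """O(n^2) template-counting sample entropy with plain loops.

    Matches are Chebyshev distance <= r with r = r_fraction * population sd;
    length-m templates start at 0..n-m, length-(m+1) at 0..n-m-1; ordered
    pairs i < j; conventions for degenerate cases mirror the documented
    contract (0 for constant/short series or no m-matches, ln(B) when no
    (m+1)-template pair matches).
    """
    x = [float(v) for v in x]
    n = len(x)
    if n < m + 2:
        return 0.0
    mean = sum(x) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in x) / n)
    if sd <= 1e-12 * max(1.0, abs(mean)):  # numerically constant
        return 0.0
    r = r_fraction * sd

    def count(mm: int) -> int:
        total = 0
        n_templates = n - mm + 1
        for i in range(n_templates):
            for j in range(i + 1, n_templates):
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= r:
                    total += 1
        return total

    b = count(m)
    if b == 0:
        return 0.0
    a = count(m + 1)
    if a == 0:
        return math.log(b)
    return -math.log(a / b)


def event_scan_bruteforce(ratio, dt: float) -> list:
    """Exhaustive window-scan event scorer.

    Tests every (start, stop) index window of the envelope-ratio grid:
    a window is a candidate core iff every sample is < 0.7; maximal cores
    are bridged while the gap stays < 0.9; spans need >= 6 s total below
    0.7 and a corrected duration >= 10 s; apnea when some sub-window below
    0.1 reaches 10 s after deep-edge correction. Returns
    (kind, onset_s, duration_s) tuples.
    """
    ratio = list(map(float, ratio))
    n = len(ratio)
    below70 = [v < 0.7 for v in ratio]
    below10 = [v < 0.1 for v in ratio]

    def maximal_windows(flags):
        nn = len(flags)
        prefix = [0]
        for f in flags:
            prefix.append(prefix[-1] + (1 if f else 0))
        qualifying = []
        for i in range(nn):
            for j in range(i + 1, nn + 1):
                if prefix[j] - prefix[i] == j - i:  # every sample flagged
                    qualifying.append((i, j))
                else:
                    break  # extending further cannot re-qualify
        maximal = [
            (i, j)
            for (i, j) in qualifying
            if (i == 0 or not flags[i - 1]) and (j == nn or not flags[j])
            and j - i == max(jj - ii for ii, jj in qualifying if ii == i)
        ]
        # deduplicate: one maximal window per run
        return sorted(set(maximal))

    cores = maximal_windows(below70)
    spans = []
    for a, b in cores:
        if spans and all(v < 0.9 for v in ratio[spans[-1][1] : a]):
            spans[-1] = (spans[-1][0], b)
        else:
            spans.append((a, b))

    def correction(depth, threshold, edge_s):
        depth = min(max(depth, 0.0), threshold - 1e-6)
        c = 2.0 * (threshold - depth) / (1.0 - depth) - 1.0
        c = min(1.0, max(-1.0, c))
        return edge_s / math.pi * math.acos(c)

    out = []
    for a, b in spans:
        inside = ratio[a:b]
        core_vals = sorted(v for v in inside if v < 0.7)
        if len(core_vals) * dt < 6.0:
            continue
        k = len(core_vals)
        depth = (
            core_vals[k // 2]
            if k % 2 == 1
            else 0.5 * (core_vals[k // 2 - 1] + core_vals[k // 2])
        )
        u = correction(depth, 0.7, 2.0)
        onset = max(0.0, a * dt - u)
        duration = b * dt + u - onset
        if duration < 10.0:
            continue
        kind = "hypopnea"
        for sa, sb in maximal_windows([v < 0.1 for v in inside]):
            sub = sorted(inside[sa:sb])
            ksub = len(sub)
            sub_depth = (
                sub[ksub // 2]
                if ksub % 2 == 1
                else 0.5 * (sub[ksub // 2 - 1] + sub[ksub // 2])
            )
            if (sb - sa) * dt + 2.0 * correction(sub_depth, 0.1, 4.0) >= 10.0:
                kind = "apnea"
                break
        out.append((kind, onset, duration))
    return out


def mannwhitney_enumeration(x, y) -> float:
    """Two-sided permutation p-value of the Mann-Whitney U statistic.

    U is computed by direct pairwise comparison (greater counts 1, tie 1/2)
    for every C(n1+n2, n1) assignment of the pooled values to group 1.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = x + y
    n1 = len(x)

    def u_stat(group1, group2):
        u = 0.0
        for a in group1:
            for b in group2:
                if a > b:
                    u += 1.0
                elif a == b:
                    u += 0.5
        return u

    center = n1 * len(y) / 2.0
    dev_obs = abs(u_stat(x, y) - center)
    hits = 0
    total = 0
    idx = range(len(pooled))
    for combo in itertools.combinations(idx, n1):
        g1 = [pooled[i] for i in combo]
        g2 = [pooled[i] for i in idx if i not in combo]
        if abs(u_stat(g1, g2) - center) >= dev_obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


def fisher_enumeration(table) -> float:
    """Two-sided Fisher p for a 2x2 table by hypergeometric enumeration."""
    (a, b), (c, d) = table
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def log_comb(nn, kk):
        return (
            math.lgamma(nn + 1) - math.lgamma(kk + 1) - math.lgamma(nn - kk + 1)
        )

    def prob(aa):
        return math.exp(
            log_comb(row1, aa)
            + log_comb(row2, col1 - aa)
            - log_comb(n, col1)
        )

    p_obs = prob(a)
    lo = max(0, col1 - row2)
    hi = min(row1, col1)
    return sum(prob(aa) for aa in range(lo, hi + 1) if prob(aa) <= p_obs * (1 + 1e-9))
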