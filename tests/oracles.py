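"""Independent brute-force oracles shared by the unit and acceptance tests.

Everything here is written from the textbook definitions, deliberately
avoiding the code paths (and the scipy entry points) used by the package.
"""

import itertools

import numpy as np


def wilcoxon_enumeration(diffs):
    """Signed-rank statistic and exact two-sided p by full 2^n enumeration.

    Zeros dropped; statistic is min(W+, W-); p is the null probability of a
    min-sum at or below the observed one, over all sign assignments with
    midranks for tied |d|.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    order = np.abs(d)
    # midranks computed by definition
    ranks = np.empty(n)
    for i, v in enumerate(order):
        less = (order < v).sum()
        equal = (order == v).sum()
        ranks[i] = less + (equal + 1) / 2
    w_plus = ranks[d > 0].sum()
    w_minus = ranks[d < 0].sum()
    w_obs = min(w_plus, w_minus)
    total = ranks.sum()
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        wp = sum(r for r, s in zip(ranks, signs) if s)
        if min(wp, total - wp) <= w_obs + 1e-12:
            count += 1
    return w_obs, count / 2**n


def rm_anova_sums_of_squares(matrix):
    """One-way within-subjects ANOVA table from definitional double loops."""
    a = [row for row in matrix]
    n = len(a)
    k = len(a[0])
    grand = sum(sum(row) for row in a) / (n * k)
    col_means = [sum(a[i][j] for i in range(n)) / n for j in range(k)]
    row_means = [sum(row) / k for row in a]
    ss_sessions = n * sum((cm - grand) ** 2 for cm in col_means)
    ss_subjects = k * sum((rm - grand) ** 2 for rm in row_means)
    ss_total = sum((a[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_error = ss_total - ss_sessions - ss_subjects
    df1 = k - 1
    df2 = (k - 1) * (n - 1)
    f = (ss_sessions / df1) / (ss_error / df2)
    return f, df1, df2


def two_pass_mean_sd(values):
    """Two-pass mean and population SD."""
    vals = list(values)
    n = len(vals)
    mean = sum(vals) / n
    var = sum((v - mean) ** 2 for v in vals) / n
    return mean, var**0.5


def naive_replay(log, weights, th, minutes=50, feedback=True, initial_fill=50.0):
    """Independent minute-by-minute re-simulation of the feedback loop.

    Scans the raw bin list per minute and applies the band/delta/color rules
    as plain if-chains; shares no code with the engine's replay path.
    """
    records = []
    fill = initial_fill
    for minute in range(1, minutes + 1):
        lo, hi = 60 * (minute - 1), 60 * minute
        c = k = s = m = 0
        for b in log:
            if lo <= b.t_start < hi:
                c += b.clicks
                k += b.keystrokes
                s += b.scroll_px
                m += b.cursor_px
        level = (
            weights.w_click * c + weights.w_key * k
            + weights.w_scroll * s + weights.w_cursor * m
        )
        if th.sigma == 0:
            if level > th.mu:
                delta = 10.0
            elif level < th.mu:
                delta = -10.0
            else:
                delta = 2.5
        elif level > th.highest:
            delta = 10.0
        elif level > th.high:
            delta = 5.0
        elif level > th.low:
            delta = 2.5
        elif level > th.lowest:
            delta = -5.0
        else:
            delta = -10.0
        if feedback:
            fill = max(0.0, min(100.0, fill + delta))
            if fill < 40:
                color = "red"
            elif fill <= 60:
                color = "yellow"
            else:
                color = "green"
            records.append((minute, level, delta, fill, color))
        else:
            records.append((minute, level, None, None, None))
    return records
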