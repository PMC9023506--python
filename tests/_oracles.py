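"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written with plain Python loops and
re-derives each quantity from first principles (the printed definitions of
the outcome measures, the textbook complete-linkage algorithm), so the
vectorized/library implementations are checked against a second route.
"""

from __future__ import annotations

import math


def behavior_vector_oracle(frames, moved, up, schedule,
                           total_exclusion_pct=1.0, omr_min_move_pct=5.0):
    """Recompute exclusions and the ten measures by direct frame counting.

    ``frames``/``moved``/``up`` are parallel per-observation lists (``up`` is
    1.0/0.0/None). Returns (excluded, dict of measures) with None for
    undefined measures.
    """
    period_index = list(schedule.frame_period_index())
    starts = list(schedule.period_starts)

    pct_move, pct_up, valid = {}, {}, {}
    for p in schedule.periods:
        n = n_moved = n_def = n_up = 0
        for f, m, u in zip(frames, moved, up):
            if period_index[f] != p.index:
                continue
            n += 1
            if m:
                n_moved += 1
            if u is not None and not (isinstance(u, float) and math.isnan(u)):
                n_def += 1
                if u >= 0.5:
                    n_up += 1
        pct_move[p.index] = 100.0 * n_moved / n if n else None
        pct_up[p.index] = 100.0 * n_up / n_def if n_def else None
        valid[p.index] = pct_move[p.index] is not None and \
            pct_move[p.index] >= omr_min_move_pct

    total_moved = sum(1 for m in moved if m)
    excluded = 100.0 * total_moved / len(moved) < total_exclusion_pct
    if excluded:
        return True, None

    p17 = schedule.periods[16]
    split = starts[16] + (p17.n_frames + 1) // 2
    fh_n = fh_m = sh_n = sh_m = 0
    for f, m in zip(frames, moved):
        if period_index[f] != 17:
            continue
        if f < split:
            fh_n += 1
            fh_m += 1 if m else 0
        else:
            sh_n += 1
            sh_m += 1 if m else 0
    first_half = 100.0 * fh_m / fh_n
    second_half = 100.0 * sh_m / sh_n

    measures = {
        "act_1h": sum(pct_move[i] for i in range(1, 7)) / 6.0,
        "act_p15": pct_move[15],
        "hab": first_half - second_half,
        "startle": pct_move[16] - pct_move[15],
        "excit": pct_move[17] - pct_move[16],
    }
    pairs = {"omr_red": (7, 8), "omr_green": (9, 10), "omr_blue": (11, 12),
             "omr_fast_red": (13, 14)}
    omrs = []
    for name, (down, upp) in pairs.items():
        if (valid[down] and valid[upp]
                and pct_up[down] is not None and pct_up[upp] is not None):
            measures[name] = pct_up[upp] - pct_up[down]
            omrs.append(measures[name])
        else:
            measures[name] = None
    measures["omr_rgb"] = sum(omrs) / len(omrs) if omrs else None
    return False, measures


def mean_sd_oracle(values):
    """Sample mean and ddof-1 standard deviation by direct summation."""
    values = [v for v in values if not (isinstance(v, float) and math.isnan(v))]
    n = len(values)
    if n == 0:
        return 0, None, None
    mean = sum(values) / n
    if n == 1:
        return n, mean, None
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
    return n, mean, sd


def weighted_euclidean_oracle(x, y, w):
    """Weight-normalised mean squared difference over mutually defined
    entries, by explicit loop."""
    num = den = 0.0
    any_defined = False
    for xi, yi, wi in zip(x, y, w):
        if math.isnan(xi) or math.isnan(yi):
            continue
        any_defined = True
        num += wi * (xi - yi) ** 2
        den += wi
    if not any_defined:
        raise ValueError("no mutually defined features")
    return num / den


def complete_linkage_oracle(rows, weights, labels):
    """Naive agglomeration: at every step recompute every inter-cluster
    complete-linkage distance from scratch (max over all member pairs of the
    brute-force pointwise distance); ties go to the lexicographically
    smallest pair of representative labels. Returns the merge list in the
    same (node_id, left, right, height) form as the implementation."""
    n = len(rows)
    clusters = {i: [i] for i in range(n)}
    rep = {i: labels[i] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if b <= a:
                    continue
                d = max(weighted_euclidean_oracle(rows[i], rows[j], weights)
                        for i in clusters[a] for j in clusters[b])
                key = tuple(sorted((rep[a], rep[b])))
                if best is None or d < best[0] - 1e-12 or (
                        abs(d - best[0]) <= 1e-12 and key < best[1]):
                    best = (d, key, a, b)
        d, _, a, b = best
        left, right = (a, b) if rep[a] <= rep[b] else (b, a)
        merges.append((next_id, left, right, d))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        rep[next_id] = min(rep[a], rep[b])
        next_id += 1
    return merges


def pearson_oracle(x, y):
    """Pearson correlation by the definitional formula."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    den = math.sqrt(sum((xi - mx) ** 2 for xi in x) * sum((yi - my) ** 2 for yi in y))
    return num / den
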