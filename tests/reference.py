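"""Independent brute-force reference implementations used as test oracles.

These deliberately re-derive every quantity from first principles with
plain loops and no shared code with the package: the propagation oracle
re-scans the whole graph each iteration instead of keeping a frontier,
and the metric oracles enumerate confusion-matrix cells and ANOVA sums of
squares directly.
"""

from __future__ import annotations

import math


def ref_propagate(neighbors: dict, demand: dict, seeds: dict,
                  capacity: dict, threshold: float = 1.0,
                  demand_floor: float = 1.0, tie_break: str = "highest-score",
                  max_iterations: int = 100_000):
    """Step-by-step simulation of the score recurrence.

    neighbors: region -> iterable of adjacent regions
    seeds: supply_id -> host region
    Returns (assignment, labelled_at).
    """
    order = {s: i for i, s in enumerate(sorted(capacity))}
    assignment = {}
    labelled_at = {}
    catch_demand = {}
    for sid, host in seeds.items():
        assignment[host] = sid
        labelled_at[host] = 0
        catch_demand[sid] = demand[host]
    scores: dict = {}

    for k in range(1, max_iterations + 1):
        # which labels border each unlabelled region, recomputed from scratch
        frontier: dict = {}
        for region in neighbors:
            if region in assignment:
                continue
            labels = {assignment[nb] for nb in neighbors[region] if nb in assignment}
            if labels:
                frontier[region] = labels
        if not frontier:
            break
        rate = {m: capacity[m] / max(catch_demand[m], demand_floor)
                for m in catch_demand}
        newly = []
        for region, labels in sorted(frontier.items()):
            for m in sorted(labels):
                scores[(region, m)] = scores.get((region, m), 0.0) + rate[m]
            crossed = [m for m in sorted(labels)
                       if scores[(region, m)] >= threshold]
            if crossed:
                if tie_break == "highest-score":
                    winner = min(crossed,
                                 key=lambda m: (-scores[(region, m)], order[m]))
                else:
                    winner = min(crossed, key=lambda m: order[m])
                newly.append((region, winner))
        for region, winner in newly:
            assignment[region] = winner
            labelled_at[region] = k
            catch_demand[winner] += demand[region]
    return assignment, labelled_at


def ref_multinomial_accuracy(pairs):
    """pairs: iterable of (predicted, observed)."""
    pairs = list(pairs)
    return sum(1 for p, o in pairs if p == o) / len(pairs)


def ref_balanced_accuracy(pairs, cls):
    tp = fn = fp = tn = 0
    for p, o in pairs:
        if o == cls:
            tp += p == cls
            fn += p != cls
        else:
            fp += p == cls
            tn += p != cls
    sens = tp / (tp + fn) if (tp + fn) else None
    spec = tn / (tn + fp) if (tn + fp) else None
    if sens is None:
        return spec, False
    if spec is None:
        return sens, True
    return (sens + spec) / 2, True


def ref_mcc(pairs):
    """Multiclass MCC from the raw confusion counts (Gorodkin)."""
    classes = sorted({p for p, _ in pairs} | {o for _, o in pairs})
    idx = {c: i for i, c in enumerate(classes)}
    K = len(classes)
    C = [[0] * K for _ in range(K)]
    for p, o in pairs:
        C[idx[o]][idx[p]] += 1
    n = len(list(pairs))
    trace = sum(C[i][i] for i in range(K))
    t = [sum(C[i]) for i in range(K)]           # true counts per class
    q = [sum(C[i][j] for i in range(K)) for j in range(K)]  # predicted counts
    cov_xy = trace * n - sum(ti * qi for ti, qi in zip(t, q))
    cov_xx = n * n - sum(ti * ti for ti in t)
    cov_yy = n * n - sum(qi * qi for qi in q)
    if cov_xx == 0 or cov_yy == 0:
        return 0.0
    return cov_xy / math.sqrt(cov_xx * cov_yy)


def ref_icc2k(matrix):
    """ICC(2,k) and 95% CI from explicit two-way ANOVA mean squares."""
    from scipy import stats

    n = len(matrix)
    k = len(matrix[0])
    grand = sum(sum(row) for row in matrix) / (n * k)
    row_means = [sum(row) / k for row in matrix]
    col_means = [sum(matrix[i][j] for i in range(n)) / n for j in range(k)]
    msr = k * sum((rm - grand) ** 2 for rm in row_means) / (n - 1)
    msc = n * sum((cm - grand) ** 2 for cm in col_means) / (k - 1)
    sse = sum((matrix[i][j] - row_means[i] - col_means[j] + grand) ** 2
              for i in range(n) for j in range(k))
    mse = sse / ((n - 1) * (k - 1))
    est = (msr - mse) / (msr + (msc - mse) / n)
    est1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    a = k * est1 / (n * (1 - est1))
    b = 1 + k * est1 * (n - 1) / (n * (1 - est1))
    v = ((a * msc + b * mse) ** 2
         / ((a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))))
    f1 = stats.f.ppf(0.975, n - 1, v)
    f2 = stats.f.ppf(0.975, v, n - 1)
    l1 = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
    u1 = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    lk = l1 * k / (1 + (k - 1) * l1)
    uk = u1 * k / (1 + (k - 1) * u1)
    return est, lk, uk


def ref_interpolate(src_geoms, src_demand, tgt_geoms):
    """Exhaustive pairwise intersection-area apportionment."""
    out = [0.0] * len(tgt_geoms)
    for g, d in zip(src_geoms, src_demand):
        if g.area == 0:
            continue
        for j, t in enumerate(tgt_geoms):
            a = g.intersection(t).area
            if a > 0:
                out[j] += d * a / g.area
    return out
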