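"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (nested Python loops, exhaustive
enumeration, grid search) and shares no code with the implementation it
checks.
"""

from __future__ import annotations

import numpy as np


def glcm_pairs_bruteforce(levels, mask, offset, ng):
    """Symmetrized co-occurrence counts by explicit pair enumeration."""
    counts = np.zeros((ng, ng), dtype=int)
    shape = levels.shape
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if not mask[z, y, x]:
                    continue
                z2, y2, x2 = z + offset[0], y + offset[1], x + offset[2]
                if not (0 <= z2 < shape[0] and 0 <= y2 < shape[1]
                        and 0 <= x2 < shape[2]):
                    continue
                if not mask[z2, y2, x2]:
                    continue
                a, b = levels[z, y, x] - 1, levels[z2, y2, x2] - 1
                counts[a, b] += 1
                counts[b, a] += 1
    return counts


def glrlm_runs_bruteforce(levels, mask, direction, ng, max_len):
    """Run-length counts by walking each maximal run voxel by voxel."""
    counts = np.zeros((ng, max_len), dtype=int)
    shape = levels.shape

    def inside(p):
        return all(0 <= c < s for c, s in zip(p, shape)) and mask[p]

    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                p = (z, y, x)
                if not inside(p):
                    continue
                prev = (z - direction[0], y - direction[1], x - direction[2])
                if inside(prev) and levels[prev] == levels[p]:
                    continue  # not a run start
                length = 1
                cur = p
                while True:
                    nxt = tuple(c + d for c, d in zip(cur, direction))
                    if inside(nxt) and levels[nxt] == levels[p]:
                        length += 1
                        cur = nxt
                    else:
                        break
                counts[levels[p] - 1, length - 1] += 1
    return counts


def glszm_zones_bruteforce(levels, mask, ng):
    """Zone (level, size) list via explicit 26-connected flood fill."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    zones = []
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if not mask[z, y, x] or seen[z, y, x]:
                    continue
                g = levels[z, y, x]
                stack = [(z, y, x)]
                seen[z, y, x] = True
                size = 0
                while stack:
                    cz, cy, cx = stack.pop()
                    size += 1
                    for dz, dy, dx in offsets:
                        nz, ny, nx_ = cz + dz, cy + dy, cx + dx
                        if (0 <= nz < shape[0] and 0 <= ny < shape[1]
                                and 0 <= nx_ < shape[2]
                                and mask[nz, ny, nx_]
                                and not seen[nz, ny, nx_]
                                and levels[nz, ny, nx_] == g):
                            seen[nz, ny, nx_] = True
                            stack.append((nz, ny, nx_))
                zones.append((int(g), size))
    return sorted(zones)


def auc_pair_enumeration(pos, neg):
    """c-statistic by exhaustive pair comparison, ties counting 1/2."""
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def km_product_limit(times, events):
    """Hand product-limit curve: [(t, S(t))] at each event time."""
    order = np.argsort(times)
    times = np.asarray(times, dtype=float)[order]
    events = np.asarray(events, dtype=int)[order]
    s = 1.0
    curve = []
    for t in np.unique(times[events == 1]):
        at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= (at_risk - d) / at_risk
        curve.append((float(t), s))
    return curve


def cox_loglik_no_ties(beta, times, events, x):
    """Cox partial log-likelihood for a single covariate, no tied events."""
    ll = 0.0
    times = np.asarray(times, dtype=float)
    x = np.asarray(x, dtype=float)
    for i in np.where(np.asarray(events) == 1)[0]:
        risk = times >= times[i]
        ll += beta * x[i] - np.log(np.exp(beta * x[risk]).sum())
    return ll


def cox_grid_mle(times, events, x, lo=-4.0, hi=4.0):
    """Coarse-then-fine grid maximizer of the partial likelihood."""
    grid = np.linspace(lo, hi, 801)
    lls = [cox_loglik_no_ties(b, times, events, x) for b in grid]
    b0 = grid[int(np.argmax(lls))]
    fine = np.linspace(b0 - 0.02, b0 + 0.02, 401)
    lls = [cox_loglik_no_ties(b, times, events, x) for b in fine]
    return float(fine[int(np.argmax(lls))])


def cox_score_test(times, events, x):
    """Score statistic U(0)^2 / I(0) for a single binary covariate."""
    times = np.asarray(times, dtype=float)
    x = np.asarray(x, dtype=float)
    u = 0.0
    info = 0.0
    for i in np.where(np.asarray(events) == 1)[0]:
        risk = times >= times[i]
        xbar = x[risk].mean()
        u += x[i] - xbar
        info += (x[risk] ** 2).mean() - xbar ** 2
    return u ** 2 / info
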