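"""Independent brute-force scan oracle for small panels.

Everything here is computed directly from first principles — distance
thresholds instead of nearest-neighbour growth, per-window loops instead
of matrix cumsums, and the window likelihood evaluated term by term — so
it shares no code path with the package's vectorized scan.
"""

import math


def llr_direct(c, E, C):
    """Poisson window log-likelihood ratio, high-rates indicator."""
    if c <= E:
        return 0.0
    val = c * math.log(c / E)
    if C - c > 0:
        val += (C - c) * math.log((C - c) / (C - E))
    return val


def spatial_candidates(loc, pop, frac):
    """All distinct distance-threshold circles under the population cap.

    A circle is {k : d(center, k) <= t} for every center and every
    threshold t equal to some inter-unit distance.
    """
    n = loc.n_units
    pt = pop.person_time.sum(axis=1)
    cap = frac * pt.sum()
    sets = set()
    for ci in range(n):
        dists = sorted(
            math.hypot(loc.lat[ci] - loc.lat[j], loc.lon[ci] - loc.lon[j])
            for j in range(n)
        )
        for t in dists:
            members = frozenset(
                j
                for j in range(n)
                if math.hypot(loc.lat[ci] - loc.lat[j], loc.lon[ci] - loc.lon[j]) <= t
            )
            if sum(pt[j] for j in members) <= cap:
                sets.add(members)
    return sets


def temporal_candidates(n_months, frac):
    max_len = math.floor(frac * n_months)
    return [
        (s, e)
        for s in range(n_months)
        for e in range(s, min(s + max_len, n_months) - 1 + 1)
        if e - s + 1 <= max_len
    ]


def best_window(cases, pop, mode, frac=0.5, loc=None):
    """Exhaustively score every admissible window; return (llr, argmax set).

    The argmax set contains every (member frozenset, month range) within
    1e-9 of the maximum, so callers can accept any tied winner.
    """
    counts = cases.counts
    pt = pop.person_time
    C = counts.sum()
    P = pt.sum()
    n_units, n_months = counts.shape
    all_units = frozenset(range(n_units))

    if mode == "spatial":
        windows = [(m, (0, n_months - 1)) for m in spatial_candidates(loc, pop, frac)]
    elif mode == "temporal":
        windows = [(all_units, r) for r in temporal_candidates(n_months, frac)]
    elif mode == "spacetime":
        windows = [
            (m, r)
            for m in spatial_candidates(loc, pop, frac)
            for r in temporal_candidates(n_months, frac)
        ]
    else:
        raise ValueError(mode)

    best = 0.0
    argmax = []
    for members, (s, e) in windows:
        c = sum(int(counts[i, m]) for i in members for m in range(s, e + 1))
        p = sum(float(pt[i, m]) for i in members for m in range(s, e + 1))
        E = p * C / P
        val = llr_direct(c, E, C)
        if val > best + 1e-9:
            best, argmax = val, [(members, (s, e))]
        elif abs(val - best) <= 1e-9 and val > 0:
            argmax.append((members, (s, e)))
    return best, argmax
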