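"""Independent reference implementations used as test oracles.

Everything here is deliberately written from first principles (explicit
Gram-Schmidt, quaternion eigenproblem, plain double loops) and shares no
code path with the package implementation it checks.
"""

import math

import numpy as np


# ---------------------------------------------------------------- frames

def gs_frame(n, ca, c):
    """Gram-Schmidt local frame: rows are x, y, z axes (global coords)."""
    y = np.asarray(n, float) - ca
    y = y / np.linalg.norm(y)
    v = np.asarray(c, float) - ca
    x = v - (v @ y) * y
    x = x / np.linalg.norm(x)
    z = np.cross(x, y)
    return np.array([x, y, z])


def oracle_local(n, ca, c, point):
    return gs_frame(n, ca, c) @ (np.asarray(point, float) - ca)


def oracle_bin(local):
    out = []
    for coord in local:
        if coord >= 0:
            out.append(int(math.floor(coord)) + 1)
        else:
            out.append(int(math.floor(coord)))
    return tuple(out)


def quaternion_rmsd(x, y):
    """Optimal-superposition RMSD via the quaternion eigenvalue method
    (Horn / Kearsley key matrix; proper rotations only)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    m = yc.T @ xc
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(key)[-1]
    ga = (xc * xc).sum()
    gb = (yc * yc).sum()
    msd = max(0.0, (ga + gb - 2.0 * lam)) / len(x)
    return math.sqrt(msd)


def dihedral_atan2(p0, p1, p2, p3):
    """Signed dihedral in degrees via the direct atan2 of projections."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    y = np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


# ------------------------------------------------------- pair enumeration

def brute_force_pairs(structure, cutoff, exclude):
    """All ordered eligible (observer, partner) pairs by explicit loops."""
    res = structure.residues
    pairs = []
    for u in range(len(res)):
        for v in range(len(res)):
            if u == v:
                continue
            if abs(res[u].seq_num - res[v].seq_num) <= exclude:
                continue
            if np.linalg.norm(res[u].ca - res[v].ca) > cutoff:
                continue
            pairs.append((u, v))
    return pairs


def brute_force_counts(corpus, cutoff, exclude):
    """(i_type, j_type, bin) observation counts via explicit loops."""
    counts = {}
    n_obs = 0
    for s in corpus:
        for u, v in brute_force_pairs(s, cutoff, exclude):
            ru, rv = s.residues[u], s.residues[v]
            b = oracle_bin(oracle_local(ru.n, ru.ca, ru.c, rv.ca))
            key = (ru.aa, rv.aa, b)
            counts[key] = counts.get(key, 0) + 1
            n_obs += 1
    return counts, n_obs


def brute_force_score(structure, counts, cutoff, exclude, penalty_mult):
    """Tableless evaluation of the log-odds score formula.

    ``counts`` is the brute-force count dict; the reference state, the
    per-pair penalties and the double loop are all recomputed here from
    scratch.
    """
    totals = {}
    for (i, j, b), c in counts.items():
        totals[b] = totals.get(b, 0) + c
    j_exp = {b: t / 400.0 for b, t in totals.items()}

    worst = {}
    for (i, j, b), c in counts.items():
        s = -math.log(c / j_exp[b])
        if (i, j) not in worst or s > worst[(i, j)]:
            worst[(i, j)] = s
    positive = [w for w in worst.values() if w > 0]
    global_base = max(positive) if positive else math.log(400.0)

    def penalty(i, j):
        w = worst.get((i, j))
        base = w if (w is not None and w > 0) else global_base
        return penalty_mult * base

    total = 0.0
    for u, v in brute_force_pairs(structure, cutoff, exclude):
        ru, rv = structure.residues[u], structure.residues[v]
        b = oracle_bin(oracle_local(ru.n, ru.ca, ru.c, rv.ca))
        c = counts.get((ru.aa, rv.aa, b), 0)
        if c > 0:
            total += -math.log(c / j_exp[b])
        else:
            total += penalty(ru.aa, rv.aa)
    return total


# ----------------------------------------------------------- set metrics

def bf_min_rank(value, values):
    return 1 + sum(1 for v in values if v < value)


def bf_native_metrics(scores, rmsds):
    """Exhaustive recomputation of the five native-recognition measures
    (native at index 0, lower score = better)."""
    n = len(scores)
    rank_nat = bf_min_rank(scores[0], scores)
    best = min(range(n), key=lambda k: (scores[k], k))
    rmsd_best = rmsds[best]
    mean = sum(scores) / n
    sd = math.sqrt(sum((s - mean) ** 2 for s in scores) / (n - 1))
    z_nat = (mean - scores[0]) / sd if sd > 0 else float("nan")
    cc_nat = bf_pearson(scores, rmsds)
    fe_nat = bf_fraction_enrichment(scores, rmsds)
    return rank_nat, rmsd_best, z_nat, cc_nat, fe_nat


def bf_decoy_metrics(scores, rmsds):
    """Exhaustive recomputation of the eight decoy-discrimination measures."""
    n = len(scores)
    best = min(range(n), key=lambda k: (scores[k], k))
    r_b1 = bf_min_rank(rmsds[best], rmsds)
    by_score = sorted(range(n), key=lambda k: (scores[k], k))[:10]
    r_b10 = min(bf_min_rank(rmsds[t], rmsds) for t in by_score)
    rmsd_decoy = rmsds[best]
    lowest = min(range(n), key=lambda k: (rmsds[k], k))
    mean = sum(scores) / n
    sd = math.sqrt(sum((s - mean) ** 2 for s in scores) / (n - 1))
    z_decoy = (mean - scores[lowest]) / sd if sd > 0 else float("nan")
    cc_decoy = bf_pearson(scores, rmsds)
    fe_decoy = bf_fraction_enrichment(scores, rmsds)
    return (r_b1, r_b10, rmsd_decoy, z_decoy, cc_decoy, fe_decoy,
            math.log10(r_b1 / n), math.log10(r_b10 / n))


def bf_pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sx = math.sqrt(sum((v - mx) ** 2 for v in x))
    sy = math.sqrt(sum((v - my) ** 2 for v in y))
    if sx == 0 or sy == 0:
        return float("nan")
    return sum((a - mx) * (b - my) for a, b in zip(x, y)) / (sx * sy)


def bf_fraction_enrichment(scores, rmsds):
    n = len(scores)
    k = math.ceil(0.1 * n)
    top_rmsd = set(sorted(range(n), key=lambda t: (rmsds[t], t))[:k])
    top_score = set(sorted(range(n), key=lambda t: (scores[t], t))[:k])
    return 100.0 * len(top_rmsd & top_score) / k


def exact_signed_rank_tail(diffs):
    """Exact one-tailed signed-rank p by exhaustive sign-flip enumeration.

    P(W+ <= observed) under the null that each |difference| is + or -
    with probability 1/2.  Feasible for n <= ~16.
    """
    import itertools

    d = [v for v in diffs if v != 0]
    n = len(d)
    ranks = _rank_abs(d)
    w_obs = sum(r for v, r in zip(d, ranks) if v > 0)
    count = 0
    for signs in itertools.product((1, -1), repeat=n):
        w = sum(r for sgn, r in zip(signs, ranks) if sgn > 0)
        if w <= w_obs:
            count += 1
    return count / 2 ** n


def _rank_abs(d):
    a = [abs(v) for v in d]
    order = sorted(range(len(a)), key=lambda k: a[k])
    ranks = [0.0] * len(a)
    k = 0
    while k < len(order):
        j = k
        while j + 1 < len(order) and a[order[j + 1]] == a[order[k]]:
            j += 1
        avg = (k + j) / 2 + 1
        for t in range(k, j + 1):
            ranks[order[t]] = avg
        k = j + 1
    return ranks
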