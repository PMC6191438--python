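"""Structured-coalescent engines for the two-deme isolation-with-migration model.

Two implementations of the same stochastic process live here:

* :func:`simulate_locus_branches` — a readable event-driven Python simulator that
  returns explicit branches (descendant bitmasks + lengths), used to drop
  infinite-sites mutations and emit genotypes;
* :func:`tally_branch_lengths` — a numba-compiled tallier that accumulates only
  E[branch length subtending (i, j) sampled lineages], the quantity needed for
  the expected joint SFS inside the likelihood optimizer.

They are cross-validated against each other (and against Watterson's closed
form) in the test suite.

Conventions: time runs backwards in units of 2*N_ref generations; a deme of
relative size nu has pairwise coalescence rate 1/nu; scaled migration rates are
2*N_ref*m in the receiving-population convention, so a lineage currently in
deme 1 jumps (backwards) to deme 2 at rate m12.
"""
from __future__ import annotations

import numpy as np
from numba import njit


def simulate_locus_branches(
    rng: np.random.Generator,
    n1: int,
    n2: int,
    nu1: float,
    nu2: float,
    T: float,
    m12: float,
    m21: float,
) -> list[tuple[int, float]]:
    """Simulate one genealogy; return closed branches as (descendant bitmask, length).

    Samples 0..n1-1 are from population 1, n1..n1+n2-1 from population 2. The
    bitmask has bit k set iff sample k descends from the branch. Branch lengths
    are in units of 2*N_ref generations.
    """
    deme = [0] * n1 + [1] * n2
    mask = [1 << k for k in range(n1 + n2)]
    length = [0.0] * (n1 + n2)
    branches: list[tuple[int, float]] = []
    t = 0.0
    merged = T == 0.0
    if merged:
        deme = [0] * len(deme)

    while len(mask) > 1:
        k1 = deme.count(0)
        k2 = len(deme) - k1
        if merged:
            rates = [k1 * (k1 - 1) / 2.0, 0.0, 0.0, 0.0]
        else:
            rates = [
                k1 * (k1 - 1) / 2.0 / nu1,
                k2 * (k2 - 1) / 2.0 / nu2,
                k1 * m12,
                k2 * m21,
            ]
        total = sum(rates)
        if total == 0.0:
            # isolated singletons before the merge: jump straight to T
            dt = T - t
        else:
            dt = rng.exponential(1.0 / total)
        if not merged and t + dt > T:
            dt = T - t
            event = "merge"
        else:
            u = rng.uniform(0.0, total)
            acc = 0.0
            event = "merge"
            for name, r in zip(("coal1", "coal2", "mig12", "mig21"), rates):
                acc += r
                if u < acc:
                    event = name
                    break
        t += dt
        for i in range(len(length)):
            length[i] += dt

        if event == "merge":
            merged = True
            deme = [0] * len(deme)
            continue
        if event in ("mig12", "mig21"):
            src = 0 if event == "mig12" else 1
            idx = [i for i, d in enumerate(deme) if d == src]
            deme[idx[int(rng.integers(len(idx)))]] = 1 - src
            continue
        # coalescence
        d = 0 if event == "coal1" else 1
        idx = [i for i, dd in enumerate(deme) if dd == d]
        a, b = rng.choice(len(idx), size=2, replace=False)
        ia, ib = idx[int(a)], idx[int(b)]
        branches.append((mask[ia], length[ia]))
        branches.append((mask[ib], length[ib]))
        new_mask = mask[ia] | mask[ib]
        # remove the higher index first so the lower index stays valid
        for j in sorted((ia, ib), reverse=True):
            mask.pop(j)
            length.pop(j)
            deme.pop(j)
        mask.append(new_mask)
        length.append(0.0)
        deme.append(d)
    return branches


@njit(cache=True)
def _tally_once(n1, n2, nu1, nu2, T, m12, m21, out):  # pragma: no cover - numba
    n = n1 + n2
    deme = np.empty(n, np.int64)
    d1 = np.empty(n, np.int64)
    d2 = np.empty(n, np.int64)
    for i in range(n1):
        deme[i] = 0
        d1[i] = 1
        d2[i] = 0
    for i in range(n1, n):
        deme[i] = 1
        d1[i] = 0
        d2[i] = 1
    k = n
    t = 0.0
    merged = T == 0.0
    if merged:
        for i in range(k):
            deme[i] = 0
    while k > 1:
        k1 = 0
        for i in range(k):
            if deme[i] == 0:
                k1 += 1
        k2 = k - k1
        if merged:
            r0 = k1 * (k1 - 1) / 2.0
            r1 = 0.0
            r2 = 0.0
            r3 = 0.0
        else:
            r0 = k1 * (k1 - 1) / 2.0 / nu1
            r1 = k2 * (k2 - 1) / 2.0 / nu2
            r2 = k1 * m12
            r3 = k2 * m21
        total = r0 + r1 + r2 + r3
        if total == 0.0:
            dt = T - t
            ev = -1
        else:
            dt = np.random.exponential(1.0 / total)
            if (not merged) and (t + dt > T):
                dt = T - t
                ev = -1
            else:
                u = np.random.uniform(0.0, total)
                if u < r0:
                    ev = 0
                elif u < r0 + r1:
                    ev = 1
                elif u < r0 + r1 + r2:
                    ev = 2
                else:
                    ev = 3
        t += dt
        for i in range(k):
            out[d1[i], d2[i]] += dt
        if ev == -1:
            merged = True
            for i in range(k):
                deme[i] = 0
            continue
        if ev == 2 or ev == 3:
            src = 0 if ev == 2 else 1
            ksrc = k1 if ev == 2 else k2
            pick = np.random.randint(ksrc)
            cnt = 0
            for i in range(k):
                if deme[i] == src:
                    if cnt == pick:
                        deme[i] = 1 - src
                        break
                    cnt += 1
            continue
        # coalescence in deme ev
        d = ev
        kd = k1 if d == 0 else k2
        a = np.random.randint(kd)
        b = np.random.randint(kd - 1)
        if b >= a:
            b += 1
        ia = -1
        ib = -1
        cnt = 0
        for i in range(k):
            if deme[i] == d:
                if cnt == a:
                    ia = i
                if cnt == b:
                    ib = i
                cnt += 1
        d1[ia] += d1[ib]
        d2[ia] += d2[ib]
        # swap-remove ib
        d1[ib] = d1[k - 1]
        d2[ib] = d2[k - 1]
        deme[ib] = deme[k - 1]
        k -= 1
    return out


@njit(cache=True)
def _tally_many(n1, n2, nu1, nu2, T, m12, m21, reps, seed):  # pragma: no cover
    np.random.seed(seed)
    out = np.zeros((n1 + 1, n2 + 1))
    for _ in range(reps):
        _tally_once(n1, n2, nu1, nu2, T, m12, m21, out)
    return out


def tally_branch_lengths(
    n1: int,
    n2: int,
    nu1: float,
    nu2: float,
    T: float,
    m12: float,
    m21: float,
    reps: int,
    seed: int,
) -> np.ndarray:
    """Monte-Carlo estimate of E[branch length subtending (i, j)] per SFS cell.

    Returns an (n1+1) x (n2+1) matrix of mean branch lengths (units of 2*N_ref
    generations) across ``reps`` genealogies. Reusing the same seed across calls
    reuses the same underlying random stream (common random numbers), which keeps
    the likelihood surface smooth for the optimizer.
    """
    if n1 < 1 or n2 < 1 or reps < 1:
        raise ValueError("n1, n2, reps must be positive")
    out = _tally_many(n1, n2, float(nu1), float(nu2), float(T),
                      float(m12), float(m21), reps, seed % (2**31))
    return out / reps
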