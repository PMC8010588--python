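"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately written by the slowest, most transparent
route available (exhaustive loops, quadrature, grid search) and shares no
code with the package internals it checks.
"""

from __future__ import annotations

import math
from typing import Dict, Set, Tuple

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.stats import norm


# ---------------------------------------------------------------------------
# Kinship


def brute_force_kinship(persons: pd.DataFrame) -> Dict[str, Set[Tuple[str, str]]]:
    """Classify every ordered pair of persons by exhaustive rule checking.

    O(n^2); both parents must be known for a person to enter any pair.
    """
    recs = persons.set_index("person_id")
    ids = [i for i in recs.index
           if pd.notna(recs.at[i, "mother_id"]) and pd.notna(recs.at[i, "father_id"])]
    parents = {i: (recs.at[i, "mother_id"], recs.at[i, "father_id"]) for i in ids}
    twin_gid = {i: recs.at[i, "twin_group_id"] for i in recs.index}

    def full_sibs(a: str, b: str) -> bool:
        return a != b and a in parents and b in parents and parents[a] == parents[b]

    out: Dict[str, Set[Tuple[str, str]]] = {
        "twin": set(), "full_sibling": set(), "half_sibling": set(),
        "cousin": set()}
    for i in ids:
        for j in ids:
            if i == j:
                continue
            gi, gj = twin_gid.get(i), twin_gid.get(j)
            is_twin = pd.notna(gi) and pd.notna(gj) and gi == gj
            if is_twin:
                out["twin"].add((i, j))
            mi, fi = parents[i]
            mj, fj = parents[j]
            if mi == mj and fi == fj:
                if not is_twin:
                    out["full_sibling"].add((i, j))
                continue
            shared = len({mi, fi} & {mj, fj})
            if shared == 1:
                out["half_sibling"].add((i, j))
                continue
            if shared == 0:
                linked = any(full_sibs(a, b)
                             for a in (mi, fi) for b in (mj, fj))
                if linked:
                    out["cousin"].add((i, j))
    return out


# ---------------------------------------------------------------------------
# Bivariate normal / tetrachoric


def orthant_quad(tau1: float, tau2: float, rho: float) -> float:
    """P(X > tau1, Y > tau2) by one-dimensional quadrature of the
    conditional normal (independent of the Owen's-T closed form)."""
    s = math.sqrt(1.0 - rho * rho)

    def integrand(x: float) -> float:
        return norm.pdf(x) * norm.sf((tau2 - rho * x) / s)

    val, _ = integrate.quad(integrand, tau1, np.inf, limit=200)
    return val


def tetrachoric_grid(n11, n10, n01, n00) -> float:
    """Successively refined rho-grid maximiser of the 2x2 bivariate-normal
    likelihood with thresholds at the margin probits and orthant
    probabilities from numerical quadrature."""
    n = n11 + n10 + n01 + n00
    p1 = (n11 + n10) / n
    p2 = (n11 + n01) / n
    t1, t2 = norm.ppf(1 - p1), norm.ppf(1 - p2)

    def loglik(rho: float) -> float:
        p11 = orthant_quad(t1, t2, rho)
        cells = (p11, p1 - p11, p2 - p11, 1 - p1 - p2 + p11)
        ll = 0.0
        for nc, pc in zip((n11, n10, n01, n00), cells):
            if nc > 0:
                if pc <= 0:
                    return -np.inf
                ll += nc * math.log(pc)
        return ll

    lo, hi = -0.995, 0.995
    best = 0.0
    for step in (1e-2, 2e-4, 2e-5):
        grid = np.arange(lo, hi + step, step)
        lls = [loglik(r) for r in grid]
        best = float(grid[int(np.argmax(lls))])
        lo, hi = max(-0.995, best - 2 * step), min(0.995, best + 2 * step)
    return best


# ---------------------------------------------------------------------------
# Survival


def km_by_hand(durations, events):
    """Product-limit estimator computed by explicit looping over distinct
    times (events precede censorings at ties)."""
    durations = np.asarray(durations, float)
    events = np.asarray(events, bool)
    times = np.unique(durations)
    s = 1.0
    out = {}
    for t in times:
        at_risk = np.sum(durations >= t)
        d = np.sum((durations == t) & events)
        if at_risk > 0:
            s *= 1.0 - d / at_risk
        out[float(t)] = s
    return out


def logrank_by_hand(da, ea, db, eb) -> float:
    """Two-group log-rank chi-square by explicit observed-minus-expected
    summation over distinct event times."""
    da, db = np.asarray(da, float), np.asarray(db, float)
    ea, eb = np.asarray(ea, bool), np.asarray(eb, bool)
    all_t = np.unique(np.concatenate([da[ea], db[eb]]))
    o_minus_e = 0.0
    var = 0.0
    for t in all_t:
        n1 = np.sum(da >= t)
        n2 = np.sum(db >= t)
        d1 = np.sum((da == t) & ea)
        d2 = np.sum((db == t) & eb)
        n = n1 + n2
        d = d1 + d2
        if n < 2:
            continue
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


# ---------------------------------------------------------------------------
# Person-years


def person_years_by_year_counting(follow: pd.DataFrame) -> float:
    """Total person-years by counting, for every calendar year, the persons
    at risk during [start, end)."""
    total = 0
    f = follow[~follow["excluded"]]
    if not len(f):
        return 0.0
    years = range(int(f["start_year"].min()), int(f["end_year"].max()) + 1)
    for y in years:
        total += int(((f["start_year"] <= y) & (y < f["end_year"])).sum())
    return float(total)
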