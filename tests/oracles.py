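"""Independent, deliberately naive reference implementations used to check
the package's estimators.

Everything here is written loop-by-loop from the published formulas, without
reusing any refstab internals, so that agreement between the two routes is a
meaningful check and not a tautology.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as _st


def sample_sd(xs):
    xs = [x for x in xs]
    n = len(xs)
    m = sum(xs) / n
    return math.sqrt(sum((x - m) ** 2 for x in xs) / (n - 1))


def delta_ct_oracle(values: dict[str, list[float]]) -> dict[str, float]:
    """Mean over partners of SD of pairwise Cq differences (NaN-pairwise)."""
    genes = list(values)
    out = {}
    for g in genes:
        sds = []
        for h in genes:
            if h == g:
                continue
            pairs = [(a, b) for a, b in zip(values[g], values[h])
                     if not (math.isnan(a) or math.isnan(b))]
            sds.append(sample_sd([a - b for a, b in pairs]))
        out[g] = sum(sds) / len(sds)
    return out


def genorm_oracle(values: dict[str, list[float]]):
    """Exhaustive recompute-after-each-exclusion geNorm.

    Returns (M_at_exclusion, exclusion_order, ranks).  Ties on the worst M
    exclude the alphabetically last symbol, mirroring the documented
    tie-break.
    """
    genes = list(values)

    def pair_sd(g, h):
        pairs = [(a, b) for a, b in zip(values[g], values[h])
                 if not (math.isnan(a) or math.isnan(b))]
        return sample_sd([a - b for a, b in pairs])

    def m_of(g, active):
        return sum(pair_sd(g, h) for h in active if h != g) / (len(active) - 1)

    active = list(genes)
    m_at_exclusion = {}
    order = []
    ranks = {}
    rank = len(genes)
    while len(active) > 2:
        ms = {g: m_of(g, active) for g in active}
        worst_m = max(ms.values())
        worst = max(g for g in active if abs(ms[g] - worst_m) < 1e-12)
        m_at_exclusion[worst] = ms[worst]
        ranks[worst] = rank
        order.append(worst)
        active.remove(worst)
        rank -= 1
    final = pair_sd(active[0], active[1])
    for g in active:
        m_at_exclusion[g] = final
        ranks[g] = 1.5
    return m_at_exclusion, order, ranks


def bestkeeper_oracle(values: dict[str, list[float]]):
    """Hand-coded BestKeeper: MAD ("SD[+-Cq]"), CV%, geometric-mean index,
    Pearson r vs index with a two-sided t-test p-value."""
    genes = list(values)
    n_samples = len(values[genes[0]])
    mad, cv = {}, {}
    for g in genes:
        xs = [x for x in values[g] if not math.isnan(x)]
        m = sum(xs) / len(xs)
        mad[g] = sum(abs(x - m) for x in xs) / len(xs)
        cv[g] = mad[g] / m * 100.0
    index = []
    for s in range(n_samples):
        logs = [math.log(values[g][s]) for g in genes
                if not math.isnan(values[g][s])]
        index.append(math.exp(sum(logs) / len(logs)) if logs else float("nan"))
    r, r_p = {}, {}
    for g in genes:
        xs, ys = [], []
        for s in range(n_samples):
            if not math.isnan(values[g][s]) and not math.isnan(index[s]):
                xs.append(values[g][s])
                ys.append(index[s])
        n = len(xs)
        mx, my = sum(xs) / n, sum(ys) / n
        sxx = sum((x - mx) ** 2 for x in xs)
        syy = sum((y - my) ** 2 for y in ys)
        sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
        if sxx == 0 or syy == 0:
            r[g], r_p[g] = float("nan"), float("nan")
            continue
        rr = sxy / math.sqrt(sxx * syy)
        r[g] = rr
        rr_c = min(max(rr, -1.0), 1.0)
        if abs(rr_c) >= 1.0:
            r_p[g] = 0.0
        else:
            t = rr_c * math.sqrt((n - 2) / (1 - rr_c ** 2))
            r_p[g] = 2 * _st.t.sf(abs(t), n - 2)
    return mad, cv, index, r, r_p


def normfinder_oracle(values: dict[str, list[float]], groups: list | None):
    """Loop-level transcription of the model-based stability estimator.

    Log signal is -Cq; samples are centered across genes; per group the
    intragroup variance uses the k/(k-2) bias correction with truncation at
    zero; intergroup deviations are shrunk by tau/(tau + var(d)); stability
    is mean over groups of |d_shrunk| + sqrt(sigma2/n_g); with one group it
    is sqrt(sigma2).
    """
    genes = list(values)
    k = len(genes)
    n_samples = len(values[genes[0]])
    assert all(not math.isnan(values[g][s]) for g in genes
               for s in range(n_samples)), "oracle expects complete data"
    if groups is None:
        groups = [0] * n_samples
    levels = list(dict.fromkeys(groups))

    y = {g: [-values[g][s] for s in range(n_samples)] for g in genes}
    r = {}
    for s in range(n_samples):
        mean_s = sum(y[g][s] for g in genes) / k
        for g in genes:
            r.setdefault(g, [0.0] * n_samples)
            r[g][s] = y[g][s] - mean_s

    z, s2, n_g = {}, {}, {}
    for lvl in levels:
        idx = [s for s in range(n_samples) if groups[s] == lvl]
        n_g[lvl] = len(idx)
        for g in genes:
            xs = [r[g][s] for s in idx]
            m = sum(xs) / len(xs)
            z[(g, lvl)] = m
            s2[(g, lvl)] = sum((x - m) ** 2 for x in xs) / (len(xs) - 1)

    sigma2 = {}
    for lvl in levels:
        gamma = sum(s2[(g, lvl)] for g in genes) / k / (k - 1)
        for g in genes:
            sigma2[(g, lvl)] = max((s2[(g, lvl)] - gamma) * k / (k - 2), 0.0)

    if len(levels) == 1:
        return {g: math.sqrt(sigma2[(g, levels[0])]) for g in genes}

    d = {}
    for g in genes:
        zbar = sum(z[(g, lvl)] for lvl in levels) / len(levels)
        for lvl in levels:
            d[(g, lvl)] = z[(g, lvl)] - zbar
    vard = {key: sigma2[key] / n_g[key[1]] for key in d}
    tau = max(sum(d[key] ** 2 - vard[key] for key in d) / len(d), 0.0)
    out = {}
    for g in genes:
        parts = []
        for lvl in levels:
            key = (g, lvl)
            denom = tau + vard[key]
            shrunk = d[key] * (tau / denom) if denom > 0 else 0.0
            parts.append(abs(shrunk) + math.sqrt(vard[key]))
        out[g] = sum(parts) / len(levels)
    return out


def student_t_oracle(a, b, equal_var=True):
    """Two-sided unpaired t-test from first principles (b vs a)."""
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    if equal_var:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = math.sqrt(sp2 * (1 / na + 1 / nb))
        df = na + nb - 2
    else:
        se = math.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    t = (mb - ma) / se
    p = 2 * _st.t.sf(abs(t), df)
    return t, p
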