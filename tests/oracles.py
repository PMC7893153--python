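"""Independent oracle implementations shared across test modules.

These deliberately use different algorithms from the package code paths they
check (Nelder-Mead in log-tau space instead of bounded TRF; explicit Python
loops instead of pandas groupby).
"""

import numpy as np
from scipy.optimize import minimize


def oracle_double_exp_fit(t, y):
    """Bleach-fit oracle: dense log-spaced tau grid with linear amplitude
    solves, then Nelder-Mead refinement in log-tau space."""

    def solve_amps(tau1, tau2):
        X = np.column_stack([np.exp(-t / tau1), np.exp(-t / tau2), np.ones_like(t)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ coef
        return coef, float(r @ r)

    taus = np.geomspace(1.0, 500.0, 40)
    best = None
    for i, t1 in enumerate(taus):
        for t2 in taus[i:]:
            coef, sse = solve_amps(t1, t2)
            if best is None or sse < best[1]:
                best = ((t1, t2), sse)

    def objective(logtau):
        return solve_amps(np.exp(logtau[0]), np.exp(logtau[1]))[1]

    res = minimize(
        objective,
        np.log(best[0]),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-16, "maxiter": 2000},
    )
    tau1, tau2 = np.exp(res.x)
    (a1, a2, c), _ = solve_amps(tau1, tau2)
    return a1, tau1, a2, tau2, c


def brute_force_pair_counts(table, pre_type, post_type, roster=None):
    """Pair-count oracle: nested loop over rows / candidate pairs."""
    counts = {}
    if roster is not None:
        for pre in roster[pre_type]:
            for post in roster[post_type]:
                counts[(pre, post)] = 0
    for _, row in table.iterrows():
        if row.pre_type == pre_type and row.post_type == post_type:
            key = (row.pre_id, row.post_id)
            counts[key] = counts.get(key, 0) + 1
    return counts
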