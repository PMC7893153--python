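"""Statistical test battery for trial-structured response data.

The battery mirrors standard practice for small-n repeated-measures
neuroscience data:

* a D'Agostino-Pearson omnibus normality gate on paired differences decides
  between the paired two-tailed t-test and the Wilcoxon matched-pairs
  signed-rank test;
* one-way (trials) or two-way (trials x odor) repeated-measures ANOVA with a
  Greenhouse-Geisser sphericity correction, gated by Mauchly's test in the
  default "auto" mode;
* Dunnett-style post-hoc comparisons of each later trial against the first,
  with family-wise adjustment from the equicorrelated multivariate-t
  distribution evaluated by deterministic quadrature.

ANOVA sums of squares, epsilon, Mauchly's W and the Dunnett adjustment are
computed here directly (no statistics package stands behind them), so the
test suite can cross-check them against independent implementations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UnbalancedDesignError

__all__ = [
    "TestResult",
    "paired_compare",
    "rm_anova_dunnett",
    "greenhouse_geisser_epsilon",
    "mauchly_test",
    "dunnett_sf",
]


@dataclass
class TestResult:
    """Outcome of one statistical test, with its gating diagnostics."""

    test_name: str
    statistic: float
    p_value: float
    normality_p: float = float("nan")
    correction: str = "none"
    epsilon: float | None = None
    df: tuple[float, float] | float | None = None
    n: int | None = None
    degenerate: bool = False
    posthoc: list[tuple[str, float]] = field(default_factory=list)
    effects: dict[str, "TestResult"] | None = None

    def to_dict(self) -> dict:
        out = {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "normality_p": self.normality_p,
            "correction": self.correction,
            "epsilon": self.epsilon,
            "df": list(self.df) if isinstance(self.df, tuple) else self.df,
            "n": self.n,
            "degenerate": self.degenerate,
            "posthoc": [[name, p] for name, p in self.posthoc],
        }
        if self.effects:
            out["effects"] = {k: v.to_dict() for k, v in self.effects.items()}
        return out


# --------------------------------------------------------------------------
# paired comparison with normality gate
# --------------------------------------------------------------------------

def paired_compare(
    x: Sequence[float],
    y: Sequence[float],
    alpha_normality: float = 0.05,
    zero_method: str = "wilcox",
) -> TestResult:
    """Paired two-sample comparison with a normality-gated test choice.

    The D'Agostino-Pearson omnibus test runs on the paired differences; if
    its p-value is >= ``alpha_normality`` (or the sample is too small for the
    omnibus, n < 8) a paired two-tailed t-test is used, otherwise the
    Wilcoxon matched-pairs signed-rank test (zero differences dropped, exact
    null for n <= 25 without ties, normal approximation with continuity
    correction otherwise).

    All-zero differences yield a degenerate result with p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("paired comparison needs at least 3 pairs")
    d = x - y
    if np.all(d == 0):
        return TestResult(
            test_name="degenerate", statistic=0.0, p_value=1.0, n=n, degenerate=True
        )

    if n >= 8:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            normality_p = float(stats.normaltest(d).pvalue)
        normal = normality_p >= alpha_normality
    else:
        normality_p = float("nan")  # omnibus needs n >= 8; default to the t-test
        normal = True

    if normal:
        res = stats.ttest_rel(x, y)
        return TestResult(
            test_name="paired_t",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            normality_p=normality_p,
            df=float(n - 1),
            n=n,
        )

    nz = d[d != 0]
    exact = (len(nz) <= 25) and (len(np.unique(np.abs(nz))) == len(nz))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.wilcoxon(
            x,
            y,
            zero_method=zero_method,
            correction=not exact,
            method="exact" if exact else "approx",
        )
    return TestResult(
        test_name="wilcoxon",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        normality_p=normality_p,
        n=n,
    )


# --------------------------------------------------------------------------
# sphericity machinery
# --------------------------------------------------------------------------

def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrasts spanning the space orthogonal to 1."""
    X = np.eye(k) - np.full((k, k), 1.0 / k)
    # QR of the centering projector; keep k-1 orthonormal rows
    q, _ = np.linalg.qr(X)
    C = q[:, : k - 1].T
    return C


def greenhouse_geisser_epsilon(data: np.ndarray) -> float:
    """Box/Greenhouse-Geisser epsilon from subjects-by-levels data.

    epsilon = tr(M)^2 / ((k-1) tr(M^2)) with M = C S C', S the sample
    covariance across subjects and C orthonormal contrasts.  Equals 1 exactly
    when the contrasted covariance is spherical (e.g. compound symmetry) and
    has lower bound 1/(k-1).
    """
    Y = np.asarray(data, dtype=float)
    n, k = Y.shape
    S = np.cov(Y, rowvar=False, ddof=1)
    C = _orthonormal_contrasts(k)
    M = C @ S @ C.T
    tr = np.trace(M)
    tr2 = np.trace(M @ M)
    if tr2 <= 0:
        return 1.0
    return float(min(1.0, (tr * tr) / ((k - 1) * tr2)))


def _epsilon_from_cov(S: np.ndarray, C: np.ndarray) -> float:
    M = C @ S @ C.T
    tr = np.trace(M)
    tr2 = np.trace(M @ M)
    if tr2 <= 0:
        return 1.0
    d = C.shape[0]
    return float(min(1.0, (tr * tr) / (d * tr2)))


def mauchly_test(data: np.ndarray) -> tuple[float, float]:
    """Mauchly's sphericity test on subjects-by-levels data.

    Returns ``(W, p)``.  With k = 2 levels (or a singular contrasted
    covariance, n too small) sphericity is untestable and ``(1.0, 1.0)`` is
    returned.
    """
    Y = np.asarray(data, dtype=float)
    n, k = Y.shape
    d = k - 1
    if d < 2 or n - 1 < d:
        return 1.0, 1.0
    S = np.cov(Y, rowvar=False, ddof=1)
    C = _orthonormal_contrasts(k)
    M = C @ S @ C.T
    eig = np.linalg.eigvalsh(M)
    if np.any(eig <= 0):
        return 0.0, 0.0
    W = float(np.prod(eig) / (np.mean(eig) ** d))
    # Box's chi-square approximation with the second-order correction term
    f = 1.0 - (2.0 * d * d + d + 2.0) / (6.0 * d * (n - 1.0))
    w2 = (
        (d + 2.0) * (d - 1.0) * (d - 2.0) * (2.0 * d ** 3 + 6.0 * d ** 2 + 3.0 * k + 2.0)
        / (288.0 * ((n - 1.0) * d * f) ** 2)
    )
    chi2 = -(n - 1.0) * f * np.log(W)
    dof = d * (d + 1) / 2 - 1
    p1 = float(stats.chi2.sf(chi2, dof))
    p2 = float(stats.chi2.sf(chi2, dof + 4))
    p = float(np.clip(p1 + w2 * (p2 - p1), 0.0, 1.0))
    return W, p


# --------------------------------------------------------------------------
# Dunnett adjustment (equicorrelated multivariate t)
# --------------------------------------------------------------------------

_HERMITE_NODES, _HERMITE_WEIGHTS = np.polynomial.hermite_e.hermegauss(96)
_HERMITE_WEIGHTS = _HERMITE_WEIGHTS / np.sqrt(2.0 * np.pi)  # weight: standard normal
_LEGENDRE_NODES, _LEGENDRE_WEIGHTS = np.polynomial.legendre.leggauss(96)


def dunnett_sf(
    tval: float, n_comparisons: int, df: float, rho: float = 0.5
) -> float:
    """Family-wise P(max_j |T_j| >= tval) for equicorrelated multivariate t.

    ``T_j`` are ``n_comparisons`` t-variates with ``df`` degrees of freedom
    and common pairwise correlation ``rho`` (0.5 for balanced many-to-one
    comparisons).  Evaluated by deterministic tensor quadrature:
    Gauss-Hermite over the shared normal factor, Gauss-Legendre in
    probability space over the chi scale factor (absolute accuracy well
    below 1e-6).
    """
    if tval <= 0:
        return 1.0
    k = int(n_comparisons)
    if k == 1:
        return float(2.0 * stats.t.sf(tval, df))
    sr, cr = np.sqrt(rho), np.sqrt(1.0 - rho)
    # scale factor s = chi_df / sqrt(df); integrate over its probability scale
    q = 0.5 * (_LEGENDRE_NODES + 1.0)
    s = stats.chi.ppf(q, df) / np.sqrt(df)
    w_s = 0.5 * _LEGENDRE_WEIGHTS
    z = _HERMITE_NODES
    a = (tval * s[:, None] - sr * z[None, :]) / cr
    b = (-tval * s[:, None] - sr * z[None, :]) / cr
    probs = stats.norm.cdf(a) - stats.norm.cdf(b)
    inner = probs ** k @ _HERMITE_WEIGHTS
    acc = float(w_s @ inner)
    return float(min(1.0, max(0.0, 1.0 - acc)))


def _dunnett_vs_first(Y: np.ndarray, labels: Sequence, prefix: str = "") -> list[tuple[str, float]]:
    """Each later column vs the first, paired contrasts with Dunnett adjustment."""
    n, k = Y.shape
    out = []
    for j in range(1, k):
        d = Y[:, j] - Y[:, 0]
        sd = d.std(ddof=1)
        if sd == 0:
            p = 1.0 if np.allclose(d, 0) else 0.0
        else:
            tj = d.mean() / (sd / np.sqrt(n))
            p = dunnett_sf(abs(tj), k - 1, n - 1)
        out.append((f"{prefix}{labels[j]} vs {labels[0]}", float(p)))
    return out


# --------------------------------------------------------------------------
# repeated-measures ANOVA
# --------------------------------------------------------------------------

def _oneway_rm(Y: np.ndarray, apply_gg) -> TestResult:
    n, k = Y.shape
    grand = Y.mean()
    col = Y.mean(axis=0)
    row = Y.mean(axis=1)
    ss_factor = n * float(np.sum((col - grand) ** 2))
    ss_subject = k * float(np.sum((row - grand) ** 2))
    ss_total = float(np.sum((Y - grand) ** 2))
    ss_error = ss_total - ss_factor - ss_subject
    df1, df2 = k - 1.0, (n - 1.0) * (k - 1.0)
    ms_factor = ss_factor / df1
    ms_error = ss_error / df2 if df2 > 0 else np.nan
    F = ms_factor / ms_error if ms_error > 0 else np.inf

    eps = greenhouse_geisser_epsilon(Y)
    _, mauchly_p = mauchly_test(Y)
    if apply_gg == "auto":
        applied = mauchly_p < 0.05
    else:
        applied = bool(apply_gg)
    if applied:
        p = float(stats.f.sf(F, df1 * eps, df2 * eps))
        correction = "greenhouse_geisser"
    else:
        p = float(stats.f.sf(F, df1, df2))
        correction = "none"
    return TestResult(
        test_name="rm_anova",
        statistic=float(F),
        p_value=p,
        correction=correction,
        epsilon=eps,
        df=(df1, df2),
        n=n,
    )


def _twoway_rm(cube: np.ndarray, a_labels, b_labels, apply_gg) -> dict[str, TestResult]:
    """Fully within-subject two-way RM-ANOVA on an (n, a, b) data cube."""
    n, a, b = cube.shape
    grand = cube.mean()
    m_i = cube.mean(axis=(1, 2))          # subject
    m_A = cube.mean(axis=(0, 2))          # factor A
    m_B = cube.mean(axis=(0, 1))          # factor B
    m_iA = cube.mean(axis=2)              # (n, a)
    m_iB = cube.mean(axis=1)              # (n, b)
    m_AB = cube.mean(axis=0)              # (a, b)

    ss_A = n * b * float(np.sum((m_A - grand) ** 2))
    ss_B = n * a * float(np.sum((m_B - grand) ** 2))
    ss_AB = n * float(
        np.sum((m_AB - m_A[:, None] - m_B[None, :] + grand) ** 2)
    )
    ss_AS = b * float(
        np.sum((m_iA - m_i[:, None] - m_A[None, :] + grand) ** 2)
    )
    ss_BS = a * float(
        np.sum((m_iB - m_i[:, None] - m_B[None, :] + grand) ** 2)
    )
    ss_total = float(np.sum((cube - grand) ** 2))
    ss_subject = a * b * float(np.sum((m_i - grand) ** 2))
    ss_ABS = ss_total - ss_subject - ss_A - ss_B - ss_AB - ss_AS - ss_BS

    C_A = _orthonormal_contrasts(a)
    C_B = _orthonormal_contrasts(b)
    flat = cube.reshape(n, a * b)
    S = np.cov(flat, rowvar=False, ddof=1)

    def eff(name, ss, df1, ss_err, df2, C_kron, gate_data):
        ms, ms_err = ss / df1, ss_err / df2
        F = ms / ms_err if ms_err > 0 else np.inf
        eps = _epsilon_from_cov(S, C_kron)
        _, mauchly_p = (
            mauchly_test(gate_data) if gate_data is not None else (1.0, 1.0)
        )
        if apply_gg == "auto":
            applied = mauchly_p < 0.05
        else:
            applied = bool(apply_gg)
        if applied and df1 > 0:
            p = float(stats.f.sf(F, df1 * eps, df2 * eps))
            corr = "greenhouse_geisser"
        else:
            p = float(stats.f.sf(F, df1, df2))
            corr = "none"
        return TestResult(
            test_name=f"rm_anova[{name}]",
            statistic=float(F),
            p_value=p,
            correction=corr,
            epsilon=eps,
            df=(df1, df2),
            n=n,
        )

    ones_a = np.full((1, a), 1.0 / np.sqrt(a))
    ones_b = np.full((1, b), 1.0 / np.sqrt(b))
    effects = {
        "trial": eff(
            "trial", ss_A, a - 1.0, ss_AS, (a - 1.0) * (n - 1.0),
            np.kron(C_A, ones_b), m_iA,
        ),
        "odor": eff(
            "odor", ss_B, b - 1.0, ss_BS, (b - 1.0) * (n - 1.0),
            np.kron(ones_a, C_B), m_iB,
        ),
        "trial_x_odor": eff(
            "trial_x_odor", ss_AB, (a - 1.0) * (b - 1.0), ss_ABS,
            (a - 1.0) * (b - 1.0) * (n - 1.0), np.kron(C_A, C_B), None,
        ),
    }
    return effects


def rm_anova_dunnett(
    trajectories: pd.DataFrame,
    apply_gg: bool | str = "auto",
    dv: str = "value",
    subject: str = "fly_id",
    within: str = "trial_index",
    between_odor: str = "odor",
) -> TestResult:
    """Repeated-measures ANOVA over trials with Dunnett comparisons vs trial 1.

    ``trajectories`` is long-format with one row per (subject, trial[, odor])
    — or a wide subjects-by-trials frame.  With a single odor a one-way RM
    ANOVA over trials is run; with both odors a fully within-subject two-way
    (trial x odor) RM ANOVA, whose headline result is the trial-by-odor
    interaction (the learning effect: the CS+ trajectory departs from CS-).

    ``apply_gg`` controls the Greenhouse-Geisser degrees-of-freedom
    correction: True (always), False (never) or "auto" (apply when Mauchly's
    test rejects sphericity at 0.05 — the calibrated default).

    The design must be balanced; missing cells raise
    :class:`UnbalancedDesignError` rather than being imputed.

    Post-hoc: each later trial vs the first trial, paired contrasts adjusted
    with critical values of the equicorrelated multivariate t (per odor in
    the two-way case).
    """
    df = trajectories
    if between_odor not in getattr(df, "columns", []) or (
        between_odor in df.columns and df[between_odor].nunique() <= 1
    ):
        # one-way: accept wide or long input
        if dv in df.columns and subject in df.columns and within in df.columns:
            wide = df.pivot(index=subject, columns=within, values=dv)
        else:
            wide = df
        if wide.isna().any().any():
            raise UnbalancedDesignError("unequal trial coverage across subjects")
        wide = wide.sort_index(axis=1)
        Y = wide.to_numpy(dtype=float)
        if Y.shape[0] < 2 or Y.shape[1] < 2:
            raise UnbalancedDesignError("need >= 2 subjects and >= 2 trials")
        res = _oneway_rm(Y, apply_gg)
        res.posthoc = _dunnett_vs_first(Y, list(wide.columns), prefix="trial ")
        return res

    # two-way: long input required
    odors = sorted(df[between_odor].unique())
    piv = df.pivot_table(
        index=subject, columns=[within, between_odor], values=dv, aggfunc="first"
    )
    full_cols = pd.MultiIndex.from_product(
        [sorted(df[within].unique()), odors], names=[within, between_odor]
    )
    piv = piv.reindex(columns=full_cols)
    if piv.isna().any().any():
        raise UnbalancedDesignError("unequal (trial, odor) coverage across subjects")
    trials = sorted(df[within].unique())
    n, a, b = len(piv), len(trials), len(odors)
    cube = piv.to_numpy(dtype=float).reshape(n, a, b)
    effects = _twoway_rm(cube, trials, odors, apply_gg)

    headline = effects["trial_x_odor"]
    posthoc = []
    for jb, odor in enumerate(odors):
        posthoc += _dunnett_vs_first(
            cube[:, :, jb], trials, prefix=f"{odor}: trial "
        )
    result = TestResult(
        test_name="rm_anova_two_way",
        statistic=headline.statistic,
        p_value=headline.p_value,
        correction=headline.correction,
        epsilon=headline.epsilon,
        df=headline.df,
        n=n,
        posthoc=posthoc,
        effects=effects,
    )
    return result
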