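"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the Lorenz largest
Lyapunov exponent comes from two-trajectory Benettin renormalization of the
true dynamics; the circular two-factor ANOVA is an explicit-loop
re-implementation of the Harrison-Kanji equations; the repeated-measures F
is computed from raw sums of squares.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import iv
from scipy.stats import chi2 as chi2_dist
from scipy.stats import f as f_dist

LORENZ_SIGMA, LORENZ_RHO, LORENZ_BETA = 10.0, 28.0, 8.0 / 3.0


def lorenz_rhs(t, s):
    x, y, z = s
    return [LORENZ_SIGMA * (y - x),
            x * (LORENZ_RHO - z) - y,
            x * y - LORENZ_BETA * z]


def lorenz_series(n: int, dt: float, transient: float = 20.0,
                  init=(1.0, 1.0, 20.0)) -> np.ndarray:
    """x-component of the Lorenz system after discarding a transient."""
    t_eval = np.arange(n) * dt + transient
    sol = solve_ivp(lorenz_rhs, (0.0, t_eval[-1]), list(init),
                    t_eval=t_eval, rtol=1e-9, atol=1e-9)
    return sol.y[0]


def benettin_lle(dt: float = 0.01, n_steps: int = 4000, d0: float = 1e-8,
                 init=(1.0, 1.0, 20.0)) -> float:
    """Largest Lyapunov exponent by periodic renormalization of a
    perturbed companion trajectory."""
    s = solve_ivp(lorenz_rhs, (0.0, 20.0), list(init),
                  rtol=1e-10, atol=1e-10).y[:, -1]
    pert = s + d0 * np.array([1.0, 0.0, 0.0])
    acc = 0.0
    for _ in range(n_steps):
        s = solve_ivp(lorenz_rhs, (0.0, dt), s, rtol=1e-10, atol=1e-10).y[:, -1]
        pert = solve_ivp(lorenz_rhs, (0.0, dt), pert,
                         rtol=1e-10, atol=1e-10).y[:, -1]
        d = float(np.linalg.norm(pert - s))
        acc += np.log(d / d0)
        pert = s + (pert - s) * (d0 / d)
    return acc / (n_steps * dt)


# ---------------------------------------------------------------------------
# Harrison-Kanji equations, explicit-loop form
# ---------------------------------------------------------------------------

def _kappa_from_r(r: float, n: int) -> float:
    r = min(r, 1.0 - 1e-10)
    if r < 0.53:
        k = 2 * r + r**3 + 5 * r**5 / 6
    elif r < 0.85:
        k = -0.4 + 1.39 * r + 0.43 / (1 - r)
    else:
        k = 1.0 / (r**3 - 4 * r**2 + 3 * r)
    if 1 < n < 15:
        k = max(k - 2.0 / (n * k), 0.0) if k < 2 else (n - 1) ** 3 * k / (n**3 + n)
    return k


def hk_oracle(angles, fa, fb):
    """Two-factor circular ANOVA statistics and p-values, loop form.

    Returns {"A": (stat, p), "B": (stat, p), "A * B": (stat, p)}.
    """
    angles = list(map(float, angles))
    fa, fb = list(fa), list(fb)
    n = len(angles)
    la = sorted(set(fa))
    lb = sorted(set(fb))
    p, q = len(la), len(lb)

    def R(sel):
        s = sum(np.sin(angles[i]) for i in sel)
        c = sum(np.cos(angles[i]) for i in sel)
        return float(np.hypot(s, c))

    all_idx = list(range(n))
    Rtot = R(all_idx)
    kappa = _kappa_from_r(Rtot / n, n)

    spp = sum(R([i for i in all_idx if fa[i] == a]) ** 2 for a in la) / (n / p)
    sqq = sum(R([i for i in all_idx if fb[i] == b]) ** 2 for b in lb) / (n / q)
    scc = sum(
        R([i for i in all_idx if fa[i] == a and fb[i] == b]) ** 2
        for a in la for b in lb
    ) / (n / (p * q))
    tot = Rtot**2 / n
    df_a, df_b, df_i = p - 1, q - 1, (p - 1) * (q - 1)

    if kappa > 2:
        beta = 1.0 / (1.0 - 1.0 / (5 * kappa) - 1.0 / (10 * kappa**2))
        eff_r = n - scc
        df_r = n - p * q
        ms_r = eff_r / df_r
        Fa = beta * max(spp - tot, 0.0) / df_a / ms_r
        Fb = beta * max(sqq - tot, 0.0) / df_b / ms_r
        Fi = max(scc - spp - sqq + tot, 0.0) / df_i / ms_r
        return {
            "A": (Fa, float(f_dist.sf(Fa, df_a, df_r))),
            "B": (Fb, float(f_dist.sf(Fb, df_b, df_r))),
            "A * B": (Fi, float(f_dist.sf(Fi, df_i, df_r))),
        }
    a1 = iv(1, kappa) / iv(0, kappa)
    scale = 2.0 / (1.0 - a1**2)
    ca = scale * max(spp - tot, 0.0)
    cb = scale * max(sqq - tot, 0.0)
    ci = scale * max(scc - spp - sqq + tot, 0.0)
    return {
        "A": (ca, float(chi2_dist.sf(ca, df_a))),
        "B": (cb, float(chi2_dist.sf(cb, df_b))),
        "A * B": (ci, float(chi2_dist.sf(ci, df_i))),
    }


def rm_anova_f_oracle(table: np.ndarray) -> float:
    """One-way repeated-measures F from raw sums of squares.

    ``table`` is (levels, subjects)."""
    table = np.asarray(table, dtype=float)
    k, n = table.shape
    grand = table.mean()
    ss_treat = n * ((table.mean(axis=1) - grand) ** 2).sum()
    ss_subj = k * ((table.mean(axis=0) - grand) ** 2).sum()
    ss_tot = ((table - grand) ** 2).sum()
    ss_err = ss_tot - ss_treat - ss_subj
    return (ss_treat / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
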