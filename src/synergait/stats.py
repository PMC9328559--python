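"""Statistical layer: repeated-measures ANOVA with Greenhouse-Geisser
correction, Holm-corrected paired post-hocs, and circular statistics for
activation-timing angles (circular mean, Harrison-Kanji two-factor ANOVA
for circular data).

The repeated-measures machinery is delegated to pingouin; the Harrison-Kanji
test is implemented here from the published equations (resultant-length
decomposition with a concentration-dependent form: corrected F statistics
for concentrated data, a chi-squared approximation otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
from scipy.special import iv
from statsmodels.stats.multitest import multipletests

MAUCHLY_ALPHA = 0.05  # sphericity violation threshold triggering GG


@dataclass
class AnovaResult:
    """One effect row: F (or chi2 for the circular test), df, p, GG epsilon."""

    effect: str
    F: float
    df_num: float
    df_den: float
    p: float
    epsilon: Optional[float] = None
    gg_applied: bool = False
    sphericity_p: Optional[float] = None

    def summary(self) -> str:
        df1 = f"{self.df_num:.2f}".rstrip("0").rstrip(".")
        df2 = f"{self.df_den:.2f}".rstrip("0").rstrip(".")
        s = f"{self.effect}: F({df1}, {df2}) = {self.F:.3f}, p = {self.p:.4g}"
        if self.gg_applied:
            s += f" (Greenhouse-Geisser, eps = {self.epsilon:.3f})"
        return s


def _mauchly_p(data: pd.DataFrame, dv: str, subject: str,
               within) -> Optional[float]:
    try:
        res = pg.sphericity(data=data, dv=dv, subject=subject, within=within)
        return float(res.pval)
    except Exception:
        return None


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: str | Sequence[str],
    subject: str,
) -> list[AnovaResult]:
    """One- or two-way repeated-measures ANOVA on a long-format table.

    For each within effect with more than one numerator df, Mauchly's test
    is run; when sphericity is violated (p < 0.05) the Greenhouse-Geisser
    epsilon scales both degrees of freedom and the corrected p-value is
    reported. Balanced complete data required.
    """
    within_list = [within] if isinstance(within, str) else list(within)
    # completeness check over the full subject x levels grid
    counts = data.groupby([subject] + within_list, observed=True)[dv].count()
    n_cells = data[subject].nunique()
    for w in within_list:
        n_cells *= data[w].nunique()
    if counts.empty or len(counts) != n_cells or counts.nunique() != 1:
        raise ValueError("missing cells: design must be balanced and complete")
    # rename dv defensively (pingouin's internal melt collides with some
    # dv names) and only request sphericity handling when meaningful
    df_in = data[[subject] + within_list + [dv]].rename(columns={dv: "_dv_"})
    want_corr = any(data[w].nunique() > 2 for w in within_list)
    within_arg = within_list[0] if len(within_list) == 1 else within_list
    try:
        tab = pg.rm_anova(data=df_in, dv="_dv_", within=within_arg,
                          subject=subject, correction=want_corr, detailed=True)
    except ZeroDivisionError:
        # sphericity machinery degenerates for very few subjects; report
        # uncorrected statistics (no basis for a Mauchly decision)
        tab = pg.rm_anova(data=df_in, dv="_dv_", within=within_arg,
                          subject=subject, correction=False, detailed=True)
    out: list[AnovaResult] = []
    for _, row in tab.iterrows():
        name = row["Source"]
        if name == "Error":
            continue
        df1 = float(row["ddof1"]) if "ddof1" in row else float(row["DF"])
        if "ddof2" in row:
            df2 = float(row["ddof2"])
        else:
            df2 = float(tab.loc[tab["Source"] == "Error", "DF"].iloc[0])
        eps = float(row["eps"]) if not pd.isna(row.get("eps", np.nan)) else None
        # Mauchly per effect: main effects on data collapsed over the other
        # factor, interaction on the full two-factor layout
        if df1 > 1:
            if " * " in name:
                spher_p = _mauchly_p(data, dv, subject, within_list)
            else:
                others = [w for w in within_list if w != name]
                collapsed = (data.groupby([subject, name], observed=True,
                                          as_index=False)[dv].mean()
                             if others else data)
                spher_p = _mauchly_p(collapsed, dv, subject, name)
        else:
            spher_p = None
        apply_gg = (df1 > 1 and spher_p is not None
                    and spher_p < MAUCHLY_ALPHA and eps is not None)
        if apply_gg:
            p = float(row.get("p_GG_corr", np.nan))
            df1_r, df2_r = df1 * eps, df2 * eps
        else:
            p = float(row.get("p_unc", np.nan))
            df1_r, df2_r = df1, df2
        F = float(row.get("F", np.nan))
        if not np.isfinite(F):  # zero residual/between-level variance
            F, p = 0.0, 1.0
        out.append(AnovaResult(
            effect=name, F=F, df_num=df1_r, df_den=df2_r, p=p,
            epsilon=eps, gg_applied=apply_gg, sphericity_p=spher_p,
        ))
    return out


def holm_posthoc(pvals: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment with monotonicity enforcement."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="holm")[1]


def paired_posthocs(
    data: pd.DataFrame,
    dv: str,
    within: str,
    subject: str,
    comparisons: Sequence[tuple[str, str]] = (("Pre", "Post1"), ("Pre", "Post2")),
) -> pd.DataFrame:
    """Paired t-tests for the listed level pairs, Holm-corrected as a family."""
    rows = []
    for a, b in comparisons:
        wide = data.pivot_table(index=subject, columns=within, values=dv,
                                observed=True)
        t, p = sps.ttest_rel(wide[a], wide[b])
        rows.append({"comparison": f"{a} vs {b}", "t": float(t),
                     "p_unc": float(p),
                     "mean_diff": float((wide[a] - wide[b]).mean())})
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_posthoc(out["p_unc"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Circular statistics
# ---------------------------------------------------------------------------

def circ_mean(angles: np.ndarray) -> float:
    """Circular mean, wrapped to [0, 2pi). Errors on a zero resultant."""
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one angle")
    s, c = np.mean(np.sin(a)), np.mean(np.cos(a))
    if np.hypot(s, c) < 1e-9:
        raise ValueError("circular mean undefined: zero resultant length")
    return float(np.arctan2(s, c) % (2.0 * np.pi))


def resultant_length(angles: np.ndarray) -> float:
    a = np.asarray(angles, dtype=float)
    return float(np.hypot(np.mean(np.sin(a)), np.mean(np.cos(a))))


def est_kappa(r: float, n: Optional[int] = None) -> float:
    """Von Mises concentration from a mean resultant length (Fisher's
    approximation, with the usual small-sample correction when n < 15)."""
    r = min(float(r), 1.0 - 1e-10)
    if r < 0.53:
        kappa = 2 * r + r**3 + 5 * r**5 / 6
    elif r < 0.85:
        kappa = -0.4 + 1.39 * r + 0.43 / (1 - r)
    else:
        kappa = 1.0 / (r**3 - 4 * r**2 + 3 * r)
    if n is not None and 1 < n < 15:
        if kappa < 2:
            kappa = max(kappa - 2.0 / (n * kappa), 0.0)
        else:
            kappa = (n - 1) ** 3 * kappa / (n**3 + n)
    return float(kappa)


def _group_R(angles: np.ndarray, labels: np.ndarray) -> dict:
    out = {}
    for lv in np.unique(labels):
        a = angles[labels == lv]
        out[lv] = float(np.hypot(np.sum(np.sin(a)), np.sum(np.cos(a))))
    return out


def circ_anova2(
    angles: np.ndarray,
    factor_a: np.ndarray,
    factor_b: np.ndarray,
    interaction: bool = True,
) -> list[AnovaResult]:
    """Harrison-Kanji two-factor ANOVA for circular data.

    Decomposes squared resultant lengths by factor level and cell. For
    concentrated data (estimated kappa > 2) corrected F statistics are used
    (the correction factor 1/(1 - 1/(5k) - 1/(10k^2)) applied to the main
    effects); otherwise a chi-squared approximation scaled by
    2/(1 - A1(kappa)^2). A near-zero resultant in any cell violates the
    test's assumptions and triggers a warning.
    """
    import warnings

    alpha = np.asarray(angles, dtype=float).ravel()
    fa = np.asarray(factor_a).ravel()
    fb = np.asarray(factor_b).ravel()
    if not (alpha.size == fa.size == fb.size):
        raise ValueError("angles and factor labels must have equal length")
    lev_a, lev_b = np.unique(fa), np.unique(fb)
    p, q = len(lev_a), len(lev_b)
    n = alpha.size
    pn, qn, cn = n / p, n / q, n / (p * q)
    # balanced design check
    cells = pd.crosstab(pd.Series(fa), pd.Series(fb)).to_numpy()
    if cells.min() != cells.max():
        raise ValueError("unbalanced design: equal cell sizes required")

    R = float(np.hypot(np.sum(np.sin(alpha)), np.sum(np.cos(alpha))))
    kappa = est_kappa(R / n, n)

    pR = _group_R(alpha, fa)
    qR = _group_R(alpha, fb)
    cell_labels = np.array([f"{a}|{b}" for a, b in zip(fa, fb)])
    cR = _group_R(alpha, cell_labels)
    for key, r_cell in cR.items():
        if r_cell / cn < 1e-6:
            warnings.warn(
                f"near-zero resultant in cell {key}: Harrison-Kanji "
                "assumptions violated", stacklevel=2)

    sum_pR2 = sum(v**2 for v in pR.values()) / pn
    sum_qR2 = sum(v**2 for v in qR.values()) / qn
    sum_cR2 = sum(v**2 for v in cR.values()) / cn
    tot = R**2 / n
    df_a, df_b, df_i = p - 1, q - 1, (p - 1) * (q - 1)

    results: list[AnovaResult] = []
    if kappa > 2:
        eff_a = sum_pR2 - tot
        eff_b = sum_qR2 - tot
        if interaction:
            beta = 1.0 / (1.0 - 1.0 / (5 * kappa) - 1.0 / (10 * kappa**2))
            eff_i = sum_cR2 - sum_pR2 - sum_qR2 + tot
            eff_r = n - sum_cR2
            df_r = n - p * q
        else:
            beta = 1.0
            eff_i = np.nan
            eff_r = n - sum_pR2 - sum_qR2 + tot
            df_r = df_i
        if eff_r < 1e-9 * n:  # zero residual dispersion: nothing to test
            for name, df1 in (("A", df_a), ("B", df_b)) + (
                    (("A * B", df_i),) if interaction else ()):
                results.append(AnovaResult(name, 0.0, df1, df_r, 1.0))
            return results
        ms_r = eff_r / df_r
        Fa = beta * max(eff_a, 0.0) / df_a / ms_r
        Fb = beta * max(eff_b, 0.0) / df_b / ms_r
        results.append(AnovaResult("A", Fa, df_a, df_r,
                                   float(sps.f.sf(Fa, df_a, df_r))))
        results.append(AnovaResult("B", Fb, df_b, df_r,
                                   float(sps.f.sf(Fb, df_b, df_r))))
        if interaction:
            Fi = max(eff_i, 0.0) / df_i / ms_r
            results.append(AnovaResult("A * B", Fi, df_i, df_r,
                                       float(sps.f.sf(Fi, df_i, df_r))))
    else:
        a1 = iv(1, kappa) / iv(0, kappa)
        scale = 2.0 / max(1.0 - a1**2, 1e-12)
        chi_a = scale * max(sum_pR2 - tot, 0.0)
        chi_b = scale * max(sum_qR2 - tot, 0.0)
        results.append(AnovaResult("A", chi_a, df_a, np.inf,
                                   float(sps.chi2.sf(chi_a, df_a))))
        results.append(AnovaResult("B", chi_b, df_b, np.inf,
                                   float(sps.chi2.sf(chi_b, df_b))))
        if interaction:
            chi_i = scale * max(sum_cR2 - sum_pR2 - sum_qR2 + tot, 0.0)
            results.append(AnovaResult("A * B", chi_i, df_i, np.inf,
                                       float(sps.chi2.sf(chi_i, df_i))))
    return results
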