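"""Inferential layer: normality screening, repeated-measures ANOVA with
Greenhouse-Geisser correction, partial eta-squared, and Bonferroni post hocs.

``rm_anova`` handles one or two within-subject factors on a complete,
balanced long table (one value per subject x cell; no imputation).  Sums
of squares come from the cell-means decomposition, each within effect is
tested against its own effect-by-subject interaction, the
Greenhouse-Geisser epsilon is computed from the covariance of the
effect's orthonormal contrast scores, and the corrected p-value uses the
epsilon-scaled F distribution.  Effect sizes are partial eta-squared,
``SS_effect / (SS_effect + SS_error)``, banded by Cohen's conventions.

Normality screening (Shapiro-Wilk) is attached as metadata, not a gate:
the ANOVA proceeds regardless, and no outliers are ever excluded.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ValidationError

__all__ = [
    "shapiro_screen",
    "rm_anova",
    "bonferroni_posthoc",
    "effect_size_label",
]

ALPHA = 0.05


def shapiro_screen(differences: np.ndarray, alpha: float = ALPHA) -> dict:
    """Shapiro-Wilk normality screen on per-subject difference scores.

    Returns ``{"W", "p", "normal"}``; on a zero-variance vector the test
    is undefined and is reported as non-computable (``normal=None``).
    """
    x = np.asarray(differences, dtype=float)
    if len(x) < 3:
        raise ValidationError("Shapiro-Wilk requires n >= 3")
    if np.ptp(x) == 0:
        return {"W": float("nan"), "p": float("nan"), "normal": None}
    w, p = sps.shapiro(x)
    return {"W": float(w), "p": float(p), "normal": bool(p > alpha)}


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k x (k-1) orthonormal (Helmert) contrast matrix."""
    H = np.zeros((k, k - 1))
    for j in range(k - 1):
        H[: j + 1, j] = 1.0
        H[j + 1, j] = -(j + 1.0)
        H[:, j] /= np.linalg.norm(H[:, j])
    return H


def _gg_epsilon(scores: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from n x r contrast scores."""
    r = scores.shape[1]
    if r == 1:
        return 1.0
    S = np.atleast_2d(np.cov(scores, rowvar=False, ddof=1))
    tr2 = float(np.trace(S @ S))
    if tr2 <= 1e-300:
        return 1.0
    eps = float(np.trace(S)) ** 2 / (r * tr2)
    return float(np.clip(eps, 1.0 / r, 1.0))


def _f_p(ss_eff: float, df_eff: float, ss_err: float, df_err: float,
         eps: float) -> tuple[float, float, float]:
    """F, uncorrected p and GG-corrected p; 0/0 counts as no effect."""
    tiny = 1e-12
    if ss_err <= tiny:
        if ss_eff <= tiny:
            return 0.0, 1.0, 1.0
        return float("inf"), 0.0, 0.0
    F = (ss_eff / df_eff) / (ss_err / df_err)
    p = float(sps.f.sf(F, df_eff, df_err))
    p_gg = float(sps.f.sf(F, eps * df_eff, eps * df_err))
    return float(F), p, p_gg


def _pivot_complete(data: pd.DataFrame, dv: str, within: Sequence[str],
                    subject: str) -> pd.DataFrame:
    for col in (dv, subject, *within):
        if col not in data.columns:
            raise ValidationError(f"column {col!r} missing from data")
    dup = data.duplicated(subset=[subject, *within])
    if dup.any():
        raise ValidationError("duplicate subject x cell rows (one value per cell required)")
    wide = data.pivot(index=subject, columns=list(within), values=dv)
    if wide.isna().any().any():
        raise ValidationError("missing cell(s); rm_anova requires a complete balanced table")
    if len(wide) < 2:
        raise ValidationError("rm_anova requires at least 2 subjects")
    return wide.sort_index(axis=1)


def rm_anova(data: pd.DataFrame, dv: str = "value",
             within: Sequence[str] = ("phase",),
             subject: str = "worker_id") -> pd.DataFrame:
    """Repeated-measures ANOVA for one or two within-subject factors.

    ``data`` is long format with one row per subject x cell.  Returns one
    row per effect (and the interaction for two factors) with columns
    ``F, df_num, df_den, epsilon_gg, p_unc, p_gg, partial_eta_sq,
    ss_effect, ss_error``; ``ss_subjects`` and ``ss_total`` are attached
    in ``.attrs`` so the decomposition can be audited.
    """
    within = list(within)
    if len(within) not in (1, 2):
        raise ValidationError("rm_anova supports 1 or 2 within factors")
    wide = _pivot_complete(data, dv, within, subject)
    Y2 = wide.to_numpy(dtype=float)
    n = Y2.shape[0]
    g = Y2.mean()
    ss_total = float(((Y2 - g) ** 2).sum())
    rows = []

    if len(within) == 1:
        k = Y2.shape[1]
        if k < 2:
            raise ValidationError("within factor needs >= 2 levels")
        subj = Y2.mean(axis=1)
        cond = Y2.mean(axis=0)
        ss_subj = float(k * ((subj - g) ** 2).sum())
        ss_eff = float(n * ((cond - g) ** 2).sum())
        ss_err = ss_total - ss_subj - ss_eff
        eps = _gg_epsilon(Y2 @ _orthonormal_contrasts(k))
        F, p, p_gg = _f_p(ss_eff, k - 1, ss_err, (k - 1) * (n - 1), eps)
        rows.append((within[0], F, k - 1, (k - 1) * (n - 1), eps, p, p_gg,
                     ss_eff, ss_err))
    else:
        a_levels = wide.columns.get_level_values(0).unique()
        b_levels = wide.columns.get_level_values(1).unique()
        a, b = len(a_levels), len(b_levels)
        if a < 2 or b < 2:
            raise ValidationError("each within factor needs >= 2 levels")
        Y = Y2.reshape(n, a, b)
        subj = Y.mean(axis=(1, 2))
        Ai = Y.mean(axis=(0, 2))
        Bj = Y.mean(axis=(0, 1))
        ABij = Y.mean(axis=0)
        AS = Y.mean(axis=2)
        BS = Y.mean(axis=1)
        ss_subj = float(a * b * ((subj - g) ** 2).sum())
        ss_a = float(n * b * ((Ai - g) ** 2).sum())
        ss_err_a = float(b * ((AS - Ai[None, :] - subj[:, None] + g) ** 2).sum())
        ss_b = float(n * a * ((Bj - g) ** 2).sum())
        ss_err_b = float(a * ((BS - Bj[None, :] - subj[:, None] + g) ** 2).sum())
        ss_ab = float(n * ((ABij - Ai[:, None] - Bj[None, :] + g) ** 2).sum())
        ss_err_ab = ss_total - ss_subj - ss_a - ss_err_a - ss_b - ss_err_b - ss_ab
        Ca, Cb = _orthonormal_contrasts(a), _orthonormal_contrasts(b)
        ja = np.full((a, 1), 1.0 / a)
        jb = np.full((b, 1), 1.0 / b)
        effects = [
            (within[0], ss_a, a - 1, ss_err_a, (a - 1) * (n - 1), np.kron(Ca, jb)),
            (within[1], ss_b, b - 1, ss_err_b, (b - 1) * (n - 1), np.kron(ja, Cb)),
            (f"{within[0]} * {within[1]}", ss_ab, (a - 1) * (b - 1),
             ss_err_ab, (a - 1) * (b - 1) * (n - 1), np.kron(Ca, Cb)),
        ]
        for name, ss_eff, df_eff, ss_err, df_err, M in effects:
            eps = _gg_epsilon(Y2 @ M)
            F, p, p_gg = _f_p(ss_eff, df_eff, ss_err, df_err, eps)
            rows.append((name, F, df_eff, df_err, eps, p, p_gg, ss_eff, ss_err))

    out = pd.DataFrame(
        rows, columns=["effect", "F", "df_num", "df_den", "epsilon_gg",
                       "p_unc", "p_gg", "ss_effect", "ss_error"])
    denom = out["ss_effect"] + out["ss_error"]
    out["partial_eta_sq"] = np.where(denom > 0, out["ss_effect"] / denom, 0.0)
    out.attrs["ss_subjects"] = ss_subj
    out.attrs["ss_total"] = ss_total
    out.attrs["n_subjects"] = n
    return out


def bonferroni_posthoc(data: pd.DataFrame, dv: str = "value",
                       within: str = "phase", subject: str = "worker_id",
                       pairs: Sequence[tuple] | None = None,
                       alpha: float = ALPHA) -> pd.DataFrame:
    """Bonferroni-adjusted paired contrasts with simultaneous 95% CIs.

    Per pair ``(a, b)`` the contrast is ``mean(a - b)`` over subjects;
    the CI is the paired-t interval at the adjusted level
    ``1 - alpha/m`` and ``p_adj = min(1, m * p)`` for ``m`` pairs.
    Defaults to all level pairs of ``within``.
    """
    wide = _pivot_complete(data, dv, [within], subject)
    levels = list(wide.columns)
    if pairs is None:
        pairs = list(combinations(levels, 2))
    pairs = list(pairs)
    if not pairs:
        raise ValidationError("empty pair list")
    m = len(pairs)
    n = len(wide)
    rows = []
    for a, b in pairs:
        if a not in levels or b not in levels:
            raise ValidationError(f"unknown level in pair ({a!r}, {b!r})")
        d = wide[a].to_numpy(dtype=float) - wide[b].to_numpy(dtype=float)
        mean_diff = float(d.mean())
        se = float(d.std(ddof=1) / np.sqrt(n))
        if se == 0.0:
            t_stat, p = (0.0, 1.0) if mean_diff == 0 else (float("inf"), 0.0)
        else:
            t_stat, p = sps.ttest_rel(wide[a], wide[b])
        crit = float(sps.t.ppf(1.0 - alpha / (2.0 * m), n - 1))
        rows.append({
            "pair": f"{a} - {b}", "mean_diff": mean_diff,
            "ci_low": mean_diff - crit * se, "ci_high": mean_diff + crit * se,
            "t": float(t_stat), "p_unc": float(p),
            "p_adj": min(1.0, float(p) * m), "n": n,
        })
    return pd.DataFrame(rows)


def effect_size_label(partial_eta_sq: float) -> str:
    """Cohen's conventional bands: small >= 0.01, medium >= 0.06, large >= 0.14."""
    if not 0.0 <= partial_eta_sq <= 1.0:
        raise ValidationError("partial eta squared must lie in [0, 1]")
    if partial_eta_sq >= 0.14:
        return "large"
    if partial_eta_sq >= 0.06:
        return "medium"
    if partial_eta_sq >= 0.01:
        return "small"
    return "negligible"
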