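"""Frequentist track: least-squares analysis of fixed effects with a random
sire term, Henderson Method III variance components, and paternal half-sib
genetic parameters.

The model is y = Xβ + Z s + e with s the sire effect.  Fixed effects are
tested by partial F-tests against the residual of the full model; sire and
residual (co)variance components come from Method III quadratic forms, and
heritability is the paternal half-sib estimator h² = 4σ²_s/(σ²_s + σ²_e) with
Swiger's large-sample standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model_design import DesignInfo

__all__ = [
    "LSMLFit",
    "HalfSibEstimate",
    "fit_fixed_model",
    "henderson3_components",
    "phs_heritability",
    "phs_correlations",
]


def significance_stars(p: float) -> str:
    """Significance code: '***' p<0.01, '**' p<0.05, '*' otherwise (ns)."""
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    return "*"


@dataclass
class LSMLFit:
    """Least-squares means, effect tests and variance components for one trait."""

    ls_means: dict            # factor -> {level: (mean, se)}
    f_tests: dict             # term -> (F, df_num, df_den, p, stars)
    covariate: dict | None    # {"estimate","se","ci_low","ci_high","p"} or None
    sigma2_e: float
    sigma2_s: float
    sigma2_s_raw: float       # before truncation at zero
    truncated: bool
    n_records: int
    n_sires: int


def _qr_basis(M: np.ndarray) -> np.ndarray:
    """Orthonormal basis for the column space of M (rank-revealing)."""
    if M.size == 0:
        return np.zeros((M.shape[0], 0))
    Q, Rm = np.linalg.qr(M, mode="reduced")
    keep = np.abs(np.diag(Rm)) > 1e-9 * max(1.0, np.abs(Rm).max())
    return Q[:, keep]


def _sse(y: np.ndarray, Q: np.ndarray) -> float:
    r = y - Q @ (Q.T @ y)
    return float(r @ r)


def fit_fixed_model(design: DesignInfo, sire_index: np.ndarray | None = None) -> LSMLFit:
    """Fit the fixed model (optionally with sire as a tested term) by least squares.

    Returns population-marginal least-squares means per fixed-factor level
    (covariate held at its mean, other factors averaged with equal weight),
    a partial F-test per term against the full-model residual, and — when a
    sire grouping is supplied — Method III sire/residual components.
    """
    y = design.y[:, 0] if design.y.ndim == 2 else design.y
    X = design.X
    n = len(y)

    terms: dict[str, np.ndarray] = {}
    for fac, idxs in design.factor_columns.items():
        terms[fac] = np.array(idxs, dtype=int)
    if design.covariate_col is not None:
        terms["covariate"] = np.array([design.covariate_col])

    Zs = None
    if sire_index is not None:
        n_sires = int(sire_index.max()) + 1
        Zs = np.zeros((n, n_sires))
        Zs[np.arange(n), sire_index] = 1.0

    W = X if Zs is None else np.column_stack([X, Zs])
    Qw = _qr_basis(W)
    rank_w = Qw.shape[1]
    sse_full = _sse(y, Qw)
    df_resid = n - rank_w
    if df_resid <= 0:
        raise ValueError("model is saturated: no residual degrees of freedom")
    mse = sse_full / df_resid

    beta, *_ = np.linalg.lstsq(X if Zs is None else W, y, rcond=None)
    XtXinv = np.linalg.pinv(W.T @ W)

    f_tests: dict = {}
    for name, idxs in terms.items():
        keep = np.setdiff1d(np.arange(W.shape[1]), idxs)
        Qr = _qr_basis(W[:, keep])
        df_num = rank_w - Qr.shape[1]
        if df_num == 0:
            f_tests[name] = (np.nan, 0, df_resid, np.nan, "*")
            continue
        F = ((_sse(y, Qr) - sse_full) / df_num) / mse
        p = float(stats.f.sf(F, df_num, df_resid))
        f_tests[name] = (float(F), df_num, df_resid, p, significance_stars(p))
    if Zs is not None:
        cols = np.arange(X.shape[1], W.shape[1])
        Qr = _qr_basis(np.delete(W, cols, axis=1))
        df_num = rank_w - Qr.shape[1]
        F = ((_sse(y, Qr) - sse_full) / max(df_num, 1)) / mse
        p = float(stats.f.sf(F, max(df_num, 1), df_resid))
        f_tests["sire"] = (float(F), df_num, df_resid, p, significance_stars(p))

    # population-marginal (least-squares) means: equal weight across the other
    # factors' levels, covariate at its mean (0 after centring), sire averaged.
    ls_means: dict = {}
    for fac, levels in design.factor_levels.items():
        per_level = {}
        for lv in levels:
            L = np.zeros(W.shape[1])
            L[0] = 1.0
            for f2, levels2 in design.factor_levels.items():
                idxs2 = design.factor_columns[f2]
                if f2 == fac:
                    if lv != levels2[-1]:
                        L[idxs2[levels2.index(lv)]] = 1.0
                else:
                    for j, lv2 in enumerate(levels2[:-1]):
                        L[idxs2[j]] = 1.0 / len(levels2)
            if Zs is not None:
                L[X.shape[1]:] = 1.0 / Zs.shape[1]
            est = float(L @ beta)
            se = float(np.sqrt(max(L @ XtXinv @ L, 0.0) * mse))
            per_level[lv] = (est, se)
        ls_means[fac] = per_level

    covariate = None
    if design.covariate_col is not None:
        j = design.covariate_col
        b = float(beta[j])
        se_b = float(np.sqrt(XtXinv[j, j] * mse))
        tcrit = stats.t.ppf(0.975, df_resid)
        tstat = b / se_b if se_b > 0 else np.inf
        covariate = {
            "estimate": b,
            "se": se_b,
            "ci_low": b - tcrit * se_b,
            "ci_high": b + tcrit * se_b,
            "p": float(2 * stats.t.sf(abs(tstat), df_resid)),
        }

    sigma2_s_raw = sigma2_s = 0.0
    truncated = False
    n_sires = 0
    if Zs is not None:
        comps = henderson3_components(y[:, None], X, sire_index)
        sigma2_s_raw = comps["sigma2_s_raw"][0, 0]
        sigma2_s = comps["sigma2_s"][0, 0]
        truncated = bool(comps["truncated"])
        n_sires = Zs.shape[1]

    return LSMLFit(
        ls_means=ls_means,
        f_tests=f_tests,
        covariate=covariate,
        sigma2_e=mse,
        sigma2_s=sigma2_s,
        sigma2_s_raw=sigma2_s_raw,
        truncated=truncated,
        n_records=n,
        n_sires=n_sires,
    )


def henderson3_components(
    Y: np.ndarray, X: np.ndarray, sire_index: np.ndarray
) -> dict:
    """Henderson Method III sire and residual (co)variance components.

    ``Y`` is (n, t) — with t > 1 the cross-products give sire/residual
    covariances between traits on the common records.  Uses the reduction
    R(sire | fixed) = y'(P_W − P_X)y with E = df·σ²_e + c·σ²_s, where
    c = tr(Z'(P_W − P_X)Z), computed through QR bases rather than explicit
    projections.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == len(sire_index) and Y.ndim == 2 and Y.shape[1] > Y.shape[0]:
        Y = Y.T
    n, t = Y.shape
    sires, sire_index = np.unique(sire_index, return_inverse=True)
    s = len(sires)
    if s < 2:
        raise ValueError("Method III needs at least 2 sires")
    Z = np.zeros((n, s))
    Z[np.arange(n), sire_index] = 1.0
    W = np.column_stack([X, Z])
    Qx = _qr_basis(X)
    Qw = _qr_basis(W)
    rank_x, rank_w = Qx.shape[1], Qw.shape[1]
    df_red = rank_w - rank_x
    df_resid = n - rank_w
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")

    # c = tr(Z'P_W Z) − tr(Z'P_X Z)
    QwZ = Qw.T @ Z
    QxZ = Qx.T @ Z
    c = float(np.sum(QwZ * QwZ) - np.sum(QxZ * QxZ))

    QwY = Qw.T @ Y
    QxY = Qx.T @ Y
    resid_cp = Y.T @ Y - QwY.T @ QwY          # Y'(I−P_W)Y
    red_cp = QwY.T @ QwY - QxY.T @ QxY        # Y'(P_W−P_X)Y

    Se = resid_cp / df_resid
    Ss_raw = (red_cp - df_red * Se) / c
    diag = np.diag(Ss_raw).copy()
    truncated = bool((diag < 0).any())
    diag_t = np.maximum(diag, 0.0)
    Ss = Ss_raw.copy()
    np.fill_diagonal(Ss, diag_t)

    counts = np.bincount(sire_index, minlength=s).astype(float)
    k_eff = (n - float(counts @ counts) / n) / (s - 1)

    return {
        "sigma2_s": Ss,
        "sigma2_s_raw": Ss_raw,
        "sigma2_e": Se,
        "truncated": truncated,
        "n": n,
        "n_sires": s,
        "k_eff": k_eff,
        "df_reduction": df_red,
        "trace_coefficient": c,
    }


@dataclass
class HalfSibEstimate:
    """Paternal half-sib heritability with Swiger's large-sample SE."""

    h2: float
    h2_raw: float             # before clipping to [0, 1]
    se: float
    t_intraclass: float
    k_eff: float
    clipped: bool = False


def phs_heritability(
    sigma2_s: float, sigma2_e: float, k_eff: float, n_sires: int, n_records: int
) -> HalfSibEstimate:
    """h² = 4σ²_s/(σ²_s+σ²_e); SE(h²) = 4·SE(t) by Swiger's formula.

    SE(t)² = 2(N−1)(1−t)²[1+(k−1)t]² / [k²(N−s)(s−1)] with N records, s sires
    and effective family size k.
    """
    if sigma2_s < 0:
        raise ValueError("sire variance must be non-negative")
    tot = sigma2_s + sigma2_e
    if tot <= 0:
        raise ValueError("total variance must be positive")
    t = sigma2_s / tot
    h2_raw = 4.0 * t
    N, s, k = n_records, n_sires, k_eff
    var_t = (
        2.0 * (N - 1) * (1 - t) ** 2 * (1 + (k - 1) * t) ** 2
        / (k**2 * (N - s) * (s - 1))
    )
    se = 4.0 * np.sqrt(max(var_t, 0.0))
    h2 = min(max(h2_raw, 0.0), 1.0)
    return HalfSibEstimate(
        h2=h2, h2_raw=h2_raw, se=float(se), t_intraclass=t, k_eff=k,
        clipped=h2 != h2_raw,
    )


def phs_correlations(components: dict) -> dict:
    """Genetic and phenotypic correlation matrices from sire-model components.

    ``components`` maps an ordered trait tuple to the dict returned by
    :func:`henderson3_components` for that pair (or one multi-trait call).
    Accepts equally a single multi-trait component dict plus a trait list via
    ``{"traits": [...], "components": comp}``.  r_g uses sire (co)variances,
    r_p the sire+residual sums; cells with a non-positive sire variance are NA
    with a reason, as happens for traits whose Method III estimate truncates.
    """
    traits = components["traits"]
    comp = components["components"]
    Ss, Se = comp["sigma2_s"], comp["sigma2_e"]
    t = len(traits)
    r_g = np.full((t, t), np.nan)
    r_p = np.full((t, t), np.nan)
    notes: dict = {}
    Sp = Ss + Se
    for i in range(t):
        for j in range(t):
            if i == j:
                r_g[i, j] = r_p[i, j] = 1.0
                continue
            if Ss[i, i] <= 0 or Ss[j, j] <= 0:
                notes[(traits[i], traits[j])] = "zero sire variance"
                continue
            rg = Ss[i, j] / np.sqrt(Ss[i, i] * Ss[j, j])
            rp = Sp[i, j] / np.sqrt(Sp[i, i] * Sp[j, j])
            if abs(rg) > 1:
                notes[(traits[i], traits[j])] = f"r_g out of range ({rg:.3f}), clipped"
                rg = float(np.clip(rg, -1, 1))
            r_g[i, j] = rg
            r_p[i, j] = float(np.clip(rp, -1, 1))
    return {"traits": traits, "r_g": r_g, "r_p": r_p, "notes": notes}


def robertson_se_rg(r_g, h2_x: HalfSibEstimate, h2_y: HalfSibEstimate) -> float:
    """Robertson's approximate SE of a sire-component genetic correlation."""
    if h2_x.h2 <= 0 or h2_y.h2 <= 0:
        return float("nan")
    return float(
        (1 - r_g**2) / np.sqrt(2.0)
        * np.sqrt(h2_x.se * h2_y.se / (h2_x.h2 * h2_y.h2))
    )
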