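"""Posterior summaries and MCMC diagnostics for stored Gibbs chains.

For each scalar parameter chain this module reports the posterior mean, mode
(Freedman–Diaconis histogram modal-bin midpoint), median, SD, 95% highest
posterior density interval (shortest contiguous window of order statistics),
effective sample size (Geyer initial-monotone-sequence truncation of the
autocorrelation sum), the Monte-Carlo error MCE = SD/√ESS, and the Geweke
stationarity z (first 10% vs last 50%, batch-means variances).

Derived genetic parameters are computed draw-by-draw from the stored (G0, R0)
matrices: heritability h² = σ²_g/(σ²_g + σ²_e), genetic correlations from G0,
phenotypic correlations from P0 = G0 + R0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PosteriorSummary",
    "summarize_chain",
    "hpd_interval",
    "effective_sample_size",
    "geweke_z",
    "monte_carlo_error",
    "derive_parameters",
]


@dataclass
class PosteriorSummary:
    """One scalar parameter's posterior summary row."""

    mean: float
    mode: float
    median: float
    sd: float
    hpd_lower: float
    hpd_upper: float
    ess: float
    mce: float
    geweke_z: float
    n: int = 0

    def as_row(self) -> dict:
        return {
            "mean": self.mean, "mode": self.mode, "median": self.median,
            "sd": self.sd, "hpd_lower": self.hpd_lower, "hpd_upper": self.hpd_upper,
            "ess": self.ess, "mce": self.mce, "geweke_z": self.geweke_z,
        }


def hpd_interval(samples, coverage: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval of order statistics covering ≥ the target.

    Among all windows of ⌈coverage·N⌉ consecutive sorted samples the shortest
    is returned; ties go to the lowest lower bound.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    N = x.size
    if not 0.0 < coverage < 1.0:
        raise ValueError("coverage must be in (0, 1)")
    m = int(np.ceil(coverage * N))
    if m < 2:
        raise ValueError("too few samples for the requested coverage")
    widths = x[m - 1:] - x[: N - m + 1]
    i = int(np.argmin(widths))  # argmin takes the first minimum: lowest lower bound
    return float(x[i]), float(x[i + m - 1])


def _autocorrelation(x: np.ndarray) -> np.ndarray:
    n = x.size
    xc = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[:n].real / n
    if acov[0] <= 0:
        return np.zeros(n)
    return acov / acov[0]


def effective_sample_size(samples) -> float:
    """ESS = N/(1 + 2Σρ_k) with Geyer's initial-monotone-sequence truncation.

    The autocorrelation sum is accumulated over lag pairs Γ_m = ρ_{2m} +
    ρ_{2m+1}, stopped at the first non-positive pair and forced monotone
    non-increasing; the result is capped at N.  A zero-variance chain has no
    defined autocorrelation; N is returned with a warning.
    """
    x = np.asarray(samples, dtype=float)
    N = x.size
    if N < 10:
        raise ValueError("need at least 10 samples")
    if np.var(x) == 0:
        warnings.warn("zero-variance chain: ESS reported as N", stacklevel=2)
        return float(N)
    rho = _autocorrelation(x)
    tau = rho[0]  # = 1, lag-0 term of 1 + 2Σρ: handled via pair sums below
    # pair sums Γ_m = ρ_{2m} + ρ_{2m+1}, m = 0, 1, ...
    gamma_prev = np.inf
    s = 0.0
    m = 0
    while 2 * m + 1 < N:
        g = rho[2 * m] + rho[2 * m + 1]
        if g <= 0:
            break
        g = min(g, gamma_prev)
        gamma_prev = g
        s += g
        m += 1
    tau = max(2.0 * s - 1.0, 1e-12)
    return float(min(N / tau, N))


def monte_carlo_error(sd: float, ess: float) -> float:
    """Monte-Carlo error of the posterior mean, MCE = SD/√ESS."""
    if ess <= 0:
        raise ValueError("effective sample size must be positive")
    return float(sd / np.sqrt(ess))


def _window_var_of_mean(x: np.ndarray) -> float:
    """Var(mean of x) allowing autocorrelation: s²/ESS with the same Geyer
    initial-sequence truncation used for the effective sample size.

    Sharing the estimator keeps the Geweke z close to its nominal N(0,1)
    calibration on the short early window, where batch-means variants are
    noticeably anticonservative.
    """
    v = float(np.var(x, ddof=1))
    if v == 0:
        return 0.0
    return v / effective_sample_size(x)


def geweke_z(samples, frac_a: float = 0.10, frac_b: float = 0.50) -> float:
    """Geweke stationarity z: first ``frac_a`` vs last ``frac_b`` of the chain.

    z = (mean_A − mean_B)/√(V̂_A + V̂_B) with autocorrelation-consistent
    variances of the two window means (initial-sequence truncation).
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    na = int(np.floor(frac_a * n))
    nb = int(np.floor(frac_b * n))
    if na < 10 or nb < 10:
        raise ValueError("Geweke windows must each contain at least 10 samples")
    a, b = x[:na], x[n - nb:]
    va = _window_var_of_mean(a)
    vb = _window_var_of_mean(b)
    denom = np.sqrt(va + vb)
    if denom == 0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)


def _fd_mode(x: np.ndarray) -> float:
    """Midpoint of the modal bin of a Freedman–Diaconis histogram."""
    n = x.size
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    if iqr <= 0 or n < 4:
        return float(np.median(x))
    width = 2.0 * iqr / n ** (1.0 / 3.0)
    nbins = max(int(np.ceil((x.max() - x.min()) / width)), 1)
    counts, edges = np.histogram(x, bins=nbins)
    k = int(np.argmax(counts))
    return float(0.5 * (edges[k] + edges[k + 1]))


def summarize_chain(samples, coverage: float = 0.95) -> PosteriorSummary:
    """Full posterior summary of one scalar chain (Table-style row)."""
    x = np.asarray(samples, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 stored samples")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        c = float(x[0])
        return PosteriorSummary(
            mean=c, mode=c, median=c, sd=0.0, hpd_lower=c, hpd_upper=c,
            ess=float(x.size), mce=0.0, geweke_z=0.0, n=x.size,
        )
    lo, hi = hpd_interval(x, coverage)
    ess = effective_sample_size(x)
    try:
        gz = geweke_z(x)
    except ValueError:  # chain too short for the 10% window
        gz = float("nan")
    return PosteriorSummary(
        mean=float(x.mean()),
        mode=_fd_mode(x),
        median=float(np.median(x)),
        sd=sd,
        hpd_lower=lo,
        hpd_upper=hi,
        ess=ess,
        mce=monte_carlo_error(sd, ess),
        geweke_z=gz,
        n=x.size,
    )


def derive_parameters(samples, summarize: bool = True) -> dict:
    """Per-draw genetic parameters from stored (G0, R0) and their summaries.

    Returns a dict with per-trait chains ``sigma2_g``, ``sigma2_e``,
    ``sigma2_p`` (= σ²_g + σ²_e exactly, per draw), ``h2``, and per-pair
    chains ``r_g`` / ``r_p``; ``summaries`` maps parameter names to
    :class:`PosteriorSummary` rows.  Draws whose G0 or P0 is not positive
    definite are excluded (count in ``n_excluded``).
    """
    G, R = samples.G0, samples.R0
    t = G.shape[1]
    traits = samples.traits or tuple(f"trait{i + 1}" for i in range(t))

    ok = np.ones(G.shape[0], dtype=bool)
    for i, (g, r) in enumerate(zip(G, R)):
        eg = np.linalg.eigvalsh(g)
        ep = np.linalg.eigvalsh(g + r)
        if eg.min() <= 0 or ep.min() <= 0:
            ok[i] = False
    Gk, Rk = G[ok], R[ok]
    Pk = Gk + Rk

    chains: dict[str, np.ndarray] = {}
    for i, tr in enumerate(traits):
        chains[f"sigma2_g[{tr}]"] = Gk[:, i, i]
        chains[f"sigma2_e[{tr}]"] = Rk[:, i, i]
        chains[f"sigma2_p[{tr}]"] = Pk[:, i, i]
        chains[f"h2[{tr}]"] = Gk[:, i, i] / Pk[:, i, i]
    for i in range(t):
        for j in range(i + 1, t):
            pair = f"{traits[i]},{traits[j]}"
            chains[f"r_g[{pair}]"] = Gk[:, i, j] / np.sqrt(Gk[:, i, i] * Gk[:, j, j])
            chains[f"r_p[{pair}]"] = Pk[:, i, j] / np.sqrt(Pk[:, i, i] * Pk[:, j, j])

    out = {
        "traits": traits,
        "chains": chains,
        "n_excluded": int((~ok).sum()),
    }
    if summarize:
        out["summaries"] = {k: summarize_chain(v) for k, v in chains.items()}
    return out
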