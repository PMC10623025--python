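"""Bayesian track: multi-trait Gibbs sampler for the animal model.

The model is y = Xβ + Zu + e with u ~ N(0, G0 ⊗ A) over all q pedigree animals
and record residuals e ~ N(0, R0) independent across records (t traits per
record, complete cases only).  One Gibbs cycle samples

  1. every fixed-effect coefficient from its scalar normal full conditional
     (Gauss–Seidel over the mixed-model equations),
  2. every animal's t-vector of breeding values from its multivariate normal
     full conditional, animal by animal, using the sparse rows of A⁻¹,
  3. G0 from inverse-Wishart(S_g + U'A⁻¹U, ν_g + q),
  4. R0 from inverse-Wishart(S_r + E'E, ν_r + n).

Every ``thinning``-th draw after ``burn_in`` is stored.  All randomness flows
from a single seed, so a chain is bit-reproducible.

The location sweep is compiled with numba when available; a NumPy fallback
with identical arithmetic (and therefore identical draws for a given seed) is
used otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, stats

__all__ = [
    "ChainConfig",
    "PriorSpec",
    "CovarianceSamples",
    "GibbsDivergenceError",
    "sample_inverse_wishart",
    "run_chain",
]


class GibbsDivergenceError(RuntimeError):
    """Chain exceeded the overflow guard or produced a non-PD conditional."""


@dataclass(frozen=True)
class ChainConfig:
    """Gibbs chain control: total length, burn-in, thinning interval, seed."""

    total_iterations: int = 30_000
    burn_in: int = 1_000
    thinning: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.total_iterations:
            raise ValueError("burn_in must be smaller than total_iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")

    @property
    def n_stored(self) -> int:
        """Number of stored draws: floor((total − burn_in)/thinning)."""
        return (self.total_iterations - self.burn_in) // self.thinning


@dataclass
class PriorSpec:
    """Inverse-Wishart priors and starting values for G0 and R0.

    ``flat=True`` uses the improper flat prior (ν = −(t+1), zero scale), in
    which case the conditionals reduce to inverse-Wishart(U'A⁻¹U, q) and
    (E'E, n); a warning notes the posterior-propriety caveat.
    """

    S_g: np.ndarray | None = None
    S_r: np.ndarray | None = None
    nu_g: float | None = None
    nu_r: float | None = None
    G0_start: np.ndarray | None = None
    R0_start: np.ndarray | None = None
    flat: bool = False

    @classmethod
    def from_phenotypes(cls, Y: np.ndarray) -> "PriorSpec":
        """Weakly informative default: ν = t+2, prior mean = half the observed
        phenotypic (co)variance diagonal; starts G0 = R0 = half phenotypic cov."""
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        if Y.shape[0] < Y.shape[1]:
            Y = Y.T
        t = Y.shape[1]
        P = np.cov(Y, rowvar=False).reshape(t, t)
        half = 0.5 * P
        nu = t + 2.0
        scale = (nu - t - 1.0) * np.diag(np.diag(half))
        return cls(
            S_g=scale.copy(), S_r=scale.copy(), nu_g=nu, nu_r=nu,
            G0_start=half.copy(), R0_start=half.copy(),
        )


@dataclass
class CovarianceSamples:
    """Stored Gibbs draws of (G0, R0), plus chain metadata."""

    G0: np.ndarray            # (n_stored, t, t)
    R0: np.ndarray
    iterations: np.ndarray    # 1-based iteration index of each stored draw
    traits: tuple[str, ...] = ()
    config: ChainConfig | None = None
    location_mean: np.ndarray | None = None  # running post-burn-in mean of [β; u]

    @property
    def n_stored(self) -> int:
        return self.G0.shape[0]


def sample_inverse_wishart(scale: np.ndarray, dof: float, rng) -> np.ndarray:
    """One draw from inverse-Wishart(scale, dof); mean scale/(dof − t − 1).

    Delegates to scipy's parameterisation, which matches the conjugate
    conditionals used here.  Raises on a non-PD scale.
    """
    scale = np.atleast_2d(np.asarray(scale, dtype=float))
    t = scale.shape[0]
    if dof <= t - 1:
        raise ValueError(f"dof must exceed t-1={t - 1}")
    try:
        np.linalg.cholesky(scale)
    except np.linalg.LinAlgError as exc:
        raise ValueError("inverse-Wishart scale must be positive definite") from exc
    draw = stats.invwishart.rvs(df=dof, scale=scale, random_state=rng)
    return np.atleast_2d(draw)


# ---------------------------------------------------------------------------
# location sweep (single-site Gauss–Seidel), numba-compiled when available


def _sweep_py(
    resid, Xc, sxx, mask, beta, u, rec_animal,
    a_indptr, a_indices, a_data,
    an_rec_indptr, an_rec_indices,
    G0inv, R0inv, z_beta, z_u,
):
    n, t = resid.shape
    p = Xc.shape[1]
    q = u.shape[0]
    zb = 0
    for tt in range(t):
        for k in range(p):
            if not mask[tt, k]:
                continue
            lam = R0inv[tt, tt] * sxx[k]
            num = 0.0
            for j in range(n):
                xjk = Xc[j, k]
                if xjk != 0.0:
                    acc = 0.0
                    for t2 in range(t):
                        acc += R0inv[tt, t2] * resid[j, t2]
                    num += xjk * acc
            new = beta[tt, k] + num / lam + z_beta[zb] / np.sqrt(lam)
            zb += 1
            delta = new - beta[tt, k]
            beta[tt, k] = new
            if delta != 0.0:
                for j in range(n):
                    resid[j, tt] -= Xc[j, k] * delta
    for i in range(q):
        prec = np.zeros((t, t))
        rhs = np.zeros(t)
        aii = 0.0
        for ptr in range(a_indptr[i], a_indptr[i + 1]):
            jj = a_indices[ptr]
            aij = a_data[ptr]
            if jj == i:
                aii = aij
            else:
                for t1 in range(t):
                    acc = 0.0
                    for t2 in range(t):
                        acc += G0inv[t1, t2] * u[jj, t2]
                    rhs[t1] -= aij * acc
        for t1 in range(t):
            for t2 in range(t):
                prec[t1, t2] = aii * G0inv[t1, t2]
        for ptr in range(an_rec_indptr[i], an_rec_indptr[i + 1]):
            j = an_rec_indices[ptr]
            for t1 in range(t):
                acc = 0.0
                for t2 in range(t):
                    acc += R0inv[t1, t2] * (resid[j, t2] + u[i, t2])
                rhs[t1] += acc
                for t2 in range(t):
                    prec[t1, t2] += R0inv[t1, t2]
        L = np.linalg.cholesky(prec)
        # mean = prec^{-1} rhs via two triangular solves
        w = np.zeros(t)
        for t1 in range(t):
            acc = rhs[t1]
            for t2 in range(t1):
                acc -= L[t1, t2] * w[t2]
            w[t1] = acc / L[t1, t1]
        mean = np.zeros(t)
        for t1 in range(t - 1, -1, -1):
            acc = w[t1]
            for t2 in range(t1 + 1, t):
                acc -= L[t2, t1] * mean[t2]
            mean[t1] = acc / L[t1, t1]
        # draw: mean + L^{-T} z
        draw = np.zeros(t)
        for t1 in range(t - 1, -1, -1):
            acc = z_u[i, t1]
            for t2 in range(t1 + 1, t):
                acc -= L[t2, t1] * draw[t2]
            draw[t1] = acc / L[t1, t1]
        for t1 in range(t):
            new = mean[t1] + draw[t1]
            delta = new - u[i, t1]
            u[i, t1] = new
            if delta != 0.0:
                for ptr in range(an_rec_indptr[i], an_rec_indptr[i + 1]):
                    resid[an_rec_indices[ptr], t1] -= delta


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _sweep = njit(cache=False)(_sweep_py)
except Exception:  # pragma: no cover
    _sweep = _sweep_py


def run_chain(
    y: np.ndarray,
    X: np.ndarray,
    animal_index: np.ndarray,
    A_inverse: sparse.spmatrix,
    prior: PriorSpec | None = None,
    config: ChainConfig | None = None,
    covariate_mask: np.ndarray | None = None,
    traits: tuple[str, ...] = (),
    fix_variances: bool = False,
    overflow_factor: float = 1e12,
) -> CovarianceSamples:
    """Run the multi-trait Gibbs sampler and return stored (G0, R0) draws.

    Parameters
    ----------
    y : (n, t) complete-case responses.
    X : (n, p) common fixed design; ``covariate_mask`` (t, p) marks which
        columns each trait uses (a response excludes its own covariate).
    animal_index : (n,) 0-based pedigree code of each record's animal.
    A_inverse : sparse (q, q) inverse numerator relationship matrix.
    fix_variances : hold G0, R0 at their starting values (the location draws
        then target the mixed-model-equation solution; used for validation).
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.shape[0] < y.shape[1]:
        y = y.T
    n, t = y.shape
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    config = config or ChainConfig()
    prior = prior or PriorSpec.from_phenotypes(y)
    if covariate_mask is None:
        covariate_mask = np.ones((t, p), dtype=bool)
    else:
        covariate_mask = np.asarray(covariate_mask, dtype=bool)

    A_inv = sparse.csr_matrix(A_inverse)
    q = A_inv.shape[0]
    if animal_index.max() >= q:
        raise ValueError("animal_index refers beyond the pedigree")

    if prior.flat:
        warnings.warn(
            "flat covariance prior: posterior propriety is not guaranteed for "
            "small data sets", stacklevel=2,
        )
        S_g = np.zeros((t, t))
        S_r = np.zeros((t, t))
        nu_g = nu_r = -(t + 1.0)
    else:
        S_g, S_r, nu_g, nu_r = prior.S_g, prior.S_r, prior.nu_g, prior.nu_r
        if S_g is None:
            default = PriorSpec.from_phenotypes(y)
            S_g, S_r = default.S_g, default.S_r
            nu_g, nu_r = default.nu_g, default.nu_r

    default_start = PriorSpec.from_phenotypes(y)
    G0 = np.array(prior.G0_start if prior.G0_start is not None else default_start.G0_start)
    R0 = np.array(prior.R0_start if prior.R0_start is not None else default_start.R0_start)
    G0 = np.atleast_2d(G0)
    R0 = np.atleast_2d(R0)
    guard = overflow_factor * max(G0.max(), R0.max())

    rng = np.random.default_rng(config.seed)

    # records per animal, CSR-style
    order = np.argsort(animal_index, kind="stable")
    an_rec_indices = order.astype(np.int64)
    an_rec_indptr = np.searchsorted(
        animal_index[order], np.arange(q + 1), side="left"
    ).astype(np.int64)

    beta = np.zeros((t, p))
    beta[:, 0] = y.mean(axis=0) if covariate_mask[:, 0].all() else 0.0
    u = np.zeros((q, t))
    resid = y - X @ beta.T
    sxx = np.einsum("np,np->p", X, X)

    n_store = config.n_stored
    G_store = np.empty((n_store, t, t))
    R_store = np.empty((n_store, t, t))
    it_store = np.empty(n_store, dtype=np.int64)
    loc_sum = np.zeros(t * p + q * t)
    loc_count = 0

    a_indptr = A_inv.indptr.astype(np.int64)
    a_indices = A_inv.indices.astype(np.int64)
    a_data = A_inv.data.astype(np.float64)
    mask8 = covariate_mask.astype(np.uint8)

    stored = 0
    for it in range(1, config.total_iterations + 1):
        G0inv = np.linalg.inv(G0)
        R0inv = np.linalg.inv(R0)
        z_beta = rng.standard_normal(int(mask8.sum()))
        z_u = rng.standard_normal((q, t))
        try:
            _sweep(
                resid, X, sxx, mask8.astype(np.bool_), beta, u, animal_index,
                a_indptr, a_indices, a_data,
                an_rec_indptr, an_rec_indices,
                G0inv, R0inv, z_beta, z_u,
            )
        except np.linalg.LinAlgError as exc:
            raise GibbsDivergenceError(
                f"non-PD conditional covariance at iteration {it}"
            ) from exc

        if not fix_variances:
            UAU = u.T @ (A_inv @ u)
            G0 = sample_inverse_wishart(S_g + UAU, nu_g + q, rng)
            EE = resid.T @ resid
            R0 = sample_inverse_wishart(S_r + EE, nu_r + n, rng)
            if max(G0.max(), R0.max()) > guard:
                raise GibbsDivergenceError(
                    f"variance draw exceeded overflow guard at iteration {it}"
                )

        if it > config.burn_in:
            # trait-major, matching the MME solution layout [β_1..β_t; u_1..u_t]
            loc_sum += np.concatenate([beta.ravel(), u.T.ravel()])
            loc_count += 1
            if (it - config.burn_in) % config.thinning == 0 and stored < n_store:
                G_store[stored] = G0
                R_store[stored] = R0
                it_store[stored] = it
                stored += 1

    return CovarianceSamples(
        G0=G_store[:stored],
        R0=R_store[:stored],
        iterations=it_store[:stored],
        traits=tuple(traits),
        config=config,
        location_mean=loc_sum / max(loc_count, 1),
    )
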