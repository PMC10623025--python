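"""BLUP sire evaluation and rank comparison between the two estimation tracks.

EBVs are predicted from Henderson's mixed-model equations

    [ X'R⁻¹X      X'R⁻¹Z            ] [β̂]   [X'R⁻¹y]
    [ Z'R⁻¹X      Z'R⁻¹Z + A⁻¹⊗G⁻¹ ] [û] = [Z'R⁻¹y]

under two routes: a sire model with the frequentist half-sib variance ratio
λ = (4 − h²)/h² (EBV = 2 × sire solution), and an animal model with the
posterior-mean G0/R0 from the Gibbs track (EBV = animal solution).  Sires
with more than three progeny are ranked per trait and the two rankings are
compared by a Spearman rank correlation with the t-test
t = r√((n−2)/(1−r²)), df = n − 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.linalg import LinearOperator, cg

__all__ = [
    "MMESolution",
    "RankComparison",
    "solve_mme_blup",
    "evaluate_sires",
    "spearman_t",
    "t_from_r",
]

MIN_PROGENY = 4  # "more than three progenies"


@dataclass
class MMESolution:
    """Solutions of the mixed-model equations for one trait set."""

    beta: np.ndarray          # (t, p)
    u: np.ndarray             # (q, t) random-effect solutions
    traits: tuple[str, ...]
    model: str                # "animal" or "sire"

    def ebv(self) -> np.ndarray:
        """Estimated breeding values: 2× solution for a sire model, else û."""
        return 2.0 * self.u if self.model == "sire" else self.u


def _solve_mme_system(C, rhs, method: str, tol: float = 1e-10, maxiter: int = 20000):
    if method == "direct":
        if sparse.issparse(C):
            C = C.toarray()
        return np.linalg.solve(C, rhs)
    # Jacobi-preconditioned conjugate gradient
    Cs = sparse.csr_matrix(C)
    d = Cs.diagonal()
    d[d == 0] = 1.0
    M = LinearOperator(Cs.shape, matvec=lambda v: v / d)
    sol = np.empty_like(rhs)
    for k in range(rhs.shape[1] if rhs.ndim == 2 else 1):
        b = rhs[:, k] if rhs.ndim == 2 else rhs
        x, info = cg(Cs, b, M=M, rtol=tol, atol=0.0, maxiter=maxiter)
        if info != 0:
            raise RuntimeError(f"conjugate gradient failed to converge (info={info})")
        if rhs.ndim == 2:
            sol[:, k] = x
        else:
            sol = x
    return sol


def solve_mme_blup(
    y: np.ndarray,
    X: np.ndarray,
    random_index: np.ndarray,
    G0: np.ndarray,
    R0: np.ndarray,
    A_inverse: sparse.spmatrix | None = None,
    model: str = "animal",
    traits: tuple[str, ...] = (),
    method: str = "auto",
) -> MMESolution:
    """Solve Henderson's MME for a (possibly multi-trait) animal or sire model.

    ``A_inverse`` is the pedigree A⁻¹ for the animal model; for the sire model
    pass ``None`` and unrelated sires are assumed (identity covariance).
    ``G0``/``R0`` are t×t (scalars accepted for t = 1).  ``method`` is
    ``"direct"`` (dense solve, default for q ≤ 2000), ``"pcg"`` or ``"auto"``.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.shape[0] < y.shape[1]:
        y = y.T
    n, t = y.shape
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    G0 = np.atleast_2d(np.asarray(G0, dtype=float))
    R0 = np.atleast_2d(np.asarray(R0, dtype=float))
    for name, M in (("G0", G0), ("R0", R0)):
        if np.linalg.eigvalsh(M).min() <= 0:
            raise ValueError(f"{name} must be positive definite")

    if A_inverse is None:
        q = int(random_index.max()) + 1
        A_inv = sparse.identity(q, format="csr")
    else:
        A_inv = sparse.csr_matrix(A_inverse)
        q = A_inv.shape[0]

    Z = sparse.csr_matrix(
        (np.ones(n), (np.arange(n), random_index)), shape=(n, q)
    )
    Rinv = np.linalg.inv(R0)
    Ginv = np.linalg.inv(G0)

    # trait-major ordering: [β_1..β_t ; u_1..u_t] with Kronecker structure
    XtX = X.T @ X
    XtZ = sparse.csr_matrix(X.T @ Z.toarray()) if q <= 5000 else (Z.T @ sparse.csr_matrix(X)).T
    ZtZ = (Z.T @ Z).tocsr()

    top_left = sparse.kron(sparse.csr_matrix(Rinv), sparse.csr_matrix(XtX))
    top_right = sparse.kron(sparse.csr_matrix(Rinv), XtZ)
    bottom_right = sparse.kron(sparse.csr_matrix(Rinv), ZtZ) + sparse.kron(
        sparse.csr_matrix(Ginv), A_inv
    )
    C = sparse.bmat(
        [[top_left, top_right], [top_right.T, bottom_right]], format="csr"
    )
    rhs = np.concatenate(
        [(X.T @ y @ Rinv).T.ravel(), np.asarray(Z.T @ y @ Rinv).T.ravel()]
    )

    if method == "auto":
        method = "direct" if q <= 2000 else "pcg"
    sol = _solve_mme_system(C, rhs, method)

    beta = sol[: t * p].reshape(t, p)
    u = sol[t * p:].reshape(t, q).T
    return MMESolution(beta=beta, u=u, traits=tuple(traits), model=model)


def evaluate_sires(
    ebv_by_animal: dict,
    progeny_counts: dict,
    min_progeny: int = MIN_PROGENY,
) -> pd.DataFrame:
    """Rank sires with enough progeny on their EBVs, one column set per trait.

    ``ebv_by_animal`` maps sire id -> EBV (scalar or per-trait array);
    ``progeny_counts`` maps sire id -> progeny count.  Rank 1 is the highest
    EBV; EBV ties break by sire id for determinism.
    """
    rows = []
    for sire, counts in progeny_counts.items():
        if counts >= min_progeny and sire in ebv_by_animal:
            rows.append((sire, counts, np.atleast_1d(ebv_by_animal[sire])))
    if not rows:
        raise ValueError(f"no sires with >= {min_progeny} progeny")
    rows.sort(key=lambda r: str(r[0]))
    sires = [r[0] for r in rows]
    counts = [r[1] for r in rows]
    ebvs = np.vstack([r[2] for r in rows])
    df = pd.DataFrame({"sire": sires, "progeny": counts})
    for j in range(ebvs.shape[1]):
        col = f"ebv{j + 1}" if ebvs.shape[1] > 1 else "ebv"
        df[col] = ebvs[:, j]
        order = np.lexsort((df["sire"].astype(str), -df[col]))
        rank = np.empty(len(df), dtype=int)
        rank[order] = np.arange(1, len(df) + 1)
        df[col.replace("ebv", "rank")] = rank
    return df


def t_from_r(r: float, n: int) -> float:
    """t statistic of a Spearman correlation: t = r·√((n−2)/(1−r²))."""
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if abs(r) >= 1.0:
        return float("inf") if r > 0 else float("-inf")
    return float(r * np.sqrt((n - 2) / (1.0 - r * r)))


@dataclass
class RankComparison:
    """Spearman rank-correlation comparison of two sire rankings."""

    r: float
    t: float
    df: int
    p: float
    significant: bool
    verdict: str

    @classmethod
    def from_ranks(cls, ranks_a, ranks_b, alpha: float = 0.05) -> "RankComparison":
        a = np.asarray(ranks_a, dtype=float)
        b = np.asarray(ranks_b, dtype=float)
        if a.shape != b.shape:
            raise ValueError("rank vectors must have equal length")
        n = a.size
        if n < 3:
            raise ValueError("need at least 3 sires to compare rankings")
        r = float(stats.spearmanr(a, b).statistic)
        if 1.0 - abs(r) < 1e-12:  # clamp floating-point noise at perfect agreement
            r = 1.0 if r > 0 else -1.0
        t = t_from_r(r, n)
        if np.isinf(t):
            return cls(r=r, t=t, df=n - 2, p=0.0, significant=True,
                       verdict="Significant (perfect rank agreement)")
        p = float(2 * stats.t.sf(abs(t), n - 2))
        sig = p < alpha
        return cls(r=r, t=t, df=n - 2, p=p, significant=sig,
                   verdict="Significant" if sig else "Non-significant")


def spearman_t(ranks_a, ranks_b, alpha: float = 0.05) -> RankComparison:
    """Spearman r between two rankings with the t-test (df = n − 2)."""
    return RankComparison.from_ranks(ranks_a, ranks_b, alpha=alpha)
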