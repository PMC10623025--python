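"""Pedigree handling: renumbering, the numerator relationship matrix A, and A⁻¹.

The animal model places a random additive-genetic effect on every animal in the
pedigree, with covariance proportional to the numerator relationship matrix A
(diagonal 1 + F, F the inbreeding coefficient).  Everything downstream — the
mixed-model equations and the Gibbs full conditionals — consumes A⁻¹, which is
built directly from pedigree structure by Henderson's rules without ever
inverting A.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "PedigreeRecord",
    "RenumberedPedigree",
    "PedigreeError",
    "read_pedigree_csv",
    "renumber_pedigree",
    "build_relationship_matrix",
    "inbreeding_coefficients",
    "build_A_inverse",
]

_UNKNOWN = {"", "0", "NA", "na", "nan", None}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, sex conflicts...)."""


@dataclass(frozen=True)
class PedigreeRecord:
    """One animal with its (possibly unknown) sire and dam, by original id."""

    animal: str
    sire: str | None = None
    dam: str | None = None

    def __post_init__(self) -> None:
        if not self.animal:
            raise PedigreeError("animal identifier must be non-empty")
        if self.animal in (self.sire, self.dam):
            raise PedigreeError(f"animal {self.animal!r} listed as its own parent")


@dataclass
class RenumberedPedigree:
    """Pedigree recoded to consecutive integers 1..q, parents before offspring.

    ``sire`` / ``dam`` hold the parent code or 0 for an unknown parent.
    ``original_id[i]`` is the input identifier of the animal coded ``i + 1``.
    """

    sire: np.ndarray  # int, length q, 0 = unknown
    dam: np.ndarray
    original_id: list[str] = field(default_factory=list)

    @property
    def q(self) -> int:
        return len(self.sire)

    def code_of(self, original: str) -> int:
        return self.original_id.index(original) + 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "code": np.arange(1, self.q + 1),
                "animal": self.original_id,
                "sire": self.sire,
                "dam": self.dam,
            }
        )


def _clean(value) -> str | None:
    if value is None:
        return None
    s = str(value).strip()
    return None if s in _UNKNOWN else s


def read_pedigree_csv(path) -> list[PedigreeRecord]:
    """Read a pedigree CSV with header ``animal,sire,dam``; ``0``/empty = unknown."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"animal", "sire", "dam"}
    if not required.issubset(df.columns):
        raise PedigreeError(f"pedigree CSV must have columns {sorted(required)}")
    return [
        PedigreeRecord(_clean(r.animal), _clean(r.sire), _clean(r.dam))
        for r in df.itertuples(index=False)
    ]


def renumber_pedigree(records: list[PedigreeRecord]) -> RenumberedPedigree:
    """Assign consecutive codes 1..q with every parent coded before its offspring.

    Animals appearing only as parents are added as founders (unknown parents).
    Ties in the topological order are broken by first appearance in the input,
    so the output is deterministic for a fixed record order.  Raises
    :class:`PedigreeError` on a parentage cycle or an identifier used both as a
    sire and as a dam.
    """
    sire_ids: set[str] = set()
    dam_ids: set[str] = set()
    parents: dict[str, tuple[str | None, str | None]] = {}
    appearance: dict[str, int] = {}

    def note(ident: str) -> None:
        if ident not in appearance:
            appearance[ident] = len(appearance)

    for rec in records:
        if rec.animal in parents:
            raise PedigreeError(f"duplicate record for animal {rec.animal!r}")
        note(rec.animal)
        parents[rec.animal] = (rec.sire, rec.dam)
        if rec.sire is not None:
            note(rec.sire)
            sire_ids.add(rec.sire)
        if rec.dam is not None:
            note(rec.dam)
            dam_ids.add(rec.dam)

    both = sire_ids & dam_ids
    if both:
        raise PedigreeError(
            f"identifier(s) used as both sire and dam: {sorted(both)[:5]}"
        )

    # parent-only animals become founders
    for ident in appearance:
        parents.setdefault(ident, (None, None))

    # Kahn's algorithm; ready queue ordered by first appearance for determinism.
    children: dict[str, list[str]] = {i: [] for i in parents}
    indeg = {i: 0 for i in parents}
    for child, (s, d) in parents.items():
        for p in (s, d):
            if p is not None:
                children[p].append(child)
                indeg[child] += 1

    ready = sorted((i for i in parents if indeg[i] == 0), key=appearance.__getitem__)
    order: list[str] = []
    import heapq

    heap = [(appearance[i], i) for i in ready]
    heapq.heapify(heap)
    while heap:
        _, ident = heapq.heappop(heap)
        order.append(ident)
        for child in children[ident]:
            indeg[child] -= 1
            if indeg[child] == 0:
                heapq.heappush(heap, (appearance[child], child))

    if len(order) != len(parents):
        on_cycle = next(i for i in parents if indeg[i] > 0)
        raise PedigreeError(f"pedigree contains a cycle involving {on_cycle!r}")

    code = {ident: i + 1 for i, ident in enumerate(order)}
    q = len(order)
    sire = np.zeros(q, dtype=np.int64)
    dam = np.zeros(q, dtype=np.int64)
    for ident in order:
        i = code[ident] - 1
        s, d = parents[ident]
        sire[i] = code[s] if s is not None else 0
        dam[i] = code[d] if d is not None else 0
    return RenumberedPedigree(sire=sire, dam=dam, original_id=order)


def build_relationship_matrix(ped: RenumberedPedigree) -> np.ndarray:
    """Dense numerator relationship matrix A by the tabular method.

    a(i,i) = 1 + 0.5·a(s,d); a(i,j) = 0.5·(a(j,s) + a(j,d)) for j < i, with an
    unknown parent contributing 0.  Diagonal is 1 + F (inbreeding coefficient).
    """
    q = ped.q
    A = np.zeros((q, q))
    s, d = ped.sire, ped.dam
    for i in range(q):
        si, di = s[i] - 1, d[i] - 1  # -1 means unknown
        A[i, i] = 1.0 + (0.5 * A[si, di] if si >= 0 and di >= 0 else 0.0)
        if i == 0:
            continue
        row = np.zeros(i)
        if si >= 0:
            row += 0.5 * A[:i, si]
        if di >= 0:
            row += 0.5 * A[:i, di]
        A[:i, i] = row
        A[i, :i] = row
    return A


def inbreeding_coefficients(ped: RenumberedPedigree) -> np.ndarray:
    """Inbreeding coefficients F_i = a(i,i) − 1 from the tabular pass."""
    return np.diag(build_relationship_matrix(ped)) - 1.0


def build_A_inverse(
    ped: RenumberedPedigree, account_inbreeding: bool = True
) -> sparse.csr_matrix:
    """Sparse A⁻¹ by Henderson's rules.

    For each animal i with parents s, d: add δ_i at (i,i), −δ_i/2 at (i,s) and
    (i,d), δ_i/4 at (s,s), (d,d), (s,d), (d,s) — terms involving an unknown
    parent are dropped.  With ``account_inbreeding`` the Mendelian-sampling
    precision uses δ_i = 1/(0.5 − 0.25·(F_s + F_d)); otherwise δ_i is the
    classical 2, 4/3 or 1 according to the number of known parents.
    """
    q = ped.q
    s, d = ped.sire, ped.dam
    if account_inbreeding:
        F = np.concatenate([[0.0], inbreeding_coefficients(ped)])  # F[0] ~ unknown
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(i: int, j: int, v: float) -> None:
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(q):
        si, di = int(s[i]), int(d[i])  # 1-based, 0 = unknown
        known = int(si > 0) + int(di > 0)
        if account_inbreeding:
            fs = F[si] if si > 0 else 0.0
            fd = F[di] if di > 0 else 0.0
            # unknown parent: its "F" contribution is replaced by the base
            # population variance, i.e. treat the missing parent term as adding
            # 0.25 to the Mendelian variance
            mend = 0.5 - 0.25 * (fs + fd)
            if known == 1:
                mend = 0.75 - 0.25 * (fs + fd)
            elif known == 0:
                mend = 1.0
            delta = 1.0 / mend
        else:
            delta = {2: 2.0, 1: 4.0 / 3.0, 0: 1.0}[known]
        add(i, i, delta)
        for p in (si, di):
            if p > 0:
                add(i, p - 1, -delta / 2.0)
                add(p - 1, i, -delta / 2.0)
        for p1 in (si, di):
            for p2 in (si, di):
                if p1 > 0 and p2 > 0:
                    add(p1 - 1, p2 - 1, delta / 4.0)

    Ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(q, q)).tocsr()
    return Ainv
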