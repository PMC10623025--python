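"""Data coding and design-matrix assembly for the herd models.

Coding rules: calendar months map to four agro-climatic seasons (summer
Apr–Jun, rainy Jul–Sep, autumn Oct–Nov, winter Dec–Mar); calving/birth years
map to five-year period classes; the age-at-first-calving covariate is binned
into Sturges classes for reporting.  The fitted models are linear mixed models
of the form y = Xβ + Zu + e with period and season as fixed factors, a linear
AFC covariate (except where AFC is the response), and a random animal or sire
term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SEASONS",
    "TraitRecord",
    "ModelSpec",
    "DesignInfo",
    "assign_season",
    "assign_period",
    "sturges_class_count",
    "sturges_bins",
    "build_design",
    "apply_edit_filters",
]

#: season label per class index 1..4
SEASONS = ("summer", "rainy", "autumn", "winter")

_MONTH_TO_SEASON = {
    4: 1, 5: 1, 6: 1,       # summer: April–June
    7: 2, 8: 2, 9: 2,       # rainy: July–September
    10: 3, 11: 3,           # autumn: October–November
    12: 4, 1: 4, 2: 4, 3: 4,  # winter: December–March
}


def assign_season(month: int) -> int:
    """Season class (1=summer, 2=rainy, 3=autumn, 4=winter) for a calendar month."""
    month = int(month)
    if month not in _MONTH_TO_SEASON:
        raise ValueError(f"month must be in 1..12, got {month}")
    return _MONTH_TO_SEASON[month]


def assign_period(year: int, base_year: int, n_periods: int, width: int = 5) -> int:
    """Five-year period class for a year, clamped to ``n_periods`` at the top."""
    year, base_year = int(year), int(base_year)
    if year < base_year:
        raise ValueError(f"year {year} precedes base year {base_year}")
    return min((year - base_year) // width + 1, n_periods)


def sturges_class_count(n: int) -> int:
    """Sturges class count k = round(1 + 3.322·log10 n) (11 at n = 964)."""
    if n < 1:
        raise ValueError("record count must be >= 1")
    return max(1, round(1.0 + 3.322 * np.log10(n)))


def sturges_bins(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width Sturges bin assignment (1..k) over the observed range.

    Returns (class labels, bin edges).  Degenerate range collapses to class 1.
    """
    values = np.asarray(values, dtype=float)
    k = sturges_class_count(values.size)
    lo, hi = values.min(), values.max()
    if hi <= lo:
        return np.ones(values.size, dtype=int), np.array([lo, hi])
    edges = np.linspace(lo, hi, k + 1)
    labels = np.clip(np.digitize(values, edges[1:-1], right=False) + 1, 1, k)
    return labels.astype(int), edges


@dataclass(frozen=True)
class TraitRecord:
    """One cow's trait values plus the dates and sire needed for coding."""

    animal: str
    traits: dict = field(default_factory=dict)  # trait name -> value (may be absent)
    birth_year: int | None = None
    birth_month: int | None = None
    calving_year: int | None = None
    calving_month: int | None = None
    sire: str | None = None


@dataclass
class ModelSpec:
    """Declares the response trait(s) and the fixed/random structure.

    ``covariate`` names a column used as a linear covariate (centred); it is
    dropped automatically for any response equal to the covariate trait, since
    a trait cannot adjust for itself.
    """

    responses: tuple[str, ...]
    factors: tuple[str, ...] = ("period", "season")
    covariate: str | None = "AFC"
    random_term: str = "animal"  # "animal" (A-structured) or "sire"

    def covariate_mask(self) -> np.ndarray:
        """Per-response flag: does this response use the covariate?

        A response never adjusts for itself; the column ``<trait>_cov`` is
        recognised as an alias of ``<trait>`` (the observed value re-used as a
        covariate for the other traits).
        """
        if self.covariate is None:
            return np.zeros(len(self.responses), dtype=bool)
        return np.array(
            [r != self.covariate and self.covariate != f"{r}_cov"
             for r in self.responses]
        )


@dataclass
class DesignInfo:
    """Design matrices with the bookkeeping needed for least-squares means."""

    y: np.ndarray            # (n, t) responses
    X: np.ndarray            # (n, p) full-rank fixed design (set-to-zero constraint)
    columns: list[str]       # labels for X's columns
    factor_levels: dict      # factor -> ordered list of level values (all levels)
    factor_columns: dict     # factor -> list of X column indices (last level omitted)
    covariate_col: int | None
    covariate_mean: float | None
    animal_index: np.ndarray  # (n,) 0-based pedigree/sire code per record
    random_ids: list          # level identity per random-effect column
    rows: np.ndarray | None = None  # positional indices of retained records


def build_design(
    spec: ModelSpec,
    data: pd.DataFrame,
    animal_col: str = "animal_code",
) -> DesignInfo:
    """Assemble y, X and the record→random-level map for a trait set.

    Records missing any response in ``spec.responses`` (or the covariate, when
    used) are dropped: each analysis is complete-case for its own trait set.
    Fixed factors use dummy coding with the last level set to zero, leaving X
    full rank; the covariate column is centred so the intercept stays
    interpretable and least-squares means evaluate at the covariate mean.
    """
    needed = list(spec.responses)
    use_cov = spec.covariate is not None and any(spec.covariate_mask())
    if use_cov and spec.covariate not in needed:
        needed = needed + [spec.covariate]
    missing_cols = [c for c in needed + list(spec.factors) if c not in data.columns]
    if missing_cols:
        raise ValueError(f"data lacks required columns: {missing_cols}")

    keep = data[needed].notna().all(axis=1)
    df = data.loc[keep]
    if df.empty:
        raise ValueError("no complete-case records for trait set " + str(spec.responses))

    y = df[list(spec.responses)].to_numpy(dtype=float)
    n = len(df)

    cols: list[np.ndarray] = [np.ones(n)]
    labels = ["intercept"]
    factor_levels: dict = {}
    factor_columns: dict = {}
    for fac in spec.factors:
        levels = sorted(df[fac].unique())
        counts = df[fac].value_counts()
        empty = [lv for lv in levels if counts.get(lv, 0) == 0]
        if empty:
            raise ValueError(f"factor {fac} has empty level(s): {empty}")
        factor_levels[fac] = levels
        idxs = []
        for lv in levels[:-1]:  # last level absorbed into the intercept
            idxs.append(len(labels))
            labels.append(f"{fac}[{lv}]")
            cols.append((df[fac] == lv).to_numpy(dtype=float))
        factor_columns[fac] = idxs

    covariate_col = covariate_mean = None
    if use_cov:
        x = df[spec.covariate].to_numpy(dtype=float)
        covariate_mean = float(x.mean())
        covariate_col = len(labels)
        labels.append(f"{spec.covariate}(cov)")
        cols.append(x - covariate_mean)

    X = np.column_stack(cols)

    codes = df[animal_col] if animal_col in df.columns else df[spec.random_term]
    uniq = list(pd.unique(codes))
    lookup = {v: i for i, v in enumerate(uniq)}
    animal_index = codes.map(lookup).to_numpy(dtype=np.int64)

    return DesignInfo(
        y=y,
        X=X,
        columns=labels,
        factor_levels=factor_levels,
        factor_columns=factor_columns,
        covariate_col=covariate_col,
        covariate_mean=covariate_mean,
        animal_index=animal_index,
        random_ids=uniq,
        rows=np.flatnonzero(keep.to_numpy()),
    )


#: editing thresholds: records strictly below any of these are discarded
EDIT_RULES = {
    "lactation_length": 100.0,   # days
    "FLMY": 500.0,               # kg milk
    "fat_pct": 3.5,              # %
}


def apply_edit_filters(
    data: pd.DataFrame, rules: dict | None = None
) -> tuple[pd.DataFrame, dict]:
    """Drop records failing the herd's standardising edits; count drops per rule.

    A record is excluded when a filtered column is present and strictly below
    its threshold (values at the threshold are retained).  Columns absent from
    the data are skipped.  Returns (filtered frame, per-rule exclusion counts).
    """
    rules = EDIT_RULES if rules is None else rules
    log = {}
    bad = pd.Series(False, index=data.index)
    for col, thr in rules.items():
        if col not in data.columns:
            log[col] = 0
            continue
        viol = data[col].notna() & (data[col] < thr)
        log[col] = int(viol.sum())
        bad |= viol
    return data.loc[~bad].copy(), log
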