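"""Synthetic herd generator: pedigrees and multi-trait phenotypes with known
genetic architecture.

The generator emulates a research dairy herd of roughly a thousand recorded
cows: founder sires and dams, random mating over a few generations, additive
breeding values transmitted as u = ½(u_s + u_d) + Mendelian sampling
N(0, ½G0), and phenotypes y = μ + period + season + b·(AFC − AFC̄) + u + e with
e ~ N(0, R0).  Trait means/SDs default to the herd's descriptive statistics
and the default G0/R0 reproduce the published heritabilities and genetic /
phenotypic correlation structure (with a minimum-eigenvalue repair where the
printed correlation tables are not jointly positive definite).

True breeding values are attached to every record so that parameter-recovery
tests can compare estimates against the simulated truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_design import assign_period, assign_season
from .pedigree import PedigreeRecord

__all__ = [
    "TRAIT_MEANS",
    "TRAIT_SDS",
    "TRAIT_H2",
    "SimulationParams",
    "default_covariances",
    "simulate_pedigree",
    "simulate_phenotypes",
    "simulate_herd",
    "descriptive_statistics",
    "coefficient_of_variation",
]

#: Published herd means (AFC/FSP/PL/HL in days, yields in kg).
TRAIT_MEANS = {
    "AFC": 1227.73, "FSP": 148.37, "FLMY": 1765.44, "FLFY": 2701.79,
    "FLSNFY": 1482.38, "LTMY": 5374.76, "PL": 1292.72, "HL": 2555.11,
}
TRAIT_SDS = {
    "AFC": 179.45, "FSP": 94.21, "FLMY": 697.26, "FLFY": 409.36,
    "FLSNFY": 269.02, "LTMY": 3119.39, "PL": 639.90, "HL": 655.63,
}
#: Posterior-mean heritabilities from the herd's multi-trait analysis.
TRAIT_H2 = {
    "AFC": 0.61, "FSP": 0.57, "FLMY": 0.57, "FLFY": 0.60,
    "FLSNFY": 0.60, "LTMY": 0.24, "PL": 0.42, "HL": 0.38,
}
_TRAITS7 = ("AFC", "FSP", "FLMY", "FLFY", "FLSNFY", "PL", "HL")
#: Genetic correlations (posterior means) among the seven jointly analysed traits.
_RG = {
    ("AFC", "FSP"): 0.32, ("AFC", "FLMY"): 0.68, ("AFC", "FLFY"): 0.80,
    ("AFC", "FLSNFY"): 0.85, ("AFC", "PL"): -0.59, ("AFC", "HL"): -0.59,
    ("FSP", "FLMY"): 0.59, ("FSP", "FLFY"): 0.65, ("FSP", "FLSNFY"): 0.63,
    ("FSP", "PL"): -0.38, ("FSP", "HL"): -0.34,
    ("FLMY", "FLFY"): 0.92, ("FLMY", "FLSNFY"): 0.93, ("FLMY", "PL"): 0.13,
    ("FLMY", "HL"): 0.23,
    ("FLFY", "FLSNFY"): 0.99, ("FLFY", "PL"): 0.33, ("FLFY", "HL"): 0.25,
    ("FLSNFY", "PL"): 0.35, ("FLSNFY", "HL"): 0.26,
    ("PL", "HL"): 0.95,
}
#: Phenotypic correlations (below-diagonal convention of the same table).
_RP = {
    ("AFC", "FSP"): 0.46, ("AFC", "FLMY"): 0.77, ("AFC", "FLFY"): 0.85,
    ("AFC", "FLSNFY"): 0.87, ("AFC", "PL"): -0.33, ("AFC", "HL"): -0.21,
    ("FSP", "FLMY"): 0.54, ("FSP", "FLFY"): 0.64, ("FSP", "FLSNFY"): 0.64,
    ("FSP", "PL"): -0.16, ("FSP", "HL"): -0.04,
    ("FLMY", "FLFY"): 0.92, ("FLMY", "FLSNFY"): 0.93, ("FLMY", "PL"): 0.19,
    ("FLMY", "HL"): 0.25,
    ("FLFY", "FLSNFY"): 0.99, ("FLFY", "PL"): 0.23, ("FLFY", "HL"): 0.23,
    ("FLSNFY", "PL"): 0.24, ("FLSNFY", "HL"): 0.23,
    ("PL", "HL"): 0.96,
}


def _corr_lookup(table, a, b):
    if a == b:
        return 1.0
    return table.get((a, b), table.get((b, a), 0.0))


def _nearest_pd(M: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Eigenvalue-floor repair keeping symmetry (printed tables need not be PD)."""
    w, V = np.linalg.eigh((M + M.T) / 2.0)
    w = np.maximum(w, floor * w.max())
    return V @ np.diag(w) @ V.T


def default_covariances(traits) -> tuple[np.ndarray, np.ndarray]:
    """Default (G0, R0) for a trait set from the published h², SDs and correlations.

    G0_ii = h²_i σ²_P,i; off-diagonals from the genetic correlations; R0 from
    R0 = P0 − G0 with P0 built from the phenotypic correlations.  Both matrices
    pass through a minimum-eigenvalue repair so any subset is usable.
    """
    traits = tuple(traits)
    t = len(traits)
    sp = np.array([TRAIT_SDS[tr] for tr in traits])
    h2 = np.array([TRAIT_H2[tr] for tr in traits])
    sg = np.sqrt(h2) * sp
    G = np.empty((t, t))
    P = np.empty((t, t))
    for i in range(t):
        for j in range(t):
            G[i, j] = _corr_lookup(_RG, traits[i], traits[j]) * sg[i] * sg[j]
            P[i, j] = _corr_lookup(_RP, traits[i], traits[j]) * sp[i] * sp[j]
    R = P - G
    G = _nearest_pd(G)
    R = _nearest_pd(R)
    return G, R


@dataclass
class SimulationParams:
    """Knobs of the synthetic herd; defaults emulate the study population.

    The default mating structure (8 founder sires, 120 founder dams, two
    offspring per dam over four generations) yields on the order of 960
    recorded cows in half-sib families large enough for sire evaluation, with
    birth/calving years spanning the herd's 1986–2019 recording window.
    """

    traits: tuple[str, ...] = ("AFC", "FSP")
    n_sires: int = 8
    n_dams: int = 120
    progeny_per_mating: int = 2
    n_generations: int = 4
    G0: np.ndarray | None = None
    R0: np.ndarray | None = None
    trait_means: dict = field(default_factory=lambda: dict(TRAIT_MEANS))
    period_effect_sd: float = 0.15   # fixed-effect spread, in phenotypic SDs
    season_effect_sd: float = 0.10
    afc_slope_sd: float = 0.05       # covariate slope scale, SD_trait per SD_AFC
    birth_base_year: int = 1986
    calving_base_year: int = 1990
    n_birth_periods: int = 7
    n_calving_periods: int = 6
    year_span: int = 30
    seed: int = 0

    def covariances(self) -> tuple[np.ndarray, np.ndarray]:
        if self.G0 is not None and self.R0 is not None:
            G = np.atleast_2d(np.asarray(self.G0, dtype=float))
            R = np.atleast_2d(np.asarray(self.R0, dtype=float))
        else:
            G, R = default_covariances(self.traits)
        for name, M in (("G0", G), ("R0", R)):
            if np.linalg.eigvalsh(M).min() <= 0:
                raise ValueError(f"{name} must be positive definite")
        h2 = np.diag(G) / (np.diag(G) + np.diag(R))
        if not ((h2 > 0) & (h2 < 1)).all():
            raise ValueError("implied heritabilities must lie in (0, 1)")
        return G, R


def simulate_pedigree(params: SimulationParams) -> list[PedigreeRecord]:
    """Founder sires/dams plus ``n_generations`` of random matings.

    Each generation mates every current dam to a random founder sire,
    producing ``progeny_per_mating`` offspring; daughters of one generation
    become the dams of the next.  Output is parent-before-offspring and fully
    reproducible from the seed.
    """
    rng = np.random.default_rng(params.seed)
    records: list[PedigreeRecord] = []
    sires = [f"S{i + 1}" for i in range(params.n_sires)]
    dams = [f"D{i + 1}" for i in range(params.n_dams)]
    for s in sires:
        records.append(PedigreeRecord(s))
    for d in dams:
        records.append(PedigreeRecord(d))
    counter = 0
    current_dams = dams
    for gen in range(1, params.n_generations + 1):
        next_dams = []
        for dam in current_dams:
            sire = sires[rng.integers(len(sires))]
            for _ in range(params.progeny_per_mating):
                counter += 1
                child = f"C{gen}_{counter}"
                records.append(PedigreeRecord(child, sire=sire, dam=dam))
                next_dams.append(child)
        # daughters replace the dam pool, keeping herd size roughly constant
        if len(next_dams) > params.n_dams:
            idx = rng.choice(len(next_dams), size=params.n_dams, replace=False)
            next_dams = [next_dams[i] for i in sorted(idx)]
        current_dams = next_dams
    return records


def simulate_phenotypes(
    records: list[PedigreeRecord],
    params: SimulationParams,
    return_all_bv: bool = False,
):
    """Phenotypes for every non-founder cow, with the simulated truth attached.

    Returns one row per recorded cow with columns: animal, sire, trait values,
    birth/calving year and month, ``period`` (calving 5-year class), ``season``
    (calving season class), the AFC covariate, and ``tbv_<trait>`` columns
    holding the true breeding values.
    """
    G0, R0 = params.covariances()
    t = len(params.traits)
    rng = np.random.default_rng(params.seed + 1)
    Lg = np.linalg.cholesky(G0)
    Lm = np.linalg.cholesky(0.5 * G0)
    Lr = np.linalg.cholesky(R0)

    means = np.array([params.trait_means[tr] for tr in params.traits])
    sds_p = np.sqrt(np.diag(G0) + np.diag(R0))
    n_periods_cal = params.n_calving_periods
    per_eff = rng.normal(0.0, params.period_effect_sd, (n_periods_cal, t)) * sds_p
    sea_eff = rng.normal(0.0, params.season_effect_sd, (4, t)) * sds_p
    sd_afc = TRAIT_SDS["AFC"]
    slopes = rng.normal(0.0, params.afc_slope_sd, t) * sds_p / sd_afc
    if "AFC" in params.traits:
        slopes[params.traits.index("AFC")] = 0.0

    bv: dict[str, np.ndarray] = {}
    rows = []
    for rec in records:
        if rec.sire is None and rec.dam is None:
            bv[rec.animal] = Lg @ rng.standard_normal(t)
            continue
        us = bv.get(rec.sire, np.zeros(t)) if rec.sire else np.zeros(t)
        ud = bv.get(rec.dam, np.zeros(t)) if rec.dam else np.zeros(t)
        u = 0.5 * (us + ud) + Lm @ rng.standard_normal(t)
        bv[rec.animal] = u

        birth_year = int(
            rng.integers(params.birth_base_year, params.birth_base_year + params.year_span)
        )
        birth_month = int(rng.integers(1, 13))
        afc_days = float(rng.normal(TRAIT_MEANS["AFC"], sd_afc))
        calving_year = max(birth_year + int(round(afc_days / 365.25)),
                           params.calving_base_year)
        calving_month = int(rng.integers(1, 13))
        period = assign_period(calving_year, params.calving_base_year, n_periods_cal)
        season = assign_season(calving_month)

        e = Lr @ rng.standard_normal(t)
        y = means + per_eff[period - 1] + sea_eff[season - 1] + u + e
        afc_cov = afc_days
        if "AFC" in params.traits:
            afc_cov = y[params.traits.index("AFC")]
        y = y + slopes * (afc_cov - TRAIT_MEANS["AFC"])
        if "AFC" in params.traits:
            y[params.traits.index("AFC")] = afc_cov

        row = {
            "animal": rec.animal,
            "sire": rec.sire,
            "birth_year": birth_year,
            "birth_month": birth_month,
            "calving_year": calving_year,
            "calving_month": calving_month,
            "period": period,
            "season": season,
            "AFC_cov" if "AFC" not in params.traits else "_afc_tmp": afc_cov,
        }
        for k, tr in enumerate(params.traits):
            row[tr] = y[k]
            row[f"tbv_{tr}"] = u[k]
        rows.append(row)

    df = pd.DataFrame(rows)
    if "_afc_tmp" in df.columns:
        df = df.drop(columns="_afc_tmp")
        df["AFC_cov"] = df["AFC"]
    elif "AFC_cov" not in df.columns:
        df["AFC_cov"] = np.nan
    if return_all_bv:
        bv_df = pd.DataFrame(
            {"animal": list(bv)}
            | {f"tbv_{tr}": [bv[a][k] for a in bv]
               for k, tr in enumerate(params.traits)}
        )
        return df, bv_df
    return df


def simulate_herd(params: SimulationParams | None = None):
    """Convenience wrapper: (pedigree records, phenotype frame) in one call."""
    params = params or SimulationParams()
    ped = simulate_pedigree(params)
    return ped, simulate_phenotypes(ped, params)


def coefficient_of_variation(mean: float, sd: float) -> float:
    """CV% = 100·SD/mean."""
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return 100.0 * sd / mean


def descriptive_statistics(data: pd.DataFrame, traits=None) -> pd.DataFrame:
    """Per-trait mean ± SE, CV%, SD, minimum and maximum over non-missing values."""
    traits = list(traits) if traits is not None else [
        c for c in data.columns if c in TRAIT_MEANS
    ]
    rows = []
    for tr in traits:
        x = data[tr].dropna().to_numpy(dtype=float) if tr in data else np.array([])
        if x.size < 2:
            rows.append({"trait": tr, "n": x.size, "mean": np.nan, "se": np.nan,
                         "cv": np.nan, "sd": np.nan, "min": np.nan, "max": np.nan})
            continue
        sd = float(np.std(x, ddof=1))
        mean = float(x.mean())
        rows.append({
            "trait": tr, "n": x.size, "mean": mean,
            "se": sd / np.sqrt(x.size),
            "cv": coefficient_of_variation(mean, sd),
            "sd": sd, "min": float(x.min()), "max": float(x.max()),
        })
    return pd.DataFrame(rows).set_index("trait")
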