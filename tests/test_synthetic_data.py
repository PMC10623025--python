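"""Synthetic herd generator: pedigree structure, genetic architecture,
descriptive statistics."""

import numpy as np
import pytest

from herdvar.synthetic_data import (
    SimulationParams,
    coefficient_of_variation,
    default_covariances,
    descriptive_statistics,
    simulate_herd,
    simulate_pedigree,
    simulate_phenotypes,
)


class TestSimulatePedigree:
    def test_minimal_trio(self):
        p = SimulationParams(n_sires=1, n_dams=1, progeny_per_mating=1, n_generations=1)
        recs = simulate_pedigree(p)
        assert len(recs) == 3

    def test_half_sib_families_for_sire_evaluation(self):
        p = SimulationParams(n_sires=8, n_dams=120, progeny_per_mating=1, n_generations=1,
                             seed=4)
        recs = simulate_pedigree(p)
        counts = {}
        for r in recs:
            if r.sire:
                counts[r.sire] = counts.get(r.sire, 0) + 1
        assert len(counts) == 8
        assert all(c > 3 for c in counts.values())

    def test_seed_reproducibility(self):
        p = SimulationParams(seed=7)
        a = simulate_pedigree(p)
        b = simulate_pedigree(p)
        assert [(r.animal, r.sire, r.dam) for r in a] == [
            (r.animal, r.sire, r.dam) for r in b
        ]


class TestSimulatePhenotypes:
    def test_founder_bv_covariance_matches_G0(self):
        G0 = np.array([[4.0, 1.2], [1.2, 2.0]])
        R0 = np.eye(2) * 3.0
        p = SimulationParams(
            traits=("AFC", "FSP"), n_sires=5000, n_dams=5000,
            progeny_per_mating=1, n_generations=1, G0=G0, R0=R0, seed=1,
        )
        recs = simulate_pedigree(p)
        _, bv = simulate_phenotypes(recs, p, return_all_bv=True)
        founders = bv[bv.animal.str.startswith(("S", "D"))]
        emp = np.cov(founders[["tbv_AFC", "tbv_FSP"]].to_numpy(), rowvar=False)
        assert np.allclose(emp, G0, rtol=0.05)

    def test_signal_only_limit_orders_families_by_sire_bv(self):
        # many progeny per sire so dam and Mendelian contributions average out
        G0, _ = default_covariances(("AFC",))
        p = SimulationParams(
            traits=("AFC",), n_sires=20, n_dams=400, progeny_per_mating=2,
            n_generations=1, G0=G0, R0=np.array([[1e-4 * G0[0, 0]]]), seed=2,
            period_effect_sd=0.0, season_effect_sd=0.0, afc_slope_sd=0.0,
        )
        recs = simulate_pedigree(p)
        df, bv = simulate_phenotypes(recs, p, return_all_bv=True)
        fam = df.groupby("sire")["AFC"].mean()
        sire_bv = bv.set_index("animal").loc[fam.index, "tbv_AFC"]
        assert np.corrcoef(fam, sire_bv)[0, 1] > 0.9

    def test_parent_offspring_regression_recovers_h2(self):
        # offspring-on-dam regression estimates h2/2 (sires are founders
        # without records, so the single-parent version is used)
        G0 = np.array([[0.5]])
        R0 = np.array([[0.5]])
        p = SimulationParams(
            traits=("AFC",), n_sires=50, n_dams=2000, progeny_per_mating=1,
            n_generations=2, G0=G0, R0=R0, seed=3,
            period_effect_sd=0.0, season_effect_sd=0.0, afc_slope_sd=0.0,
        )
        recs = simulate_pedigree(p)
        df = simulate_phenotypes(recs, p)
        pheno = df.set_index("animal")["AFC"]
        dam_of = {r.animal: r.dam for r in recs if r.dam}
        pairs = [
            (pheno[d], pheno[o])
            for o, d in dam_of.items()
            if o in pheno.index and d in pheno.index
        ]
        x, y = np.array(pairs).T
        b = np.cov(x, y)[0, 1] / np.var(x, ddof=1)
        assert 2 * b == pytest.approx(0.5, rel=0.10)

    def test_non_pd_covariance_rejected(self):
        p = SimulationParams(
            traits=("AFC", "FSP"),
            G0=np.array([[1.0, 2.0], [2.0, 1.0]]), R0=np.eye(2),
        )
        with pytest.raises(ValueError):
            simulate_phenotypes(simulate_pedigree(p), p)

    def test_default_covariances_pd_any_subset(self):
        for traits in (("AFC",), ("AFC", "PL"), ("FLMY", "FLFY", "FLSNFY"),
                       ("AFC", "FSP", "FLMY", "FLFY", "FLSNFY", "PL", "HL")):
            G, R = default_covariances(traits)
            assert np.linalg.eigvalsh(G).min() > 0
            assert np.linalg.eigvalsh(R).min() > 0


class TestDescriptiveStatistics:
    def test_cv_published_rows(self):
        # herd descriptive rows: AFC 1,227.73 / 179.45 -> CV 14.62;
        # FSP 148.37 / 94.21 -> CV 63.50
        assert coefficient_of_variation(1_227.73, 179.45) == pytest.approx(14.62, abs=0.005)
        assert coefficient_of_variation(148.37, 94.21) == pytest.approx(63.50, abs=0.005)

    def test_table_consistency(self, rng):
        import pandas as pd

        df = pd.DataFrame({"AFC": rng.normal(1200, 180, 500),
                           "FSP": rng.normal(150, 90, 500)})
        stats = descriptive_statistics(df)
        for tr in ("AFC", "FSP"):
            row = stats.loc[tr]
            assert row["cv"] == pytest.approx(100 * row["sd"] / row["mean"])
            assert row["se"] == pytest.approx(row["sd"] / np.sqrt(row["n"]))
            assert row["min"] <= row["mean"] <= row["max"]

    def test_constant_column(self):
        import pandas as pd

        stats = descriptive_statistics(pd.DataFrame({"AFC": [5.0] * 10}))
        assert stats.loc["AFC", "sd"] == 0.0 and stats.loc["AFC", "cv"] == 0.0


class TestRoundTrip:
    def test_csv_round_trip_lossless(self, tmp_path):
        from herdvar.io import (
            read_pedigree_csv,
            read_phenotypes_csv,
            write_pedigree_csv,
            write_phenotypes_csv,
        )

        p = SimulationParams(n_sires=3, n_dams=6, progeny_per_mating=1,
                             n_generations=2, seed=9)
        recs, pheno = simulate_herd(p)
        write_pedigree_csv(recs, tmp_path / "ped.csv")
        back = read_pedigree_csv(tmp_path / "ped.csv")
        assert [(r.animal, r.sire, r.dam) for r in back] == [
            (r.animal, r.sire, r.dam) for r in recs
        ]
        write_phenotypes_csv(pheno, tmp_path / "ph.csv")
        back_df = read_phenotypes_csv(tmp_path / "ph.csv")
        assert np.allclose(back_df["AFC"], pheno["AFC"])
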