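"""RILT binarization, Spearman statistics, dominance labels, Table-1/-2 shapes."""

import numpy as np
import pytest
from scipy import stats

from vqlung.cohort import (
    COHORT_CSV_COLUMNS,
    ConstantInputError,
    CorrelationResult,
    chi2_2x2_yates,
    compare_characteristics,
    dominance_groups,
    dominance_label,
    read_cohort_csv,
    rilt_event,
    spearman,
    subgroup_correlations,
    write_cohort_csv,
)
from vqlung.synthetic import table1_fixture


class TestRiltEvent:
    @pytest.mark.parametrize("grade,event", [(0, 0), (1, 0), (2, 1), (3, 1), (4, 1), (5, 1)])
    def test_grade_threshold(self, grade, event):
        assert rilt_event(grade) == event

    def test_monotone_in_grade(self):
        events = [rilt_event(g) for g in range(6)]
        assert events == sorted(events)

    @pytest.mark.parametrize("bad", [-1, 6, 2.5, "2"])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            rilt_event(bad)


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.array([1.0, 2, 3, 4, 5])
        assert spearman(x, x**3).r == 1.0
        assert spearman(x, -x).r == -1.0

    def test_hand_computed_tie_corrected_value(self):
        # x = 1..5, y = (1,1,2,2,3): rank_y = (1.5,1.5,3.5,3.5,5);
        # Pearson of the rank vectors = 9 / sqrt(10 * 9) = 3/sqrt(10)
        res = spearman([1, 2, 3, 4, 5], [1, 1, 2, 2, 3])
        assert res.r == pytest.approx(3.0 / np.sqrt(10.0), abs=1e-15)

    def test_matches_scipy_with_ties(self, rng):
        x = rng.integers(0, 6, 40).astype(float)
        y = 0.5 * x + rng.integers(0, 4, 40)
        res = spearman(x, y)
        ref_r, ref_p = stats.spearmanr(x, y)
        assert res.r == pytest.approx(ref_r, abs=1e-12)
        assert res.p == pytest.approx(ref_p, abs=1e-12)

    def test_symmetric_and_monotone_invariant(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        base = spearman(x, y).r
        assert spearman(y, x).r == pytest.approx(base, abs=1e-12)
        assert spearman(np.exp(x), y).r == pytest.approx(base, abs=1e-12)
        assert spearman(x, 3.0 * y - 7.0).r == pytest.approx(base, abs=1e-12)

    def test_permutation_p_is_seeded_and_ordered(self, rng):
        x = rng.normal(size=25)
        strong = x + 0.2 * rng.normal(size=25)
        weak = 0.2 * x + rng.normal(size=25)
        p_strong = spearman(x, strong, p_method="permutation", n_perm=2000, seed=7).p
        p_weak = spearman(x, weak, p_method="permutation", n_perm=2000, seed=7).p
        assert p_strong < p_weak  # both estimators are monotone in |r|
        again = spearman(x, strong, p_method="permutation", n_perm=2000, seed=7).p
        assert again == p_strong
        assert p_strong >= 1.0 / 2001.0  # add-one estimator floor

    def test_errors(self):
        with pytest.raises(ConstantInputError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])
        with pytest.raises(ValueError, match="equal-length"):
            spearman([1, 2, 3], [1, 2])
        with pytest.raises(ValueError, match="at least 3"):
            spearman([1, 2], [2, 1])
        with pytest.raises(ValueError, match="seed"):
            spearman([1, 2, 3, 4], [1, 3, 2, 4], p_method="permutation")


def _six_results(ct, q, v):
    out = []
    for fam, names in (("CT", ("V20", "MLD")), ("Q", ("Q_V20", "Q_MLD")),
                       ("V", ("V_V20", "V_MLD"))):
        r = {"CT": ct, "Q": q, "V": v}[fam]
        for name in names:
            out.append(CorrelationResult(metric_name=name, r=r, p=0.05, n=10))
    return out


class TestDominanceLabel:
    def test_close_pair_above_gap(self):
        assert dominance_label(_six_results(0.40, 0.69, 0.70)) == "V ≈ Q > CT"

    def test_all_equal(self):
        assert dominance_label(_six_results(0.5, 0.5, 0.5)) == "V ≈ Q ≈ CT"

    def test_strict_ordering(self):
        assert dominance_label(_six_results(0.45, 0.60, 0.75)) == "V > Q > CT"

    def test_absolute_value_is_used(self):
        assert dominance_label(_six_results(-0.45, -0.60, -0.75)) == "V > Q > CT"

    def test_not_computable_gives_na(self):
        results = _six_results(0.4, 0.5, 0.6)[:5]
        results.append(
            CorrelationResult(metric_name="V_MLD", r=float("nan"), p=float("nan"),
                              n=2, computable=False, reason="too small")
        )
        assert dominance_label(results) == "n/a"

    def test_groups_parse_round_trip(self):
        assert dominance_groups("V ≈ Q > CT") == [frozenset({"V", "Q"}), frozenset({"CT"})]
        assert dominance_groups("Q ≈ V > CT") == [frozenset({"V", "Q"}), frozenset({"CT"})]
        assert dominance_groups("V > Q > CT") == [
            frozenset({"V"}), frozenset({"Q"}), frozenset({"CT"})
        ]
        assert dominance_groups("n/a") == []


class TestSubgroupCorrelations:
    def test_fixture_cohort_strata_shape(self):
        table = subgroup_correlations(table1_fixture())
        df = table.to_dataframe()
        # all + 4 stratifiers x 2 levels = 9 subgroups x 6 metrics
        assert sorted(df.subgroup.unique()) == sorted(
            ["all", "copd=yes", "copd=no", "pft=worse", "pft=good",
             "location=central", "location=peripheral", "stage=I-II", "stage=III"]
        )
        assert len(df) == 9 * 6
        assert df[df.subgroup == "all"].n.unique().tolist() == [57]

    def test_constant_outcome_stratum_flagged(self):
        cohort = [rec for rec in table1_fixture() if rec.rilt_event == 0]
        table = subgroup_correlations(cohort, strata=())
        assert all(not res.computable for res in table.results)
        assert {res.reason for res in table.results} == {"constant outcome"}
        assert table.labels["all"] == "n/a"

    def test_single_level_stratifier_equals_all_patients(self):
        cohort = [rec for rec in table1_fixture() if rec.copd == "yes"]
        table = subgroup_correlations(cohort, strata=("copd",))
        df = table.to_dataframe()
        all_r = df[(df.subgroup == "all")].set_index("metric").r
        yes_r = df[(df.subgroup == "copd=yes")].set_index("metric").r
        assert (all_r == yes_r).all()
        assert not df[df.subgroup == "copd=no"].computable.any()

    def test_unknown_stratifier_rejected(self):
        with pytest.raises(ValueError, match="unknown stratifier"):
            subgroup_correlations(table1_fixture(), strata=("histology_typo",))

    def test_ordinal_grade_outcome_mode(self):
        table = subgroup_correlations(table1_fixture(), strata=(), outcome="grade")
        assert all(res.computable for res in table.results)


class TestCompareCharacteristics:
    def test_textbook_chi_square_oracle(self):
        # Yates-corrected 2x2, computed cellwise from expected counts with the
        # clamped |O-E| - 0.5 correction (independent of the implementation's
        # ad-bc short form)
        table = np.array([[11.0, 4.0], [32.0, 10.0]])
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        corr = np.maximum(np.abs(table - expected) - 0.5, 0.0)
        chi2_ref = float((corr**2 / expected).sum())
        p_ref = float(stats.chi2.sf(chi2_ref, df=1))
        chi2_got, p_got = chi2_2x2_yates(table)
        assert chi2_got == pytest.approx(chi2_ref, abs=1e-10)
        assert p_got == pytest.approx(p_ref, abs=1e-10)

    def test_balanced_covariate_is_null(self):
        # identical sex distribution in both outcome groups, large cells
        cohort = []
        fixture = table1_fixture()
        template = fixture[0]
        from dataclasses import replace

        i = 0
        for event_grade, n_group in ((3, 30), (0, 30)):
            for j in range(n_group):
                cohort.append(
                    replace(
                        template,
                        patient_id=f"B{i:03d}",
                        rilt_grade=event_grade,
                        sex="male" if j % 2 == 0 else "female",
                    )
                )
                i += 1
        row = compare_characteristics(cohort, covariates=("sex",)).iloc[0]
        assert row.test == "chi2_yates"
        assert row.p == pytest.approx(1.0, abs=1e-9)

    def test_small_cells_trigger_fisher(self):
        fixture = table1_fixture()
        df = compare_characteristics(fixture)
        # pft: expected RILT/worse count = 15*15/57 < 5 -> Fisher
        assert df.set_index("covariate").loc["pft", "test"] == "fisher_exact"
        # copd expected counts all >= 5 -> Yates chi-square
        assert df.set_index("covariate").loc["copd", "test"] == "chi2_yates"
        # k > 2 levels use the plain chi-square
        assert df.set_index("covariate").loc["stage", "test"] == "chi2"
        assert df.set_index("covariate").loc["chemo", "test"] == "chi2"

    def test_single_level_covariate_flagged(self):
        from dataclasses import replace

        cohort = [replace(rec, sex="male") for rec in table1_fixture()]
        df = compare_characteristics(cohort, covariates=("sex",))
        assert not df.iloc[0].computable

    def test_holm_column_optional(self):
        df = compare_characteristics(table1_fixture(), holm=True)
        assert "p_holm" in df.columns
        assert (df.p_holm.dropna() >= df.p.dropna() - 1e-12).all()


class TestCohortCsv:
    def test_round_trip_and_exact_header(self, tmp_path):
        cohort = table1_fixture()
        path = tmp_path / "cohort.csv"
        write_cohort_csv(cohort, path)
        header = path.read_text().splitlines()[0]
        assert header == ",".join(COHORT_CSV_COLUMNS)
        back = read_cohort_csv(path)
        assert len(back) == len(cohort)
        assert back[0].metrics.as_dict() == pytest.approx(cohort[0].metrics.as_dict())
        assert [r.rilt_grade for r in back] == [r.rilt_grade for r in cohort]

    def test_missing_column_named(self, tmp_path):
        import pandas as pd

        write_cohort_csv(table1_fixture(), tmp_path / "full.csv")
        df = pd.read_csv(tmp_path / "full.csv").drop(columns=["Q_MLD"])
        df.to_csv(tmp_path / "broken.csv", index=False)
        with pytest.raises(ValueError, match="Q_MLD"):
            read_cohort_csv(tmp_path / "broken.csv")
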