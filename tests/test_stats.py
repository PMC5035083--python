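import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from drtriage.grading import ReferralCategory
from drtriage.stats import (
    MISSING,
    ConfusionTable2x2,
    StudyDataset,
    build_confusion,
    cohens_kappa,
    compare_auc,
    diagnostics,
    evaluate_study,
    kappa_band,
    load_pilot_confusion,
    read_study,
    sample_size_chisq,
    stratify,
    write_study,
)

RED = ReferralCategory.RED_IMMEDIATE
YELLOW = ReferralCategory.YELLOW_REVIEW_6_MONTHS
GREEN = ReferralCategory.GREEN_REVIEW_1_YEAR


def small_dataset() -> StudyDataset:
    """2 readers x 3 images with one missing response (n == 5)."""
    gold = pd.Series(["red", "yellow", "green"], index=["i1", "i2", "i3"])
    responses = pd.DataFrame(
        {
            "reader_id": ["r1", "r1", "r1", "r2", "r2", "r2"],
            "image_id": ["i1", "i2", "i3", "i1", "i2", "i3"],
            "response": ["red", "yellow", "green", "red", MISSING, "yellow"],
        }
    )
    attrs = pd.DataFrame(
        {"group": ["student", "working"], "prior_grading": [False, True]},
        index=pd.Index(["r1", "r2"], name="reader_id"),
    )
    return StudyDataset(gold=gold, responses=responses, reader_attrs=attrs)


class TestStudyDataset:
    def test_counts(self):
        ds = small_dataset()
        assert ds.expected_responses == 6
        assert ds.n_missing == 1
        assert ds.actual_responses == 5

    def test_unknown_image_rejected(self):
        gold = pd.Series(["red"], index=["i1"])
        responses = pd.DataFrame(
            {"reader_id": ["r1"], "image_id": ["i99"], "response": ["red"]}
        )
        with pytest.raises(ValueError, match="unknown image"):
            StudyDataset(gold=gold, responses=responses, reader_attrs=pd.DataFrame())


class TestBuildConfusion:
    def test_pilot_red_fixture(self):
        table = load_pilot_confusion()[RED]
        assert (table.a, table.b, table.c, table.d) == (1857, 522, 204, 2197)
        assert table.n == 4780

    def test_all_three_fixture_tables_total_4780(self):
        for table in load_pilot_confusion().values():
            assert table.n == 4780

    def test_perfect_agreement_off_diagonal_zero(self):
        gold = pd.Series(["red", "green", "yellow"], index=["i1", "i2", "i3"])
        responses = pd.DataFrame(
            {
                "reader_id": ["r1"] * 3,
                "image_id": ["i1", "i2", "i3"],
                "response": ["red", "green", "yellow"],
            }
        )
        ds = StudyDataset(gold=gold, responses=responses, reader_attrs=pd.DataFrame())
        for cat in (RED, YELLOW, GREEN):
            t = build_confusion(ds, cat)
            assert t.b == 0 and t.c == 0

    def test_missing_excluded_pairwise(self):
        t = build_confusion(small_dataset(), RED)
        assert t.n == 5  # hand count: six cells, one missing

    def test_hand_counted_cells(self):
        # non-missing pairs: (red,red), (yellow,yellow), (green,green),
        # (red,red), (green,yellow) -> for RED: a=2 (yy,gg... non-red pairs
        # without red response: yy, gg, gy), d=2, b=0, c=0
        t = build_confusion(small_dataset(), RED)
        assert (t.a, t.b, t.c, t.d) == (3, 0, 0, 2)

    def test_empty_dataset_errors(self):
        gold = pd.Series(["red"], index=["i1"])
        responses = pd.DataFrame(
            {"reader_id": ["r1"], "image_id": ["i1"], "response": [MISSING]}
        )
        ds = StudyDataset(gold=gold, responses=responses, reader_attrs=pd.DataFrame())
        with pytest.raises(ValueError):
            build_confusion(ds, RED)


class TestCohensKappa:
    def test_pilot_red_kappa(self):
        agree = cohens_kappa(load_pilot_confusion()[RED])
        assert round(agree.kappa, 3) == 0.696
        assert round(agree.se_kappa, 3) == 0.010  # printed SE matches this row

    def test_pilot_yellow_kappa(self):
        assert round(cohens_kappa(load_pilot_confusion()[YELLOW]).kappa, 3) == 0.462

    def test_pilot_green_kappa(self):
        assert round(cohens_kappa(ConfusionTable2x2(3483, 159, 555, 583)).kappa, 3) == 0.532

    def test_perfect_agreement(self):
        assert cohens_kappa(ConfusionTable2x2(10, 0, 0, 10)).kappa == 1.0

    def test_kappa_identity(self):
        agree = cohens_kappa(load_pilot_confusion()[RED])
        assert agree.kappa == pytest.approx(
            (agree.p_observed - agree.p_expected) / (1 - agree.p_expected)
        )

    def test_degenerate_marginals_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            cohens_kappa(ConfusionTable2x2(10, 0, 0, 0))

    @given(
        st.tuples(
            st.integers(0, 500), st.integers(0, 500),
            st.integers(0, 500), st.integers(0, 500),
        )
    )
    @settings(max_examples=1000, deadline=None)
    def test_kappa_bounds_random_tables(self, cells):
        a, b, c, d = cells
        t = ConfusionTable2x2(a, b, c, d)
        n = t.n
        if n == 0:
            return
        pe = ((a + b) * (a + c) + (c + d) * (b + d)) / n**2
        if pe >= 1.0:
            return
        agree = cohens_kappa(t)
        assert -1.0 - 1e-12 <= agree.kappa <= agree.p_observed + 1e-12
        assert (agree.kappa == pytest.approx(1.0)) == (b == 0 and c == 0)


class TestKappaBand:
    @pytest.mark.parametrize(
        "kappa,label",
        [
            (0.10, "slight agreement"),
            (0.30, "fair agreement"),
            (0.462, "moderate agreement"),
            (0.405, "moderate agreement"),  # rounds to 0.41 before banding
            (0.696, "substantial agreement"),
            (0.90, "almost perfect agreement"),
        ],
    )
    def test_bands(self, kappa, label):
        assert kappa_band(kappa) == label

    def test_out_of_band_values_unclassified(self):
        assert kappa_band(1.0).startswith("unclassified")
        assert kappa_band(0.0).startswith("unclassified")
        assert kappa_band(-0.5).startswith("unclassified")

    def test_band_consistency_random(self):
        rng = np.random.default_rng(1)
        cutoffs = [
            (0.01, 0.20, "slight agreement"),
            (0.21, 0.40, "fair agreement"),
            (0.41, 0.60, "moderate agreement"),
            (0.61, 0.80, "substantial agreement"),
            (0.81, 0.99, "almost perfect agreement"),
        ]
        for kappa in rng.uniform(-1, 1, size=1000):
            label = kappa_band(kappa)
            k2 = round(kappa, 2)
            expected = next(
                (name for lo, hi, name in cutoffs if lo <= k2 <= hi),
                None,
            )
            if expected is None:
                assert label.startswith("unclassified")
            else:
                assert label == expected


class TestDiagnostics:
    def test_pilot_red_percent_correct(self):
        assert diagnostics(load_pilot_confusion()[RED]).percent_correct == 91.5

    def test_pilot_yellow_percent_correct(self):
        assert diagnostics(ConfusionTable2x2(2996, 543, 465, 776)).percent_correct == 62.5

    def test_pilot_red_sensitivity_specificity(self):
        diag = diagnostics(load_pilot_confusion()[RED])
        assert int(100 * diag.sensitivity) == 91
        assert int(100 * diag.specificity) == 78

    def test_perfect_table(self):
        diag = diagnostics(ConfusionTable2x2(10, 0, 0, 10))
        assert diag.sensitivity == diag.specificity == diag.auc == 1.0

    def test_ci_brackets_point_estimate(self):
        diag = diagnostics(load_pilot_confusion()[RED])
        assert diag.sensitivity_ci[0] <= diag.sensitivity <= diag.sensitivity_ci[1]
        assert diag.specificity_ci[0] <= diag.specificity <= diag.specificity_ci[1]
        assert diag.auc_ci[0] <= diag.auc <= diag.auc_ci[1]

    def test_empty_margin_errors_name_the_margin(self):
        with pytest.raises(ValueError, match="sensitivity"):
            diagnostics(ConfusionTable2x2(5, 5, 0, 0))
        with pytest.raises(ValueError, match="specificity"):
            diagnostics(ConfusionTable2x2(0, 0, 5, 5))

    def test_wald_switch(self):
        wilson = diagnostics(ConfusionTable2x2(50, 10, 5, 40), ci_method="wilson")
        wald = diagnostics(ConfusionTable2x2(50, 10, 5, 40), ci_method="wald")
        assert wilson.sensitivity == wald.sensitivity
        assert wilson.sensitivity_ci != wald.sensitivity_ci

    def test_wilson_coverage_2000_simulated_studies(self):
        """Wilson 95% CI for sensitivity covers truth in >= 93% of studies."""
        rng = np.random.default_rng(12345)
        p_true = 0.8
        n = 200
        d = rng.binomial(n, p_true, size=2000)
        covered = 0
        for di in d:
            diag = diagnostics(ConfusionTable2x2(5, 5, int(n - di), int(di)))
            if diag.sensitivity_ci[0] <= p_true <= diag.sensitivity_ci[1]:
                covered += 1
        assert covered / 2000 >= 0.93


class TestStratify:
    def test_partition_by_group_disjoint_readers(self):
        groups = stratify(small_dataset(), "group")
        assert set(groups) == {"student", "working"}
        r1 = set(groups["student"].responses["reader_id"])
        r2 = set(groups["working"].responses["reader_id"])
        assert r1.isdisjoint(r2)

    def test_image_block_split(self):
        gold = pd.Series(
            ["red"] * 50, index=[f"img{i:03d}" for i in range(1, 51)]
        )
        responses = pd.DataFrame(
            {
                "reader_id": ["r1"] * 50,
                "image_id": gold.index,
                "response": ["red"] * 50,
            }
        )
        ds = StudyDataset(gold=gold, responses=responses, reader_attrs=pd.DataFrame())
        blocks = stratify(ds, ("image-block", 25))
        assert set(blocks) == {"block1", "block2"}
        assert all(b.n_images == 25 for b in blocks.values())

    def test_stratify_then_pool_additivity(self):
        ds = small_dataset()
        pooled = build_confusion(ds, RED)
        parts = [build_confusion(sub, RED) for sub in stratify(ds, "group").values()]
        total = parts[0]
        for p in parts[1:]:
            total = total + p
        assert total == pooled

    def test_unknown_attribute_errors(self):
        with pytest.raises(ValueError, match="unknown reader attribute"):
            stratify(small_dataset(), "shoe_size")

    def test_reader_id_permutation_invariance(self):
        ds = small_dataset()
        relabeled = StudyDataset(
            gold=ds.gold,
            responses=ds.responses.assign(
                reader_id=ds.responses["reader_id"].map({"r1": "zz", "r2": "aa"})
            ),
            reader_attrs=ds.reader_attrs.rename(index={"r1": "zz", "r2": "aa"}),
        )
        for cat in (RED, YELLOW, GREEN):
            assert build_confusion(ds, cat) == build_confusion(relabeled, cat)


class TestCompareAuc:
    def test_identical_groups(self):
        result = compare_auc(0.85, 100, 100, 0.85, 100, 100)
        assert result.statistic == 0.0
        assert result.p_value == 1.0

    def test_sign_flips_p_constant(self):
        r12 = compare_auc(0.86, 2450, 2330, 0.84, 2450, 2330)
        r21 = compare_auc(0.84, 2450, 2330, 0.86, 2450, 2330)
        assert r12.statistic == pytest.approx(-r21.statistic)
        assert r12.p_value == pytest.approx(r21.p_value)

    def test_against_permutation_oracle(self):
        """z-test p agrees with a 10,000-shuffle permutation p on a small study."""
        from drtriage.simulate import SimulationConfig, simulate_reader_study, uniform_profiles

        confusion = np.array(
            [[0.75, 0.15, 0.10], [0.15, 0.70, 0.15], [0.10, 0.10, 0.80]]
        )
        readers = uniform_profiles(6, confusion, group="student") + uniform_profiles(
            6, confusion, group="working"
        )
        cfg = SimulationConfig(n_images=30, readers=readers, seed=99)
        ds = simulate_reader_study(cfg)

        def auc_of(sub: StudyDataset) -> tuple[float, int, int]:
            t = build_confusion(sub, RED)
            diag = diagnostics(t)
            return diag.auc, t.c + t.d, t.a + t.b

        groups = stratify(ds, "group")
        (auc1, np1, nn1) = auc_of(groups["student"])
        (auc2, np2, nn2) = auc_of(groups["working"])
        p_z = compare_auc(auc1, np1, nn1, auc2, np2, nn2).p_value

        # permutation oracle: shuffle reader group labels, recompute AUC diff
        per_reader = {}
        gold = ds.gold
        for rid, sub in ds.responses.groupby("reader_id"):
            nonmiss = sub[sub["response"] != MISSING]
            gp = gold.loc[nonmiss["image_id"]].to_numpy() == "red"
            rp = nonmiss["response"].to_numpy() == "red"
            per_reader[rid] = np.array(
                [
                    np.sum(gp & rp),  # d
                    np.sum(gp & ~rp),  # c
                    np.sum(~gp & ~rp),  # a
                    np.sum(~gp & rp),  # b
                ]
            )
        ids = sorted(per_reader)
        counts = np.array([per_reader[r] for r in ids])

        def diff(labels: np.ndarray) -> float:
            g1 = counts[labels].sum(axis=0)
            g2 = counts[~labels].sum(axis=0)

            def auc(v):
                d_, c_, a_, b_ = v
                return (d_ / (c_ + d_) + a_ / (a_ + b_)) / 2

            return auc(g1) - auc(g2)

        obs_labels = np.array(
            [ds.reader_attrs.loc[r, "group"] == "student" for r in ids]
        )
        observed = abs(diff(obs_labels))
        rng = np.random.default_rng(7)
        hits = 0
        n_shuffles = 10_000
        for _ in range(n_shuffles):
            perm = rng.permutation(obs_labels)
            if abs(diff(perm)) >= observed - 1e-15:
                hits += 1
        p_perm = hits / n_shuffles
        assert abs(p_z - p_perm) < 0.2
        assert (p_z < 0.01) == (p_perm < 0.01)

    def test_zero_variance_unequal_errors(self):
        with pytest.raises(ValueError, match="zero-variance"):
            compare_auc(1.0, 10, 10, 0.0, 10, 10)


class TestSampleSize:
    def test_published_scenario(self):
        assert sample_size_chisq(0.05, 0.3, 0.85, df=1) == 100

    def test_matches_normal_closed_form_for_df1(self):
        from scipy.stats import norm

        n = math.ceil((norm.ppf(0.975) + norm.ppf(0.85)) ** 2 / 0.3**2)
        assert sample_size_chisq(0.05, 0.3, 0.85, df=1) == n == 100

    def test_doubling_w_quarters_n(self):
        n1 = sample_size_chisq(0.05, 0.3, 0.85, df=1)
        n2 = sample_size_chisq(0.05, 0.6, 0.85, df=1)
        assert n1 / 4 - 2 <= n2 <= n1 / 4 + 2

    def test_minimality(self):
        from scipy.stats import chi2, ncx2

        n = sample_size_chisq(0.05, 0.3, 0.85, df=1)
        crit = chi2.ppf(0.95, 1)
        assert ncx2.sf(crit, 1, n * 0.09) >= 0.85
        assert ncx2.sf(crit, 1, (n - 1) * 0.09) < 0.85

    @pytest.mark.parametrize("bad", [dict(alpha=0), dict(effect_size_w=0), dict(power=1), dict(df=0)])
    def test_invalid_inputs(self, bad):
        kwargs = dict(alpha=0.05, effect_size_w=0.3, power=0.85, df=1)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            sample_size_chisq(**kwargs)


class TestEvaluateStudy:
    def test_single_reader_perfect_dataset(self):
        gold = pd.Series(["red", "yellow", "green", "red"], index=list("abcd"))
        responses = pd.DataFrame(
            {
                "reader_id": ["r1"] * 4,
                "image_id": list("abcd"),
                "response": ["red", "yellow", "green", "red"],
            }
        )
        ds = StudyDataset(gold=gold, responses=responses, reader_attrs=pd.DataFrame())
        report = evaluate_study(ds)
        assert (report["kappa"] == 1.0).all()

    def test_report_shape_and_precisions(self):
        # complete responses so every subgroup has both margins per category
        gold = pd.Series(["red", "yellow", "green"], index=["i1", "i2", "i3"])
        responses = pd.DataFrame(
            {
                "reader_id": ["r1"] * 3 + ["r2"] * 3,
                "image_id": ["i1", "i2", "i3"] * 2,
                "response": ["red", "yellow", "green", "red", "green", "yellow"],
            }
        )
        attrs = pd.DataFrame(
            {"group": ["student", "working"], "prior_grading": [False, True]},
            index=pd.Index(["r1", "r2"], name="reader_id"),
        )
        ds = StudyDataset(gold=gold, responses=responses, reader_attrs=attrs)
        report = evaluate_study(ds, by="group")
        assert set(report["subgroup"]) == {"all", "student", "working"}
        row = report[(report["subgroup"] == "all") & (report["category"] == "red")].iloc[0]
        assert row["kappa_3dp"] == f"{row['kappa']:.3f}"
        assert row["sensitivity_pct"] == int(100 * row["sensitivity"])

    def test_csv_round_trip(self, tmp_path):
        ds = small_dataset()
        paths = [str(tmp_path / f"{n}.csv") for n in ("gold", "resp", "readers")]
        write_study(ds, *paths)
        back = read_study(*paths)
        assert back.gold.sort_index().equals(ds.gold.sort_index())
        a = back.sorted_responses()
        b = ds.sorted_responses()
        pd.testing.assert_frame_equal(a, b)
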