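"""Risk-model loading, dosage harmonization, scoring, and the diagnosis contrast."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from radiotox.risk import (
    DosagePanel,
    MannWhitneyResult,
    RiskModel,
    RiskModelError,
    RiskVariant,
    STATUS_AMBIGUOUS_DROPPED,
    STATUS_AMBIGUOUS_KEPT,
    STATUS_DIRECT,
    STATUS_STRAND_FLIPPED,
    STATUS_STRAND_FLIPPED_SWAPPED,
    STATUS_SWAPPED,
    STATUS_UNMATCHED_DROPPED,
    compare_by_diagnosis,
    compute_scores,
    harmonize_dosages,
    load_risk_model,
)
from radiotox.simulate import draw_genotypes

from conftest import make_panel

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


class TestLoadRiskModel:
    def test_single_row_round_trips(self, tmp_path):
        p = tmp_path / "model.tsv"
        p.write_text(
            "variant_id\tchrom\tpos\trisk_allele\tother_allele\todds_ratio\teaf\n"
            "rs1\t1\t12345\tG\tT\t1.25\t0.4\n"
        )
        model = load_risk_model(p)
        assert len(model) == 1
        v = model.variants[0]
        assert (v.risk_allele, v.other_allele, v.odds_ratio, v.eaf) == ("G", "T", 1.25, 0.4)
        out = tmp_path / "roundtrip.tsv"
        model.to_tsv(out)
        assert load_risk_model(out).to_frame().equals(model.to_frame())

    def test_nonpositive_or_names_variant(self, tmp_path):
        p = tmp_path / "model.tsv"
        p.write_text(
            "variant_id\tchrom\tpos\trisk_allele\tother_allele\todds_ratio\n"
            "rs_bad\t1\t1\tG\tT\t0\n"
        )
        with pytest.raises(RiskModelError, match="rs_bad"):
            load_risk_model(p)

    @pytest.mark.parametrize(
        "risk,other,message",
        [("G", "G", "risk and other"), ("N", "T", "malformed"), ("G", "X", "malformed")],
    )
    def test_allele_validation(self, risk, other, message):
        with pytest.raises(RiskModelError, match=message):
            RiskVariant("rs1", "1", 1, risk, other, 1.1)

    def test_duplicate_id_rejected(self):
        v = RiskVariant("rs1", "1", 1, "G", "T", 1.1)
        with pytest.raises(RiskModelError, match="rs1"):
            RiskModel([v, v])

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "model.tsv"
        p.write_text("variant_id\tchrom\tpos\trisk_allele\n" "rs1\t1\t1\tG\n")
        with pytest.raises(RiskModelError, match="odds_ratio"):
            load_risk_model(p)


class TestHarmonization:
    def test_all_eight_orientations_classified(self):
        """Enumerate every panel orientation of a G/T variant against the model.

        For each the harmonized dosage must count risk-allele (G) copies;
        orientations consistent with neither strand are dropped.
        """
        model = RiskModel([RiskVariant("v", "1", 10, "G", "T", 1.2)])
        d = 0.6  # panel dosage, counts allele_b
        expected = {
            ("T", "G"): (STATUS_DIRECT, d),
            ("G", "T"): (STATUS_SWAPPED, 2 - d),
            ("A", "C"): (STATUS_STRAND_FLIPPED, d),  # rc(A,C) = (T,G)
            ("C", "A"): (STATUS_STRAND_FLIPPED_SWAPPED, 2 - d),
        }
        for a, b in itertools.permutations("ACGT", 2):
            panel = DosagePanel(
                sample_ids=["s"],
                variants=pd.DataFrame(
                    [{"variant_id": "v", "chrom": "1", "pos": 10, "allele_a": a, "allele_b": b}]
                ),
                dosage=np.array([[d]]),
            )
            out, report = harmonize_dosages(panel, model)
            status = report.loc[0, "status"]
            if (a, b) in expected:
                want_status, want_d = expected[(a, b)]
                assert status == want_status, (a, b)
                assert out.dosage[0, 0] == pytest.approx(want_d)
            else:
                assert status == STATUS_UNMATCHED_DROPPED, (a, b)
                assert out.n_variants == 0

    def test_palindromic_kept_by_exact_label_and_dropped_on_request(self):
        model = RiskModel([RiskVariant("v", "1", 10, "A", "T", 1.1)])
        panel = DosagePanel(
            sample_ids=["s"],
            variants=pd.DataFrame(
                [{"variant_id": "v", "chrom": "1", "pos": 10, "allele_a": "A", "allele_b": "T"}]
            ),
            dosage=np.array([[0.5]]),
        )
        out, report = harmonize_dosages(panel, model)
        assert report.loc[0, "status"] == STATUS_AMBIGUOUS_KEPT
        # panel counts T = other allele, so the dosage flips
        assert out.dosage[0, 0] == pytest.approx(1.5)
        out2, report2 = harmonize_dosages(panel, model, drop_ambiguous=True)
        assert report2.loc[0, "status"] == STATUS_AMBIGUOUS_DROPPED
        assert out2.n_variants == 0

    def test_unmatched_variant_dropped_without_error(self, tiny_model):
        panel = make_panel(tiny_model, np.array([[1.0, 0.5, 2.0]]))
        panel.variants.loc[0, "variant_id"] = "not_in_model"
        panel.variants.loc[0, "chrom"] = "9"  # break the chrom:pos fallback too
        out, report = harmonize_dosages(panel, tiny_model)
        assert report.set_index("variant_id").loc["v1", "status"] == STATUS_UNMATCHED_DROPPED
        assert out.n_variants == 2

    def test_chrom_pos_fallback_match(self, tiny_model):
        panel = make_panel(tiny_model, np.array([[1.0, 0.5, 2.0]]))
        panel.variants["variant_id"] = ["x1", "x2", "x3"]
        out, report = harmonize_dosages(panel, tiny_model)
        assert (report["status"] == STATUS_DIRECT).all()
        assert out.n_variants == 3

    def test_swap_involution_preserves_scores(self, tiny_model):
        """A panel stored as other-allele counts scores identically after flip."""
        rng = np.random.default_rng(5)
        d = rng.uniform(0, 2, size=(20, 3))
        direct, _ = harmonize_dosages(make_panel(tiny_model, d.copy(), "risk"), tiny_model)
        flipped, report = harmonize_dosages(make_panel(tiny_model, d.copy(), "other"), tiny_model)
        assert (report["status"] == STATUS_SWAPPED).all()
        s1 = compute_scores(direct, tiny_model).scores
        s2 = compute_scores(flipped, tiny_model).scores
        pd.testing.assert_frame_equal(s1, s2)


class TestComputeScores:
    def test_hand_example(self, tiny_model):
        panel = make_panel(tiny_model, np.array([[2.0, 1.0, 0.0]]))
        s = compute_scores(panel, tiny_model).scores
        assert s.loc["S0", "prs"] == pytest.approx(3.0)
        assert s.loc["S0", "wprs"] == pytest.approx(2 * 1.2 + 1 * 1.5 + 0 * 0.8)

    def test_unit_weights_make_wprs_equal_prs(self):
        model = RiskModel(
            [RiskVariant(f"v{i}", "1", i + 1, "G", "T", 1.0) for i in range(4)]
        )
        rng = np.random.default_rng(0)
        panel = make_panel(model, rng.uniform(0, 2, (10, 4)))
        s = compute_scores(panel, model).scores
        np.testing.assert_allclose(s["prs"], s["wprs"], rtol=0, atol=1e-12)

    def test_homozygous_sample_hits_upper_bound(self, tiny_model):
        panel = make_panel(tiny_model, np.full((1, 3), 2.0))
        s = compute_scores(panel, tiny_model)
        assert s.scores["prs"].iloc[0] == pytest.approx(2 * len(tiny_model))
        assert s.n_variants_used == len(tiny_model)

    def test_log_or_weight_scheme(self, tiny_model):
        panel = make_panel(tiny_model, np.array([[1.0, 1.0, 1.0]]))
        s = compute_scores(panel, tiny_model, weight_scheme="log_or").scores
        expected = np.log(1.2) + np.log(1.5) + np.log(0.8)
        assert s["wprs"].iloc[0] == pytest.approx(expected)

    def test_brute_force_oracle_on_random_panels(self, packaged_model):
        """Vectorized scores equal a naive per-sample, per-variant double loop."""
        rng = np.random.default_rng(123)
        variants = packaged_model.variants
        for _ in range(50):
            n_s = int(rng.integers(1, 8))
            n_v = int(rng.integers(1, 12))
            sub = RiskModel(list(rng.choice(variants, size=n_v, replace=False)))
            d = rng.uniform(0, 2, size=(n_s, n_v))
            panel = make_panel(sub, d)
            s = compute_scores(panel, sub).scores
            for i in range(n_s):
                prs = wprs = 0.0
                for j, v in enumerate(sub):
                    prs += d[i, j]
                    wprs += v.odds_ratio * d[i, j]
                assert abs(s["prs"].iloc[i] - prs) <= 1e-12
                assert abs(s["wprs"].iloc[i] - wprs) <= 1e-12

    def test_missing_dosage_imputed_from_eaf_and_counted(self, tiny_model):
        d = np.array([[np.nan, 1.0, 1.0], [1.0, 1.0, 1.0]])
        panel = make_panel(tiny_model, d)
        s = compute_scores(panel, tiny_model).scores
        # v1 has eaf 0.3 -> imputed dosage 0.6
        assert s.loc["S0", "prs"] == pytest.approx(0.6 + 2.0)
        assert s.loc["S0", "n_dosages_imputed"] == 1
        assert s.loc["S1", "n_dosages_imputed"] == 0

    def test_missing_dosage_falls_back_to_cohort_mean(self):
        model = RiskModel([RiskVariant("v", "1", 1, "G", "T", 1.0)])  # no eaf
        panel = make_panel(model, np.array([[np.nan], [0.5], [1.5]]))
        s = compute_scores(panel, model).scores
        assert s["prs"].iloc[0] == pytest.approx(1.0)

    def test_zero_retained_variants_errors(self, tiny_model):
        panel = make_panel(tiny_model, np.zeros((2, 3)))
        empty = DosagePanel(
            sample_ids=panel.sample_ids,
            variants=panel.variants.iloc[:0],
            dosage=np.empty((2, 0)),
        )
        with pytest.raises(ValueError, match="no variants"):
            compute_scores(empty, tiny_model)

    @given(
        delta=st.floats(min_value=0.01, max_value=1.0),
        col=st.integers(min_value=0, max_value=2),
    )
    @settings(max_examples=25, deadline=None)
    def test_monotonicity_in_single_dosage(self, delta, col):
        """Raising one dosage by delta raises prs by delta and wprs by w*delta."""
        model = RiskModel(
            [
                RiskVariant("a", "1", 1, "G", "T", 1.2),
                RiskVariant("b", "2", 2, "A", "C", 0.9),
                RiskVariant("c", "3", 3, "C", "T", 1.4),
            ]
        )
        base = np.full((1, 3), 0.5)
        bumped = base.copy()
        bumped[0, col] += delta
        s0 = compute_scores(make_panel(model, base), model).scores
        s1 = compute_scores(make_panel(model, bumped), model).scores
        w = model.variants[col].odds_ratio
        assert s1["prs"].iloc[0] - s0["prs"].iloc[0] == pytest.approx(delta)
        assert s1["wprs"].iloc[0] - s0["wprs"].iloc[0] == pytest.approx(w * delta)

    def test_dosage_clamp_tolerance(self, tiny_model):
        ok = make_panel(tiny_model, np.array([[2.0 + 5e-7, 0.0, -5e-7]]))
        assert ok.dosage.max() <= 2.0 and ok.dosage.min() >= 0.0
        with pytest.raises(ValueError, match="outside"):
            make_panel(tiny_model, np.array([[2.1, 0.0, 0.0]]))


class TestCompareByDiagnosis:
    def test_exact_enumeration_example(self):
        """Fully separated groups of 3: U=0 and exact two-sided p = 2/20."""
        res = compare_by_diagnosis([1, 2, 3, 4, 5, 6], [True, True, True, False, False, False])
        assert res.u == 0
        assert res.method == "exact"
        assert res.p == pytest.approx(0.1)

    def test_identical_tied_groups_give_p_one(self):
        res = compare_by_diagnosis([5.0, 5.0, 5.0, 5.0], [True, True, False, False])
        assert res.p == pytest.approx(1.0)
        assert res.method == "asymptotic"  # ties force the normal approximation

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            compare_by_diagnosis([1.0, 2.0], [True, True])

    def test_null_rejection_rate_near_nominal(self):
        """Same-distribution groups (n=200 each): rejection at .05 within binomial noise."""
        rng = np.random.default_rng(99)
        reject = 0
        n_rep = 400
        for _ in range(n_rep):
            x = rng.normal(size=400)
            flag = np.zeros(400, dtype=bool)
            flag[:200] = True
            reject += compare_by_diagnosis(x, flag).p < 0.05
        rate = reject / n_rep
        # 99% binomial band around 0.05 at 400 replicates
        assert 0.022 <= rate <= 0.078


def test_hwe_panel_scores_match_expectation(packaged_model):
    """Mean PRS over a large HWE cohort approximates 2 * sum(eaf)."""
    panel = draw_genotypes(packaged_model, 4000, seed=3)
    s = compute_scores(panel, packaged_model).scores
    expected = 2 * sum(v.eaf for v in packaged_model)
    se = np.sqrt(sum(2 * v.eaf * (1 - v.eaf) for v in packaged_model) / 4000)
    assert abs(s["prs"].mean() - expected) < 4 * se
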