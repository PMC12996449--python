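import numpy as np
import pandas as pd
import pytest
from scipy import stats

from circscape import pharmaco as ph
from circscape.errors import AnalysisError, ConfigurationError
from circscape.io import DrugResponseMatrix

from conftest import counts_frame


class TestWelchT:
    def test_textbook_example(self):
        t, df, p = ph.welch_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert df == pytest.approx(4.0)
        assert p == pytest.approx(0.021, abs=2e-3)

    def test_identical_samples_null(self):
        t, _, p = ph.welch_t([1, 2, 3], [3, 2, 1])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_equal_n_equal_var_matches_student(self, rng):
        x = rng.normal(0, 1, 30)
        y = x + 1.0  # identical sample variance, shifted mean
        t, df, p = ph.welch_t(x, y)
        t_s, p_s = stats.ttest_ind(x, y, equal_var=True)
        assert t == pytest.approx(t_s)
        assert df == pytest.approx(58.0)
        assert p == pytest.approx(p_s)

    def test_matches_scipy_welch(self, rng):
        x, y = rng.normal(0, 1, 12), rng.normal(1, 3, 25)
        t, _, p = ph.welch_t(x, y)
        t_s, p_s = stats.ttest_ind(x, y, equal_var=False)
        assert t == pytest.approx(t_s)
        assert p == pytest.approx(p_s)

    def test_too_small_group_rejected(self):
        with pytest.raises(AnalysisError):
            ph.welch_t([1], [2, 3])


def _drm(values, patients, drugs, orientation="higher_better"):
    return DrugResponseMatrix(
        pd.DataFrame(values, index=patients, columns=drugs), orientation
    )


class TestDrugAssociation:
    def test_hand_example_dss(self):
        patients = [f"p{i}" for i in range(6)]
        drm = _drm([[5], [6], [7], [9], [10], [11]], patients, ["d"])
        labels = pd.Series(["low"] * 3 + ["high"] * 3, index=patients)
        res = ph.drug_group_association(drm, labels)
        row = res.loc["d"]
        assert row["median_diff"] == pytest.approx(4.0)
        assert row["t"] == pytest.approx(-4.899, abs=1e-3)
        assert row["p"] == pytest.approx(0.008, abs=2e-3)
        assert row["significant"]
        assert row["favored"] == "high"

    def test_rule_is_conjunctive(self, rng):
        patients = [f"p{i}" for i in range(40)]
        vals = np.concatenate([rng.normal(0, 0.01, 20), rng.normal(0.5, 0.01, 20)])
        drm = _drm(vals[:, None], patients, ["d"])
        labels = pd.Series(["low"] * 20 + ["high"] * 20, index=patients)
        row = ph.drug_group_association(drm, labels).loc["d"]
        assert row["p"] < 1e-6 and abs(row["median_diff"]) < 1
        assert not row["significant"]

    def test_sparse_drug_skipped_with_note(self):
        patients = [f"p{i}" for i in range(5)]
        vals = [[1.0], [np.nan], [np.nan], [2.0], [3.0]]
        drm = _drm(vals, patients, ["d"])
        labels = pd.Series(["low", "low", "low", "high", "high"], index=patients)
        row = ph.drug_group_association(drm, labels).loc["d"]
        assert row["note"] == "too few responders"
        assert not row["significant"]

    def test_orientation_duality(self, rng):
        patients = [f"p{i}" for i in range(30)]
        vals = rng.normal(10, 2, size=(30, 4))
        vals[15:, 0] += 5
        labels = pd.Series(["low"] * 15 + ["high"] * 15, index=patients)
        dss = ph.drug_group_association(_drm(vals, patients, list("abcd")), labels)
        auc = ph.drug_group_association(
            _drm(-vals, patients, list("abcd"), "lower_better"), labels
        )
        pd.testing.assert_series_equal(dss["significant"], auc["significant"])
        pd.testing.assert_series_equal(dss["favored"], auc["favored"])
        np.testing.assert_allclose(dss["p"], auc["p"])


class TestTransferSignature:
    def _de_frame(self):
        return pd.DataFrame(
            {
                "baseMean": [10.0, 20.0, 30.0, 40.0],
                "log2FC": [3.0, -2.5, 2.2, 0.1],
                "FDR": [1e-5, 1e-4, 1e-3, 0.9],
            },
            index=["g1", "g2", "g3", "g4"],
        )

    def test_mean_expression_rule_is_binding(self):
        # g1, g2 are strongly DE but below the median mean (25): excluded
        sig = ph.build_transfer_signature(
            counts_frame(np.ones((4, 4), dtype=int), ["g1", "g2", "g3", "g4"]),
            pd.Series(["low", "low", "high", "high"], index=["s0", "s1", "s2", "s3"]),
            de_result=self._de_frame(),
        )
        assert list(sig.directions.index) == ["g3"]
        assert sig.directions.loc["g3"] == 1

    def test_all_null_raises(self, rng):
        counts = counts_frame(rng.poisson(20, size=(30, 40)))
        labels = pd.Series(["low"] * 20 + ["high"] * 20, index=counts.columns)
        with pytest.raises(AnalysisError, match="empty transfer signature"):
            ph.build_transfer_signature(counts, labels)

    def test_planted_signature_recovered(self, rng):
        n = 100
        counts = rng.poisson(50, size=(40, n)).astype(float)
        high = np.array([0] * 50 + [1] * 50)
        for i in range(8):  # planted |log2FC| = 2, high baseline
            counts[i] = rng.poisson(80 * 4.0**high)
        frame = counts_frame(counts.astype(int))
        labels = pd.Series(np.where(high, "high", "low"), index=frame.columns)
        sig = ph.build_transfer_signature(frame, labels)
        assert set(sig.directions.index) >= {f"f{i}" for i in range(8)}
        assert (sig.directions.loc[[f"f{i}" for i in range(8)]] == 1).all()


class TestAssignTransferLabels:
    def test_hand_vote_example(self):
        sig = ph.TransferSignature(
            pd.Series([1, 1, -1], index=["g1", "g2", "g3"]), 0.05, 1.0
        )
        # patient p0 sits above g1's median, below g2's, below g3's
        expr = counts_frame(
            [[5.0, 1, 1, 1], [1.0, 5, 5, 5], [1.0, 5, 5, 5]],
            ["g1", "g2", "g3"],
            ["p0", "p1", "p2", "p3"],
        )
        labels = ph.assign_transfer_labels(sig, expr)
        # votes for p0: g1 high, g2 low, g3 high (below median of a -1 gene)
        assert labels.loc["p0", "votes_high"] == 2
        assert labels.loc["p0", "votes_low"] == 1
        assert labels.loc["p0", "label"] == "high-like"

    def test_all_positive_above_median(self):
        sig = ph.TransferSignature(pd.Series([1, 1], index=["g1", "g2"]), 0.05, 1.0)
        expr = counts_frame([[9.0, 1, 2, 3], [9.0, 1, 2, 3]], ["g1", "g2"],
                            ["p0", "p1", "p2", "p3"])
        labels = ph.assign_transfer_labels(sig, expr)
        assert labels.loc["p0", "label"] == "high-like"

    def test_exact_median_abstains(self):
        sig = ph.TransferSignature(pd.Series([1], index=["g1"]), 0.05, 1.0)
        expr = counts_frame([[1.0, 2.0, 3.0]], ["g1"], ["p0", "p1", "p2"])
        labels = ph.assign_transfer_labels(sig, expr)
        assert labels.loc["p1", "abstain"] == 1
        assert labels.loc["p1", "label"] == "unassigned"

    def test_votes_partition_signature(self, rng):
        sig = ph.TransferSignature(
            pd.Series(rng.choice([1, -1], 9), index=[f"g{i}" for i in range(9)]), 0.05, 1.0
        )
        expr = counts_frame(rng.normal(0, 1, size=(9, 21)), [f"g{i}" for i in range(9)])
        labels = ph.assign_transfer_labels(sig, expr)
        total = labels["votes_high"] + labels["votes_low"] + labels["abstain"]
        assert (total == 9).all()

    def test_monotone_transform_invariance(self, rng):
        sig = ph.TransferSignature(
            pd.Series([1, -1, 1], index=["g0", "g1", "g2"]), 0.05, 1.0
        )
        expr = counts_frame(rng.normal(5, 2, size=(3, 30)), ["g0", "g1", "g2"])
        before = ph.assign_transfer_labels(sig, expr)
        transformed = expr.copy()
        transformed.iloc[0] = np.exp(transformed.iloc[0])      # strictly increasing
        transformed.iloc[1] = transformed.iloc[1] ** 3
        transformed.iloc[2] = 10 * transformed.iloc[2] + 2
        after = ph.assign_transfer_labels(sig, transformed)
        pd.testing.assert_frame_equal(before, after)

    def test_batch_shift_invariance(self, rng):
        """Additive per-gene shifts cannot move any patient across its gene median."""
        sig = ph.TransferSignature(
            pd.Series(rng.choice([1, -1], 15), index=[f"g{i}" for i in range(15)]), 0.05, 1.0
        )
        expr = counts_frame(rng.normal(0, 1, size=(15, 40)), [f"g{i}" for i in range(15)])
        shifted = expr + rng.normal(0, 3, size=(15, 1))
        pd.testing.assert_frame_equal(
            ph.assign_transfer_labels(sig, expr), ph.assign_transfer_labels(sig, shifted)
        )

    def test_absent_genes_dropped_with_warning(self, rng):
        sig = ph.TransferSignature(pd.Series([1, 1], index=["g0", "gX"]), 0.05, 1.0)
        expr = counts_frame(rng.normal(0, 1, size=(1, 10)), ["g0"])
        with pytest.warns(UserWarning, match="absent"):
            labels = ph.assign_transfer_labels(sig, expr)
        assert ((labels["votes_high"] + labels["votes_low"] + labels["abstain"]) == 1).all()


class TestValidateDrug:
    def _setup(self, rng, effect=-8.0, orientation="lower_better"):
        # AUC cohort: high-like responds better (lower AUC) when effect < 0
        patients = [f"v{i}" for i in range(40)]
        labels = pd.DataFrame(
            {"votes_high": 1, "votes_low": 0, "abstain": 0,
             "label": ["high-like"] * 20 + ["low-like"] * 20},
            index=patients,
        )
        vals = rng.normal(100, 2, 40)
        vals[:20] += effect
        drm = _drm(vals[:, None], patients, ["d"], orientation)
        return labels, drm

    def test_concordant_effect_validated(self, rng):
        labels, drm = self._setup(rng)
        out = ph.validate_drug_association(labels, drm, "d", "high")
        assert out["verdict"] == "validated"
        assert out["favored"] == "high"

    def test_flipped_sign_not_validated(self, rng):
        labels, drm = self._setup(rng, effect=+8.0)
        out = ph.validate_drug_association(labels, drm, "d", "high")
        assert out["p"] < 0.05
        assert out["verdict"] == "not validated"

    def test_direction_is_required(self, rng):
        labels, drm = self._setup(rng)
        with pytest.raises(ConfigurationError):
            ph.validate_drug_association(labels, drm, "d", "better")

    def test_lower_auc_means_better_response(self, rng):
        labels, drm = self._setup(rng, effect=-8.0, orientation="lower_better")
        out = ph.validate_drug_association(labels, drm, "d", "high")
        assert out["median_diff"] < 0  # high-like has lower AUC
        assert out["favored"] == "high"
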