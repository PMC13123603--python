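"""Bait normalization, contrasts, BH adjustment and response grouping."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from pulldown.differential import (
    DifferentialInteractome,
    assign_groups,
    bh_adjust,
    build_profiles,
    contrast,
    filter_protein_evidence,
    flag_significant,
    impute_protein_level,
    normalize_to_bait,
    run_contrasts,
)
from pulldown.quantify import ImputationParams


def bh_bruteforce(p):
    """Step-up BH transcription: sort, scale by m/rank, enforce monotone."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


def _abundance(rows):
    return pd.DataFrame(
        [
            {
                "protein_id": p,
                "cell_line": line,
                "condition_id": c,
                "replicate": r,
                "log2_abundance": v,
                "n_unique_peptides": npep,
            }
            for (p, line, c, r, v, npep) in rows
        ]
    )


class TestEvidenceFilter:
    def test_boundary(self):
        t = _abundance(
            [("A", "WT", "E1", 1, 10.0, 1), ("B", "WT", "E1", 1, 10.0, 2)]
        )
        kept, log = filter_protein_evidence(t)
        assert set(kept["protein_id"]) == {"B"}
        assert log["protein_id"].tolist() == ["A"]

    def test_empty(self):
        t = _abundance([]).reindex(
            columns=["protein_id", "cell_line", "condition_id", "replicate",
                     "log2_abundance", "n_unique_peptides"]
        )
        kept, _ = filter_protein_evidence(t)
        assert kept.empty


class TestProteinImputation:
    def test_complete_table_is_identity(self):
        t = _abundance(
            [("A", "WT", "E1", r, 10.0 + r, 3) for r in range(1, 5)]
        )
        out, log = impute_protein_level(t)
        pd.testing.assert_frame_equal(out, t)
        assert log.empty

    def test_left_censored_fill_within_replicate_bounds(self):
        """A protein missing in 3 of 4 replicates gets a left-censored
        draw from its own replicate's observed distribution."""
        rng = np.random.default_rng(0)
        rows = []
        for j in range(60):
            for r in range(1, 5):
                rows.append((f"P{j}", "WT", "E1", r, rng.normal(18, 2), 3))
        for r in range(1, 5):
            rows.append(("PX", "WT", "E1", r, 18.0 if r == 1 else np.nan, 3))
        t = _abundance(rows)
        out, _ = impute_protein_level(t, ImputationParams(deterministic_mode=True))
        filled = out[(out["protein_id"] == "PX")]
        assert filled["log2_abundance"].notna().all()
        obs = t[(t["protein_id"] != "PX")]
        for r in range(2, 5):
            rep_obs = obs.loc[obs["replicate"] == r, "log2_abundance"]
            mu, sigma = rep_obs.mean(), rep_obs.std(ddof=1)
            got = filled.loc[filled["replicate"] == r, "log2_abundance"].iloc[0]
            # deterministic midpoint of [mu-3s, mu-2s], within rounding of
            # the slightly different sample including PX's observed value
            assert mu - 3.2 * sigma <= got <= mu - 1.8 * sigma

    def test_deterministic_mode_reproducible(self):
        rows = [("A", "WT", "E1", r, 10.0 + r if r < 4 else np.nan, 3)
                for r in range(1, 5)]
        rows += [("B", "WT", "E1", r, 12.0 + 0.5 * r, 3) for r in range(1, 5)]
        rows += [("C", "WT", "E1", r, 9.0 + 0.2 * r, 3) for r in range(1, 5)]
        t = _abundance(rows)
        a, _ = impute_protein_level(t, ImputationParams(deterministic_mode=True))
        b, _ = impute_protein_level(t, ImputationParams(deterministic_mode=True))
        pd.testing.assert_frame_equal(a, b)


class TestBaitNormalization:
    def _table(self):
        return _abundance(
            [
                ("CDH1", "WT", "E1", 1, 20.0, 30),
                ("A", "WT", "E1", 1, 18.0, 3),
                ("B", "WT", "E1", 1, 16.0, 3),
                ("CDH1", "KO", "E1", 1, 21.0, 30),
                ("A", "KO", "E1", 1, 18.0, 3),
                ("B", "KO", "E1", 1, 17.0, 3),
            ]
        )

    def test_subtraction_and_bait_zero(self):
        out = normalize_to_bait(self._table(), "CDH1")
        a = out[(out["protein_id"] == "A") & (out["cell_line"] == "WT")]
        assert a["log2_abundance"].iloc[0] == pytest.approx(-2.0)
        bait = out[out["protein_id"] == "CDH1"]
        assert (bait["log2_abundance"] == 0).all()

    def test_idempotent_and_preserves_within_sample_differences(self):
        once = normalize_to_bait(self._table(), "CDH1")
        twice = normalize_to_bait(once, "CDH1")
        pd.testing.assert_frame_equal(once, twice)
        raw = self._table()
        for (line, c, r), grp in raw.groupby(["cell_line", "condition_id", "replicate"]):
            norm = once[(once["cell_line"] == line) & (once["replicate"] == r)]
            d_raw = grp.set_index("protein_id")["log2_abundance"]
            d_norm = norm.set_index("protein_id")["log2_abundance"]
            assert (d_raw["A"] - d_raw["B"]) == pytest.approx(
                d_norm["A"] - d_norm["B"]
            )

    def test_bait_missing_in_sample_errors(self):
        t = self._table()
        t.loc[
            (t["protein_id"] == "CDH1") & (t["cell_line"] == "KO"),
            "log2_abundance",
        ] = np.nan
        with pytest.raises(ValueError, match="KO"):
            normalize_to_bait(t, "CDH1")


class TestContrast:
    def _table(self, ko, wt):
        rows = []
        for r, v in enumerate(ko, 1):
            rows.append(("P1", "KO", "E1", r, float(v), 3))
        for r, v in enumerate(wt, 1):
            rows.append(("P1", "WT", "E1", r, float(v), 3))
        return _abundance(rows)

    def test_identical_samples_give_zero_fc_p_one(self):
        out = contrast(self._table([1, 2, 3], [1, 2, 3]), "KO", "E1")
        assert out["log2fc"].iloc[0] == 0.0
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_matches_closed_form_pooled_t(self):
        """KO {1,2,3} vs WT {3,4,5}: log2fc -2, pooled t with 4 df."""
        out = contrast(self._table([1, 2, 3], [3, 4, 5]), "KO", "E1")
        assert out["log2fc"].iloc[0] == pytest.approx(-2.0)
        sp = math.sqrt((2 * 1.0 + 2 * 1.0) / 4)  # pooled SD, both vars 1
        t = -2.0 / (sp * math.sqrt(2 / 3))
        p = 2 * sps.t.sf(abs(t), 4)
        assert out["p_value"].iloc[0] == pytest.approx(p, rel=1e-10)

    def test_single_replicate_arm_skipped(self):
        out = contrast(self._table([1], [3, 4, 5]), "KO", "E1")
        assert out.empty

    def test_zero_variance_differing_means_flagged(self):
        out = contrast(self._table([1, 1, 1], [2, 2, 2]), "KO", "E1")
        assert out["p_value"].iloc[0] == 0.0 and out["degenerate"].iloc[0]

    def test_welch_option(self):
        t = self._table([1.0, 2.0, 3.0, 4.0], [3.0, 3.1, 2.9, 3.0])
        pooled = contrast(t, "KO", "E1")["p_value"].iloc[0]
        welch = contrast(t, "KO", "E1", equal_var=False)["p_value"].iloc[0]
        assert pooled != welch


class TestBhAdjust:
    def test_worked_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = rng.uniform(0, 1, size=rng.integers(1, 40))
            assert np.max(np.abs(bh_adjust(p) - bh_bruteforce(p))) <= 1e-12


@given(
    st.lists(
        st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
        min_size=1,
        max_size=30,
    )
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_bh_property_matches_bruteforce_and_is_monotone(p):
    """Adjusted p-values equal the step-up transcription and preserve the
    ordering of the raw p-values."""
    adj = bh_adjust(p)
    assert np.max(np.abs(adj - bh_bruteforce(p))) <= 1e-12
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(adj[order]) >= -1e-15)


class TestFlagSignificant:
    @pytest.mark.parametrize(
        "fc, padj, expected",
        [(-1.5, 0.01, True), (-0.9, 0.001, False), (-2.0, 0.2, False), (1.0, 0.05, True)],
    )
    def test_threshold_rule(self, fc, padj, expected):
        df = pd.DataFrame({"log2fc": [fc], "p_value": [padj / 2], "p_adj": [padj]})
        assert flag_significant(df)["significant"].iloc[0] == expected

    def test_requires_adjusted_column(self):
        with pytest.raises(ValueError, match="adjust"):
            flag_significant(pd.DataFrame({"log2fc": [1.0], "p_value": [0.01]}))

    def test_raw_p_mode(self):
        df = pd.DataFrame({"log2fc": [2.0], "p_value": [0.01], "p_adj": [0.2]})
        assert flag_significant(df, use_adjusted=False)["significant"].iloc[0]


class TestProfiles:
    def _results(self, fcs, sigs, pid="A", ko="TMTC2"):
        return pd.DataFrame(
            {
                "protein_id": pid,
                "ko_line": ko,
                "condition_id": [f"E{i+1}" for i in range(len(fcs))],
                "log2fc": fcs,
                "significant": sigs,
            }
        )

    def test_uniform_profile(self):
        prof = build_profiles(self._results([-1.0] * 6, [True] * 6), {"A"})
        assert prof["avg_log2fc"].iloc[0] == pytest.approx(-1.0)
        assert prof["n_sig_conditions"].iloc[0] == 6

    def test_mixed_profile(self):
        prof = build_profiles(
            self._results([-2, -2, 0, 0, 0, 0], [True, True, False, False, False, False]),
            {"A"},
        )
        assert prof["avg_log2fc"].iloc[0] == pytest.approx(-2 / 3)
        assert prof["n_sig_conditions"].iloc[0] == 2

    def test_non_validated_protein_excluded(self):
        prof = build_profiles(self._results([-1.0] * 6, [True] * 6), {"OTHER"})
        assert prof.empty

    def test_partial_coverage_recorded(self):
        prof = build_profiles(self._results([-1.0] * 4, [True] * 4), {"A"})
        assert prof["n_conditions_covered"].iloc[0] == 4


class TestAssignGroups:
    def _profiles(self, centroids, n_each=3, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for g, cent in enumerate(centroids, 1):
            for j in range(n_each):
                pid = f"G{g}_{j}"
                for k, ko in enumerate(["K1", "K2", "K3", "K4"]):
                    rows.append(
                        {
                            "protein_id": pid,
                            "ko_line": ko,
                            "avg_log2fc": cent + noise * rng.normal(),
                            "n_sig_conditions": 0,
                        }
                    )
        return pd.DataFrame(rows)

    def test_exact_recovery_and_effect_ordering(self):
        prof = self._profiles([-3.5, -1.8, 0.0, 0.3, 1.8])
        out = assign_groups(prof, n_groups=5)
        lab = out.drop_duplicates("protein_id").set_index("protein_id")["group_label"]
        for g in range(1, 6):
            members = lab[lab.index.str.startswith(f"G{g}_")]
            assert (members == g).all()

    def test_fewer_profiles_than_groups_errors(self):
        prof = self._profiles([-1.0])
        with pytest.raises(ValueError, match="group"):
            assign_groups(prof[prof["protein_id"] == "G1_0"], n_groups=5)

    def test_identical_profiles_degenerate(self):
        prof = self._profiles([0.0] * 5)
        with pytest.raises(ValueError, match="degenerate"):
            assign_groups(prof, n_groups=5)

    def test_row_order_invariance(self):
        prof = self._profiles([-3.5, -1.8, 0.0, 0.3, 1.8], noise=0.05, seed=3)
        out1 = assign_groups(prof, n_groups=5)
        shuffled = prof.sample(frac=1.0, random_state=5).reset_index(drop=True)
        out2 = assign_groups(shuffled, n_groups=5)
        m1 = out1.drop_duplicates("protein_id").set_index("protein_id")["group_label"]
        m2 = out2.drop_duplicates("protein_id").set_index("protein_id")["group_label"]
        pd.testing.assert_series_equal(m1.sort_index(), m2.sort_index())


class TestModelEndToEnd:
    def test_recovers_planted_group_structure(self, small_labelfree):
        ab, truth = small_labelfree
        spec = truth.loc[truth["group_label"].notna(), "protein_id"].tolist()
        res = DifferentialInteractome(ab, spec).fit()
        prof = res.profiles.merge(
            truth[["protein_id", "group_label"]], on="protein_id",
            suffixes=("", "_true"),
        )
        planted = prof.groupby(["group_label_true", "ko_line"])["avg_log2fc"].median()
        assert planted.loc[(1, "TMTC2")] == pytest.approx(-3.4, abs=0.3)
        assert planted.loc[(5, "TMTC1-4")] == pytest.approx(2.4, abs=0.3)
        assert "group median avg_log2fc" in res.summary()
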