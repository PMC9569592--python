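"""Discretization, AIC scoring, Tabu structure learning, Bayesian CPT
estimation, likelihood-weighting inference and cross-fitted risk."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from fusionlab import clinical_bn as cb
from fusionlab import (
    GeneratorConfig,
    aic_score,
    discretize_clinical,
    estimate_parameters,
    exact_posterior,
    extract_malignancy_risk,
    generate_clinical,
    learn_structure,
    query_risk,
)


def _raw(rows):
    df = pd.DataFrame(rows, columns=["sex", "age", "tumor_size", "bethesda", "label"])
    df["sex"] = pd.Categorical(df["sex"], categories=["F", "M"])
    df["bethesda"] = pd.Categorical(df["bethesda"], categories=["II", "III", "IV", "V", "VI"])
    df["label"] = pd.Categorical(df["label"], categories=["benign", "malignant"])
    return df


class TestDiscretize:
    def test_band_boundaries(self):
        raw = _raw(
            [
                ("F", 45, 3.0, "IV", "benign"),
                ("M", 61, 0.5, "VI", "malignant"),
                ("F", 20, 1.5, "II", "benign"),
                ("F", 19, 4.2, "III", "benign"),
            ]
        )
        t = discretize_clinical(raw)
        assert list(t["age_band"]) == ["(20,45]", ">60", "<20", "<20"]
        assert list(t["size_band"]) == ["XL", "XS", "M", "XXL"]
        assert list(t["bethesda"]) == ["IV", "VI", "II", "III"]

    def test_rejects_nonpositive_with_row_index(self):
        raw = _raw([("F", 30, 1.0, "III", "benign"), ("M", -1, 1.0, "IV", "benign")])
        with pytest.raises(ValueError, match="age at rows \\[1\\]"):
            discretize_clinical(raw)
        raw2 = _raw([("F", 30, np.nan, "III", "benign")])
        with pytest.raises(ValueError, match="tumor_size"):
            discretize_clinical(raw2)


class TestAicScore:
    def test_single_binary_node_closed_form(self):
        df = pd.DataFrame({"A": pd.Categorical(["a"] * 6 + ["b"] * 4)})
        expected = 6 * np.log(0.6) + 4 * np.log(0.4) - 1
        assert aic_score({"A": ()}, df) == pytest.approx(expected, abs=1e-9)

    def test_decomposes_over_families(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "A": pd.Categorical(rng.integers(0, 3, 50)),
                "B": pd.Categorical(rng.integers(0, 2, 50)),
            }
        )
        dag = {"A": (), "B": ("A",)}
        total = aic_score(dag, df)
        parts = aic_score({"A": ()}, df[["A"]]) + (
            aic_score({"A": (), "B": ("A",)}, df) - aic_score({"A": ()}, df[["A"]])
        )
        assert total == pytest.approx(parts)

    def test_edge_between_independent_columns_rarely_helps(self):
        """The parameter penalty dominates the likelihood gain from a
        spurious edge: on independent columns the with-edge score loses
        on average and in almost all draws (AIC admits a small
        chi-square false-positive rate by construction)."""
        deltas = []
        for s in range(10):
            rng = np.random.default_rng(s)
            df = pd.DataFrame(
                {
                    "A": pd.Categorical(rng.integers(0, 3, 2000)),
                    "B": pd.Categorical(rng.integers(0, 3, 2000)),
                }
            )
            deltas.append(
                aic_score({"A": (), "B": ("A",)}, df)
                - aic_score({"A": (), "B": ()}, df)
            )
        assert np.mean(deltas) < 0
        assert np.mean(np.array(deltas) <= 0) >= 0.9

    def test_empty_data_rejected(self):
        df = pd.DataFrame({"A": pd.Categorical([], categories=["a", "b"])})
        with pytest.raises(ValueError, match="empty"):
            aic_score({"A": ()}, df)


class TestLearnStructure:
    def test_recovers_strong_dependence(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 3, 2000)
        b = (a + (rng.random(2000) < 0.2).astype(int)) % 3
        df = pd.DataFrame({"A": pd.Categorical(a), "B": pd.Categorical(b)})
        dag = learn_structure(df)
        edges = {(p, c) for c, pas in dag.items() for p in pas}
        assert edges in ({("A", "B")}, {("B", "A")})

    def test_independent_columns_give_aic_optimal_empty_graph(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {k: pd.Categorical(rng.integers(0, 3, 2000)) for k in "ABC"}
        )
        best = max(cb.all_dags(df.columns), key=lambda d: aic_score(d, df))
        assert sum(len(p) for p in best.values()) == 0
        assert learn_structure(df) == best

    @pytest.mark.parametrize("seed", range(4))
    def test_tabu_matches_exhaustive_on_three_nodes(self, seed):
        rng = np.random.default_rng(seed)
        n = 400
        a = rng.integers(0, 3, n)
        b = (a + (rng.random(n) < 0.3).astype(int)) % 3
        c = (b + (rng.random(n) < 0.4).astype(int)) % 3 if seed % 2 else rng.integers(0, 3, n)
        df = pd.DataFrame(
            {"A": pd.Categorical(a), "B": pd.Categorical(b), "C": pd.Categorical(c)}
        )
        best = max(aic_score(d, df) for d in cb.all_dags(df.columns))
        assert aic_score(learn_structure(df), df) == pytest.approx(best, abs=1e-9)

    def test_constant_dataset_warns_and_returns_empty(self):
        df = pd.DataFrame(
            {
                "A": pd.Categorical(["a"] * 20, categories=["a", "b"]),
                "B": pd.Categorical(["x"] * 20, categories=["x", "y"]),
            }
        )
        with pytest.warns(UserWarning, match="constant"):
            dag = learn_structure(df)
        assert dag == {"A": (), "B": ()}


class TestEstimateParameters:
    def test_posterior_mean_hand_value(self):
        df = pd.DataFrame({"A": pd.Categorical(["b"] * 10, categories=["a", "b"])})
        net = estimate_parameters({"A": ()}, df, iss=1.0)
        np.testing.assert_allclose(net.cpts["A"].ravel(), [0.5 / 11, 10.5 / 11])

    def test_zero_rows_gives_uniform_cpts(self):
        df = pd.DataFrame(
            {
                "A": pd.Categorical([], categories=["a", "b"]),
                "B": pd.Categorical([], categories=["x", "y", "z"]),
            }
        )
        net = estimate_parameters({"A": (), "B": ("A",)}, df, iss=1.0)
        np.testing.assert_allclose(net.cpts["A"], 0.5)
        np.testing.assert_allclose(net.cpts["B"], 1 / 3)

    def test_small_iss_approaches_mle_and_entries_positive(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"A": pd.Categorical(rng.integers(0, 2, 100))})
        mle = np.bincount(df["A"].cat.codes) / 100
        net = estimate_parameters({"A": ()}, df, iss=1e-9)
        np.testing.assert_allclose(net.cpts["A"].ravel(), mle, atol=1e-9)
        assert (net.cpts["A"] > 0).all()
        with pytest.raises(ValueError, match="iss"):
            estimate_parameters({"A": ()}, df, iss=0.0)

    def test_cpt_columns_sum_to_one(self, clinical_net):
        df = cb.sample_from_net(clinical_net, 500, seed=0)
        net = estimate_parameters(clinical_net.parents, df, iss=1.0)
        for node, cpt in net.cpts.items():
            np.testing.assert_allclose(cpt.sum(axis=0), 1.0, atol=1e-9)


class TestQueryRisk:
    def test_matches_enumeration_with_evidence(self, clinical_net):
        post = exact_posterior(clinical_net, "Risk", {"Bethesda": "VI"})["malignant"]
        est = query_risk(clinical_net, {"Bethesda": "VI"}, n_draws=10**5, seed=0)
        assert abs(est - post) < 0.01

    def test_empty_evidence_matches_marginal(self, clinical_net):
        marg = exact_posterior(clinical_net, "Risk", {})["malignant"]
        est = query_risk(clinical_net, {}, n_draws=10**5, seed=1)
        assert abs(est - marg) < 0.01

    def test_isolated_risk_ignores_evidence(self):
        net = cb.BayesNet(
            nodes=["Risk", "X"],
            domains={"Risk": ["benign", "malignant"], "X": ["lo", "hi"]},
            parents={"Risk": (), "X": ()},
            cpts={"Risk": np.array([[0.7], [0.3]]), "X": np.array([[0.5], [0.5]])},
        )
        with pytest.warns(UserWarning, match="Markov blanket"):
            est = query_risk(net, {"X": "hi"}, n_draws=20000, seed=0)
        assert est == pytest.approx(0.3, abs=0.02)

    def test_blanket_restriction_warns(self, clinical_net):
        with pytest.warns(UserWarning, match="Sex"):
            query_risk(clinical_net, {"Sex": "F", "Bethesda": "V"}, n_draws=100, seed=0)

    def test_rejects_bad_draw_count(self, clinical_net):
        with pytest.raises(ValueError):
            query_risk(clinical_net, {}, n_draws=0)


class TestExtractRisk:
    def test_contract_length_and_range(self, small_cohort):
        _, _, table, risk, _ = small_cohort
        assert len(risk) == len(table)
        assert np.all((risk >= 0) & (risk <= 1))

    def test_strong_signal_recovers_high_auc(self, study_cohort):
        _, _, table, risk, y = study_cohort
        assert roc_auc_score(y, risk) > 0.85

    def test_null_signal_gives_chance_auc(self):
        """Labels independent of the clinical variables: cross-fitted risk
        has no association with the label (mean AUC over seeds ~ 0.5)."""
        aucs = []
        for s in range(5):
            clin = generate_clinical(GeneratorConfig(seed=100 + s, clinical_signal=0.0))
            t = discretize_clinical(clin)
            r = extract_malignancy_risk(t, k=10, seed=s, method="exact")
            aucs.append(roc_auc_score((t["label"] == "malignant").astype(int), r))
        assert abs(np.mean(aucs) - 0.5) < 0.06

    def test_label_permutation_destroys_association(self, small_cohort):
        _, _, table, _, _ = small_cohort
        rng = np.random.default_rng(0)
        aucs = []
        for s in range(3):
            t = table.copy()
            t["label"] = pd.Categorical(
                t["label"].to_numpy()[rng.permutation(len(t))],
                categories=["benign", "malignant"],
            )
            r = extract_malignancy_risk(t, k=10, seed=s, method="exact")
            aucs.append(roc_auc_score((t["label"] == "malignant").astype(int), r))
        assert abs(np.mean(aucs) - 0.5) < 0.08

    def test_lw_and_exact_agree(self, small_cohort):
        _, _, table, _, _ = small_cohort
        r_lw = extract_malignancy_risk(table, k=5, n_draws=20000, seed=0, method="lw")
        r_ex = extract_malignancy_risk(table, k=5, seed=0, method="exact")
        assert np.max(np.abs(r_lw - r_ex)) < 0.03

    def test_rejects_small_k(self, small_cohort):
        _, _, table, _, _ = small_cohort
        with pytest.raises(ValueError):
            extract_malignancy_risk(table, k=1)
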