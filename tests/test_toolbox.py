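import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq
from scipy.stats import norm

from responsekit.datatypes import FeatureId, OmicDataset, Signature
from responsekit.feature_prep import dichotomize
from responsekit.models import train_signature
from responsekit.synthetic_data import simulate_tumor_cohort
from responsekit.toolbox import (
    INTERMEDIATE,
    RESISTANT,
    SENSITIVE,
    CutoffPair,
    apply_signature,
    assign_status,
    rank_compounds,
    rescale_probability,
    select_cutoffs,
    signature_coherence,
)


@pytest.fixture(scope="module")
def featdrug_signature(planted_panel, planted_response_matrix):
    labels = dichotomize(planted_response_matrix, "featdrug")
    lines = sorted(labels.labels)
    ds = planted_panel.datasets["expression_array"].subset_samples(lines)
    return train_signature(
        ds.values, labels.y(lines), ds.feature_keys(),
        ["expression_array"] * ds.n_features, "featdrug",
        gi50_threshold=labels.threshold, dynamic_range=1.0,
    ), labels, lines


class TestApplySignature:
    def test_resubstitution_recovers_training_classes(
        self, planted_panel, featdrug_signature
    ):
        sig, labels, lines = featdrug_signature
        profiles = {
            "expression_array":
                planted_panel.datasets["expression_array"].subset_samples(lines)
        }
        probs = apply_signature(sig, profiles)
        correct = np.mean(
            [
                (probs[s] > 0.5) == (labels.labels[s] == "sensitive")
                for s in lines
            ]
        )
        assert correct >= 0.9

    def test_mean_profile_probability_between_class_means(
        self, planted_panel, featdrug_signature
    ):
        sig, labels, lines = featdrug_signature
        ds = planted_panel.datasets["expression_array"].subset_samples(lines)
        mean_profile = OmicDataset(
            "expression_array", list(ds.feature_ids), ["mean_tumor"],
            ds.values.mean(axis=0, keepdims=True),
        )
        p_mean = apply_signature(
            sig, {"expression_array": mean_profile}
        ).iloc[0]
        probs = apply_signature(sig, {"expression_array": ds})
        p_sens = np.mean([probs[s] for s in lines
                          if labels.labels[s] == "sensitive"])
        p_res = np.mean([probs[s] for s in lines
                         if labels.labels[s] == "resistant"])
        assert p_res < p_mean < p_sens

    def test_insufficient_overlap_refused(
        self, planted_panel, featdrug_signature
    ):
        sig, _, lines = featdrug_signature
        ds = planted_panel.datasets["expression_array"].subset_samples(lines)
        n_half = len(sig.model_payload["feature_keys"]) // 2
        keep = [
            i for i, k in enumerate(ds.feature_keys())
            if k not in set(sig.model_payload["feature_keys"][n_half:])
        ]
        half = ds.subset_features(keep)
        with pytest.raises(ValueError, match="%"):
            apply_signature(sig, {"expression_array": half})

    def test_tumor_cohort_responders_score_higher(
        self, planted_panel, featdrug_signature
    ):
        sig, _, _ = featdrug_signature
        profiles, truth = simulate_tumor_cohort(
            planted_panel, "featdrug", n_patients=100,
            responder_fraction=0.3, seed=11,
        )
        probs = apply_signature(
            sig, {"expression_array": profiles["expression_array"]}
        )
        assert probs[truth].mean() > probs[~truth].mean() + 0.2


def _mixture_sample(rng, means, sd, n_per):
    return np.clip(
        np.concatenate([rng.normal(m, sd, n_per) for m in means]), 0, 1
    )


def _analytic_intersection(m1, m2, sd):
    return brentq(
        lambda x: norm.pdf(x, m1, sd) - norm.pdf(x, m2, sd), m1, m2
    )


class TestSelectCutoffs:
    def test_three_component_recovery(self):
        # equal weights/sds: intersections at the midpoints 0.35 and 0.65
        assert _analytic_intersection(0.2, 0.5, 0.05) == pytest.approx(0.35)
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            p = _mixture_sample(rng, (0.2, 0.5, 0.8), 0.05, 100)
            cp = select_cutoffs(p, seed=seed)
            ok += (
                abs(cp.cutoff1 - 0.35) <= 0.05
                and abs(cp.cutoff2 - 0.65) <= 0.05
            )
        assert ok >= 18

    def test_bimodal_cutoff2_near_midpoint(self):
        rng = np.random.default_rng(5)
        p = _mixture_sample(rng, (0.2, 0.8), 0.05, 150)
        cp = select_cutoffs(p, seed=0)
        assert cp.n_components == 2
        assert abs(cp.cutoff2 - 0.5) <= 0.05
        assert cp.cutoff1 < cp.cutoff2

    def test_degenerate_distribution_falls_back(self):
        cp = select_cutoffs(np.full(50, 0.4), seed=0)
        assert cp.fallback == "unimodal"
        assert 0 <= cp.cutoff1 < cp.cutoff2 <= 1

    def test_unimodal_flagged_with_quantile_cutoffs(self):
        rng = np.random.default_rng(3)
        p = np.clip(rng.normal(0.5, 0.08, 300), 0, 1)
        cp = select_cutoffs(p, seed=0)
        if cp.fallback == "unimodal":
            assert cp.cutoff1 == pytest.approx(np.quantile(p, 0.25), abs=1e-9)
            assert cp.cutoff2 == pytest.approx(np.quantile(p, 0.75), abs=1e-9)

    def test_needs_thirty_values(self):
        with pytest.raises(ValueError, match="30"):
            select_cutoffs(np.linspace(0, 1, 10))


class TestStatusAndRescale:
    CP = CutoffPair("d", 0.3, 0.7, 2, 0.0)

    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.3, RESISTANT),  # boundary belongs to lower band
            (0.5, INTERMEDIATE),
            (0.7, INTERMEDIATE),
            (0.71, SENSITIVE),
            (1.0, SENSITIVE),
            (0.0, RESISTANT),
        ],
    )
    def test_assignment(self, p, expected):
        assert assign_status(p, self.CP) == expected

    def test_anchor_points(self):
        cp = CutoffPair("d", 0.5, 0.75, 2, 0.0)
        assert rescale_probability(0.5, cp) == pytest.approx(1 / 3)
        assert rescale_probability(0.75, cp) == pytest.approx(2 / 3)
        assert rescale_probability(0.0, cp) == 0.0
        assert rescale_probability(1.0, cp) == 1.0
        assert rescale_probability(0.625, cp) == pytest.approx(0.5)

    def test_strictly_increasing_and_consistent_with_status(self):
        cp = self.CP
        grid = np.linspace(0, 1, 201)
        vals = [rescale_probability(p, cp) for p in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        for p, v in zip(grid, vals):
            status = assign_status(p, cp)
            if status == RESISTANT:
                assert v <= 1 / 3 + 1e-12
            elif status == INTERMEDIATE:
                assert 1 / 3 - 1e-12 < v <= 2 / 3 + 1e-12
            else:
                assert v > 2 / 3 - 1e-12


def _sig(compound, mean_auc, dynamic_range):
    return Signature(
        compound_id=compound, method="lssvm", data_types_used=["expression_array"],
        selected_features=[], hyperparameters={},
        per_split_auc=[mean_auc], mean_auc=mean_auc,
        gi50_threshold=7.0, dynamic_range=dynamic_range,
    )


class TestRankCompounds:
    CUTS = {
        c: CutoffPair(c, 0.3, 0.7, 2, 0.0)
        for c in ("dA", "dB", "dC", "dX")
    }

    def test_equal_probability_broken_by_dynamic_range(self):
        probs = pd.DataFrame(
            {"dA": [0.8], "dB": [0.8]}, index=["pat1"]
        )
        sigs = {"dA": _sig("dA", 0.8, 1.0), "dB": _sig("dB", 0.8, 2.0)}
        rep = rank_compounds(probs, sigs, self.CUTS)
        ranked = rep.per_patient.sort_values("rank")["compound"].tolist()
        assert ranked == ["dB", "dA"]  # larger dynamic range first

    def test_auc_floor_excludes(self):
        probs = pd.DataFrame({"dA": [0.9], "dB": [0.9]}, index=["p"])
        sigs = {"dA": _sig("dA", 0.65, 1.0), "dB": _sig("dB", 0.75, 1.0)}
        rep = rank_compounds(probs, sigs, self.CUTS)
        assert set(rep.per_patient["compound"]) == {"dB"}

    def test_prob_floor_excludes_compound_cohortwide(self):
        probs = pd.DataFrame(
            {"dA": [0.9, 0.2], "dX": [0.6, 0.5]}, index=["p1", "p2"]
        )
        sigs = {"dA": _sig("dA", 0.8, 1.0), "dX": _sig("dX", 0.9, 1.0)}
        rep = rank_compounds(probs, sigs, self.CUTS)
        assert "dX" not in set(rep.per_patient["compound"])

    def test_empty_report_explains(self):
        probs = pd.DataFrame({"dA": [0.2]}, index=["p"])
        sigs = {"dA": _sig("dA", 0.6, 1.0)}
        rep = rank_compounds(probs, sigs, self.CUTS)
        assert rep.per_patient.empty and "no compound" in rep.note

    def test_deterministic_and_order_invariant(self, rng):
        patients = [f"p{i}" for i in range(8)]
        comps = ["dA", "dB", "dC"]
        probs = pd.DataFrame(
            rng.random((8, 3)), index=patients, columns=comps
        )
        sigs = {c: _sig(c, 0.8, i + 1.0) for i, c in enumerate(comps)}
        probs.iloc[0] = 0.9  # force the prob floor to pass
        r1 = rank_compounds(probs, sigs, self.CUTS)
        shuffled = probs[["dC", "dA", "dB"]].sample(frac=1, random_state=4)
        r2 = rank_compounds(shuffled, sigs, self.CUTS)
        m1 = r1.per_patient.sort_values(["patient", "rank"]).reset_index(drop=True)
        m2 = r2.per_patient.sort_values(["patient", "rank"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(m1, m2)

    def test_percent_sensitive_matches_status_fraction(self, rng):
        patients = [f"p{i}" for i in range(30)]
        probs = pd.DataFrame({"dA": rng.random(30)}, index=patients)
        probs.iloc[0] = 0.95
        sigs = {"dA": _sig("dA", 0.8, 1.0)}
        rep = rank_compounds(probs, sigs, self.CUTS)
        frac = (rep.per_patient["status"] == SENSITIVE).mean()
        assert rep.percent_sensitive["dA"] == pytest.approx(100 * frac)


class TestSignatureCoherence:
    def _expr(self, values, genes):
        return OmicDataset(
            "expression_array", [FeatureId(g) for g in genes],
            [f"s{i}" for i in range(values.shape[0])], values,
        )

    def test_identical_matrices_give_unit_jaccard(self, rng):
        n, g = 30, 12
        latent = rng.standard_normal((n, 3))
        load = rng.standard_normal((3, g))
        X = latent @ load + 0.3 * rng.standard_normal((n, g))
        genes = [f"G{i}" for i in range(g)]
        ds = self._expr(X, genes)
        res = signature_coherence(genes[:8], ds, ds, n_perm=99, seed=0)
        assert res.jaccard == 1.0

    def test_permuted_tumors_break_coherence(self, rng):
        n, g = 40, 30
        latent = rng.standard_normal((n, 2))
        load = rng.standard_normal((2, g))
        X = latent @ load + 0.5 * rng.standard_normal((n, g))
        genes = [f"G{i}" for i in range(g)]
        cells = self._expr(X, genes)
        perm = np.column_stack(
            [rng.permutation(X[:, j]) for j in range(g)]
        )
        tumors = self._expr(perm, genes)
        res = signature_coherence(genes[:10], cells, tumors, n_perm=199,
                                  seed=1)
        assert res.p_value > 0.05

    def test_shared_coregulation_block_is_significant(self, rng):
        """Only the signature block is co-regulated in *both* cohorts.

        The remaining genes carry cohort-specific co-regulation, so random
        gene sets pick up edges present in one matrix but not the other.
        """
        n, g = 50, 40
        sig_genes = [f"G{i}" for i in range(10)]
        all_genes = [f"G{i}" for i in range(g)]

        def cohort(seed, private_block):
            r = np.random.default_rng(seed)
            X = r.standard_normal((n, g))
            factor = r.standard_normal(n)
            X[:, :10] += 2.0 * factor[:, None]  # shared signature block
            pf = r.standard_normal(n)
            X[:, private_block] += 2.0 * pf[:, None]  # cohort-specific
            return self._expr(X, all_genes)

        cells = cohort(1, slice(10, 25))
        tumors = cohort(2, slice(25, 40))
        res = signature_coherence(
            sig_genes, cells, tumors, n_perm=199, seed=2
        )
        assert res.p_value <= 0.01
        assert res.jaccard > 0.5

    def test_too_few_genes_refused(self, rng):
        ds = self._expr(rng.standard_normal((10, 6)),
                        [f"G{i}" for i in range(6)])
        with pytest.raises(ValueError, match=">=5"):
            signature_coherence(["G0", "G1"], ds, ds)
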