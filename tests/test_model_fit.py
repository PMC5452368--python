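import numpy as np
import pytest

from mpapredict.ct_data import (
    GenePanel,
    HOUSEKEEPING_GENE,
    PANEL_GENES,
    ResponseLabel,
)
from mpapredict.ddct import FoldChangeProfile
from mpapredict.model_fit import (
    StepwiseConfig,
    TrainingSet,
    derive_boundary,
    fit_prediction_model,
    stepwise_select,
)
from mpapredict.scoring import predict_index, published_model
from mpapredict.simulate import SyntheticConfig, generate_cohort


def _training_set(profiles, dummies):
    labels = [ResponseLabel.POOR if d else ResponseLabel.GOOD for d in dummies]
    return TrainingSet(profiles=tuple(profiles), responses=tuple(labels))


def _linear_training_set(rng, n=40, intercept=-5.0, coef_scale=0.1, pivot_coef=2.0):
    """Noise-free linear construction: binary responses that are *exactly*
    an affine function of the fold profiles.  15 genes get random small
    coefficients and random folds; the 16th fold is solved so that
    intercept + Σ coef·fold equals the 0/1 response with zero residual.
    The generating coefficients are the unique OLS solution."""
    genes = list(PANEL_GENES)
    coefs = dict(zip(genes[:15], rng.uniform(-coef_scale, coef_scale, 15)))
    coefs[genes[15]] = pivot_coef
    y = np.array([0.0] * (n // 2) + [1.0] * (n - n // 2))
    profiles = []
    for i in range(n):
        folds = dict(zip(genes[:15], rng.uniform(0.5, 2.0, 15)))
        partial = intercept + sum(coefs[g] * folds[g] for g in genes[:15])
        folds[genes[15]] = (y[i] - partial) / pivot_coef
        assert folds[genes[15]] > 0
        profiles.append(FoldChangeProfile(patient_id=f"P{i}", fold=folds))
    return _training_set(profiles, y), intercept, coefs


class TestDeriveBoundary:
    def test_seventeen_good_five_poor_give_023(self):
        responses = [ResponseLabel.GOOD] * 17 + [ResponseLabel.POOR] * 5
        b = derive_boundary(responses)
        assert b == pytest.approx(5 / 22)
        assert round(b, 2) == 0.23

    @pytest.mark.parametrize(
        "responses, expected",
        [
            ([ResponseLabel.GOOD] * 4, 0.0),
            ([ResponseLabel.GOOD, ResponseLabel.POOR], 0.5),
            ([ResponseLabel.POOR] * 3, 1.0),
        ],
    )
    def test_small_cases(self, responses, expected):
        assert derive_boundary(responses) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            derive_boundary([])

    def test_always_inside_unit_interval(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 40))
            resp = [
                ResponseLabel.POOR if rng.random() < 0.5 else ResponseLabel.GOOD
                for _ in range(n)
            ]
            b = derive_boundary(resp)
            assert 0.0 <= b <= 1.0
            if 0.0 < b < 1.0:
                assert len(set(resp)) == 2


class TestOlsFit:
    def test_exact_recovery_on_noise_free_linear_data(self, rng):
        train, intercept, coefs = _linear_training_set(rng)
        model = fit_prediction_model(train, genes=PANEL_GENES)
        # Independent oracle: normal-equations solve.
        X = train.design(PANEL_GENES)
        beta = np.linalg.solve(X.T @ X, X.T @ train.dummies)
        assert model.intercept == pytest.approx(intercept, abs=1e-8)
        assert model.intercept == pytest.approx(beta[0], abs=1e-8)
        for j, g in enumerate(PANEL_GENES, start=1):
            assert model.coefficients[g] == pytest.approx(coefs[g], abs=1e-8)
            assert model.coefficients[g] == pytest.approx(beta[j], abs=1e-8)
        assert model.boundary == pytest.approx(0.5)

    def test_residuals_orthogonal_to_design(self, rng):
        profiles = [
            FoldChangeProfile(
                patient_id=f"P{i}",
                fold=dict(zip(PANEL_GENES, rng.uniform(0.2, 3.0, 16))),
            )
            for i in range(60)
        ]
        y = (rng.random(60) < 0.3).astype(float)
        train = _training_set(profiles, y)
        model = fit_prediction_model(train, genes=PANEL_GENES)
        X = train.design(PANEL_GENES)
        beta = np.array([model.intercept] + [model.coefficients[g] for g in PANEL_GENES])
        resid = train.dummies - X @ beta
        assert np.max(np.abs(X.T @ resid)) < 1e-8

    def test_constant_response_flagged_degenerate(self, rng):
        profiles = [
            FoldChangeProfile(
                patient_id=f"P{i}",
                fold=dict(zip(PANEL_GENES, rng.uniform(0.2, 3.0, 16))),
            )
            for i in range(10)
        ]
        train = _training_set(profiles, np.zeros(10))
        model = fit_prediction_model(train, genes=PANEL_GENES)
        assert model.degenerate
        assert model.intercept == 0.0
        assert all(c == 0.0 for c in model.coefficients.values())

    def test_permutation_invariance(self, rng):
        train, *_ = _linear_training_set(rng, n=30)
        perm = rng.permutation(len(train))
        shuffled = TrainingSet(
            profiles=tuple(train.profiles[i] for i in perm),
            responses=tuple(train.responses[i] for i in perm),
        )
        m1 = fit_prediction_model(train, genes=PANEL_GENES)
        m2 = fit_prediction_model(shuffled, genes=PANEL_GENES)
        assert m1.intercept == pytest.approx(m2.intercept, abs=1e-10)
        for g in PANEL_GENES:
            assert m1.coefficients[g] == pytest.approx(m2.coefficients[g], abs=1e-10)

    def test_collinear_design_names_genes(self, rng):
        profiles = []
        for i in range(30):
            folds = dict(zip(PANEL_GENES[:3], rng.uniform(0.2, 3.0, 3)))
            folds["IFIT5"] = folds["IRF7"]  # exact duplicate column
            profiles.append(FoldChangeProfile(patient_id=f"P{i}", fold=folds))
        y = (rng.random(30) < 0.4).astype(float)
        train = _training_set(profiles, y)
        with pytest.raises(np.linalg.LinAlgError, match="IFIT5"):
            fit_prediction_model(train, genes=["IRF7", "IFIT1", "IFIT5"])

    def test_insufficient_patients_rejected(self, rng):
        profiles = [
            FoldChangeProfile(
                patient_id=f"P{i}",
                fold=dict(zip(PANEL_GENES, rng.uniform(0.2, 3.0, 16))),
            )
            for i in range(10)
        ]
        train = _training_set(profiles, (rng.random(10) < 0.5).astype(float))
        with pytest.raises(ValueError, match="insufficient"):
            fit_prediction_model(train, genes=PANEL_GENES)

    def test_closed_loop_with_published_model(self, rng):
        """Data generated exactly by the published index is refit to the
        published coefficients."""
        pub = published_model("formula_text")
        genes = list(pub.genes)
        others = [g for g in genes if g != "IFIT5"]
        profiles, dummies = [], []
        for i in range(40):
            y = float(i % 2)
            folds = dict(zip(others, rng.uniform(0.98, 1.02, 15)))
            partial = pub.intercept + sum(pub.coefficients[g] * folds[g] for g in others)
            folds["IFIT5"] = (partial - y) / 1.44
            assert folds["IFIT5"] > 0
            profiles.append(FoldChangeProfile(patient_id=f"P{i}", fold=folds))
            dummies.append(y)
        train = _training_set(profiles, dummies)
        model = fit_prediction_model(train, genes=genes)
        assert model.intercept == pytest.approx(pub.intercept, abs=1e-8)
        for g in genes:
            assert model.coefficients[g] == pytest.approx(pub.coefficients[g], abs=1e-8)


def _selection_problem(n_patients=200, seed=11):
    cohort, truth = generate_cohort(SyntheticConfig(n_patients=n_patients, seed=seed))
    panel = GenePanel(
        predictor_genes=truth.candidate_genes, housekeeping_gene=HOUSEKEEPING_GENE
    )
    return TrainingSet.from_cohort(cohort, panel=panel), truth


class TestStepwiseSelect:
    def test_recovers_informative_genes(self):
        train, truth = _selection_problem()
        config = StepwiseConfig(candidate_genes=truth.candidate_genes, seed=11)
        result = stepwise_select(train, config)
        assert len(result.selected_genes) == 16
        recovered = set(result.selected_genes) & set(truth.informative_genes)
        assert len(recovered) >= 14

    def test_same_seed_gives_identical_result(self):
        train, truth = _selection_problem(n_patients=80, seed=5)
        config = StepwiseConfig(candidate_genes=truth.candidate_genes, seed=5)
        r1 = stepwise_select(train, config)
        r2 = stepwise_select(train, config)
        assert r1.selected_genes == r2.selected_genes
        assert [t.criterion for t in r1.trace] == [t.criterion for t in r2.trace]

    def test_candidates_equal_panel_size_skips_sweep(self):
        train, truth = _selection_problem(n_patients=80, seed=5)
        sixteen = truth.informative_genes
        config = StepwiseConfig(candidate_genes=sixteen, panel_size=16, seed=5)
        result = stepwise_select(train, config)
        actions = {t.action for t in result.trace}
        assert "swap_in" not in actions and "swap_out" not in actions
        assert "drop" in actions
        assert set(result.selected_genes) == set(sixteen)

    def test_selection_stays_within_candidates_and_trace_bounded(self):
        train, truth = _selection_problem(n_patients=80, seed=5)
        config = StepwiseConfig(candidate_genes=truth.candidate_genes, seed=5)
        result = stepwise_select(train, config)
        assert set(result.selected_genes) <= set(truth.candidate_genes)
        refits = [t for t in result.trace if t.action in ("start", "swap_in", "drop")]
        assert len(refits) <= config.max_sweeps + config.panel_size + 1

    def test_single_class_rejected(self, rng):
        profiles = [
            FoldChangeProfile(
                patient_id=f"P{i}",
                fold=dict(zip(PANEL_GENES, rng.uniform(0.2, 3.0, 16))),
            )
            for i in range(20)
        ]
        train = _training_set(profiles, np.zeros(20))
        with pytest.raises(ValueError, match="both response classes"):
            stepwise_select(train, StepwiseConfig(candidate_genes=PANEL_GENES, seed=0))

    def test_panel_size_exceeding_candidates_rejected(self):
        with pytest.raises(ValueError, match="panel_size"):
            StepwiseConfig(candidate_genes=PANEL_GENES[:4], panel_size=5)

    @pytest.mark.parametrize("metric", ["abs_z", "aic_delta"])
    def test_alternative_influence_metrics_run(self, metric):
        train, truth = _selection_problem(n_patients=60, seed=3)
        config = StepwiseConfig(
            candidate_genes=truth.informative_genes[:6] + truth.decoy_genes[:2],
            panel_size=4,
            seed=3,
            influence_metric=metric,
        )
        result = stepwise_select(train, config)
        assert len(result.selected_genes) == 4
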