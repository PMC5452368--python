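"""Model training: dummy-coded regression, boundary, stepwise selection.

The prediction model is trained as a linear probability model: the 0/1
dummy-coded response (good = 0, poor = 1) is regressed by ordinary least
squares on the per-gene fold changes, and the decision boundary is the
mean of the training dummies — for 17 good and 5 poor responders,
5/22 ≈ 0.23.  The final index must be linear and thresholded at that
mean, which is only coherent for OLS; logistic regression enters solely
as the influence-ranking engine inside the stepwise gene-selection
procedure, mirroring the original analysis's mixed use of the two.

The stepwise procedure reconstructed here starts from a random draw of
``panel_size`` genes out of the candidate pool, repeatedly replaces the
minimum-influence gene with a not-yet-tried candidate until every
candidate has been used (the *sweep* phase), then strips the
minimum-influence gene one at a time down to a single gene (the
*backward* phase), recording a selection criterion (AIC of the logistic
fit) at every panel visited.  The procedure as originally described
leaves the influence statistic and the panel-size policy open; both are
configuration here, and the full trace is returned so any alternative
criterion can be recomputed.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Optional, Sequence, Union

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .ct_data import Cohort, GenePanel, ResponseLabel
from .ddct import FoldChangeProfile, cohort_fold_changes
from .scoring import PredictionModel

__all__ = [
    "TrainingSet",
    "StepwiseConfig",
    "TraceStep",
    "SelectionResult",
    "derive_boundary",
    "fit_prediction_model",
    "stepwise_select",
    "write_trace",
]


@dataclass
class TrainingSet:
    """Paired fold-change profiles and observed responses."""

    profiles: tuple[FoldChangeProfile, ...]
    responses: tuple[ResponseLabel, ...]

    def __post_init__(self) -> None:
        self.profiles = tuple(self.profiles)
        self.responses = tuple(self.responses)
        if len(self.profiles) != len(self.responses):
            raise ValueError(
                f"{len(self.profiles)} profiles but {len(self.responses)} responses"
            )

    def __len__(self) -> int:
        return len(self.profiles)

    @property
    def dummies(self) -> np.ndarray:
        return np.array([r.dummy for r in self.responses], dtype=float)

    def design(self, genes: Sequence[str]) -> np.ndarray:
        """n × (1 + p) design matrix: intercept column then fold changes."""
        X = np.empty((len(self.profiles), len(genes) + 1))
        X[:, 0] = 1.0
        for j, gene in enumerate(genes, start=1):
            for i, prof in enumerate(self.profiles):
                try:
                    X[i, j] = prof.fold[gene]
                except KeyError:
                    raise KeyError(
                        f"profile of patient {prof.patient_id!r} lacks gene {gene!r}"
                    ) from None
        return X

    @classmethod
    def from_cohort(
        cls, cohort: Cohort, panel: Optional[GenePanel] = None
    ) -> "TrainingSet":
        """Build a training set from a cohort whose records carry responses."""
        profiles = cohort_fold_changes(cohort, panel=panel)
        responses = []
        for rec in cohort.records:
            if rec.actual_response is None:
                raise ValueError(
                    f"patient {rec.patient_id!r} lacks actual_response; cannot train"
                )
            responses.append(rec.actual_response)
        return cls(profiles=tuple(profiles), responses=tuple(responses))


def derive_boundary(responses: Sequence[ResponseLabel]) -> float:
    """Decision boundary: the mean of the dummy-coded responses.

    Equals (#poor)/n, returned at full precision (0.2272… for 17 good and
    5 poor; displayed as 0.23).
    """
    if len(responses) == 0:
        raise ValueError("cannot derive a boundary from zero responses")
    return sum(r.dummy for r in responses) / len(responses)


def _collinear_genes(X: np.ndarray, genes: Sequence[str]) -> list[str]:
    """Genes whose fold-change column is (nearly) linearly dependent on
    the intercept and the preceding columns."""
    bad = []
    for j in range(1, X.shape[1]):
        sub = X[:, : j + 1]
        if np.linalg.matrix_rank(sub) < sub.shape[1]:
            bad.append(genes[j - 1])
    return bad


def fit_prediction_model(
    train: TrainingSet, genes: Optional[Sequence[str]] = None
) -> PredictionModel:
    """OLS of the dummy responses on fold changes; boundary = dummy mean.

    ``genes`` defaults to the genes of the first profile, in profile
    order.  Raises on an underdetermined (n ≤ p) or rank-deficient
    design, naming the collinear genes in the latter case.  An all-equal
    response vector yields the degenerate constant model (zero slopes,
    intercept = the common dummy), flagged ``degenerate=True``.
    """
    if len(train) == 0:
        raise ValueError("empty training set")
    if genes is None:
        genes = train.profiles[0].genes()
    genes = list(genes)
    y = train.dummies
    X = train.design(genes)
    n, p1 = X.shape

    if len(set(y)) == 1:
        return PredictionModel(
            intercept=float(y[0]),
            coefficients={g: 0.0 for g in genes},
            boundary=float(y[0]),
            provenance="fitted",
            degenerate=True,
        )
    if n <= p1 - 1:
        raise ValueError(
            f"insufficient data: n={n} patients for p={p1 - 1} genes "
            "(need n > p for a full-rank fit)"
        )
    if np.linalg.matrix_rank(X) < p1:
        raise np.linalg.LinAlgError(
            f"singular design: collinear genes {_collinear_genes(X, genes)}"
        )
    res = sm.OLS(y, X).fit()
    params = np.asarray(res.params, dtype=float)
    return PredictionModel(
        intercept=float(params[0]),
        coefficients={g: float(b) for g, b in zip(genes, params[1:])},
        boundary=derive_boundary(train.responses),
        provenance="fitted",
    )


# ---------------------------------------------------------------------------
# Logistic fitting with a ridge fallback under separation
# ---------------------------------------------------------------------------


@dataclass
class _LogisticFit:
    params: np.ndarray
    pvalues: np.ndarray  # per design column, intercept first
    zvalues: np.ndarray
    aic: float
    penalized: bool


def _loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = np.clip(X @ beta, -500, 500)
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def _ridge_logistic(X: np.ndarray, y: np.ndarray, alpha: float) -> _LogisticFit:
    """Newton solver for logistic regression with an L2 penalty on the
    slopes (intercept unpenalized).  The penalty keeps the Hessian
    nonsingular under complete separation, so Wald statistics stay
    defined; the AIC uses the unpenalized log-likelihood at the penalized
    estimate."""
    n, p = X.shape
    pen = np.full(p, alpha)
    pen[0] = 0.0
    beta = np.zeros(p)
    for _ in range(200):
        eta = np.clip(X @ beta, -500, 500)
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - mu) - pen * beta
        W = mu * (1.0 - mu)
        H = (X.T * W) @ X + np.diag(pen)
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = np.clip(X @ beta, -500, 500)
    mu = 1.0 / (1.0 + np.exp(-eta))
    H = (X.T * (mu * (1.0 - mu))) @ X + np.diag(pen)
    cov = np.linalg.inv(H)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return _LogisticFit(
        params=beta,
        pvalues=pvals,
        zvalues=z,
        aic=-2.0 * _loglik(X, y, beta) + 2.0 * p,
        penalized=True,
    )


def _fit_logistic(X: np.ndarray, y: np.ndarray, ridge_alpha: float = 1.0) -> _LogisticFit:
    try:
        with warnings.catch_warnings(), np.errstate(all="ignore"):
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200, warn_convergence=False)
            params = np.asarray(res.params, dtype=float)
            ok = (
                bool(res.mle_retvals.get("converged", False))
                and np.all(np.isfinite(res.bse))
                and np.max(np.abs(params)) < 30.0
            )
            if ok:
                return _LogisticFit(
                    params=params,
                    pvalues=np.asarray(res.pvalues, dtype=float),
                    zvalues=np.asarray(res.tvalues, dtype=float),
                    aic=float(res.aic),
                    penalized=False,
                )
    except Exception:  # statsmodels raises several flavours on separation
        pass
    return _ridge_logistic(X, y, ridge_alpha)


# ---------------------------------------------------------------------------
# Stepwise selection
# ---------------------------------------------------------------------------


@dataclass
class StepwiseConfig:
    """Knobs of the stepwise reconstruction.

    ``influence_metric`` ranks genes within a fitted logistic model:
    ``wald_p`` (default: the largest Wald p-value is the least
    influential — the most common stepwise convention), ``abs_z``
    (smallest |z|), or ``aic_delta`` (smallest AIC increase when the gene
    is dropped).
    """

    candidate_genes: tuple[str, ...]
    panel_size: int = 16
    seed: int = 0
    influence_metric: str = "wald_p"
    max_sweeps: int = 100
    ridge_alpha: float = 1.0
    select: str = "panel_size"  # or "aic": global AIC-best panel of any size

    def __post_init__(self) -> None:
        self.candidate_genes = tuple(self.candidate_genes)
        if self.panel_size > len(self.candidate_genes):
            raise ValueError(
                f"panel_size {self.panel_size} exceeds the "
                f"{len(self.candidate_genes)} candidate genes"
            )
        if self.panel_size < 1:
            raise ValueError("panel_size must be >= 1")
        if self.influence_metric not in ("wald_p", "abs_z", "aic_delta"):
            raise ValueError(f"unknown influence_metric {self.influence_metric!r}")
        if self.select not in ("panel_size", "aic"):
            raise ValueError(f"unknown select rule {self.select!r}")


@dataclass(frozen=True)
class TraceStep:
    step: int
    action: str  # start | swap_out | swap_in | drop | select
    gene: str
    criterion: float  # AIC of the logistic fit on the panel after the action
    panel: tuple[str, ...]
    penalized: bool = False


@dataclass
class SelectionResult:
    selected_genes: tuple[str, ...]
    model: PredictionModel
    trace: tuple[TraceStep, ...]
    seed: int
    aic_best_genes: tuple[str, ...]  # global AIC optimum across all panel sizes


def _min_influence_gene(
    train: TrainingSet,
    panel: list[str],
    fit: _LogisticFit,
    y: np.ndarray,
    metric: str,
    ridge_alpha: float,
) -> str:
    """The panel gene with the least influence on the prediction."""
    if metric == "wald_p":
        scores = {g: fit.pvalues[j + 1] for j, g in enumerate(panel)}
        return max(panel, key=lambda g: (scores[g], g))
    if metric == "abs_z":
        scores = {g: abs(fit.zvalues[j + 1]) for j, g in enumerate(panel)}
        return min(panel, key=lambda g: (scores[g], g))
    # aic_delta: refit without each gene; smallest AIC increase = least influence
    deltas = {}
    for g in panel:
        rest = [h for h in panel if h != g]
        sub = _fit_logistic(train.design(rest), y, ridge_alpha)
        deltas[g] = sub.aic - fit.aic
    return min(panel, key=lambda g: (deltas[g], g))


def stepwise_select(train: TrainingSet, config: StepwiseConfig) -> SelectionResult:
    """Reconstruct the randomized sweep + backward-elimination selection.

    Phases: (1) draw ``panel_size`` genes at random (seeded) from the
    candidates; (2) *sweep* — refit a logistic regression of response on
    the current panel's fold changes, replace the minimum-influence gene
    with a not-yet-used candidate, until every candidate has been tried
    or ``max_sweeps`` is reached; (3) *backward* — drop the
    minimum-influence gene one at a time down to one gene.  Every panel
    visited is logged with its AIC.  The returned ``selected_genes`` is
    the best-AIC panel of exactly ``panel_size`` genes (the procedure's
    published output had the full panel size); ``config.select="aic"``
    returns the best-AIC panel of any size instead.  The global optimum
    is always reported in ``aic_best_genes``.
    """
    y = train.dummies
    classes = set(y)
    if classes != {0.0, 1.0}:
        raise ValueError(
            "stepwise selection needs both response classes present in training data"
        )
    rng = np.random.default_rng(config.seed)
    candidates = list(config.candidate_genes)
    order = list(rng.permutation(len(candidates)))
    panel = [candidates[i] for i in order[: config.panel_size]]
    unused = [candidates[i] for i in order[config.panel_size :]]

    trace: list[TraceStep] = []
    visited: list[tuple[float, tuple[str, ...]]] = []
    step = 0

    def refit(action: str, gene: str) -> _LogisticFit:
        nonlocal step
        fit = _fit_logistic(train.design(panel), y, config.ridge_alpha)
        trace.append(
            TraceStep(step, action, gene, fit.aic, tuple(panel), fit.penalized)
        )
        visited.append((fit.aic, tuple(panel)))
        step += 1
        return fit

    fit = refit("start", "")

    # Sweep phase: every unused candidate gets one chance in the panel.
    sweeps = 0
    while unused and sweeps < config.max_sweeps:
        out = _min_influence_gene(
            train, panel, fit, y, config.influence_metric, config.ridge_alpha
        )
        incoming = unused.pop(0)
        trace.append(TraceStep(step, "swap_out", out, fit.aic, tuple(panel)))
        step += 1
        panel[panel.index(out)] = incoming
        fit = refit("swap_in", incoming)
        sweeps += 1

    full_panels = [(aic, p) for aic, p in visited if len(p) == config.panel_size]

    # Backward phase: strip minimum-influence genes down to one.
    while len(panel) > 1:
        out = _min_influence_gene(
            train, panel, fit, y, config.influence_metric, config.ridge_alpha
        )
        panel.remove(out)
        fit = refit("drop", out)

    aic_best = min(visited, key=lambda t: t[0])[1]
    if config.select == "aic":
        selected = aic_best
    else:
        selected = min(full_panels, key=lambda t: t[0])[1]
    trace.append(
        TraceStep(step, "select", "", min(visited, key=lambda t: t[0])[0], selected)
    )

    model = fit_prediction_model(train, genes=selected)
    return SelectionResult(
        selected_genes=selected,
        model=model,
        trace=tuple(trace),
        seed=config.seed,
        aic_best_genes=aic_best,
    )


def write_trace(
    trace: Sequence[TraceStep], sink: Union[str, Path, IO[str]]
) -> None:
    """Export a selection trace as CSV ``step,action,gene,criterion``."""
    own = isinstance(sink, (str, Path))
    fh = open(sink, "w", encoding="utf-8", newline="") if own else sink
    try:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["step", "action", "gene", "criterion"])
        for t in trace:
            writer.writerow([t.step, t.action, t.gene, repr(t.criterion)])
    finally:
        if own:
            fh.close()
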