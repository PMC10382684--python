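"""LogitDA and KNNDA training protocols.

LogitDA: logistic ridge regression (mean negative log-likelihood plus
lam * ||beta||^2, intercept unpenalized) over a grid of top-p gene counts,
with a two-stage log10 grid search for the ridge penalty:

* stage 1: exponents -3.0, -2.7, ..., 0.0 (11 points);
* stage 2: exponents a1 - 0.05, ..., a1 + 0.05 in steps of 0.01
  (11 points), centered on the stage-1 winner a1.

KNNDA: K-nearest-neighbor with distance 1 - Spearman's rho between sample
profiles; a sample's score is the fraction of its K nearest training
neighbors labeled sensitive.  Both are scored by repeated stratified
5-fold cross-validated AUC.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.model_selection import StratifiedKFold

from .datasets_io import DataError, DomainDataset, ExpressionMatrix
from .evaluation import repeat_summary, roc_auc
from .featsel import FeatureRanking


def default_p_grid() -> tuple[int, ...]:
    """Top-p gene counts: 50(10)200, 200(20)400, 400(100)1000, deduplicated."""
    grid = sorted(
        set(range(50, 201, 10)) | set(range(200, 401, 20)) | set(range(400, 1001, 100))
    )
    return tuple(grid)


def stage1_exponents() -> np.ndarray:
    return np.round(np.linspace(-3.0, 0.0, 11), 10)


def stage2_exponents(a1: float, halfwidth: float = 0.05, step: float = 0.01) -> np.ndarray:
    n = int(round(2 * halfwidth / step)) + 1
    return np.round(a1 + np.linspace(-halfwidth, halfwidth, n), 10)


@dataclass
class TrainingConfig:
    p_grid: tuple[int, ...] = field(default_factory=default_p_grid)
    folds: int = 5
    repeats: int = 10
    seed: int = 0
    lambda_stage1_exponents: tuple[float, ...] = field(
        default_factory=lambda: tuple(stage1_exponents())
    )
    lambda_stage2_halfwidth: float = 0.05
    lambda_stage2_step: float = 0.01
    k_grid: tuple[int, ...] = field(default_factory=lambda: tuple(range(3, 30, 2)))
    cv_pooling: Literal["pooled", "per_fold"] = "pooled"

    def __post_init__(self) -> None:
        self.p_grid = tuple(sorted(set(int(p) for p in self.p_grid)))
        if not self.p_grid or not self.k_grid or not self.lambda_stage1_exponents:
            raise DataError("all hyperparameter grids must be non-empty")
        if self.folds < 2:
            raise DataError("folds must be >= 2")


@dataclass
class TrainedPredictor:
    """A fitted LogitDA or KNNDA predictor."""

    kind: Literal["logitda", "knnda"]
    genes: list[str]
    hyperparams: dict
    cv_score: float
    cv_se: float
    intercept: float | None = None
    coef: np.ndarray | None = None
    ref_X: np.ndarray | None = None  # knnda: training samples x genes
    ref_y: np.ndarray | None = None
    score_table: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "kind": self.kind,
            "genes": self.genes,
            "hyperparams": self.hyperparams,
            "cv_score": self.cv_score,
            "cv_se": self.cv_se,
            "intercept": self.intercept,
            "coef": None if self.coef is None else self.coef.tolist(),
            "ref_X": None if self.ref_X is None else self.ref_X.tolist(),
            "ref_y": None if self.ref_y is None else self.ref_y.tolist(),
            "score_table": self.score_table,
        }
        Path(path).write_text(json.dumps(obj, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrainedPredictor":
        obj = json.loads(Path(path).read_text())
        return cls(
            kind=obj["kind"],
            genes=obj["genes"],
            hyperparams=obj["hyperparams"],
            cv_score=obj["cv_score"],
            cv_se=obj["cv_se"],
            intercept=obj["intercept"],
            coef=None if obj["coef"] is None else np.array(obj["coef"]),
            ref_X=None if obj["ref_X"] is None else np.array(obj["ref_X"]),
            ref_y=None if obj["ref_y"] is None else np.array(obj["ref_y"], dtype=int),
            score_table=obj.get("score_table", []),
        )


# ---------------------------------------------------------------------------
# Logistic ridge


def _ridge_objective(w: np.ndarray, X: np.ndarray, y: np.ndarray, lam: float):
    n = X.shape[0]
    z = w[0] + X @ w[1:]
    # mean NLL: softplus(z) - y z, numerically stable
    nll = (np.logaddexp(0.0, z) - y * z).mean()
    obj = nll + lam * (w[1:] @ w[1:])
    s = 1.0 / (1.0 + np.exp(-z))
    resid = (s - y) / n
    grad = np.empty_like(w)
    grad[0] = resid.sum()
    grad[1:] = X.T @ resid + 2.0 * lam * w[1:]
    return obj, grad


def fit_logistic_ridge(
    X: np.ndarray, y: np.ndarray, lam: float, tol: float = 1e-8, maxiter: int = 2000
) -> tuple[float, np.ndarray]:
    """Fit logistic ridge: argmin mean-NLL + lam*||beta||^2, free intercept.

    Returns (intercept, coefficients).  Raises if the gradient norm at the
    solution exceeds ``tol`` (non-convergence).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if lam <= 0 and len(np.unique(y)) < 2:
        raise DataError("both classes must be present")
    if len(np.unique(y)) < 2:
        raise DataError("both classes must be present")
    w0 = np.zeros(X.shape[1] + 1)
    res = optimize.minimize(
        _ridge_objective,
        w0,
        args=(X, y, lam),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-15, "gtol": 1e-10},
    )
    w = _newton_polish(res.x, X, y, lam, tol)
    return float(w[0]), w[1:].copy()


def _newton_polish(
    w: np.ndarray, X: np.ndarray, y: np.ndarray, lam: float, tol: float
) -> np.ndarray:
    """Damped Newton steps until the gradient inf-norm drops below tol."""
    n = X.shape[0]
    Xd = np.hstack([np.ones((n, 1)), X])
    obj, grad = _ridge_objective(w, X, y, lam)
    for _ in range(50):
        gnorm = float(np.linalg.norm(grad, ord=np.inf))
        if gnorm <= tol:
            return w
        z = Xd @ w
        s = 1.0 / (1.0 + np.exp(-z))
        W = s * (1.0 - s) / n
        H = (Xd * W[:, None]).T @ Xd
        H[1:, 1:] += 2.0 * lam * np.eye(X.shape[1])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        t = 1.0
        for _ in range(40):
            cand = w - t * step
            cobj, cgrad = _ridge_objective(cand, X, y, lam)
            # near machine precision the objective cannot resolve progress;
            # a shrinking gradient is the reliable acceptance signal there
            if cobj < obj or np.linalg.norm(cgrad, ord=np.inf) < gnorm:
                w, obj, grad = cand, cobj, cgrad
                break
            t /= 2.0
        else:
            break
    gnorm = float(np.linalg.norm(grad, ord=np.inf))
    if gnorm > tol:
        raise DataError(
            f"logistic ridge did not converge: |grad|_inf={gnorm:.2e} "
            f"(lam={lam}, n={X.shape[0]}, p={X.shape[1]})"
        )
    return w


def ridge_objective_value(
    intercept: float, coef: np.ndarray, X: np.ndarray, y: np.ndarray, lam: float
) -> float:
    w = np.concatenate([[intercept], coef])
    return float(_ridge_objective(w, np.asarray(X, float), np.asarray(y, float), lam)[0])


# ---------------------------------------------------------------------------
# Cross-validation


def _repeat_seeds(seed: int, repeats: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.integers(0, 2**31 - 1, size=repeats)


def cv_auc(
    X: np.ndarray,
    y: np.ndarray,
    model_factory: Callable[[np.ndarray, np.ndarray], Callable[[np.ndarray], np.ndarray]],
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
    pooling: Literal["pooled", "per_fold"] = "pooled",
) -> tuple[float, float, np.ndarray]:
    """Repeated stratified K-fold CV AUC.

    ``model_factory(X_train, y_train)`` must return a callable mapping a
    test matrix to scores.  Per repeat, out-of-fold scores are pooled and a
    single AUC computed (default), or per-fold AUCs averaged.  Returns
    (mean, s.e. over repeats, per-repeat AUCs); bit-reproducible for a
    fixed seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise DataError(
            f"smallest class has {counts.min()} samples < {folds} folds; "
            "reduce the number of folds"
        )
    aucs = np.empty(repeats)
    for rep, rs in enumerate(_repeat_seeds(seed, repeats)):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(rs))
        oof = np.empty(len(y))
        fold_aucs = []
        for tr, te in skf.split(X, y):
            score_fn = model_factory(X[tr], y[tr])
            oof[te] = score_fn(X[te])
            if pooling == "per_fold":
                fold_aucs.append(roc_auc(oof[te], y[te]))
        aucs[rep] = np.mean(fold_aucs) if pooling == "per_fold" else roc_auc(oof, y)
    if repeats >= 2:
        mean, se = repeat_summary(aucs)
    else:
        mean, se = float(aucs[0]), 0.0
    return mean, se, aucs


def _logit_factory(lam: float):
    def factory(Xtr: np.ndarray, ytr: np.ndarray):
        b0, b = fit_logistic_ridge(Xtr, ytr, lam)

        def score(Xte: np.ndarray) -> np.ndarray:
            z = b0 + Xte @ b
            return 1.0 / (1.0 + np.exp(-z))

        return score

    return factory


def tune_lambda_two_stage(
    X: np.ndarray, y: np.ndarray, config: TrainingConfig
) -> tuple[float, float, dict]:
    """Two-stage log-grid search for the ridge penalty, by mean CV AUC.

    Ties go to the smaller penalty.  Returns (lambda, cv_score, info) where
    info records both stage tables for auditability.
    """
    def scan(exponents: np.ndarray) -> list[tuple[float, float]]:
        out = []
        for a in exponents:
            lam = 10.0 ** float(a)
            mean, _, _ = cv_auc(
                X, y, _logit_factory(lam),
                folds=config.folds, repeats=config.repeats,
                seed=config.seed, pooling=config.cv_pooling,
            )
            out.append((float(a), mean))
        return out

    s1 = scan(np.asarray(config.lambda_stage1_exponents, dtype=float))
    a1 = min(s1, key=lambda t: (-t[1], t[0]))[0]
    s2 = scan(
        stage2_exponents(a1, config.lambda_stage2_halfwidth, config.lambda_stage2_step)
    )
    a_max, score = min(s2, key=lambda t: (-t[1], t[0]))
    return 10.0 ** a_max, score, {"stage1": s1, "stage2": s2, "a1": a1}


def _ranking_matrix(source: DomainDataset, ranking: FeatureRanking) -> np.ndarray:
    """Source samples x ranked-genes matrix, in ranking order."""
    expr = source.expr.subset_genes(ranking.gene_ids)
    return expr.values.T.copy()


def train_logitda(
    source: DomainDataset, ranking: FeatureRanking, config: TrainingConfig
) -> TrainedPredictor:
    """Tune (p, lambda) by CV AUC over the p-grid, refit on all source data.

    Ties are broken toward smaller p, then smaller lambda (parsimony).
    """
    p_values = [p for p in config.p_grid if p <= len(ranking)]
    if not p_values:
        raise DataError(
            f"ranking has {len(ranking)} genes, below the smallest p "
            f"({min(config.p_grid)}) in the grid"
        )
    Xfull = _ranking_matrix(source, ranking)
    y = source.labels.y
    table = []
    for p in p_values:
        lam, score, info = tune_lambda_two_stage(Xfull[:, :p], y, config)
        table.append({"p": p, "lambda": lam, "cv_score": score})
    best = min(table, key=lambda r: (-r["cv_score"], r["p"], r["lambda"]))
    p, lam = best["p"], best["lambda"]
    mean, se, _ = cv_auc(
        Xfull[:, :p], y, _logit_factory(lam),
        folds=config.folds, repeats=config.repeats,
        seed=config.seed, pooling=config.cv_pooling,
    )
    b0, b = fit_logistic_ridge(Xfull[:, :p], y, lam)
    return TrainedPredictor(
        kind="logitda",
        genes=ranking.top(p),
        hyperparams={"p": p, "lambda": lam},
        cv_score=mean,
        cv_se=se,
        intercept=b0,
        coef=b,
        score_table=table,
    )


# ---------------------------------------------------------------------------
# Spearman-distance KNN


def spearman_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 - Spearman's rho between two expression profiles (range [0, 2])."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1 or len(u) < 2:
        raise DataError("vectors must be 1-D, equal length >= 2")
    if np.ptp(u) == 0 or np.ptp(v) == 0:
        raise DataError("Spearman's rho undefined for constant profiles")
    rho = stats.spearmanr(u, v).statistic
    return float(1.0 - rho)


def _spearman_dist_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise 1 - rho between rows of A and rows of B (average-rank ties)."""
    ra = stats.rankdata(A, axis=1)
    rb = stats.rankdata(B, axis=1)
    ra = ra - ra.mean(axis=1, keepdims=True)
    rb = rb - rb.mean(axis=1, keepdims=True)
    na = np.sqrt((ra**2).sum(axis=1))
    nb = np.sqrt((rb**2).sum(axis=1))
    if (na == 0).any() or (nb == 0).any():
        raise DataError("Spearman's rho undefined for constant profiles")
    rho = (ra @ rb.T) / np.outer(na, nb)
    return 1.0 - rho


def knn_scores(
    X_ref: np.ndarray, y_ref: np.ndarray, X_query: np.ndarray, k: int
) -> np.ndarray:
    """Vote-fraction scores: share of the K nearest reference samples labeled 1.

    Neighbors are ranked by Spearman distance; exact distance ties are broken
    by reference sample order (stable sort) for determinism.
    """
    if k < 1 or k > X_ref.shape[0]:
        raise DataError(f"K={k} out of range for {X_ref.shape[0]} reference samples")
    D = _spearman_dist_matrix(np.asarray(X_query, float), np.asarray(X_ref, float))
    order = np.argsort(D, axis=1, kind="stable")[:, :k]
    return np.asarray(y_ref, dtype=float)[order].mean(axis=1)


def _knn_factory(k: int):
    def factory(Xtr: np.ndarray, ytr: np.ndarray):
        def score(Xte: np.ndarray) -> np.ndarray:
            return knn_scores(Xtr, ytr, Xte, k)

        return score

    return factory


def train_knnda(
    source: DomainDataset, ranking: FeatureRanking, config: TrainingConfig
) -> TrainedPredictor:
    """Tune (p, K) by CV AUC; the final predictor stores all source samples.

    K values exceeding the smallest training-fold size are skipped with a
    warning.  Ties break toward smaller K, then smaller p.
    """
    p_values = [p for p in config.p_grid if p <= len(ranking)]
    if not p_values:
        raise DataError(
            f"ranking has {len(ranking)} genes, below the smallest p in the grid"
        )
    Xfull = _ranking_matrix(source, ranking)
    y = source.labels.y
    n = len(y)
    min_fold_train = n - (n // config.folds + (1 if n % config.folds else 0))
    usable_k = [k for k in config.k_grid if k <= min_fold_train]
    skipped = sorted(set(config.k_grid) - set(usable_k))
    if skipped:
        warnings.warn(f"skipping K values exceeding training-fold size: {skipped}")
    if not usable_k:
        raise DataError("every K in the grid exceeds the training-fold size")
    table = []
    for p in p_values:
        Xp = Xfull[:, :p]
        for k in usable_k:
            mean, _, _ = cv_auc(
                Xp, y, _knn_factory(k),
                folds=config.folds, repeats=config.repeats,
                seed=config.seed, pooling=config.cv_pooling,
            )
            table.append({"p": p, "K": k, "cv_score": mean})
    best = min(table, key=lambda r: (-r["cv_score"], r["K"], r["p"]))
    p, k = best["p"], best["K"]
    mean, se, _ = cv_auc(
        Xfull[:, :p], y, _knn_factory(k),
        folds=config.folds, repeats=config.repeats,
        seed=config.seed, pooling=config.cv_pooling,
    )
    return TrainedPredictor(
        kind="knnda",
        genes=ranking.top(p),
        hyperparams={"p": p, "K": k},
        cv_score=mean,
        cv_se=se,
        ref_X=Xfull[:, :p].copy(),
        ref_y=y.copy(),
        score_table=table,
    )


def predict_proba(model: TrainedPredictor, target_expr: ExpressionMatrix) -> np.ndarray:
    """Score target samples with a trained predictor (probability-like, [0,1])."""
    missing = [g for g in model.genes if g not in target_expr.gene_ids]
    if missing:
        raise DataError(f"target expression lacks model genes: {missing[:10]}")
    X = target_expr.subset_genes(model.genes).values.T
    if model.kind == "logitda":
        z = model.intercept + X @ model.coef
        return 1.0 / (1.0 + np.exp(-z))
    if model.kind == "knnda":
        return knn_scores(model.ref_X, model.ref_y, X, model.hyperparams["K"])
    raise DataError(f"unknown predictor kind {model.kind!r}")
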