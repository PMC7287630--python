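"""Logistic modelling core: fitting, RFE, split search, CV, evaluation.

The model is a plain (unpenalized) binomial logit over region count
features with age, sex and BMI always included as covariates; the
three-class path fits one-vs-rest binary logits so that each class gets
its own named coefficient set.

Solver policy: deterministic Newton maximum likelihood is the default
(statsmodels ``Logit`` plus a gradient-polish step); an SGD mode is
provided for procedural fidelity, finished with the same Newton polish
so both modes satisfy the gradient-norm postcondition.  Perfect
separation or a singular Hessian triggers a ridge-stabilized refit that
is flagged on the returned model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import (
    DegenerateOutcomeError,
    FoldError,
    LeakageError,
    ValidationError,
)
from .parcellation_features import FeatureTable

DEFAULT_COVARIATES = ("age", "sex", "bmi")
DEFAULT_GTOL = 1e-8
_SEX_CODES = {"m": 1, "male": 1, "f": 0, "female": 0}


# ---------------------------------------------------------------------------
# Model containers


@dataclass
class FittedLogit:
    """Intercept plus named coefficients with Wald p-values.

    Binary models hold scalar ``intercept`` and flat ``coefficients``;
    three-class (one-vs-rest) models hold per-class dicts keyed by class
    label.  ``classes`` is ``[negative, positive]`` for binary models.
    """

    classes: list
    intercept: float | dict
    coefficients: dict
    p_values: dict
    p_values_sidak: dict
    feature_names: list[str]
    covariates: list[str]
    multiclass: bool = False
    training: dict = field(default_factory=dict)

    @property
    def positive_class(self):
        if self.multiclass:
            raise ValidationError("positive_class is defined for binary models only")
        return self.classes[1]

    @property
    def negative_class(self):
        if self.multiclass:
            raise ValidationError("negative_class is defined for binary models only")
        return self.classes[0]

    def _design(self, table: FeatureTable) -> np.ndarray:
        cols = []
        for name in self.feature_names:
            if name not in table.counts.columns:
                raise ValidationError(f"feature {name!r} missing from table")
            cols.append(table.counts[name].to_numpy(dtype=float))
        for name in self.covariates:
            cols.append(_covariate_column(table, name))
        return np.column_stack(cols) if cols else np.empty((table.n_subjects, 0))

    def _eta(self, X: np.ndarray, cls=None) -> np.ndarray:
        if self.multiclass:
            coef = self.coefficients[cls]
            b0 = self.intercept[cls]
        else:
            coef, b0 = self.coefficients, self.intercept
        beta = np.array([coef[n] for n in (*self.feature_names, *self.covariates)])
        return b0 + X @ beta

    def predict_proba(self, table: FeatureTable):
        """P(positive) per subject for binary; per-class DataFrame for 3-class."""
        X = self._design(table)
        if not self.multiclass:
            return _sigmoid(self._eta(X))
        probs = {cls: _sigmoid(self._eta(X, cls)) for cls in self.classes}
        return pd.DataFrame(probs, index=table.counts.index)

    def predict(self, table: FeatureTable) -> np.ndarray:
        if self.multiclass:
            proba = self.predict_proba(table)
            return proba.idxmax(axis=1).to_numpy()
        p = self.predict_proba(table)
        # tie at exactly 0.5 goes to the negative class
        return np.where(p > 0.5, self.positive_class, self.negative_class)

    def to_json(self, path=None) -> str:
        payload = {
            "classes": list(self.classes),
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "p_values": self.p_values,
            "p_values_sidak": self.p_values_sidak,
            "feature_names": self.feature_names,
            "covariates": self.covariates,
            "multiclass": self.multiclass,
            "training": self.training,
        }
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "FittedLogit":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(**payload)


@dataclass
class EvaluationReport:
    """Confusion counts and the ratio metrics defined from them.

    For three-class models ``per_class`` maps each class to its
    one-vs-rest confusion counts; the headline counts then refer to the
    micro-averaged (summed) table.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    per_class: dict | None = None
    n_correct: int | None = None
    n_total: int | None = None
    cv_mean_accuracy: float | None = None
    k: int | None = None

    @property
    def n(self) -> int:
        if self.n_total is not None:
            return self.n_total
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        # three-class: plain fraction of subjects assigned their true class
        if self.n_correct is not None:
            return self.n_correct / self.n_total
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp)

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn)

    def to_json(self) -> str:
        payload = {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "per_class": self.per_class,
            "cv_mean_accuracy": self.cv_mean_accuracy,
            "k": self.k,
        }
        return json.dumps(payload, indent=2)


# ---------------------------------------------------------------------------
# Design-matrix plumbing


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta, dtype=float)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    ex = np.exp(eta[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _covariate_column(table: FeatureTable, name: str) -> np.ndarray:
    if name not in table.metadata.columns:
        raise ValidationError(f"covariate {name!r} missing from metadata")
    col = table.metadata[name]
    if col.dtype == object:
        col = col.map(lambda v: _SEX_CODES.get(str(v).strip().lower(), v))
    return pd.to_numeric(col).to_numpy(dtype=float)


def _binary_order(classes) -> list:
    """Deterministic [negative, positive] ordering for two labels."""
    classes = sorted(classes, key=str)
    if "control" in classes:
        return ["control"] + [c for c in classes if c != "control"]
    return classes


def _build_xy(table: FeatureTable, outcome: str, features, covariates):
    names = list(features) + list(covariates)
    cols = [table.counts[f].to_numpy(dtype=float) for f in features]
    cols += [_covariate_column(table, c) for c in covariates]
    X = np.column_stack([np.ones(table.n_subjects)] + cols)
    y_raw = table.metadata[outcome].to_numpy()
    return X, y_raw, ["intercept"] + names


# ---------------------------------------------------------------------------
# Solvers


def _grad(X, y, beta, ridge=0.0):
    g = X.T @ (y - _sigmoid(X @ beta))
    if ridge:
        g = g - ridge * np.r_[0.0, beta[1:]]
    return g


def _newton(X, y, ridge=0.0, gtol=DEFAULT_GTOL, maxiter=100, beta0=None):
    """IRLS with step halving; returns (beta, cov, converged, grad_norm)."""
    n, k = X.shape
    beta = np.zeros(k) if beta0 is None else beta0.astype(float).copy()
    pen = np.r_[0.0, np.full(k - 1, ridge)] if ridge else np.zeros(k)

    def negll(b):
        eta = X @ b
        # log(1+e^eta) - y*eta, stably
        val = np.logaddexp(0.0, eta).sum() - y @ eta
        return val + 0.5 * (pen * b * b).sum()

    f = negll(beta)
    H = None
    for _ in range(maxiter):
        p = _sigmoid(X @ beta)
        g = _grad(X, y, beta, ridge)
        if np.max(np.abs(g)) <= gtol:
            break
        w = np.clip(p * (1.0 - p), 1e-12, None)
        H = (X * w[:, None]).T @ X + np.diag(pen)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            return beta, None, False, float(np.max(np.abs(g)))
        t = 1.0
        for _ in range(40):
            cand = beta + t * step
            fc = negll(cand)
            if fc <= f + 1e-12:
                beta, f = cand, fc
                break
            t *= 0.5
        else:
            break
    g = _grad(X, y, beta, ridge)
    gnorm = float(np.max(np.abs(g)))
    p = _sigmoid(X @ beta)
    w = np.clip(p * (1.0 - p), 1e-12, None)
    H = (X * w[:, None]).T @ X + np.diag(pen)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = None
    return beta, cov, gnorm <= max(gtol, 1e-6), gnorm


def _sgd(X, y, seed, epochs=150, eta0=0.1):
    """Per-sample stochastic gradient ascent on standardized features."""
    rng = np.random.default_rng(seed)
    n, k = X.shape
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    mu[0], sd[0] = 0.0, 1.0  # leave the constant column alone
    Z = (X - mu) / sd
    beta = np.zeros(k)
    t = 0
    for _ in range(epochs):
        for i in rng.permutation(n):
            t += 1
            eta = eta0 / (1.0 + 0.01 * t)
            p = _sigmoid(Z[i] @ beta)
            beta += eta * (y[i] - p) * Z[i]
    # back-transform to the raw feature scale
    raw = beta / sd
    raw[0] = beta[0] - np.sum(beta[1:] * mu[1:] / sd[1:])
    return raw


def _fit_binary_core(X, y, method, seed, gtol, ridge_alpha):
    """Fit one binary logit; returns beta, cov, flags dict."""
    flags = {"method": method, "separation_flagged": False, "ridge_alpha": 0.0}
    beta0 = None
    if method == "sgd":
        beta0 = _sgd(X, y, seed)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(y, X).fit(method="newton", maxiter=100, tol=1e-10, disp=0)
                beta0 = np.asarray(res.params, dtype=float)
            except Exception:
                beta0 = None
        if beta0 is not None and not np.isfinite(beta0).all():
            beta0 = None
    # polish (or fit from scratch) with Newton under the gradient criterion
    beta, cov, converged, gnorm = _newton(X, y, gtol=gtol, beta0=beta0)
    blown_up = not np.isfinite(beta).all() or np.max(np.abs(beta)) > 1e3
    # perfect separation: the likelihood has no finite maximum and the
    # training residuals collapse to zero as coefficients diverge
    if np.isfinite(beta).all():
        resid = np.abs(y - _sigmoid(X @ beta))
        separated = bool(np.max(resid) < 1e-3)
    else:
        separated = True
    if cov is None or not converged or blown_up or separated:
        # perfect separation / singular Hessian: ridge-stabilized refit
        beta, cov, converged, gnorm = _newton(X, y, ridge=ridge_alpha, gtol=gtol)
        flags["separation_flagged"] = True
        flags["ridge_alpha"] = ridge_alpha
    flags["converged"] = bool(converged)
    flags["grad_max_norm"] = gnorm
    return beta, cov, flags


def _wald_pvalues(beta, cov):
    if cov is None:
        return np.full_like(beta, np.nan)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf)
    return 2.0 * stats.norm.sf(np.abs(z))


# ---------------------------------------------------------------------------
# Operations


def logistic_probability(model: FittedLogit, features: dict) -> float:
    """Evaluate 1/(1+e^-eta) at a named feature vector (binary models)."""
    if model.multiclass:
        raise ValidationError("logistic_probability applies to binary models")
    eta = float(model.intercept)
    for name, coef in model.coefficients.items():
        if name not in features:
            raise ValidationError(f"missing feature {name!r}")
        eta += coef * float(features[name])
    return float(_sigmoid(np.array([eta]))[0])


def sidak_adjust(p_values, m: int):
    """Sidak multiple-comparison adjustment: p -> 1 - (1 - p)^m."""
    p = np.asarray(p_values, dtype=float)
    if m < 1 or int(m) != m:
        raise ValidationError(f"m must be a positive integer, got {m}")
    finite = p[np.isfinite(p)]
    if finite.size and ((finite < 0).any() or (finite > 1).any()):
        raise ValidationError("p-values must lie in [0, 1]")
    adj = 1.0 - np.power(1.0 - p, m)
    adj = np.clip(adj, 0.0, 1.0)
    if np.isscalar(p_values) or np.ndim(p_values) == 0:
        return float(adj)
    return adj.tolist() if isinstance(p_values, list) else adj


def fit_logistic(
    table: FeatureTable,
    outcome: str = "group",
    features=None,
    covariates=DEFAULT_COVARIATES,
    method: str = "newton",
    seed: int = 0,
    gtol: float = DEFAULT_GTOL,
    ridge_alpha: float = 1e-3,
    m_sidak: int | None = None,
    training_meta: dict | None = None,
) -> FittedLogit:
    """Maximum-likelihood logit of ``outcome`` on region features + covariates.

    Two classes give a single binary model; three or more give
    one-vs-rest binary fits with per-class coefficient sets sharing the
    same feature support.
    """
    if features is None:
        features = table.region_names
    features = list(features)
    unknown = [f for f in features if f not in table.counts.columns]
    if unknown:
        raise ValidationError(f"features not in table: {unknown}")
    if method not in ("newton", "sgd"):
        raise ValidationError(f"unknown method {method!r}")
    y_raw = table.metadata[outcome].to_numpy()
    classes = pd.unique(y_raw).tolist()
    if len(classes) < 2:
        raise DegenerateOutcomeError(f"outcome {outcome!r} has a single class: {classes}")
    X, _, names = _build_xy(table, outcome, features, covariates)
    m = m_sidak if m_sidak is not None else max(len(features), 1)
    meta = {
        "outcome": outcome,
        "seed": seed,
        "method": method,
        "selected_features": features,
        "n_obs": table.n_subjects,
        "training_ids": list(table.subject_ids),
        "m_sidak": m,
        **(training_meta or {}),
    }

    if len(classes) == 2:
        ordered = _binary_order(classes)
        y = (y_raw == ordered[1]).astype(float)
        beta, cov, flags = _fit_binary_core(X, y, method, seed, gtol, ridge_alpha)
        pvals = _wald_pvalues(beta, cov)
        coef = dict(zip(names[1:], beta[1:].tolist()))
        p_raw = dict(zip(names[1:], pvals[1:].tolist()))
        p_adj = {k: sidak_adjust(v, m) if np.isfinite(v) else float("nan") for k, v in p_raw.items()}
        meta.update(flags)
        return FittedLogit(
            classes=ordered,
            intercept=float(beta[0]),
            coefficients=coef,
            p_values=p_raw,
            p_values_sidak=p_adj,
            feature_names=features,
            covariates=list(covariates),
            multiclass=False,
            training=meta,
        )

    # one-vs-rest: one named coefficient set per class, shared support
    ordered = sorted(classes, key=str)
    intercepts, coefs, p_raw_all, p_adj_all, flag_all = {}, {}, {}, {}, {}
    for cls in ordered:
        y = (y_raw == cls).astype(float)
        beta, cov, flags = _fit_binary_core(X, y, method, seed, gtol, ridge_alpha)
        pvals = _wald_pvalues(beta, cov)
        intercepts[cls] = float(beta[0])
        coefs[cls] = dict(zip(names[1:], beta[1:].tolist()))
        p_raw_all[cls] = dict(zip(names[1:], pvals[1:].tolist()))
        p_adj_all[cls] = {
            k: sidak_adjust(v, m) if np.isfinite(v) else float("nan")
            for k, v in p_raw_all[cls].items()
        }
        flag_all[cls] = flags
    meta["per_class_fit"] = flag_all
    return FittedLogit(
        classes=ordered,
        intercept=intercepts,
        coefficients=coefs,
        p_values=p_raw_all,
        p_values_sidak=p_adj_all,
        feature_names=features,
        covariates=list(covariates),
        multiclass=True,
        training=meta,
    )


# ---------------------------------------------------------------------------
# Splits and cross-validation


def stratified_split(labels, ratio: float, seed: int = 0):
    """Largest-remainder stratified train/test split.

    Returns (train_idx, test_idx) as integer positions.  The total
    training size is round(n * ratio); per-class quotas take the floor
    of n_c * ratio and the leftover seats go to the classes with the
    largest fractional remainders (ties broken by first appearance).
    """
    labels = np.asarray(labels)
    n = labels.size
    if not 0.0 < ratio < 1.0:
        raise ValidationError(f"ratio must be in (0, 1), got {ratio}")
    classes = pd.unique(labels)
    n_train = int(np.floor(n * ratio + 0.5))
    quotas = {}
    remainders = []
    for order, cls in enumerate(classes):
        exact = (labels == cls).sum() * ratio
        quotas[cls] = int(np.floor(exact))
        remainders.append((-(exact - np.floor(exact)), order, cls))
    leftover = n_train - sum(quotas.values())
    for _, _, cls in sorted(remainders)[: max(leftover, 0)]:
        quotas[cls] += 1
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        q = quotas[cls]
        if q < 1 or q >= idx.size:
            raise ValidationError(
                f"ratio {ratio} leaves class {cls!r} empty in train or test"
            )
        perm = rng.permutation(idx)
        train_parts.append(perm[:q])
        test_parts.append(perm[q:])
    return np.sort(np.concatenate(train_parts)), np.sort(np.concatenate(test_parts))


@dataclass
class SplitSearchResult:
    chosen_ratio: float
    results: pd.DataFrame  # ratio, mean_accuracy, sd_accuracy, n_repeats
    accuracies: dict


def split_search(
    table: FeatureTable,
    outcome: str = "group",
    features=None,
    ratios=(0.5, 0.6, 0.7, 0.8, 0.9),
    n_repeats: int = 20,
    seed: int = 0,
    covariates=DEFAULT_COVARIATES,
) -> SplitSearchResult:
    """Repeated stratified holdout over a grid of train fractions.

    The chosen ratio maximizes mean test accuracy; ties go to the most
    stable ratio (lowest SD), then to the smaller training fraction.
    Ratios infeasible for the class sizes are skipped with a warning.
    """
    if features is None:
        features = table.region_names
    labels = table.metadata[outcome].to_numpy()
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(ratios) * n_repeats, dtype=np.uint32)
    rows, acc_map = [], {}
    for ri, ratio in enumerate(ratios):
        accs = []
        for rep in range(n_repeats):
            child = int(child_seeds[ri * n_repeats + rep])
            try:
                tr, te = stratified_split(labels, ratio, seed=child)
            except ValidationError as exc:
                warnings.warn(f"ratio {ratio} skipped: {exc}")
                accs = None
                break
            train = table.subset(np.array(table.subject_ids)[tr])
            test = table.subset(np.array(table.subject_ids)[te])
            model = fit_logistic(train, outcome, features, covariates=covariates, seed=child)
            accs.append(evaluate(model, test).accuracy)
        if accs is None:
            continue
        acc_map[ratio] = accs
        rows.append(
            {
                "ratio": ratio,
                "mean_accuracy": float(np.mean(accs)),
                "sd_accuracy": float(np.std(accs)),
                "n_repeats": n_repeats,
            }
        )
    if not rows:
        raise ValidationError("no feasible split ratio for these class sizes")
    frame = pd.DataFrame(rows)
    best = frame.sort_values(
        by=["mean_accuracy", "sd_accuracy", "ratio"], ascending=[False, True, True]
    ).iloc[0]
    return SplitSearchResult(chosen_ratio=float(best["ratio"]), results=frame, accuracies=acc_map)


def kfold_cv(
    table: FeatureTable,
    outcome: str = "group",
    features=None,
    k: int = 10,
    seed: int = 0,
    covariates=DEFAULT_COVARIATES,
) -> float:
    """Mean accuracy over stratified k folds (k = n gives leave-one-out)."""
    if features is None:
        features = table.region_names
    n = table.n_subjects
    if n < k:
        raise FoldError(f"n={n} < k={k}")
    labels = table.metadata[outcome].to_numpy()
    ids = np.array(table.subject_ids)
    if k == n:
        folds = [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)]
    else:
        from sklearn.model_selection import StratifiedKFold

        counts = pd.Series(labels).value_counts()
        if counts.min() < k:
            raise FoldError(
                f"stratified {k}-fold needs >= {k} members per class (min is {counts.min()})"
            )
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % (2**32))
        folds = list(skf.split(np.zeros(n), labels))
    accs = []
    for tr, te in folds:
        model = fit_logistic(table.subset(ids[tr]), outcome, features, covariates=covariates, seed=seed)
        accs.append(evaluate(model, table.subset(ids[te])).accuracy)
    return float(np.mean(accs))


# ---------------------------------------------------------------------------
# Recursive feature elimination


@dataclass
class RFESelection:
    selected: list[str]
    elimination_order: list[str]
    path_scores: dict  # n_features -> inner CV accuracy


def recursive_feature_elimination(
    table: FeatureTable,
    outcome: str = "group",
    candidates=None,
    covariates=DEFAULT_COVARIATES,
    inner_k: int = 5,
    min_features: int = 1,
    seed: int = 0,
) -> RFESelection:
    """Greedy backward elimination of region features.

    Each round refits the model and drops the feature with the smallest
    importance (|coefficient| x training SD of the feature; standardized
    scale, so raw count magnitudes do not distort the ranking).
    Covariates are exempt.  The retained count is the one maximizing
    inner stratified CV accuracy along the elimination path, ties broken
    toward fewer features.
    """
    if candidates is None:
        candidates = table.region_names
    candidates = list(candidates)
    if not candidates:
        raise ValidationError("no candidate regions for elimination")
    labels = table.metadata[outcome].to_numpy()
    class_min = pd.Series(labels).value_counts().min()
    k_inner = int(min(inner_k, class_min, table.n_subjects))
    sds = table.counts[candidates].to_numpy(dtype=float).std(axis=0)
    sd_by_name = dict(zip(candidates, sds))

    active = candidates.copy()
    order: list[str] = []
    path = {len(active): active.copy()}
    while len(active) > min_features:
        model = fit_logistic(table, outcome, active, covariates=covariates, seed=seed)
        if model.multiclass:
            importance = {
                f: sum(abs(model.coefficients[c][f]) for c in model.classes) * max(sd_by_name[f], 1e-12)
                for f in active
            }
        else:
            importance = {
                f: abs(model.coefficients[f]) * max(sd_by_name[f], 1e-12) for f in active
            }
        # weakest feature out; ties drop the later-ordered member
        weakest = min(active, key=lambda f: (importance[f], -active.index(f)))
        active.remove(weakest)
        order.append(weakest)
        path[len(active)] = active.copy()

    scores = {}
    for size in sorted(path):
        if k_inner >= 2 and table.n_subjects >= k_inner:
            scores[size] = kfold_cv(table, outcome, path[size], k=k_inner, seed=seed, covariates=covariates)
        else:  # degenerate data: fall back to training accuracy
            model = fit_logistic(table, outcome, path[size], covariates=covariates, seed=seed)
            preds = model.predict(table)
            scores[size] = float(np.mean(preds == labels))
    best_size = max(sorted(scores), key=lambda s: (scores[s], -s))
    return RFESelection(selected=path[best_size], elimination_order=order, path_scores=scores)


# ---------------------------------------------------------------------------
# Evaluation


def evaluate(model: FittedLogit, table: FeatureTable) -> EvaluationReport:
    """Score a fitted model on held-out rows (train/test overlap rejected)."""
    train_ids = set(model.training.get("training_ids", []))
    overlap = train_ids & set(table.subject_ids)
    if overlap:
        raise LeakageError(f"evaluation rows overlap training rows: {sorted(overlap)[:5]} ...")
    y = table.metadata[model.training.get("outcome", "group")].to_numpy()
    preds = model.predict(table)
    if not model.multiclass:
        pos, neg = model.positive_class, model.negative_class
        tp = int(np.sum((preds == pos) & (y == pos)))
        fp = int(np.sum((preds == pos) & (y != pos)))
        tn = int(np.sum((preds != pos) & (y != pos)))
        fn = int(np.sum((preds != pos) & (y == pos)))
        return EvaluationReport(tp=tp, fp=fp, tn=tn, fn=fn)
    per_class = {}
    totals = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
    for cls in model.classes:
        tp = int(np.sum((preds == cls) & (y == cls)))
        fp = int(np.sum((preds == cls) & (y != cls)))
        tn = int(np.sum((preds != cls) & (y != cls)))
        fn = int(np.sum((preds != cls) & (y == cls)))
        per_class[cls] = {"tp": tp, "fp": fp, "tn": tn, "fn": fn}
        for key, val in zip(("tp", "fp", "tn", "fn"), (tp, fp, tn, fn)):
            totals[key] += val
    return EvaluationReport(
        per_class=per_class,
        n_correct=int(np.sum(preds == y)),
        n_total=int(y.size),
        **totals,
    )


# ---------------------------------------------------------------------------
# End-to-end model build (split -> screen -> RFE -> fit -> test accuracy)


@dataclass
class PipelineConfig:
    """Everything needed to rebuild the model from a labelled table."""

    outcome: str = "group"
    ratio: float = 0.7
    r_max: float = 0.9
    screen: bool = True
    rfe: bool = True
    candidates: list[str] | None = None
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    inner_k: int = 5
    min_features: int = 1
    method: str = "newton"


@dataclass
class PipelineResult:
    model: FittedLogit
    report: EvaluationReport
    selected: list[str]
    train_ids: list[str]
    test_ids: list[str]

    @property
    def accuracy(self) -> float:
        return self.report.accuracy


def run_pipeline(table: FeatureTable, config: PipelineConfig, seed: int = 0) -> PipelineResult:
    """One full model build: stratified split, collinearity screen across
    train/test/full, RFE on the training set, final fit, held-out accuracy."""
    from .collinearity_screen import screen_across_splits

    labels = table.metadata[config.outcome].to_numpy()
    tr, te = stratified_split(labels, config.ratio, seed=seed)
    ids = np.array(table.subject_ids)
    train, test = table.subset(ids[tr]), table.subset(ids[te])

    candidates = list(config.candidates) if config.candidates is not None else table.region_names
    if config.screen:
        report = screen_across_splits(table, ids[tr], ids[te], r_max=config.r_max)
        candidates = [c for c in candidates if c in set(report.retained)]
        if not candidates:
            raise ValidationError("collinearity screen removed every candidate region")
    if config.rfe:
        selection = recursive_feature_elimination(
            train,
            config.outcome,
            candidates,
            covariates=config.covariates,
            inner_k=config.inner_k,
            min_features=config.min_features,
            seed=seed,
        )
        selected = selection.selected
    else:
        selected = candidates
    model = fit_logistic(
        train,
        config.outcome,
        selected,
        covariates=config.covariates,
        method=config.method,
        seed=seed,
        training_meta={"split_ratio": config.ratio},
    )
    report = evaluate(model, test)
    return PipelineResult(
        model=model,
        report=report,
        selected=selected,
        train_ids=list(ids[tr]),
        test_ids=list(ids[te]),
    )
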