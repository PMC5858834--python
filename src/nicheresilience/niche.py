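"""Native presence-absence niche models.

A small registry of suitability methods mapping the four bioclimatic
predictors to a score in [0, 1]:

* ``envelope`` — a surface-range envelope: quantile-trimmed rectangular
  bounds on the presence values of each predictor; inside all bounds -> 1.
* ``logistic_glm`` — maximum-likelihood logistic regression (IRLS) on
  standardized predictors, with polynomial terms up to a configurable
  degree.
* ``discriminant`` — a two-class linear discriminant with pooled covariance
  shrunk toward its diagonal; predicts the Gaussian posterior of presence.
* ``tree`` — greedy binary recursive partitioning minimizing Gini impurity;
  leaves predict their presence fraction.

All methods are deterministic given their inputs. Standardization constants
are learned on training data only and reused verbatim at projection time.
New methods can be plugged in with :func:`register_method`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .grids import MISSING, PREDICTORS, STATES, ClimateGrid

__all__ = [
    "NicheMethodSpec",
    "FittedNicheModel",
    "METHOD_REGISTRY",
    "register_method",
    "fit_method",
    "fit_envelope",
    "fit_logistic",
    "fit_discriminant",
    "fit_tree",
    "variable_importance",
    "project",
    "model_to_json",
    "model_from_json",
]

MODEL_FORMAT_VERSION = 1


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class NicheMethodSpec:
    """A registry method name plus its hyperparameters."""

    name: str
    hyperparams: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in METHOD_REGISTRY:
            raise ValueError(f"unknown niche method {self.name!r}; registered: {sorted(METHOD_REGISTRY)}")


@dataclass
class FittedNicheModel:
    """A fitted suitability model.

    ``predict`` takes an (n, len(predictors)) array in the training
    predictor order (or a DataFrame with those columns) and returns scores
    in [0, 1]. ``parameters`` is a JSON-serializable record of the fitted
    state.
    """

    method: str
    hyperparams: dict
    predictors: tuple[str, ...]
    parameters: dict
    training_summary: dict
    _predict_fn: Callable[[np.ndarray], np.ndarray]
    variable_importance_: dict[str, float] | None = None

    def predict(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[list(self.predictors)].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.predictors):
            raise ValueError(f"expected {len(self.predictors)} predictor columns, got {X.shape[1]}")
        out = np.clip(self._predict_fn(X), 0.0, 1.0)
        return out


def _design(table: pd.DataFrame, ecosystem: str, predictors: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    if ecosystem not in STATES:
        raise ValueError(f"unknown ecosystem {ecosystem!r}")
    X = table[list(predictors)].to_numpy(dtype=float)
    y = table[f"present_{ecosystem}"].to_numpy(dtype=int)
    return X, y


# ---------------------------------------------------------------- envelope


def fit_envelope(
    table: pd.DataFrame, ecosystem: str, trim_q: float = 0.025, predictors: Sequence[str] = PREDICTORS
) -> FittedNicheModel:
    """Surface-range envelope: quantile bounds of presence values.

    Per predictor the bounds are the [trim_q, 1 - trim_q] empirical
    quantiles (linear interpolation) of the presence rows; a point scores 1
    iff every predictor falls inside every bound.
    """
    if not 0.0 <= trim_q < 0.5:
        raise ValueError("trim_q must be in [0, 0.5)")
    X, y = _design(table, ecosystem, predictors)
    pres = X[y == 1]
    if pres.shape[0] < 10:
        raise FitError(f"envelope needs >= 10 presence rows, got {pres.shape[0]}")
    lo = np.quantile(pres, trim_q, axis=0)
    hi = np.quantile(pres, 1.0 - trim_q, axis=0)

    def _predict(Z: np.ndarray) -> np.ndarray:
        inside = np.all((Z >= lo) & (Z <= hi), axis=1)
        return inside.astype(float)

    return FittedNicheModel(
        method="envelope",
        hyperparams={"trim_q": trim_q},
        predictors=tuple(predictors),
        parameters={"lower": lo.tolist(), "upper": hi.tolist()},
        training_summary={"n_presence": int((y == 1).sum()), "n_absence": int((y == 0).sum())},
        _predict_fn=_predict,
    )


# ------------------------------------------------------------ logistic GLM


def _poly_design(Z: np.ndarray, degree: int) -> np.ndarray:
    cols = [np.ones(Z.shape[0]), *(Z[:, j] for j in range(Z.shape[1]))]
    if degree == 2:
        cols.extend(Z[:, j] ** 2 for j in range(Z.shape[1]))
    return np.column_stack(cols)


def fit_logistic(
    table: pd.DataFrame,
    ecosystem: str,
    degree: int = 2,
    predictors: Sequence[str] = PREDICTORS,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> FittedNicheModel:
    """Logistic regression by IRLS on standardized predictors.

    Polynomial terms up to ``degree`` (1 = linear, 2 = adds squared terms,
    no interactions). If IRLS diverges (complete separation), the fit
    restarts with a small ridge penalty and the fallback is flagged in
    ``training_summary['ridge_fallback']``.
    """
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    X, y = _design(table, ecosystem, predictors)
    if len(np.unique(y)) < 2:
        raise FitError("logistic fit needs both presence and absence rows")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mean) / sd
    D = _poly_design(Z, degree)

    def _irls(ridge: float) -> tuple[np.ndarray, np.ndarray, int, bool]:
        beta = np.zeros(D.shape[1])
        for it in range(1, max_iter + 1):
            eta = D @ beta
            p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
            w = np.clip(p * (1.0 - p), 1e-10, None)
            H = D.T @ (D * w[:, None]) + ridge * np.eye(D.shape[1])
            g = D.T @ (y - p) - ridge * beta
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                return beta, H, it, False
            beta = beta + step
            if np.max(np.abs(step)) < tol:
                return beta, H, it, True
            if np.max(np.abs(beta)) > 1e3:
                return beta, H, it, False
        return beta, H, max_iter, False

    ridge_fallback = False
    beta, H, n_iter, ok = _irls(0.0)
    if not ok:
        ridge_fallback = True
        beta, H, n_iter, ok = _irls(1e-4 * len(y))
        if not ok:
            raise FitError(f"logistic IRLS failed to converge after {n_iter} iterations (ridge fallback)")
    cov = np.linalg.inv(H)

    def _predict(Xnew: np.ndarray) -> np.ndarray:
        Dn = _poly_design((Xnew - mean) / sd, degree)
        return 1.0 / (1.0 + np.exp(-np.clip(Dn @ beta, -35, 35)))

    return FittedNicheModel(
        method="logistic_glm",
        hyperparams={"degree": degree},
        predictors=tuple(predictors),
        parameters={
            "coef": beta.tolist(),
            "cov": cov.tolist(),
            "mean": mean.tolist(),
            "sd": sd.tolist(),
            "degree": degree,
            "n_iter": n_iter,
        },
        training_summary={
            "n_presence": int((y == 1).sum()),
            "n_absence": int((y == 0).sum()),
            "ridge_fallback": ridge_fallback,
            "n_iter": n_iter,
        },
        _predict_fn=_predict,
    )


def logistic_coefficients_original_scale(model: FittedNicheModel) -> tuple[np.ndarray, np.ndarray]:
    """Map a degree-1 logistic fit back to the raw predictor scale.

    Returns ``(coef, se)`` with the intercept first. Only defined for
    degree-1 fits (the quadratic map is not affine in the raw predictors).
    """
    p = model.parameters
    if p["degree"] != 1:
        raise ValueError("original-scale coefficients are defined for degree-1 fits only")
    beta = np.asarray(p["coef"])
    cov = np.asarray(p["cov"])
    mean = np.asarray(p["mean"])
    sd = np.asarray(p["sd"])
    k = len(sd)
    # beta_x = A @ beta_z with affine reparametrization of the linear predictor
    A = np.zeros((k + 1, k + 1))
    A[0, 0] = 1.0
    A[0, 1:] = -mean / sd
    for j in range(k):
        A[j + 1, j + 1] = 1.0 / sd[j]
    coef = A @ beta
    se = np.sqrt(np.diag(A @ cov @ A.T))
    return coef, se


# ------------------------------------------------------------ discriminant


def fit_discriminant(
    table: pd.DataFrame, ecosystem: str, reg: float = 0.05, predictors: Sequence[str] = PREDICTORS
) -> FittedNicheModel:
    """Two-class linear discriminant with diagonal shrinkage.

    The pooled within-class covariance is shrunk toward its diagonal,
    ``S_reg = (1 - reg) * S + reg * diag(S)``; prediction is the posterior
    probability of presence under equal-covariance Gaussian class models
    with empirical priors.
    """
    if not 0.0 <= reg <= 1.0:
        raise ValueError("reg must be in [0, 1]")
    X, y = _design(table, ecosystem, predictors)
    k = X.shape[1]
    for cls in (0, 1):
        if (y == cls).sum() < k + 1:
            raise FitError(f"discriminant needs >= {k + 1} rows per class")
    mu0 = X[y == 0].mean(axis=0)
    mu1 = X[y == 1].mean(axis=0)
    n0, n1 = int((y == 0).sum()), int((y == 1).sum())
    S = ((X[y == 0] - mu0).T @ (X[y == 0] - mu0) + (X[y == 1] - mu1).T @ (X[y == 1] - mu1)) / (
        n0 + n1 - 2
    )
    S_reg = (1.0 - reg) * S + reg * np.diag(np.diag(S))
    try:
        S_inv = np.linalg.inv(S_reg)
    except np.linalg.LinAlgError as exc:
        raise FitError("singular pooled covariance; increase reg above 0") from exc
    w = S_inv @ (mu1 - mu0)
    b = -0.5 * (mu1 + mu0) @ w + np.log(n1 / n0)

    def _predict(Z: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-np.clip(Z @ w + b, -35, 35)))

    return FittedNicheModel(
        method="discriminant",
        hyperparams={"reg": reg},
        predictors=tuple(predictors),
        parameters={
            "weights": w.tolist(),
            "bias": float(b),
            "mean_absence": mu0.tolist(),
            "mean_presence": mu1.tolist(),
            "reg": reg,
        },
        training_summary={"n_presence": n1, "n_absence": n0},
        _predict_fn=_predict,
    )


# -------------------------------------------------------------------- tree


def _gini_best_split(
    X: np.ndarray, y: np.ndarray, min_leaf: int
) -> tuple[int, float, float] | None:
    """Best (feature, threshold, gain) under Gini; None if no valid split.

    Ties in gain keep the lowest feature index, then the lowest threshold
    (features scanned in order, thresholds ascending, strictly-better
    comparison).
    """
    n = len(y)
    parent_pos = y.sum()
    parent_gini = 1.0 - (parent_pos / n) ** 2 - ((n - parent_pos) / n) ** 2
    best: tuple[int, float, float] | None = None
    best_gain = 0.0
    for j in range(X.shape[1]):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        ys = y[order]
        cum_pos = np.cumsum(ys)
        # candidate split after position i (left = [0..i]); need distinct values
        idx = np.arange(n - 1)
        valid = (xs[idx] < xs[idx + 1]) & (idx + 1 >= min_leaf) & (n - idx - 1 >= min_leaf)
        cand = idx[valid]
        if cand.size == 0:
            continue
        nl = cand + 1.0
        nr = n - nl
        pl = cum_pos[cand] / nl
        pr = (parent_pos - cum_pos[cand]) / nr
        gini = (nl * (1 - pl**2 - (1 - pl) ** 2) + nr * (1 - pr**2 - (1 - pr) ** 2)) / n
        gains = parent_gini - gini
        k = int(np.argmax(gains))  # first max = lowest threshold on ties
        if gains[k] > best_gain + 1e-15:
            best_gain = float(gains[k])
            i = cand[k]
            best = (j, float(0.5 * (xs[i] + xs[i + 1])), best_gain)
    return best


def _grow_tree(X: np.ndarray, y: np.ndarray, depth: int, max_depth: int, min_leaf: int) -> dict:
    n = len(y)
    value = float(y.mean())
    if depth >= max_depth or n < 2 * min_leaf or value in (0.0, 1.0):
        return {"leaf": True, "value": value, "n": n}
    split = _gini_best_split(X, y, min_leaf)
    if split is None:
        return {"leaf": True, "value": value, "n": n}
    j, thr, _ = split
    left = X[:, j] <= thr
    return {
        "leaf": False,
        "feature": j,
        "threshold": thr,
        "n": n,
        "left": _grow_tree(X[left], y[left], depth + 1, max_depth, min_leaf),
        "right": _grow_tree(X[~left], y[~left], depth + 1, max_depth, min_leaf),
    }


def _tree_predict(node: dict, Z: np.ndarray, out: np.ndarray, mask: np.ndarray) -> None:
    if node["leaf"]:
        out[mask] = node["value"]
        return
    go_left = mask & (Z[:, node["feature"]] <= node["threshold"])
    _tree_predict(node["left"], Z, out, go_left)
    _tree_predict(node["right"], Z, out, mask & ~go_left)


def tree_features_used(node: dict) -> set[int]:
    if node["leaf"]:
        return set()
    return {node["feature"]} | tree_features_used(node["left"]) | tree_features_used(node["right"])


def fit_tree(
    table: pd.DataFrame,
    ecosystem: str,
    max_depth: int = 6,
    min_leaf: int = 10,
    predictors: Sequence[str] = PREDICTORS,
) -> FittedNicheModel:
    """Classification tree: greedy Gini partitioning, leaf presence fraction."""
    X, y = _design(table, ecosystem, predictors)
    root = _grow_tree(X, y, 0, max_depth, min_leaf)

    def _predict(Z: np.ndarray) -> np.ndarray:
        out = np.empty(Z.shape[0])
        _tree_predict(root, Z, out, np.ones(Z.shape[0], dtype=bool))
        return out

    return FittedNicheModel(
        method="tree",
        hyperparams={"max_depth": max_depth, "min_leaf": min_leaf},
        predictors=tuple(predictors),
        parameters={"root": root},
        training_summary={"n_presence": int((y == 1).sum()), "n_absence": int((y == 0).sum())},
        _predict_fn=_predict,
    )


# ----------------------------------------------------------------- registry

METHOD_REGISTRY: dict[str, Callable[..., FittedNicheModel]] = {}


def register_method(name: str, fit_fn: Callable[..., FittedNicheModel]) -> None:
    """Register a fit function ``fit_fn(table, ecosystem, **hyperparams)``.

    The plug-in point for additional suitability methods: fitted models must
    expose ``predict`` returning values in [0, 1].
    """
    METHOD_REGISTRY[name] = fit_fn


register_method("envelope", fit_envelope)
register_method("logistic_glm", fit_logistic)
register_method("discriminant", fit_discriminant)
register_method("tree", fit_tree)


def fit_method(spec: NicheMethodSpec, table: pd.DataFrame, ecosystem: str) -> FittedNicheModel:
    """Fit the registry method named by ``spec`` with its hyperparameters."""
    return METHOD_REGISTRY[spec.name](table, ecosystem, **dict(spec.hyperparams))


# --------------------------------------------------- importance & projection


def variable_importance(
    model: FittedNicheModel, table: pd.DataFrame, n_shuffles: int = 5, seed: int = 0
) -> dict[str, float]:
    """Permutation importance: 1 - correlation of original vs permuted scores.

    For each predictor, its column is permuted and the Pearson correlation
    between the model's original and permuted predictions is computed;
    importance is ``1 - mean correlation`` over ``n_shuffles`` permutations,
    clipped to [0, 1]. If the original predictions are constant, every
    importance is 0 (flagged on the model's training summary); if only the
    permuted predictions are constant the correlation is taken as 0.
    """
    rng = np.random.default_rng(seed)
    X = table[list(model.predictors)].to_numpy(dtype=float)
    base = model.predict(X)
    out: dict[str, float] = {}
    if np.std(base) == 0:
        model.training_summary["constant_predictions"] = True
        out = {p: 0.0 for p in model.predictors}
    else:
        for j, pred in enumerate(model.predictors):
            corrs = []
            for _ in range(n_shuffles):
                Xp = X.copy()
                Xp[:, j] = Xp[rng.permutation(len(Xp)), j]
                perm = model.predict(Xp)
                corrs.append(1.0 if np.array_equal(perm, base) else _safe_corr(base, perm))
            out[pred] = float(np.clip(1.0 - np.mean(corrs), 0.0, 1.0))
    model.variable_importance_ = out
    return out


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(b) == 0 or np.std(a) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def project(model: FittedNicheModel, climate: ClimateGrid) -> np.ndarray:
    """Project a fitted model over a climate grid.

    Returns a float array of per-pixel suitability in [0, 1]; nodata pixels
    are NaN.
    """
    for p in model.predictors:
        if p not in climate.layers:
            raise ValueError(f"climate grid is missing layer {p!r} required by the model")
    valid = ~climate.nodata_mask
    rows, cols = np.nonzero(valid)
    X = np.column_stack([climate.layers[p][rows, cols] for p in model.predictors])
    out = np.full(climate.shape, np.nan)
    out[rows, cols] = model.predict(X)
    return out


# ------------------------------------------------------------- serialization


def model_to_json(model: FittedNicheModel) -> str:
    """Serialize a fitted model to a versioned JSON document."""
    return json.dumps(
        {
            "format_version": MODEL_FORMAT_VERSION,
            "method": model.method,
            "hyperparams": model.hyperparams,
            "predictors": list(model.predictors),
            "parameters": model.parameters,
            "training_summary": model.training_summary,
        }
    )


def model_from_json(doc: str) -> FittedNicheModel:
    """Rebuild a fitted model (with a working ``predict``) from JSON."""
    d = json.loads(doc)
    if d.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {d.get('format_version')}")
    method = d["method"]
    params = d["parameters"]
    predictors = tuple(d["predictors"])
    if method == "envelope":
        lo = np.asarray(params["lower"])
        hi = np.asarray(params["upper"])

        def _predict(Z: np.ndarray) -> np.ndarray:
            return np.all((Z >= lo) & (Z <= hi), axis=1).astype(float)

    elif method == "logistic_glm":
        beta = np.asarray(params["coef"])
        mean = np.asarray(params["mean"])
        sd = np.asarray(params["sd"])
        degree = params["degree"]

        def _predict(Z: np.ndarray) -> np.ndarray:
            D = _poly_design((Z - mean) / sd, degree)
            return 1.0 / (1.0 + np.exp(-np.clip(D @ beta, -35, 35)))

    elif method == "discriminant":
        w = np.asarray(params["weights"])
        b = params["bias"]

        def _predict(Z: np.ndarray) -> np.ndarray:
            return 1.0 / (1.0 + np.exp(-np.clip(Z @ w + b, -35, 35)))

    elif method == "tree":
        root = params["root"]

        def _predict(Z: np.ndarray) -> np.ndarray:
            out = np.empty(Z.shape[0])
            _tree_predict(root, Z, out, np.ones(Z.shape[0], dtype=bool))
            return out

    else:
        raise ValueError(f"cannot rebuild unknown method {method!r}")
    return FittedNicheModel(
        method=method,
        hyperparams=d["hyperparams"],
        predictors=predictors,
        parameters=params,
        training_summary=d["training_summary"],
        _predict_fn=_predict,
    )
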