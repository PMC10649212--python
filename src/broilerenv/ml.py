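"""Cross-validated prediction of 35-d performance and variable importance.

Three model families predict body weight or FCR at 35 d from early (<= 21 d)
performance plus farm attributes: multiple linear regression with VIF-based
collinearity filtering and backward p-value elimination, a random-forest
regressor, and a single-hidden-layer neural network with sigmoid activation.
All are evaluated with k-fold cross-validation (R^2 and RMSE averaged over
folds), with dummy coding and min-max scaling fitted on the training folds
only (fitting the scaler globally would leak held-out information).

Variable importance comes in three flavours matching the model families:

* ``pct_ss``   — partial (Type III) sum of squares of each kept MLR
  predictor over the model sum of squares, in percent;
* ``pct_inc_mse`` — permutation importance of a forest: percent increase of
  the out-of-bag MSE when one column is permuted;
* ``connection_weights`` — Olden's measure for a one-hidden-layer network:
  sum over hidden nodes of (input->hidden weight) x (hidden->output
  weight), signed, ranked by magnitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestRegressor
from sklearn.neural_network import MLPRegressor

__all__ = [
    "ModelMatrix",
    "CVResult",
    "ImportanceRanking",
    "encode_and_scale",
    "kfold_split",
    "evaluate",
    "fit_mlr_selected",
    "mlr_contribution",
    "cross_validate_mlr",
    "fit_rf",
    "permutation_importance",
    "fit_ann",
    "olden_importance",
]


@dataclass
class ModelMatrix:
    """Dummy-coded, [0, 1]-scaled design matrix with frozen scaling params.

    ``transform`` re-applies the stored dummy layout and min/max to new raw
    rows; held-out values outside the fitting range scale below 0 or above 1
    by design (the parameters are frozen at fit time).
    """

    X: pd.DataFrame
    y: pd.Series
    col_min: pd.Series
    col_max: pd.Series
    dummy_columns: list[str]
    reference_levels: dict[str, str]
    dropped_constant: list[str] = field(default_factory=list)

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)

    def transform(self, raw: pd.DataFrame) -> pd.DataFrame:
        enc = _dummy_encode(raw)
        enc = enc.reindex(columns=self.columns, fill_value=0.0)
        rng = (self.col_max - self.col_min).replace(0, 1.0)
        return (enc - self.col_min) / rng


def _dummy_encode(raw: pd.DataFrame) -> pd.DataFrame:
    cat_cols = [c for c in raw.columns
                if raw[c].dtype == object or isinstance(raw[c].dtype, pd.CategoricalDtype)]
    enc = pd.get_dummies(raw, columns=cat_cols, drop_first=True, dtype=float)
    return enc.astype(float)


def encode_and_scale(raw: pd.DataFrame, response: str) -> ModelMatrix:
    """Dummy-code categoricals (first level as reference) and scale to [0, 1].

    Rows with any missing predictor or response are dropped.  Constant
    columns carry no information and are dropped with a warning.
    """
    if response not in raw.columns:
        raise ValueError(f"response column {response!r} not in table")
    data = raw.dropna(axis=0, how="any").reset_index(drop=True)
    y = data[response].astype(float)
    preds = data.drop(columns=[response])
    refs = {}
    for c in preds.columns:
        if preds[c].dtype == object or isinstance(preds[c].dtype, pd.CategoricalDtype):
            levels = sorted(preds[c].astype(str).unique())
            refs[c] = levels[0]
    enc = _dummy_encode(preds)
    constant = [c for c in enc.columns if enc[c].nunique() <= 1]
    if constant:
        warnings.warn(f"dropping constant predictor columns: {constant}")
        enc = enc.drop(columns=constant)
    col_min = enc.min()
    col_max = enc.max()
    rng = (col_max - col_min).replace(0, 1.0)
    X = (enc - col_min) / rng
    dummies = [c for c in X.columns if any(c.startswith(f"{v}_") for v in refs)]
    return ModelMatrix(X=X, y=y, col_min=col_min, col_max=col_max,
                       dummy_columns=dummies, reference_levels=refs,
                       dropped_constant=constant)


def kfold_split(n: int, k: int = 5, seed: int = 0) -> np.ndarray:
    """Random fold label (0..k-1) per row; fold sizes differ by at most one."""
    if n < k:
        raise ValueError(f"cannot split {n} rows into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, k)):
        labels[chunk] = f
    return labels


def evaluate(predictions, truth) -> tuple[float, float]:
    """(R^2, RMSE) of predictions against truth: R^2 = 1 - SSE/SST."""
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape or p.ndim != 1 or p.size < 2:
        raise ValueError("predictions and truth must be equal-length vectors, n >= 2")
    sst = float(((t - t.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("R^2 undefined for constant truth")
    sse = float(((t - p) ** 2).sum())
    return 1.0 - sse / sst, float(np.sqrt(sse / p.size))


@dataclass
class CVResult:
    fold_r2: list[float]
    fold_rmse: list[float]
    seed: int

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.fold_r2))

    @property
    def mean_rmse(self) -> float:
        return float(np.mean(self.fold_rmse))


@dataclass
class ImportanceRanking:
    method: str
    table: pd.DataFrame  # columns: variable, score, rank


def _rank_table(method: str, scores: dict[str, float]) -> ImportanceRanking:
    tab = pd.DataFrame({"variable": list(scores), "score": list(scores.values())})
    key = tab["score"].abs() if method == "connection_weights" else tab["score"]
    tab["rank"] = key.rank(ascending=False, method="first").astype(int)
    tab = tab.sort_values("rank", kind="stable").reset_index(drop=True)
    return ImportanceRanking(method=method, table=tab)


# ----------------------------------------------------------------- MLR ----

@dataclass
class MlrModel:
    results: object                 # statsmodels RegressionResults
    columns: list[str]
    dropped_vif: list[str]
    dropped_pvalue: list[str]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return np.asarray(self.results.predict(sm.add_constant(X[self.columns], has_constant="add")))


def _vif(X: pd.DataFrame, col: str) -> float:
    others = X.drop(columns=[col])
    design = sm.add_constant(others, has_constant="add")
    r2 = sm.OLS(X[col], design).fit().rsquared
    return np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)


def fit_mlr_selected(X: pd.DataFrame, y, vif_max: float = 10.0,
                     alpha: float = 0.05) -> MlrModel:
    """OLS after VIF filtering and backward elimination by p-value.

    Repeatedly drops the predictor with the highest VIF while any exceeds
    ``vif_max``, then drops the predictor with the largest p >= alpha until
    all remaining are significant.  Raises when nothing survives.
    """
    X = X.copy()
    y = pd.Series(np.asarray(y, dtype=float), index=X.index)
    dropped_vif = []
    while X.shape[1] > 1:
        vifs = {c: _vif(X, c) for c in X.columns}
        worst = max(vifs, key=lambda c: vifs[c])
        if vifs[worst] <= vif_max:
            break
        X = X.drop(columns=[worst])
        dropped_vif.append(worst)
    dropped_p = []
    while X.shape[1] >= 1:
        res = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
        pvals = res.pvalues.drop("const", errors="ignore")
        worst = pvals.idxmax()
        if pvals[worst] < alpha:
            break
        X = X.drop(columns=[worst])
        dropped_p.append(worst)
        if X.shape[1] == 0:
            raise ValueError("backward elimination removed every predictor")
    res = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    return MlrModel(results=res, columns=list(X.columns),
                    dropped_vif=dropped_vif, dropped_pvalue=dropped_p)


def mlr_contribution(model: MlrModel, X: pd.DataFrame, y) -> ImportanceRanking:
    """Percent contribution of each kept predictor: partial SS / model SS.

    The partial (Type III) sum of squares of predictor j is the increase in
    residual SS when j is removed from the full model; the denominator is
    the model (regression) sum of squares.  Partial SS is order-invariant,
    and for mutually orthogonal predictors equals the sequential SS.
    """
    y = np.asarray(y, dtype=float)
    cols = model.columns
    full = sm.OLS(y, sm.add_constant(X[cols], has_constant="add")).fit()
    sse_full = float(full.ssr)
    sst = float(((y - y.mean()) ** 2).sum())
    ss_model = sst - sse_full
    scores = {}
    for c in cols:
        reduced_cols = [k for k in cols if k != c]
        design = sm.add_constant(X[reduced_cols], has_constant="add")
        sse_red = float(sm.OLS(y, design).fit().ssr)
        scores[c] = 100.0 * (sse_red - sse_full) / ss_model
    return _rank_table("pct_ss", scores)


def cross_validate_mlr(raw: pd.DataFrame, response: str, k: int = 5,
                       seed: int = 0, vif_max: float = 10.0,
                       alpha: float = 0.05) -> CVResult:
    """k-fold CV of the selected MLR with all preprocessing inside the folds."""
    data = raw.dropna(axis=0, how="any").reset_index(drop=True)
    folds = kfold_split(len(data), k=k, seed=seed)
    r2s, rmses = [], []
    for f in range(k):
        train = data[folds != f]
        test = data[folds == f]
        mm = encode_and_scale(train, response)
        model = fit_mlr_selected(mm.X, mm.y, vif_max=vif_max, alpha=alpha)
        X_test = mm.transform(test.drop(columns=[response]))
        pred = model.predict(X_test)
        r2, rmse = evaluate(pred, test[response].to_numpy(float))
        r2s.append(r2)
        rmses.append(rmse)
    return CVResult(fold_r2=r2s, fold_rmse=rmses, seed=seed)


# ------------------------------------------------------------------ RF ----

@dataclass
class RfModel:
    forest: RandomForestRegressor
    mtry: int
    cv: CVResult
    oob_mse: float


def _oob_sets(forest: RandomForestRegressor, n: int) -> list[np.ndarray]:
    """Per-tree out-of-bag row indices, reproducing the bootstrap draws."""
    from sklearn.utils import check_random_state

    sets = []
    for tree in forest.estimators_:
        rs = check_random_state(tree.random_state)
        sampled = rs.randint(0, n, n)
        mask = np.ones(n, dtype=bool)
        mask[sampled] = False
        sets.append(np.flatnonzero(mask))
    return sets


def _oob_predict(forest, X: np.ndarray, oob_sets) -> np.ndarray:
    n = X.shape[0]
    total = np.zeros(n)
    count = np.zeros(n)
    for tree, oob in zip(forest.estimators_, oob_sets):
        if oob.size == 0:
            continue
        total[oob] += tree.predict(X[oob])
        count[oob] += 1
    seen = count > 0
    pred = np.full(n, np.nan)
    pred[seen] = total[seen] / count[seen]
    return pred


def _oob_mse(forest, X: np.ndarray, y: np.ndarray, oob_sets) -> float:
    pred = _oob_predict(forest, X, oob_sets)
    seen = ~np.isnan(pred)
    return float(np.mean((pred[seen] - y[seen]) ** 2))


def fit_rf(X: pd.DataFrame, y, mtry_grid=None, n_trees: int = 300,
           k: int = 5, seed: int = 0) -> RfModel:
    """Random forest with mtry (max_features) chosen by CV mean RMSE."""
    y = np.asarray(y, dtype=float)
    p = X.shape[1]
    if mtry_grid is None:
        mtry_grid = sorted({max(1, p // 3), max(1, p // 2), p})
    folds = kfold_split(len(X), k=k, seed=seed)
    best = None
    for mtry in mtry_grid:
        mtry = min(int(mtry), p)
        r2s, rmses = [], []
        for f in range(k):
            tr, te = folds != f, folds == f
            rf = RandomForestRegressor(n_estimators=n_trees, max_features=mtry,
                                       random_state=seed, bootstrap=True)
            rf.fit(X[tr], y[tr])
            r2, rmse = evaluate(rf.predict(X[te]), y[te])
            r2s.append(r2)
            rmses.append(rmse)
        cv = CVResult(fold_r2=r2s, fold_rmse=rmses, seed=seed)
        if best is None or cv.mean_rmse < best[1].mean_rmse:
            best = (mtry, cv)
    mtry, cv = best
    forest = RandomForestRegressor(n_estimators=n_trees, max_features=mtry,
                                   random_state=seed, bootstrap=True)
    forest.fit(X, y)
    oob = _oob_mse(forest, X.to_numpy(float), y, _oob_sets(forest, len(X)))
    return RfModel(forest=forest, mtry=mtry, cv=cv, oob_mse=oob)


def permutation_importance(model: RfModel, X: pd.DataFrame, y,
                           n_reps: int = 10, seed: int = 0) -> ImportanceRanking:
    """Out-of-bag permutation importance as percent increase in MSE.

    For each variable, its column is permuted and the forest's out-of-bag
    MSE recomputed; the score is 100 * (MSE_perm - MSE_orig) / MSE_orig
    averaged over ``n_reps`` permutations.
    """
    y = np.asarray(y, dtype=float)
    Xn = X.to_numpy(float)
    n = Xn.shape[0]
    oob_sets = _oob_sets(model.forest, n)
    mse0 = _oob_mse(model.forest, Xn, y, oob_sets)
    rng = np.random.default_rng(seed)
    scores = {}
    for j, col in enumerate(X.columns):
        incs = []
        for _ in range(n_reps):
            Xp = Xn.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            mse = _oob_mse(model.forest, Xp, y, oob_sets)
            incs.append(100.0 * (mse - mse0) / mse0)
        scores[col] = float(np.mean(incs))
    return _rank_table("pct_inc_mse", scores)


# ----------------------------------------------------------------- ANN ----

@dataclass
class AnnModel:
    net: MLPRegressor
    n_nodes: int
    cv: CVResult
    y_min: float
    y_max: float
    converged: bool

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        z = self.net.predict(np.asarray(X, dtype=float))
        return z * (self.y_max - self.y_min) + self.y_min


def _train_ann(X: np.ndarray, z: np.ndarray, nodes: int, decay: float,
               max_iter: int, n_restarts: int, seed: int):
    """Best-of-restarts single-hidden-layer sigmoid network on scaled data."""
    best = None
    converged = False
    for r in range(n_restarts):
        net = MLPRegressor(hidden_layer_sizes=(nodes,), activation="logistic",
                           solver="lbfgs", alpha=decay, max_iter=max_iter,
                           random_state=seed * 1000 + r)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net.fit(X, z)
        loss = float(np.mean((net.predict(X) - z) ** 2))
        if best is None or loss < best[1]:
            best = (net, loss)
        converged = converged or net.n_iter_ < max_iter
    return best[0], converged


def fit_ann(X: pd.DataFrame, y, nodes_grid=(1, 2, 3, 5), decay: float = 1e-3,
            max_iter: int = 500, n_restarts: int = 3, k: int = 5,
            seed: int = 0) -> AnnModel:
    """Single-hidden-layer network; node count selected by CV mean RMSE.

    The response is min-max scaled to [0, 1] for training and predictions
    are back-transformed, so RMSE is in response units.  Non-convergence
    after all restarts is flagged on the returned model, not raised.
    """
    y = np.asarray(y, dtype=float)
    y_min, y_max = float(y.min()), float(y.max())
    if y_max == y_min:
        y_max = y_min + 1.0
    z = (y - y_min) / (y_max - y_min)
    Xn = np.asarray(X, dtype=float)
    folds = kfold_split(len(X), k=k, seed=seed)
    best = None
    for nodes in nodes_grid:
        r2s, rmses = [], []
        for f in range(k):
            tr, te = folds != f, folds == f
            net, _ = _train_ann(Xn[tr], z[tr], nodes, decay, max_iter,
                                n_restarts, seed)
            pred = net.predict(Xn[te]) * (y_max - y_min) + y_min
            r2, rmse = evaluate(pred, y[te])
            r2s.append(r2)
            rmses.append(rmse)
        cv = CVResult(fold_r2=r2s, fold_rmse=rmses, seed=seed)
        if best is None or cv.mean_rmse < best[1].mean_rmse:
            best = (nodes, cv)
    nodes, cv = best
    net, converged = _train_ann(Xn, z, nodes, decay, max_iter, n_restarts, seed)
    return AnnModel(net=net, n_nodes=nodes, cv=cv, y_min=y_min, y_max=y_max,
                    converged=converged)


def olden_importance(model: AnnModel | MLPRegressor,
                     feature_names=None) -> ImportanceRanking:
    """Olden connection-weights importance for a one-hidden-layer network.

    importance(input i) = sum_h w[i, h] * w[h, out]; signed, ranked by
    absolute value.  Any other architecture raises.
    """
    net = model.net if isinstance(model, AnnModel) else model
    if len(net.coefs_) != 2:
        raise ValueError("connection-weights importance requires exactly one hidden layer")
    w_ih, w_ho = net.coefs_
    raw = w_ih @ w_ho  # (p, 1)
    raw = np.asarray(raw).ravel()
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(raw.size)]
    return _rank_table("connection_weights",
                       dict(zip(feature_names, raw.astype(float))))
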