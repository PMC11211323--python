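"""Risk classifier: clinical-table preparation, SMOTE, tuning, XGBoost.

Branches: ``multimodal`` (MRI latents + ECG latents + clinical), or a single
block (``mri`` / ``ecg`` / ``clinical``). Preparation steps (column filter,
random-forest imputation, one-hot + z-score encoding) are fitted on
development rows only and applied unchanged to external rows; SMOTE balances
classes inside training data only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from xgboost import XGBClassifier

from .metrics import auroc

BRANCHES = ("multimodal", "mri", "ecg", "clinical")
MAX_MISSING_FRACTION = 0.30


class StratificationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Missing data
# ---------------------------------------------------------------------------


def filter_missing_columns(df: pd.DataFrame, max_fraction: float = MAX_MISSING_FRACTION) -> pd.DataFrame:
    """Drop feature columns with strictly more than ``max_fraction`` missing."""
    frac = df.isna().mean()
    keep = frac.index[frac <= max_fraction]
    return df[list(keep)]


def impute_missing(
    df: pd.DataFrame,
    seed: int = 0,
    max_rounds: int = 10,
    tol: float = 1e-3,
    n_estimators: int = 50,
) -> pd.DataFrame:
    """Iterative random-forest imputation (missForest-style).

    Columns above the 30%-missing threshold are removed first. Missing cells
    are initialized with the column mean (continuous) or mode (categorical);
    then, visiting incomplete columns from least to most missing, a random
    forest is fitted on the currently-complete remainder and missing entries
    are re-predicted. Iteration stops when successive fills change less than
    ``tol`` (relative, continuous; disagreement fraction, categorical) or
    after ``max_rounds``.
    """
    df = filter_missing_columns(df)
    out = df.copy()
    na_mask = df.isna()
    incomplete = [c for c in df.columns if na_mask[c].any()]
    if not incomplete:
        return out
    is_num = {c: pd.api.types.is_numeric_dtype(df[c]) for c in df.columns}
    for c in df.columns:
        if na_mask[c].any():
            fill = df[c].mean() if is_num[c] else df[c].mode(dropna=True).iloc[0]
            out[c] = out[c].fillna(fill)
    # encode categoricals as integer codes for the forests
    def design(frame: pd.DataFrame, drop: str) -> np.ndarray:
        cols = []
        for c in frame.columns:
            if c == drop:
                continue
            col = frame[c]
            cols.append(col.to_numpy(float) if is_num[c] else col.astype("category").cat.codes.to_numpy(float))
        return np.column_stack(cols)

    order = sorted(incomplete, key=lambda c: na_mask[c].sum())
    rng = np.random.default_rng(seed)
    for _ in range(max_rounds):
        max_change = 0.0
        for c in order:
            miss = na_mask[c].to_numpy()
            X_obs = design(out.loc[~miss], c)
            X_mis = design(out.loc[miss], c)
            y_obs = out.loc[~miss, c]
            rf_seed = int(rng.integers(2**31))
            if is_num[c]:
                rf = RandomForestRegressor(n_estimators=n_estimators, random_state=rf_seed, n_jobs=1)
                rf.fit(X_obs, y_obs.to_numpy(float))
                new = rf.predict(X_mis)
                old = out.loc[miss, c].to_numpy(float)
                scale = max(float(df[c].std(skipna=True)), 1e-9)
                max_change = max(max_change, float(np.max(np.abs(new - old))) / scale if new.size else 0.0)
                out.loc[miss, c] = new
            else:
                rf = RandomForestClassifier(n_estimators=n_estimators, random_state=rf_seed, n_jobs=1)
                rf.fit(X_obs, y_obs.astype(str))
                new = rf.predict(X_mis)
                old = out.loc[miss, c].astype(str).to_numpy()
                max_change = max(max_change, float(np.mean(new != old)) if new.size else 0.0)
                out.loc[miss, c] = new
        if max_change < tol:
            break
    return out


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------


class FeatureEncoder:
    """One-hot categoricals + z-score continuous, fitted on development rows.

    The fitted category lists and standardization statistics are frozen; the
    same transform is applied to external rows. Unseen categories map to
    all-zero indicators (with a warning).
    """

    def __init__(self):
        self.categories_: dict[str, list] = {}
        self.means_: dict[str, float] = {}
        self.sds_: dict[str, float] = {}
        self.columns_: list[str] = []

    def fit(self, df: pd.DataFrame) -> "FeatureEncoder":
        self.categories_.clear()
        self.means_.clear()
        self.sds_.clear()
        cols = []
        for c in df.columns:
            if pd.api.types.is_numeric_dtype(df[c]):
                self.means_[c] = float(df[c].mean())
                sd = float(df[c].std(ddof=0))
                self.sds_[c] = sd if sd > 1e-12 else 1.0
                cols.append(c)
            else:
                levels = sorted(df[c].dropna().astype(str).unique())
                self.categories_[c] = levels
                cols.extend(f"{c}={lv}" for lv in levels)
        self.columns_ = cols
        return self

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        if not self.columns_:
            raise RuntimeError("encoder is not fitted")
        out = {}
        for c in df.columns:
            if c in self.means_:
                out[c] = (df[c].to_numpy(float) - self.means_[c]) / self.sds_[c]
            elif c in self.categories_:
                vals = df[c].astype(str)
                unseen = set(vals.unique()) - set(self.categories_[c])
                if unseen:
                    warnings.warn(f"unseen categories in {c!r}: {sorted(unseen)}; encoded as all-zero")
                for lv in self.categories_[c]:
                    out[f"{c}={lv}"] = (vals == lv).to_numpy(float)
        return pd.DataFrame(out, index=df.index)[self.columns_]

    def fit_transform(self, df: pd.DataFrame) -> pd.DataFrame:
        return self.fit(df).transform(df)


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------


def smote_oversample(
    X: np.ndarray, y: np.ndarray, k: int = 5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Balance classes 1:1 by synthetic minority interpolation.

    Each synthetic row is ``x + lambda * (x_nn - x)`` with ``lambda ~ U(0,1)``
    and ``x_nn`` one of the ``k`` nearest minority neighbours of ``x``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    counts = np.bincount(y, minlength=2)
    minority = int(np.argmin(counts))
    n_min, n_maj = counts[minority], counts[1 - minority]
    if n_min < 2:
        raise ValueError("SMOTE requires at least 2 minority samples")
    n_new = int(n_maj - n_min)
    if n_new <= 0:
        return X, y
    Xm = X[y == minority]
    k_eff = min(k, n_min - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xm)
    _, idx = nn.kneighbors(Xm)  # column 0 is the point itself
    rng = np.random.default_rng(seed)
    base = rng.integers(0, n_min, n_new)
    pick = rng.integers(1, k_eff + 1, n_new)
    lam = rng.random(n_new)[:, None]
    neighbours = Xm[idx[base, pick]]
    synthetic = Xm[base] + lam * (neighbours - Xm[base])
    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_new, minority)])
    return X_out, y_out


# ---------------------------------------------------------------------------
# Hyperparameter search (GP expected-improvement)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SearchSpace:
    """Ranges per XGBoost hyperparameter: (low, high); log/integer flags fixed."""

    max_depth: tuple[int, int] = (2, 8)
    learning_rate: tuple[float, float] = (0.01, 0.3)  # log scale
    n_estimators: tuple[int, int] = (50, 500)
    subsample: tuple[float, float] = (0.5, 1.0)
    min_child_weight: tuple[float, float] = (1.0, 10.0)
    reg_alpha: tuple[float, float] = (0.0, 5.0)
    reg_lambda: tuple[float, float] = (0.0, 5.0)

    _LOG = ("learning_rate",)
    _INT = ("max_depth", "n_estimators")

    def names(self) -> list[str]:
        return ["max_depth", "learning_rate", "n_estimators", "subsample",
                "min_child_weight", "reg_alpha", "reg_lambda"]

    def __post_init__(self):
        for name in self.names():
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"empty range for {name}")

    def from_unit(self, u: np.ndarray) -> dict:
        out = {}
        for ui, name in zip(u, self.names()):
            lo, hi = getattr(self, name)
            if name in self._LOG:
                val = float(np.exp(np.log(lo) + ui * (np.log(hi) - np.log(lo))))
            else:
                val = float(lo + ui * (hi - lo))
            if name in self._INT:
                val = int(round(val))
            out[name] = val
        return out

    @property
    def is_point(self) -> bool:
        return all(getattr(self, n)[0] == getattr(self, n)[1] for n in self.names())


def _cv_auroc(X: np.ndarray, y: np.ndarray, params: dict, k_folds: int, seed: int, smote_k: int = 5) -> float:
    """Stratified k-fold CV AUROC with SMOTE refit inside each training fold."""
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    aucs = []
    for fold, (tr, va) in enumerate(skf.split(X, y)):
        if y[va].min() == y[va].max() or y[tr].min() == y[tr].max():
            raise StratificationError("a CV fold contains a single class")
        Xb, yb = smote_oversample(X[tr], y[tr], k=smote_k, seed=seed + fold)
        model = _make_xgb(params, seed)
        model.fit(Xb, yb)
        aucs.append(auroc(model.predict_proba(X[va])[:, 1], y[va]))
    return float(np.mean(aucs))


def _make_xgb(params: dict, seed: int) -> XGBClassifier:
    return XGBClassifier(
        **params,
        objective="binary:logistic",
        tree_method="hist",
        random_state=seed,
        n_jobs=1,
        eval_metric="logloss",
    )


def tune_hyperparameters(
    X,
    y,
    space: SearchSpace = SearchSpace(),
    k_folds: int = 5,
    n_trials: int = 50,
    seed: int = 0,
) -> tuple[dict, pd.DataFrame]:
    """Sequential model-based search maximizing mean CV AUROC.

    A Gaussian-process surrogate (Matern kernel) over the unit hypercube is
    fitted to past trials; each new point maximizes expected improvement over
    a seeded random candidate set. The first third of the budget is random
    exploration. Deterministic given the seed. Returns (best config, trial log).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if space.is_point:
        cfg = space.from_unit(np.zeros(len(space.names())))
        score = _cv_auroc(X, y, cfg, k_folds, seed)
        return cfg, pd.DataFrame([{**cfg, "cv_auroc": score, "trial": 0}])

    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import Matern
    from scipy.stats import norm as _norm

    rng = np.random.default_rng(seed)
    d = len(space.names())
    n_init = max(5, n_trials // 3)
    tried_u: list[np.ndarray] = []
    scores: list[float] = []
    log = []
    for trial in range(n_trials):
        if trial < n_init:
            u = rng.random(d)
        else:
            # fixed length scale: trial counts are too small to fit kernel
            # hyperparameters stably, and collapsed dimensions degenerate
            gp = GaussianProcessRegressor(
                kernel=Matern(nu=2.5, length_scale=np.full(d, 0.3),
                              length_scale_bounds="fixed"),
                alpha=1e-4,
                normalize_y=True,
                random_state=seed,
            )
            gp.fit(np.array(tried_u), -np.array(scores))  # GP minimizes -AUROC
            cand = rng.random((256, d))
            mu_c, sd_c = gp.predict(cand, return_std=True)
            best_obs = float(np.min(-np.array(scores)))
            imp = best_obs - mu_c
            with np.errstate(divide="ignore", invalid="ignore"):
                zz = np.where(sd_c > 0, imp / sd_c, 0.0)
                ei = np.where(sd_c > 0, imp * _norm.cdf(zz) + sd_c * _norm.pdf(zz), 0.0)
            u = cand[int(np.argmax(ei))]
        cfg = space.from_unit(u)
        score = _cv_auroc(X, y, cfg, k_folds, seed)
        tried_u.append(u)
        scores.append(score)
        log.append({**cfg, "cv_auroc": score, "trial": trial})
    best = int(np.argmax(scores))
    return space.from_unit(tried_u[best]), pd.DataFrame(log)


# ---------------------------------------------------------------------------
# Training / prediction
# ---------------------------------------------------------------------------


@dataclass
class RiskModel:
    """A trained branch classifier with its frozen feature contract."""

    branch: str
    model: XGBClassifier
    feature_names: list[str]
    config: dict
    seed: int


def train_classifier(
    X: pd.DataFrame, y, config: Optional[dict] = None, seed: int = 0,
    branch: str = "multimodal", smote_k: int = 5, use_smote: bool = True,
) -> RiskModel:
    """Fit the gradient-boosted ensemble on (optionally SMOTE-balanced) data."""
    X = pd.DataFrame(X)
    y = np.asarray(y).astype(int)
    if y.min() == y.max():
        raise ValueError("training labels contain a single class")
    config = dict(config or {"max_depth": 3, "learning_rate": 0.1, "n_estimators": 200})
    names = [str(c) for c in X.columns]
    Xa = X.to_numpy(float)
    if use_smote:
        Xa, y = smote_oversample(Xa, y, k=smote_k, seed=seed)
    model = _make_xgb(config, seed)
    model.fit(Xa, y)
    return RiskModel(branch=branch, model=model, feature_names=names, config=config, seed=seed)


def save_risk_model(rm: RiskModel, path) -> None:
    """Persist a trained branch model: booster JSON + sidecar contract."""
    import json
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rm.model.get_booster().save_model(str(path))
    sidecar = {"branch": rm.branch, "feature_names": rm.feature_names,
               "config": rm.config, "seed": rm.seed}
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(sidecar, indent=2))


def load_risk_model(path) -> RiskModel:
    import json
    from pathlib import Path

    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    model = _make_xgb(sidecar["config"], sidecar["seed"])
    model.load_model(str(path))
    return RiskModel(branch=sidecar["branch"], model=model,
                     feature_names=sidecar["feature_names"],
                     config=sidecar["config"], seed=sidecar["seed"])


@dataclass(frozen=True)
class RiskPrediction:
    patient_id: str
    probability: float
    branch: str


def predict_risk(rm: RiskModel, X: pd.DataFrame, patient_ids=None) -> list[RiskPrediction]:
    """Predicted event probabilities, row order preserved."""
    X = pd.DataFrame(X).copy()
    X.columns = X.columns.astype(str)
    missing = [c for c in rm.feature_names if c not in X.columns]
    if missing:
        raise KeyError(f"missing feature columns: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    probs = rm.model.predict_proba(X[rm.feature_names].to_numpy(float))[:, 1]
    if patient_ids is None:
        patient_ids = [str(i) for i in range(len(probs))]
    out = [RiskPrediction(str(pid), float(p), rm.branch) for pid, p in zip(patient_ids, probs)]
    if any(not (0.0 <= r.probability <= 1.0) for r in out):
        raise RuntimeError("predicted probability outside [0, 1]")
    return out


def branch_columns(
    mri_latents: pd.DataFrame, ecg_latents: pd.DataFrame, clinical: pd.DataFrame, branch: str
) -> pd.DataFrame:
    """Assemble the design matrix for a branch (indices must align)."""
    if branch == "multimodal":
        return pd.concat([mri_latents, ecg_latents, clinical], axis=1)
    if branch == "mri":
        return mri_latents.copy()
    if branch == "ecg":
        return ecg_latents.copy()
    if branch == "clinical":
        return clinical.copy()
    raise ValueError(f"unknown branch {branch!r}; expected one of {BRANCHES}")


def latent_frame(latents: np.ndarray, prefix: str, index=None) -> pd.DataFrame:
    """Name latent columns ``{prefix}_000 ...`` for downstream explainability."""
    cols = [f"{prefix}_{i:03d}" for i in range(latents.shape[1])]
    return pd.DataFrame(np.asarray(latents, dtype=float), columns=cols, index=index)
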