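"""Confound-aware nested cross-validated elastic-net outcome prediction.

The outcome (BMI) is predicted from trajectory features with an elastic net
(mixing parameter fixed at 0.5) under nested cross-validation: outer folds
give out-of-fold predictions, inner folds select the penalty by minimum mean
squared error along a log-spaced path.  Confounds (age, sex, diagnosis,
pre-task cortisol responder, log mean framewise displacement) are always
included unpenalized; by the Frisch-Waugh-Lovell argument this is implemented
exactly by running the elastic net on confound-residualized features and
outcome (residualization fitted on training rows only) and recovering the
confound coefficients afterwards.  Features are standardized with training
means/SDs.  Incremental performance is the out-of-fold R^2 of the full model
minus that of an out-of-fold confound-only OLS baseline on the same folds.

Significance comes from a permutation test that shuffles the outcome
*together with* the confounds against the feature rows, preserving the
outcome-confound correlation under the null; each iteration redraws its own
fold partition so partition variance propagates into the null.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.linear_model import enet_path

from .features import FeatureMatrix

CONFOUNDS_DEFAULT = ("age", "sex", "diagnosis", "pretask_responder",
                     "log_mean_fd")


@dataclass(frozen=True)
class PredictionConfig:
    l1_ratio: float = 0.5
    outer_folds: int = 10
    inner_folds: int = 10
    n_alphas: int = 100
    alpha_min_ratio: float = 1e-3
    n_permutations: int = 1000  # study analyses used 10,000
    seed: int = 0
    stability_threshold: float = 0.80
    confounds: tuple[str, ...] = CONFOUNDS_DEFAULT
    penalize_confounds: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.l1_ratio <= 1.0:
            raise ValueError("l1_ratio must be in (0, 1]")
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")
        if self.n_permutations < 100:
            raise ValueError("need at least 100 permutation iterations")
        if not 0.0 < self.stability_threshold <= 1.0:
            raise ValueError("stability threshold must be in (0, 1]")
        if self.n_alphas < 2:
            raise ValueError("penalty path needs at least 2 values")


@dataclass
class PredictionResult:
    subjects: list[str]
    observed: np.ndarray
    predicted: np.ndarray       # out-of-fold full-model predictions
    baseline: np.ndarray        # out-of-fold confound-only predictions
    fold: np.ndarray            # outer-fold id per subject
    r2_full: float
    r2_baseline: float
    delta_r2: float
    fold_weights: pd.DataFrame  # outer folds x features, standardized scale
    selected_alphas: np.ndarray
    config: PredictionConfig

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"participant_id": self.subjects,
                             "observed": self.observed,
                             "predicted_oof": self.predicted,
                             "baseline_oof": self.baseline,
                             "fold": self.fold})


@dataclass
class PermutationResult:
    observed_r2: float
    null_r2: np.ndarray
    p_perm: float
    percentile_bounds: tuple[float, float]
    observed_delta_r2: float
    null_delta_r2: np.ndarray


@dataclass
class TransferResult:
    """Cross-sex transfer plus per-sex nested-CV results."""

    transfer_r: dict[str, float]   # "female_to_male", "male_to_female"
    transfer_r2: dict[str, float]
    per_sex: dict[str, PredictionResult]


# ---------------------------------------------------------------------------
# numeric core
# ---------------------------------------------------------------------------

def _folds(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    return [np.sort(f) for f in np.array_split(rng.permutation(n), k)]


def _alpha_path(xt_y: np.ndarray, n: int, cfg: PredictionConfig) -> np.ndarray:
    amax = float(np.max(np.abs(xt_y))) / (n * cfg.l1_ratio)
    if amax <= 0 or not np.isfinite(amax):
        amax = 1e-3
    return np.logspace(np.log10(amax), np.log10(amax * cfg.alpha_min_ratio),
                       cfg.n_alphas)


def _fit_enet_train(Xs: np.ndarray, y: np.ndarray, C1: np.ndarray,
                    cfg: PredictionConfig, rng: np.random.Generator
                    ) -> tuple[np.ndarray, np.ndarray, float]:
    """Inner-CV penalty selection and refit on one training set.

    ``Xs`` standardized features, ``C1`` confound design incl. intercept.
    Returns (enet coefficients on standardized features, confound
    coefficients, selected alpha)."""
    # residualize outcome and features against confounds (training fit)
    A, *_ = np.linalg.lstsq(C1, np.column_stack([y, Xs]), rcond=None)
    R = np.column_stack([y, Xs]) - C1 @ A
    y_t, X_t = R[:, 0], np.asfortranarray(R[:, 1:])

    alphas = _alpha_path(X_t.T @ y_t, len(y_t), cfg)
    k = min(cfg.inner_folds, len(y_t) // 2)
    mse = np.zeros(cfg.n_alphas)
    for va in _folds(len(y_t), k, rng):
        tr = np.setdiff1d(np.arange(len(y_t)), va, assume_unique=True)
        Xi, yi = X_t[tr], y_t[tr]
        mu_x, mu_y = Xi.mean(axis=0), yi.mean()
        _, coefs, _ = enet_path(np.asfortranarray(Xi - mu_x), yi - mu_y,
                                l1_ratio=cfg.l1_ratio, alphas=alphas,
                                check_input=False)
        pred = (X_t[va] - mu_x) @ coefs + mu_y
        mse += np.mean((pred - y_t[va][:, None]) ** 2, axis=0)
    best = int(np.argmin(mse))
    _, coefs, _ = enet_path(X_t, y_t, l1_ratio=cfg.l1_ratio,
                            alphas=alphas[:best + 1], check_input=False)
    beta = coefs[:, -1]
    gamma, *_ = np.linalg.lstsq(C1, y - Xs @ beta, rcond=None)
    return beta, gamma, float(alphas[best])


def _nested_cv(X: np.ndarray, y: np.ndarray, C: np.ndarray,
               cfg: PredictionConfig, rng: np.random.Generator) -> dict:
    n, p = X.shape
    if n < 2 * cfg.outer_folds:
        raise ValueError("need at least 2 subjects per outer fold")
    if np.ptp(y) == 0:
        raise ValueError("constant outcome: R^2 undefined")
    if np.isnan(C).any():
        raise ValueError("missing confound values")

    pred = np.empty(n)
    base = np.empty(n)
    fold_id = np.empty(n, dtype=int)
    weights = np.zeros((cfg.outer_folds, p))
    alphas = np.zeros(cfg.outer_folds)
    for f, te in enumerate(_folds(n, cfg.outer_folds, rng)):
        tr = np.setdiff1d(np.arange(n), te, assume_unique=True)
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0)
        sd[sd == 0] = 1.0
        Xs_tr = (X[tr] - mu) / sd
        Xs_te = (X[te] - mu) / sd
        C1_tr = np.column_stack([np.ones(len(tr)), C[tr]])
        C1_te = np.column_stack([np.ones(len(te)), C[te]])
        if cfg.penalize_confounds:
            Z_tr = np.column_stack([Xs_tr, C1_tr[:, 1:]])
            Z_te = np.column_stack([Xs_te, C1_te[:, 1:]])
            beta, gamma, a = _fit_enet_train(
                Z_tr, y[tr], np.ones((len(tr), 1)), cfg, rng)
            pred[te] = Z_te @ beta + gamma[0]
            weights[f] = beta[:p]
        else:
            beta, gamma, a = _fit_enet_train(Xs_tr, y[tr], C1_tr, cfg, rng)
            pred[te] = Xs_te @ beta + C1_te @ gamma
            weights[f] = beta
        g0, *_ = np.linalg.lstsq(C1_tr, y[tr], rcond=None)
        base[te] = C1_te @ g0
        fold_id[te] = f
        alphas[f] = a

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2_full = 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot
    r2_base = 1.0 - float(np.sum((y - base) ** 2)) / ss_tot
    return {"pred": pred, "base": base, "fold": fold_id, "weights": weights,
            "alphas": alphas, "r2_full": r2_full, "r2_base": r2_base}


def _extract(features: FeatureMatrix, participants: pd.DataFrame,
             cfg: PredictionConfig, outcome: str = "bmi"
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    part = participants.set_index("participant_id").loc[features.subjects]
    y = part[outcome].to_numpy(dtype=float)
    missing = [c for c in cfg.confounds if c not in part.columns]
    if missing:
        raise ValueError(f"missing confound columns: {missing}")
    C = np.column_stack([
        (part[c] == "male").astype(float) if c == "sex"
        else part[c].astype(float)
        for c in cfg.confounds]) if cfg.confounds else np.empty((len(y), 0))
    X = features.data.to_numpy(dtype=float)
    return X, y, C, features.subjects


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def nested_cv_elastic_net(features: FeatureMatrix,
                          participants: pd.DataFrame,
                          cfg: PredictionConfig | None = None,
                          outcome: str = "bmi") -> PredictionResult:
    """Out-of-fold elastic-net prediction with unpenalized confounds.

    Predictions exhibit shrinkage toward the training mean (a narrower range
    than the observed outcome is expected, not an error)."""
    cfg = cfg or PredictionConfig()
    X, y, C, subjects = _extract(features, participants, cfg, outcome)
    rng = np.random.default_rng(cfg.seed)
    res = _nested_cv(X, y, C, cfg, rng)
    return PredictionResult(
        subjects, y, res["pred"], res["base"], res["fold"],
        res["r2_full"], res["r2_base"], res["r2_full"] - res["r2_base"],
        pd.DataFrame(res["weights"], columns=list(features.data.columns)),
        res["alphas"], cfg)


def permutation_test(features: FeatureMatrix, participants: pd.DataFrame,
                     cfg: PredictionConfig | None = None,
                     outcome: str = "bmi") -> PermutationResult:
    """Permutation null for the out-of-fold R^2, shuffling (outcome, confounds)
    jointly against the features; p uses the add-one estimator."""
    cfg = cfg or PredictionConfig()
    X, y, C, _ = _extract(features, participants, cfg, outcome)
    rng = np.random.default_rng(cfg.seed)
    obs = _nested_cv(X, y, C, cfg, rng)
    B = cfg.n_permutations
    null_r2 = np.empty(B)
    null_d = np.empty(B)
    for b in range(B):
        perm = rng.permutation(len(y))
        res = _nested_cv(X, y[perm], C[perm], cfg, rng)
        null_r2[b] = res["r2_full"]
        null_d[b] = res["r2_full"] - res["r2_base"]
    p = (1 + int(np.sum(null_r2 >= obs["r2_full"]))) / (B + 1)
    lo, hi = np.percentile(null_r2, [2.5, 97.5])
    return PermutationResult(obs["r2_full"], null_r2, p, (float(lo), float(hi)),
                             obs["r2_full"] - obs["r2_base"], null_d)


def feature_set_importance(features: FeatureMatrix,
                           participants: pd.DataFrame,
                           cfg: PredictionConfig | None = None,
                           grouping: dict[str, list[str]] | None = None,
                           outcome: str = "bmi") -> pd.DataFrame:
    """Leave-feature-set-out importance.

    For each group (default: all timepoints of one region/subnetwork) the
    nested CV is refit without the group's columns; importance is the drop in
    out-of-fold R^2.  Returned sorted by importance."""
    cfg = cfg or PredictionConfig()
    grouping = grouping or features.groups()
    all_cols = set(features.data.columns)
    for g, cols in grouping.items():
        if not set(cols) <= all_cols:
            raise ValueError(f"group {g!r} has unknown feature columns")
    full = nested_cv_elastic_net(features, participants, cfg, outcome)
    rows = []
    for g, cols in grouping.items():
        sub = FeatureMatrix(features.data.drop(columns=cols))
        res = nested_cv_elastic_net(sub, participants, cfg, outcome)
        rows.append((g, full.r2_full - res.r2_full, res.r2_full))
    out = pd.DataFrame(rows, columns=["group", "importance", "r2_without"])
    out["r2_full"] = full.r2_full
    return out.sort_values("importance", ascending=False,
                           kind="stable").reset_index(drop=True)


def weight_stability(result: PredictionResult,
                     threshold: float | None = None) -> pd.DataFrame:
    """Features retained (nonzero weight) in >= threshold of outer folds."""
    thr = result.config.stability_threshold if threshold is None else threshold
    W = result.fold_weights.to_numpy()
    frac = (W != 0).mean(axis=0)
    mean_w = W.mean(axis=0)
    keep = frac >= thr
    out = pd.DataFrame({
        "feature": result.fold_weights.columns[keep],
        "retained_fraction": frac[keep],
        "mean_weight": mean_w[keep],
        "sign": np.sign(mean_w[keep]).astype(int),
    })
    return out.sort_values("mean_weight", key=np.abs, ascending=False,
                           kind="stable").reset_index(drop=True)


def cross_sex_transfer(features: FeatureMatrix, participants: pd.DataFrame,
                       cfg: PredictionConfig | None = None,
                       outcome: str = "bmi") -> TransferResult:
    """Train on one sex (inner CV only), predict the other, both directions;
    plus per-sex nested-CV results with sex dropped from the confounds."""
    cfg = cfg or PredictionConfig()
    part = participants.set_index("participant_id").loc[features.subjects]
    sex = part["sex"].to_numpy()
    strat_cfg = replace(cfg, confounds=tuple(c for c in cfg.confounds
                                             if c != "sex"))
    X, y, C, subjects = _extract(features, part.reset_index(), strat_cfg,
                                 outcome)
    transfer_r: dict[str, float] = {}
    transfer_r2: dict[str, float] = {}
    per_sex: dict[str, PredictionResult] = {}
    for train_sex, test_sex in (("female", "male"), ("male", "female")):
        tr = np.flatnonzero(sex == train_sex)
        te = np.flatnonzero(sex == test_sex)
        if len(tr) < 10 or len(te) < 10:
            raise ValueError("need at least 10 subjects per sex for "
                             "stratified training")
        rng = np.random.default_rng(cfg.seed)
        mu, sd = X[tr].mean(axis=0), X[tr].std(axis=0)
        sd[sd == 0] = 1.0
        C1_tr = np.column_stack([np.ones(len(tr)), C[tr]])
        C1_te = np.column_stack([np.ones(len(te)), C[te]])
        beta, gamma, _a = _fit_enet_train((X[tr] - mu) / sd, y[tr], C1_tr,
                                          strat_cfg, rng)
        pred = (X[te] - mu) / sd @ beta + C1_te @ gamma
        key = f"{train_sex}_to_{test_sex}"
        if np.std(pred) == 0:
            transfer_r[key] = 0.0  # fully shrunk model carries no ranking
        else:
            transfer_r[key] = float(np.corrcoef(pred, y[te])[0, 1])
        transfer_r2[key] = 1.0 - float(np.sum((y[te] - pred) ** 2)
                                       / np.sum((y[te] - y[te].mean()) ** 2))
        sub_feat = FeatureMatrix(features.data.iloc[tr])
        sub_part = part.reset_index().iloc[tr]
        per_sex[train_sex] = nested_cv_elastic_net(sub_feat, sub_part,
                                                   strat_cfg, outcome)
    return TransferResult(transfer_r, transfer_r2, per_sex)
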