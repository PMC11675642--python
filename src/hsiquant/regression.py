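"""Feature fusion, calibration models and evaluation metrics.

Selected-band spectra and the 14 spatial features are fused by
horizontal concatenation with per-column z-standardization fitted on
calibration rows only.  Models: gradient-boosted trees (LightGBM,
primary), PLSR and RBF-kernel SVR, tuned by exhaustive grid search on
cross-validated RMSE and refit on the full calibration set.  Evaluation
reports R2 (coefficient of determination), RMSE, MAE and
RPD = SD(reference values of the evaluated set) / RMSE.

The ablation harness re-runs the synthetic pipeline with stages toggled
(preprocessing, PSO vs VSPSO selection, texture/color features) to check
the qualitative contribution of each stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from ._pls import kfold_indices

__all__ = [
    "FusedFeatureMatrix",
    "ColumnStandardizer",
    "ModelSpec",
    "RegressionMetrics",
    "FittedModel",
    "fuse",
    "fit",
    "evaluate",
    "metrics_from_predictions",
    "ablation_harness",
    "ABLATION_CASES",
]


@dataclass
class FusedFeatureMatrix:
    X: np.ndarray
    columns: list[str]
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.columns = list(self.columns)
        if self.X.shape[1] != len(self.columns):
            raise ValueError("column labels must match feature count")
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("column labels must be unique")
        if self.X.shape[0] != self.y.size:
            raise ValueError("rows must align with targets")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("fused features contain non-finite values")


class ColumnStandardizer:
    """Per-column z-score with statistics frozen at fit time."""

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "ColumnStandardizer":
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("standardizer not fitted")
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_


def fuse(selected_spectra: np.ndarray, spatial: np.ndarray | None,
         y: np.ndarray, band_labels: list[str] | None = None,
         spatial_labels: list[str] | None = None) -> FusedFeatureMatrix:
    """Concatenate spectral and spatial blocks into one labelled matrix.

    Standardization is separate (``ColumnStandardizer``) so prediction
    rows can be scaled with calibration statistics only.
    """
    Xs = np.atleast_2d(np.asarray(selected_spectra, dtype=float))
    blocks = [Xs]
    labels = (list(band_labels) if band_labels is not None
              else [f"band_{k}" for k in range(Xs.shape[1])])
    if spatial is not None:
        Xp = np.atleast_2d(np.asarray(spatial, dtype=float))
        if Xp.shape[0] != Xs.shape[0]:
            raise ValueError("spectral and spatial row counts differ")
        blocks.append(Xp)
        labels += (list(spatial_labels) if spatial_labels is not None
                   else [f"spatial_{k}" for k in range(Xp.shape[1])])
    return FusedFeatureMatrix(np.hstack(blocks), labels, y)


@dataclass
class ModelSpec:
    """Model family plus hyperparameter grid searched by CV RMSE.

    Default grids stay inside the study's search spaces: SVR C in
    [0, 10] and gamma in [5, 5000]; PLSR latent variables in [1, 60];
    boosted trees around the reported optimum (depth 3, learning rate
    0.08-0.19, L1/L2 in [0, 1], early rounds in [1, 3000]).
    """

    family: str = "gbt"
    grid: dict = field(default_factory=dict)
    cv_folds: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.family not in {"gbt", "plsr", "svr"}:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    def effective_grid(self, n_train: int, n_features: int) -> list[dict]:
        grid = dict(self.grid)
        if not grid:
            if self.family == "plsr":
                top = min(60, n_features, n_train - 1)
                grid = {"n_components": list(range(1, top + 1))}
            elif self.family == "svr":
                grid = {"C": [0.1, 1.0, 5.0, 10.0],
                        "gamma": [5.0, 50.0, 500.0, 5000.0]}
            else:
                grid = {"n_estimators": [100, 400], "learning_rate": [0.08, 0.19],
                        "max_depth": [3], "reg_alpha": [0.0, 0.4],
                        "reg_lambda": [0.0, 0.1]}
        keys = sorted(grid)
        combos = [dict(zip(keys, vals)) for vals in product(*(grid[k] for k in keys))]
        if self.family == "plsr":
            cap = min(n_features, n_train - 1)
            combos = [c for c in combos if c.get("n_components", 1) <= cap]
        if not combos:
            raise ValueError("empty hyperparameter grid")
        return combos


@dataclass
class RegressionMetrics:
    r2: float
    rmse: float
    mae: float
    rpd: float  # math.inf flags an undefined ratio (rmse == 0)
    n_eval: int

    def as_dict(self) -> dict:
        return {"r2": self.r2, "rmse": self.rmse, "mae": self.mae,
                "rpd": self.rpd, "n_eval": self.n_eval}


@dataclass
class FittedModel:
    family: str
    model: object
    best_params: dict
    cv_rmse: float
    standardizer: ColumnStandardizer | None = None
    feature_names: list[str] | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.standardizer is not None:
            X = self.standardizer.transform(X)
        return np.asarray(self.model.predict(_named(X, self.feature_names))).ravel()


def _named(X: np.ndarray, names: list[str] | None):
    """Wrap features in a DataFrame so estimators see stable column names."""
    if names is None:
        return X
    import pandas as pd

    return pd.DataFrame(np.asarray(X, dtype=float), columns=names)


def _make_estimator(family: str, params: dict, seed: int):
    if family == "plsr":
        from sklearn.cross_decomposition import PLSRegression

        return PLSRegression(n_components=params.get("n_components", 2),
                             scale=False)
    if family == "svr":
        from sklearn.svm import SVR

        return SVR(kernel="rbf", C=params.get("C", 1.0),
                   gamma=params.get("gamma", "scale"),
                   epsilon=params.get("epsilon", 0.1))
    from lightgbm import LGBMRegressor

    defaults = dict(n_estimators=100, learning_rate=0.08, max_depth=3,
                    reg_alpha=0.0, reg_lambda=0.0, num_leaves=8,
                    min_child_samples=5, random_state=seed, n_jobs=1,
                    verbose=-1)
    defaults.update(params)
    return LGBMRegressor(**defaults)


def fit(train: FusedFeatureMatrix, spec: ModelSpec,
        standardize: bool = True) -> FittedModel:
    """Grid search by CV RMSE, then refit the winner on all rows."""
    spec.validate()
    n = train.X.shape[0]
    if n <= spec.cv_folds:
        raise ValueError("need more training rows than CV folds")
    if np.std(train.y) == 0:
        raise ValueError("degenerate target: zero variance")
    scaler = ColumnStandardizer().fit(train.X) if standardize else None
    X = scaler.transform(train.X) if scaler else train.X
    y = train.y
    folds = kfold_indices(n, spec.cv_folds, spec.seed)
    combos = spec.effective_grid(n, X.shape[1])

    names = [f"f{i}" for i in range(X.shape[1])]
    best = (np.inf, None)
    for params in combos:
        sq, cnt = 0.0, 0
        for tr, te in folds:
            est = _make_estimator(spec.family, params, spec.seed)
            est.fit(_named(X[tr], names), y[tr])
            resid = y[te] - np.asarray(est.predict(_named(X[te], names))).ravel()
            sq += float(resid @ resid)
            cnt += te.size
        score = math.sqrt(sq / cnt)
        if score < best[0]:
            best = (score, params)
    winner = best[1]
    model = _make_estimator(spec.family, winner, spec.seed)
    model.fit(_named(X, names), y)
    return FittedModel(spec.family, model, winner, best[0], scaler, names)


def metrics_from_predictions(y: np.ndarray, yhat: np.ndarray) -> RegressionMetrics:
    """R2, RMSE, MAE and RPD for a labelled evaluation set.

    R2 is the coefficient of determination (may be negative); RPD uses
    the sample (n-1) standard deviation of the reference values; a zero
    RMSE is flagged with RPD = inf.
    """
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size:
        raise ValueError("prediction/reference length mismatch")
    if y.size < 2:
        raise ValueError("need at least 2 evaluation samples for R2/RPD")
    resid = y - yhat
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("reference values have zero variance")
    r2 = 1.0 - float((resid**2).sum()) / ss_tot
    sd = float(np.std(y, ddof=1))
    rpd = math.inf if rmse == 0 else sd / rmse
    return RegressionMetrics(r2=r2, rmse=rmse, mae=mae, rpd=rpd, n_eval=y.size)


def evaluate(model: FittedModel, test: FusedFeatureMatrix) -> RegressionMetrics:
    if test.X.shape[0] == 0:
        raise ValueError("empty evaluation set")
    return metrics_from_predictions(test.y, model.predict(test.X))


# --- ablation harness ---------------------------------------------------------

# case -> (preprocess, selection, texture, color)
ABLATION_CASES = {
    "raw": (False, "none", False, False),
    "pre": (True, "none", False, False),
    "pre+pso": (True, "pso", False, False),
    "pre+vspso": (True, "vspso", False, False),
    "spatial_only": (False, "spatial", True, True),
    "fused_tex": (True, "vspso", True, False),
    "fused_col": (True, "vspso", False, True),
    "fused": (True, "vspso", True, True),
}


def ablation_harness(cases: list[str], n_repeats: int = 10,
                     base_config=None, component: int = 0,
                     model_spec: ModelSpec | None = None,
                     selection_iters: int = 40, selection_particles: int = 20,
                     lam: float = 0.2, calibration_fraction: float = 0.7,
                     seed: int = 0):
    """Run toggled pipeline variants on fresh synthetic datasets.

    Returns a tidy DataFrame (case, repeat, r2, rmse, mae, rpd,
    n_selected).  Each repeat draws a new dataset seed derived from
    ``seed``, splits calibration/prediction at random, and shares the
    dataset, split and selection across cases so differences reflect
    the toggled stages only.
    """
    import pandas as pd

    from . import band_selection as bs
    from . import preprocessing as pp
    from . import synthetic as syn
    from .spatial_features import SPATIAL_FEATURE_NAMES, spatial_feature_vector

    for case in cases:
        if case not in ABLATION_CASES:
            raise ValueError(f"unknown ablation case {case!r}; "
                             f"known: {sorted(ABLATION_CASES)}")
    base_config = base_config or syn.SyntheticConfig()
    model_spec = model_spec or ModelSpec(
        family="gbt", grid={"n_estimators": [300], "learning_rate": [0.08],
                            "max_depth": [3]})

    records = []
    for rep in range(n_repeats):
        ds_seed = (seed * 10007 + rep) % (2**31)
        import dataclasses as _dc

        cfg = _dc.replace(base_config, seed=ds_seed)
        ds = syn.generate_dataset(cfg)
        y = ds.references.iloc[:, 1 + component].to_numpy(float)
        rng = np.random.default_rng(ds_seed + 1)
        perm = rng.permutation(cfg.n_samples)
        n_cal = int(round(calibration_fraction * cfg.n_samples))
        cal, pred = np.sort(perm[:n_cal]), np.sort(perm[n_cal:])

        # shared ingredients, computed once per repeat
        ppcfg = pp.PreprocessConfig()
        cal_raw = syn.SpectrumSet(ds.spectra.X[cal], ds.spectra.wavelengths,
                                  [ds.spectra.sample_ids[i] for i in cal])
        pred_raw = syn.SpectrumSet(ds.spectra.X[pred], ds.spectra.wavelengths,
                                   [ds.spectra.sample_ids[i] for i in pred])
        cal_pp, state = pp.apply_pipeline(cal_raw, ppcfg)
        pred_pp, _ = pp.apply_pipeline(pred_raw, ppcfg, state, fit=False)

        full_mask = np.ones(ds.images.shape[1:3], dtype=bool)
        spatial = np.array([spatial_feature_vector(ds.images[i], full_mask)
                            for i in range(cfg.n_samples)])

        need_sel = {ABLATION_CASES[c][1] for c in cases}
        selections: dict[str, np.ndarray] = {}
        for method in ("pso", "vspso"):
            if method in need_sel:
                res = bs.run_vspso(
                    cal_pp.X, y[cal],
                    bs.SwarmConfig(n_particles=selection_particles,
                                   max_iter=selection_iters, seed=ds_seed + 2),
                    bs.FitnessConfig(lam=0.0 if method == "pso" else lam,
                                     cv_seed=ds_seed + 3))
                selections[method] = res.selected_indices

        for case in cases:
            use_pp, sel_method, use_tex, use_col = ABLATION_CASES[case]
            cal_spec = cal_pp if use_pp else cal_raw
            pred_spec = pred_pp if use_pp else pred_raw
            if sel_method in ("pso", "vspso"):
                idx = selections[sel_method]
                Xc, Xp = cal_spec.X[:, idx], pred_spec.X[:, idx]
                labels = [f"{cal_spec.wavelengths[i]:.1f}nm" for i in idx]
                n_selected = idx.size
            elif sel_method == "spatial":
                Xc = np.empty((cal.size, 0))
                Xp = np.empty((pred.size, 0))
                labels, n_selected = [], 0
            else:
                Xc, Xp = cal_spec.X, pred_spec.X
                labels = [f"{w:.1f}nm" for w in cal_spec.wavelengths]
                n_selected = cal_spec.n_bands

            sp_cols = []
            if use_col:
                sp_cols += list(range(9))
            if use_tex:
                sp_cols += list(range(9, 14))
            sp_cal = spatial[np.ix_(cal, sp_cols)] if sp_cols else None
            sp_pred = spatial[np.ix_(pred, sp_cols)] if sp_cols else None
            sp_labels = [SPATIAL_FEATURE_NAMES[k] for k in sp_cols]

            train = fuse(Xc, sp_cal, y[cal], labels, sp_labels)
            test = fuse(Xp, sp_pred, y[pred], labels, sp_labels)
            fitted = fit(train, model_spec)
            m = evaluate(fitted, test)
            records.append({"case": case, "repeat": rep, **m.as_dict(),
                            "n_selected": n_selected})
    return pd.DataFrame.from_records(records)
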