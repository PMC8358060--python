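"""Bagged-tree upscaling of site Vcmax25 to the grid.

The model is an ensemble of bagged regression trees (200 by default) fit to
site observations.  Workflow, mirroring the derivation of the gridded
Vcmax25 product:

1. :meth:`VcmaxForest.rank_importance` — permutation importance of every
   candidate predictor from an all-predictor ensemble; categorical
   predictors (PFT, Köppen class) are one-hot encoded for the trees but
   permuted and scored as a single unit.
2. :meth:`VcmaxForest.select_predictors` — forward addition in importance
   order; stop at the first step where out-of-bag (OOB) r² no longer
   increases AND OOB mean-squared error no longer decreases.
3. :meth:`VcmaxForest.fit` — final ensemble on the selected predictors;
   returns :class:`VcmaxForestResults`.
4. :meth:`VcmaxForest.cross_validate` — conventional 80/20 holdout or
   spatial cross-validation where validation points within a great-circle
   exclusion radius (150 km default) of any training point are dropped.
5. :meth:`VcmaxForestResults.predict_grid` — gridded mean and per-tree
   standard deviation (the map's uncertainty layer).

No species-abundance weighting is applied; tree hyperparameters beyond the
ensemble size are library defaults.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import mean_squared_error, r2_score

from .grids import CATEGORICAL_PREDICTORS, PFT_CLASSES, CovariateGrid, UncertainMap

__all__ = [
    "VcmaxForest",
    "VcmaxForestResults",
    "CVReport",
    "haversine_km",
    "spatial_exclusion_filter",
]

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

#: tolerance absorbing float jitter in the OOB stopping rule
_STOP_EPS = 1e-6


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km between (lat1, lon1) and (lat2, lon2)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def spatial_exclusion_filter(
    lat: np.ndarray,
    lon: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    radius_km: float,
) -> np.ndarray:
    """Drop test rows within ``radius_km`` (great-circle) of any training row."""
    tlat, tlon = np.asarray(lat)[train_idx], np.asarray(lon)[train_idx]
    keep = [
        k
        for k in np.asarray(test_idx)
        if np.min(haversine_km(lat[k], lon[k], tlat, tlon)) >= radius_km
    ]
    return np.array(keep, dtype=int)


@dataclass
class CVReport:
    """Cross-validation summary over repetitions."""

    mode: str
    r2_mean: float
    r2_sd: float
    rmse_mean: float
    rmse_sd: float
    n_reps: int
    holdout_fraction: float
    exclusion_radius_km: Optional[float]
    n_validation_effective: float

    def to_dict(self) -> Dict[str, object]:
        return {
            "mode": self.mode,
            "r2_mean": self.r2_mean,
            "r2_sd": self.r2_sd,
            "rmse_mean": self.rmse_mean,
            "rmse_sd": self.rmse_sd,
            "n_reps": self.n_reps,
            "holdout_fraction": self.holdout_fraction,
            "exclusion_radius_km": self.exclusion_radius_km,
            "n_validation_effective": self.n_validation_effective,
        }


class _Encoder:
    """One-hot design builder with fixed category sets per categorical unit."""

    def __init__(self, obs: pd.DataFrame, predictors: Sequence[str]):
        self.predictors = list(predictors)
        self.categories: Dict[str, List] = {}
        for p in self.predictors:
            if p in CATEGORICAL_PREDICTORS:
                if p == "pft":
                    cats = [c for c in PFT_CLASSES]
                else:
                    cats = sorted(pd.unique(obs[p].dropna()))
                self.categories[p] = cats
        self.columns: List[Tuple[str, object]] = []
        for p in self.predictors:
            if p in self.categories:
                self.columns.extend((p, c) for c in self.categories[p])
            else:
                self.columns.append((p, None))
        self.groups: Dict[str, np.ndarray] = {}
        for p in self.predictors:
            self.groups[p] = np.array(
                [k for k, (name, _) in enumerate(self.columns) if name == p]
            )

    def design(self, df: pd.DataFrame) -> np.ndarray:
        cols = []
        for name, cat in self.columns:
            if cat is None:
                cols.append(df[name].to_numpy(dtype=float))
            else:
                cols.append((df[name].to_numpy() == cat).astype(float))
        return np.column_stack(cols)


def _oob_metrics(rf: RandomForestRegressor, y: np.ndarray) -> Tuple[float, float]:
    pred = rf.oob_prediction_
    ok = np.isfinite(pred)
    return float(r2_score(y[ok], pred[ok])), float(
        mean_squared_error(y[ok], pred[ok])
    )


class VcmaxForest:
    """Bagged-tree model of site Vcmax25 on environmental covariates.

    Parameters
    ----------
    obs : DataFrame
        Site table; must contain ``response`` plus every candidate
        predictor, and ``lat``/``lon`` for spatial cross-validation.
    candidate_predictors : sequence of str
        Candidate predictor names ('pft' and 'koeppen' are categorical).
    response : str
        Response column, Vcmax25 at 25 °C (µmol m⁻² s⁻¹).
    n_trees : int
        Ensemble size (200 by default).
    seed : int
        Controls bootstrap resampling and permutation draws.
    """

    def __init__(
        self,
        obs: pd.DataFrame,
        candidate_predictors: Sequence[str],
        response: str = "vcmax25",
        n_trees: int = 200,
        seed: int = 0,
        min_rows: int = 30,
    ):
        missing = [c for c in list(candidate_predictors) + [response] if c not in obs.columns]
        if missing:
            raise ValueError(f"observation table missing columns: {missing}")
        if len(obs) < min_rows:
            raise ValueError(
                f"need at least {min_rows} observations, got {len(obs)}"
            )
        self.obs = obs.reset_index(drop=True)
        self.candidates = list(candidate_predictors)
        self.response = response
        self.n_trees = int(n_trees)
        self.seed = int(seed)
        self.min_rows = int(min_rows)
        self.y = self.obs[response].to_numpy(dtype=float)

    # -- internals ---------------------------------------------------------

    def _fit_ensemble(
        self, predictors: Sequence[str], seed: int, df: Optional[pd.DataFrame] = None
    ) -> Tuple[RandomForestRegressor, _Encoder, np.ndarray]:
        df = self.obs if df is None else df
        enc = _Encoder(self.obs, predictors)
        X = enc.design(df)
        rf = RandomForestRegressor(
            n_estimators=self.n_trees,
            max_features=1.0,  # bagged trees: every split sees all features
            bootstrap=True,
            oob_score=True,
            random_state=seed,
            n_jobs=1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # few-tree OOB coverage warnings
            rf.fit(X, df[self.response].to_numpy(dtype=float))
        return rf, enc, X

    # -- spec operations ---------------------------------------------------

    def rank_importance(self, n_repeats: int = 5) -> Dict[str, float]:
        """Permutation importance per predictor unit, descending.

        Fits an all-candidate ensemble, then permutes each predictor unit
        (all one-hot columns of a categorical jointly, with one shared row
        permutation) and records the mean r² drop on the training response.
        Constant predictors get importance 0.
        """
        if len(self.obs) < 50:
            raise ValueError("importance ranking requires >= 50 observations")
        rf, enc, X = self._fit_ensemble(self.candidates, self.seed)
        rng = np.random.default_rng(self.seed + 1)
        base = r2_score(self.y, rf.predict(X))
        scores: Dict[str, float] = {}
        for p in self.candidates:
            col_idx = enc.groups[p]
            if all(np.ptp(X[:, k]) == 0 for k in col_idx):
                logger.info("predictor %r is constant; importance set to 0", p)
                scores[p] = 0.0
                continue
            drops = []
            for _ in range(n_repeats):
                perm = rng.permutation(len(X))
                Xp = X.copy()
                Xp[:, col_idx] = X[np.ix_(perm, col_idx)]
                drops.append(base - r2_score(self.y, rf.predict(Xp)))
            scores[p] = float(np.mean(drops))
        return dict(sorted(scores.items(), key=lambda kv: -kv[1]))

    def select_predictors(
        self, ranking: Optional[Dict[str, float]] = None
    ) -> Tuple[List[str], List[Tuple[float, float]]]:
        """Forward selection in importance order with OOB stopping.

        Predictors are added one at a time; at the first step where OOB r²
        does not increase and OOB MSE does not decrease (both, within a
        1e-6 epsilon), selection stops and the set before the failed step
        is returned together with the per-step (r², MSE) trace.
        """
        if ranking is None:
            ranking = self.rank_importance()
        ordered = list(ranking)
        if not ordered:
            raise ValueError("empty importance ranking")
        selected: List[str] = []
        trace: List[Tuple[float, float]] = []
        best_r2, best_mse = -np.inf, np.inf
        for step, p in enumerate(ordered):
            rf, _, _ = self._fit_ensemble(selected + [p], self.seed + 10 + step)
            r2, mse = _oob_metrics(rf, self.y)
            trace.append((r2, mse))
            if r2 <= best_r2 + _STOP_EPS and mse >= best_mse - _STOP_EPS:
                if not selected:
                    logger.info(
                        "first predictor already at stopping condition; "
                        "returning singleton set"
                    )
                    selected = [p]
                break
            selected.append(p)
            best_r2, best_mse = max(best_r2, r2), min(best_mse, mse)
        return selected, trace

    def fit(self, predictors: Optional[Sequence[str]] = None) -> "VcmaxForestResults":
        """Fit the final ensemble on all rows with the given predictors."""
        predictors = list(predictors) if predictors is not None else self.candidates
        rf, enc, X = self._fit_ensemble(predictors, self.seed)
        oob_r2, oob_mse = _oob_metrics(rf, self.y)
        return VcmaxForestResults(
            model=self,
            rf=rf,
            encoder=enc,
            predictors=predictors,
            oob_r2=oob_r2,
            oob_mse=oob_mse,
        )

    def cross_validate(
        self,
        predictors: Sequence[str],
        mode: str = "conventional",
        holdout_fraction: float = 0.2,
        exclusion_radius_km: float = 150.0,
        n_reps: int = 10,
        seed: Optional[int] = None,
    ) -> CVReport:
        """Repeated holdout validation, conventional or spatial.

        In spatial mode, validation rows within ``exclusion_radius_km``
        (great-circle) of any training row are removed before scoring,
        breaking the optimistic effect of spatial autocorrelation between
        clustered sites.  The exclusion is applied independently in each
        repetition.
        """
        if mode not in ("conventional", "spatial"):
            raise ValueError(f"unknown mode {mode!r}")
        if n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not (0 <= holdout_fraction < 1):
            raise ValueError("holdout_fraction must be in [0, 1)")
        seed = self.seed if seed is None else int(seed)
        rng = np.random.default_rng(seed)
        n = len(self.obs)
        n_test = max(1, int(round(holdout_fraction * n)))
        r2s, rmses, n_val = [], [], []
        for rep in range(n_reps):
            perm = rng.permutation(n)
            test_idx, train_idx = perm[:n_test], perm[n_test:]
            if mode == "spatial" and exclusion_radius_km > 0:
                test_idx = spatial_exclusion_filter(
                    self.obs["lat"].to_numpy(),
                    self.obs["lon"].to_numpy(),
                    train_idx,
                    test_idx,
                    exclusion_radius_km,
                )
            if len(test_idx) == 0:
                warnings.warn(f"rep {rep}: no surviving validation rows; skipped")
                continue
            train = self.obs.iloc[train_idx]
            enc = _Encoder(self.obs, predictors)
            rf = RandomForestRegressor(
                n_estimators=self.n_trees,
                max_features=1.0,
                bootstrap=True,
                random_state=seed + 100 + rep,
                n_jobs=1,
            )
            rf.fit(enc.design(train), train[self.response].to_numpy(dtype=float))
            test = self.obs.iloc[test_idx]
            pred = rf.predict(enc.design(test))
            ytest = test[self.response].to_numpy(dtype=float)
            if len(test_idx) >= 2 and np.ptp(ytest) > 0:
                r2s.append(r2_score(ytest, pred))
            rmses.append(float(np.sqrt(mean_squared_error(ytest, pred))))
            n_val.append(len(test_idx))
        if not rmses:
            raise RuntimeError("all cross-validation repetitions were skipped")
        return CVReport(
            mode=mode,
            r2_mean=float(np.mean(r2s)) if r2s else float("nan"),
            r2_sd=float(np.std(r2s, ddof=1)) if len(r2s) > 1 else 0.0,
            rmse_mean=float(np.mean(rmses)),
            rmse_sd=float(np.std(rmses, ddof=1)) if len(rmses) > 1 else 0.0,
            n_reps=n_reps,
            holdout_fraction=holdout_fraction,
            exclusion_radius_km=exclusion_radius_km if mode == "spatial" else None,
            n_validation_effective=float(np.mean(n_val)),
        )


@dataclass
class VcmaxForestResults:
    """Fitted ensemble with OOB diagnostics and gridded prediction."""

    model: VcmaxForest
    rf: RandomForestRegressor
    encoder: _Encoder
    predictors: List[str]
    oob_r2: float
    oob_mse: float

    def predict_table(self, df: pd.DataFrame) -> Tuple[np.ndarray, np.ndarray]:
        """Per-row ensemble mean and per-tree standard deviation."""
        X = self.encoder.design(df)
        per_tree = np.stack([t.predict(X) for t in self.rf.estimators_])
        return per_tree.mean(axis=0), per_tree.std(axis=0, ddof=0)

    def predict_grid(self, grid: CovariateGrid) -> UncertainMap:
        """Extrapolate to the grid; masked cells stay missing.

        The uncertainty layer is the standard deviation of the per-tree
        estimates at each cell.
        """
        missing = [
            p
            for p in self.predictors
            if p not in grid.layers and not (p == "pft")
        ]
        if missing:
            raise ValueError(f"grid is missing predictor layers: {missing}")
        table = grid.table()
        mean_v, sd_v = self.predict_table(table)
        return UncertainMap(
            lat=grid.lat,
            lon=grid.lon,
            mean=grid.field_from_values(mean_v),
            sd=grid.field_from_values(sd_v),
            quantity="vcmax25",
            units="umol m-2 s-1",
        )

    def summary(self) -> str:
        lines = [
            "Bagged-tree Vcmax25 model",
            f"  trees: {self.rf.n_estimators}",
            f"  predictors: {', '.join(self.predictors)}",
            f"  OOB r2:  {self.oob_r2:.3f}",
            f"  OOB MSE: {self.oob_mse:.3f}",
        ]
        return "\n".join(lines)
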