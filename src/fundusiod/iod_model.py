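"""Model construction: cohort split, LASSO feature ordering, adjusted-R2
feature-count selection, and linear imaging indicators of the optic disc.

The indicator (IOD) for a choroidal-thickness target is an ordinary
least-squares fit of the target (micrometers) on a small set of standardized
imaging features, reported in units of 10 um.  Features are ordered by their
entry point along a decreasing-lambda LASSO regularization path fitted on the
training set; the number of features k* is the last k at which the test-set
adjusted R2 was still strictly increasing (its first local maximum), which
operationalizes "grow the model while both curves rise, stop when the test
curve turns over".  The final per-k fits and the shipped model are
unpenalized OLS; standardization parameters always come from the training
set only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import lasso_path

MODEL_SCHEMA_VERSION = 1

#: Reference six-feature indicator compositions, shipped as templates so the
#: same feature sets can be refit on new cohorts.
TEMPLATE_IOD_MCHT = (
    "ppa_width", "disc_fovea_distance", "OT_A_skewness",
    "IT_L_range", "OT_A_range", "OT_B_range",
)
TEMPLATE_IOD_PCHT = (
    "ppa_perimeter", "I_B_skewness", "OT_A_skewness",
    "IT_L_range", "OT_A_range", "OT_B_range",
)


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """adjR2 = 1 - (1 - R2) (n - 1) / (n - p - 1)."""
    if n - p - 1 <= 0:
        return float("nan")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def split_cohort(index, train_fraction: float = 0.70, seed: int = 0
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Simple random split of case ids; train size = floor(fraction * n)."""
    ids = np.asarray(index)
    n = len(ids)
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    if n < 10:
        raise ValueError("cohort too small to split (n < 10)")
    n_train = int(np.floor(train_fraction * n))
    if n_train == 0 or n_train == n:
        raise ValueError("degenerate split sizes")
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(ids[perm[:n_train]]), np.sort(ids[perm[n_train:]])


@dataclass
class SelectionPath:
    """Feature entry order along the LASSO path plus per-k adjusted R2."""

    entry_order: list[str]
    adj_r2_train: np.ndarray = field(default_factory=lambda: np.zeros(0))
    adj_r2_test: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def to_frame(self) -> pd.DataFrame:
        k = len(self.adj_r2_train)
        return pd.DataFrame({
            "k": np.arange(1, k + 1),
            "feature_entered": self.entry_order[:k],
            "adj_r2_train": self.adj_r2_train,
            "adj_r2_test": self.adj_r2_test,
        })


def _standardize(X: pd.DataFrame, means: pd.Series, sds: pd.Series
                 ) -> np.ndarray:
    return ((X - means) / sds).to_numpy(dtype=float)


def lasso_order(X: pd.DataFrame, y: np.ndarray, k_max: int = 30,
                n_alphas: int = 200) -> SelectionPath:
    """Order features by first entry along a decreasing-lambda LASSO path.

    ``X`` is standardized internally with its own means/sds (callers pass the
    training block).  Zero-variance columns are excluded with a warning; ties
    in entry step are broken by larger |correlation with y|, then name.
    """
    y = np.asarray(y, dtype=float)
    sds = X.std(ddof=0)
    dead = sds[sds <= 1e-12].index.tolist()
    if dead:
        shown = ", ".join(dead[:5]) + ("..." if len(dead) > 5 else "")
        warnings.warn(f"excluding {len(dead)} zero-variance features "
                      f"({shown})")
        X = X.drop(columns=dead)
        sds = sds.drop(dead)
    if X.shape[1] == 0 or np.std(y) <= 1e-15:
        return SelectionPath(entry_order=[])
    Z = _standardize(X, X.mean(), sds)
    yc = y - y.mean()
    try:
        alphas, coefs, _ = lasso_path(Z, yc, alphas=n_alphas, eps=1e-3)
    except (TypeError, ValueError):  # older API: alphas must be an array
        alphas, coefs, _ = lasso_path(Z, yc, n_alphas=n_alphas, eps=1e-3)
    nonzero = np.abs(coefs) > 1e-12
    first_idx = np.full(Z.shape[1], np.iinfo(np.int32).max, dtype=np.int64)
    for j in range(Z.shape[1]):
        hits = np.flatnonzero(nonzero[j])
        if hits.size:
            first_idx[j] = hits[0]
    corr = np.zeros(Z.shape[1])
    for j in range(Z.shape[1]):
        sd = Z[:, j].std()
        if sd > 0:
            corr[j] = abs(np.corrcoef(Z[:, j], yc)[0, 1])
    names = list(X.columns)
    entered = [j for j in range(Z.shape[1])
               if first_idx[j] < np.iinfo(np.int32).max]
    entered.sort(key=lambda j: (first_idx[j], -corr[j], names[j]))
    return SelectionPath(entry_order=[names[j] for j in entered[:k_max]])


def _ols_fit(Z: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """OLS coefficients and intercept via least squares on centered target."""
    A = np.column_stack([np.ones(len(Z)), Z])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return beta[1:], float(beta[0])


def _r2(y: np.ndarray, pred: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 1.0
    return 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot


def select_feature_count(path: SelectionPath,
                         X_train: pd.DataFrame, y_train: np.ndarray,
                         X_test: pd.DataFrame, y_test: np.ndarray
                         ) -> tuple[int, list[str]]:
    """Choose k* = last k at which test adjR2 was still strictly increasing.

    For each k the first k path features are refit by unpenalized OLS on the
    training set; adjusted R2 is evaluated on both sets and stored on the
    path.  Returns (k*, the first k* features).
    """
    if not path.entry_order:
        raise ValueError("selection path is empty")
    y_train = np.asarray(y_train, dtype=float)
    y_test = np.asarray(y_test, dtype=float)
    k_max = len(path.entry_order)
    adj_tr = np.zeros(k_max)
    adj_te = np.zeros(k_max)
    means = X_train.mean()
    sds = X_train.std(ddof=0)
    for k in range(1, k_max + 1):
        feats = path.entry_order[:k]
        Ztr = _standardize(X_train[feats], means[feats], sds[feats])
        Zte = _standardize(X_test[feats], means[feats], sds[feats])
        coef, icpt = _ols_fit(Ztr, y_train)
        adj_tr[k - 1] = adjusted_r2(_r2(y_train, Ztr @ coef + icpt),
                                    len(y_train), k)
        adj_te[k - 1] = adjusted_r2(_r2(y_test, Zte @ coef + icpt),
                                    len(y_test), k)
    path.adj_r2_train = adj_tr
    path.adj_r2_test = adj_te
    k_star = stopping_k(adj_te)
    return k_star, path.entry_order[:k_star]


def stopping_k(adj_r2_test) -> int:
    """Largest k whose prefix of test adjR2 values is strictly increasing
    (the curve's first local maximum)."""
    seq = np.asarray(adj_r2_test, dtype=float)
    if seq.size == 0:
        raise ValueError("empty adjusted-R2 sequence")
    k_star = 1
    for k in range(2, seq.size + 1):
        if seq[k - 1] > seq[k - 2]:
            k_star = k
        else:
            break
    return k_star


@dataclass
class IODModel:
    """Linear imaging indicator of the optic disc for one ChT target.

    Prediction: standardize the input features with the stored training
    means/sds, apply the OLS coefficients plus intercept (micrometers), and
    divide by 10 — the indicator is expressed in 10-um units.
    """

    target: str                       # "mChT" | "pChT"
    feature_names: list[str]
    means: np.ndarray
    sds: np.ndarray
    coef: np.ndarray                  # per standardized feature, um
    intercept: float                  # um
    schema_version: int = MODEL_SCHEMA_VERSION

    OUTPUT_UNIT = "10 um"

    def predict(self, features) -> np.ndarray:
        """IOD values (10-um units) for a DataFrame or mapping of features."""
        if isinstance(features, dict):
            features = pd.DataFrame([features])
        missing = [f for f in self.feature_names if f not in features.columns]
        if missing:
            raise ValueError(f"missing model features: {missing}")
        Z = (features[self.feature_names].to_numpy(dtype=float)
             - self.means) / self.sds
        return (Z @ self.coef + self.intercept) / 10.0

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "target": self.target,
            "output_unit": self.OUTPUT_UNIT,
            "feature_names": list(self.feature_names),
            "means": [float(v) for v in self.means],
            "sds": [float(v) for v in self.sds],
            "coef": [float(v) for v in self.coef],
            "intercept": float(self.intercept),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IODModel":
        if d.get("schema_version") != MODEL_SCHEMA_VERSION:
            raise ValueError(f"schema_version: unsupported "
                             f"{d.get('schema_version')!r}")
        required = ("target", "feature_names", "means", "sds", "coef",
                    "intercept")
        missing = [k for k in required if k not in d]
        if missing:
            raise ValueError(f"model file missing fields: {missing}")
        names = list(d["feature_names"])
        if not (len(d["means"]) == len(d["sds"]) == len(d["coef"])
                == len(names)):
            raise ValueError("coefficient/parameter lengths disagree")
        return cls(
            target=d["target"], feature_names=names,
            means=np.asarray(d["means"], dtype=float),
            sds=np.asarray(d["sds"], dtype=float),
            coef=np.asarray(d["coef"], dtype=float),
            intercept=float(d["intercept"]),
        )


def fit_iod(X_train: pd.DataFrame, y_train: np.ndarray,
            feature_names, target: str) -> IODModel:
    """OLS of the ChT target (um) on standardized selected features."""
    feature_names = list(feature_names)
    missing = [f for f in feature_names if f not in X_train.columns]
    if missing:
        raise ValueError(f"selected features absent from table: {missing}")
    y = np.asarray(y_train, dtype=float)
    means = X_train[feature_names].mean()
    sds = X_train[feature_names].std(ddof=0)
    flat = sds[sds <= 1e-12].index.tolist()
    if flat:
        raise ValueError(f"zero-variance selected features: {flat}")
    Z = _standardize(X_train[feature_names], means, sds)
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError(f"collinear selected feature set: {feature_names}")
    coef, icpt = _ols_fit(Z, y)
    return IODModel(target=target, feature_names=feature_names,
                    means=means.to_numpy(), sds=sds.to_numpy(),
                    coef=coef, intercept=icpt)


def predict_iod(model: IODModel, features) -> np.ndarray:
    """Indicator values in 10-um units (see :meth:`IODModel.predict`)."""
    return model.predict(features)
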