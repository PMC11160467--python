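"""Sparse penalized predictors of log life-history traits.

Models are elastic-net linear regressions on standardized per-stratum
mean beta values. The penalty strength is chosen by internal k-fold
cross-validation on the training strata only; coefficients are reported
back on the original beta scale. Generalization error is estimated by
leave-one-species-out (LOSO) cross-validation, by a modified
leave-one-clade-out (LOCO) scheme that holds out whole taxonomic orders
(retaining only the extreme-life-span pair of orders with more than 20
species), or by a random 70/30 split of species.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold

from .containers import AggregatedMatrix, CVResult, MethylationMatrix
from .errors import (
    DegenerateResponseError,
    InsufficientDataError,
    InvalidArgumentError,
)
from .traits import CalibrationState, calibrate

logger = logging.getLogger(__name__)

#: orders larger than this keep only their extreme-life-span pair in training
LOCO_LARGE_ORDER = 20


@dataclass
class TrainConfig:
    """Elastic-net training settings.

    ``l1_ratio`` is the L1/L2 mixing parameter of the elastic net;
    penalty strength is selected on an ``n_alphas``-point path by
    ``cv_folds``-fold internal cross-validation minimizing mean squared
    error. All randomness (fold shuffling) flows from ``seed``.
    """

    l1_ratio: float = 0.5
    cv_folds: int = 10
    n_alphas: int = 25
    eps: float = 1e-2  # ratio of smallest to largest penalty on the path
    tol: float = 1e-3
    max_iter: int = 5000
    include_taxonomy_indicators: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.l1_ratio <= 1):
            raise InvalidArgumentError("l1_ratio must be in (0, 1]")
        if self.cv_folds < 2:
            raise InvalidArgumentError("cv_folds must be >= 2")


@dataclass
class PredictorModel:
    """A fitted sparse linear predictor on the log-trait scale."""

    trait: str
    intercept: float
    coef: pd.Series  # beta-scale coefficients over the filtered CpG universe
    feature_means: pd.Series
    feature_sds: pd.Series
    calibration: CalibrationState | None
    mode: str = "species"
    indicator_coef: pd.Series | None = None  # taxonomy one-hot coefficients
    log_base: str = "e"

    @property
    def nonzero_cpgs(self) -> list[str]:
        return list(self.coef.index[self.coef != 0.0])

    def predict(self, X: pd.DataFrame, calibrated: bool = True) -> np.ndarray:
        """Linear prediction for rows already on the model's CpG universe."""
        Xv = X[self.coef.index].to_numpy(dtype=float)
        out = self.intercept + Xv @ self.coef.to_numpy()
        if calibrated and self.calibration is not None:
            out = self.calibration.apply(out)
        return out

    def to_json(self, path=None) -> str:
        payload = {
            "trait": self.trait,
            "intercept": self.intercept,
            "cpgs": [
                {"id": c, "coef": float(v)}
                for c, v in self.coef.items()
                if v != 0.0
            ],
            "universe": list(self.coef.index),
            "standardization": {
                "means": self.feature_means.to_dict(),
                "sds": self.feature_sds.to_dict(),
            },
            "calibration": None
            if self.calibration is None
            else self.calibration.to_dict(),
            "mode": self.mode,
            "log_base": self.log_base,
            "indicator_coef": None
            if self.indicator_coef is None
            else self.indicator_coef.to_dict(),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PredictorModel":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        d = json.loads(text)
        coef = pd.Series(0.0, index=pd.Index(d["universe"]))
        for item in d["cpgs"]:
            coef.loc[item["id"]] = item["coef"]
        return cls(
            trait=d["trait"],
            intercept=d["intercept"],
            coef=coef,
            feature_means=pd.Series(d["standardization"]["means"]),
            feature_sds=pd.Series(d["standardization"]["sds"]),
            calibration=None
            if d["calibration"] is None
            else CalibrationState.from_dict(d["calibration"]),
            mode=d["mode"],
            indicator_coef=None
            if d["indicator_coef"] is None
            else pd.Series(d["indicator_coef"]),
            log_base=d["log_base"],
        )


def _as_frame(X) -> tuple[pd.DataFrame, str, pd.Series]:
    if isinstance(X, AggregatedMatrix):
        return X.values, X.mode, X.species_of_rows()
    if isinstance(X, pd.DataFrame):
        if isinstance(X.index, pd.MultiIndex):
            species = pd.Series(X.index.get_level_values(0), index=X.index)
            return X, "species_tissue", species
        return X, "species", pd.Series(X.index, index=X.index)
    raise InvalidArgumentError("X must be an AggregatedMatrix or DataFrame")


def train(
    X,
    y: pd.Series,
    config: TrainConfig | None = None,
    orders: dict[str, str] | None = None,
    trait: str = "max_lifespan",
) -> PredictorModel:
    """Fit an elastic-net predictor of a log trait on stratum means.

    Parameters
    ----------
    X
        AggregatedMatrix (or plain DataFrame) of stratum x CpG means.
    y
        Log-scale trait values aligned with the rows of ``X``.
    config
        Penalty and internal-CV settings.
    orders
        Species -> taxonomic order map; only consulted when
        ``config.include_taxonomy_indicators`` is set, in which case
        one-hot order indicators compete with CpGs for selection.
    """
    config = config or TrainConfig()
    frame, mode, species = _as_frame(X)
    y = pd.Series(np.asarray(y, dtype=float), index=frame.index)
    if frame.shape[0] < 10:
        raise InsufficientDataError("need at least 10 training strata")
    if frame.isna().any().any():
        raise InvalidArgumentError("X contains missing cells; impute first")
    if float(y.std(ddof=0)) == 0.0:
        raise DegenerateResponseError("response is constant")

    feats = frame
    indicator_cols: list[str] = []
    if config.include_taxonomy_indicators:
        if orders is None:
            raise InvalidArgumentError("orders required for taxonomy indicators")
        dummies = pd.get_dummies(
            species.map(orders), prefix="order", dtype=float
        )
        dummies.index = frame.index
        indicator_cols = list(dummies.columns)
        feats = pd.concat([frame, dummies], axis=1)

    means = feats.mean()
    sds = feats.std(ddof=0).replace(0.0, 1.0)
    Z = (feats - means) / sds

    cv = KFold(
        n_splits=min(config.cv_folds, len(y)),
        shuffle=True,
        random_state=config.seed % (2**32),
    )
    enet = ElasticNetCV(
        l1_ratio=config.l1_ratio,
        alphas=config.n_alphas,
        eps=config.eps,
        cv=cv,
        max_iter=config.max_iter,
        tol=config.tol,
        random_state=config.seed % (2**32),
    )
    with np.errstate(all="ignore"):
        enet.fit(Z.to_numpy(), y.to_numpy())

    coef_std = pd.Series(enet.coef_, index=feats.columns)
    coef = coef_std / sds
    intercept = float(enet.intercept_ - (coef * means).sum())

    cpg_coef = coef.drop(indicator_cols) if indicator_cols else coef
    ind_coef = coef[indicator_cols] if indicator_cols else None
    model = PredictorModel(
        trait=trait,
        intercept=intercept,
        coef=cpg_coef,
        feature_means=means.drop(indicator_cols) if indicator_cols else means,
        feature_sds=sds.drop(indicator_cols) if indicator_cols else sds,
        calibration=None,
        mode=mode,
        indicator_coef=ind_coef,
    )
    fitted = model.predict(frame, calibrated=False)
    if ind_coef is not None and (ind_coef != 0).any():
        # indicator contributions enter the fitted values used for calibration
        fitted = fitted + (
            pd.get_dummies(species.map(orders), prefix="order", dtype=float)
            .reindex(columns=indicator_cols, fill_value=0.0)
            .to_numpy()
            @ ind_coef.to_numpy()
        )
    if float(np.std(fitted)) > 0:
        _, model.calibration = calibrate(fitted, y.to_numpy())
    else:
        logger.info("degenerate (intercept-only) fit; calibration skipped")
    return model


# ---------------------------------------------------------------------------
# fold construction
# ---------------------------------------------------------------------------


def loso_folds(species_list) -> list[tuple[str, list[str], list[str]]]:
    """One fold per species: (fold id, training species, test species)."""
    uniq = sorted(set(species_list))
    return [(sp, [s for s in uniq if s != sp], [sp]) for sp in uniq]


def loco_folds(
    lifespan: pd.Series, orders: dict[str, str]
) -> list[tuple[str, list[str], list[str]]]:
    """Modified leave-one-clade-out folds.

    One fold per taxonomic order. Orders with more than 20 species keep
    exactly two species in training — the minimum- and maximum-life-span
    members (ties broken lexicographically) — and the rest are tested;
    orders with at most 20 species are held out whole. ``lifespan`` is
    indexed by species (log or natural scale; only the ordering is used).
    """
    missing = [s for s in lifespan.index if s not in orders]
    if missing:
        raise InvalidArgumentError(f"species without order label: {missing[:5]}")
    all_species = sorted(lifespan.index)
    by_order: dict[str, list[str]] = {}
    for sp in all_species:
        by_order.setdefault(orders[sp], []).append(sp)
    folds = []
    for order_name in sorted(by_order):
        members = by_order[order_name]
        if len(members) > LOCO_LARGE_ORDER:
            ranked = sorted((float(lifespan.loc[s]), s) for s in members)
            lo, hi = ranked[0][1], ranked[-1][1]
            if ranked[0][0] == ranked[1][0] or ranked[-1][0] == ranked[-2][0]:
                logger.info(
                    "order %s has tied extreme life spans; lexicographic "
                    "tie-break retained %s and %s", order_name, lo, hi
                )
            test = [s for s in members if s not in (lo, hi)]
        else:
            test = list(members)
        train_set = [s for s in all_species if s not in set(test)]
        folds.append((order_name, train_set, test))
    return folds


def _run_folds(frame, y, species, folds, config, orders, trait, scheme) -> CVResult:
    rows = []
    for fold_id, train_species, test_species in folds:
        train_mask = species.isin(train_species).to_numpy()
        test_mask = species.isin(test_species).to_numpy()
        if not test_mask.any():
            continue
        model = train(
            frame.loc[train_mask], y.loc[train_mask],
            config=config, orders=orders, trait=trait,
        )
        preds = model.predict(frame.loc[test_mask])
        for stratum, sp, obs, pred in zip(
            frame.index[test_mask],
            species[test_mask],
            y.loc[test_mask],
            preds,
        ):
            rows.append(
                {
                    "stratum": stratum,
                    "species": sp,
                    "fold": fold_id,
                    "observed": float(obs),
                    "predicted": float(pred),
                }
            )
    table = pd.DataFrame(rows).set_index("stratum")
    return CVResult(table=table, scheme=scheme)


def loso_cv(
    X,
    y: pd.Series,
    config: TrainConfig | None = None,
    orders: dict[str, str] | None = None,
    trait: str = "max_lifespan",
) -> CVResult:
    """Leave-one-species-out cross-validation.

    In tissue-aware mode all strata of the held-out species leave the
    training set together, so a species never informs its own
    prediction.
    """
    frame, mode, species = _as_frame(X)
    y = pd.Series(np.asarray(y, dtype=float), index=frame.index)
    uniq = sorted(set(species))
    if len(uniq) < 10:
        raise InsufficientDataError("need at least 10 species for LOSO")
    folds = loso_folds(uniq)
    return _run_folds(frame, y, species, folds, config, orders, trait, "loso")


def loco_cv(
    X,
    y: pd.Series,
    orders: dict[str, str],
    traits: pd.DataFrame | None = None,
    config: TrainConfig | None = None,
    trait: str = "max_lifespan",
) -> CVResult:
    """Modified leave-one-clade-out cross-validation.

    Species whose life span was imputed (``traits['lifespan_imputed']``)
    are excluded from both training and testing, mirroring the
    restriction of the comparison to species with actual records.
    Fold training sets keep, for each order of more than 20 species,
    only its minimum- and maximum-life-span members.
    """
    frame, mode, species = _as_frame(X)
    y = pd.Series(np.asarray(y, dtype=float), index=frame.index)
    if traits is not None and "lifespan_imputed" in traits.columns:
        imputed = set(traits.index[traits["lifespan_imputed"].astype(bool)])
        if imputed:
            keep = ~species.isin(imputed).to_numpy()
            frame, y, species = frame.loc[keep], y.loc[keep], species[keep]
    lifespan_by_species = y.groupby(species.to_numpy()).mean()
    folds = loco_folds(lifespan_by_species, orders)
    return _run_folds(frame, y, species, folds, config, orders, trait, "loco")


def split_train_test(
    species_list, fraction: float = 0.7, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Seeded random partition of species into train/test sets."""
    uniq = sorted(set(species_list))
    if len(uniq) < 10:
        raise InsufficientDataError("need at least 10 species to split")
    if not (0 < fraction < 1):
        raise InvalidArgumentError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(uniq))
    n_train = int(round(fraction * len(uniq)))
    train_species = sorted(uniq[i] for i in perm[:n_train])
    test_species = sorted(uniq[i] for i in perm[n_train:])
    return train_species, test_species


def predict_samples(model: PredictorModel, matrix: MethylationMatrix) -> pd.DataFrame:
    """Apply a stratum-level model to individual samples.

    CpGs missing from a sample are imputed with the model's stored
    training means. Samples missing more than 20% of the model's CpGs
    are still predicted but flagged ``low_confidence``.
    """
    X = matrix.beta.reindex(columns=model.coef.index)
    miss_frac = X.isna().mean(axis=1)
    X = X.fillna(model.feature_means)
    preds = model.predict(X)
    out = matrix.samples.copy()
    out["predicted"] = preds
    out["low_confidence"] = (miss_frac > 0.2).to_numpy()
    if out["low_confidence"].any():
        logger.warning(
            "%d samples missing >20%% of model CpGs; predictions flagged",
            int(out["low_confidence"].sum()),
        )
    return out
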