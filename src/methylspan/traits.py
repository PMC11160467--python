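"""Trait-scale rules: the 1.3 life-span correction, log transforms,
mean/SD calibration of predictions, and phylogenetic K=1 imputation.

Recorded maximum life spans understate the true species potential when
they rest on few observed individuals, so all species except the two
exhaustively documented ones (humans and mice) get a multiplicative
correction before modelling. All three life-history traits are heavily
right-skewed and are modelled on the natural-log scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateResponseError,
    InvalidArgumentError,
)
from .phylo import Phylogeny

#: species whose recorded maximum life span is considered definitive
DEFAULT_EXEMPT = frozenset({"Homo sapiens", "Mus musculus"})


@dataclass
class CorrectionConfig:
    """Multiplicative life-span correction (default +30%)."""

    factor: float = 1.3
    exempt_species: frozenset = DEFAULT_EXEMPT

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise InvalidArgumentError("correction factor must be > 0")


def apply_correction(
    traits: pd.DataFrame, config: CorrectionConfig | None = None
) -> pd.DataFrame:
    """Scale recorded maximum life spans of non-exempt species by ``factor``.

    Rows already carrying ``lifespan_corrected == True`` are left alone,
    so the operation is idempotent. Other traits are untouched.
    """
    config = config or CorrectionConfig()
    out = traits.copy()
    if "lifespan_corrected" not in out.columns:
        out["lifespan_corrected"] = False
    todo = ~out["lifespan_corrected"].astype(bool)
    scale = ~out.index.isin(list(config.exempt_species)) & todo
    out.loc[scale, "max_lifespan_years"] *= config.factor
    out.loc[todo, "lifespan_corrected"] = True
    return out


def to_log(value):
    """Natural log of a (strictly positive) trait value."""
    arr = np.asarray(value, dtype=float)
    if np.any(arr <= 0):
        raise InvalidArgumentError("trait values must be strictly positive")
    out = np.log(arr)
    return float(out) if np.isscalar(value) or arr.ndim == 0 else out


def from_log(value):
    """Inverse of :func:`to_log`."""
    arr = np.asarray(value, dtype=float)
    out = np.exp(arr)
    return float(out) if np.isscalar(value) or arr.ndim == 0 else out


@dataclass
class CalibrationState:
    """Affine map aligning a predictor's output distribution with the
    observed trait distribution (log scale): standardize by the training
    prediction mean/SD, then rescale to the observed mean/SD."""

    pred_mean: float
    pred_sd: float
    obs_mean: float
    obs_sd: float

    def __post_init__(self) -> None:
        if self.pred_sd <= 0 or self.obs_sd <= 0:
            raise DegenerateResponseError("calibration requires positive SDs")

    def apply(self, predictions):
        arr = np.asarray(predictions, dtype=float)
        return (arr - self.pred_mean) / self.pred_sd * self.obs_sd + self.obs_mean

    def to_dict(self) -> dict:
        return {
            "pred_mean": self.pred_mean,
            "pred_sd": self.pred_sd,
            "obs_mean": self.obs_mean,
            "obs_sd": self.obs_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationState":
        return cls(**d)


def calibrate(predictions, observed) -> tuple[np.ndarray, CalibrationState]:
    """Fit and apply the mean/SD calibration map.

    Returns the calibrated predictions together with the frozen state so
    the identical affine map can be applied to new predictions.
    """
    pred = np.asarray(predictions, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape or pred.size < 2:
        raise InvalidArgumentError("need two equal-length vectors of size >= 2")
    state = CalibrationState(
        pred_mean=float(pred.mean()),
        pred_sd=float(pred.std(ddof=1)),
        obs_mean=float(obs.mean()),
        obs_sd=float(obs.std(ddof=1)),
    )
    return state.apply(pred), state


def impute_missing_lifespan(
    traits: pd.DataFrame, phylo: Phylogeny
) -> pd.DataFrame:
    """Fill missing maximum life spans from the patristically nearest
    observed species (K=1), recording the source and setting the
    imputed flag. Distance ties break by lexicographic species name.
    """
    out = traits.copy()
    if "lifespan_imputed" not in out.columns:
        out["lifespan_imputed"] = False
        out["lifespan_imputed_from"] = ""
    missing = out.index[out["max_lifespan_years"].isna()]
    if len(missing) == 0:
        return out
    observed = [s for s in out.index if s not in set(missing)]
    if not observed:
        raise InvalidArgumentError("all maximum life spans missing")
    dist = phylo.patristic_distances()
    for sp in missing:
        row = dist.loc[sp, observed]
        source = min(zip(row.to_numpy(dtype=float), observed))[1]
        out.loc[sp, "max_lifespan_years"] = out.loc[source, "max_lifespan_years"]
        out.loc[sp, "lifespan_imputed"] = True
        out.loc[sp, "lifespan_imputed_from"] = source
    return out
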