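"""Probe filtering and sample-to-stratum aggregation.

Before any model fitting, the sample-level matrix is reduced to the CpGs
that are reliably detected across the species panel and aggregated into
one observation per species (tissue-agnostic) or per (species, tissue)
stratum (tissue-aware).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from .containers import AggregatedMatrix, MethylationMatrix
from .errors import InvalidArgumentError


@dataclass
class FilterConfig:
    """Detection-based probe filter settings.

    A CpG is kept when its per-species median detection p-value is
    significant (Benjamini-Hochberg FDR < ``fdr_threshold``, adjusted
    within each species across CpGs) in at least ``species_fraction`` of
    the species panel.
    """

    fdr_threshold: float = 0.05
    species_fraction: float = 0.85

    def __post_init__(self) -> None:
        if not (0 < self.fdr_threshold < 1 and 0 < self.species_fraction < 1):
            raise InvalidArgumentError(
                "fdr_threshold and species_fraction must be in (0, 1)"
            )


def filter_probes(
    detection: pd.DataFrame, config: FilterConfig | None = None
) -> list[str]:
    """Return CpG ids reliably detected across the species panel.

    Parameters
    ----------
    detection
        Species x CpG table of median detection p-values. Missing cells
        count against the probe (treated as p = 1).
    config
        Filter thresholds; defaults to FDR < 0.05 in 85% of species.

    Returns
    -------
    CpG ids in their input column order.
    """
    config = config or FilterConfig()
    if detection.empty:
        raise InvalidArgumentError("empty detection table")
    if detection.shape[0] < 2:
        raise InvalidArgumentError("detection table must cover >= 2 species")
    pvals = detection.to_numpy(dtype=float)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    qvals = np.vstack([false_discovery_control(row, method="bh") for row in pvals])
    n_species = detection.shape[0]
    need = math.ceil(config.species_fraction * n_species)
    n_sig = (qvals < config.fdr_threshold).sum(axis=0)
    return [c for c, k in zip(detection.columns, n_sig) if k >= need]


def aggregate(matrix: MethylationMatrix, mode: str = "species") -> AggregatedMatrix:
    """Average beta values within species or (species, tissue) strata.

    Stratum means ignore missing beta values; any cell still missing
    after aggregation (no non-missing sample in the stratum) is imputed
    with the column mean over strata so downstream design matrices are
    complete.
    """
    if matrix.n_samples == 0:
        raise InvalidArgumentError("empty methylation matrix")
    if mode == "species":
        keys = matrix.samples["species"]
    elif mode == "species_tissue":
        keys = [matrix.samples["species"], matrix.samples["tissue"]]
    else:
        raise InvalidArgumentError(f"unknown aggregation mode: {mode!r}")
    grouped = matrix.beta.groupby(keys)
    values = grouped.mean()
    counts = grouped.size()
    if mode == "species_tissue":
        values.index.names = ["species", "tissue"]
    else:
        values.index.name = "species"
    if values.isna().any().any():
        values = values.fillna(values.mean())
    return AggregatedMatrix(values=values, counts=counts, mode=mode)


def select_young(
    matrix: MethylationMatrix, traits: pd.DataFrame, age_cap: float = 5.0
) -> MethylationMatrix:
    """Keep samples from animals younger than both sexual maturity and 5 years.

    Samples with unknown age are dropped (neither condition can be
    verified); species with no qualifying sample vanish from the result.
    """
    maturity = traits["maturity_years"]
    unknown = set(matrix.species) - set(maturity.index)
    if unknown:
        raise InvalidArgumentError(
            f"species missing age at sexual maturity: {sorted(unknown)[:5]}"
        )
    age = matrix.samples["age_years"]
    lim = matrix.species.map(maturity)
    keep = age.notna() & (age < lim) & (age < age_cap)
    return matrix.subset(matrix.samples.index[keep])
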