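"""In-memory containers for methylation data and aggregated design matrices.

The package keeps methylation data as a pair of aligned pandas DataFrames:
a samples x CpGs matrix of beta values (methylated fraction, in [0, 1])
and a sample sheet carrying species, tissue, sex, age and (optionally)
breed annotations. Aggregated per-stratum matrices keep the same column
universe but one row per species or per (species, tissue) stratum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

#: Columns every sample sheet must carry.
SAMPLE_COLUMNS = ("species", "tissue", "sex", "age_years")


@dataclass
class MethylationMatrix:
    """Sample-level beta values plus sample metadata.

    Parameters
    ----------
    beta
        DataFrame indexed by sample id, one column per CpG, values in
        [0, 1] (NaN allowed for missing measurements).
    samples
        Sample sheet indexed by sample id with at least the columns
        ``species``, ``tissue``, ``sex`` and ``age_years``. Sex uses the
        labels ``female`` / ``male`` / ``unknown``; age may be NaN.
    """

    beta: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.beta.index.equals(self.samples.index):
            raise InvalidArgumentError("beta and sample sheet indexes differ")
        if not self.beta.index.is_unique:
            raise InvalidArgumentError("sample ids are not unique")
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise InvalidArgumentError(f"sample sheet lacks columns: {missing}")
        vals = self.beta.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = np.nansum((vals < 0) | (vals > 1))
        if bad:
            raise InvalidArgumentError("beta values outside [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.beta.shape[0]

    @property
    def cpg_ids(self) -> pd.Index:
        return self.beta.columns

    @property
    def species(self) -> pd.Series:
        return self.samples["species"]

    def subset(self, sample_ids) -> "MethylationMatrix":
        """Row subset preserving order of ``sample_ids``."""
        return MethylationMatrix(
            beta=self.beta.loc[sample_ids].copy(),
            samples=self.samples.loc[sample_ids].copy(),
        )


@dataclass
class AggregatedMatrix:
    """Per-stratum mean beta values.

    ``values`` is indexed by species (mode ``"species"``) or by a
    (species, tissue) MultiIndex (mode ``"species_tissue"``); ``counts``
    records how many samples entered each stratum mean.
    """

    values: pd.DataFrame
    counts: pd.Series
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in ("species", "species_tissue"):
            raise InvalidArgumentError(f"unknown aggregation mode: {self.mode!r}")
        if not self.values.index.equals(self.counts.index):
            raise InvalidArgumentError("values and counts indexes differ")

    @property
    def strata(self) -> pd.Index:
        return self.values.index

    def species_of_rows(self) -> pd.Series:
        """Species label of each stratum row."""
        if self.mode == "species":
            return pd.Series(self.values.index, index=self.values.index)
        return pd.Series(
            self.values.index.get_level_values(0), index=self.values.index
        )

    def to_methylation(self) -> MethylationMatrix:
        """View each stratum mean as a single pseudo-sample.

        Useful for re-aggregation (idempotence) and for applying
        sample-level prediction to stratum means.
        """
        if self.mode == "species":
            sheet = pd.DataFrame(
                {
                    "species": list(self.values.index),
                    "tissue": "aggregate",
                    "sex": "unknown",
                    "age_years": np.nan,
                },
                index=self.values.index.astype(str),
            )
            beta = self.values.copy()
            beta.index = beta.index.astype(str)
        else:
            ids = [f"{sp}|{ti}" for sp, ti in self.values.index]
            sheet = pd.DataFrame(
                {
                    "species": self.values.index.get_level_values(0),
                    "tissue": self.values.index.get_level_values(1),
                    "sex": "unknown",
                    "age_years": np.nan,
                },
                index=pd.Index(ids),
            )
            beta = self.values.copy()
            beta.index = pd.Index(ids)
        return MethylationMatrix(beta=beta, samples=sheet)


@dataclass
class CVResult:
    """Held-out predictions from a cross-validation scheme.

    ``table`` has one row per held-out stratum with columns ``species``,
    ``fold``, ``observed`` and ``predicted`` (log-trait scale). Summary
    metrics are recomputed from the table on demand so they can never
    drift out of sync with the per-stratum rows.
    """

    table: pd.DataFrame
    scheme: str
    extra: dict = field(default_factory=dict)

    def summary(self) -> dict:
        from .evaluate import accuracy_metrics

        return accuracy_metrics(
            self.table["observed"].to_numpy(), self.table["predicted"].to_numpy()
        )
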