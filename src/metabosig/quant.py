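"""Sample x metabolite quantification matrices with limit-of-quantification flags.

The central container is :class:`QuantMatrix`, which bundles a concentration
table (samples in rows, metabolites in columns), per-metabolite lower/upper
limits of quantification (LLOQ/ULOQ), per-value quantification-status flags and
per-sample metadata (group label, tissue, tissue weight).  Concentrations are
micromolar for plasma and amount per mg tissue after weight normalization.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

#: per-value quantification status codes
VALID = 0
BELOW_LLOQ = 1
ABOVE_ULOQ = 2

STATUS_LABELS = {VALID: "valid", BELOW_LLOQ: "below_LLOQ", ABOVE_ULOQ: "above_ULOQ"}
STATUS_CODES = {v: k for k, v in STATUS_LABELS.items()}

#: metadata columns required for every sample
METADATA_COLUMNS = ("group", "tissue", "weight_mg")


class SchemaError(ValueError):
    """Raised when an input table violates the documented schema."""


def derive_status(values: pd.DataFrame, loq: pd.DataFrame) -> pd.DataFrame:
    """Assign quantification-status flags by comparing values to LOQ bounds.

    A value strictly below its metabolite's LLOQ is ``below_LLOQ``; strictly
    above the ULOQ is ``above_ULOQ``; anything else (bounds included) is
    ``valid``.
    """
    lloq = loq["lloq"].reindex(values.columns).to_numpy()
    uloq = loq["uloq"].reindex(values.columns).to_numpy()
    arr = values.to_numpy()
    status = np.full(arr.shape, VALID, dtype=np.int8)
    status[arr < lloq[None, :]] = BELOW_LLOQ
    status[arr > uloq[None, :]] = ABOVE_ULOQ
    return pd.DataFrame(status, index=values.index, columns=values.columns)


@dataclasses.dataclass
class QuantMatrix:
    """A quantified metabolomics dataset for one tissue.

    Parameters
    ----------
    values : DataFrame
        Concentrations, samples in rows and metabolites in columns.
    loq : DataFrame
        Indexed by metabolite id, columns ``lloq`` and ``uloq``.
    samples : DataFrame
        Indexed by sample id, columns ``group`` (binary labels, e.g.
        sham/stroke), ``tissue`` (plasma/heart) and ``weight_mg`` (NaN for
        plasma).
    status : DataFrame, optional
        Per-value flags; derived from ``loq`` when omitted.  Supplied
        explicitly by transforms (weight normalization, imputation) whose
        output is no longer in raw assay units.
    weight_normalized : bool
        True once concentrations have been divided by tissue weight; the LOQ
        table then still refers to raw assay units.
    """

    values: pd.DataFrame
    loq: pd.DataFrame
    samples: pd.DataFrame
    status: pd.DataFrame | None = None
    weight_normalized: bool = False

    def __post_init__(self) -> None:
        if self.values.shape[0] == 0:
            raise ValueError("QuantMatrix requires at least one sample")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate sample ids: {dup}")
        missing = [c for c in METADATA_COLUMNS if c not in self.samples.columns]
        if missing:
            raise SchemaError(f"sample metadata missing columns: {missing}")
        if not self.values.index.equals(self.samples.index):
            self.samples = self.samples.reindex(self.values.index)
            if self.samples.isna().all(axis=1).any():
                raise SchemaError("sample metadata does not cover all samples")
        absent = [m for m in self.values.columns if m not in self.loq.index]
        if absent:
            raise SchemaError(f"metabolites missing from LOQ table: {absent[:5]}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative concentrations are not allowed")
        groups = self.samples["group"].unique()
        if len(groups) > 2:
            raise ValueError(f"group labels must be binary, got {sorted(groups)}")
        if self.status is None:
            self.status = derive_status(self.values, self.loq)
        else:
            self.status = self.status.reindex(
                index=self.values.index, columns=self.values.columns
            ).astype(np.int8)

    # -- basic views --------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def metabolites(self) -> list[str]:
        return list(self.values.columns)

    @property
    def groups(self) -> pd.Series:
        return self.samples["group"]

    def binary_labels(self) -> tuple[np.ndarray, str]:
        """Encode groups as 0/1 and return the positive label.

        ``stroke`` is the positive class when present; otherwise the
        lexicographically later label.
        """
        labels = sorted(self.groups.unique())
        if len(labels) != 2:
            raise ValueError("binary_labels requires exactly two groups")
        positive = "stroke" if "stroke" in labels else labels[-1]
        return (self.groups == positive).to_numpy(dtype=int), positive

    def group_values(self, metabolite: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (reference-group, positive-group) value arrays for one metabolite."""
        y, _ = self.binary_labels()
        col = self.values[metabolite].to_numpy()
        return col[y == 0], col[y == 1]

    def out_of_loq_fraction(self) -> pd.Series:
        """Per-metabolite share of values flagged outside [LLOQ, ULOQ]."""
        return (self.status != VALID).mean(axis=0)

    # -- subsetting ---------------------------------------------------------

    def subset_samples(self, sample_ids) -> "QuantMatrix":
        ids = list(sample_ids)
        return QuantMatrix(
            values=self.values.loc[ids].copy(),
            loq=self.loq,
            samples=self.samples.loc[ids].copy(),
            status=self.status.loc[ids].copy(),
            weight_normalized=self.weight_normalized,
        )

    def subset_metabolites(self, metabolite_ids) -> "QuantMatrix":
        cols = list(metabolite_ids)
        return QuantMatrix(
            values=self.values[cols].copy(),
            loq=self.loq.loc[cols].copy(),
            samples=self.samples,
            status=self.status[cols].copy(),
            weight_normalized=self.weight_normalized,
        )

    def copy(self) -> "QuantMatrix":
        return QuantMatrix(
            values=self.values.copy(),
            loq=self.loq.copy(),
            samples=self.samples.copy(),
            status=self.status.copy(),
            weight_normalized=self.weight_normalized,
        )

    # -- I/O ----------------------------------------------------------------

    def write(self, directory, stem: str = "matrix") -> dict[str, Path]:
        """Write the TSV trio (values, LOQ bounds, sample metadata).

        Returns the paths written, keyed ``values``/``loq``/``samples``.
        """
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "values": directory / f"{stem}.tsv",
            "loq": directory / f"{stem}_loq.tsv",
            "samples": directory / f"{stem}_samples.tsv",
        }
        self.values.to_csv(paths["values"], sep="\t", index_label="sample_id")
        self.loq.to_csv(paths["loq"], sep="\t", index_label="metabolite_id")
        self.samples.to_csv(paths["samples"], sep="\t", index_label="sample_id")
        return paths


def read_quant_matrix(values_path, loq_path, samples_path) -> QuantMatrix:
    """Load a :class:`QuantMatrix` from the TSV trio.

    Status flags are assigned by cross-checking each value against its
    metabolite's LOQ bounds.  Schema violations (duplicate sample ids,
    non-numeric cells, missing columns) raise :class:`SchemaError` with the
    offending coordinates.
    """
    values = pd.read_csv(values_path, sep="\t", index_col="sample_id")
    for col in values.columns:
        if not pd.api.types.is_numeric_dtype(values[col]):
            bad = values[col][pd.to_numeric(values[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise SchemaError(
                f"non-numeric concentration in column {col!r}, sample {row!r}"
            )
    loq = pd.read_csv(loq_path, sep="\t", index_col="metabolite_id")
    for col in ("lloq", "uloq"):
        if col not in loq.columns:
            raise SchemaError(f"LOQ table missing column {col!r}")
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
    return QuantMatrix(values=values, loq=loq, samples=samples)
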