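"""Core in-memory containers shared across the pipeline.

A :class:`PeakTable` holds a samples × peaks intensity matrix together with
its detection mask and per-peak metadata (m/z, retention time, ionization
mode, and — once annotated — compound/class information).  A
:class:`Cohort` holds the species-level trait table and the sample-level
metadata that tie every measurement to a species, tissue and individual.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

TISSUES = ("liver", "muscle", "kidney", "heart", "cortex", "cerebellum")
BRAIN_TISSUES = ("cortex", "cerebellum")
NONNEURAL_TISSUES = ("liver", "muscle", "kidney")
CLADES = ("rodent", "primate", "bat")

#: peak-metadata columns always present
PEAK_META_COLS = ("mz", "rt", "mode")


@dataclass
class PeakTable:
    """Samples × peaks matrix with detection mask and peak metadata.

    Parameters
    ----------
    values : DataFrame
        Intensity matrix, samples in rows, peaks in columns.  Undetected
        entries are NaN.  Raw (arbitrary-unit) scale unless ``log_scale``.
    detected : DataFrame
        Boolean mask, same shape/index/columns as ``values``.
    peak_meta : DataFrame
        Indexed by peak id; at least ``mz`` (Da), ``rt`` (minutes) and
        ``mode`` ('pos'/'neg'); annotated tables add compound columns.
    log_scale : bool
        True once the table has been IS-normalized and log transformed.
    tissue : str or None
        Tissue the table was measured in, when it is tissue-specific.
    """

    values: pd.DataFrame
    detected: pd.DataFrame
    peak_meta: pd.DataFrame
    log_scale: bool = False
    tissue: str | None = None

    def __post_init__(self) -> None:
        if self.values.shape != self.detected.shape:
            raise ValueError("values and detected must have the same shape")
        if not self.values.columns.equals(self.detected.columns):
            raise ValueError("values and detected must share peak columns")
        missing = self.values.columns.difference(self.peak_meta.index)
        if len(missing):
            raise ValueError(f"peaks without metadata: {list(missing)[:5]}")

    # -- basic geometry -------------------------------------------------
    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def peak_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_peaks(self) -> int:
        return self.values.shape[1]

    # -- subsetting -----------------------------------------------------
    def subset_peaks(self, peak_ids) -> "PeakTable":
        peak_ids = pd.Index(peak_ids)
        return replace(
            self,
            values=self.values.loc[:, peak_ids],
            detected=self.detected.loc[:, peak_ids],
            peak_meta=self.peak_meta.loc[peak_ids],
        )

    def subset_samples(self, sample_ids) -> "PeakTable":
        sample_ids = pd.Index(sample_ids)
        return replace(
            self,
            values=self.values.loc[sample_ids],
            detected=self.detected.loc[sample_ids],
        )

    def copy(self) -> "PeakTable":
        return replace(
            self,
            values=self.values.copy(),
            detected=self.detected.copy(),
            peak_meta=self.peak_meta.copy(),
        )


@dataclass
class Cohort:
    """Species traits plus per-sample metadata.

    ``species``: indexed by species_id with columns ``clade``, ``mls``
    (years), ``bmr`` (W), ``body_mass`` (g), ``body_temp`` (°C), ``diet``,
    ``hibernates``.

    ``samples``: indexed by sample_id with columns ``individual_id``,
    ``species_id``, ``tissue``, ``sex``, ``age`` (years), ``is_level``
    (internal-standard intensity for that measurement).
    """

    species: pd.DataFrame
    samples: pd.DataFrame
    tissues: tuple = field(default=TISSUES)

    def __post_init__(self) -> None:
        unknown = set(self.samples["species_id"]) - set(self.species.index)
        if unknown:
            raise ValueError(f"samples reference unknown species: {sorted(unknown)[:5]}")

    def samples_for_tissue(self, tissue: str) -> pd.DataFrame:
        return self.samples[self.samples["tissue"] == tissue]

    def species_of(self, sample_ids) -> pd.Series:
        return self.samples.loc[sample_ids, "species_id"]

    def clades(self) -> pd.Series:
        return self.species["clade"]

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def sample_factor(cohort: Cohort, sample_ids, column: str) -> pd.Series:
    """Value of a species- or sample-level factor for each listed sample."""
    samples = cohort.samples.loc[sample_ids]
    if column in samples.columns:
        return samples[column]
    if column in cohort.species.columns:
        return cohort.species.loc[samples["species_id"], column].set_axis(samples.index)
    raise KeyError(f"unknown factor column {column!r}")


def species_means(values: pd.DataFrame, species_of_sample: pd.Series) -> pd.DataFrame:
    """Per-species mean of each peak column (NaN-aware)."""
    return values.groupby(species_of_sample.loc[values.index].to_numpy()).mean()


def as_json_safe(obj):
    """Recursively convert numpy/pandas scalars and containers for json.dump."""
    if isinstance(obj, dict):
        return {str(k): as_json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [as_json_safe(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [as_json_safe(v) for v in obj.tolist()]
    if isinstance(obj, pd.Series):
        return as_json_safe(obj.to_dict())
    if isinstance(obj, pd.DataFrame):
        return as_json_safe(obj.to_dict(orient="list"))
    return obj
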