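"""Shared fixtures: small synthetic cohorts and processed tables.

Everything is generated programmatically at test time; fixture sizes are
kept small so single tests stay fast, while the acceptance suite builds
the full default benchmark once per session.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import lifelipid as ll
from lifelipid.datatypes import PeakTable


@pytest.fixture(scope="session")
def cohort():
    """Default 35-species, 6-tissue cohort."""
    return ll.generate_cohort(seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced cohort (12 species, 2 tissues) for fast unit tests."""
    return ll.generate_cohort(
        n_species_per_clade={"rodent": 5, "primate": 4, "bat": 3},
        n_individuals=3, tissues=("liver", "cortex"), seed=7)


@pytest.fixture(scope="session")
def small_lipidome(small_cohort):
    tables, reference, truth = ll.generate_lipidome(
        small_cohort, n_peaks=120, n_predictors=10,
        n_confounded_per_factor=2, n_duplicate_pairs=6, seed=13)
    return tables, reference, truth


@pytest.fixture(scope="session")
def processed_liver(small_cohort, small_lipidome):
    """Liver table after normalization, detection filter, merge, imputation."""
    tables, reference, truth = small_lipidome
    norm, _ = ll.normalize_by_internal_standard(tables["liver"], "IS_PC34_0")
    norm = norm.subset_peaks(ll.detection_filter(norm, small_cohort))
    ann = ll.annotate_adducts(norm, reference)
    merged, composites = ll.merge_peaks(norm, ann)
    return ll.impute_half_minimum(merged), composites


def make_table(values: np.ndarray, sample_ids=None, peak_ids=None,
               mz=None, rt=None, mode=None, detected=None,
               log_scale=True, tissue="liver", compound_id=None) -> PeakTable:
    """Hand-built PeakTable for oracle fixtures."""
    n, m = np.asarray(values).shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    peak_ids = peak_ids or [f"p{j}" for j in range(m)]
    vals = pd.DataFrame(np.asarray(values, dtype=float),
                        index=sample_ids, columns=peak_ids)
    det = pd.DataFrame(True, index=sample_ids, columns=peak_ids) \
        if detected is None else pd.DataFrame(detected, index=sample_ids,
                                              columns=peak_ids)
    meta = pd.DataFrame({
        "mz": mz if mz is not None else np.linspace(400.0, 900.0, m),
        "rt": rt if rt is not None else np.linspace(1.0, 10.0, m),
        "mode": mode if mode is not None else ["pos"] * m,
    }, index=peak_ids)
    if compound_id is not None:
        meta["compound_id"] = compound_id
    vals = vals.where(det, np.nan)
    return PeakTable(values=vals, detected=det, peak_meta=meta,
                     log_scale=log_scale, tissue=tissue)
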