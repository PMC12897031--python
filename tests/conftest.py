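"""Shared fixtures: synthetic datasets at two scales plus the standard
filter -> normalize -> correct -> test chain used by several test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from kbhb_atlas import differential as diff
from kbhb_atlas import preprocess_quant as pq
from kbhb_atlas import synthetic_data as synth

STUDY_SEED = 101
NULL_SEED = 202
SMALL_SEED = 11


@pytest.fixture(scope="session")
def design():
    from kbhb_atlas.formats_io import two_group_design
    return two_group_design()


@pytest.fixture(scope="session")
def small_dataset():
    """A quick dataset (~150 sites) for structural/IO/round-trip tests."""
    return synth.generate_dataset(synth.GeneratorConfig(n_proteins=60, seed=SMALL_SEED))


@pytest.fixture(scope="session")
def study_dataset():
    """The study conditions: ~2,000 sites, 4 vs 4, CV 0.2, 10% up at
    log2FC 1, ~10% protein-confounded at protein log2FC 1."""
    return synth.generate_dataset(synth.GeneratorConfig(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def null_dataset():
    """No effects anywhere: every site and protein is null."""
    return synth.generate_dataset(synth.GeneratorConfig(
        seed=NULL_SEED, frac_sites_up=0.0, frac_sites_down=0.0,
        frac_proteins_changed=0.0, frac_confounded_sites=0.0))


def site_differential_chain(dataset, corrected: bool = True):
    """filter -> center-scale -> (parent-protein correct) -> t-test/classify.

    Returns (records, site_meta, value_matrix).
    """
    meta, intensities = dataset.site_frames()
    filtered, _ = pq.filter_features(intensities, dataset.design, site_meta=meta)
    meta = meta.loc[filtered.index]
    site_rel, _ = pq.center_scale(filtered)
    if corrected:
        prot_filtered, _ = pq.filter_features(dataset.proteome, dataset.design)
        qn = pq.quantile_normalize(np.log2(prot_filtered))
        protein_rel, _ = pq.center_scale(np.power(2.0, qn))
        correction = pq.protein_correct(site_rel, protein_rel, meta["protein"].to_dict())
        matrix = correction.corrected
    else:
        matrix = site_rel
    records, _ = diff.differential_analysis(matrix, dataset.design)
    return records, meta, matrix


@pytest.fixture(scope="session")
def study_run(study_dataset):
    rec_c, meta, mat_c = site_differential_chain(study_dataset, corrected=True)
    rec_u, _, mat_u = site_differential_chain(study_dataset, corrected=False)
    return {"corrected": rec_c, "uncorrected": rec_u, "meta": meta,
            "corrected_matrix": mat_c, "raw_relative": mat_u,
            "truth": study_dataset.truth}


@pytest.fixture(scope="session")
def null_run(null_dataset):
    records, meta, _ = site_differential_chain(null_dataset, corrected=True)
    return {"records": records, "meta": meta, "truth": null_dataset.truth}
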