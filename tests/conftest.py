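"""Shared fixtures: the standard synthetic suite, computed once per session."""

from __future__ import annotations

from types import SimpleNamespace

import hypothesis
import numpy as np
import pytest

from tadgc import (
    GenomicInterval,
    classify_all,
    fit_pca,
    profile_matrix,
    standard_suite,
    tad_gc_profile,
)


@pytest.fixture(scope="session")
def suite():
    """Standard synthetic suite: 600 TADs, 100 per class, mean GC uniform
    on 33-59%, gradient amplitude 5, per-bin noise sd 1.0, seed 7."""
    genome, tads = standard_suite(seed=7)
    profiles = [
        tad_gc_profile(
            genome,
            GenomicInterval(r.chrom, int(r.start), int(r.end)),
            tad_id=r.tad_id,
        )
        for r in tads.itertuples(index=False)
    ]
    return SimpleNamespace(genome=genome, tads=tads, profiles=profiles)


@pytest.fixture(scope="session")
def suite_classification(suite):
    return classify_all(suite.profiles)


@pytest.fixture(scope="session")
def suite_pca(suite):
    ids, mat, mean_gc, fams = profile_matrix(suite.profiles)
    return SimpleNamespace(
        ids=ids, matrix=mat, mean_gc=mean_gc, families=fams, result=fit_pca(mat, k=3)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


hypothesis.settings.register_profile("deterministic", derandomize=True)
hypothesis.settings.load_profile("deterministic")
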