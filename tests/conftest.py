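"""Shared fixtures: synthetic bundles (clean and noisy) and pipeline runs.

The bundles are session-scoped because generation plus a full pipeline run
takes a few seconds; tests must not mutate them.
"""

import warnings

import pytest

import enhancermap as em
from enhancermap.pipeline import run_pipeline


@pytest.fixture(scope="session")
def clean_bundle():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return em.generate(em.SimulationConfig(noise=0.0), seed=7)


@pytest.fixture(scope="session")
def noisy_bundle():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return em.generate(seed=7)


def _run(bundle, seed=7):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(
            bundle.genes, bundle.tes, bundle.genome, bundle.replicate_peaks,
            bundle.tracks, bundle.methylation, bundle.expression,
            mask=bundle.mask, cns=bundle.cns, seed=seed,
        )


@pytest.fixture(scope="session")
def clean_result(clean_bundle):
    return _run(clean_bundle)


@pytest.fixture(scope="session")
def noisy_result(noisy_bundle):
    return _run(noisy_bundle)
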