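import dataclasses

import numpy as np
import pytest

import sirtdose as sd


@pytest.fixture(scope="session")
def default_bundle():
    """Default 64^3 phantom (SPECT-like spacing), shared across tests."""
    return sd.generate(sd.PhantomSpec(rng_seed=1))


@pytest.fixture(scope="session")
def small_bundle():
    """Compact 32^3 phantom for cheap per-test work."""
    return sd.generate(sd.small_spec(seed=2))


@pytest.fixture(scope="session")
def noiseless_counts(default_bundle):
    """Unblurred, noise-free expectation image on the default phantom."""
    b = default_bundle
    return sd.simulate_spect(
        b.activity_truth.data, b.spacing, 0.0, b.spec.total_counts, poisson=False
    )


def table_from(bundle, counts, margin_mm=0.0, disposition="excluded_partition"):
    return sd.partition_counts(
        counts,
        bundle.territory_truth.labels,
        [t.data for t in bundle.tumor_masks],
        bundle.lung_mask.data,
        sd.MarginPolicy(margin_mm, disposition),
        spacing=bundle.spacing,
    )


@pytest.fixture(scope="session")
def noiseless_table(default_bundle, noiseless_counts):
    return table_from(default_bundle, noiseless_counts)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def replace_spec(spec, **kw):
    return dataclasses.replace(spec, **kw)
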