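import numpy as np
import pytest

import coremetab as cm
from coremetab.pathways import PATHWAY_NAMES, PathwayProfile


@pytest.fixture(scope="session")
def template():
    return cm.load_packaged_template()


@pytest.fixture(scope="session")
def models(template):
    """All packaged organism-like fixture models, built once."""
    return {
        name: cm.build_core_model(template, cm.load_fixture(name))
        for name in cm.FIXTURE_NAMES
    }


@pytest.fixture(scope="session")
def ecoli(models):
    return models["ecoli_like"]


@pytest.fixture()
def closed_media():
    """A medium with every exchange shut: uptake and secretion zero."""
    from coremetab.template import Media

    class _Closed(Media):
        def bounds_for(self, compound_id):
            return (0.0, 0.0)

    return _Closed(name="closed", exchange_bounds={"x": (1.0, 0.0)},
                   carbon_source="x", electron_acceptor=None)


def make_profile(genome_id, vector, model_size=100, respiration="none",
                 seq_key=None, quality=None):
    """Build a PathwayProfile from a 12-long 0/1 vector."""
    presence = {name: bool(v) for name, v in zip(PATHWAY_NAMES, vector)}
    return PathwayProfile(
        genome_id=genome_id, presence=presence, respiration=respiration,
        model_size=model_size, seq_key=seq_key, quality=quality,
    )


def random_profiles(rng, n, p=0.5, model_sizes=None):
    vectors = rng.random((n, len(PATHWAY_NAMES))) < p
    sizes = model_sizes if model_sizes is not None else np.full(n, 100)
    return [
        make_profile(f"g{i:04d}", vectors[i], model_size=int(sizes[i]))
        for i in range(n)
    ]
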