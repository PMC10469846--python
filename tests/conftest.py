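import logging

import pytest

from metaprotbench import dbforge, synthio

# builder warnings about genome-less taxa are expected on synthetic fixtures
logging.getLogger("metaprotbench").setLevel(logging.ERROR)


def make_record(rid, seq, species="Species_X", genus="Genus_X", strain="st1",
                category="bacterial", source="public"):
    return dbforge.ProteinRecord(
        record_id=rid, sequence=seq, species=species, strain=strain,
        genus=genus, category=category, source=source,
    )


@pytest.fixture(scope="session")
def tiny_config():
    return synthio.CommunityConfig(seed=5, n_species=8, n_samples=3, n_spectra=150)


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    return synthio.generate_study(tiny_config)


@pytest.fixture(scope="session")
def tiny_core(tiny_study):
    return dbforge.core_set(tiny_study.host)
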