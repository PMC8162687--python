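import pytest

from platekit import PlateGeometry, attach_results, read_layout
from platekit.fixtures import (
    make_drc_fixture,
    make_infection_fixture,
    make_screening_fixture,
)


@pytest.fixture(scope="session")
def geo96() -> PlateGeometry:
    return PlateGeometry.from_format(96)


@pytest.fixture(scope="session")
def screening_files(tmp_path_factory):
    return make_screening_fixture(
        tmp_path_factory.mktemp("screening"), n_plates=3, seed=1
    )


@pytest.fixture(scope="session")
def drc_files(tmp_path_factory):
    return make_drc_fixture(tmp_path_factory.mktemp("drc"), seed=1)


@pytest.fixture(scope="session")
def infection_files(tmp_path_factory):
    return make_infection_fixture(tmp_path_factory.mktemp("infection"), seed=1)


@pytest.fixture(scope="session")
def screening(screening_files):
    return read_layout(screening_files.layout), attach_results(
        screening_files.results
    )


@pytest.fixture(scope="session")
def drc(drc_files):
    return read_layout(drc_files.layout), attach_results(drc_files.results)


@pytest.fixture(scope="session")
def infection(infection_files):
    return read_layout(infection_files.layout), attach_results(
        infection_files.results
    )
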