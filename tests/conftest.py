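import pytest

from tephrisim import available_species, load_species, synth_weather


@pytest.fixture(scope="session", params=available_species())
def species(request):
    return load_species(request.param)


@pytest.fixture(scope="session")
def medfly():
    return load_species("medfly")


@pytest.fixture(scope="session")
def melon_fly():
    return load_species("melon_fly")


@pytest.fixture(scope="session")
def oriental_fly():
    return load_species("oriental_fly")


@pytest.fixture(scope="session")
def mexfly():
    return load_species("mexfly")


@pytest.fixture(scope="session")
def tropical_series():
    return synth_weather("tropical", years=3, seed=11)


@pytest.fixture
def weather_csv(tmp_path):
    """Write a small valid weather CSV and return its path."""
    series = synth_weather("tropical", years=1, seed=3)
    path = tmp_path / "cell.csv"
    series.to_csv(path)
    return path
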