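import pytest

from palaeofeed.synthetic_data import WorldConfig, generate_world, write_world


@pytest.fixture(scope="session")
def world():
    """Default synthetic world, fixed seed, shared across the session."""
    return generate_world(WorldConfig(seed=11))


@pytest.fixture(scope="session")
def world_dir(world, tmp_path_factory):
    """The same world written through the public I/O path."""
    out = tmp_path_factory.mktemp("world")
    write_world(world, out)
    return out
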