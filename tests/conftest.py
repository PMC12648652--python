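
import pytest


from focuslib.blocks import load_blocks
from focuslib.enumeration import enumerate_library
from focuslib.fixtures import FixtureSpec, gen_blocks


@pytest.fixture(scope="session")
def toy_blocks(tmp_path_factory):
    """3 amines x 4 sulfonyl chlorides with pairwise-distinct products."""
    out = tmp_path_factory.mktemp("blocks")
    amines_path, sulfonyls_path = gen_blocks(FixtureSpec(3, 4), out)
    return load_blocks(amines_path), load_blocks(sulfonyls_path)


@pytest.fixture(scope="session")
def toy_library(toy_blocks):
    amines, sulfonyls = toy_blocks
    return enumerate_library(amines, sulfonyls)
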