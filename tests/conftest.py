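import pytest

from dnacipher import io_synth


@pytest.fixture(scope="session")
def table2_book():
    """The published 50-entry table extended to a full 256-word codebook."""
    return io_synth.table2_codebook()


@pytest.fixture(scope="session")
def gen_book():
    """A fully generated certified codebook (seed 0)."""
    return io_synth.generated_codebook(0)


@pytest.fixture(scope="session")
def key():
    return bytes(range(16))
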