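import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from reference_data import BASE_SEQ, PROBE_SEQ  # noqa: E402

from usm import encode


@pytest.fixture(scope="session")
def base_enc():
    return encode(BASE_SEQ)


@pytest.fixture(scope="session")
def probe_enc(base_enc):
    return encode(PROBE_SEQ, base_enc.assignment)
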