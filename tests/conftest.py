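"""Shared fixtures.

The full desk-scale demonstration run is expensive (several minutes), so it
is executed once per session and shared by every test that needs trained
models or study results.
"""

import pytest

from motionseg.pipeline import run_demo


@pytest.fixture(scope="session")
def demo_result(tmp_path_factory):
    out = tmp_path_factory.mktemp("demo")
    return run_demo(out, seed=7)
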