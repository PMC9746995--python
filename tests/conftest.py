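import pytest

from ampseq.panel import FilterConfig
from ampseq.simreads import demo_panel, demo_sheet


@pytest.fixture(scope="session")
def panel():
    return demo_panel()


@pytest.fixture(scope="session")
def sheet_1pool():
    return demo_sheet(samples_per_pool=20, n_pools=1)


@pytest.fixture(scope="session")
def sheet_2pools():
    return demo_sheet(samples_per_pool=20, n_pools=2)


@pytest.fixture()
def cfg():
    return FilterConfig()
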