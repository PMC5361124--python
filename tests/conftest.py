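import pytest

import mtpop


@pytest.fixture(scope="session")
def panel():
    return mtpop.load_xibe_panel()


@pytest.fixture(scope="session")
def xibe(panel):
    return mtpop.load_xibe_sample(panel)


@pytest.fixture(scope="session")
def fst_table():
    return mtpop.parse_fst_pvalue_table(mtpop.xibe_fst_table_text())
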