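import numpy as np
import pytest

from lipidlens.cohort import default_panel
from lipidlens.nomenclature import BiophysRuleTable, annotate_table


@pytest.fixture(scope="session")
def panel() -> list[str]:
    return default_panel()


@pytest.fixture(scope="session")
def rules() -> BiophysRuleTable:
    return BiophysRuleTable.default()


@pytest.fixture(scope="session")
def panel_annotation(panel, rules):
    return annotate_table(panel, rules)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
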