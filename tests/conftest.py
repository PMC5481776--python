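import numpy as np
import pandas as pd
import pytest

from scgpcr.datatypes import CtMatrix, GenePanel
from scgpcr.simulate import default_panel


@pytest.fixture(scope="session")
def panel() -> GenePanel:
    return default_panel()


@pytest.fixture
def tiny_panel() -> GenePanel:
    """Minimal hand-built panel: 3 GPCRs (one non-spanning), markers, QC."""
    rows = [
        ("GprA", "gpcr", "none", True),
        ("GprB", "gpcr", "none", True),
        ("GprC", "gpcr", "none", False),
        ("Cdh5", "identity", "target_ec", True),
        ("Myh11", "identity", "target_smc", True),
        ("Ptprc", "identity", "lineage_exclusion", True),
        ("Cdh1", "identity", "lineage_exclusion", True),
        ("Icam1", "function", "none", True),
        ("Gapdh", "reference", "quality_control", True),
        ("Hprt", "reference", "quality_control", True),
    ]
    tab = pd.DataFrame(rows, columns=["gene", "category", "marker_role",
                                      "intron_spanning"]).set_index("gene")
    tab.index.name = None
    return GenePanel(tab)


@pytest.fixture
def tiny_ct(tiny_panel) -> CtMatrix:
    """Four hand-crafted cells: pure SMC, pure EC, leukocyte, QC failure."""
    na = np.nan
    data = {
        #          GprA GprB GprC Cdh5 Myh11 Ptprc Cdh1 Icam1 Gapdh Hprt
        "smc1":   [20.0, na,  18., na,  15.0, na,   na,  21.0, 13.0, 14.0],
        "ec1":    [na,  19.0, na,  14.5, na,  na,   na,  na,   12.5, 13.5],
        "leuko1": [na,  na,   na,  na,  na,   16.0, na,  20.0, 13.0, 14.0],
        "bad1":   [22.0, na,  na,  15.0, na,  na,   na,  na,   na,   14.0],
    }
    genes = list(tiny_panel.genes)
    ct = pd.DataFrame.from_dict(data, orient="index", columns=genes)
    meta = pd.DataFrame({"group": ["s"] * 4}, index=ct.index)
    return CtMatrix(ct, meta)
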