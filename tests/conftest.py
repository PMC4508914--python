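import pytest

import leukotype as lt

# Published per-subtype one-vs-rest counts for the 160-patient clinical
# cohort, with the percentages the printed report derives from them.
TABLE1_COUNTS = {
    "BCR-ABL1": (16, 2, 141, 1),
    "TCF3-PBX1": (13, 0, 145, 2),
    "MLL rearrangement": (4, 1, 154, 1),
    "T-ALL": (20, 8, 132, 0),
    "ETV6-RUNX1": (47, 0, 106, 7),
    "hyperdiploid >50": (36, 4, 119, 1),
    "Others": (6, 3, 145, 6),
}

TABLE1_METRICS = {
    "BCR-ABL1": (98.13, 94.12, 98.60),
    "TCF3-PBX1": (98.75, 86.67, 100.00),
    "MLL rearrangement": (98.75, 80.00, 99.35),
    "T-ALL": (95.00, 100.00, 94.29),
    "ETV6-RUNX1": (95.63, 87.04, 100.00),
    "hyperdiploid >50": (96.88, 97.30, 96.75),
    "Others": (94.38, 50.00, 97.97),
}


@pytest.fixture(scope="session")
def panel_pair():
    """(PanelDefinition, MarkerPanel) of the bundled synthetic panel."""
    return lt.default_panel()


@pytest.fixture(scope="session")
def panel(panel_pair):
    return panel_pair[1]


@pytest.fixture(scope="session")
def panel_def(panel_pair):
    return panel_pair[0]


@pytest.fixture(scope="session")
def small_cfg():
    """A small, fast cohort: 8 samples per subtype."""
    return lt.SimulationConfig(
        n_per_subtype={s: 8 for s in lt.SUBTYPES}, seed=123
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return lt.simulate_cohort(small_cfg, platform="microarray")
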