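import numpy as np
import pandas as pd
import pytest

from congenicqtl import CongenicPanel, MarkerMap, default_config, prepare_phenotypes, simulate_panel


@pytest.fixture
def three_marker_map() -> MarkerMap:
    return MarkerMap(
        ("mA", "mB", "mC"),
        ("chr9", "chr9", "chr9"),
        (10_000_000, 20_000_000, 30_000_000),
    )


def make_panel(markers: MarkerMap, rows: dict[str, list[str]], strains: dict[str, str],
               depot=None, bw=None) -> CongenicPanel:
    """Hand-build a small panel from genotype rows."""
    mice = list(rows)
    geno = pd.DataFrame.from_dict(rows, orient="index", columns=list(markers.marker_ids))
    geno.index.name = "mouse_id"
    rng = np.random.default_rng(0)
    pheno = pd.DataFrame(
        {
            "strain": [strains[m] for m in mice],
            "depot_g": depot if depot is not None else rng.uniform(0.3, 0.8, len(mice)),
            "bw_g": bw if bw is not None else rng.normal(31, 3, len(mice)),
            "age_d": 180,
            "excluded": False,
            "reason": "",
        },
        index=pd.Index(mice, name="mouse_id"),
    )
    return CongenicPanel(markers, geno, pheno)


@pytest.fixture(scope="session")
def prepared_default_panel():
    """One prepared instance of the default 12-strain, 4-QTL panel."""
    panel, truth = simulate_panel(default_config(seed=11))
    prepared, report = prepare_phenotypes(panel)
    return prepared, truth, report
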