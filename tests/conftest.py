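import numpy as np
import pandas as pd
import pytest

from ctxlife.simulate import (
    LogSdModel,
    PanelDesign,
    TrueComponents,
    simulate_lifespan_panel,
)

NO_MISSING = {18: 0.0, 25: 0.0, 28: 0.0}


@pytest.fixture(scope="session")
def small_panel() -> pd.DataFrame:
    """Balanced 20-line panel, all six components positive, no truncation."""
    design = PanelDesign(
        n_lines=20, vials_per_line_per_temp=6,
        missing_line_fraction_per_temp=NO_MISSING,
    )
    comp = TrueComponents(logsd_model=LogSdModel(0, 0, 0))
    return simulate_lifespan_panel(design, comp, seed=42)


@pytest.fixture(scope="session")
def oneway_frame() -> pd.DataFrame:
    """Balanced one-way layout (line + error) for closed-form oracles."""
    rng = np.random.default_rng(7)
    L, n = 30, 8
    a = np.repeat(rng.normal(0, 3, L), n)
    return pd.DataFrame(
        {
            "line": np.repeat([f"L{i:02d}" for i in range(L)], n),
            "y": a + rng.normal(0, 2, L * n),
        }
    )


@pytest.fixture()
def toy_genes() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": ["g1", "g2", "g3", "g4"],
            "chrom": ["2L", "2L", "2R", "3L"],
            "start": [1000, 8000, 500, 2000],
            "end": [2000, 9500, 1500, 2000],
        }
    ).assign(length=lambda d: d.end - d.start + 1)
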