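import pandas as pd
import pytest

from oncoint import synthetic_data as sd


@pytest.fixture(scope="session")
def default_config() -> sd.SimulationConfig:
    return sd.SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def tap_sim(default_config):
    """(evidence, manifest, truth) for the default TAP simulation."""
    return sd.simulate_tap(default_config)


@pytest.fixture()
def tiny_evidence() -> pd.DataFrame:
    """Two-protein toy: P1 has specific peptide a, P2 only shares b."""
    return pd.DataFrame(
        [
            {"run_id": "r1", "peptide_id": "a", "protein_ids": "P1", "spectral_count": 3},
            {"run_id": "r1", "peptide_id": "b", "protein_ids": "P1;P2", "spectral_count": 2},
        ]
    )


@pytest.fixture()
def small_screen() -> "sd.ViabilityScreen":
    """Two lines, two genes, triplicates, noiseless planted means."""
    from oncoint.rnai_screen import ViabilityScreen

    rows = []
    planted = {("L1", "g_hit"): 0.4, ("L1", "g_null"): 1.0,
               ("L2", "g_hit"): 0.42, ("L2", "g_null"): 0.98}
    deltas = (-0.02, 0.0, 0.02)
    for line in ("L1", "L2"):
        for rep, d in enumerate(deltas, start=1):
            rows.append({"cell_line": line, "gene": "NTC", "replicate": rep,
                         "readout": 2000.0 * (1 + d), "is_control": True})
        for gene in ("g_hit", "g_null"):
            for rep, d in enumerate(deltas, start=1):
                rows.append({"cell_line": line, "gene": gene, "replicate": rep,
                             "readout": 2000.0 * (planted[(line, gene)] + d),
                             "is_control": False})
    return ViabilityScreen(data=pd.DataFrame(rows))
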