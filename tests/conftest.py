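import numpy as np
import pytest

from mipd.decode import read_sample_sheet, tally
from mipd.library_design import LibraryDesign, default_design, load_design
from mipd.pipeline import simulate_stage

# Scaled-down screen: keeps the planted-to-background ratio of the default
# study conditions (~1.5%) so competition for reads behaves comparably.
SMALL_SIM = {
    "n_background": 800,
    "lognormal_sigma": 1.0,
    "beta": 50.0,
    "epsilon": 0.0,
    "families": [
        {"family_id": "MDM2.C1", "consensus": "HWFSDWDVDRSL", "kd_nM": 5.0,
         "n_members": 5, "substitution_rate": 0.1},
        {"family_id": "MDM2.C2", "consensus": "WNNSFDWSTQSN", "kd_nM": 50.0,
         "n_members": 5, "substitution_rate": 0.1},
        {"family_id": "MDM2.C3", "consensus": "WVESQFRLLISQ", "kd_nM": 500.0,
         "n_members": 5, "substitution_rate": 0.1},
    ],
    "layout": {"reads_per_well": 6000},
}


@pytest.fixture(scope="session")
def design() -> LibraryDesign:
    return default_design()


@pytest.fixture(scope="session")
def toy_design() -> LibraryDesign:
    """Three positions (variable sizes 2 and 3, one fixed), tiny flanks."""
    return load_design({
        "name": "toy",
        "alphabet": "AWV",
        "codon_map": {"A": "GCT", "W": "TGG", "V": "GTT"},
        "positions": [{"variable": ["A", "W"]}, {"fixed": "W"},
                      {"variable": ["A", "W", "V"]}],
        "flank5": "ACGTAC",
        "flank3": "TTGGCC",
        "spike_in_dna": "AAAGGTAAA",
        "spike_in_label": "SPIKE",
    })


@pytest.fixture(scope="session")
def small_screen(design, tmp_path_factory):
    """A small noiseless simulated screen plus its decoded count matrix."""
    outdir = tmp_path_factory.mktemp("small_screen")
    screen = simulate_stage(SMALL_SIM, design, outdir, seed=11)
    sheet = read_sample_sheet(screen.sample_sheet)
    counts = tally(sheet, design)
    return screen, sheet, counts


@pytest.fixture(scope="session")
def noisy_screen(design, tmp_path_factory):
    """Small screen with substitution errors, reverse-complemented reads and
    low-quality tails, to exercise every decode path."""
    cfg = dict(SMALL_SIM)
    cfg.update(epsilon=0.01, rc_fraction=0.3, low_quality_tail_fraction=0.2,
               n_background=200, layout={"reads_per_well": 2000})
    outdir = tmp_path_factory.mktemp("noisy_screen")
    screen = simulate_stage(cfg, design, outdir, seed=12)
    sheet = read_sample_sheet(screen.sample_sheet)
    counts = tally(sheet, design)
    return screen, sheet, counts


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
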