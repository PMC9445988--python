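"""Shared setup for the numbered analysis scripts.

Each script is self-contained: it regenerates the study from the fixed
root seed, runs one stage, prints what it found and writes its tables
under results/.  ROOT_SEED fixes the whole analysis.
"""

from pathlib import Path

from tissuemod.config import PipelineConfig
from tissuemod.simulate import SimulationConfig, simulate_gwas_fixture, simulate_study

ROOT_SEED = 20260930
RESULTS = Path(__file__).resolve().parent.parent / "results"

#: Soft power used for the bundle networks (see docs/methods.md).
BUNDLE_POWER = 8

CONFIG = PipelineConfig(seed=ROOT_SEED, power_override=BUNDLE_POWER)

DISEASES = ("MDD", "BP")


def disease_study(disease: str):
    """Datasets, ground truth and GWAS fixture for one simulated disease."""
    seed = CONFIG.stage_seed(f"bundle_{disease}")
    datasets, truth = simulate_study(SimulationConfig(seed=seed))
    variants, bed = simulate_gwas_fixture(
        truth, window_hits=10, decoys=5,
        seed=CONFIG.stage_seed(f"gwas_{disease}"))
    return datasets, truth, variants, bed


def outdir(name: str) -> Path:
    path = RESULTS / name
    path.mkdir(parents=True, exist_ok=True)
    return path
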