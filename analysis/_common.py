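"""Shared plumbing for the numbered analysis drivers."""

from pathlib import Path

from pouchchar.pipeline import StudyConfig, simulate_study_inputs

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
INPUT_DIR = ROOT / "scratch" / "study_inputs"
SEED = 1


def ensure_inputs(seed: int = SEED) -> StudyConfig:
    """(Re)generate the synthetic study inputs; deterministic under `seed`."""
    RESULTS.mkdir(exist_ok=True)
    return simulate_study_inputs(INPUT_DIR, seed=seed)
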