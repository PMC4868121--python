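"""Shared study configuration for the numbered analysis drivers.

Every driver regenerates the same seeded cohort, so each one can be run
independently while all of them describe the same synthetic study.
"""

from pathlib import Path

from esescan import SyntheticConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
STUDY_SEED = 20160331

STUDY_CONFIG = SyntheticConfig(n_genes=150, seed=STUDY_SEED)


def results_dir(name: str) -> Path:
    out = RESULTS / name
    out.mkdir(parents=True, exist_ok=True)
    return out
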