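"""Shared configuration for the analysis drivers.

One desk-scale run configuration (3 partners x 2,000 training molecules,
20,000-molecule pool, 500+500 federated set) and one run directory; every
driver re-executes the deterministic pipeline up to the stage it reports
on, so the scripts can be run independently and in any order.
"""

from pathlib import Path

from fluidsim.synthetic_data import WorldConfig
from fluidsim.workflow import RunConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
RUN_DIR = RESULTS / "desk_run"
SEED = 0


def desk_config(seed: int = SEED) -> RunConfig:
    return RunConfig(
        world=WorldConfig(n_pool_eval=2000),
        student_variants=("T", "HI", "HF", "PI", "RI", "F", "RF"),
        seed=seed,
    )
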