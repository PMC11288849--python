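"""Seed protocol: one master seed, independent named child streams per stage.

Each pipeline stage (population, effects, trials, splits, ...) derives its
generator from the master seed plus the stage name, so stages can be re-run
in isolation and the whole pipeline is reproducible bitwise.
"""

from __future__ import annotations

import numpy as np

__all__ = ["stage_rng", "stage_seed_sequence"]


def stage_seed_sequence(master_seed: int, stage: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(master_seed), *stage.encode("utf-8")])


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed_sequence(master_seed, stage))
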