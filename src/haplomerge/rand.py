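"""Seed plumbing: one independent stream per pipeline stage.

Stage streams are derived from the master seed by hashing the stage name, so
adding a stage never perturbs the draws of earlier stages.
"""
from __future__ import annotations

import hashlib

import numpy as np


def stage_seed(master_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(master_seed, stage))
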