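"""Stratified permuted-block randomization to the two dose arms.

Participants are assigned 1:1 to the 15- vs 30-minute dose within strata
defined by four binary factors: site, sex assigned at birth, prior
mindfulness experience (3+ sessions), and current treatment.  Within each
stratum, assignments follow seeded permuted blocks (default block size 2),
so arm counts per stratum never differ by more than the block tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

ARMS = ("min15", "min30")
STRATUM_FIELDS = ("site", "sex", "prior_mindfulness", "current_treatment")


@dataclass(frozen=True)
class Strata:
    site: str                     # "CU" | "NEU"
    sex: str
    prior_mindfulness: bool       # >= 3 prior mindfulness sessions
    current_treatment: bool

    def key(self) -> Tuple:
        return (self.site, self.sex, self.prior_mindfulness,
                self.current_treatment)


class StratifiedRandomizer:
    """Seeded permuted-block allocator, one block stream per stratum."""

    def __init__(self, seed: int = 0, block_size: int = 2):
        if block_size < 2 or block_size % len(ARMS):
            raise ValueError("block size must be a positive multiple of 2")
        self.block_size = block_size
        self._rng = np.random.default_rng(seed)
        self._pending: Dict[Tuple, List[str]] = {}
        self.log: List[Dict] = []

    def assign(self, strata: Strata) -> str:
        key = strata.key()
        if any(v is None for v in key):
            raise ValueError("strata fields must be complete")
        queue = self._pending.setdefault(key, [])
        if not queue:
            block = list(ARMS) * (self.block_size // len(ARMS))
            self._rng.shuffle(block)
            queue.extend(block)
        arm = queue.pop(0)
        self.log.append({**dict(zip(STRATUM_FIELDS, key)), "arm": arm})
        return arm


def randomize(participants: Sequence[Strata], seed: int = 0,
              block_size: int = 2) -> List[str]:
    """Assign a sequence of participants; returns the arm per participant."""
    r = StratifiedRandomizer(seed=seed, block_size=block_size)
    return [r.assign(p) for p in participants]
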