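"""Counter-based seed derivation.

Every source of randomness in an experiment (per-patient simulation, model
init, shuffling, per-epoch augmentation substreams, per-fold fine-tuning)
derives its seed from one master seed plus integer keys, so a whole run is
reproducible from a single integer and independent substreams never collide.
"""

from __future__ import annotations

import numpy as np


def substream(seed: int, *keys: int) -> int:
    """Derive a deterministic child seed (< 2**31) from a seed and keys."""
    ss = np.random.SeedSequence([int(seed)] + [int(k) for k in keys])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))
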