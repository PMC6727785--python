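"""Shared numerics: FDR adjustment and reproducible per-stage seeds."""

from __future__ import annotations

import hashlib

import numpy as np
from statsmodels.stats.multitest import multipletests


def bh_q(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (two-sided p in, q out)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def derive_seed(seed: int, stage: str) -> int:
    """Stable sub-seed for a named stage (independent of hash randomization)."""
    digest = hashlib.blake2s(f"{seed}:{stage}".encode("utf-8"), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)
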