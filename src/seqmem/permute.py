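"""Seeded permutation engine shared by every chance-level calibration.

Every stochastic operation in the package takes an explicit integer seed; the
streams produced here are bit-reproducible for a given (seed, n_perm, scheme).

Schemes
-------
label-shuffle        permutation of item indices (shuffles labels against data)
time-shuffle         permutation of time-bin indices (shuffles the time factor
                     of a rate map)
cycle-order-shuffle  permutation of theta-cycle indices within a trial
downsample           subsample of ``size`` items without replacement
"""

from __future__ import annotations

from collections.abc import Iterator

import numpy as np

SCHEMES = ("label-shuffle", "time-shuffle", "cycle-order-shuffle", "downsample")


def permutation_stream(
    n_items: int,
    n_perm: int,
    seed: int,
    scheme: str = "label-shuffle",
    size: int | None = None,
) -> Iterator[np.ndarray]:
    """Yield ``n_perm`` index arrays drawn reproducibly from ``seed``."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if scheme == "downsample":
        if size is None:
            raise ValueError("downsample scheme requires size")
        if size > n_items:
            raise ValueError(f"downsample size {size} exceeds population {n_items}")
    rng = np.random.default_rng(seed)
    for _ in range(n_perm):
        if scheme == "downsample":
            yield rng.choice(n_items, size=size, replace=False)
        else:
            yield rng.permutation(n_items)


def derive_seed(seed: int, *salt: int) -> int:
    """Deterministically derive an independent child seed below 2**31."""
    ss = np.random.SeedSequence([int(seed), *[int(s) for s in salt]])
    return int(ss.generate_state(1)[0] % (2**31))
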