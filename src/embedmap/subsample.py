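"""Subset selection for building the reference embedding.

Every-nth selection is the workhorse scheme for raster data (it preserves
spatial coverage); a seeded uniform random subset is provided as an
alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SubsampleResult", "every_nth", "random_subset"]


@dataclass
class SubsampleResult:
    indices: np.ndarray
    n_total: int
    scheme: str
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if len(self.indices) and (
            self.indices.min() < 0
            or self.indices.max() >= self.n_total
            or np.any(np.diff(self.indices) <= 0)
        ):
            raise ValueError("indices must be strictly increasing and in range")

    @property
    def complement(self) -> np.ndarray:
        mask = np.ones(self.n_total, dtype=bool)
        mask[self.indices] = False
        return np.flatnonzero(mask)

    def __len__(self) -> int:
        return len(self.indices)


def every_nth(n_total: int, n: int) -> SubsampleResult:
    """Select indices 0, n, 2n, ... below ``n_total`` (count = ceil(n_total/n))."""
    if n < 1:
        raise ValueError("step n must be >= 1")
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    return SubsampleResult(
        indices=np.arange(0, n_total, n),
        n_total=n_total,
        scheme="every_nth",
        parameters={"n": n},
    )


def random_subset(n_total: int, k: int, seed: int) -> SubsampleResult:
    """Seeded uniform subset of k unique indices (returned sorted)."""
    if not 1 <= k <= n_total:
        raise ValueError("require 1 <= k <= n_total")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n_total, size=k, replace=False))
    return SubsampleResult(
        indices=idx, n_total=n_total, scheme="random", parameters={"k": k, "seed": seed}
    )
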