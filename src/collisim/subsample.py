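"""Seeded random subsampling of a marker family over a size grid.

Database growth is simulated by drawing random subsets of a family's
records at increasing sizes (e.g. 10,000 to 200,000 in steps of 10,000
for large references, or 1,000 to 5,000 in steps of 1,000 for a single
deeply sampled genus), with bootstrap-style replication (typically 100
replicates) to estimate variability.

Draws are uniform without replacement over *record instances*, not
unique sequences, so duplicated sequences in a non-deduplicated source
can co-occur in a subset, as in the real databases.  Each subset is
reproducible from ``(seed, family, size, replicate)`` alone: the child
seed is a SHA-256 hash of that tuple, which makes subsets independent of
evaluation order and safe to compute in parallel.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["SubsampleSpec", "Subset", "subsample", "child_seed", "write_manifest"]


@dataclass(frozen=True)
class SubsampleSpec:
    """Size grid and replication for one subsampling experiment.

    With ``nested=True`` each replicate draws a single permutation of the
    family and the subset at each size is a prefix of it, so subsets grow
    monotonically within a replicate (lower-variance growth curves, at
    the cost of dependence across sizes).  The default draws each size
    independently.
    """

    sizes: tuple[int, ...]
    n_replicates: int = 100
    seed: int = 0
    nested: bool = False

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.sizes)
        object.__setattr__(self, "sizes", sizes)
        if not sizes or any(s < 1 for s in sizes):
            raise ValueError("sizes must be positive")
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("sizes must be strictly increasing")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class Subset:
    family: str
    size: int
    replicate: int
    record_ids: tuple[str, ...]


def child_seed(master_seed: int, family: str, size: int, replicate: int) -> int:
    """Platform-stable child seed: SHA-256 of the identifying tuple,
    reduced to a 31-bit integer."""
    digest = hashlib.sha256(f"{master_seed}|{family}|{size}|{replicate}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % (2**31)


def subsample(
    record_ids: Sequence[str],
    spec: SubsampleSpec,
    family: str = "",
) -> Iterator[Subset]:
    """Yield subsets for every (size, replicate) pair of the spec.

    Sizes exceeding the family's record count are skipped with a warning.
    Record ids within a subset are emitted in source order.
    """
    ids = np.asarray(record_ids, dtype=object)
    n = ids.size
    for size in spec.sizes:
        if size > n:
            logger.warning(
                "family %r: subset size %d exceeds population %d; skipped", family, size, n
            )
            continue
        for rep in range(spec.n_replicates):
            if spec.nested:
                rng = np.random.default_rng(child_seed(spec.seed, family, -1, rep))
                idx = rng.permutation(n)[:size]
            else:
                rng = np.random.default_rng(child_seed(spec.seed, family, size, rep))
                idx = rng.choice(n, size=size, replace=False)
            idx.sort()
            yield Subset(family=family, size=size, replicate=rep, record_ids=tuple(ids[idx]))


def write_manifest(subsets: Sequence[Subset], path: str | Path) -> None:
    rows = [
        {"family": s.family, "size": s.size, "replicate": s.replicate, "record_id": rid}
        for s in subsets
        for rid in s.record_ids
    ]
    pd.DataFrame(rows, columns=["family", "size", "replicate", "record_id"]).to_csv(
        path, sep="\t", index=False
    )
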