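"""Pooled eco-tilling arithmetic.

Pooling DNA of K individuals before multiplex amplicon sequencing divides
the PCR and library cost by the pool count while diluting each allele: one
heterozygous diploid carrier in a pool of 10 plants contributes 1 of 20
alleles, i.e. an expected 5% relative haplotype frequency.  A 2D layout
places N plants on a grid and pools each row and each column, so every
plant sits in exactly one X pool and one Y pool; a variant seen in one X
and one Y pool localises its carrier to the single intersecting plant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence


@dataclass
class PoolLayout:
    """Assignment of plants to 1D or 2D pools.

    ``pools`` maps pool_id -> (axis, member plant ids); ``plant_coords``
    maps each plant to the pools containing it (one pool in 1D, an X and a
    Y pool in 2D).
    """

    n_plants: int
    pool_size: int
    dimension: int
    pools: dict[str, tuple[str, tuple[int, ...]]]
    plant_coords: dict[int, tuple[str, ...]]

    @property
    def n_pools(self) -> int:
        return len(self.pools)

    def validate(self) -> None:
        per_plant = {p: 0 for p in range(1, self.n_plants + 1)}
        for _, (_, members) in self.pools.items():
            if len(members) > self.pool_size:
                raise ValueError("pool exceeds pool_size")
            for m in members:
                per_plant[m] += 1
        want = 1 if self.dimension == 1 else 2
        if any(c != want for c in per_plant.values()):
            raise ValueError(f"every plant must be in exactly {want} pool(s)")


def expected_pool_frequency(
    n_het_carriers: int,
    n_hom_carriers: int,
    pool_size: int,
    ploidy: int = 2,
) -> float:
    """Expected relative frequency of a carrier haplotype in one pool.

    Each heterozygous carrier contributes 1 allele and each homozygous
    carrier ``ploidy`` alleles out of ``pool_size * ploidy`` total.
    """
    if ploidy < 1 or pool_size < 1:
        raise ValueError("pool_size and ploidy must be >= 1")
    if n_het_carriers < 0 or n_hom_carriers < 0:
        raise ValueError("carrier counts must be non-negative")
    if n_het_carriers + n_hom_carriers > pool_size:
        raise ValueError("more carriers than plants in the pool")
    return (n_het_carriers + n_hom_carriers * ploidy) / (pool_size * ploidy)


def layout_1d(n_plants: int, pool_size: int) -> PoolLayout:
    """ceil(n/pool_size) pools; plants assigned in order."""
    if n_plants < 1 or pool_size < 1:
        raise ValueError("n_plants and pool_size must be >= 1")
    pools = {}
    coords: dict[int, tuple[str, ...]] = {}
    n_pools = math.ceil(n_plants / pool_size)
    for i in range(n_pools):
        members = tuple(
            range(i * pool_size + 1, min((i + 1) * pool_size, n_plants) + 1)
        )
        pid = f"P{i + 1}"
        pools[pid] = ("none", members)
        for m in members:
            coords[m] = (pid,)
    return PoolLayout(n_plants, pool_size, 1, pools, coords)


def layout_2d(n_plants: int, pool_size: int) -> PoolLayout:
    """Row-major grid of side pool_size: one pool per occupied row (X) and
    per occupied column (Y); each plant lands in exactly two pools."""
    if n_plants < 1 or pool_size < 1:
        raise ValueError("n_plants and pool_size must be >= 1")
    if n_plants > pool_size**2:
        raise ValueError(
            f"{n_plants} plants exceed a {pool_size}x{pool_size} grid; "
            "increase pool_size (3D pooling is out of scope)"
        )
    rows: dict[int, list[int]] = {}
    cols: dict[int, list[int]] = {}
    for plant in range(1, n_plants + 1):
        r, c = divmod(plant - 1, pool_size)
        rows.setdefault(r, []).append(plant)
        cols.setdefault(c, []).append(plant)
    pools = {}
    coords: dict[int, tuple[str, ...]] = {p: () for p in range(1, n_plants + 1)}
    for r in sorted(rows):
        pid = f"X{r + 1}"
        pools[pid] = ("X", tuple(rows[r]))
        for m in rows[r]:
            coords[m] = coords[m] + (pid,)
    for c in sorted(cols):
        pid = f"Y{c + 1}"
        pools[pid] = ("Y", tuple(cols[c]))
        for m in cols[c]:
            coords[m] = coords[m] + (pid,)
    return PoolLayout(n_plants, pool_size, 2, pools, coords)


def pcr_savings(layout: PoolLayout) -> float:
    """Fold reduction in PCR count: reactions on individuals / on pools."""
    return layout.n_plants / layout.n_pools


def locate_carriers(
    positive_pools: Sequence[str], layout: PoolLayout
) -> tuple[set[int], bool]:
    """Candidate carriers = plants at intersections of every positive X pool
    with every positive Y pool.  ``unambiguous`` is True iff exactly one X
    and one Y pool are positive (single plant identified without a second
    screening round)."""
    if layout.dimension != 2:
        raise ValueError("carrier localisation requires a 2D layout")
    xs, ys = [], []
    for pid in positive_pools:
        if pid not in layout.pools:
            raise ValueError(f"unknown pool id {pid!r}")
        axis, members = layout.pools[pid]
        (xs if axis == "X" else ys).append(set(members))
    candidates: set[int] = set()
    for x in xs:
        for y in ys:
            candidates |= x & y
    unambiguous = len(xs) == 1 and len(ys) == 1
    return candidates, unambiguous


def write_layout_tsv(layout: PoolLayout, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("plant_id\tx_pool\ty_pool\n")
        for plant in range(1, layout.n_plants + 1):
            pids = layout.plant_coords[plant]
            if layout.dimension == 1:
                fh.write(f"{plant}\t{pids[0]}\t\n")
            else:
                x = next(p for p in pids if p.startswith("X"))
                y = next(p for p in pids if p.startswith("Y"))
                fh.write(f"{plant}\t{x}\t{y}\n")
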