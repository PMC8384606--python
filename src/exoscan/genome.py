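"""Chromosome bookkeeping: sizes files, subgenome assignment, fixed-width bin grids.

Hexaploid wheat chromosomes are conventionally named ``chr1A`` .. ``chr7D``;
the trailing letter identifies the subgenome (A, B or D).  Everything here is
convention-driven but overridable, so non-standard contig names can be mapped
explicitly.
"""

from __future__ import annotations

import math
from typing import Mapping

import pandas as pd

SUBGENOMES = ("A", "B", "D")


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` file into an ordered dict."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, length = line.split("\t")[:2]
            sizes[chrom] = int(length)
    if not sizes:
        raise ValueError(f"no chromosome sizes found in {path}")
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def subgenome_of(chrom: str, mapping: Mapping[str, str] | None = None) -> str:
    """Subgenome label for a chromosome name.

    By default the trailing alphabetic character is used (``chr3D`` -> ``D``);
    an explicit ``mapping`` overrides the convention.
    """
    if mapping is not None and chrom in mapping:
        return mapping[chrom]
    suffix = chrom.rstrip("0123456789")  # tolerate e.g. "chr3D" (no-op) or "3D"
    last = chrom[-1].upper()
    if last in SUBGENOMES:
        return last
    raise ValueError(
        f"cannot infer subgenome for chromosome {chrom!r}; "
        "supply an explicit subgenome mapping"
    )


def subgenome_chroms(
    sizes: Mapping[str, int], subgenome: str, mapping: Mapping[str, str] | None = None
) -> list[str]:
    return [c for c in sizes if subgenome_of(c, mapping) == subgenome]


def subgenome_length(
    sizes: Mapping[str, int], subgenome: str, mapping: Mapping[str, str] | None = None
) -> int:
    chroms = subgenome_chroms(sizes, subgenome, mapping)
    if not chroms:
        raise ValueError(f"no chromosomes assigned to subgenome {subgenome!r}")
    return sum(sizes[c] for c in chroms)


def n_bins(length: int, width: int) -> int:
    if width <= 0:
        raise ValueError("bin width must be positive")
    return max(1, math.ceil(length / width))


def tile_bins(sizes: Mapping[str, int], width: int) -> pd.DataFrame:
    """Tile every chromosome with fixed-width bins.

    Bins are 0-based half-open ``[i*w, (i+1)*w)``; the final bin of each
    chromosome is truncated at the chromosome end so the tiling is exact.
    Returns columns ``chrom, start, end`` in input chromosome order.
    """
    rows = []
    for chrom, length in sizes.items():
        k = n_bins(length, width)
        for i in range(k):
            rows.append((chrom, i * width, min((i + 1) * width, length)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])
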