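"""Genomic regions: the feature unit of expressed-region phenotype prediction.

Coordinates follow the BED convention: 0-based, half-open ``[start, end)``.
Region ID strings are ``chrom:start-end`` using those coordinates literally.
Strand is ignored throughout (expressed-region coverage is unstranded).
"""

from __future__ import annotations

import re
from typing import NamedTuple


class Region(NamedTuple):
    """A genomic interval identified by (chrom, start, end).

    ``start`` is 0-based inclusive, ``end`` is 0-based exclusive.
    """

    chrom: str
    start: int
    end: int

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.id


_REGION_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


def parse_region_id(region_id: str) -> Region:
    """Parse a ``chrom:start-end`` identifier into a :class:`Region`.

    Raises
    ------
    ValueError
        If the string does not match the format or violates ``start < end``.
    """
    m = _REGION_RE.match(region_id.strip())
    if m is None:
        raise ValueError(
            f"malformed region ID {region_id!r}: expected 'chrom:start-end'"
        )
    chrom = m.group("chrom")
    start = int(m.group("start"))
    end = int(m.group("end"))
    if not chrom:
        raise ValueError(f"malformed region ID {region_id!r}: empty chromosome")
    if start >= end:
        raise ValueError(
            f"invalid region {region_id!r}: start ({start}) must be < end ({end})"
        )
    return Region(chrom, start, end)


def regions_to_bed(regions, path) -> None:
    """Write regions as 3-column BED."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


def regions_from_bed(path) -> list[Region]:
    """Read regions from a 3-column BED file."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >= 3 BED columns")
            r = Region(fields[0], int(fields[1]), int(fields[2]))
            if r.start >= r.end:
                raise ValueError(f"{path}: line {lineno}: start >= end in {r.id}")
            out.append(r)
    return out
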