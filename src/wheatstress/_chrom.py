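"""Wheat chromosome naming helpers.

Bread wheat (*Triticum aestivum*) is an allohexaploid: each of the seven
homoeologous groups carries one chromosome per subgenome (A, B, D), giving
21 nuclear chromosomes named 1A..7D.  Unplaced scaffolds are conventionally
labelled "Un".
"""

from __future__ import annotations

import re

SUBGENOMES = ("A", "B", "D")
GROUPS = tuple(range(1, 8))

_CHROM_RE = re.compile(r"^(?:chr)?([1-7])([ABD])$", re.IGNORECASE)


def parse_chromosome(name: str) -> tuple[int, str] | None:
    """Parse a chromosome name into (homoeologous group, subgenome).

    Returns ``None`` for unplaced ("Un") or otherwise unparseable names.
    """
    m = _CHROM_RE.match(str(name).strip())
    if m is None:
        return None
    return int(m.group(1)), m.group(2).upper()


def wheat_chromosomes() -> list[str]:
    """The 21 nuclear chromosome names, group-major (1A, 1B, 1D, 2A, ...)."""
    return [f"{g}{s}" for g in GROUPS for s in SUBGENOMES]
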