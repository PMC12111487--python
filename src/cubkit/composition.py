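"""Nucleotide-composition statistics: A3/T3/C3/G3, GC, GC1/GC2/GC3, GC12, GC3s.

Two dialects coexist deliberately, mirroring the two tool families used in
codon-usage studies:

* third-position base fractions (A3, T3, C3, G3) and GC3s are computed over
  the 59-codon synonymous analysis set by default (the codonW convention:
  Met, Trp and stops excluded), with ``synonymous_only=False`` available for
  raw third-position fractions;
* positional GC (GC, GC1, GC2, GC3) is computed over ALL codons of the
  filtered CDS, terminal stop included (the EMBOSS cusp convention).

GC12 is the arithmetic mean of GC1 and GC2.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

from .cds_io import GeneRecord, codon_count_vector
from .exceptions import StatisticUndefinedError
from .genetic_code import CodonSpace

_GC = frozenset("GC")


@dataclass
class CompositionStats:
    """Composition summary for one gene or one genome (pooled counts)."""

    scope_id: str
    a3: float
    t3: float
    c3: float
    g3: float
    gc_all: float
    gc1: float
    gc2: float
    gc3: float
    gc3s: float

    @property
    def gc12(self) -> float:
        return (self.gc1 + self.gc2) / 2.0


def _as_counts(x: str | Mapping[str, int]) -> Mapping[str, int]:
    if isinstance(x, str):
        return codon_count_vector(x)
    return x


def third_position_composition(
    counts: str | Mapping[str, int],
    space: CodonSpace,
    synonymous_only: bool = True,
) -> tuple[float, float, float, float]:
    """Fractions of A/T/C/G at third codon positions.

    With ``synonymous_only`` (default) only the 59 analysis codons
    contribute; otherwise every codon present in ``counts`` does.

    Raises
    ------
    StatisticUndefinedError
        If no codon falls in the included set.
    """
    counts = _as_counts(counts)
    include = space.analysis_codon_set if synonymous_only else None
    base_tally = Counter()
    for codon, n in counts.items():
        if n <= 0:
            continue
        if include is not None and codon not in include:
            continue
        base_tally[codon[2]] += n
    total = sum(base_tally.values())
    if total == 0:
        raise StatisticUndefinedError("no codons in the included set")
    return tuple(base_tally.get(b, 0) / total for b in "ATCG")  # type: ignore[return-value]


def positional_gc(
    x: str | Mapping[str, int], position: int | str
) -> float:
    """G+C fraction at codon position 1, 2, 3 or ``'all'``, over all codons.

    Accepts a DNA sequence (length divisible by 3) or a codon-count map.
    All codons contribute, including Met/Trp and the terminal stop, matching
    cusp-style positional GC.
    """
    counts = _as_counts(x)
    total = sum(n for n in counts.values() if n > 0)
    if total == 0:
        raise StatisticUndefinedError("empty input")
    positions = (0, 1, 2) if position == "all" else (int(position) - 1,)
    if any(p not in (0, 1, 2) for p in positions):
        raise ValueError(f"position must be 1, 2, 3 or 'all', got {position!r}")
    gc = sum(
        n * sum(codon[p] in _GC for p in positions)
        for codon, n in counts.items()
        if n > 0
    )
    return gc / (total * len(positions))


def gc3s(counts: str | Mapping[str, int], space: CodonSpace) -> float:
    """G+C fraction at third positions of synonymous codons (59-codon set)."""
    _, _, c3, g3 = third_position_composition(counts, space, synonymous_only=True)
    return c3 + g3


def composition_stats(
    counts: str | Mapping[str, int],
    space: CodonSpace,
    scope_id: str = "",
    synonymous_only: bool = True,
) -> CompositionStats:
    """All composition statistics for one gene or pooled genome counts."""
    counts = _as_counts(counts)
    a3, t3, c3, g3 = third_position_composition(counts, space, synonymous_only)
    return CompositionStats(
        scope_id=scope_id,
        a3=a3,
        t3=t3,
        c3=c3,
        g3=g3,
        gc_all=positional_gc(counts, "all"),
        gc1=positional_gc(counts, 1),
        gc2=positional_gc(counts, 2),
        gc3=positional_gc(counts, 3),
        gc3s=gc3s(counts, space) if synonymous_only else c3 + g3,
    )


def pooled_counts(genes: Iterable[GeneRecord]) -> Counter:
    """Sum codon-count vectors over genes (genome-level pooling)."""
    out: Counter = Counter()
    for g in genes:
        out.update(g.codon_counts)
    return out


def genome_composition(
    genes: list[GeneRecord], space: CodonSpace, genome_id: str = "genome"
) -> CompositionStats:
    """Genome-level composition from pooled filtered-CDS codon counts."""
    return composition_stats(pooled_counts(genes), space, scope_id=genome_id)
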