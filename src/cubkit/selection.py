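"""Mutation-versus-selection diagnostics.

Three classical plots discriminate mutational pressure from selective
constraint on codon usage:

* the ENC plot: per-gene observed ENC against GC3s, compared with the
  mutation-only expectation ENC_exp(s) = 2 + s + 29 / (s^2 + (1 - s)^2);
  genes on the curve look mutation-driven, genes below it selected;
* the PR2 plot: A3/(A3+T3) against G3/(G3+C3); under strand-symmetric
  mutation alone, points cluster at (0.5, 0.5);
* the neutrality plot: per-gene GC12 against GC3.  A regression slope near 1
  indicates mutation-dominated bias, near 0 selection-dominated; 100*slope
  is read as the mutational share of the influence, the remainder as
  selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cds_io import GeneRecord
from .composition import composition_stats
from .exceptions import InsufficientDataError, StatisticUndefinedError
from .genetic_code import CodonSpace
from .indices import enc


@dataclass
class NeutralityFit:
    """OLS fit of the neutrality plot with its slope decomposition."""

    genome_id: str
    slope: float
    intercept: float
    r: float
    p_value: float
    n_genes: int
    orientation: str  # "gc12_x" (x=GC12, y=GC3) or "gc3_x"

    @property
    def mutation_pct(self) -> float:
        return 100.0 * self.slope

    @property
    def selection_pct(self) -> float:
        return 100.0 - self.mutation_pct


def enc_expected(gc3s: float) -> float:
    """Mutation-only ENC expectation at synonymous third-position GC ``s``."""
    if not 0.0 <= gc3s <= 1.0:
        raise ValueError(f"gc3s must be in [0, 1], got {gc3s}")
    s = gc3s
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)


def enc_ratio(enc_exp: float, enc_obs: float) -> float:
    """Relative shortfall of observed ENC: (ENC_exp - ENC_obs) / ENC_exp."""
    if enc_exp <= 0:
        raise ValueError("enc_exp must be positive")
    return (enc_exp - enc_obs) / enc_exp


def enc_ratio_histogram(
    ratios: Sequence[float], bin_width: float = 0.05
) -> pd.DataFrame:
    """Bin ENC ratios into half-open bins [a, a + w) with edges aligned to 0.

    Returns a DataFrame with columns bin_left, bin_right, count covering the
    observed range (empty interior bins reported as zero).
    """
    arr = np.asarray(list(ratios), dtype=float)
    if arr.size == 0:
        raise ValueError("empty ratio list")
    lo = math.floor(arr.min() / bin_width)
    hi = math.floor(arr.max() / bin_width) + 1
    edges = np.arange(lo, hi + 1) * bin_width
    counts, _ = np.histogram(arr, bins=edges)
    # np.histogram closes the last bin on the right; shift exact top-edge
    # values into their own half-open bin.
    top_hits = int(np.sum(arr == edges[-1]))
    if top_hits:
        counts[-1] -= top_hits
        edges = np.append(edges, edges[-1] + bin_width)
        counts = np.append(counts, top_hits)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


def pr2_point(
    a3: float, t3: float, c3: float, g3: float
) -> tuple[float, float]:
    """PR2 coordinates (x, y) = (G3/(G3+C3), A3/(A3+T3)).

    Raises
    ------
    StatisticUndefinedError
        If either denominator is zero (caller excludes the gene and logs).
    """
    if a3 + t3 <= 0 or g3 + c3 <= 0:
        raise StatisticUndefinedError("degenerate PR2 denominator")
    return g3 / (g3 + c3), a3 / (a3 + t3)


def fourfold_blocks(space: CodonSpace) -> list[tuple[str, ...]]:
    """The eight four-codon blocks sharing their first two bases (the five
    strict four-fold families plus the four-codon halves of Leu/Ser/Arg).
    These are the sites classical PR2 analysis uses, because the third base
    is free of amino-acid constraint there."""
    groups: dict[str, list[str]] = {}
    for codon in space.analysis_codons:
        groups.setdefault(codon[:2], []).append(codon)
    return [
        tuple(sorted(cs))
        for cs in groups.values()
        if len(cs) == 4 and len({space.family_of[c] for c in cs}) == 1
    ]


def pr2_fourfold_point(
    counts, space: CodonSpace
) -> tuple[float, float]:
    """PR2 coordinates computed over four-fold degenerate sites only.

    Under strand-symmetric mutation with no selection these concentrate at
    (0.5, 0.5); the synonymous-59 dialect does not share that property
    because two-fold families constrain which third bases exist.
    """
    tally = {b: 0 for b in "ATCG"}
    for block in fourfold_blocks(space):
        for codon in block:
            tally[codon[2]] += counts.get(codon, 0)
    total = sum(tally.values())
    if total == 0:
        raise StatisticUndefinedError("no four-fold codons observed")
    a3, t3, c3, g3 = (tally[b] / total for b in "ATCG")
    return pr2_point(a3, t3, c3, g3)


def neutrality_fit(
    points: Sequence[tuple[float, float]],
    genome_id: str = "genome",
    orientation: str = "gc12_x",
) -> NeutralityFit:
    """OLS neutrality regression over per-gene (GC12, GC3) points.

    ``orientation='gc12_x'`` regresses GC3 on GC12 (x = GC12); the
    conventional alternative ``'gc3_x'`` regresses GC12 on GC3.  Slopes
    differ between orientations, so the choice is recorded on the result.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise InsufficientDataError("need >= 3 (gc12, gc3) points")
    if orientation == "gc12_x":
        x, y = pts[:, 0], pts[:, 1]
    elif orientation == "gc3_x":
        x, y = pts[:, 1], pts[:, 0]
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    if np.ptp(x) == 0:
        raise InsufficientDataError("degenerate x variance in neutrality fit")
    res = stats.linregress(x, y)
    return NeutralityFit(
        genome_id=genome_id,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p_value=float(res.pvalue),
        n_genes=len(pts),
        orientation=orientation,
    )


def selection_diagnostics(
    genes: Sequence[GeneRecord], space: CodonSpace, pr2_dialect: str = "synonymous"
) -> pd.DataFrame:
    """Per-gene diagnostics table for the three plots.

    Columns: gene_id, gc3s, gc12, gc3, enc_obs, enc_exp, enc_ratio, pr2_x,
    pr2_y, pr2_defined.  ``pr2_dialect`` selects third-position fractions
    over the 59 synonymous codons (default) or over four-fold degenerate
    sites only (the classical formulation).  Genes with undefined PR2
    denominators keep NaN coordinates and pr2_defined = False; genes with
    undefined ENC are dropped (they carry no synonymous information at
    all).
    """
    if pr2_dialect not in ("synonymous", "fourfold"):
        raise ValueError(f"unknown pr2_dialect {pr2_dialect!r}")
    rows = []
    for g in genes:
        try:
            stats_g = composition_stats(g.codon_counts, space, g.gene_id)
            enc_g = enc(g.codon_counts, space, g.gene_id)
        except StatisticUndefinedError:
            continue
        exp = enc_expected(stats_g.gc3s)
        try:
            if pr2_dialect == "fourfold":
                x, y = pr2_fourfold_point(g.codon_counts, space)
            else:
                x, y = pr2_point(stats_g.a3, stats_g.t3, stats_g.c3, stats_g.g3)
            pr2_ok = True
        except StatisticUndefinedError:
            x = y = float("nan")
            pr2_ok = False
        rows.append(
            {
                "gene_id": g.gene_id,
                "gc3s": stats_g.gc3s,
                "gc12": stats_g.gc12,
                "gc3": stats_g.gc3,
                "enc_obs": enc_g.enc_obs,
                "enc_exp": exp,
                "enc_ratio": enc_ratio(exp, enc_g.enc_obs),
                "pr2_x": x,
                "pr2_y": y,
                "pr2_defined": pr2_ok,
            }
        )
    return pd.DataFrame(rows)
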