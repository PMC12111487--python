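"""Codon-usage indices: RSCU, Wright's ENC, CAI, CBI, optimal codons.

RSCU
    Within a synonymous family of degeneracy k with total count N, codon j
    with count x_j has RSCU_j = x_j / (N / k): 1 means no preference, >1
    preferred.  Observed families therefore sum to k.

ENC (effective number of codons)
    Wright's statistic.  Per family with n >= 2 codons observed, the
    bias-corrected homozygosity is F = (n * sum(p^2) - 1) / (n - 1) with p
    the within-family codon proportions.  Class means over the 9 two-fold,
    1 three-fold, 5 four-fold and 3 six-fold families give
    ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6, capped at 61.  20 means one codon
    per family; 61 means uniform usage.

CAI (codon adaptation index)
    Geometric mean of relative adaptiveness w over the gene's analysis
    codons, with w derived from a reference set of putatively highly
    expressed genes (per-family RSCU scaled so the family max is 1).

CBI (codon bias index)
    Excess usage of a designated optimal-codon set over random expectation,
    scaled to [-1, 1].

Optimal codons
    Genes ranked by ENC; the low-ENC decile is the putative high-expression
    group and the high-ENC decile the low-expression group.  Codons with
    high-group RSCU > 1 and dRSCU = RSCU_high - RSCU_low > 0.08 are optimal.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .cds_io import GeneRecord
from .exceptions import (
    ConfigurationError,
    InsufficientDataError,
    StatisticUndefinedError,
)
from .genetic_code import CodonSpace, Family

ENC_MAX = 61.0

#: Relative adaptiveness assigned to codons absent from the reference set,
#: so the geometric mean stays finite.
DEFAULT_W_FLOOR = 0.01


@dataclass
class RSCUTable:
    """RSCU over the 59 analysis codons for one gene or pooled scope.

    Families with zero observations are flagged in ``zero_families`` and
    their codons carry the all-zero sentinel.
    """

    scope_id: str
    rscu: dict[str, float]
    zero_families: frozenset[str] = frozenset()


@dataclass
class ENCResult:
    """Wright's ENC for one gene, with per-class mean homozygosities."""

    gene_id: str
    f_bar: dict[int, float]
    enc_raw: float
    enc_obs: float
    n_classes_imputed: int = 0


@dataclass
class OptimalCodonResult:
    """Outcome of the decile/dRSCU optimal-codon procedure for one genome."""

    genome_id: str
    high_group: list[str]
    low_group: list[str]
    delta_rscu: dict[str, float]
    rscu_high: dict[str, float]
    rscu_low: dict[str, float]
    optimal_codons: frozenset[str]
    high_frequency_codons: frozenset[str]


@dataclass
class IndexSummary:
    """Per-gene index bundle used for correlations and reports."""

    gene_id: str
    enc_obs: float
    cai: float
    cbi: float
    gc3s: float
    L_aa: int


def rscu(
    counts: Mapping[str, int], space: CodonSpace, scope_id: str = ""
) -> RSCUTable:
    """Relative synonymous codon usage over the 59 analysis codons."""
    values: dict[str, float] = {}
    zero: set[str] = set()
    any_observed = False
    for fam in space.families:
        total = sum(counts.get(c, 0) for c in fam.codons)
        if total == 0:
            zero.add(fam.aa)
            for c in fam.codons:
                values[c] = 0.0
            continue
        any_observed = True
        expected = total / fam.k
        for c in fam.codons:
            values[c] = counts.get(c, 0) / expected
    if not any_observed:
        raise StatisticUndefinedError("no codons in the analysis set")
    return RSCUTable(scope_id=scope_id, rscu=values, zero_families=frozenset(zero))


def family_homozygosity(family_counts: Sequence[int]) -> float | None:
    """Bias-corrected homozygosity F for one family's codon counts.

    Returns None when the family is unusable (n < 2 or F <= 0).
    """
    n = sum(family_counts)
    if n < 2:
        return None
    sum_p2 = sum((x / n) ** 2 for x in family_counts)
    f = (n * sum_p2 - 1.0) / (n - 1.0)
    return f if f > 0 else None


def enc(
    counts: Mapping[str, int], space: CodonSpace, gene_id: str = ""
) -> ENCResult:
    """Wright's effective number of codons with standard class handling.

    Unusable families (n < 2 or non-positive homozygosity) drop out of their
    class mean.  A fully missing three-fold class is imputed as the mean of
    the available two- and four-fold class means (Wright's prescription);
    any other fully missing class falls back to the pooled mean of all
    usable family homozygosities.  The result is capped at 61.
    """
    by_k = space.families_by_degeneracy()
    f_values: dict[int, list[float]] = {k: [] for k in by_k}
    for k, fams in by_k.items():
        for fam in fams:
            f = family_homozygosity([counts.get(c, 0) for c in fam.codons])
            if f is not None:
                f_values[k].append(f)
    all_f = [f for fs in f_values.values() for f in fs]
    if not all_f:
        raise StatisticUndefinedError("no usable synonymous family for ENC")

    f_bar: dict[int, float] = {
        k: sum(fs) / len(fs) for k, fs in f_values.items() if fs
    }
    imputed = 0
    if 3 not in f_bar and 3 in by_k:
        neighbours = [f_bar[k] for k in (2, 4) if k in f_bar]
        if neighbours:
            f_bar[3] = sum(neighbours) / len(neighbours)
            imputed += 1
    pooled = sum(all_f) / len(all_f)
    for k in by_k:
        if k not in f_bar:
            f_bar[k] = pooled
            imputed += 1

    enc_raw = 2.0 + sum(len(by_k[k]) / f_bar[k] for k in by_k)
    return ENCResult(
        gene_id=gene_id,
        f_bar=f_bar,
        enc_raw=enc_raw,
        enc_obs=min(enc_raw, ENC_MAX),
        n_classes_imputed=imputed,
    )


def reference_w_from_high_set(
    high_genes: Iterable[GeneRecord],
    space: CodonSpace,
    floor: float = DEFAULT_W_FLOOR,
) -> dict[str, float]:
    """Relative adaptiveness w from a reference set of genes.

    Pools codon counts over the reference genes, converts to RSCU and scales
    each family so its most-used codon has w = 1.  Codons unobserved in the
    reference (including whole unobserved families) get the floor.
    """
    pooled: Counter = Counter()
    n = 0
    for g in high_genes:
        pooled.update(g.codon_counts)
        n += 1
    if n == 0:
        raise ConfigurationError("empty reference set for CAI")
    table = rscu(pooled, space, scope_id="reference")
    w: dict[str, float] = {}
    for fam in space.families:
        fam_max = max(table.rscu[c] for c in fam.codons)
        for c in fam.codons:
            w[c] = table.rscu[c] / fam_max if fam_max > 0 else floor
            if w[c] <= 0:
                w[c] = floor
    return w


def cai(
    counts: Mapping[str, int],
    reference_w: Mapping[str, float],
    space: CodonSpace,
    floor: float = DEFAULT_W_FLOOR,
) -> float:
    """Codon adaptation index: geometric mean of w over analysis codons."""
    if not reference_w:
        raise ConfigurationError("empty CAI reference")
    log_sum = 0.0
    n = 0
    for codon in space.analysis_codons:
        x = counts.get(codon, 0)
        if x <= 0:
            continue
        w = reference_w.get(codon, floor)
        if w <= 0:
            w = floor
        log_sum += x * math.log(w)
        n += x
    if n == 0:
        raise StatisticUndefinedError("no analysis codons for CAI")
    return math.exp(log_sum / n)


def cbi(
    counts: Mapping[str, int],
    optimal: Iterable[str],
    space: CodonSpace,
) -> float:
    """Codon bias index against a designated optimal-codon set.

    CBI = (N_opt - N_ran) / (N_tot - N_ran), where N_tot counts codons in
    families containing at least one optimal codon, N_opt the optimal-codon
    occurrences, and N_ran the usage expected under uniform within-family
    choice.
    """
    optimal = frozenset(optimal)
    if not optimal:
        raise ConfigurationError("empty optimal-codon set for CBI")
    n_tot = n_opt = 0
    n_ran = 0.0
    for fam in space.families:
        m = sum(1 for c in fam.codons if c in optimal)
        if m == 0:
            continue
        fam_total = sum(counts.get(c, 0) for c in fam.codons)
        n_tot += fam_total
        n_opt += sum(counts.get(c, 0) for c in fam.codons if c in optimal)
        n_ran += fam_total * m / fam.k
    if n_tot == 0 or math.isclose(n_tot, n_ran):
        raise StatisticUndefinedError("degenerate CBI denominator")
    return (n_opt - n_ran) / (n_tot - n_ran)


def high_frequency_codons(table: RSCUTable) -> frozenset[str]:
    """Codons with RSCU strictly above 1 (preferred codons)."""
    return frozenset(c for c, v in table.rscu.items() if v > 1.0)


def optimal_codons(
    genes: Sequence[GeneRecord],
    space: CodonSpace,
    decile: float = 0.10,
    delta_threshold: float = 0.08,
    high_group_low_enc: bool = True,
    rscu_scope: str = "high_group",
    genome_id: str = "genome",
) -> OptimalCodonResult:
    """Identify optimal codons by the ENC-decile dRSCU procedure.

    Genes are ranked by ENC (ties broken by gene id for determinism).  With
    ``high_group_low_enc`` (default) the low-ENC decile is the putative
    high-expression group — strong bias read as high expression — which
    makes positive dRSCU select preferred codons.  ``rscu_scope`` chooses
    whether the RSCU > 1 condition is evaluated in the high group's pooled
    RSCU (default) or the whole-genome pooled RSCU.
    """
    if len(genes) < 10:
        raise InsufficientDataError(
            f"need >= 10 genes for decile grouping, got {len(genes)}"
        )
    ranked = []
    for g in genes:
        try:
            e = enc(g.codon_counts, space, g.gene_id).enc_obs
        except StatisticUndefinedError:
            continue
        ranked.append((e, g.gene_id, g))
    if len(ranked) < 10:
        raise InsufficientDataError("fewer than 10 genes with defined ENC")
    ranked.sort(key=lambda t: (t[0], t[1]))
    size = math.ceil(decile * len(ranked))
    low_enc = [t[2] for t in ranked[:size]]
    high_enc = [t[2] for t in ranked[-size:]]
    high_group, low_group = (
        (low_enc, high_enc) if high_group_low_enc else (high_enc, low_enc)
    )

    from .composition import pooled_counts  # local import to avoid cycle

    rscu_high = rscu(pooled_counts(high_group), space, "high_group").rscu
    rscu_low = rscu(pooled_counts(low_group), space, "low_group").rscu
    delta = {c: rscu_high[c] - rscu_low[c] for c in space.analysis_codons}

    if rscu_scope == "high_group":
        scope_rscu = rscu_high
    elif rscu_scope == "genome":
        scope_rscu = rscu(pooled_counts(genes), space, "genome").rscu
    else:
        raise ConfigurationError(f"unknown rscu_scope {rscu_scope!r}")

    optimal = frozenset(
        c
        for c in space.analysis_codons
        if scope_rscu[c] > 1.0 and delta[c] > delta_threshold
    )
    return OptimalCodonResult(
        genome_id=genome_id,
        high_group=[g.gene_id for g in high_group],
        low_group=[g.gene_id for g in low_group],
        delta_rscu=delta,
        rscu_high=rscu_high,
        rscu_low=rscu_low,
        optimal_codons=optimal,
        high_frequency_codons=frozenset(
            c for c, v in scope_rscu.items() if v > 1.0
        ),
    )
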