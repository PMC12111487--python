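"""Genetic-code bookkeeping for codon-usage-bias analysis.

Bias statistics operate on the 59 synonymous codons coding for the 18 amino
acids with degenerate codon families.  Met (ATG) and Trp (TGG) are
single-codon families and the three stop codons (TAA, TAG, TGA) terminate
translation, so none of them carries synonymous-choice information and all
five are excluded from the analysis set.

Codons are kept in the DNA alphabet (T, not U) because inputs are DNA;
:func:`to_rna` renders U for display.  Six-codon amino acids (Leu, Ser, Arg)
are treated as single six-fold families, the convention under which the
effective number of codons partitions the 18 families into 9 two-fold,
1 three-fold, 5 four-fold and 3 six-fold classes.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data import CodonTable

from .exceptions import ConfigurationError

#: codonW-style base order used to sort codons deterministically
BASE_ORDER = "TCAG"

#: Accepted genetic-code identifiers.  The standard code (NCBI table 1) and
#: the bacterial/plastid code (table 11) have identical codon->amino-acid
#: assignments; table 11 differs only in permitted start codons, which are
#: irrelevant here because filtering demands an ATG start.
_CODE_ALIASES = {
    "standard": 1,
    "1": 1,
    "plastid": 11,
    "bacterial": 11,
    "11": 11,
}


def to_rna(codon: str) -> str:
    """Render a DNA codon in the RNA alphabet for display (T -> U)."""
    return codon.replace("T", "U")


@dataclass(frozen=True)
class Family:
    """A synonymous-codon family: one amino acid and its codons."""

    aa: str
    codons: tuple[str, ...]

    @property
    def k(self) -> int:
        """Degeneracy (number of synonymous codons)."""
        return len(self.codons)


@dataclass(frozen=True)
class CodonSpace:
    """The 64-codon partition used by every statistic in the package.

    Attributes
    ----------
    code_id : str
        Identifier of the genetic code the space was built from.
    family_of : dict
        Map codon -> amino acid, over all sense codons (including Met/Trp).
    families : tuple of Family
        The 18 analysis families (degeneracy >= 2), sorted by amino acid.
    analysis_codons : tuple of str
        The 59 codons retained for bias analysis.
    stop_codons : frozenset of str
        The three stop codons.
    excluded_single_codons : frozenset of str
        Met and Trp codons ({ATG, TGG} in the supported codes).
    """

    code_id: str
    family_of: dict[str, str]
    families: tuple[Family, ...]
    analysis_codons: tuple[str, ...]
    stop_codons: frozenset[str]
    excluded_single_codons: frozenset[str]

    def families_by_degeneracy(self) -> dict[int, tuple[Family, ...]]:
        """Group analysis families by degeneracy class k."""
        out: dict[int, list[Family]] = {}
        for fam in self.families:
            out.setdefault(fam.k, []).append(fam)
        return {k: tuple(v) for k, v in sorted(out.items())}

    @property
    def analysis_codon_set(self) -> frozenset[str]:
        return frozenset(self.analysis_codons)

    def family_containing(self, codon: str) -> Family | None:
        """Return the analysis family of ``codon``, or None if excluded."""
        aa = self.family_of.get(codon)
        if aa is None:
            return None
        fam = self._family_index.get(aa)
        return fam

    @property
    def _family_index(self) -> dict[str, Family]:
        # frozen dataclass: cache on the instance dict via object.__setattr__
        cached = self.__dict__.get("_family_index_cache")
        if cached is None:
            cached = {f.aa: f for f in self.families}
            object.__setattr__(self, "_family_index_cache", cached)
        return cached


def _codon_sort_key(codon: str) -> tuple[int, int, int]:
    return tuple(BASE_ORDER.index(b) for b in codon)  # type: ignore[return-value]


def build_codon_space(code_id: str = "standard") -> CodonSpace:
    """Construct the codon bookkeeping for a named genetic code.

    Parameters
    ----------
    code_id : str
        One of ``standard``/``1`` or ``plastid``/``bacterial``/``11``.

    Raises
    ------
    ConfigurationError
        If the identifier is unknown.
    """
    key = str(code_id).lower()
    if key not in _CODE_ALIASES:
        raise ConfigurationError(
            f"unknown genetic code {code_id!r}; supported: {sorted(_CODE_ALIASES)}"
        )
    table = CodonTable.unambiguous_dna_by_id[_CODE_ALIASES[key]]

    family_of = dict(table.forward_table)  # codon -> aa, sense codons only
    stops = frozenset(table.stop_codons)

    by_aa: dict[str, list[str]] = {}
    for codon, aa in family_of.items():
        by_aa.setdefault(aa, []).append(codon)

    families = []
    singles = []
    for aa in sorted(by_aa):
        codons = tuple(sorted(by_aa[aa], key=_codon_sort_key))
        if len(codons) == 1:
            singles.append(codons[0])
        else:
            families.append(Family(aa, codons))

    analysis = tuple(
        sorted((c for f in families for c in f.codons), key=_codon_sort_key)
    )

    space = CodonSpace(
        code_id=key,
        family_of=family_of,
        families=tuple(families),
        analysis_codons=analysis,
        stop_codons=stops,
        excluded_single_codons=frozenset(singles),
    )
    _check_partition(space)
    return space


def _check_partition(space: CodonSpace) -> None:
    """Assert the 64-codon partition invariants of the supported codes."""
    all_codons = {
        a + b + c for a in BASE_ORDER for b in BASE_ORDER for c in BASE_ORDER
    }
    covered = (
        set(space.analysis_codons)
        | set(space.stop_codons)
        | set(space.excluded_single_codons)
    )
    if covered != all_codons:
        raise ConfigurationError("codon partition does not cover the 64 codons")
    if len(space.analysis_codons) != sum(f.k for f in space.families):
        raise ConfigurationError("analysis codons inconsistent with families")
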