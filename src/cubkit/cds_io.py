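"""Reading, extracting and quality-filtering coding sequences.

Inputs are either GenBank flat files (CDS features are spliced and
strand-corrected, honouring ``complement``/``join`` locations) or multi-FASTA
files of pre-extracted CDSs.  Filtering applies the conventional
codon-usage-study criteria: length >= 300 nt and divisible by 3, ATG start,
terminal stop, no internal stop, no ambiguous base.  Rejections are tallied,
never raised; a sequence failing several criteria is counted once, under the
first failing reason in a fixed precedence order, so tallies are
well-defined.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.SeqFeature import AfterPosition, BeforePosition

from .exceptions import InputError
from .genetic_code import CodonSpace

MIN_LENGTH_NT = 300

#: Rejection reasons in check order; the first failing check claims the tally.
REJECTION_REASONS = (
    "partial",
    "not_multiple_of_3",
    "short",
    "no_atg_start",
    "no_stop_end",
    "internal_stop",
    "ambiguous_base",
)


@dataclass
class RawCDS:
    """A CDS as extracted from a file, before quality filtering."""

    seq: str
    source_id: str
    partial: bool = False


@dataclass
class GeneRecord:
    """One filtered CDS with its codon counts.

    ``codon_counts`` covers every codon of the CDS including the terminal
    stop, so it sums to ``length_nt / 3``; downstream statistics restrict to
    the 59-codon analysis set as needed.  ``L_aa`` is the protein length
    (codons minus the stop).
    """

    gene_id: str
    genome_id: str
    sequence: str
    length_nt: int = field(init=False)
    codon_counts: dict[str, int] = field(init=False)
    L_aa: int = field(init=False)

    def __post_init__(self) -> None:
        self.length_nt = len(self.sequence)
        self.codon_counts = dict(codon_count_vector(self.sequence))
        self.L_aa = self.length_nt // 3 - 1


@dataclass
class FilterReport:
    """Per-genome accounting of the filter: raw in, passed, rejected by reason."""

    genome_id: str
    n_raw: int
    n_pass: int
    rejection_tally: dict[str, int]


def codon_count_vector(sequence: str) -> Counter:
    """Count codons of an in-frame DNA sequence (length divisible by 3)."""
    if len(sequence) % 3:
        raise ValueError("sequence length not divisible by 3")
    return Counter(sequence[i : i + 3] for i in range(0, len(sequence), 3))


def _is_partial_location(feature) -> bool:
    loc = feature.location
    return isinstance(loc.start, BeforePosition) or isinstance(loc.end, AfterPosition)


def _sniff_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext in {".fa", ".fasta", ".fna", ".ffn"}:
        return "fasta"
    if ext in {".gb", ".gbk", ".gbff", ".genbank"}:
        return "genbank"
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "fasta" if line.startswith(">") else "genbank"
    raise InputError(f"{path}: empty file")


def extract_cds(path: str, genome_id: str, fmt: str | None = None) -> list[RawCDS]:
    """Extract raw CDS sequences from a GenBank or FASTA file.

    GenBank CDS features are spliced (join) and strand-corrected
    (complement) into 5'->3' coding orientation; features with fuzzy
    boundaries (``<``/``>``) are tagged partial.  FASTA entries are taken
    verbatim (no location metadata, so never partial).

    Raises
    ------
    InputError
        If the file cannot be parsed or contains no CDS.
    """
    fmt = fmt or _sniff_format(path)
    raw: list[RawCDS] = []
    try:
        if fmt == "fasta":
            for rec in SeqIO.parse(path, "fasta"):
                raw.append(RawCDS(str(rec.seq).upper(), rec.id))
        elif fmt == "genbank":
            for rec in SeqIO.parse(path, "genbank"):
                idx = 0
                for feature in rec.features:
                    if feature.type != "CDS":
                        continue
                    idx += 1
                    quals = feature.qualifiers
                    name = (
                        quals.get("gene", quals.get("locus_tag", quals.get("product", ["cds"])))
                    )[0]
                    seq = str(feature.extract(rec.seq)).upper()
                    raw.append(
                        RawCDS(
                            seq,
                            f"{name}_{idx}",
                            partial=_is_partial_location(feature),
                        )
                    )
        else:
            raise InputError(f"unsupported format {fmt!r}")
    except InputError:
        raise
    except Exception as exc:  # Biopython parse failure
        raise InputError(f"{path}: cannot parse as {fmt}: {exc}") from exc
    if not raw:
        raise InputError(f"{path}: no CDS found")
    return raw


def _rejection_reason(cds: RawCDS, space: CodonSpace) -> str | None:
    """First failing criterion in precedence order, or None if clean."""
    seq = cds.seq
    if cds.partial:
        return "partial"
    if len(seq) % 3:
        return "not_multiple_of_3"
    if len(seq) < MIN_LENGTH_NT:
        return "short"
    if not seq.startswith("ATG"):
        return "no_atg_start"
    if seq[-3:] not in space.stop_codons:
        return "no_stop_end"
    codons = [seq[i : i + 3] for i in range(0, len(seq) - 3, 3)]
    if any(c in space.stop_codons for c in codons):
        return "internal_stop"
    if set(seq) - set("ACGT"):
        return "ambiguous_base"
    return None


def filter_cds(
    raw: list[RawCDS] | list[str],
    space: CodonSpace,
    genome_id: str = "genome",
) -> tuple[list[GeneRecord], FilterReport]:
    """Apply the quality filters and return passing genes plus a report.

    Accepts either :class:`RawCDS` items or bare uppercase DNA strings
    (which are wrapped with ordinal ids).  Rejections are tallied under
    exactly one reason each; nothing is raised for a bad sequence.
    """
    items: list[RawCDS] = [
        c if isinstance(c, RawCDS) else RawCDS(c, f"seq_{i + 1}")
        for i, c in enumerate(raw)
    ]
    tally: Counter = Counter()
    genes: list[GeneRecord] = []
    for item in items:
        reason = _rejection_reason(item, space)
        if reason is None:
            genes.append(GeneRecord(item.source_id, genome_id, item.seq))
        else:
            tally[reason] += 1
    report = FilterReport(
        genome_id=genome_id,
        n_raw=len(items),
        n_pass=len(genes),
        rejection_tally={r: tally.get(r, 0) for r in REJECTION_REASONS},
    )
    return genes, report


def write_fasta(genes: list[GeneRecord], path: str, width: int = 70) -> None:
    """Write filtered CDSs as FASTA (deterministic, input order preserved)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f">{g.gene_id}\n")
            for i in range(0, len(g.sequence), width):
                fh.write(g.sequence[i : i + width] + "\n")


def write_filter_report(reports: list[FilterReport], path: str) -> None:
    """Write one TSV row per genome: id, raw, passed, one column per reason."""
    with open(path, "w") as fh:
        fh.write("genome_id\tn_raw\tn_pass\t" + "\t".join(REJECTION_REASONS) + "\n")
        for r in reports:
            cells = [r.genome_id, str(r.n_raw), str(r.n_pass)] + [
                str(r.rejection_tally.get(k, 0)) for k in REJECTION_REASONS
            ]
            fh.write("\t".join(cells) + "\n")
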