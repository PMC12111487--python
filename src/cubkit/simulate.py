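"""Synthetic chloroplast-like CDS sets with known compositional and
selective structure.

Every gene is ATG + sampled sense codons + a stop, so generated data pass
the quality filters by construction.  Three planted structures make the
pipeline testable end to end:

* a per-gene third-position GC level (``gc3_target``) imposed by weighting
  each family's codons by their third base, solved by bisection so the
  expected synonymous GC3s equals the target exactly (including the
  three-fold Ile family, whose restricted third-base alphabet would
  otherwise bias the realisation);
* a planted neutrality slope: a latent per-gene mutational drive shifts
  GC12 (via an exponential tilt on amino-acid family frequencies) and GC3
  (via the third-base weights) jointly, with d(GC3)/d(GC12) equal to
  ``neutrality_slope``;
* a planted optimal-codon set: a configurable fraction of genes
  (``class_mixture``) receives a log-scale preference ``bias_strength`` for
  one planted codon per family, lowering their ENC and giving the
  decile/dRSCU optimal-codon procedure a known answer.

Targets are planted in the synonymous (59-codon) coordinate system; the
fixed codons every CDS must carry (start, stop, Met, Trp) shift the
all-codon GC dialects by a small, nearly constant offset that cancels in
slope recovery.

Generation is deterministic for a fixed seed: same spec, byte-identical
FASTA.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .cds_io import RawCDS
from .exceptions import ConfigurationError
from .genetic_code import CodonSpace, build_codon_space

_GC = frozenset("GC")
_T_BRACKET = (1e-6, 1.0 - 1e-6)
_ETA_BRACKET = (-60.0, 60.0)
_BISECT_STEPS = 60


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic genome.

    Defaults emulate the conditions of AT-rich green-algal chloroplast
    genomes: 44 filtered CDSs of 300-1503 nt, synonymous third-position GC
    around 0.08, GC12 around 0.33, and a mutational share of 0.37 in the
    GC12-GC3 co-variation.  Selection features (``bias_strength``,
    ``class_mixture``, ``planted_optimal``) are off by default and planted
    explicitly per experiment.
    """

    seed: int
    genome_id: str = "synthetic"
    n_genes: int = 44
    length_range: tuple[int, int] = (300, 1503)
    gc3_target: float = 0.08
    gc12_target: float = 0.33
    gc12_spread: float = 0.05
    neutrality_slope: float = 0.37
    bias_strength: float = 0.0
    class_mixture: float = 0.0
    planted_optimal: tuple[str, ...] | None = None
    met_rate: float = 0.02
    trp_rate: float = 0.02
    aa_frequencies: tuple[float, ...] | None = None  # over the 18 families


@dataclass
class GeneTruth:
    """Planted per-gene ground truth."""

    gene_id: str
    high_bias: bool
    length_nt: int
    gc12_free_target: float
    gc3_free_target: float


@dataclass
class GroundTruth:
    """Planted genome-level ground truth accompanying a synthetic FASTA."""

    genome_id: str
    planted_slope: float
    planted_optimal: tuple[str, ...]
    genes: list[GeneTruth] = field(default_factory=list)


class _FamilyData:
    """Precomputed per-family arrays used by the samplers and solvers."""

    def __init__(self, fam, planted: frozenset[str]):
        self.aa = fam.aa
        self.codons = list(fam.codons)
        self.gc3 = np.array([1.0 if c[2] in _GC else 0.0 for c in fam.codons])
        self.gc12 = np.array(
            [sum(b in _GC for b in c[:2]) / 2.0 for c in fam.codons]
        )
        self.planted = np.array(
            [1.0 if c in planted else 0.0 for c in fam.codons]
        )

    def probs(self, t: float, bias: float) -> np.ndarray:
        w = np.where(self.gc3 > 0, t / 2.0, (1.0 - t) / 2.0)
        if bias:
            w = w * np.exp(bias * self.planted)
        return w / w.sum()


def default_at_planted(space: CodonSpace) -> tuple[str, ...]:
    """One planted preferred codon per family, all A/T-ending.

    Picks the first T-ending codon of each family, falling back to the
    first A-ending one; every family of the supported codes has at least
    one of the two.
    """
    out = []
    for fam in space.families:
        pick = next((c for c in fam.codons if c[2] == "T"), None)
        if pick is None:
            pick = next(c for c in fam.codons if c[2] == "A")
        out.append(pick)
    return tuple(out)


def _bisect(fn, lo: float, hi: float, what: str) -> float:
    f_lo, f_hi = fn(lo), fn(hi)
    if f_lo > 0 or f_hi < 0:
        raise ConfigurationError(
            f"infeasible synthetic spec: {what} target outside achievable "
            f"range [{f_lo:+.4f}, {f_hi:+.4f}] at bracket ends"
        )
    for _ in range(_BISECT_STEPS):
        mid = 0.5 * (lo + hi)
        if fn(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _solve_gene(
    fams: list[_FamilyData],
    base_freq: np.ndarray,
    gc12_free: float,
    gc3_free: float,
) -> tuple[np.ndarray, float]:
    """Family shares and third-base GC weight hitting the gene's targets.

    Solves the mutational background only (no selection bias): alternates
    two monotone bisection problems, an exponential tilt eta on family
    frequencies (expected GC12 is a softmax-weighted mean of family GC12,
    increasing in eta) and the third-base weight t (expected GC3 is
    increasing in t for fixed shares).  The coupling is weak (only the
    six-fold families' GC12 depends on t), so three sweeps converge far
    below sampling noise.  Selection is applied on top of this background
    at sampling time, so planted codon preference shifts a high-bias
    gene's realized composition away from the mutational targets exactly
    the way selection would.
    """
    t = min(max(gc3_free, 1e-4), 1.0 - 1e-4)
    shares = base_freq
    for _ in range(3):
        fam_gc12 = np.array(
            [f.probs(t, 0.0) @ f.gc12 for f in fams]
        )

        def gc12_err(eta: float) -> float:
            w = base_freq * np.exp(eta * fam_gc12)
            w = w / w.sum()
            return float(w @ fam_gc12) - gc12_free

        eta = _bisect(gc12_err, *_ETA_BRACKET, what="GC12")
        shares = base_freq * np.exp(eta * fam_gc12)
        shares = shares / shares.sum()

        def gc3_err(tt: float) -> float:
            fam_gc3 = np.array([f.probs(tt, 0.0) @ f.gc3 for f in fams])
            return float(shares @ fam_gc3) - gc3_free

        t = _bisect(gc3_err, *_T_BRACKET, what="GC3")
    return shares, t


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``."""
    raw = weights / weights.sum() * total
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def generate_genome(
    spec: SyntheticSpec, space: CodonSpace | None = None
) -> tuple[list[RawCDS], GroundTruth]:
    """Sample one genome's CDS set and its planted ground truth."""
    space = space or build_codon_space()
    rng = np.random.default_rng(spec.seed)
    n_fam = len(space.families)

    if spec.aa_frequencies is not None:
        base_freq = np.asarray(spec.aa_frequencies, dtype=float)
        if base_freq.shape != (n_fam,) or (base_freq <= 0).any():
            raise ConfigurationError(
                f"aa_frequencies must be {n_fam} positive weights"
            )
    else:
        base_freq = np.ones(n_fam)
    base_freq = base_freq / base_freq.sum()

    if not 0.0 <= spec.class_mixture <= 1.0:
        raise ConfigurationError("class_mixture must be in [0, 1]")
    planted: tuple[str, ...] = spec.planted_optimal or ()
    if spec.class_mixture > 0 and spec.bias_strength > 0 and not planted:
        planted = default_at_planted(space)
    unknown = set(planted) - set(space.analysis_codons)
    if unknown:
        raise ConfigurationError(f"planted codons outside analysis set: {unknown}")

    fams = [_FamilyData(f, frozenset(planted)) for f in space.families]
    stops = sorted(space.stop_codons)
    lo_nt, hi_nt = spec.length_range
    lo3, hi3 = math.ceil(max(lo_nt, 300) / 3), hi_nt // 3
    if lo3 > hi3:
        raise ConfigurationError(f"empty length range {spec.length_range}")

    n_high = round(spec.class_mixture * spec.n_genes)
    high_idx = set(rng.permutation(spec.n_genes)[:n_high].tolist())

    truth = GroundTruth(
        genome_id=spec.genome_id,
        planted_slope=spec.neutrality_slope,
        planted_optimal=planted,
    )
    genes: list[RawCDS] = []
    for i in range(spec.n_genes):
        gene_id = f"{spec.genome_id}_g{i + 1:03d}"
        high = i in high_idx
        u = rng.uniform(-1.0, 1.0)
        g12 = spec.gc12_target + spec.gc12_spread * u
        g3 = spec.gc3_target + spec.neutrality_slope * spec.gc12_spread * u
        if not (0.0 < g3 < 1.0 and 0.0 < g12 < 1.0):
            raise ConfigurationError(
                f"infeasible synthetic spec: gene targets GC12={g12:.3f}, "
                f"GC3={g3:.3f} outside (0, 1)"
            )
        bias = spec.bias_strength if high else 0.0
        shares, t = _solve_gene(fams, base_freq, g12, g3)

        n_cod = int(rng.integers(lo3, hi3 + 1))
        n_sense = n_cod - 2
        n_met = round(spec.met_rate * n_sense)
        n_trp = round(spec.trp_rate * n_sense)
        n_free = n_sense - n_met - n_trp
        if n_free < n_fam:
            raise ConfigurationError("gene too short for the family mixture")

        fam_counts = _largest_remainder(shares, n_free)
        codons: list[str] = ["ATG"] * n_met + ["TGG"] * n_trp
        for fdata, n_f in zip(fams, fam_counts):
            if n_f == 0:
                continue
            draws = rng.multinomial(n_f, fdata.probs(t, bias))
            for codon, m in zip(fdata.codons, draws):
                codons.extend([codon] * int(m))
        order = rng.permutation(len(codons))
        body = "".join(codons[j] for j in order)
        stop = stops[int(rng.integers(len(stops)))]
        genes.append(RawCDS("ATG" + body + stop, gene_id))
        truth.genes.append(
            GeneTruth(
                gene_id=gene_id,
                high_bias=high,
                length_nt=3 * n_cod,
                gc12_free_target=g12,
                gc3_free_target=g3,
            )
        )
    return genes, truth


def write_fasta(genes: Sequence[RawCDS], path: str, width: int = 70) -> None:
    """Write generated CDSs as FASTA (byte-deterministic)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f">{g.source_id}\n")
            for i in range(0, len(g.seq), width):
                fh.write(g.seq[i : i + width] + "\n")


def generate_cohort(
    specs: Sequence[SyntheticSpec],
    outdir: str,
    space: CodonSpace | None = None,
) -> dict[str, tuple[str, GroundTruth]]:
    """Generate one FASTA per spec plus a ground-truth manifest.

    Returns a map genome_id -> (fasta path, ground truth).  The manifest
    (``manifest.tsv``) and per-genome truth (``ground_truth.json``) make the
    directory directly consumable as pipeline input with known answers.
    """
    if not specs:
        raise ConfigurationError("need at least one spec")
    ids = [s.genome_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ConfigurationError("duplicate genome ids in cohort")
    space = space or build_codon_space()
    os.makedirs(outdir, exist_ok=True)
    out: dict[str, tuple[str, GroundTruth]] = {}
    manifest_rows = []
    truth_blob = {}
    for spec in specs:
        genes, truth = generate_genome(spec, space)
        path = os.path.join(outdir, f"{spec.genome_id}.fasta")
        write_fasta(genes, path)
        out[spec.genome_id] = (path, truth)
        manifest_rows.append(
            (
                spec.genome_id,
                f"{spec.genome_id}.fasta",
                str(spec.n_genes),
                f"{spec.gc3_target:.4f}",
                f"{spec.neutrality_slope:.4f}",
                f"{spec.bias_strength:.4f}",
                f"{spec.class_mixture:.4f}",
            )
        )
        truth_blob[spec.genome_id] = {
            "spec": asdict(spec),
            "planted_slope": truth.planted_slope,
            "planted_optimal": list(truth.planted_optimal),
            "genes": [asdict(g) for g in truth.genes],
        }
    with open(os.path.join(outdir, "manifest.tsv"), "w") as fh:
        fh.write(
            "genome_id\tfasta\tn_genes\tgc3_target\tplanted_slope\t"
            "bias_strength\tclass_mixture\n"
        )
        for row in manifest_rows:
            fh.write("\t".join(row) + "\n")
    with open(os.path.join(outdir, "ground_truth.json"), "w") as fh:
        json.dump(truth_blob, fh, indent=1, sort_keys=True)
    return out
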