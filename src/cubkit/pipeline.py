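"""End-to-end orchestration: per-genome and cross-genome codon-usage reports.

``run_genome`` executes the full chain — CDS filtering, composition, RSCU,
ENC/CAI/CBI, optimal codons, selection diagnostics, correspondence analysis
with Axis-1 correlations — and writes tab-separated tables (plus optional
SVG figures, each with a TSV twin holding exactly the plotted values).
``run_cohort`` adds the cross-genome artifacts: the shared high-frequency
codon set with its codon-ending tally, the genomes x 59 RSCU matrix, a
per-genome composition table and ENC summary (average ENC, genes below the
strong-bias threshold of 35, genes in [35, 61]), and the neutrality-slope
summary.

The CAI reference set is the genome's own low-ENC decile (self-contained:
no foreign-organism reference), and the CBI optimal set is the genome's own
identified optimal codons.  All outputs are deterministic for a fixed
config; run metadata carries a config fingerprint.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import __version__
from .cds_io import (
    FilterReport,
    GeneRecord,
    RawCDS,
    extract_cds,
    filter_cds,
    write_filter_report,
)
from .composition import composition_stats, genome_composition, pooled_counts
from .exceptions import CodonUsageError, StatisticUndefinedError
from .genetic_code import CodonSpace, build_codon_space, to_rna
from .indices import (
    OptimalCodonResult,
    cai,
    cbi,
    enc,
    high_frequency_codons,
    optimal_codons,
    reference_w_from_high_set,
    rscu,
)
from .ordination import CAResult, axis1_correlations, correspondence_analysis, orient_axes
from .selection import (
    NeutralityFit,
    enc_expected,
    enc_ratio_histogram,
    neutrality_fit,
    selection_diagnostics,
)

ENC_STRONG_BIAS = 35.0


@dataclass(frozen=True)
class RunConfig:
    """Dialect switches and thresholds of one analysis run."""

    output_dir: str
    code_id: str = "standard"
    synonymous_only: bool = True
    neutrality_orientation: str = "gc12_x"  # x = GC12, y = GC3
    rscu_scope: str = "high_group"
    high_group_low_enc: bool = True
    correlation_method: str = "spearman"
    decile: float = 0.10
    delta_rscu_threshold: float = 0.08
    enc_strong_threshold: float = ENC_STRONG_BIAS
    cai_w_floor: float = 0.01
    enc_ratio_bin_width: float = 0.05
    make_figures: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.decile <= 0.5:
            raise ValueError("decile must be in (0, 0.5]")
        if self.delta_rscu_threshold <= 0 or self.enc_strong_threshold <= 0:
            raise ValueError("thresholds must be positive")

    def fingerprint(self) -> str:
        """Hash of the analysis-relevant settings (where outputs land and
        whether figures are drawn do not change any computed value)."""
        d = dataclasses.asdict(self)
        d.pop("output_dir")
        d.pop("make_figures")
        blob = json.dumps(d, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class GenomeResult:
    """All per-genome artifacts, kept in memory and mirrored as TSVs."""

    genome_id: str
    filter_report: FilterReport
    genes: list[GeneRecord]
    composition_row: dict
    gene_table: pd.DataFrame
    rscu_pooled: dict[str, float]
    optimal: OptimalCodonResult
    diagnostics: pd.DataFrame
    neutrality: NeutralityFit
    ca: CAResult
    correlations: pd.DataFrame
    enc_summary: dict


@dataclass
class CohortResult:
    """Cross-genome artifacts plus per-genome results and failures."""

    genomes: dict[str, GenomeResult]
    failures: dict[str, str]
    shared_high_frequency: frozenset[str]
    ending_tally: dict[str, int]
    rscu_matrix: pd.DataFrame
    slope_summary: dict


def _load_genes(
    source, genome_id: str, space: CodonSpace
) -> tuple[list[GeneRecord], FilterReport]:
    if isinstance(source, str):
        raw = extract_cds(source, genome_id)
    else:
        raw = list(source)  # RawCDS or str sequences
    return filter_cds(raw, space, genome_id)


def _per_gene_variable_table(
    genes: list[GeneRecord],
    space: CodonSpace,
    config: RunConfig,
    optimal: OptimalCodonResult,
    reference_w: dict[str, float],
) -> pd.DataFrame:
    rows = []
    for g in genes:
        try:
            comp = composition_stats(g.codon_counts, space, g.gene_id)
            enc_g = enc(g.codon_counts, space, g.gene_id).enc_obs
        except StatisticUndefinedError:
            continue
        try:
            cai_g = cai(g.codon_counts, reference_w, space, config.cai_w_floor)
        except StatisticUndefinedError:
            cai_g = float("nan")
        try:
            cbi_g = cbi(g.codon_counts, optimal.optimal_codons, space)
        except (StatisticUndefinedError, CodonUsageError):
            cbi_g = float("nan")
        rows.append(
            {
                "gene_id": g.gene_id,
                "GC1": comp.gc1,
                "GC2": comp.gc2,
                "GC3": comp.gc3,
                "GC3s": comp.gc3s,
                "GC_all": comp.gc_all,
                "ENC": enc_g,
                "CAI": cai_g,
                "CBI": cbi_g,
                "L_aa": g.L_aa,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def run_genome(
    config: RunConfig,
    source,
    genome_id: str,
    space: CodonSpace | None = None,
    write: bool = True,
) -> GenomeResult:
    """Run the full per-genome analysis.

    ``source`` is a GenBank/FASTA path, or an in-memory list of RawCDS /
    sequence strings (synthetic input).
    """
    space = space or build_codon_space(config.code_id)
    genes, report = _load_genes(source, genome_id, space)
    if not genes:
        raise CodonUsageError(f"{genome_id}: no gene passed filtering")

    comp = genome_composition(genes, space, genome_id)
    pooled = pooled_counts(genes)
    rscu_pooled = rscu(pooled, space, genome_id).rscu

    optimal = optimal_codons(
        genes,
        space,
        decile=config.decile,
        delta_threshold=config.delta_rscu_threshold,
        high_group_low_enc=config.high_group_low_enc,
        rscu_scope=config.rscu_scope,
        genome_id=genome_id,
    )
    high_set = {g for g in optimal.high_group}
    reference_w = reference_w_from_high_set(
        [g for g in genes if g.gene_id in high_set], space, config.cai_w_floor
    )

    gene_table = _per_gene_variable_table(genes, space, config, optimal, reference_w)
    diagnostics = selection_diagnostics(genes, space)
    fit = neutrality_fit(
        diagnostics[["gc12", "gc3"]].to_numpy(),
        genome_id,
        orientation=config.neutrality_orientation,
    )

    rscu_rows = pd.DataFrame(
        {
            g.gene_id: rscu(g.codon_counts, space, g.gene_id).rscu
            for g in genes
        }
    ).T.reindex(columns=list(space.analysis_codons))
    ca = correspondence_analysis(rscu_rows)
    if ca.n_axes > 0:
        gc3s_ref = diagnostics.set_index("gene_id")["gc3s"].reindex(rscu_rows.index)
        ca = orient_axes(ca, gc3s_ref.to_numpy(), axes=(1,))
        per_gene = gene_table.reindex(ca.row_scores.index)
        corr_frames = [
            axis1_correlations(ca, per_gene, method=m)
            for m in (config.correlation_method,
                      "pearson" if config.correlation_method == "spearman" else "spearman")
        ]
        correlations = pd.concat(corr_frames, ignore_index=True)
    else:
        correlations = pd.DataFrame(
            columns=["variable_a", "variable_b", "coefficient", "p_value", "method"]
        )

    enc_vals = gene_table["ENC"].to_numpy()
    enc_summary = {
        "genome_id": genome_id,
        "average_enc": float(np.mean(enc_vals)),
        "n_enc_below_35": int(np.sum(enc_vals < config.enc_strong_threshold)),
        "n_enc_35_to_61": int(
            np.sum((enc_vals >= config.enc_strong_threshold) & (enc_vals <= 61.0))
        ),
        "n_genes": int(len(enc_vals)),
    }

    composition_row = {
        "genome_id": genome_id,
        "A3_pct": round(100 * comp.a3, 2),
        "T3_pct": round(100 * comp.t3, 2),
        "C3_pct": round(100 * comp.c3, 2),
        "G3_pct": round(100 * comp.g3, 2),
        "GC_pct": round(100 * comp.gc_all, 2),
        "GC1_pct": round(100 * comp.gc1, 2),
        "GC2_pct": round(100 * comp.gc2, 2),
        "GC3_pct": round(100 * comp.gc3, 2),
        "GC3s_pct": round(100 * comp.gc3s, 2),
    }

    result = GenomeResult(
        genome_id=genome_id,
        filter_report=report,
        genes=genes,
        composition_row=composition_row,
        gene_table=gene_table,
        rscu_pooled=rscu_pooled,
        optimal=optimal,
        diagnostics=diagnostics,
        neutrality=fit,
        ca=ca,
        correlations=correlations,
        enc_summary=enc_summary,
    )
    if write:
        _write_genome(config, result, space)
    return result


def _tsv(df: pd.DataFrame, path: str, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def _write_genome(config: RunConfig, res: GenomeResult, space: CodonSpace) -> None:
    outdir = os.path.join(config.output_dir, res.genome_id)
    os.makedirs(outdir, exist_ok=True)
    fp = config.fingerprint()

    write_filter_report([res.filter_report], os.path.join(outdir, "filter_report.tsv"))
    _tsv(res.gene_table.reset_index(), os.path.join(outdir, "gene_indices.tsv"))
    _tsv(res.diagnostics, os.path.join(outdir, "diagnostics.tsv"))

    rscu_df = pd.DataFrame(
        {
            "codon": list(space.analysis_codons),
            "codon_rna": [to_rna(c) for c in space.analysis_codons],
            "amino_acid": [space.family_of[c] for c in space.analysis_codons],
            "rscu": [res.rscu_pooled[c] for c in space.analysis_codons],
        }
    )
    _tsv(rscu_df, os.path.join(outdir, "rscu.tsv"))

    opt = res.optimal
    opt_df = pd.DataFrame(
        {
            "codon": list(space.analysis_codons),
            "rscu_high": [opt.rscu_high[c] for c in space.analysis_codons],
            "rscu_low": [opt.rscu_low[c] for c in space.analysis_codons],
            "delta_rscu": [opt.delta_rscu[c] for c in space.analysis_codons],
            "optimal": [c in opt.optimal_codons for c in space.analysis_codons],
        }
    )
    _tsv(opt_df, os.path.join(outdir, "optimal_codons.tsv"))

    hist = enc_ratio_histogram(
        res.diagnostics["enc_ratio"], config.enc_ratio_bin_width
    )
    _tsv(hist, os.path.join(outdir, "enc_ratio_hist.tsv"))

    neut = pd.DataFrame(
        [
            {
                "genome_id": res.genome_id,
                "slope": res.neutrality.slope,
                "intercept": res.neutrality.intercept,
                "r": res.neutrality.r,
                "p_value": res.neutrality.p_value,
                "mutation_pct": res.neutrality.mutation_pct,
                "selection_pct": res.neutrality.selection_pct,
                "orientation": res.neutrality.orientation,
                "config_fp": fp,
            }
        ]
    )
    _tsv(neut, os.path.join(outdir, "neutrality.tsv"))

    if res.ca.n_axes > 0:
        _tsv(res.ca.row_scores.reset_index(names="gene_id"),
             os.path.join(outdir, "ca_row_scores.tsv"))
        _tsv(res.ca.col_scores.reset_index(names="codon"),
             os.path.join(outdir, "ca_col_scores.tsv"))
        scree = pd.DataFrame(
            {
                "axis": np.arange(1, res.ca.n_axes + 1),
                "inertia_pct": res.ca.inertia_pct,
            }
        )
        _tsv(scree, os.path.join(outdir, "ca_scree.tsv"))
    _tsv(res.correlations, os.path.join(outdir, "correlations.tsv"))

    if config.make_figures:
        _figures(config, res, outdir)


def _figures(config: RunConfig, res: GenomeResult, outdir: str) -> None:
    diag = res.diagnostics

    fig, ax = plt.subplots(figsize=(5, 4))
    s_grid = np.arange(0.0, 1.0001, 0.001)
    ax.plot(s_grid, [enc_expected(s) for s in s_grid], "k-", lw=1, label="expected")
    ax.scatter(diag["gc3s"], diag["enc_obs"], s=12, alpha=0.7)
    ax.set_xlabel("GC3s")
    ax.set_ylabel("ENC")
    ax.legend()
    fig.savefig(os.path.join(outdir, "enc_plot.svg"))
    plt.close(fig)

    hist = enc_ratio_histogram(diag["enc_ratio"], config.enc_ratio_bin_width)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.bar(hist["bin_left"], hist["count"], width=config.enc_ratio_bin_width,
           align="edge", edgecolor="k")
    ax.set_xlabel("ENC ratio")
    ax.set_ylabel("genes")
    fig.savefig(os.path.join(outdir, "enc_ratio_hist.svg"))
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ok = diag["pr2_defined"]
    ax.scatter(diag.loc[ok, "pr2_x"], diag.loc[ok, "pr2_y"], s=12, alpha=0.7)
    ax.axhline(0.5, color="k", lw=0.8)
    ax.axvline(0.5, color="k", lw=0.8)
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel("G3/(G3+C3)")
    ax.set_ylabel("A3/(A3+T3)")
    fig.savefig(os.path.join(outdir, "pr2_plot.svg"))
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    x, y = ("gc12", "gc3") if res.neutrality.orientation == "gc12_x" else ("gc3", "gc12")
    ax.scatter(diag[x], diag[y], s=12, alpha=0.7)
    xv = np.linspace(diag[x].min(), diag[x].max(), 10)
    ax.plot(xv, res.neutrality.intercept + res.neutrality.slope * xv, "k-",
            label=f"slope={res.neutrality.slope:.3f}")
    ax.set_xlabel(x.upper())
    ax.set_ylabel(y.upper())
    ax.legend()
    fig.savefig(os.path.join(outdir, "neutrality_plot.svg"))
    plt.close(fig)

    if res.ca.n_axes >= 2:
        fig, ax = plt.subplots(figsize=(5, 4.5))
        ax.scatter(res.ca.row_scores["Axis1"], res.ca.row_scores["Axis2"],
                   s=12, alpha=0.7, label="genes")
        ax.scatter(res.ca.col_scores["Axis1"], res.ca.col_scores["Axis2"],
                   s=10, marker="x", color="crimson", label="codons")
        ax.axhline(0, color="k", lw=0.5)
        ax.axvline(0, color="k", lw=0.5)
        ax.set_xlabel(f"Axis 1 ({res.ca.inertia_pct[0]:.1f}%)")
        ax.set_ylabel(f"Axis 2 ({res.ca.inertia_pct[1]:.1f}%)")
        ax.legend()
        fig.savefig(os.path.join(outdir, "ca_biplot.svg"))
        plt.close(fig)


def run_cohort(
    config: RunConfig,
    sources: dict[str, object],
    space: CodonSpace | None = None,
    write: bool = True,
) -> CohortResult:
    """Run every genome and assemble the cross-genome report.

    ``sources`` maps genome_id -> path or in-memory CDS list.  A failing
    genome is recorded and the cohort continues.
    """
    space = space or build_codon_space(config.code_id)
    genomes: dict[str, GenomeResult] = {}
    failures: dict[str, str] = {}
    for gid, src in sources.items():
        try:
            genomes[gid] = run_genome(config, src, gid, space, write=write)
        except CodonUsageError as exc:
            failures[gid] = str(exc)

    if not genomes:
        raise CodonUsageError("every genome failed")

    hf_sets = [
        high_frequency_codons(
            rscu(pooled_counts(r.genes), space, gid)
        )
        for gid, r in genomes.items()
    ]
    shared = frozenset.intersection(*hf_sets)
    ending = {b: sum(1 for c in shared if c[2] == b) for b in "ATCG"}

    rscu_matrix = pd.DataFrame(
        {gid: r.rscu_pooled for gid, r in genomes.items()}
    ).T.reindex(columns=list(space.analysis_codons))
    slopes = np.array([r.neutrality.slope for r in genomes.values()])
    slope_summary = {
        "min_slope": float(slopes.min()),
        "max_slope": float(slopes.max()),
        "mean_slope": float(slopes.mean()),
        "n_genomes": int(len(slopes)),
    }

    result = CohortResult(
        genomes=genomes,
        failures=failures,
        shared_high_frequency=shared,
        ending_tally=ending,
        rscu_matrix=rscu_matrix,
        slope_summary=slope_summary,
    )
    if write:
        _write_cohort(config, result, space)
    return result


def _write_cohort(config: RunConfig, res: CohortResult, space: CodonSpace) -> None:
    outdir = config.output_dir
    os.makedirs(outdir, exist_ok=True)
    fp = config.fingerprint()

    table1 = pd.DataFrame([r.composition_row for r in res.genomes.values()])
    table1["config_fp"] = fp
    _tsv(table1, os.path.join(outdir, "composition_table.tsv"))

    table2 = pd.DataFrame([r.enc_summary for r in res.genomes.values()])
    table2["average_enc"] = table2["average_enc"].round(2)
    table2["config_fp"] = fp
    _tsv(table2, os.path.join(outdir, "enc_summary_table.tsv"))

    shared_df = pd.DataFrame(
        {
            "codon": sorted(res.shared_high_frequency),
            "codon_rna": [to_rna(c) for c in sorted(res.shared_high_frequency)],
            "ending_base": [c[2] for c in sorted(res.shared_high_frequency)],
        }
    )
    _tsv(shared_df, os.path.join(outdir, "shared_high_frequency_codons.tsv"))

    _tsv(res.rscu_matrix.reset_index(names="genome_id"),
         os.path.join(outdir, "rscu_matrix.tsv"))

    neut = pd.DataFrame(
        [
            {
                "genome_id": gid,
                "slope": r.neutrality.slope,
                "mutation_pct": r.neutrality.mutation_pct,
                "selection_pct": r.neutrality.selection_pct,
            }
            for gid, r in res.genomes.items()
        ]
    )
    _tsv(neut, os.path.join(outdir, "neutrality_slopes.tsv"))

    meta = {
        "tool": "cubkit",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "config_fingerprint": fp,
        "n_genomes": len(res.genomes),
        "failures": res.failures,
        "ending_tally": res.ending_tally,
        "slope_summary": res.slope_summary,
    }
    with open(os.path.join(outdir, "run_metadata.json"), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
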