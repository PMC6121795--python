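"""End-to-end orchestration: run every stage on one dataset directory and
emit the integrated per-gene report.

Stage outputs are TSV files whose headers carry the package version, the
seed, and a digest of the parameters, so a rerun with the same inputs and
seed is byte-identical and every number in the report traces to exactly
one stage file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from . import io as obpio
from .cnv import CoverageTable, coverage_fold_test, detect_deletions, detect_duplications
from .coexpression import (
    CoexpressionConfig,
    adjacency_tom,
    detect_modules,
    eigengene_group_test,
    module_eigengene,
    module_overlap_fisher,
)
from .divergence import (
    annotate_with_gene,
    classify_codon_changes,
    estimate_dnds,
    find_fixed_differences,
    polarize_substitutions,
    summarize_gene,
)
from .diversity import pi_per_window, sweep_candidates
from .expression import (
    direction_binomial_test,
    ks_pvalue_shift,
    nb_wald_test,
    region_enrichment_chi2,
)
from .genome import SampleVariant, extract_cds, translate_and_flag

log = logging.getLogger("obpdiv")


@dataclass
class PipelineConfig:
    data_dir: str
    out_dir: str
    group_a: str = "SB"
    group_b: str = "Sb"
    outgroup: str = "outgroup"
    min_called: Optional[int] = None  # None -> full group size
    window_bp: int = 10_000
    sweep_quantile: float = 0.25
    alpha: float = 0.05
    fold_threshold: float = 1.75
    coexpress_top_genes: int = 300
    seed: int = 0
    stages: tuple[str, ...] = (
        "divergence", "cnv", "diversity", "expression", "coexpress", "report",
    )

    def digest(self) -> str:
        # parameters only: paths do not alter results and would break
        # byte-identity of reruns in different directories
        params = {k: v for k, v in asdict(self).items()
                  if k not in ("data_dir", "out_dir")}
        payload = json.dumps(params, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _header(config: PipelineConfig, stage: str) -> str:
    return (
        f"obpdiv {__version__} | stage={stage} | seed={config.seed} "
        f"| params={config.digest()}"
    )


def _allele_cds(cds, diffs, which: str):
    """Allele-specific CDS from the SNP fixed differences of one gene."""
    # the reference may match either lineage; apply each lineage's alleles
    # on top of the reference by substituting that lineage's base
    variants = [
        SampleVariant(
            d.scaffold, d.pos,
            ref="N",  # unused for SNP substitution
            alt=d.allele_b if which == "B" else d.allele_a,
        )
        for d in diffs
        if not d.is_indel
    ]
    from .genome import apply_haplotype

    return apply_haplotype(cds, variants)


def run_divergence(config: PipelineConfig, data: Path, out: Path) -> pd.DataFrame:
    genome = obpio.read_fasta(data / "reference.fasta")
    models = obpio.read_gff3(data / "genes.gff3")
    geno = obpio.read_vcf(data / "genotypes.vcf", data / "groups.tsv")
    diffs = find_fixed_differences(
        geno, config.group_a, config.group_b, config.min_called
    )
    pols = polarize_substitutions(geno, diffs, config.outgroup)
    pol_by_site = {(p.scaffold, p.pos): p for p in pols}
    rows = []
    for m in models:
        cds = extract_cds(genome, m)
        gene_diffs = annotate_with_gene(diffs, cds)
        snps = [d for d in gene_diffs if not d.is_indel]
        indels = [d for d in gene_diffs if d.is_indel]
        cds_a = _allele_cds(cds, snps, "A")
        cds_b = _allele_cds(cds, snps, "B")
        changes = classify_codon_changes(
            # allele CDSs built by substitution only: always codon-aligned
            cds_a, cds_b
        )
        notes = []
        _prot_a, stop_a = translate_and_flag(cds_a)
        _prot_b, stop_b = translate_and_flag(cds_b)
        if stop_a.premature:
            notes.append(
                f"premature stop in {config.group_a} at codon "
                f"{stop_a.position} of {stop_a.n_codons}"
            )
        if stop_b.premature:
            notes.append(
                f"premature stop in {config.group_b} at codon "
                f"{stop_b.position} of {stop_b.n_codons}"
            )
        for d in indels:
            span = abs(len(d.allele_a) - len(d.allele_b))
            kind = "insertion" if len(d.allele_b) > len(d.allele_a) else "deletion"
            shift = "frameshift " if span % 3 else ""
            notes.append(
                f"{shift}{kind} of {span} bp at codon {d.codon_index} "
                f"(nucleotide position {(d.codon_index - 1) * 3 + d.position_in_codon})"
            )
        dnds = estimate_dnds(cds_a, cds_b)
        gene_pols = [
            pol_by_site[(d.scaffold, d.pos)]
            for d in snps
            if (d.scaffold, d.pos) in pol_by_site
        ]
        s = summarize_gene(m.gene_id, changes, gene_pols, dnds, "; ".join(notes))
        rows.append({
            "gene_id": s.gene_id,
            "in_supergene": m.in_supergene,
            "n_nonsynonymous": s.n_nonsynonymous,
            "n_synonymous": s.n_synonymous,
            "n_nonsense": s.n_nonsense,
            "n_total": s.n_total,
            "dn": s.dn, "ds": s.ds, "dnds": s.dnds,
            "n_derived_on_b": s.n_derived_on_b,
            "n_derived_on_a": s.n_derived_on_a,
            "n_unresolved": s.n_unresolved,
            "structural_notes": s.structural_notes,
        })
    summary = pd.DataFrame(rows, columns=[
        "gene_id", "in_supergene", "n_nonsynonymous", "n_synonymous",
        "n_nonsense", "n_total", "dn", "ds", "dnds", "n_derived_on_b",
        "n_derived_on_a", "n_unresolved", "structural_notes",
    ])
    obpio.write_table(out / "divergence_summary.tsv", summary,
                      _header(config, "divergence"))
    obpio.write_table(
        out / "fixed_differences.tsv",
        pd.DataFrame([vars(d) for d in diffs],
                     columns=["scaffold", "pos", "allele_a", "allele_b",
                              "n_called_a", "n_called_b", "is_indel",
                              "gene_id", "codon_index", "position_in_codon"]),
        _header(config, "divergence"),
    )
    obpio.write_table(
        out / "polarization.tsv",
        pd.DataFrame([vars(p) for p in pols],
                     columns=["scaffold", "pos", "allele_a", "allele_b",
                              "outgroup_state", "ancestral_allele",
                              "derived_on"]),
        _header(config, "divergence"),
    )
    return summary


def run_cnv(config: PipelineConfig, data: Path, out: Path) -> pd.DataFrame:
    genes = obpio.read_table(data / "coverage_genes.tsv")
    windows = obpio.read_table(data / "coverage_windows.tsv")
    background = (data / "background_units.txt").read_text().split()
    groups = obpio.read_groups(data / "groups.tsv")
    models = obpio.read_gff3(data / "genes.gff3")
    cov = CoverageTable(genes, background)
    by_group = {
        g: [s for s, gg in groups.items() if gg == g]
        for g in (config.group_a, config.group_b)
    }
    rows = []
    focal = [m.gene_id for m in models]
    results = {}
    for unit in focal:
        per_group = {}
        for g, samples in by_group.items():
            r = coverage_fold_test(cov, unit, "multi-sample", samples,
                                   config.alpha)
            per_group[g] = r
            rows.append({
                "unit": unit, "group": g, "fold": r.fold,
                "ci_low": r.ci_low, "ci_high": r.ci_high,
                "t_statistic": r.t_statistic, "df": r.df,
                "p_value": r.p_value, "mode": r.mode,
            })
        results[unit] = per_group
    tests = pd.DataFrame(rows)
    obpio.write_table(out / "coverage_tests.tsv", tests, _header(config, "cnv"))
    calls = []
    for unit, per_group in results.items():
        for dup in detect_duplications(per_group, config.fold_threshold):
            calls.append({
                "type": "duplication", "unit": dup.unit,
                "carrier_group": dup.carrier_group, "copies": dup.copies,
                "detail": json.dumps(dup.fold_by_group),
            })
    wcov = CoverageTable(windows, [])
    for carrier, other in ((config.group_b, config.group_a),
                           (config.group_a, config.group_b)):
        for d in detect_deletions(wcov, groups, carrier, other, models):
            calls.append({
                "type": "deletion",
                "unit": f"{d.scaffold}:{d.start}-{d.end}",
                "carrier_group": d.carrier_group,
                "copies": 0,
                "detail": json.dumps({
                    "length": d.length, "genes": d.genes,
                    "exons_lost": {k: list(v) for k, v in d.exons_lost.items()},
                    "coding_bp_lost": d.coding_bp_lost,
                    "frameshift": d.frameshift,
                }),
            })
    calls_df = pd.DataFrame(
        calls, columns=["type", "unit", "carrier_group", "copies", "detail"]
    )
    obpio.write_table(out / "cnv_calls.tsv", calls_df, _header(config, "cnv"))
    return calls_df


def run_diversity(config: PipelineConfig, data: Path, out: Path) -> pd.DataFrame:
    genome = obpio.read_fasta(data / "reference.fasta")
    models = obpio.read_gff3(data / "genes.gff3")
    geno = obpio.read_vcf(data / "genotypes.vcf", data / "groups.tsv")
    lengths = {k: len(v) for k, v in genome.sequences.items()}
    # the sweep scan targets the recombining lineage only: the entire
    # non-recombining haplotype carries a sweep signature and is excluded
    windows = pi_per_window(geno, config.group_a, lengths, config.window_bp)
    threshold, runs = sweep_candidates(windows, models, config.sweep_quantile)
    df = pd.DataFrame([
        {"scaffold": w.scaffold, "start": w.start, "end": w.end,
         "n_sites": w.n_sites_called, "pi": w.pi, "flagged": w.flagged}
        for w in windows
    ])
    obpio.write_table(out / "pi_windows.tsv", df, _header(config, "diversity")
                      + f" | pi_quantile_threshold={threshold:.6g}")
    with open(out / "sweep_runs.bed", "w") as fh:
        for r in runs:
            fh.write(
                f"{r.scaffold}\t{r.start}\t{r.end}\t{','.join(r.genes)}\t"
                f"{r.min_pi:.6g}\n"
            )
    return df


def run_expression(config: PipelineConfig, data: Path, out: Path) -> dict:
    models = obpio.read_gff3(data / "genes.gff3")
    supergene = {m.gene_id for m in models if m.in_supergene}
    focal = [m.gene_id for m in models]
    out_stats = {}
    for caste in ("queen", "worker"):
        counts_path = data / f"counts_{caste}.tsv"
        if not counts_path.exists():
            log.warning("no counts for caste %s; skipped", caste)
            continue
        counts = obpio.read_table(counts_path).set_index("gene_id")
        meta = obpio.read_table(data / f"samples_{caste}.tsv").set_index("sample")
        de = nb_wald_test(counts, meta["social_form"], config.alpha)
        obpio.write_table(out / f"de_results_{caste}.tsv", de,
                          _header(config, "expression")
                          + f" | method={de.attrs['method']}")
        tested = de.dropna(subset=["p_value"])
        universe = set(tested.gene_id)
        n_universe = len(universe)
        expected = len(supergene & universe) / n_universe if n_universe else 0.0
        sig = tested[tested.significant]
        enr = []
        if len(sig) and 0 < expected < 1:
            chi = region_enrichment_chi2(
                int(sig.gene_id.isin(supergene).sum()), len(sig), expected)
            enr.append({"caste": caste, **_enr_row(chi)})
        focal_sig = sig[sig.gene_id.isin(focal)]
        if len(focal_sig):
            k = int((focal_sig.direction > 0).sum())
            k = max(k, int((focal_sig.direction < 0).sum()))
            binom = direction_binomial_test(k, len(focal_sig))
            enr.append({"caste": caste, **_enr_row(binom)})
        focal_p = tested.loc[tested.gene_id.isin(focal), "p_value"]
        rest_p = tested.loc[~tested.gene_id.isin(focal), "p_value"]
        if len(focal_p) and len(rest_p):
            ks = ks_pvalue_shift(focal_p, rest_p)
            enr.append({"caste": caste, **_enr_row(ks)})
        out_stats[caste] = {"de": de, "enrichment": enr}
    all_enr = [row for st in out_stats.values() for row in st["enrichment"]]
    obpio.write_table(out / "enrichment.tsv", pd.DataFrame(all_enr),
                      _header(config, "expression"))
    return out_stats


def _enr_row(e) -> dict:
    return {"statistic_name": e.statistic_name, "statistic": e.statistic,
            "p_value": e.p_value, "inputs": json.dumps(e.inputs)}


def run_coexpress(config: PipelineConfig, data: Path, out: Path) -> None:
    assignments = {}
    for caste in ("queen", "worker"):
        counts_path = data / f"counts_{caste}.tsv"
        if not counts_path.exists():
            continue
        counts = obpio.read_table(counts_path).set_index("gene_id")
        meta = obpio.read_table(data / f"samples_{caste}.tsv").set_index("sample")
        expr = np.log1p(counts)
        top = expr.var(axis=1).nlargest(config.coexpress_top_genes).index
        expr = expr.loc[top]
        cconf = CoexpressionConfig()
        tom = adjacency_tom(expr, cconf)
        assign = detect_modules(tom, cconf)
        assignments[caste] = assign
        obpio.write_table(
            out / f"modules_{caste}.tsv",
            assign.labels.rename("module").rename_axis("gene_id").reset_index(),
            _header(config, "coexpress"),
        )
        eigengenes = [
            module_eigengene(expr, assign, mod) for mod in assign.modules()
        ]
        if eigengenes:
            eg_df = pd.DataFrame({e.module: e.scores for e in eigengenes})
            obpio.write_table(out / f"eigengenes_{caste}.tsv",
                              eg_df.rename_axis("sample").reset_index(),
                              _header(config, "coexpress"))
            tests = eigengene_group_test(
                eigengenes, meta["social_form"],
                "multiple-queen", "single-queen",
            )
            obpio.write_table(out / f"module_tests_{caste}.tsv", tests,
                              _header(config, "coexpress"))
    if len(assignments) == 2:
        overlap = module_overlap_fisher(assignments["queen"],
                                        assignments["worker"])
        obpio.write_table(out / "module_overlap.tsv", overlap,
                          _header(config, "coexpress"))


def report_table(
    divergence_summary: pd.DataFrame,
    de_by_caste: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """One row per gene: substitution counts, structural notes, and
    DE-in-queens / DE-in-workers flags."""
    out = divergence_summary.copy()
    for caste in ("queen", "worker"):
        col = f"de_in_{caste}s"
        de = de_by_caste.get(caste)
        if de is None:
            out[col] = "NA"
            continue
        sig = de.set_index("gene_id")["significant"]
        out[col] = [
            ("Yes" if bool(sig.get(g, False)) else "No") if g in sig.index else "NA"
            for g in out.gene_id
        ]
    return out


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages in dependency order; outputs land in
    ``config.out_dir``.  Missing inputs fail fast with the offending path."""
    data = Path(config.data_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for required in ("reference.fasta", "genes.gff3", "genotypes.vcf",
                     "groups.tsv"):
        if not (data / required).exists():
            raise FileNotFoundError(data / required)
    summary = None
    de_by_caste: dict[str, pd.DataFrame] = {}
    if "divergence" in config.stages:
        log.info("stage: divergence")
        summary = run_divergence(config, data, out)
    if "cnv" in config.stages:
        log.info("stage: cnv")
        run_cnv(config, data, out)
    if "diversity" in config.stages:
        log.info("stage: diversity")
        run_diversity(config, data, out)
    if "expression" in config.stages:
        log.info("stage: expression")
        stats = run_expression(config, data, out)
        de_by_caste = {c: s["de"] for c, s in stats.items()}
    if "coexpress" in config.stages:
        log.info("stage: coexpress")
        run_coexpress(config, data, out)
    if "report" in config.stages and summary is not None:
        log.info("stage: report")
        obpio.write_table(out / "report.tsv",
                          report_table(summary, de_by_caste),
                          _header(config, "report"))
    return out
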