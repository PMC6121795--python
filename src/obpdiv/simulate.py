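"""Synthetic SB/Sb/outgroup datasets with known truth.

The generator emulates the study design this toolkit targets: seven
haploid males per supergene haplotype group plus one pooled outgroup
library from a species that split before the SB/Sb divergence.  It emits a
reference assembly (one scaffold per linkage group), gene models, a
haploid VCF, per-gene and per-window coverage tables, and gene x sample
expression counts — together with truth tables recording every planted
event, so each downstream stage can be verified exactly.

What is planted, by default:

* coding substitutions with exact synonymous/nonsynonymous counts in
  supergene genes (rejection-sampled so the truth counts are exact);
* a premature-stop allele on one lineage and a frameshifting 17-bp
  insertion on the other in one gene;
* a group-specific ~2.6 kb deletion removing 3 of 5 coding exons
  (89 of 139 codons, no frameshift);
* a two-copy lineage-specific duplication and a four-copy duplication
  shared by both lineages;
* a low-diversity ("swept") interval covering two 10-kb windows over a
  tight cluster of three genes;
* negative-binomial expression with all-positive social-form effects on
  the designated focal genes.

Within-group diversity is two orders of magnitude lower on Sb than on SB,
matching the suppressed-recombination sweep signature of the system.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome import (
    MISSING,
    STOP_CODONS,
    CodingSequence,
    GeneModel,
    GenomeRef,
    HaploidGenotypeMatrix,
    extract_cds,
    revcomp,
    translate_codon,
)
from . import io as obpio

SENSE_CODONS = [
    "".join(c) for c in itertools.product("ACGT", repeat=3)
    if "".join(c) not in STOP_CODONS and "".join(c) != "ATG"
]

GROUP_A = "SB"
GROUP_B = "Sb"
OUTGROUP = "outgroup"

# mean per-site pi contributed by one segregating site when the carrier
# count among 7 haploids is uniform on 1..6 (unbiased estimator)
_MEAN_SITE_PI_7 = float(
    np.mean([(7 / 6) * (1 - (k / 7) ** 2 - ((7 - k) / 7) ** 2) for k in range(1, 7)])
)


@dataclass
class PlantedEvent:
    gene_id: str
    kind: str  # substitutions | premature-stop | frameshift-indel | deletion | duplication
    n_nonsyn: int = 0
    n_syn: int = 0
    stop_codon: int = 16  # 1-based codon index for premature-stop (derived on SB)
    indel_length: int = 17
    indel_nt_pos: int = 74  # 1-based CDS nucleotide of the insertion anchor
    length: int = 2600  # deletion length, bp
    copies: int = 2
    carrier: str = GROUP_B  # Sb | SB | both


@dataclass
class ExpressionDesign:
    caste: str
    n_multiple_queen: int
    n_single_queen: int
    de_genes: tuple[str, ...]  # focal genes carrying the planted effect


@dataclass
class SimulationConfig:
    """All knobs of the generator; the defaults are the study conditions."""

    seed: int = 0
    n_samples_per_group: int = 7
    scaffold_length: int = 100_000
    supergene_scaffold: str = "lg16"
    supergene_interval: tuple[int, int] = (10_000, 70_000)
    sweep_scaffold: str = "lg3"
    low_pi_interval: tuple[int, int] = (30_000, 50_000)
    low_pi_factor: float = 0.02
    outgroup_divergence: float = 0.02  # per-site, genome-wide
    sb_divergence: float = 0.002  # per-site inside the supergene, non-coding
    diversity_sb: float = 1e-3  # within-SB pi target
    diversity_sb_small: float = 1e-5  # within-Sb pi target (two orders lower)
    unpolarizable_fraction: float = 0.125
    mean_depth: float = 8.0
    depth_log2_sd: float = 0.25
    coverage_gene_length: int = 400
    n_background_coverage_genes: int = 1000
    window_bp: int = 200
    # expression
    baseline_mean: float = 200.0
    baseline_log_sd: float = 0.5
    dispersion: float = 0.1
    log2_effect: float = 2.0
    n_background_expression_genes: int = 2000
    background_de_fraction: float = 0.02
    size_factor_log_sd: float = 0.2
    planted_events: Optional[tuple[PlantedEvent, ...]] = None  # None -> defaults

    def __post_init__(self) -> None:
        for p in (self.outgroup_divergence, self.sb_divergence,
                  self.diversity_sb, self.diversity_sb_small,
                  self.unpolarizable_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.planted_events is None:
            self.planted_events = tuple(default_events())
        else:
            self.planted_events = tuple(self.planted_events)


def default_events() -> tuple[PlantedEvent, ...]:
    """The default planted-event set mirrors the divergence classes the
    study reports: an 8+1 gene, a 3+2 gene, single-substitution genes, a
    premature-stop/frameshift gene, a deletion, and two duplications."""
    return (
        PlantedEvent("sg01", "substitutions", n_nonsyn=8, n_syn=1),
        PlantedEvent("sg02", "substitutions", n_nonsyn=3, n_syn=2),
        PlantedEvent("sg03", "substitutions", n_nonsyn=1, n_syn=0),
        PlantedEvent("sg04", "substitutions", n_nonsyn=0, n_syn=1),
        PlantedEvent("sg05", "premature-stop", stop_codon=16),
        PlantedEvent("sg05", "frameshift-indel", indel_length=17, indel_nt_pos=74),
        PlantedEvent("sg06", "deletion", length=2600, carrier=GROUP_B),
        PlantedEvent("sg07", "duplication", copies=2, carrier=GROUP_B),
        PlantedEvent("sw03", "duplication", copies=4, carrier="both"),
    )


@dataclass
class TruthTables:
    """Everything the generator planted, for exact downstream checks."""

    fixed_differences: pd.DataFrame  # scaffold,pos,gene_id,effect,derived_on,polarizable
    copy_number: pd.DataFrame  # gene_id,group,copies
    deletions: pd.DataFrame  # gene_id,scaffold,start,end,carrier,exons_lost,exons_total,coding_bp_lost
    expression_effects: pd.DataFrame  # caste,gene_id,log2_effect
    swept_windows: pd.DataFrame  # scaffold,start,end
    events: tuple[PlantedEvent, ...] = ()


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genome: GenomeRef
    models: list[GeneModel]
    genotypes: HaploidGenotypeMatrix
    truth: TruthTables


# --------------------------------------------------------------- genes

def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + sense codons + stop; no internal stop by construction."""
    body = rng.choice(SENSE_CODONS, size=n_codons - 2)
    stop = rng.choice(["TAA", "TAG", "TGA"])
    return "ATG" + "".join(body) + stop


def _split_exons(rng: np.random.Generator, cds_len: int, n_exons: int) -> list[int]:
    if n_exons == 1:
        return [cds_len]
    cuts = sorted(rng.choice(np.arange(30, cds_len - 30), size=n_exons - 1,
                             replace=False))
    sizes = np.diff([0, *cuts, cds_len])
    if (sizes < 20).any():
        return _split_exons(rng, cds_len, n_exons)
    return [int(s) for s in sizes]


def _place_gene(
    rng: np.random.Generator,
    scaffold_seq: list[str],
    gene_id: str,
    scaffold: str,
    start: int,
    cds: str,
    strand: str,
    exon_sizes: list[int],
    intron_sizes: list[int],
    in_supergene: bool,
    linkage_group: str,
) -> GeneModel:
    """Write a CDS into the scaffold at ``start`` and return the model."""
    plus = cds if strand == "+" else revcomp(cds)
    exons: list[tuple[int, int]] = []
    pos = start
    offset = 0
    for i, size in enumerate(exon_sizes):
        exons.append((pos, pos + size))
        scaffold_seq[pos : pos + size] = plus[offset : offset + size]
        offset += size
        pos += size
        if i < len(intron_sizes):
            pos += intron_sizes[i]
    return GeneModel(
        gene_id=gene_id, scaffold=scaffold, strand=strand, cds_exons=exons,
        linkage_group=linkage_group, in_supergene=in_supergene,
    )


def _build_genome(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[GenomeRef, list[GeneModel]]:
    scaffolds = {
        name: list(rng.choice(list("ACGT"), size=config.scaffold_length))
        for name in ("lg1", "lg3", "lg16")
    }
    models: list[GeneModel] = []

    def add(gene_id, scaffold, start, n_codons, strand, n_exons,
            in_supergene=False, exon_sizes=None, intron_sizes=None,
            fix_codons=None):
        cds = _random_cds(rng, n_codons)
        for ci, codon in (fix_codons or {}).items():
            cds = cds[: 3 * ci] + codon + cds[3 * ci + 3 :]
        if exon_sizes is None:
            exon_sizes = _split_exons(rng, len(cds), n_exons)
        if intron_sizes is None:
            intron_sizes = [int(rng.integers(100, 400))
                            for _ in range(len(exon_sizes) - 1)]
        models.append(
            _place_gene(rng, scaffolds[scaffold], gene_id, scaffold, start,
                        cds, strand, exon_sizes, intron_sizes,
                        in_supergene, scaffold)
        )

    # ten supergene genes, evenly spaced inside the supergene interval
    for i in range(10):
        gid = f"sg{i + 1:02d}"
        start = config.supergene_interval[0] + 2_000 + i * 5_500
        if gid == "sg05":
            # premature-stop / frameshift gene: plus strand, 176 sense
            # codons; codon 16 fixed to CAG so a single C>T change yields
            # the TAG stop on the derived lineage
            add(gid, config.supergene_scaffold, start, 177, "+", 3,
                fix_codons={15: "CAG"})
        elif gid == "sg06":
            # deletion gene: 139 codons + stop over five exons; the middle
            # three exons hold exactly 89 codons (267 bp, no frameshift)
            add(gid, config.supergene_scaffold, start, 140, "+", 5,
                in_supergene=True,
                exon_sizes=[75, 90, 87, 90, 78],
                intron_sizes=[400, 500, 450, 1308])
            continue
        else:
            add(gid, config.supergene_scaffold, start,
                int(rng.integers(100, 200)), rng.choice(["+", "-"]), 2)
        models[-1].in_supergene = True
    # three tightly clustered genes inside the low-diversity interval
    for i, start in enumerate((34_000, 40_000, 46_000)):
        add(f"sw{i + 1:02d}", config.sweep_scaffold, start,
            int(rng.integers(100, 160)), rng.choice(["+", "-"]), 2)
    # remaining focal genes elsewhere
    for i in range(10):
        add(f"bg{i + 1:02d}", "lg1", 10_000 + i * 8_000,
            int(rng.integers(100, 200)), rng.choice(["+", "-"]), 2)
    add("bg11", config.sweep_scaffold, 75_000, int(rng.integers(100, 200)),
        rng.choice(["+", "-"]), 2)

    genome = GenomeRef({k: "".join(v) for k, v in scaffolds.items()})
    return genome, models


# --------------------------------------------------------------- variants

def _pick_substitution(
    rng: np.random.Generator,
    cds: CodingSequence,
    used_codons: set[int],
    want: str,
) -> tuple[int, int, str, str]:
    """(codon index 0-based, pos in codon, ref base, alt base) realizing a
    synonymous or nonsynonymous single-nucleotide change (never a stop)."""
    n = cds.n_codons
    for _ in range(10_000):
        ci = int(rng.integers(1, n - 1))
        if ci in used_codons:
            continue
        codon = cds.codon(ci)
        k = int(rng.integers(0, 3))
        alt = rng.choice([b for b in "ACGT" if b != codon[k]])
        mutated = codon[:k] + alt + codon[k + 1 :]
        if mutated in STOP_CODONS:
            continue
        effect = (
            "synonymous"
            if translate_codon(mutated) == translate_codon(codon)
            else "nonsynonymous"
        )
        if effect == want:
            used_codons.add(ci)
            return ci, k, codon[k], alt
    raise ValueError(
        f"{cds.gene_id}: could not place a {want} substitution "
        "(requested counts exceed available codon positions?)"
    )


def _plus_strand_allele(base: str, strand: str) -> str:
    return base if strand == "+" else revcomp(base)


class _SiteRegistry:
    """Accumulates variant sites; resolves them into a genotype matrix."""

    def __init__(self, samples: list[str]) -> None:
        self.samples = samples
        self.records: dict[tuple[str, int], dict] = {}

    def used(self, scaffold: str, pos: int) -> bool:
        return (scaffold, pos) in self.records

    def add(
        self,
        scaffold: str,
        pos: int,
        ref: str,
        alt: str,
        carriers: Sequence[str],
        missing: Sequence[str] = (),
    ) -> None:
        key = (scaffold, pos)
        rec = self.records.setdefault(
            key, {"ref": ref, "alts": [], "carrier_of": {}, "missing": set()}
        )
        if alt not in rec["alts"]:
            rec["alts"].append(alt)
        ai = rec["alts"].index(alt) + 1
        for s in carriers:
            rec["carrier_of"][s] = ai
        rec["missing"].update(missing)

    def build(self, groups: dict[str, str]) -> HaploidGenotypeMatrix:
        sites = []
        calls = []
        for (scaffold, pos), rec in sorted(self.records.items()):
            sites.append((scaffold, pos, rec["ref"], tuple(rec["alts"])))
            row = []
            for s in self.samples:
                if s in rec["missing"]:
                    row.append(MISSING)
                else:
                    row.append(rec["carrier_of"].get(s, 0))
            calls.append(row)
        return HaploidGenotypeMatrix(sites, calls, self.samples, groups)


def simulate_haplotypes(config: SimulationConfig) -> SyntheticDataset:
    """Reference + gene models + haploid genotype matrix + truth tables.

    At every planted SB-Sb difference the outgroup carries the ancestral
    allele, except for a deterministic ``unpolarizable_fraction`` of them
    (outgroup call set to missing), applied per event in planting order.
    """
    rng = np.random.default_rng(config.seed)
    genome, models = _build_genome(config, rng)
    model_by_id = {m.gene_id: m for m in models}
    n = config.n_samples_per_group
    samples_a = [f"{GROUP_A}{i + 1}" for i in range(n)]
    samples_b = [f"{GROUP_B}{i + 1}" for i in range(n)]
    out_sample = "geminata_pool"
    samples = samples_a + samples_b + [out_sample]
    groups = {**{s: GROUP_A for s in samples_a},
              **{s: GROUP_B for s in samples_b},
              out_sample: OUTGROUP}
    reg = _SiteRegistry(samples)

    fixed_rows: list[dict] = []
    cn_rows: list[dict] = []
    del_rows: list[dict] = []

    cds_cache = {m.gene_id: extract_cds(genome, m) for m in models}
    used_codons: dict[str, set[int]] = {m.gene_id: set() for m in models}

    def plant_diff(gene_id, ci, k, ref_b, alt_b, effect, derived_group):
        """Plant one fixed difference: derived allele on every sample of
        ``derived_group``; returns the truth row (polarizable filled later)."""
        m = model_by_id[gene_id]
        cds = cds_cache[gene_id]
        scaffold, gpos, strand = cds.codon_map[ci][k]
        ref_plus = _plus_strand_allele(ref_b, strand)
        alt_plus = _plus_strand_allele(alt_b, strand)
        carriers = samples_b if derived_group == GROUP_B else samples_a
        reg.add(scaffold, gpos, ref_plus, alt_plus, carriers)
        return {
            "scaffold": scaffold, "pos": gpos, "gene_id": gene_id,
            "codon_index": ci + 1, "effect": effect,
            "derived_on": derived_group, "polarizable": True,
            "is_indel": False,
        }

    for ev in config.planted_events:
        if ev.kind == "substitutions":
            cds = cds_cache[ev.gene_id]
            rows = []
            for _ in range(ev.n_nonsyn):
                ci, k, ref_b, alt_b = _pick_substitution(
                    rng, cds, used_codons[ev.gene_id], "nonsynonymous")
                rows.append(plant_diff(ev.gene_id, ci, k, ref_b, alt_b,
                                       "nonsynonymous", GROUP_B))
            for _ in range(ev.n_syn):
                ci, k, ref_b, alt_b = _pick_substitution(
                    rng, cds, used_codons[ev.gene_id], "synonymous")
                rows.append(plant_diff(ev.gene_id, ci, k, ref_b, alt_b,
                                       "synonymous", GROUP_B))
            # deterministic unpolarizable share, in planting order
            n_unpol = int(round(config.unpolarizable_fraction * len(rows)))
            for row in rows[:n_unpol]:
                reg.records[(row["scaffold"], row["pos"])]["missing"].add(out_sample)
                row["polarizable"] = False
                row["derived_on"] = "unresolved"
            fixed_rows.extend(rows)
        elif ev.kind == "premature-stop":
            cds = cds_cache[ev.gene_id]
            ci = ev.stop_codon - 1
            codon = cds.codon(ci)
            # single-base change to a stop codon, derived on the A lineage
            choice = None
            for stop in ("TAG", "TAA", "TGA"):
                diff = [k for k in range(3) if codon[k] != stop[k]]
                if len(diff) == 1:
                    choice = (diff[0], stop[diff[0]])
                    break
            if choice is None:  # force the middle base then the first
                choice = (0, "T") if codon[0] != "T" else (1, "A")
            k, alt_b = choice
            used_codons[ev.gene_id].add(ci)
            fixed_rows.append(
                plant_diff(ev.gene_id, ci, k, codon[k], alt_b, "nonsense", GROUP_A)
            )
        elif ev.kind == "frameshift-indel":
            cds = cds_cache[ev.gene_id]
            i = ev.indel_nt_pos - 1  # anchor: 0-based CDS position
            scaffold, gpos, strand = cds.codon_map[i // 3][i % 3]
            assert strand == "+", "frameshift event genes are laid out on +"
            anchor = cds.nucleotides[i]
            ins = "".join(rng.choice(list("ACGT"), size=ev.indel_length))
            reg.add(scaffold, gpos, anchor, anchor + ins, samples_b)
            fixed_rows.append({
                "scaffold": scaffold, "pos": gpos, "gene_id": ev.gene_id,
                "codon_index": i // 3 + 1, "effect": "frameshift-indel",
                "derived_on": GROUP_B, "polarizable": True, "is_indel": True,
            })
        elif ev.kind == "deletion":
            m = model_by_id[ev.gene_id]
            start = m.cds_exons[0][1] + 225  # inside intron 1
            end = start + ev.length
            lost = sum(1 for s, e in m.cds_exons if s >= start and e <= end)
            coding = sum(max(0, min(e, end) - max(s, start))
                         for s, e in m.cds_exons)
            del_rows.append({
                "gene_id": ev.gene_id, "scaffold": m.scaffold,
                "start": start, "end": end, "carrier": ev.carrier,
                "exons_lost": lost, "exons_total": len(m.cds_exons),
                "coding_bp_lost": coding,
            })
        elif ev.kind == "duplication":
            for group in ([GROUP_A, GROUP_B] if ev.carrier == "both"
                          else [ev.carrier]):
                cn_rows.append({"gene_id": ev.gene_id, "group": group,
                                "copies": ev.copies})
        else:
            raise ValueError(f"unknown event kind {ev.kind!r}")

    cds_positions = {
        (sc, p)
        for cds in cds_cache.values()
        for codon in cds.codon_map
        for sc, p, _ in codon
    }

    # background supergene divergence (non-coding, derived on Sb)
    sc = config.supergene_scaffold
    lo, hi = config.supergene_interval
    n_bg = rng.binomial(hi - lo, config.sb_divergence)
    for pos in rng.choice(np.arange(lo, hi), size=n_bg, replace=False):
        pos = int(pos)
        if reg.used(sc, pos) or (sc, pos) in cds_positions:
            continue
        ref = genome.sequences[sc][pos]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        reg.add(sc, pos, ref, alt, samples_b)

    # outgroup-lineage divergence, genome-wide
    for scaffold, seq in genome.sequences.items():
        n_div = rng.binomial(len(seq), config.outgroup_divergence)
        for pos in rng.choice(len(seq), size=n_div, replace=False):
            pos = int(pos)
            if reg.used(scaffold, pos):
                continue
            ref = seq[pos]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            reg.add(scaffold, pos, ref, alt, [out_sample])

    # within-group polymorphism; SB carries the configured diversity, Sb is
    # two orders of magnitude lower, and the swept interval is depressed
    def plant_polymorphism(group_samples: list[str], target_pi: float,
                           depress_sweep: bool) -> None:
        density = target_pi / _MEAN_SITE_PI_7
        for scaffold, seq in genome.sequences.items():
            n_sites = rng.binomial(len(seq), density)
            for pos in rng.choice(len(seq), size=n_sites, replace=False):
                pos = int(pos)
                if depress_sweep and scaffold == config.sweep_scaffold:
                    s0, s1 = config.low_pi_interval
                    if s0 <= pos < s1 and rng.random() > config.low_pi_factor:
                        continue
                if reg.used(scaffold, pos):
                    continue
                ref = seq[pos]
                alt = rng.choice([b for b in "ACGT" if b != ref])
                k = int(rng.integers(1, len(group_samples)))
                carriers = list(rng.choice(group_samples, size=k, replace=False))
                reg.add(scaffold, pos, ref, alt, carriers)

    plant_polymorphism(samples_a, config.diversity_sb, depress_sweep=True)
    plant_polymorphism(samples_b, config.diversity_sb_small, depress_sweep=False)

    geno = reg.build(groups)

    wlo = config.low_pi_interval[0] // 10_000 * 10_000
    whi = (config.low_pi_interval[1] + 9_999) // 10_000 * 10_000
    swept = pd.DataFrame(
        [
            {"scaffold": config.sweep_scaffold, "start": s, "end": s + 10_000}
            for s in range(wlo, whi, 10_000)
        ]
    )
    truth = TruthTables(
        fixed_differences=pd.DataFrame(
            fixed_rows,
            columns=["scaffold", "pos", "gene_id", "codon_index", "effect",
                     "derived_on", "polarizable", "is_indel"],
        ).sort_values(["scaffold", "pos"]).reset_index(drop=True),
        copy_number=pd.DataFrame(cn_rows, columns=["gene_id", "group", "copies"]),
        deletions=pd.DataFrame(
            del_rows,
            columns=["gene_id", "scaffold", "start", "end", "carrier",
                     "exons_lost", "exons_total", "coding_bp_lost"],
        ),
        expression_effects=_expression_truth(config),
        swept_windows=swept,
        events=config.planted_events,
    )
    return SyntheticDataset(config, genome, models, geno, truth)


# --------------------------------------------------------------- coverage

def simulate_coverage(
    config: SimulationConfig,
    dataset: SyntheticDataset,
    seed_offset: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Per-gene and per-window depth tables.

    Gene depth = median per-base Poisson depth, with per-(gene, sample)
    multiplicative lognormal noise on the expected depth (sigma of
    ``depth_log2_sd`` in log2 units).  Windows tile the scaffolds that
    carry a planted deletion; windows fully inside a deletion have zero
    expected depth in carrier samples.  Returns (genes, windows,
    background unit ids).
    """
    rng = np.random.default_rng(config.seed + seed_offset)
    samples = dataset.genotypes.samples
    groups = dataset.genotypes.groups
    cn = {
        (r.gene_id, r.group): r.copies
        for r in dataset.truth.copy_number.itertuples()
    }
    gene_rows = []
    units = [m.gene_id for m in dataset.models] + [
        f"bgcov{i + 1:04d}" for i in range(config.n_background_coverage_genes)
    ]
    background = units[len(dataset.models):]
    lengths = {m.gene_id: max(m.cds_length, 100) for m in dataset.models}
    for unit in units:
        L = lengths.get(unit, config.coverage_gene_length)
        for s in samples:
            grp = groups[s]
            copies = cn.get((unit, grp), 1) if grp != OUTGROUP else (
                cn.get((unit, GROUP_A), 1)
                if cn.get((unit, GROUP_A)) == cn.get((unit, GROUP_B))
                else 1
            )
            lam = config.mean_depth * copies * 2.0 ** rng.normal(0, config.depth_log2_sd)
            depth = float(np.median(rng.poisson(lam, size=L)))
            gene_rows.append({"unit": unit, "sample": s, "depth": depth})
    genes_df = pd.DataFrame(gene_rows)

    window_rows = []
    w = config.window_bp
    del_by_scaffold: dict[str, list[tuple[int, int, str]]] = {}
    for r in dataset.truth.deletions.itertuples():
        del_by_scaffold.setdefault(r.scaffold, []).append((r.start, r.end, r.carrier))
    for scaffold in sorted(del_by_scaffold):
        length = len(dataset.genome.sequences[scaffold])
        for start in range(0, length, w):
            end = min(start + w, length)
            for s in samples:
                grp = groups[s]
                frac = 1.0
                for dstart, dend, carrier in del_by_scaffold[scaffold]:
                    if grp == carrier:
                        ov = max(0, min(end, dend) - max(start, dstart))
                        frac -= ov / (end - start)
                lam = config.mean_depth * max(frac, 0.0) \
                    * 2.0 ** rng.normal(0, config.depth_log2_sd)
                depth = rng.poisson(lam * (end - start)) / (end - start)
                window_rows.append({
                    "unit": f"{scaffold}:{start}-{end}", "sample": s,
                    "depth": float(depth),
                })
    windows_df = pd.DataFrame(window_rows)
    return genes_df, windows_df, background


# --------------------------------------------------------------- counts

def _expression_truth(config: SimulationConfig) -> pd.DataFrame:
    """Planted social-form effects: in queens, 14 focal genes (the 7
    divergent supergene genes plus 7 others) all overexpressed in
    multiple-queen colonies; in workers, 4 supergene genes, same sign."""
    queen_genes = [f"sg{i + 1:02d}" for i in range(7)] + \
        [f"bg{i + 1:02d}" for i in range(7)]
    worker_genes = [f"sg{i + 1:02d}" for i in range(4)]
    rows = [{"caste": "queen", "gene_id": g, "log2_effect": config.log2_effect}
            for g in queen_genes]
    rows += [{"caste": "worker", "gene_id": g, "log2_effect": config.log2_effect}
             for g in worker_genes]
    return pd.DataFrame(rows)


def queen_design(config: SimulationConfig) -> ExpressionDesign:
    eff = _expression_truth(config)
    return ExpressionDesign(
        caste="queen", n_multiple_queen=3, n_single_queen=2,
        de_genes=tuple(eff.loc[eff.caste == "queen", "gene_id"]),
    )


def worker_design(config: SimulationConfig) -> ExpressionDesign:
    eff = _expression_truth(config)
    return ExpressionDesign(
        caste="worker", n_multiple_queen=2, n_single_queen=3,
        de_genes=tuple(eff.loc[eff.caste == "worker", "gene_id"]),
    )


def simulate_counts(
    config: SimulationConfig,
    design: ExpressionDesign,
    gene_ids: Optional[Sequence[str]] = None,
    seed_offset: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Gene x sample NB counts for one caste.

    counts ~ NB(mean * sizefactor * 2^(effect * [multiple-queen]),
    dispersion) drawn as a gamma-Poisson mixture.  Focal genes carry the
    planted all-positive effect; a ``background_de_fraction`` of the
    background transcriptome carries random-sign effects.  Returns
    (counts, sample metadata, per-gene truth effects).
    """
    rng = np.random.default_rng(
        config.seed + seed_offset + (0 if design.caste == "queen" else 1)
    )
    if gene_ids is None:
        gene_ids = [f"sg{i + 1:02d}" for i in range(10)] + \
            [f"sw{i + 1:02d}" for i in range(3)] + \
            [f"bg{i + 1:02d}" for i in range(11)]
    genes = list(gene_ids) + [
        f"tx{i + 1:05d}" for i in range(config.n_background_expression_genes)
    ]
    n_mq, n_sq = design.n_multiple_queen, design.n_single_queen
    sample_names = [f"{design.caste}_MQ{i + 1}" for i in range(n_mq)] + \
        [f"{design.caste}_SQ{i + 1}" for i in range(n_sq)]
    social = ["multiple-queen"] * n_mq + ["single-queen"] * n_sq
    meta = pd.DataFrame({"sample": sample_names, "caste": design.caste,
                         "social_form": social}).set_index("sample")

    base = rng.lognormal(np.log(config.baseline_mean),
                         config.baseline_log_sd, size=len(genes))
    effects = np.zeros(len(genes))
    gene_index = {g: i for i, g in enumerate(genes)}
    for g in design.de_genes:
        effects[gene_index[g]] = config.log2_effect
    n_bg_de = int(config.background_de_fraction
                  * config.n_background_expression_genes)
    bg_start = len(gene_ids)
    bg_de = rng.choice(
        np.arange(bg_start, len(genes)), size=n_bg_de, replace=False)
    effects[bg_de] = rng.choice([-1.0, 1.0], size=n_bg_de) * config.log2_effect
    sf = rng.lognormal(0, config.size_factor_log_sd, size=len(sample_names))
    is_mq = np.array([s == "multiple-queen" for s in social], dtype=float)
    mu = base[:, None] * sf[None, :] * 2.0 ** (effects[:, None] * is_mq[None, :])
    shape = 1.0 / config.dispersion
    lam = rng.gamma(shape, mu / shape)
    counts = rng.poisson(lam)
    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"),
                             columns=sample_names)
    truth = pd.DataFrame({"gene_id": genes, "log2_effect": effects,
                          "baseline_mean": base})
    return counts_df, meta, truth


# --------------------------------------------------------------- output

def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> None:
    """Write the full dataset in the formats the pipeline consumes, plus
    truth/*.tsv.  Same seed, same bytes."""
    out = Path(outdir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    config = dataset.config
    obpio.write_fasta(out / "reference.fasta", dataset.genome.sequences)
    obpio.write_gff3(out / "genes.gff3", dataset.models)
    obpio.write_vcf(
        out / "genotypes.vcf", dataset.genotypes,
        {k: len(v) for k, v in dataset.genome.sequences.items()},
    )
    obpio.write_groups(out / "groups.tsv", dict(dataset.genotypes.groups))
    genes_df, windows_df, background = simulate_coverage(config, dataset)
    obpio.write_table(out / "coverage_genes.tsv", genes_df)
    obpio.write_table(out / "coverage_windows.tsv", windows_df)
    (out / "background_units.txt").write_text("\n".join(background) + "\n")
    for design_fn in (queen_design, worker_design):
        design = design_fn(config)
        counts, meta, truth_eff = simulate_counts(config, design)
        obpio.write_table(out / f"counts_{design.caste}.tsv",
                          counts.reset_index())
        obpio.write_table(out / f"samples_{design.caste}.tsv",
                          meta.reset_index())
        obpio.write_table(out / "truth" / f"expression_{design.caste}.tsv",
                          truth_eff)
    t = dataset.truth
    obpio.write_table(out / "truth" / "fixed_differences.tsv", t.fixed_differences)
    obpio.write_table(out / "truth" / "copy_number.tsv", t.copy_number)
    obpio.write_table(out / "truth" / "deletions.tsv", t.deletions)
    obpio.write_table(out / "truth" / "swept_windows.tsv", t.swept_windows)
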