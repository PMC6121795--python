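"""Fixed-difference detection, codon-effect classification, outgroup
polarization, and NG86-style dN/dS between two haploid lineages.

The central objects are the two supergene haplotype groups (canonically SB
and Sb).  A *fixed difference* is a site at which every called haploid of
one group carries one allele and every called haploid of the other group a
different allele.  Polarization assigns each fixed difference a derived
lineage by comparing against an outgroup that predates the split.

dN/dS uses Nei-Gojobori (1986) site counting: the synonymous-site content
of a codon is the fraction of its nine single-nucleotide neighbours that
preserve the amino acid, and multi-hit codons contribute substitution
counts averaged over all mutational pathways (equally weighted, pathways
through stop codons excluded).  A Jukes-Cantor correction maps proportions
to rates.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .genome import (
    MISSING,
    STOP_CODONS,
    CodingSequence,
    HaploidGenotypeMatrix,
    translate_codon,
)

NUCS = "ACGT"


# ------------------------------------------------------------- data types

@dataclass
class FixedDifference:
    scaffold: str
    pos: int
    allele_a: str
    allele_b: str
    n_called_a: int
    n_called_b: int
    is_indel: bool = False
    gene_id: Optional[str] = None
    codon_index: Optional[int] = None  # 1-based
    position_in_codon: Optional[int] = None  # 1..3


@dataclass
class SiteEffect:
    """Effect of one nucleotide change, labelled in the A background."""

    position_in_codon: int  # 1..3
    effect: str  # synonymous | nonsynonymous | nonsense
    ambiguous: bool = False  # label differs in the B background


@dataclass
class CodonChange:
    gene_id: str
    codon_index: int  # 1-based
    codon_a: str
    codon_b: str
    aa_a: str
    aa_b: str
    effect: str  # synonymous | nonsynonymous | nonsense | multi-hit
    n_nuc_changes: int
    site_effects: list[SiteEffect] = field(default_factory=list)


@dataclass
class Polarization:
    scaffold: str
    pos: int
    allele_a: str
    allele_b: str
    outgroup_state: str  # matches-A | matches-B | third-allele | missing | polymorphic
    ancestral_allele: Optional[str]
    derived_on: str  # A-lineage | B-lineage | unresolved


@dataclass
class DnDsResult:
    n_sites: float
    s_sites: float
    nd: float
    sd: float
    pn: float
    ps: float
    dn: float
    ds: float
    ratio: Optional[float]  # None when dS = 0
    method: str = "NG86-pathway-JC"
    excluded_premature_stop: bool = False


@dataclass
class DivergenceSummary:
    gene_id: str
    n_nonsynonymous: int
    n_synonymous: int
    n_nonsense: int
    n_total: int
    dn: Optional[float] = None
    ds: Optional[float] = None
    dnds: Optional[float] = None
    n_derived_on_b: int = 0
    n_derived_on_a: int = 0
    n_unresolved: int = 0
    structural_notes: str = ""


# --------------------------------------------------- fixed differences

def find_fixed_differences(
    geno: HaploidGenotypeMatrix,
    group_a: str,
    group_b: str,
    min_called: Optional[int] = None,
) -> list[FixedDifference]:
    """Sites where the two haploid groups are reciprocally monomorphic.

    ``min_called`` defaults to the full group size, i.e. by default no
    missing calls are tolerated when declaring a difference fixed.
    """
    idx_a = geno.sample_indices(group_a)
    idx_b = geno.sample_indices(group_b)
    if not idx_a or not idx_b:
        raise ValueError(f"unknown or empty group among {group_a!r}, {group_b!r}")
    min_a = len(idx_a) if min_called is None else min_called
    min_b = len(idx_b) if min_called is None else min_called
    out: list[FixedDifference] = []
    for i in range(geno.n_sites):
        row = geno.calls[i]
        called_a = [row[j] for j in idx_a if row[j] != MISSING]
        called_b = [row[j] for j in idx_b if row[j] != MISSING]
        if len(called_a) < min_a or len(called_b) < min_b:
            continue
        set_a, set_b = set(called_a), set(called_b)
        if len(set_a) == 1 and len(set_b) == 1 and set_a != set_b:
            alleles = geno.alleles(i)
            scaffold, pos, _r, _alts = geno.sites[i]
            out.append(
                FixedDifference(
                    scaffold=scaffold,
                    pos=pos,
                    allele_a=alleles[set_a.pop()],
                    allele_b=alleles[set_b.pop()],
                    n_called_a=len(called_a),
                    n_called_b=len(called_b),
                    is_indel=geno.is_indel(i),
                )
            )
    out.sort(key=lambda d: (d.scaffold, d.pos))
    return out


def annotate_with_gene(
    diffs: Iterable[FixedDifference], cds: CodingSequence
) -> list[FixedDifference]:
    """Attach gene id / codon index / within-codon position to the
    differences that fall inside the coding sequence."""
    index = cds.genomic_to_cds()
    hit = []
    for d in diffs:
        j = index.get((d.scaffold, d.pos))
        if j is None:
            continue
        d.gene_id = cds.gene_id
        d.codon_index = j // 3 + 1
        d.position_in_codon = j % 3 + 1
        hit.append(d)
    return hit


# --------------------------------------------------- codon classification

def _site_effect_label(codon_from: str, codon_to_base: str, offset: int) -> str:
    mutated = codon_from[:offset] + codon_to_base + codon_from[offset + 1 :]
    aa0, aa1 = translate_codon(codon_from), translate_codon(mutated)
    if aa1 == "*" or aa0 == "*":
        return "nonsense" if aa0 != aa1 else "synonymous"
    return "synonymous" if aa0 == aa1 else "nonsynonymous"


def classify_codon_changes(
    cds_a: CodingSequence,
    cds_b: CodingSequence,
    deleted_codons_a: Sequence[int] = (),
    deleted_codons_b: Sequence[int] = (),
) -> list[CodonChange]:
    """Per-codon comparison of two codon-aligned alleles of one gene.

    In-frame indels must consume whole codons, passed as 0-based codon
    indices to drop from either allele before the walk; a residual length
    mismatch raises.  Multi-hit codons get per-site labels by substituting
    each changed site alone into the A background, flagged ambiguous when
    the B-background label disagrees.
    """
    seq_a = _drop_codons(cds_a.nucleotides, deleted_codons_a)
    seq_b = _drop_codons(cds_b.nucleotides, deleted_codons_b)
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"{cds_a.gene_id}: alleles not codon-aligned "
            f"({len(seq_a)} vs {len(seq_b)} nt after recorded indels)"
        )
    changes: list[CodonChange] = []
    for i in range(len(seq_a) // 3):
        ca, cb = seq_a[3 * i : 3 * i + 3], seq_b[3 * i : 3 * i + 3]
        if ca == cb:
            continue
        aa_a, aa_b = translate_codon(ca), translate_codon(cb)
        diff_pos = [k for k in range(3) if ca[k] != cb[k]]
        if len(diff_pos) > 1:
            effect = "multi-hit"
        elif aa_a == aa_b:
            effect = "synonymous"
        elif "*" in (aa_a, aa_b):
            effect = "nonsense"
        else:
            effect = "nonsynonymous"
        site_effects = []
        for k in diff_pos:
            lab_a = _site_effect_label(ca, cb[k], k)
            lab_b = _site_effect_label(cb, ca[k], k)
            site_effects.append(
                SiteEffect(
                    position_in_codon=k + 1,
                    effect=lab_a,
                    ambiguous=(lab_a != lab_b) and len(diff_pos) > 1,
                )
            )
        changes.append(
            CodonChange(
                gene_id=cds_a.gene_id,
                codon_index=i + 1,
                codon_a=ca,
                codon_b=cb,
                aa_a=aa_a,
                aa_b=aa_b,
                effect=effect,
                n_nuc_changes=len(diff_pos),
                site_effects=site_effects,
            )
        )
    return changes


def _drop_codons(seq: str, deleted: Sequence[int]) -> str:
    if not deleted:
        return seq
    drop = set(deleted)
    return "".join(
        seq[3 * i : 3 * i + 3] for i in range(len(seq) // 3) if i not in drop
    )


# --------------------------------------------------- polarization

def polarize_substitutions(
    geno: HaploidGenotypeMatrix,
    diffs: Iterable[FixedDifference],
    outgroup: str = "outgroup",
) -> list[Polarization]:
    """Class each fixed difference as derived on the A or B lineage from the
    outgroup allele; missing/third-allele/polymorphic outgroups stay
    unresolved."""
    idx_out = geno.sample_indices(outgroup)
    site_index = {(s, p): i for i, (s, p, _r, _a) in enumerate(geno.sites)}
    out: list[Polarization] = []
    for d in diffs:
        i = site_index.get((d.scaffold, d.pos))
        state = "missing"
        ancestral = None
        derived_on = "unresolved"
        if i is not None and idx_out:
            calls = [geno.calls[i][j] for j in idx_out if geno.calls[i][j] != MISSING]
            if not calls:
                state = "missing"
            elif len(set(calls)) > 1:
                state = "polymorphic"
            else:
                allele = geno.alleles(i)[calls[0]]
                if allele == d.allele_a:
                    state, ancestral, derived_on = "matches-A", allele, "B-lineage"
                elif allele == d.allele_b:
                    state, ancestral, derived_on = "matches-B", allele, "A-lineage"
                else:
                    state = "third-allele"
        out.append(
            Polarization(
                scaffold=d.scaffold,
                pos=d.pos,
                allele_a=d.allele_a,
                allele_b=d.allele_b,
                outgroup_state=state,
                ancestral_allele=ancestral,
                derived_on=derived_on,
            )
        )
    return out


# --------------------------------------------------- NG86 dN/dS

def _codon_site_counts(codon: str) -> tuple[float, float]:
    s = 0.0
    for k in range(3):
        for b in NUCS:
            if b == codon[k]:
                continue
            mutated = codon[:k] + b + codon[k + 1 :]
            if (
                mutated not in STOP_CODONS
                and translate_codon(mutated) == translate_codon(codon)
            ):
                s += 1.0
    s /= 3.0
    return s, 3.0 - s


def ng86_site_counts(cds: CodingSequence | str) -> tuple[float, float]:
    """(S, N): synonymous and nonsynonymous site counts of a CDS.

    Per codon, the synonymous fraction at each position is the share of the
    three alternative bases that leave the amino acid unchanged (mutations
    creating stop codons count as nonsynonymous), so S + N = 3 x codons.
    Stop codons themselves are skipped.
    """
    seq = cds if isinstance(cds, str) else cds.nucleotides
    s_total = n_total = 0.0
    for i in range(len(seq) // 3):
        codon = seq[3 * i : 3 * i + 3]
        if codon in STOP_CODONS:
            continue
        s, n = _codon_site_counts(codon)
        s_total += s
        n_total += n
    return s_total, n_total


def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(Nd, Sd) for one codon pair, averaged over all stop-free orderings of
    the single-nucleotide changes; if every ordering passes through a stop,
    all orderings are used with stop-gaining steps counted nonsynonymous."""
    diff = [k for k in range(3) if codon_a[k] != codon_b[k]]
    if not diff:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(diff):
        current = codon_a
        nd = sd = 0.0
        has_stop = False
        for k in order:
            nxt = current[:k] + codon_b[k] + current[k + 1 :]
            if nxt in STOP_CODONS:
                has_stop = True
            if translate_codon(nxt) == translate_codon(current):
                sd += 1.0
            else:
                nd += 1.0
            current = nxt
        pathways.append((nd, sd, has_stop))
    clean = [(nd, sd) for nd, sd, stop in pathways if not stop]
    use = clean if clean else [(nd, sd) for nd, sd, _ in pathways]
    nd = sum(p[0] for p in use) / len(use)
    sd = sum(p[1] for p in use) / len(use)
    return nd, sd


def jukes_cantor(p: float) -> float:
    """d = -(3/4) ln(1 - 4p/3); undefined for p >= 3/4."""
    if p >= 0.75:
        raise ValueError(f"proportion {p:.4f} >= 3/4: Jukes-Cantor correction undefined")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def estimate_dnds(
    cds_a: CodingSequence | str,
    cds_b: CodingSequence | str,
    check_internal_stops: bool = True,
) -> DnDsResult:
    """NG86 dN/dS between two codon-aligned alleles.

    Sites are averaged between the two sequences; substitution counts use
    equal-weight pathway averaging; Jukes-Cantor maps pN/pS to dN/dS.  The
    ratio is None when dS = 0 (Nd/Sd still reported).  Alleles with an
    internal (premature) stop are rejected — such genes carry no meaningful
    ratio and are reported via structural notes instead.
    """
    seq_a = cds_a if isinstance(cds_a, str) else cds_a.nucleotides
    seq_b = cds_b if isinstance(cds_b, str) else cds_b.nucleotides
    if len(seq_a) != len(seq_b):
        raise ValueError("alleles must be codon-aligned (equal length)")
    n_codons = len(seq_a) // 3
    if check_internal_stops:
        for name, seq in (("A", seq_a), ("B", seq_b)):
            stops = [
                i for i in range(n_codons) if seq[3 * i : 3 * i + 3] in STOP_CODONS
            ]
            if any(i < n_codons - 1 for i in stops):
                warnings.warn(
                    f"allele {name} carries an internal stop codon; "
                    "gene excluded from dN/dS"
                )
                return DnDsResult(
                    n_sites=float("nan"), s_sites=float("nan"), nd=0.0, sd=0.0,
                    pn=float("nan"), ps=float("nan"), dn=float("nan"),
                    ds=float("nan"), ratio=None, excluded_premature_stop=True,
                )
    # trailing stop codons carry no sites
    s_a, n_a = ng86_site_counts(seq_a)
    s_b, n_b = ng86_site_counts(seq_b)
    s_sites = (s_a + s_b) / 2.0
    n_sites = (n_a + n_b) / 2.0
    nd = sd = 0.0
    for i in range(n_codons):
        ca, cb = seq_a[3 * i : 3 * i + 3], seq_b[3 * i : 3 * i + 3]
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        d_nd, d_sd = _pathway_counts(ca, cb)
        nd += d_nd
        sd += d_sd
    pn = nd / n_sites if n_sites > 0 else 0.0
    ps = sd / s_sites if s_sites > 0 else 0.0
    dn = jukes_cantor(pn)
    ds = jukes_cantor(ps)
    ratio = dn / ds if ds > 0 else None
    return DnDsResult(
        n_sites=n_sites, s_sites=s_sites, nd=nd, sd=sd,
        pn=pn, ps=ps, dn=dn, ds=ds, ratio=ratio,
    )


# --------------------------------------------------- gene summary

def summarize_gene(
    gene_id: str,
    codon_changes: Sequence[CodonChange],
    polarizations: Sequence[Polarization] = (),
    dnds: Optional[DnDsResult] = None,
    structural_notes: str = "",
) -> DivergenceSummary:
    """One Table-style row: substitution-effect counts, derived-lineage
    tallies, dN/dS, and free-text structural notes."""
    n_syn = n_non = n_stop = 0
    for ch in codon_changes:
        for se in ch.site_effects:
            if se.effect == "synonymous":
                n_syn += 1
            elif se.effect == "nonsense":
                n_stop += 1
            else:
                n_non += 1
    n_a = sum(1 for p in polarizations if p.derived_on == "A-lineage")
    n_b = sum(1 for p in polarizations if p.derived_on == "B-lineage")
    n_u = sum(1 for p in polarizations if p.derived_on == "unresolved")
    return DivergenceSummary(
        gene_id=gene_id,
        n_nonsynonymous=n_non,
        n_synonymous=n_syn,
        n_nonsense=n_stop,
        n_total=n_syn + n_non + n_stop,
        dn=None if dnds is None or dnds.excluded_premature_stop else dnds.dn,
        ds=None if dnds is None or dnds.excluded_premature_stop else dnds.ds,
        dnds=None if dnds is None else dnds.ratio,
        n_derived_on_b=n_b,
        n_derived_on_a=n_a,
        n_unresolved=n_u,
        structural_notes=structural_notes,
    )
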