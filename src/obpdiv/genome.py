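"""Gene models, reference sequences, and coding-sequence reconstruction.

Coordinates are 0-based half-open internally.  User-facing codon positions
are 1-based ("codon position 16 of 176" style), matching the convention of
the population-genetics literature this toolkit serves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

STOP_CODONS = frozenset(standard_dna_table.stop_codons)
MISSING = -1

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """Standard-code translation of one codon; stop -> '*', ambiguous -> 'X'."""
    if codon in STOP_CODONS:
        return "*"
    try:
        return standard_dna_table.forward_table[codon]
    except KeyError:
        return "X"


class CoordinateError(ValueError):
    """An interval or position falls outside its scaffold."""


class ModelError(ValueError):
    """A gene model violates its structural invariants."""


@dataclass
class GenomeRef:
    """Reference assembly: scaffold id -> uppercase A/C/G/T/N sequence."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"scaffold {name!r} is empty")
            if set(seq) - set("ACGTN"):
                raise ValueError(f"scaffold {name!r} has bases outside ACGTN")

    def fetch(self, scaffold: str, start: int, end: int) -> str:
        seq = self.sequences[scaffold]
        if start < 0 or end > len(seq) or start > end:
            raise CoordinateError(
                f"{scaffold}:{start}-{end} outside scaffold of length {len(seq)}"
            )
        return seq[start:end]


@dataclass
class GeneModel:
    """A protein-coding gene: ordered CDS exons on one scaffold.

    ``in_supergene`` marks membership in the non-recombining supergene
    interval; it is input metadata (assembly gaps can leave it undetermined
    from coordinates alone).
    """

    gene_id: str
    scaffold: str
    strand: str
    cds_exons: list[tuple[int, int]]
    linkage_group: Optional[str] = None
    in_supergene: bool = False
    incomplete: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ModelError(f"{self.gene_id}: strand must be '+' or '-'")
        exons = sorted(self.cds_exons)
        if exons != sorted(self.cds_exons, key=lambda e: e[0]):
            raise ModelError(f"{self.gene_id}: exons not sortable")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if e1 > s2:
                raise ModelError(f"{self.gene_id}: overlapping CDS exons")
        for s, e in exons:
            if s >= e:
                raise ModelError(f"{self.gene_id}: empty exon {s}-{e}")
        self.cds_exons = exons
        if self.cds_length % 3 != 0 and not self.incomplete:
            raise ModelError(
                f"{self.gene_id}: CDS length {self.cds_length} not divisible "
                "by 3 and model not flagged incomplete"
            )

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.cds_exons[0][0], self.cds_exons[-1][1]


@dataclass
class CodingSequence:
    """Spliced CDS in coding orientation with a genomic codon map.

    ``codon_map[i]`` holds the three genomic (scaffold, pos, strand)
    coordinates of codon i; for minus-strand genes the genomic positions
    decrease along the coding direction.
    """

    gene_id: str
    nucleotides: str
    codon_map: list[tuple[tuple[str, int, str], ...]]
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if len(self.nucleotides) % 3 != 0:
            raise ModelError(f"{self.gene_id}: CDS length not divisible by 3")
        if self.codon_map and len(self.codon_map) != len(self.nucleotides) // 3:
            raise ModelError(f"{self.gene_id}: codon map / sequence length mismatch")

    @property
    def n_codons(self) -> int:
        return len(self.nucleotides) // 3

    def codon(self, index0: int) -> str:
        return self.nucleotides[3 * index0 : 3 * index0 + 3]

    def genomic_to_cds(self) -> dict[tuple[str, int], int]:
        """Map (scaffold, genomic pos) -> 0-based position in the CDS."""
        out: dict[tuple[str, int], int] = {}
        i = 0
        for codon in self.codon_map:
            for scaffold, pos, _strand in codon:
                out[(scaffold, pos)] = i
                i += 1
        return out


@dataclass
class SampleVariant:
    """One allele carried by a haplotype: SNP or indel at a genomic position.

    ``ref``/``alt`` are plus-strand strings as in a VCF record: equal-length-1
    pairs are SNPs; a longer ``alt`` is an insertion after the anchor base, a
    longer ``ref`` a deletion of the bases after the anchor.
    """

    scaffold: str
    pos: int
    ref: str
    alt: str

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


def extract_cds(genome: GenomeRef, model: GeneModel) -> CodingSequence:
    """Splice and orient a gene's CDS, building the codon map.

    Minus-strand genes are reverse-complemented; their codon-map positions
    run in decreasing genomic order.
    """
    parts = [genome.fetch(model.scaffold, s, e) for s, e in model.cds_exons]
    plus = "".join(parts)
    positions = [p for s, e in model.cds_exons for p in range(s, e)]
    if model.strand == "-":
        seq = revcomp(plus)
        positions = positions[::-1]
    else:
        seq = plus
    n_codons = len(seq) // 3
    codon_map = [
        tuple(
            (model.scaffold, positions[3 * i + j], model.strand) for j in range(3)
        )
        for i in range(n_codons)
    ]
    # incomplete models keep only whole codons in the map
    return CodingSequence(model.gene_id, seq[: 3 * n_codons], codon_map)


def apply_haplotype(
    cds: CodingSequence, variants: Iterable[SampleVariant]
) -> CodingSequence:
    """Rebuild an allele-specific CDS from per-site variant assignments.

    Insertions and deletions shift the downstream reading frame; the net
    frame offset (total inserted minus deleted bases, mod 3) is recorded on
    the returned sequence.  Variants outside the CDS are ignored with a
    warning.  The returned sequence is truncated to a codon boundary and
    carries no codon map (its genomic anchoring is no longer one-to-one).
    """
    index = cds.genomic_to_cds()
    strand = cds.codon_map[0][0][2] if cds.codon_map else "+"
    chars: list[str] = list(cds.nucleotides)
    # inserted sequence attached after a CDS position; deletions mark positions
    insertions: dict[int, str] = {}
    deleted: set[int] = set()
    net = 0
    seen: set[int] = set()
    for v in sorted(variants, key=lambda v: v.pos):
        key = (v.scaffold, v.pos)
        if key not in index:
            warnings.warn(f"variant at {v.scaffold}:{v.pos} outside CDS; ignored")
            continue
        i = index[key]
        if v.is_snp:
            if i in seen:
                raise ValueError(f"conflicting variants at CDS position {i}")
            seen.add(i)
            base = v.alt if strand == "+" else revcomp(v.alt)
            chars[i] = base
        elif len(v.alt) > len(v.ref):  # insertion after the anchor base
            ins = v.alt[len(v.ref) :]
            if i in insertions:
                raise ValueError(f"conflicting insertions at CDS position {i}")
            if strand == "+":
                insertions[i] = ins
            else:
                # anchor base precedes the insertion on the plus strand, so in
                # coding orientation the insert lands before the anchor
                insertions[i - 1] = revcomp(ins)
            net += len(ins)
        else:  # deletion of the bases after the anchor
            ndel = len(v.ref) - len(v.alt)
            for k in range(1, ndel + 1):
                gpos = v.pos + k
                j = index.get((v.scaffold, gpos))
                if j is None:
                    continue
                if j in deleted:
                    raise ValueError(f"conflicting deletions at CDS position {j}")
                deleted.add(j)
                net -= 1
    out: list[str] = []
    for i, c in enumerate(chars):
        if i not in deleted:
            out.append(c)
        if i in insertions:
            out.append(insertions[i])
    seq = "".join(out)
    seq = seq[: 3 * (len(seq) // 3)]
    return CodingSequence(cds.gene_id, seq, [], frame_offset=net % 3)


@dataclass
class StopAnnotation:
    """First stop codon of a translated CDS, 1-based codon index."""

    position: Optional[int]
    n_codons: int
    premature: bool


def translate_and_flag(cds: CodingSequence) -> tuple[str, StopAnnotation]:
    """Translate with the standard code and locate the first stop codon.

    A stop strictly before the final codon is premature.  Translation
    continues past a premature stop so downstream changes remain visible.
    """
    protein = []
    first_stop: Optional[int] = None
    n = cds.n_codons
    for i in range(n):
        aa = translate_codon(cds.codon(i))
        if aa == "X":
            warnings.warn(f"{cds.gene_id}: ambiguous base in codon {i + 1}")
        if aa == "*" and first_stop is None:
            first_stop = i + 1
        protein.append(aa)
    ann = StopAnnotation(
        position=first_stop,
        n_codons=n,
        premature=first_stop is not None and first_stop < n,
    )
    return "".join(protein), ann


@dataclass
class HaploidGenotypeMatrix:
    """Site x haploid-sample allele calls with group labels.

    ``sites`` holds (scaffold, pos, ref, alts); ``calls[i][j]`` is the allele
    index of sample j at site i (0 = ref) or MISSING.  ``indel[i]`` flags
    sites whose alleles differ in length.
    """

    sites: list[tuple[str, int, str, tuple[str, ...]]]
    calls: list[list[int]]
    samples: list[str]
    groups: Mapping[str, str]

    def __post_init__(self) -> None:
        for s in self.samples:
            if s not in self.groups:
                raise ValueError(f"sample {s!r} has no group label")
        by_scaffold: dict[str, int] = {}
        for scaffold, pos, _r, _a in self.sites:
            prev = by_scaffold.get(scaffold)
            if prev is not None and pos <= prev:
                raise ValueError(f"sites not strictly increasing on {scaffold}")
            by_scaffold[scaffold] = pos
        for i, (scaffold, pos, ref, alts) in enumerate(self.sites):
            nall = 1 + len(alts)
            for j, c in enumerate(self.calls[i]):
                if c != MISSING and not 0 <= c < nall:
                    raise ValueError(
                        f"allele index {c} invalid at {scaffold}:{pos} sample {j}"
                    )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_indices(self, group: str) -> list[int]:
        return [j for j, s in enumerate(self.samples) if self.groups[s] == group]

    def group_names(self) -> list[str]:
        return sorted(set(self.groups.values()))

    def alleles(self, i: int) -> tuple[str, ...]:
        scaffold, pos, ref, alts = self.sites[i]
        return (ref,) + tuple(alts)

    def is_indel(self, i: int) -> bool:
        alleles = self.alleles(i)
        return len({len(a) for a in alleles}) > 1
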