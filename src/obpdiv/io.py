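"""Standard-format I/O: FASTA, GFF3, VCF v4.2, and the pipeline's TSV tables.

GFF3 gene models round-trip through the attribute ``supergene=true|false``;
sample groups travel in a separate two-column TSV (``sample<TAB>group``)
because VCF has no standard slot for population labels.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import MISSING, GeneModel, GenomeRef, HaploidGenotypeMatrix


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | os.PathLike) -> GenomeRef:
    seqs = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    return GenomeRef(seqs)


def write_fasta(path: str | os.PathLike, sequences: dict[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------- GFF3

def write_gff3(path: str | os.PathLike, models: Iterable[GeneModel]) -> None:
    """Emit gene + CDS features; internal 0-based half-open coordinates
    become GFF3 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            lo, hi = m.span
            attrs = [f"ID={m.gene_id}", f"supergene={'true' if m.in_supergene else 'false'}"]
            if m.linkage_group:
                attrs.append(f"linkage_group={m.linkage_group}")
            if m.incomplete:
                attrs.append("incomplete=true")
            fh.write(
                "\t".join(
                    [m.scaffold, "obpdiv", "gene", str(lo + 1), str(hi), ".",
                     m.strand, ".", ";".join(attrs)]
                )
                + "\n"
            )
            for s, e in m.cds_exons:
                fh.write(
                    "\t".join(
                        [m.scaffold, "obpdiv", "CDS", str(s + 1), str(e), ".",
                         m.strand, "0", f"ID=cds-{m.gene_id};Parent={m.gene_id}"]
                    )
                    + "\n"
                )


def _parse_attrs(field: str) -> dict[str, str]:
    out = {}
    for part in field.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                continue
            scaffold, _src, ftype, start, end, _score, strand, _frame, attrs = cols[:9]
            a = _parse_attrs(attrs)
            if ftype == "gene":
                gid = a["ID"]
                order.append(gid)
                genes[gid] = {
                    "scaffold": scaffold,
                    "strand": strand,
                    "exons": [],
                    "in_supergene": a.get("supergene", "false") == "true",
                    "linkage_group": a.get("linkage_group"),
                    "incomplete": a.get("incomplete", "false") == "true",
                }
            elif ftype == "CDS":
                gid = a.get("Parent") or a.get("ID")
                genes.setdefault(gid, {"scaffold": scaffold, "strand": strand,
                                       "exons": [], "in_supergene": False,
                                       "linkage_group": None, "incomplete": False})
                genes[gid]["exons"].append((int(start) - 1, int(end)))
                if gid not in order:
                    order.append(gid)
    return [
        GeneModel(
            gene_id=gid,
            scaffold=g["scaffold"],
            strand=g["strand"],
            cds_exons=sorted(g["exons"]),
            linkage_group=g["linkage_group"],
            in_supergene=g["in_supergene"],
            incomplete=g["incomplete"],
        )
        for gid in order
        if (g := genes[gid])["exons"]
    ]


# ---------------------------------------------------------------- VCF

def write_vcf(
    path: str | os.PathLike,
    geno: HaploidGenotypeMatrix,
    contig_lengths: Optional[dict[str, int]] = None,
) -> None:
    """Plain VCF v4.2 with haploid GT calls (``0``/``1``/``.``)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if contig_lengths:
            for name, length in contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.samples)
            + "\n"
        )
        for i, (scaffold, pos, ref, alts) in enumerate(geno.sites):
            alt = ",".join(alts) if alts else "."
            gts = "\t".join(
                "." if c == MISSING else str(c) for c in geno.calls[i]
            )
            fh.write(f"{scaffold}\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(
    vcf_path: str | os.PathLike, groups_path: str | os.PathLike
) -> HaploidGenotypeMatrix:
    """Load haploid genotypes with cyvcf2 plus a sample->group TSV."""
    from cyvcf2 import VCF

    groups = read_groups(groups_path)
    vcf = VCF(str(vcf_path), gts012=False)
    samples = list(vcf.samples)
    sites = []
    calls = []
    for rec in vcf:
        alts = tuple(a for a in (rec.ALT or []) if a != ".")
        sites.append((rec.CHROM, rec.POS - 1, rec.REF, alts))
        row = []
        for g in rec.genotypes:  # [allele, (allele2), phased]; haploid -> one allele
            a = g[0]
            row.append(MISSING if a is None or a < 0 else int(a))
        calls.append(row)
    return HaploidGenotypeMatrix(sites, calls, samples, groups)


def read_groups(path: str | os.PathLike) -> dict[str, str]:
    groups = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, group = line.split("\t")[:2]
            groups[sample] = group
    return groups


def write_groups(path: str | os.PathLike, groups: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for sample, group in groups.items():
            fh.write(f"{sample}\t{group}\n")


# ---------------------------------------------------------------- TSV tables

def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_table(path: str | os.PathLike, df: pd.DataFrame,
                header_comment: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
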