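"""File readers and writers.

External formats: FASTA for sequences (via Biopython), BED6 for TE
annotation (0-based half-open, name field ``te_id;family;superfamily``),
GFF3 for gene models (1-based closed, converted on read/write; the
translated protein rides in the gene attributes), YAML for region breaks,
and tab-separated tables with a mandatory header and ``.`` for missing
values for everything per accession.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .isbp import IsbpMarker
from .reference import GeneModel, MappingSummary, ReferenceModel, TeCopy
from .snp import GENOTYPE_NAMES, GenotypeMatrix

__all__ = [
    "read_reference",
    "write_reference",
    "read_mapping_summary",
    "write_mapping_summary",
    "write_markers",
    "read_markers",
    "write_genotypes_tsv",
    "write_genotypes_vcf",
    "write_fastq",
]

MISSING = "."


class ParseError(ValueError):
    pass


def _read_fasta(path: Path) -> tuple[str, str]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ParseError(f"{path}: expected exactly one sequence, found {len(records)}")
    return records[0].id, str(records[0].seq).upper()


def _read_te_bed(path: Path, chrom_id: str, length: int) -> list[TeCopy]:
    tes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 BED fields, got {len(fields)}")
            chrom, start, end, name, _, strand = fields[:6]
            if chrom != chrom_id:
                raise ParseError(f"{path}:{lineno}: chromosome {chrom!r} != {chrom_id!r}")
            try:
                s, e = int(start), int(end)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if not (0 <= s < e <= length):
                raise ParseError(f"{path}:{lineno}: interval [{s},{e}) out of bounds")
            parts = name.split(";")
            if len(parts) != 3:
                raise ParseError(f"{path}:{lineno}: name must be 'te_id;family;superfamily'")
            tes.append(TeCopy(parts[0], parts[1], parts[2], s, e, strand))
    return tes


def _read_gene_gff(path: Path, chrom_id: str, length: int) -> list[GeneModel]:
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF fields, got {len(fields)}")
            chrom, _, ftype, start, end, _, _, _, attrs = fields
            if chrom != chrom_id:
                raise ParseError(f"{path}:{lineno}: chromosome {chrom!r} != {chrom_id!r}")
            try:  # GFF is 1-based closed; internal coords 0-based half-open
                s, e = int(start) - 1, int(end)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if not (0 <= s < e <= length):
                raise ParseError(f"{path}:{lineno}: interval out of bounds")
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = attr.get("ID")
                if not gid:
                    raise ParseError(f"{path}:{lineno}: gene without ID")
                genes[gid] = {"start": s, "end": e, "protein": attr.get("protein", ""), "exons": []}
                order.append(gid)
            elif ftype == "CDS":
                parent = attr.get("Parent")
                if parent not in genes:
                    raise ParseError(f"{path}:{lineno}: CDS with unknown Parent {parent!r}")
                genes[parent]["exons"].append((s, e))
    out = []
    for gid in order:
        g = genes[gid]
        out.append(
            GeneModel(gid, g["start"], g["end"], tuple(sorted(g["exons"])), g["protein"])
        )
    return out


def read_reference(fasta, te_bed, gene_gff, region_config) -> ReferenceModel:
    """Assemble and validate a ReferenceModel from its four input files."""
    chrom_id, sequence = _read_fasta(Path(fasta))
    length = len(sequence)
    tes = _read_te_bed(Path(te_bed), chrom_id, length)
    genes = _read_gene_gff(Path(gene_gff), chrom_id, length)
    with open(region_config) as fh:
        cfg = yaml.safe_load(fh)
    breaks = tuple(int(b) for b in cfg["region_breaks"])
    if len(breaks) != 4:
        raise ParseError(f"{region_config}: expected 4 region breaks, got {len(breaks)}")
    model = ReferenceModel(chrom_id, sequence, tes, genes, breaks)
    model.validate()
    return model


def write_reference(model: ReferenceModel, outdir) -> dict[str, Path]:
    """Write FASTA/BED/GFF3/YAML; returns the path of each file written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "reference.fa",
        "te_bed": outdir / "te.bed",
        "gene_gff": outdir / "genes.gff3",
        "region_config": outdir / "regions.yaml",
    }
    SeqIO.write(
        [SeqRecord(Seq(model.sequence), id=model.chrom_id, description="")],
        str(paths["fasta"]),
        "fasta",
    )
    with open(paths["te_bed"], "w") as fh:
        for te in sorted(model.te_set, key=lambda t: (t.start, t.end)):
            name = f"{te.te_id};{te.family};{te.superfamily}"
            fh.write(f"{model.chrom_id}\t{te.start}\t{te.end}\t{name}\t0\t{te.strand}\n")
    with open(paths["gene_gff"], "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(model.gene_set, key=lambda g: (g.start, g.end)):
            fh.write(
                f"{model.chrom_id}\tchromopan\tgene\t{g.start + 1}\t{g.end}\t.\t+\t.\t"
                f"ID={g.gene_id};protein={g.protein}\n"
            )
            for s, e in g.coding_exons:
                fh.write(
                    f"{model.chrom_id}\tchromopan\tCDS\t{s + 1}\t{e}\t.\t+\t0\tParent={g.gene_id}\n"
                )
    with open(paths["region_config"], "w") as fh:
        yaml.safe_dump({"region_breaks": list(model.region_breaks)}, fh)
    return paths


# -- mapping summaries -------------------------------------------------------

_SUMMARY_FILES = {
    "locus_depth": ("locus_id", "depth"),
    "gene_counts": ("gene_id", "read_count", "covered_fraction"),
    "isbp_support": ("marker_id", "support"),
    "allele_counts": ("pos", "ref_count", "alt_count"),
    "te_weighted_counts": ("te_id", "weighted_count"),
}


def write_mapping_summary(summary: MappingSummary, outdir) -> Path:
    """One TSV per table, in a directory named after the accession."""
    d = Path(outdir) / summary.accession_id
    d.mkdir(parents=True, exist_ok=True)
    tables = {
        "locus_depth": [(k, repr(v)) for k, v in summary.locus_depth.items()],
        "gene_counts": [(k, str(c), repr(f)) for k, (c, f) in summary.gene_counts.items()],
        "isbp_support": [(k, str(v)) for k, v in summary.isbp_support.items()],
        "allele_counts": [(str(k), str(r), str(a)) for k, (r, a) in summary.allele_counts.items()],
        "te_weighted_counts": [(k, repr(v)) for k, v in summary.te_weighted_counts.items()],
    }
    for name, header in _SUMMARY_FILES.items():
        with open(d / f"{name}.tsv", "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(header)
            w.writerows(tables[name])
    return d


def read_mapping_summary(accession_dir) -> MappingSummary:
    d = Path(accession_dir)
    summary = MappingSummary(accession_id=d.name)

    def rows(name):
        path = d / f"{name}.tsv"
        with open(path) as fh:
            r = csv.reader(fh, delimiter="\t")
            header = next(r)
            if tuple(header) != _SUMMARY_FILES[name]:
                raise ParseError(f"{path}: unexpected header {header}")
            yield from r

    summary.locus_depth = {k: float(v) for k, v in rows("locus_depth")}
    summary.gene_counts = {k: (int(c), float(f)) for k, c, f in rows("gene_counts")}
    summary.isbp_support = {k: int(v) for k, v in rows("isbp_support")}
    summary.allele_counts = {int(p): (int(r), int(a)) for p, r, a in rows("allele_counts")}
    summary.te_weighted_counts = {k: float(v) for k, v in rows("te_weighted_counts")}
    summary.validate()
    return summary


# -- markers -----------------------------------------------------------------


def write_markers(markers: Sequence[IsbpMarker], chrom_id: str, bed_path, fasta_path) -> None:
    with open(bed_path, "w") as fh:
        for m in markers:
            fh.write(f"{chrom_id}\t{m.start}\t{m.stop}\t{m.marker_id};{m.te_id};{m.end}\t0\t+\n")
    SeqIO.write(
        [SeqRecord(Seq(m.sequence), id=m.marker_id, description=f"{m.te_id} {m.end}'") for m in markers],
        str(fasta_path),
        "fasta",
    )


def read_markers(bed_path, fasta_path) -> list[IsbpMarker]:
    seqs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta_path), "fasta")}
    out = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            _, start, _stop, name = fields[:4]
            marker_id, te_id, end = name.split(";")
            start = int(start)
            junction = start + 75
            out.append(IsbpMarker(marker_id, te_id, end, junction, start, seqs[marker_id]))
    return out


# -- genotypes ---------------------------------------------------------------


def write_genotypes_tsv(matrix: GenotypeMatrix, path) -> None:
    df = matrix.geno.replace({-1: None})
    out = pd.concat([matrix.sites[["ref", "alt"]], df], axis=1)
    out.to_csv(path, sep="\t", na_rep=MISSING, index_label="pos")


def write_genotypes_vcf(matrix: GenotypeMatrix, chrom_id: str, path) -> None:
    """Minimal VCF 4.2 with a GT field only."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        accs = matrix.accessions
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(accs) + "\n")
        for pos, site in matrix.sites.iterrows():
            gts = "\t".join(gt_map[int(matrix.geno.at[pos, a])] for a in accs)
            fh.write(f"{chrom_id}\t{pos + 1}\t.\t{site['ref']}\t{site['alt']}\t.\tPASS\t.\tGT\t{gts}\n")


def write_fastq(reads: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
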