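"""Genome and annotation I/O with a strand- and origin-aware sequence model.

Internal convention: 0-based half-open intervals on the forward strand.
User-facing reports are 1-based inclusive (GenBank convention). Circular
contigs permit origin-wrapping intervals, expressed with ``end > len``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class GenomeFormatError(ValueError):
    """Raised when an input file cannot be parsed under its declared format."""


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet.

    Involution: ``revcomp(revcomp(x)) == x``.
    """
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"illegal characters in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeRecord:
    """One contig: id, uppercase sequence over {A,C,G,T,N}, explicit topology."""

    contig_id: str
    sequence: str
    topology: str = "linear"  # "circular" | "linear"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ValueError(f"illegal characters in {self.contig_id}: {sorted(bad)}")
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"topology must be circular|linear, got {self.topology!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """One annotated ORF: 0-based half-open [start, end) on the forward strand.

    For genes wrapping the origin of a circular contig, ``end`` exceeds the
    contig length (normalized wrapped interval).
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str  # "+" | "-"
    product: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end}) for {self.gene_id}")

    def __len__(self) -> int:
        return self.end - self.start


def subsequence(genome: GenomeRecord, start: int, end: int, strand: str = "+") -> str:
    """Extract [start, end) on the requested strand.

    ``end > len(genome)`` wraps the origin and is only legal on circular
    contigs. strand "-" returns the reverse complement.
    """
    n = len(genome)
    if not (0 <= start < end):
        raise ValueError(f"bad interval [{start}, {end})")
    if end - start > n:
        raise ValueError("interval longer than contig")
    if end > n:
        if genome.topology != "circular":
            raise ValueError(
                f"interval [{start}, {end}) wraps origin of linear contig {genome.contig_id}"
            )
        seq = (genome.sequence + genome.sequence)[start:end]
    else:
        seq = genome.sequence[start:end]
    return revcomp(seq) if strand == "-" else seq


def gene_sequence(genome: GenomeRecord, gene: GeneModel) -> str:
    """Coding-strand (5'->3') sequence of a gene."""
    return subsequence(genome, gene.start, gene.end, gene.strand)


def _feature_to_gene(
    feat: SeqFeature, contig_id: str, contig_len: int, idx: int
) -> GeneModel:
    quals = feat.qualifiers
    locus = quals.get("locus_tag", [None])[0]
    if locus is None:
        locus = f"{contig_id}_feat{idx:05d}"
        warnings.warn(f"feature without locus_tag; synthesized id {locus}", stacklevel=2)
    product = quals.get("product", [None])[0]
    strand = "-" if feat.location.strand == -1 else "+"
    parts = sorted(feat.location.parts, key=lambda p: int(p.start))
    start = int(parts[0].start)
    end = int(parts[-1].end)
    # Origin-wrapping compound feature on a circular contig: [x, L) + [0, y)
    if len(parts) == 2 and int(parts[0].start) == 0 and int(parts[1].end) == contig_len:
        start = int(parts[1].start)
        end = contig_len + int(parts[0].end)
    return GeneModel(locus, contig_id, start, end, strand, product)


def read_genbank(path: str | Path, include_rna: bool = False):
    """Parse a GenBank flat file into genome records and gene models.

    Returns ``(genomes, genes, meta)`` where meta reports both the strict-CDS
    count and the all-feature count (CDS + RNA features).
    """
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # pragma: no cover - biopython error paths vary
        raise GenomeFormatError(f"cannot parse {path} as GenBank: {exc}") from exc
    if not records:
        raise GenomeFormatError(f"no GenBank records in {path}")

    rna_types = ("rRNA", "tRNA", "ncRNA", "tmRNA", "misc_RNA")
    genomes: list[GenomeRecord] = []
    genes: list[GeneModel] = []
    n_cds = 0
    n_all = 0
    for rec in records:
        topo = rec.annotations.get("topology", "linear")
        genomes.append(GenomeRecord(rec.id, str(rec.seq).upper(), topo))
        idx = 0
        for feat in rec.features:
            is_cds = feat.type == "CDS"
            is_rna = feat.type in rna_types
            if not (is_cds or is_rna):
                continue
            n_all += 1
            if is_cds:
                n_cds += 1
            if is_cds or (include_rna and is_rna):
                genes.append(_feature_to_gene(feat, rec.id, len(rec.seq), idx))
                idx += 1
    _check_unique([g.gene_id for g in genes])
    meta = {"n_cds": n_cds, "n_cds_plus_rna": n_all, "n_genes": len(genes)}
    return genomes, genes, meta


def _check_unique(ids: Sequence[str]) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate gene_id {i!r}")
        seen.add(i)


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise GenomeFormatError(f"no FASTA records in {path}")
    return [GenomeRecord(r.id, str(r.seq).upper()) for r in records]


def read_gff3(path: str | Path, contigs: dict[str, int]) -> list[GeneModel]:
    """Minimal GFF3 reader: CDS/gene rows become GeneModels (0-based half-open).

    ``contigs`` maps contig id -> length for coordinate validation on linear
    topology.
    """
    genes: list[GeneModel] = []
    idx = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GenomeFormatError(f"malformed GFF3 line: {line!r}")
            seqid, _, ftype, start, end, _, strand, _, attrs = cols
            if ftype not in ("CDS", "gene"):
                continue
            start0, end0 = int(start) - 1, int(end)
            if seqid in contigs and end0 > contigs[seqid]:
                raise ValueError(
                    f"feature [{start0},{end0}) outside contig {seqid} (len {contigs[seqid]})"
                )
            attrd = dict(
                kv.split("=", 1) for kv in attrs.split(";") if kv and "=" in kv
            )
            locus = attrd.get("locus_tag") or attrd.get("ID")
            if not locus:
                locus = f"{seqid}_feat{idx:05d}"
                warnings.warn(f"GFF3 feature without ID; synthesized {locus}", stacklevel=2)
            genes.append(
                GeneModel(locus, seqid, start0, end0, strand, attrd.get("product"))
            )
            idx += 1
    _check_unique([g.gene_id for g in genes])
    return genes


def read_genome(
    path: str | Path, gff3: str | Path | None = None, include_rna: bool = False
):
    """Read a genome from a GenBank file or a FASTA + GFF3 pair.

    Format is inferred from content: a file whose first non-blank line starts
    with ``LOCUS`` is GenBank; ``>`` is FASTA (``gff3`` then optional).
    """
    path = Path(path)
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line
                break
    if first.startswith("LOCUS"):
        return read_genbank(path, include_rna=include_rna)
    if first.startswith(">"):
        genomes = read_fasta(path)
        lengths = {g.contig_id: len(g) for g in genomes}
        genes = read_gff3(gff3, lengths) if gff3 else []
        meta = {"n_cds": len(genes), "n_cds_plus_rna": len(genes), "n_genes": len(genes)}
        return genomes, genes, meta
    raise GenomeFormatError(f"unrecognized format for {path} (not GenBank or FASTA)")


def write_fasta(genomes: Iterable[GenomeRecord], path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(g.sequence), id=g.contig_id, description="") for g in genomes
    ]
    SeqIO.write(recs, str(path), "fasta")


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};locus_tag={g.gene_id}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write(
                f"{g.contig_id}\tibcrispr\tCDS\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t0\t{attrs}\n"
            )


def write_genbank(
    genomes: Iterable[GenomeRecord], genes: Iterable[GeneModel], path: str | Path
) -> None:
    """Write contigs + CDS features as a GenBank flat file (round-trippable)."""
    by_contig: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_contig.setdefault(g.contig_id, []).append(g)
    recs = []
    for gen in genomes:
        rec = SeqRecord(Seq(gen.sequence), id=gen.contig_id, name=gen.contig_id[:16])
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["topology"] = gen.topology
        rec.annotations["date"] = "01-JAN-2000"  # fixed so output is byte-stable
        for gm in sorted(by_contig.get(gen.contig_id, []), key=lambda x: x.start):
            loc = FeatureLocation(gm.start, gm.end, strand=1 if gm.strand == "+" else -1)
            quals = {"locus_tag": [gm.gene_id]}
            if gm.product:
                quals["product"] = [gm.product]
            rec.features.append(SeqFeature(loc, type="CDS", qualifiers=quals))
        recs.append(rec)
    SeqIO.write(recs, str(path), "genbank")


def write_bed6(
    intervals: Iterable[tuple[str, int, int, str, int, str]], path: str | Path
) -> None:
    """Write BED6 rows (chrom, start, end, name, score, strand), 0-based half-open."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")
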