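"""Uniform gene nomenclature and a built-in naive ORF caller.

Every annotated sequence is renamed with a fixed-width identifier so that
downstream family tables stay human readable.  The contig-level header is
exactly 20 characters::

    SSSS.MMYY.GGGGG.CCCC
    species code . session date . genome index . contig number

and a gene identifier appends a border flag ('b' if the gene is the first or
last gene of its contig, 'i' otherwise) and a 5-digit gene number, for 27
characters total, e.g. ``TEST.0121.00001.0001b_00001``.

The ORF caller is a deliberately naive stand-in for a real prokaryotic gene
finder: it reports maximal open reading frames (ATG/GTG/TTG start to the
first in-frame TAA/TAG/TGA stop) of at least ``min_len`` nucleotides on both
strands, resolving overlaps by keeping the longer ORF.  Externally produced
annotations (GFF3 + genome FASTA) can be loaded instead.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

from Bio.Seq import Seq

from .prepare import Assembly, write_fasta

START_CODONS = {"ATG", "GTG", "TTG"}
STOP_CODONS = {"TAA", "TAG", "TGA"}
DEFAULT_MIN_ORF = 90
TRANSLATION_TABLE = 11  # bacterial


@dataclass(frozen=True)
class GenomeName:
    """Standardised genome name: 4-char species code, MMYY session date and
    a 1..99999 genome index; renders as e.g. ``TEST.0121.00001``."""

    species_code: str
    session_date: str
    genome_index: int

    def __post_init__(self) -> None:
        if not re.fullmatch(r"[A-Za-z0-9]{4}", self.species_code):
            raise ValueError("species code must be exactly 4 alphanumeric characters")
        if not re.fullmatch(r"\d{4}", self.session_date):
            raise ValueError("session date must be exactly 4 digits (MMYY)")
        if not 1 <= self.genome_index <= 99999:
            raise ValueError("genome index must be in 1..99999")

    def __str__(self) -> str:
        return f"{self.species_code}.{self.session_date}.{self.genome_index:05d}"


@dataclass
class GeneRecord:
    """One called gene: location on its contig, strand, border flag, and the
    coding and translated sequences (``nt_seq`` keeps the stop codon)."""

    genome: GenomeName
    contig_number: int
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # '+' or '-'
    border: bool
    gene_number: int
    protein_seq: str
    nt_seq: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def gene_id(self) -> str:
        return format_gene_id(self)


def format_contig_header(name: GenomeName, contig_number: int) -> str:
    """20-character contig header: name + '.' + 4-digit contig number."""
    if not 1 <= contig_number <= 9999:
        raise ValueError(f"contig number {contig_number} exceeds 4-digit capacity")
    return f"{name}.{contig_number:04d}"


def format_gene_id(rec: GeneRecord) -> str:
    """27-character gene identifier: contig header, border flag, gene number."""
    if not 1 <= rec.gene_number <= 99999:
        raise ValueError(f"gene number {rec.gene_number} exceeds 5-digit capacity")
    flag = "b" if rec.border else "i"
    return f"{format_contig_header(rec.genome, rec.contig_number)}{flag}_{rec.gene_number:05d}"


def translate_cds(nt: str) -> str:
    """Bacterial-code translation; alternative start codons become M."""
    prot = str(Seq(nt).translate(table=TRANSLATION_TABLE))
    if prot.endswith("*"):
        prot = prot[:-1]
    if prot and nt[:3] in START_CODONS:
        prot = "M" + prot[1:]
    return prot


def _scan_frame(seq: str, frame: int, min_len: int):
    """Maximal complete ORFs (start..stop) in one frame of ``seq``.

    Yields (start_idx, end_idx) 0-based inclusive on ``seq``.  For each stop,
    the maximal ORF begins at the first start codon after the previous stop.
    """
    first_start = None
    for i in range(frame, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            if first_start is not None and (i + 3 - first_start) >= min_len:
                yield first_start, i + 2
            first_start = None
        elif first_start is None and codon in START_CODONS:
            first_start = i


def call_orfs(assembly: Assembly, min_len: int = DEFAULT_MIN_ORF,
              name: GenomeName | None = None) -> list[GeneRecord]:
    """Call maximal ORFs >= ``min_len`` nt (stop codon included) on both
    strands of every contig; overlapping calls keep the longer ORF (ties:
    leftmost, then forward strand).  Genes are numbered 1..n in (contig,
    start) order."""
    if min_len < 3 or min_len % 3:
        raise ValueError("min_len must be >= 3 and divisible by 3")
    name = name or GenomeName("NONE", "0000", 1)
    candidates = []  # (contig_no, start, end, strand, nt_seq)
    for contig_no, (_cid, seq) in enumerate(assembly.contigs, start=1):
        fwd = seq.upper()
        rev = str(Seq(fwd).reverse_complement())
        n = len(fwd)
        for frame in range(3):
            for s, e in _scan_frame(fwd, frame, min_len):
                candidates.append((contig_no, s + 1, e + 1, "+", fwd[s : e + 1]))
            for s, e in _scan_frame(rev, frame, min_len):
                # map back to forward coordinates
                candidates.append((contig_no, n - e, n - s, "-", rev[s : e + 1]))
    # overlap resolution: longer first, then leftmost, then '+' strand
    candidates.sort(key=lambda c: (-(c[2] - c[1]), c[0], c[1], c[3]))
    kept: list[tuple] = []
    occupied: dict[int, list[tuple[int, int]]] = {}
    for cand in candidates:
        contig_no, start, end = cand[0], cand[1], cand[2]
        if any(start <= e and end >= s for s, e in occupied.get(contig_no, ())):
            continue
        occupied.setdefault(contig_no, []).append((start, end))
        kept.append(cand)
    kept.sort(key=lambda c: (c[0], c[1]))
    records = []
    for num, (contig_no, start, end, strand, nt) in enumerate(kept, start=1):
        records.append(
            GeneRecord(
                genome=name, contig_number=contig_no, start=start, end=end,
                strand=strand, border=False, gene_number=num,
                protein_seq=translate_cds(nt), nt_seq=nt,
            )
        )
    _mark_borders(records)
    return records


def _mark_borders(records: list[GeneRecord]) -> None:
    """A gene is a border gene iff it is the first or last gene of its contig."""
    by_contig: dict[int, list[GeneRecord]] = {}
    for rec in records:
        by_contig.setdefault(rec.contig_number, []).append(rec)
    for recs in by_contig.values():
        for rec in recs:
            rec.border = rec is recs[0] or rec is recs[-1]


def write_genome_outputs(assembly: Assembly, genes: list[GeneRecord],
                         name: GenomeName, out_dir: str | Path) -> dict[str, Path]:
    """Write the five per-genome files: renamed sequence FASTA (.fna), gene
    FASTA (.gen), protein FASTA (.prt), GFF3 (.gff) and summary TSV (.txt)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise RuntimeError(f"duplicate gene identifiers emitted for genome {name}")
    base = str(name)
    paths = {ext: out / f"{base}.{ext}" for ext in ("fna", "gen", "prt", "gff", "txt")}
    contig_headers = [
        format_contig_header(name, i) for i in range(1, assembly.nb_contigs + 1)
    ]
    write_fasta(paths["fna"], list(zip(contig_headers, (s for _, s in assembly.contigs))))
    write_fasta(paths["gen"], [(g.gene_id, g.nt_seq) for g in genes])
    write_fasta(paths["prt"], [(g.gene_id, g.protein_seq) for g in genes])
    with paths["gff"].open("w") as fh:
        fh.write("##gff-version 3\n")
        for header, (_cid, seq) in zip(contig_headers, assembly.contigs):
            fh.write(f"##sequence-region {header} 1 {len(seq)}\n")
        for g in genes:
            header = format_contig_header(name, g.contig_number)
            fh.write(
                f"{header}\tpancore\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\t"
                f"ID={g.gene_id}\n"
            )
    with paths["txt"].open("w") as fh:
        fh.write("genome_name\tsource_file\ttotal_length\tnb_contigs\tL90\tnb_genes\n")
        fh.write(
            f"{base}\t{assembly.source_file or '-'}\t{assembly.total_length}\t"
            f"{assembly.nb_contigs}\t{assembly.l90}\t{len(genes)}\n"
        )
    return paths


def read_gff_annotations(gff_path: str | Path, fasta_path: str | Path,
                         name: GenomeName) -> list[GeneRecord]:
    """Rebuild GeneRecords from a GFF3 file plus the renamed genome FASTA.

    Accepts both this package's output (round trip) and external annotations
    whose seqids match the renamed contig headers.
    """
    from .prepare import _parse_fasta_text

    contig_seqs = {
        h: s for h, s in _parse_fasta_text(Path(fasta_path).read_text())
    }
    records: list[GeneRecord] = []
    for line in Path(gff_path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9 or cols[2] != "CDS":
            continue
        seqid, _src, _type, start, end, _score, strand, _phase, attrs = cols
        gene_id = dict(
            kv.split("=", 1) for kv in attrs.rstrip(";").split(";") if "=" in kv
        )["ID"]
        seq = contig_seqs[seqid]
        nt = seq[int(start) - 1 : int(end)].upper()
        if strand == "-":
            nt = str(Seq(nt).reverse_complement())
        contig_number = int(seqid.rsplit(".", 1)[1])
        flag, num = gene_id[20], int(gene_id[22:])
        records.append(
            GeneRecord(
                genome=name, contig_number=contig_number, start=int(start),
                end=int(end), strand=strand, border=flag == "b", gene_number=num,
                protein_seq=translate_cds(nt), nt_seq=nt,
            )
        )
    records.sort(key=lambda r: (r.contig_number, r.start))
    return records
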