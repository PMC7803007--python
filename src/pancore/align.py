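"""Persistent-genome alignment: protein star alignment, codon
back-translation, gap padding and per-genome concatenation.

Each family is aligned at the protein level and back-translated so that every
aligned nucleotide row, once its gaps are removed, is *identical* to the
original coding sequence (minus the terminal stop codon).  Genomes in which a
family is absent, or present in more than one copy, receive an all-gap row of
the family's alignment length; the padded family rows are then concatenated
in ascending family-id order into one equal-length matrix per genome, the
input for distance-based tree inference.

The built-in aligner is a star alignment (centre = longest sequence, global
pairwise alignments merged under the once-a-gap-always-a-gap rule) with the
same fixed scoring as the family construction stage (BLOSUM62, gap open -11,
extend -1).  Externally produced protein alignments can be supplied per
family instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .annotate import STOP_CODONS, translate_cds
from .pangenome import make_aligner
from .prepare import write_fasta

GAP = "-"


@dataclass
class FamilyAlignment:
    """Codon alignment of one family over all genomes.

    Every row has length ``3 * aln_protein_len``; absent/multi genomes carry
    all-gap rows.
    """

    family_id: int
    rows: dict[str, str]
    aln_protein_len: int
    status: dict[str, str] = field(default_factory=dict)  # single|absent|multi


@dataclass
class Concatenate:
    genomes: list[str]
    rows: dict[str, str]
    n_columns: int

    def gap_fraction(self, genome_id: str) -> float:
        row = self.rows[genome_id]
        return row.count(GAP) / len(row) if row else 0.0


def align_proteins(family_proteins: list[tuple[str, str]]) -> dict[str, str]:
    """Star-align a family's proteins; returns id -> equal-length gapped row.

    Centre = longest sequence (ties: lexicographically smallest id); every
    other sequence is globally aligned to the centre and the pairwise gap
    patterns are merged (a gap column introduced by any sequence appears in
    all rows).
    """
    if not family_proteins:
        raise ValueError("cannot align an empty family")
    for gid, prot in family_proteins:
        if not prot:
            raise ValueError(f"empty protein sequence for {gid!r}")
    if len(family_proteins) == 1:
        gid, prot = family_proteins[0]
        return {gid: prot}
    center_id, center = min(family_proteins, key=lambda p: (-len(p[1]), p[0]))
    aligner = make_aligner()
    L = len(center)
    # per sequence: insertions[i] = chars inserted before centre residue i
    # (i == L means after the last residue), and matched[i] = residue or gap
    per_seq: dict[str, tuple[list[list[str]], list[str]]] = {}
    master_ins = [0] * (L + 1)
    for gid, prot in family_proteins:
        if gid == center_id and prot == center:
            continue
        aln = aligner.align(center, prot)[0]
        gapped_c, gapped_s = str(aln[0]), str(aln[1])
        ins: list[list[str]] = [[] for _ in range(L + 1)]
        matched: list[str] = []
        pos = 0  # next centre residue index
        for cc, sc in zip(gapped_c, gapped_s):
            if cc == GAP:
                ins[pos].append(sc)
            else:
                matched.append(sc)
                pos += 1
        per_seq[gid] = (ins, matched)
        for i in range(L + 1):
            master_ins[i] = max(master_ins[i], len(ins[i]))
    rows: dict[str, str] = {}
    for gid, prot in family_proteins:
        parts: list[str] = []
        if gid == center_id and prot == center:
            for i in range(L):
                parts.append(GAP * master_ins[i] + center[i])
            parts.append(GAP * master_ins[L])
        else:
            ins, matched = per_seq[gid]
            for i in range(L):
                parts.append("".join(ins[i]).ljust(master_ins[i], GAP) + matched[i])
            parts.append("".join(ins[L]).ljust(master_ins[L], GAP))
        rows[gid] = "".join(parts)
    lengths = {len(r) for r in rows.values()}
    assert len(lengths) == 1, "star merge produced unequal row lengths"
    return rows


def trim_stop(nt_gene: str) -> str:
    """Drop the terminal stop codon of a coding sequence, if present."""
    if len(nt_gene) >= 3 and len(nt_gene) % 3 == 0 and nt_gene[-3:].upper() in STOP_CODONS:
        return nt_gene[:-3]
    return nt_gene


def backtranslate(prot_row: str, nt_gene: str, gene_id: str = "") -> str:
    """Replace each amino acid of the aligned protein row by its original
    codon and each gap by three gaps."""
    nt = trim_stop(nt_gene.upper())
    prot = prot_row.replace(GAP, "")
    if len(nt) != 3 * len(prot):
        raise ValueError(
            f"gene {gene_id or '?'}: coding sequence length {len(nt)} does not "
            f"match {len(prot)} aligned residues"
        )
    if translate_cds(nt) != prot:
        raise ValueError(
            f"gene {gene_id or '?'}: protein row does not translate from the "
            "coding sequence"
        )
    out: list[str] = []
    pos = 0
    for aa in prot_row:
        if aa == GAP:
            out.append(GAP * 3)
        else:
            out.append(nt[3 * pos : 3 * pos + 3])
            pos += 1
    return "".join(out)


def align_family(
    family_id: int,
    members: dict[str, list[tuple[str, str]]],
    all_genomes: list[str],
    protein_alignment: dict[str, str] | None = None,
) -> FamilyAlignment:
    """Build the padded codon alignment of one family.

    ``members`` maps genome_id -> [(gene_id, nt_seq), ...].  Genomes with
    exactly one member are aligned; genomes with zero or several members are
    padded with gaps.  ``protein_alignment`` (genome_id -> gapped protein
    row) substitutes an externally computed alignment for the built-in star
    aligner.
    """
    status = {}
    single: dict[str, tuple[str, str]] = {}
    for g in all_genomes:
        genes = members.get(g, [])
        if len(genes) == 1:
            status[g] = "single"
            single[g] = genes[0]
        elif not genes:
            status[g] = "absent"
        else:
            status[g] = "multi"
    if not single:
        raise ValueError(f"family {family_id}: no single-copy genome to align")
    if protein_alignment is None:
        proteins = [
            (g, translate_cds(trim_stop(nt))) for g, (_gid, nt) in single.items()
        ]
        protein_alignment = align_proteins(sorted(proteins))
    aln_len = len(next(iter(protein_alignment.values())))
    rows = {}
    for g, (gene_id, nt) in single.items():
        rows[g] = backtranslate(protein_alignment[g], nt, gene_id=gene_id)
    fam = FamilyAlignment(family_id, rows, aln_len, status)
    return pad_missing(fam, all_genomes)


def pad_missing(fam: FamilyAlignment, all_genomes: list[str]) -> FamilyAlignment:
    """Give every genome a row: absent/multi genomes get all-gap rows."""
    width = 3 * fam.aln_protein_len
    for g in all_genomes:
        if g not in fam.rows:
            fam.rows[g] = GAP * width
            fam.status.setdefault(g, "absent")
    return fam


def concatenate(fams: list[FamilyAlignment], all_genomes: list[str]) -> Concatenate:
    """Join padded family rows in ascending family-id order."""
    rows = {g: [] for g in all_genomes}
    total = 0
    for fam in sorted(fams, key=lambda f: f.family_id):
        width = 3 * fam.aln_protein_len
        total += width
        for g in all_genomes:
            row = fam.rows.get(g)
            if row is None or len(row) != width:
                raise RuntimeError(
                    f"family {fam.family_id}: genome {g} row missing or of "
                    f"wrong length (expected {width})"
                )
            rows[g].append(row)
    return Concatenate(
        genomes=list(all_genomes),
        rows={g: "".join(parts) for g, parts in rows.items()},
        n_columns=total,
    )


def write_concatenate(c: Concatenate, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    write_fasta(path, [(g, c.rows[g]) for g in c.genomes])


def read_concatenate(path: str | Path) -> Concatenate:
    from .prepare import _parse_fasta_text

    entries = _parse_fasta_text(Path(path).read_text())
    genomes = [h for h, _ in entries]
    rows = dict(entries)
    lengths = {len(s) for s in rows.values()}
    if len(lengths) > 1:
        raise ValueError("concatenated alignment rows have unequal lengths")
    return Concatenate(genomes=genomes, rows=rows, n_columns=lengths.pop() if lengths else 0)
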