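"""Assembly intake and dataset curation.

Draft genomes often concatenate contigs into a single FASTA entry joined by
runs of ``N``.  This module splits such entries back into contigs, computes
per-assembly quality statistics (contig count, total length, L90 — the
minimum number of contigs covering at least 90% of the assembly), filters
assemblies on those statistics, orders the survivors by quality, and applies
a greedy pairwise-distance filter that removes near-duplicates and
taxonomic outliers in a single sweep over the quality-ordered list.

Coordinates throughout the package are 1-based inclusive (GFF3 convention).
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path

# Defaults mirrored by the CLI.
DEFAULT_CUTN = 5
DEFAULT_L90_MAX = 100
DEFAULT_NBCONT_MAX = 999
DEFAULT_MIN_DIST = 1e-4
DEFAULT_MAX_DIST = 0.06

IUPAC_NT = set("ACGTURYSWKMBDHVN")


@dataclass
class Assembly:
    """A genome as an ordered list of contigs plus QC statistics."""

    genome_id: str
    contigs: list[tuple[str, str]]  # (contig_id, sequence)
    source_file: str | None = None
    discarded_reason: str | None = None

    @property
    def nb_contigs(self) -> int:
        return len(self.contigs)

    @property
    def total_length(self) -> int:
        return sum(len(seq) for _, seq in self.contigs)

    @property
    def l90(self) -> int:
        return compute_l90([len(seq) for _, seq in self.contigs])

    @property
    def sequence(self) -> str:
        """All contigs concatenated (sketching input)."""
        return "".join(seq for _, seq in self.contigs)


@dataclass
class Discard:
    genome_id: str
    reason: str  # l90_exceeded | nbcont_exceeded | too_close | too_distant
    partner: str | None = None
    distance: float | None = None


@dataclass
class FilterReport:
    """Outcome of a filtering pass: kept genome ids (order preserved) and
    discarded genomes with the reason and, for distance discards, the kept
    partner that triggered the discard."""

    kept: list[str]
    discarded: list[Discard] = field(default_factory=list)

    def discarded_ids(self) -> set[str]:
        return {d.genome_id for d in self.discarded}


def split_contigs(entries, genome_id: str = "", cutn: int = DEFAULT_CUTN) -> Assembly:
    """Split FASTA entries at every run of at least ``cutn`` consecutive Ns.

    ``entries`` is FASTA text or a list of (header, sequence) pairs.  Runs of
    length >= cutn are removed and split the entry; shorter runs are kept
    verbatim; empty fragments are dropped.  ``cutn=0`` disables splitting.
    Contigs are numbered in input order starting at 1.
    """
    if isinstance(entries, str):
        entries = _parse_fasta_text(entries)
    if not entries:
        raise ValueError("empty FASTA input: no sequence entries found")
    if cutn < 0:
        raise ValueError("cutn must be >= 0")
    splitter = re.compile(f"[Nn]{{{cutn},}}") if cutn >= 1 else None
    contigs: list[tuple[str, str]] = []
    num = 0
    for header, seq in entries:
        bad = set(seq.upper()) - IUPAC_NT
        if bad:
            raise ValueError(
                f"non-IUPAC character {sorted(bad)[0]!r} in entry {header!r}"
            )
        fragments = splitter.split(seq) if splitter else [seq]
        for frag in fragments:
            if not frag:
                continue
            num += 1
            contigs.append((f"{num}", frag))
    return Assembly(genome_id=genome_id or "genome", contigs=contigs)


def _parse_fasta_text(text: str) -> list[tuple[str, str]]:
    entries: list[tuple[str, str]] = []
    header = None
    chunks: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                entries.append((header, "".join(chunks)))
            header = line[1:].split()[0] if len(line) > 1 else ""
            chunks = []
        elif header is None:
            raise ValueError("FASTA input does not start with a '>' header")
        else:
            chunks.append(line)
    if header is not None:
        entries.append((header, "".join(chunks)))
    return entries


def read_fasta_file(path: str | Path, genome_id: str | None = None,
                    cutn: int = DEFAULT_CUTN) -> Assembly:
    """Read one (optionally gzip-compressed) FASTA file into a split Assembly."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        text = fh.read()
    gid = genome_id or path.name.removesuffix(".gz").rsplit(".", 1)[0]
    asm = split_contigs(text, genome_id=gid, cutn=cutn)
    asm.source_file = str(path)
    return asm


def compute_l90(contig_lengths: list[int]) -> int:
    """Smallest m such that the m largest contigs cover >= 90% of the total."""
    if not contig_lengths:
        raise ValueError("cannot compute L90 of an empty assembly")
    if any(x <= 0 for x in contig_lengths):
        raise ValueError("contig lengths must be positive")
    target = 0.9 * sum(contig_lengths)
    acc = 0
    for m, length in enumerate(sorted(contig_lengths, reverse=True), start=1):
        acc += length
        if acc >= target:
            return m
    return len(contig_lengths)  # unreachable; guards float edge cases


def quality_filter(
    assemblies: list[Assembly],
    l90_max: int = DEFAULT_L90_MAX,
    nbcont_max: int = DEFAULT_NBCONT_MAX,
) -> FilterReport:
    """Discard assemblies with L90 *higher than* ``l90_max`` or *more than*
    ``nbcont_max`` contigs; equality passes.  Input order is preserved."""
    if l90_max < 1 or nbcont_max < 1:
        raise ValueError("thresholds must be >= 1")
    report = FilterReport(kept=[])
    for asm in assemblies:
        if asm.l90 > l90_max:
            asm.discarded_reason = "l90_exceeded"
            report.discarded.append(Discard(asm.genome_id, "l90_exceeded"))
        elif asm.nb_contigs > nbcont_max:
            asm.discarded_reason = "nbcont_exceeded"
            report.discarded.append(Discard(asm.genome_id, "nbcont_exceeded"))
        else:
            report.kept.append(asm.genome_id)
    return report


def sort_by_quality(assemblies: list[Assembly]) -> list[Assembly]:
    """Order by increasing L90, then increasing contig count, then genome id."""
    return sorted(assemblies, key=lambda a: (a.l90, a.nb_contigs, a.genome_id))


def greedy_distance_filter(
    ordered: list[Assembly],
    distances,
    min_dist: float = DEFAULT_MIN_DIST,
    max_dist: float = DEFAULT_MAX_DIST,
) -> FilterReport:
    """Sweep the quality-ordered list; each surviving genome discards every
    later survivor closer than ``min_dist`` (too_close) or farther than
    ``max_dist`` (too_distant).  Thresholds are strict, so equality passes.

    ``distances`` is a DistanceMatrix or a mapping keyed by
    ``frozenset({id_a, id_b})``.  The report names, for each discarded
    genome, the kept partner that triggered the discard.
    """
    if not 0 <= min_dist < max_dist:
        raise ValueError("need 0 <= min_dist < max_dist")
    lookup = distances.lookup() if hasattr(distances, "lookup") else distances
    ids = [a.genome_id for a in ordered]
    alive = dict.fromkeys(ids, True)
    discards: list[Discard] = []
    for i, g in enumerate(ids):
        if not alive[g]:
            continue
        for h in ids[i + 1 :]:
            if not alive[h]:
                continue
            key = frozenset((g, h))
            if key not in lookup:
                raise KeyError(f"missing pairwise distance for ({g}, {h})")
            d = lookup[key]
            if d < min_dist:
                alive[h] = False
                discards.append(Discard(h, "too_close", partner=g, distance=d))
            elif d > max_dist:
                alive[h] = False
                discards.append(Discard(h, "too_distant", partner=g, distance=d))
    return FilterReport(kept=[g for g in ids if alive[g]], discarded=discards)


def write_prepare_outputs(
    assemblies: list[Assembly],
    reports: list[FilterReport],
    out_dir: str | Path,
) -> None:
    """Write per-genome split FASTA, an assembly-info TSV and a discarded TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    discarded = {d.genome_id: d for rep in reports for d in rep.discarded}
    with (out / "assembly_info.tsv").open("w") as fh:
        fh.write("genome_id\tsource_file\ttotal_length\tnb_contigs\tL90\n")
        for asm in assemblies:
            fh.write(
                f"{asm.genome_id}\t{asm.source_file or '-'}\t"
                f"{asm.total_length}\t{asm.nb_contigs}\t{asm.l90}\n"
            )
    with (out / "discarded.tsv").open("w") as fh:
        fh.write("genome_id\treason\tpartner\tdistance\n")
        for d in discarded.values():
            dist = f"{d.distance:.6g}" if d.distance is not None else "-"
            fh.write(f"{d.genome_id}\t{d.reason}\t{d.partner or '-'}\t{dist}\n")
    fasta_dir = out / "split_fasta"
    fasta_dir.mkdir(exist_ok=True)
    for asm in assemblies:
        if asm.genome_id in discarded:
            continue
        write_fasta(
            fasta_dir / f"{asm.genome_id}.fna",
            [(f"{asm.genome_id}_contig{cid}", seq) for cid, seq in asm.contigs],
        )


def write_fasta(path: str | Path, entries: list[tuple[str, str]], width: int = 60) -> None:
    """Write entries as multi-FASTA wrapped at ``width`` columns."""
    with Path(path).open("w") as fh:
        for header, seq in entries:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
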