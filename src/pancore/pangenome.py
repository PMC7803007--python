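"""Protein-family (pangenome) construction.

All proteins of all genomes are compared pairwise by global alignment
(BLOSUM62, affine gaps open -11 / extend -1); a similarity edge is kept when
the alignment identity is at least ``min_id`` (default 0.8) and the aligned
span covers at least ``min_cov`` (default 0.8) of *both* sequences.  Identity
is counted over all alignment columns, internal gaps included.  Families are
then the connected components of the edge graph (the default), or one of two
greedy alternatives (set cover, greedy incremental).  Pre-computed cluster
tables are accepted as input.

The all-vs-all comparison is quadratic by design; an exact k-mer prefilter
(pairs sharing no protein 5-mer cannot reach 80% identity at these lengths
and are skipped) speeds it up without changing results and can be disabled.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import networkx as nx
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

DEFAULT_MIN_ID = 0.8
DEFAULT_MIN_COV = 0.8
PREFILTER_KMER = 5

_STD_GENE_ID = re.compile(r"[A-Za-z0-9]{4}\.\d{4}\.\d{5}\.\d{4}[bi]_\d{5}")


@dataclass(frozen=True)
class SimilarityEdge:
    gene_a: str
    gene_b: str
    identity: float
    coverage_a: float
    coverage_b: float


@dataclass
class PangenomeMatrix:
    """A partition of all genes into families, with per-genome copy counts.

    ``families`` maps family_id (1..F, ordered by the lexicographically
    smallest member) to the sorted member gene ids; ``counts`` is a
    families x genomes DataFrame of copy numbers and ``presence`` its
    binarisation.
    """

    families: dict[int, list[str]]
    counts: pd.DataFrame
    presence: pd.DataFrame

    @property
    def n_families(self) -> int:
        return len(self.families)

    @property
    def genomes(self) -> list[str]:
        return list(self.counts.columns)


def genome_of_gene(gene_id: str) -> str:
    """Genome name of a gene: the 15-character prefix for standardised ids,
    the id itself otherwise (so toy graphs degrade gracefully)."""
    if _STD_GENE_ID.fullmatch(gene_id):
        return gene_id[:15]
    return gene_id


def make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


def _kmer_set(prot: str, k: int = PREFILTER_KMER) -> frozenset:
    return frozenset(prot[i : i + k] for i in range(len(prot) - k + 1))


def similarity_edge(
    id_a: str, a: str, id_b: str, b: str,
    aligner: Align.PairwiseAligner,
    min_id: float, min_cov: float,
) -> SimilarityEdge | None:
    """Align one pair and return its edge if it passes all three thresholds."""
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    identity = counts.identities / columns if columns else 0.0
    ta, tb = aln.aligned
    cov_a = (ta[-1][1] - ta[0][0]) / len(a) if len(ta) else 0.0
    cov_b = (tb[-1][1] - tb[0][0]) / len(b) if len(tb) else 0.0
    if identity >= min_id and cov_a >= min_cov and cov_b >= min_cov:
        return SimilarityEdge(id_a, id_b, identity, cov_a, cov_b)
    return None


def pairwise_similarity(
    proteins: list[tuple[str, str]],
    min_id: float = DEFAULT_MIN_ID,
    min_cov: float = DEFAULT_MIN_COV,
    prefilter: bool = True,
) -> list[SimilarityEdge]:
    """All-vs-all similarity edges over (gene_id, protein) pairs."""
    if not 0 < min_id <= 1 or not 0 < min_cov <= 1:
        raise ValueError("thresholds must be in (0, 1]")
    usable = []
    for gid, prot in proteins:
        if not prot:
            warnings.warn(f"empty protein {gid!r} skipped", stacklevel=2)
            continue
        usable.append((gid, prot))
    aligner = make_aligner()
    kmers = {gid: _kmer_set(prot) for gid, prot in usable} if prefilter else None
    edges: list[SimilarityEdge] = []
    for (ida, a), (idb, b) in combinations(usable, 2):
        if kmers is not None and kmers[ida].isdisjoint(kmers[idb]):
            continue
        edge = similarity_edge(ida, a, idb, b, aligner, min_id, min_cov)
        if edge is not None:
            edges.append(edge)
    return edges


def _check_edges(edges, all_genes: list[str]) -> None:
    known = set(all_genes)
    for e in edges:
        for g in (e.gene_a, e.gene_b):
            if g not in known:
                raise ValueError(f"edge references unknown gene {g!r}")


def _build_matrix(groups: list[list[str]], all_genes: list[str]) -> PangenomeMatrix:
    """Number families by smallest member id and tabulate per-genome copies."""
    assigned = [g for grp in groups for g in grp]
    if sorted(assigned) != sorted(all_genes):
        raise ValueError("family groups do not partition the gene set")
    ordered = sorted((sorted(grp) for grp in groups), key=lambda grp: grp[0])
    families = {fid: members for fid, members in enumerate(ordered, start=1)}
    genomes = sorted({genome_of_gene(g) for g in all_genes})
    counts = pd.DataFrame(0, index=list(families), columns=genomes, dtype=int)
    for fid, members in families.items():
        for g in members:
            counts.loc[fid, genome_of_gene(g)] += 1
    return PangenomeMatrix(families, counts, (counts >= 1).astype(int))


def cluster_connected(edges, all_genes: list[str]) -> PangenomeMatrix:
    """Families = connected components of the similarity graph; edge-less
    genes become singleton families."""
    _check_edges(edges, all_genes)
    graph = nx.Graph()
    graph.add_nodes_from(all_genes)
    graph.add_edges_from((e.gene_a, e.gene_b) for e in edges)
    return _build_matrix([list(c) for c in nx.connected_components(graph)], all_genes)


def cluster_greedy(
    edges, all_genes: list[str], mode: str,
    lengths: dict[str, int] | None = None,
) -> PangenomeMatrix:
    """Greedy clustering of the same similarity graph.

    ``set_cover`` repeatedly promotes the unassigned gene with the most
    unassigned neighbours to representative of a new family (ties broken by
    gene id).  ``greedy_incremental`` processes genes in decreasing length
    order (``lengths``; ties by gene id); each gene joins the earliest
    representative it has an edge to, else founds a new family.
    """
    _check_edges(edges, all_genes)
    adj: dict[str, set[str]] = {g: set() for g in all_genes}
    for e in edges:
        adj[e.gene_a].add(e.gene_b)
        adj[e.gene_b].add(e.gene_a)
    groups: list[list[str]] = []
    if mode == "set_cover":
        unassigned = set(all_genes)
        while unassigned:
            best = max(len(adj[g] & unassigned) for g in unassigned)
            rep = min(g for g in unassigned if len(adj[g] & unassigned) == best)
            members = {rep} | (adj[rep] & unassigned)
            unassigned -= members
            groups.append(sorted(members))
    elif mode == "greedy_incremental":
        lengths = lengths or {}
        order = sorted(all_genes, key=lambda g: (-lengths.get(g, 0), g))
        reps: list[str] = []
        membership: dict[str, list[str]] = {}
        for g in order:
            for rep in reps:
                if rep in adj[g]:
                    membership[rep].append(g)
                    break
            else:
                reps.append(g)
                membership[g] = [g]
        groups = [membership[rep] for rep in reps]
    else:
        raise ValueError(f"unknown clustering mode {mode!r}")
    return _build_matrix(groups, all_genes)


def read_external_clusters(path: str | Path, all_genes: list[str]) -> PangenomeMatrix:
    """Load a two-column representative<TAB>member cluster table."""
    by_rep: dict[str, list[str]] = {}
    seen: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        rep, member = line.rstrip("\n").split("\t")[:2]
        if member in seen and seen[member] != rep:
            raise ValueError(
                f"gene {member!r} listed under representatives "
                f"{seen[member]!r} and {rep!r}: not a partition"
            )
        if member not in seen:
            seen[member] = rep
            by_rep.setdefault(rep, []).append(member)
    return _build_matrix(list(by_rep.values()), all_genes)


def write_pangenome(m: PangenomeMatrix, out: str | Path, stem: str = "pangenome") -> dict[str, Path]:
    """Write the membership list (.lst), presence TSV and counts TSV."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "lst": out / f"{stem}.lst",
        "presence": out / f"{stem}_presence.tsv",
        "counts": out / f"{stem}_counts.tsv",
    }
    with paths["lst"].open("w") as fh:
        for fid, members in m.families.items():
            fh.write(" ".join([str(fid), *sorted(members)]) + "\n")
    m.presence.to_csv(paths["presence"], sep="\t", index_label="family_id")
    m.counts.to_csv(paths["counts"], sep="\t", index_label="family_id")
    return paths


def read_pangenome_lst(path: str | Path) -> PangenomeMatrix:
    """Rebuild a PangenomeMatrix from a membership .lst file.

    Family ids stored in the file are preserved (a persistent-genome file
    keeps the numbering of the full pangenome it was selected from).
    """
    families: dict[int, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        families[int(parts[0])] = sorted(parts[1:])
    seen: set[str] = set()
    for members in families.values():
        for g in members:
            if g in seen:
                raise ValueError(f"gene {g!r} occurs in more than one family")
            seen.add(g)
    genomes = sorted({genome_of_gene(g) for g in seen})
    counts = pd.DataFrame(0, index=sorted(families), columns=genomes, dtype=int)
    for fid, members in families.items():
        for g in members:
            counts.loc[fid, genome_of_gene(g)] += 1
    families = {fid: families[fid] for fid in sorted(families)}
    return PangenomeMatrix(families, counts, (counts >= 1).astype(int))
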