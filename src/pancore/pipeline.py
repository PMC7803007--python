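"""End-to-end orchestration of the pipeline stages.

These helpers chain prepare -> sketch -> annotate -> pangenome -> corepers ->
align -> tree on in-memory assemblies; the CLI's ``all`` command and the
test-suite's ground-truth recovery checks both go through them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from . import align as align_mod
from . import annotate, corepers, pangenome, prepare, sketch, tree
from .distances import DistanceMatrix


@dataclass
class AnnotatedGenomes:
    """Gene records per genome, keyed by the rendered genome name."""

    names: dict[str, annotate.GenomeName]  # original genome_id -> name
    records: dict[str, list[annotate.GeneRecord]]  # rendered name -> genes

    def proteins(self) -> list[tuple[str, str]]:
        return [
            (rec.gene_id, rec.protein_seq)
            for recs in self.records.values()
            for rec in recs
        ]

    def gene_index(self) -> dict[str, annotate.GeneRecord]:
        return {
            rec.gene_id: rec for recs in self.records.values() for rec in recs
        }


def curate(
    assemblies: list[prepare.Assembly],
    l90_max: int = prepare.DEFAULT_L90_MAX,
    nbcont_max: int = prepare.DEFAULT_NBCONT_MAX,
    min_dist: float = prepare.DEFAULT_MIN_DIST,
    max_dist: float = prepare.DEFAULT_MAX_DIST,
    k: int = sketch.DEFAULT_K,
    sketch_size: int = sketch.DEFAULT_SKETCH_SIZE,
) -> tuple[list[prepare.Assembly], list[prepare.FilterReport], DistanceMatrix]:
    """Quality filter, quality sort, sketch and greedy distance filter.

    Returns the kept assemblies in quality order, the two filter reports and
    the sketch distance matrix over the quality-filtered genomes.
    """
    qrep = prepare.quality_filter(assemblies, l90_max=l90_max, nbcont_max=nbcont_max)
    survivors = [a for a in assemblies if a.genome_id in set(qrep.kept)]
    ordered = prepare.sort_by_quality(survivors)
    sketches = [
        sketch.make_sketch(a.sequence, genome_id=a.genome_id, k=k, s=sketch_size)
        for a in ordered
    ]
    if not sketches:
        import numpy as np

        return [], [qrep], DistanceMatrix([], np.zeros((0, 0)))
    dm = sketch.pairwise_distances(sketches)
    drep = prepare.greedy_distance_filter(ordered, dm, min_dist=min_dist, max_dist=max_dist)
    kept = [a for a in ordered if a.genome_id in set(drep.kept)]
    return kept, [qrep, drep], dm


def annotate_genomes(
    assemblies: list[prepare.Assembly],
    species: str = "TEST",
    date: str = "0121",
    min_orf: int = annotate.DEFAULT_MIN_ORF,
    out_dir: str | Path | None = None,
) -> AnnotatedGenomes:
    """Call ORFs and assign standardised names in the given (quality) order."""
    names: dict[str, annotate.GenomeName] = {}
    records: dict[str, list[annotate.GeneRecord]] = {}
    for index, asm in enumerate(assemblies, start=1):
        name = annotate.GenomeName(species, date, index)
        genes = annotate.call_orfs(asm, min_len=min_orf, name=name)
        names[asm.genome_id] = name
        records[str(name)] = genes
        if out_dir is not None:
            annotate.write_genome_outputs(asm, genes, name, out_dir)
    return AnnotatedGenomes(names=names, records=records)


def build_pangenome(
    ann: AnnotatedGenomes,
    min_id: float = pangenome.DEFAULT_MIN_ID,
    min_cov: float = pangenome.DEFAULT_MIN_COV,
    mode: str = "connected",
) -> pangenome.PangenomeMatrix:
    proteins = ann.proteins()
    all_genes = [gid for gid, _ in proteins]
    edges = pangenome.pairwise_similarity(proteins, min_id=min_id, min_cov=min_cov)
    if mode == "connected":
        return pangenome.cluster_connected(edges, all_genes)
    lengths = {gid: len(p) for gid, p in proteins}
    return pangenome.cluster_greedy(edges, all_genes, mode=mode, lengths=lengths)


def align_persistent(
    ann: AnnotatedGenomes,
    m: pangenome.PangenomeMatrix,
    selection: corepers.PersistenceResult,
) -> align_mod.Concatenate:
    """Align every selected family and concatenate over all genomes."""
    gene_index = ann.gene_index()
    all_genomes = sorted(ann.records)
    fams = []
    for fid in selection.selected:
        members: dict[str, list[tuple[str, str]]] = {}
        for gid in m.families[fid]:
            rec = gene_index[gid]
            genome = pangenome.genome_of_gene(gid)
            members.setdefault(genome, []).append((gid, rec.nt_seq))
        fams.append(align_mod.align_family(fid, members, all_genomes))
    return align_mod.concatenate(fams, all_genomes)


@dataclass
class PipelineResult:
    kept: list[prepare.Assembly]
    reports: list[prepare.FilterReport]
    mash: DistanceMatrix
    annotated: AnnotatedGenomes
    matrix: pangenome.PangenomeMatrix
    persistence: corepers.PersistenceResult
    concatenate: align_mod.Concatenate | None
    phylogeny: tree.PhyloTree | None
    outputs: dict[str, Path] = field(default_factory=dict)


def run_all(
    assemblies: list[prepare.Assembly],
    out_dir: str | Path | None = None,
    species: str = "TEST",
    date: str = "0121",
    tol: float = 1.0,
    mode: str = "strict",
    min_orf: int = annotate.DEFAULT_MIN_ORF,
    tree_source: str = "alignment",
    **curate_kwargs,
) -> PipelineResult:
    """Run every stage in order; writes standard outputs when ``out_dir``
    is given.  ``tree_source`` is 'alignment' (p-distances of the persistent
    concatenate) or 'mash' (sketch distance matrix)."""
    out = Path(out_dir) if out_dir is not None else None
    kept, reports, dm = curate(assemblies, **curate_kwargs)
    if out is not None:
        prepare.write_prepare_outputs(assemblies, reports, out / "prepare")
        dm.write_tsv(out / "prepare" / "mash_distances.tsv")
    ann = annotate_genomes(
        kept, species=species, date=date, min_orf=min_orf,
        out_dir=None if out is None else out / "annotate",
    )
    matrix = build_pangenome(ann)
    persistence = corepers.classify(matrix, tol=tol, mode=mode)
    outputs: dict[str, Path] = {}
    if out is not None:
        outputs.update(pangenome.write_pangenome(matrix, out / "pangenome"))
        outputs["persistent"] = corepers.write_persistent(
            persistence, matrix, out / "corepers" / "persistent.lst"
        )
    concat = phylo = None
    if persistence.selected:
        concat = align_persistent(ann, matrix, persistence)
        if tree_source == "mash":
            rename = {a.genome_id: str(ann.names[a.genome_id]) for a in kept}
            keep_ids = [gid for gid in dm.ids if gid in rename]
            idx = [dm.ids.index(g) for g in keep_ids]
            sub = dm.values[idx][:, idx]
            tdm = DistanceMatrix([rename[g] for g in keep_ids], sub)
        else:
            tdm = tree.p_distances(concat)
        if len(tdm) >= 3:
            phylo = tree.neighbor_joining(tdm)
        if out is not None:
            align_mod.write_concatenate(concat, out / "align" / "concatenate.aln")
            if phylo is not None:
                (out / "tree").mkdir(parents=True, exist_ok=True)
                (out / "tree" / "tree.nwk").write_text(phylo.newick() + "\n")
    return PipelineResult(
        kept=kept, reports=reports, mash=dm, annotated=ann, matrix=matrix,
        persistence=persistence, concatenate=concat, phylogeny=phylo,
        outputs=outputs,
    )
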