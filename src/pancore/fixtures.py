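"""Synthetic genomes with known ground truth.

Every downstream stage is testable without downloads: this module simulates
random genomes, diverged genome pairs at a known substitution rate (so the
expected sketch distance is known), fragmented draft assemblies, and sets of
genomes carrying planted gene families (core / accessory / multi-copy) whose
family table is the exact truth the pangenome and persistence stages must
recover.

All randomness flows through NumPy's default PCG64 generator, seeded
explicitly; the seed is recorded on the dataset, and regenerating with the
same seed is byte-identical.

Planted genomes are deliberately unambiguous for the naive ORF caller:

* genes sit on the forward strand, non-overlapping, separated by 60 bp
  spacers built from the self-reverse-complementary 12-mer ``TTAATTAATTAA``,
  which contains a stop codon in all six reading frames of every 12 bp
  window and no G (hence no ATG/GTG/TTG start codon) — no open reading
  frame can cross a spacer;
* every planted gene (ancestor or mutated variant) is accepted only if,
  embedded between two spacers, the ORF caller reports it as the unique ORF
  with exact coordinates; otherwise it is redrawn.

Family sequences diverge by i.i.d. per-site substitution (1% per variant
against the family ancestor, so within-family identity stays >= 95%)
with no indels, keeping truth identities computable in closed form; unrelated
families are independent random sequences (< 50% identity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import annotate
from .prepare import Assembly, write_fasta

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
SPACER_UNIT = "TTAATTAATTAA"
SPACER = SPACER_UNIT * 5  # 60 bp, >= 50 bp intergenic spacing
STOPS = ("TAA", "TAG", "TGA")
MIN_GENE_CODONS = 110
MAX_GENE_CODONS = 150
# each variant diverges from the family ancestor at this per-site rate, so
# two variants are ~2x this apart; 0.01 keeps within-family identity >= 95%
VARIANT_SUBST_RATE = 0.01


@dataclass
class PlantedGene:
    family_id: int
    genome_id: str
    copy_index: int
    start: int  # 1-based inclusive, stop codon included
    end: int
    nt_seq: str


@dataclass
class SimulatedDataset:
    genomes: list[Assembly]
    truth_families: dict[int, list[tuple[str, int]]]  # fid -> [(genome, copies)]
    truth_genes: dict[str, list[PlantedGene]] = field(default_factory=dict)
    truth_distances: dict[frozenset, float] = field(default_factory=dict)
    seed: int = 0

    @property
    def n_families(self) -> int:
        return len(self.truth_families)


def simulate_genome(length: int, gc: float = 0.5, seed: int = 0) -> str:
    """Random genome of ``length`` bases with expected G+C fraction ``gc``."""
    if length <= 0:
        raise ValueError("genome length must be positive")
    if not 0 <= gc <= 1:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=length, p=p).tobytes().decode("ascii")


def mutate_genome(seq: str, subst_rate: float, seed: int = 0) -> str:
    """Substitute each position, independently with probability
    ``subst_rate``, by a uniformly chosen *different* base."""
    if not 0 <= subst_rate < 1:
        raise ValueError("subst_rate must be in [0, 1)")
    if subst_rate == 0:
        return seq
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < subst_rate
    idx = np.nonzero(hit)[0]
    code = np.searchsorted(BASES, arr[idx])  # ACGT are sorted
    new_code = (code + rng.integers(1, 4, size=len(idx))) % 4
    arr[idx] = BASES[new_code]
    return arr.tobytes().decode("ascii")


def simulate_pair(length: int, subst_rate: float, seed: int = 0,
                  gc: float = 0.5) -> tuple[str, str]:
    """A genome and a copy diverged at ``subst_rate`` (ANI = 1 - rate)."""
    ancestor = simulate_genome(length, gc=gc, seed=seed)
    return ancestor, mutate_genome(ancestor, subst_rate, seed=seed + 1)


def fragment_assembly(seq: str, n_pieces: int, n_run: int = 5, seed: int = 0) -> str:
    """One draft FASTA entry: ``seq`` cut into ``n_pieces`` fragments joined
    by runs of ``n_run`` Ns.  Re-splitting at cutn <= n_run recovers the
    fragments exactly."""
    if n_pieces < 1:
        raise ValueError("n_pieces must be >= 1")
    if n_run < 0:
        raise ValueError("n_run must be >= 0")
    if n_pieces > len(seq):
        raise ValueError("cannot cut a sequence into more pieces than bases")
    rng = np.random.default_rng(seed)
    cuts = sorted(rng.choice(np.arange(1, len(seq)), size=n_pieces - 1, replace=False))
    pieces = [seq[i:j] for i, j in zip([0, *cuts], [*cuts, len(seq)])]
    body = ("N" * n_run).join(pieces)
    lines = [body[i : i + 60] for i in range(0, len(body), 60)]
    return ">draft\n" + "\n".join(lines) + "\n"


def _random_gene(rng: np.random.Generator) -> str:
    """Random coding sequence ATG + non-stop codons + TAA."""
    n_codons = int(rng.integers(MIN_GENE_CODONS, MAX_GENE_CODONS + 1))
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        codon = rng.choice(BASES, size=3).tobytes().decode("ascii")
        if codon not in STOPS:
            codons.append(codon)
    codons.append("TAA")
    return "".join(codons)


def _is_clean(gene: str) -> bool:
    """True iff the ORF caller, given spacer+gene+spacer, reports exactly the
    planted gene."""
    asm = Assembly(genome_id="probe", contigs=[("1", SPACER + gene + SPACER)])
    recs = annotate.call_orfs(asm, min_len=annotate.DEFAULT_MIN_ORF)
    return (
        len(recs) == 1
        and recs[0].strand == "+"
        and recs[0].start == len(SPACER) + 1
        and recs[0].end == len(SPACER) + len(gene)
    )


def _clean_gene(rng: np.random.Generator, max_tries: int = 200) -> str:
    for _ in range(max_tries):
        gene = _random_gene(rng)
        if _is_clean(gene):
            return gene
    raise RuntimeError("could not draw an unambiguous gene sequence")


def _mutate_gene(gene: str, rng: np.random.Generator, rate: float = VARIANT_SUBST_RATE,
                 max_tries: int = 200) -> str:
    """Diverged family variant: per-site substitutions that keep the start
    and stop codons, introduce no in-frame stop, and stay unambiguous for
    the ORF caller."""
    for _ in range(max_tries):
        arr = np.frombuffer(gene.encode("ascii"), dtype=np.uint8).copy()
        hit = np.nonzero(rng.random(len(arr)) < rate)[0]
        hit = hit[(hit >= 3) & (hit < len(arr) - 3)]
        code = np.searchsorted(BASES, arr[hit])
        arr[hit] = BASES[(code + rng.integers(1, 4, size=len(hit))) % 4]
        variant = arr.tobytes().decode("ascii")
        internal_stop = any(
            variant[i : i + 3] in STOPS for i in range(3, len(variant) - 3, 3)
        )
        if not internal_stop and _is_clean(variant):
            return variant
    raise RuntimeError("could not draw an unambiguous family variant")


def plant_families(
    n_genomes: int,
    n_core: int,
    n_accessory: int = 0,
    n_multicopy: int = 0,
    seed: int = 0,
) -> SimulatedDataset:
    """Genomes carrying planted gene families with an exact truth table.

    Core families occur exactly once in every genome; accessory families in
    a random strict subset; multi-copy families carry two copies in one
    (randomly chosen) genome of their subset.
    """
    if n_genomes < 1:
        raise ValueError("need at least one genome")
    if min(n_core, n_accessory, n_multicopy) < 0:
        raise ValueError("family counts must be >= 0")
    rng = np.random.default_rng(seed)
    genome_ids = [f"genome{i:02d}" for i in range(1, n_genomes + 1)]
    plan: dict[int, dict[str, int]] = {}  # fid -> genome -> copies
    ancestors: dict[int, str] = {}
    fid = 0
    for _ in range(n_core):
        fid += 1
        plan[fid] = {g: 1 for g in genome_ids}
    for _ in range(n_accessory):
        fid += 1
        size = int(rng.integers(1, n_genomes)) if n_genomes > 1 else 1
        subset = rng.choice(genome_ids, size=size, replace=False)
        plan[fid] = {g: 1 for g in sorted(subset)}
    for _ in range(n_multicopy):
        fid += 1
        size = int(rng.integers(1, n_genomes + 1))
        subset = sorted(rng.choice(genome_ids, size=size, replace=False))
        copies = {g: 1 for g in subset}
        copies[subset[int(rng.integers(0, len(subset)))]] = 2
        plan[fid] = copies
    for f in sorted(plan):
        ancestors[f] = _clean_gene(rng)
    genomes: list[Assembly] = []
    truth_genes: dict[str, list[PlantedGene]] = {g: [] for g in genome_ids}
    for g in genome_ids:
        parts = [SPACER]
        pos = len(SPACER)
        for f in sorted(plan):
            for copy_index in range(1, plan[f].get(g, 0) + 1):
                variant = _mutate_gene(ancestors[f], rng)
                truth_genes[g].append(
                    PlantedGene(
                        family_id=f, genome_id=g, copy_index=copy_index,
                        start=pos + 1, end=pos + len(variant), nt_seq=variant,
                    )
                )
                parts.append(variant)
                parts.append(SPACER)
                pos += len(variant) + len(SPACER)
        genomes.append(Assembly(genome_id=g, contigs=[("1", "".join(parts))]))
    truth_families = {
        f: [(g, c) for g, c in sorted(plan[f].items())] for f in sorted(plan)
    }
    return SimulatedDataset(
        genomes=genomes,
        truth_families=truth_families,
        truth_genes=truth_genes,
        seed=seed,
    )


def write_dataset(ds: SimulatedDataset, out_dir: str | Path) -> None:
    """Write one 60-column FASTA per genome plus the truth table TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for asm in ds.genomes:
        write_fasta(
            out / f"{asm.genome_id}.fna",
            [(f"{asm.genome_id}_contig{cid}", seq) for cid, seq in asm.contigs],
        )
    with (out / "truth_families.tsv").open("w") as fh:
        fh.write("family_id\tgenome_id\tgene_id\tcopy_index\tstart\tend\n")
        for g in sorted(ds.truth_genes):
            for pg in ds.truth_genes[g]:
                gene_id = f"{pg.genome_id}_f{pg.family_id:04d}_c{pg.copy_index}"
                fh.write(
                    f"{pg.family_id}\t{pg.genome_id}\t{gene_id}\t"
                    f"{pg.copy_index}\t{pg.start}\t{pg.end}\n"
                )
    (out / "seed.txt").write_text(f"{ds.seed}\n")
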