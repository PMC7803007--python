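"""Shared synthetic datasets.

Everything is generated at test time from seeded generators; the larger
planted dataset and its pipeline run are session-scoped because several
suites check different facets of the same ground-truth recovery.
"""

import pytest

from pancore import fixtures, pipeline


@pytest.fixture(scope="session")
def planted_small():
    """4 genomes, 10 core + 4 accessory + 2 multi-copy families."""
    return fixtures.plant_families(4, 10, 4, 2, seed=11)


@pytest.fixture(scope="session")
def annotated_small(planted_small):
    return pipeline.annotate_genomes(planted_small.genomes)


@pytest.fixture(scope="session")
def planted_large():
    """The reference recovery scenario: 10 genomes, 50 core, 20 accessory,
    5 multi-copy families."""
    return fixtures.plant_families(10, 50, 20, 5, seed=11)


@pytest.fixture(scope="session")
def large_result(planted_large):
    """Full pipeline on the large planted dataset (distance filter opened up
    so that curation never interferes with family-recovery checks)."""
    return pipeline.run_all(
        planted_large.genomes, tol=1.0, mode="strict", min_dist=0.0, max_dist=1.0
    )


def truth_family_of_genes(ds, ann):
    """Map recovered gene ids to planted family ids via exact coordinates."""
    rendered = {g: str(name) for g, name in ann.names.items()}
    lookup = {}
    for genome_id, planted in ds.truth_genes.items():
        by_coord = {(p.start, p.end): p.family_id for p in planted}
        for rec in ann.records[rendered[genome_id]]:
            fid = by_coord.get((rec.start, rec.end))
            if fid is not None:
                lookup[rec.gene_id] = fid
    return lookup
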