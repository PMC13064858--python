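import random

import pytest

from defcore.config import PipelineConfig
from defcore.models import (
    GeneRecord,
    GenomeManifest,
    HitRecord,
    SystemInstance,
)
from defcore.simulate import SimConfig, simulate_pangenome


@pytest.fixture
def cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_sim():
    """One 10-genome species with planted structure (session-cached)."""
    sim_cfg = SimConfig(n_species=1, genomes_per_species=10, rng_seed=11)
    dataset, truth = simulate_pangenome(sim_cfg)
    return dataset, truth


def make_manifest(species_id, genome_ids, size=4_000_000):
    return [
        GenomeManifest(
            species_id=species_id,
            genome_id=g,
            genome_size_bp=size,
            completeness_pct=100.0,
            contamination_pct=0.0,
        )
        for g in genome_ids
    ]


def make_genes(genome_id, n, replicon="chrom", circular=False, spacing=400, length=300):
    return [
        GeneRecord(
            genome_id=genome_id,
            replicon_id=replicon,
            gene_id=f"{genome_id}_g{r:03d}",
            rank=r,
            start=1 + r * spacing,
            end=r * spacing + length,
            strand="+",
            is_circular_replicon=circular,
        )
        for r in range(n)
    ]


def make_system(uid, genome_id, family, gene_ids, polarity="defense", replicon="chrom"):
    return SystemInstance(
        system_uid=uid,
        genome_id=genome_id,
        replicon_id=replicon,
        family=family,
        polarity=polarity,
        component_gene_ids=tuple(gene_ids),
        complete=True,
    )


def make_hit(q, s, qg, sg, identity=99.0, qcov=1.0, scov=1.0, evalue=1e-30, bitscore=200.0):
    return HitRecord(
        query_gene_id=q,
        subject_gene_id=s,
        pct_identity=identity,
        query_coverage_frac=qcov,
        subject_coverage_frac=scov,
        evalue=evalue,
        bitscore=bitscore,
        query_genome_id=qg,
        subject_genome_id=sg,
    )


def hits_from_matrix(matrix, genome_a="A", genome_b="B", identity=99.0, evalue=1e-30):
    """Symmetric hit table from a bitscore matrix; all hits admissible."""
    hits = []
    for i, row in enumerate(matrix):
        for j, score in enumerate(row):
            a, b = f"a{i}", f"b{j}"
            hits.append(make_hit(a, b, genome_a, genome_b, identity=identity, evalue=evalue, bitscore=score))
            hits.append(make_hit(b, a, genome_b, genome_a, identity=identity, evalue=evalue, bitscore=score))
    return hits


def rbh_bruteforce(matrix):
    """Mutual-argmax oracle on an all-admissible score matrix.

    Ties broken by smallest partner id, mirroring the documented chain
    (equal evalue and identity here).
    """
    n, m = len(matrix), len(matrix[0])
    best_a = {}
    for i in range(n):
        best = max(range(m), key=lambda j: (matrix[i][j], -j))
        best_a[i] = best
    best_b = {}
    for j in range(m):
        best = max(range(n), key=lambda i: (matrix[i][j], -i))
        best_b[j] = best
    return {(i, j) for i, j in best_a.items() if best_b[j] == i}


def random_matrix(rng, n, m, low=100.0, high=500.0):
    return [[rng.uniform(low, high) for _ in range(m)] for _ in range(n)]
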