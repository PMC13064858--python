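import dataclasses
import random

import pytest

from defcore.config import PipelineConfig
from defcore.io import Dataset
from defcore.orthology import (
    build_hit_table,
    compute_rbh,
    link_systems,
    pairwise_similarity,
    write_hit_table,
)
from defcore.models import RBHPair

from conftest import (
    hits_from_matrix,
    make_genes,
    make_hit,
    make_manifest,
    make_system,
    random_matrix,
    rbh_bruteforce,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng, n=100):
    return "".join(rng.choice(AA) for _ in range(n))


class TestPairwiseSimilarity:
    def test_identical(self):
        rng = random.Random(0)
        seq = random_protein(rng, 100)
        h = pairwise_similarity(seq, seq)
        assert h.pct_identity == 100.0
        assert h.query_coverage_frac == 1.0
        assert h.subject_coverage_frac == 1.0
        assert h.evalue < 1e-10

    def test_half_sequence_coverage(self):
        rng = random.Random(1)
        seq = random_protein(rng, 100)
        h = pairwise_similarity(seq, seq[:50])
        assert h.subject_coverage_frac == 1.0
        assert h.query_coverage_frac == 0.5

    def test_four_substitutions_identity(self):
        # oracle: column-by-column count on the known (gap-free) alignment.
        # Interior substitutions so the local alignment keeps full span.
        rng = random.Random(2)
        seq = random_protein(rng, 100)
        mutated = list(seq)
        for pos in (20, 40, 60, 80):
            mutated[pos] = next(c for c in AA if c != seq[pos])
        h = pairwise_similarity(seq, "".join(mutated))
        assert h.pct_identity == pytest.approx(96.0)
        assert h.query_coverage_frac == 1.0

    def test_empty_sequence_error(self):
        with pytest.raises(ValueError):
            pairwise_similarity("", "MKT")

    def test_identity_only_mode_zero_evalue(self):
        h = pairwise_similarity("MKTAYIAKQR", "MKTAYIAKQR", mode="identity_only")
        assert h.evalue == 0.0


def two_genome_dataset():
    manifest = make_manifest("SPX", ["GA", "GB"])
    genes = make_genes("GA", 6) + make_genes("GB", 6)
    rng = random.Random(7)
    proteins = {g.gene_id: random_protein(rng, 80) for g in genes}
    # GA: 3 defense proteins, GB: 2
    systems = [
        make_system("GA_s1", "GA", "Gabija", ["GA_g000", "GA_g001", "GA_g002"]),
        make_system("GB_s1", "GB", "Septu", ["GB_g000", "GB_g001"]),
    ]
    return Dataset(manifest=manifest, genes=genes, systems=systems, mges=[], proteins=proteins)


class TestBuildHitTable:
    def test_ordered_pair_count(self):
        ds = two_genome_dataset()
        hits = build_hit_table(ds, "SPX", backend="builtin")
        assert len(hits) == 2 * (3 * 2)

    def test_single_genome_empty(self):
        manifest = make_manifest("SPY", ["GA"])
        genes = make_genes("GA", 3)
        systems = [make_system("s", "GA", "Gabija", ["GA_g000"])]
        ds = Dataset(
            manifest=manifest, genes=genes, systems=systems, mges=[], proteins={"GA_g000": "MKT" * 10, "GA_g001": "A", "GA_g002": "A"}
        )
        assert build_hit_table(ds, "SPY") == []

    def test_external_round_trip_same_rbh(self, tmp_path, cfg):
        ds = two_genome_dataset()
        hits = build_hit_table(ds, "SPX", backend="builtin")
        path = tmp_path / "hits.tsv"
        write_hit_table(hits, path)
        hits2 = build_hit_table(ds, "SPX", backend="external_tsv", external_path=path)
        assert compute_rbh(hits, cfg) == compute_rbh(hits2, cfg)

    def test_external_unknown_gene_fatal(self, tmp_path):
        ds = two_genome_dataset()
        path = tmp_path / "hits.tsv"
        write_hit_table([make_hit("nope", "GB_g000", "", "")], path)
        with pytest.raises(Exception, match="nope"):
            build_hit_table(ds, "SPX", backend="external_tsv", external_path=path)


class TestComputeRBH:
    def test_mutual_pair(self, cfg):
        hits = [
            make_hit("a1", "b1", "A", "B", identity=97, qcov=0.9, scov=0.9),
            make_hit("b1", "a1", "B", "A", identity=97, qcov=0.9, scov=0.9),
        ]
        assert compute_rbh(hits, cfg) == [RBHPair("a1", "b1", "A", "B")]

    def test_identity_below_threshold(self, cfg):
        hits = [
            make_hit("a1", "b1", "A", "B", identity=94.9),
            make_hit("b1", "a1", "B", "A", identity=94.9),
        ]
        assert compute_rbh(hits, cfg) == []

    @pytest.mark.parametrize("field,value", [
        ("qcov", 0.79), ("scov", 0.79), ("evalue", 2e-4),
    ])
    def test_other_thresholds(self, cfg, field, value):
        kwargs = {field: value}
        hits = [
            make_hit("a1", "b1", "A", "B", **kwargs),
            make_hit("b1", "a1", "B", "A", **kwargs),
        ]
        assert compute_rbh(hits, cfg) == []

    def test_boundary_values_admissible(self, cfg):
        hits = [
            make_hit("a1", "b1", "A", "B", identity=95.0, qcov=0.80, scov=0.80, evalue=1e-4),
            make_hit("b1", "a1", "B", "A", identity=95.0, qcov=0.80, scov=0.80, evalue=1e-4),
        ]
        assert len(compute_rbh(hits, cfg)) == 1

    def test_3x3_matrix_oracle(self, cfg):
        rng = random.Random(3)
        matrix = random_matrix(rng, 3, 3)
        pairs = compute_rbh(hits_from_matrix(matrix), cfg)
        got = {(int(p.gene_a[1:]), int(p.gene_b[1:])) for p in pairs}
        assert got == rbh_bruteforce(matrix)

    def test_random_8x8_oracle(self, cfg):
        rng = random.Random(4)
        for _ in range(50):
            matrix = random_matrix(rng, 8, 8)
            pairs = compute_rbh(hits_from_matrix(matrix), cfg)
            got = {(int(p.gene_a[1:]), int(p.gene_b[1:])) for p in pairs}
            assert got == rbh_bruteforce(matrix)

    def test_tie_break_lexicographic(self, cfg):
        # equal scores everywhere: every gene's best is the lexicographically
        # smallest partner, so only (a0, b0) is mutual
        matrix = [[300.0, 300.0], [300.0, 300.0]]
        pairs = compute_rbh(hits_from_matrix(matrix), cfg)
        assert {(p.gene_a, p.gene_b) for p in pairs} == {("a0", "b0")}

    def test_symmetric_deduplicated(self, cfg):
        rng = random.Random(5)
        matrix = random_matrix(rng, 4, 4)
        pairs = compute_rbh(hits_from_matrix(matrix), cfg)
        assert len(pairs) == len(set(pairs))
        assert len(pairs) <= 4

    def test_threshold_monotonicity(self):
        rng = random.Random(6)
        hits = []
        for i in range(5):
            for j in range(5):
                identity = rng.uniform(90, 100)
                cov = rng.uniform(0.7, 1.0)
                ev = 10 ** rng.uniform(-40, -2)
                score = rng.uniform(100, 400)
                hits.append(make_hit(f"a{i}", f"b{j}", "A", "B", identity, cov, cov, ev, score))
                hits.append(make_hit(f"b{j}", f"a{i}", "B", "A", identity, cov, cov, ev, score))
        base = PipelineConfig()
        baseline = set(compute_rbh(hits, base))
        for kwargs in (
            {"min_identity_pct": 97.0},
            {"min_coverage_frac": 0.9},
            {"max_evalue": 1e-20},
        ):
            stricter = dataclasses.replace(base, **kwargs)
            assert set(compute_rbh(hits, stricter)) <= baseline

    def test_empty_input(self, cfg):
        assert compute_rbh([], cfg) == []


class TestLinkSystems:
    def _systems(self):
        return [
            make_system("sA", "GA", "Gabija", ["a1", "a2", "a3"]),
            make_system("sB", "GB", "Gabija", ["b1", "b2", "b3"]),
        ]

    def test_full_match_links(self):
        rbh = [RBHPair.canonical(f"a{i}", f"b{i}", "GA", "GB") for i in (1, 2, 3)]
        links = link_systems(rbh, self._systems())
        assert len(links) == 1
        assert links[0].matched_component_count == 3

    def test_partial_match_no_link(self):
        rbh = [RBHPair.canonical(f"a{i}", f"b{i}", "GA", "GB") for i in (1, 2)]
        assert link_systems(rbh, self._systems()) == []

    def test_family_mismatch_never_links(self):
        systems = [
            make_system("sA", "GA", "Gabija", ["a1"]),
            make_system("sB", "GB", "RM_Type_I", ["b1"]),
        ]
        rbh = [RBHPair.canonical("a1", "b1", "GA", "GB")]
        assert link_systems(rbh, systems) == []

    def test_relaxed_component_fraction(self):
        rbh = [RBHPair.canonical(f"a{i}", f"b{i}", "GA", "GB") for i in (1, 2)]
        links = link_systems(rbh, self._systems(), min_component_frac=0.5)
        assert len(links) == 1

    def test_same_genome_never_links(self):
        systems = [
            make_system("s1", "GA", "Gabija", ["a1"]),
            make_system("s2", "GA", "Gabija", ["a2"]),
        ]
        rbh = [RBHPair.canonical("a1", "a2", "GA", "GA")]
        assert link_systems(rbh, systems) == []
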