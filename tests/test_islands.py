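import dataclasses
import random

import pytest

from defcore.islands import detect_defense_islands, island_membership
from defcore.models import HCADSBlock

from conftest import make_genes, make_system


def place_systems(genome_id, placements, n_genes=100, circular=False):
    """placements: list of (family, [ranks]). Returns (genes, systems)."""
    genes = make_genes(genome_id, n_genes, circular=circular)
    systems = []
    for i, (family, ranks) in enumerate(placements):
        gene_ids = [genes[r].gene_id for r in ranks]
        systems.append(make_system(f"{genome_id}_s{i}", genome_id, family, gene_ids))
    return genes, systems


def brute_force_islands(defense, n_genes, circular, limit, min_genes, min_families):
    """Independent oracle: enumerate maximal gap-bounded runs.

    ``defense``: dict rank -> family.  Returns a set of frozensets of ranks.
    """
    ranks = sorted(defense)
    if not ranks:
        return set()
    # adjacency between cyclically/linearly consecutive defense genes
    edges = []
    for a, b in zip(ranks, ranks[1:]):
        if b - a <= limit:
            edges.append((a, b))
    if circular and len(ranks) > 1:
        wrap = (n_genes - ranks[-1]) + ranks[0]
        if wrap <= limit:
            edges.append((ranks[-1], ranks[0]))
    # connected components over that adjacency
    parent = {r: r for r in ranks}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for a, b in edges:
        parent[find(a)] = find(b)
    comps = {}
    for r in ranks:
        comps.setdefault(find(r), set()).add(r)
    out = set()
    for comp in comps.values():
        fams = {defense[r] for r in comp}
        if len(comp) >= min_genes and len(fams) >= min_families:
            out.add(frozenset(comp))
    return out


class TestWorkedExamples:
    def test_three_family_island(self, cfg):
        genes, systems = place_systems(
            "GA", [("famA", [5, 6, 7]), ("famB", [12]), ("famC", [15, 16])]
        )
        islands = detect_defense_islands(genes, systems, cfg)
        assert len(islands) == 1
        isl = islands[0]
        assert isl.member_defense_gene_count == 6
        assert isl.distinct_family_count == 3
        assert (isl.start_rank, isl.end_rank) == (5, 16)

    def test_too_few_genes(self, cfg):
        genes, systems = place_systems(
            "GA", [("famA", [5]), ("famB", [7]), ("famC", [9, 10])]
        )
        assert detect_defense_islands(genes, systems, cfg) == []

    def test_too_few_families(self, cfg):
        genes, systems = place_systems("GA", [("famA", [5, 6, 7]), ("famB", [9, 10, 11])])
        assert detect_defense_islands(genes, systems, cfg) == []

    def test_gap_boundary(self, cfg):
        # gap of exactly 10 intervening genes chains; 11 splits
        genes, systems = place_systems(
            "GA", [("famA", [0, 1]), ("famB", [12, 13]), ("famC", [24])]
        )
        islands = detect_defense_islands(genes, systems, cfg)
        assert len(islands) == 1 and islands[0].member_defense_gene_count == 5
        genes, systems = place_systems(
            "GA", [("famA", [0, 1]), ("famB", [13, 14]), ("famC", [25])]
        )
        assert detect_defense_islands(genes, systems, cfg) == []

    def test_rank_gap_mode(self, cfg):
        strict = dataclasses.replace(cfg, island_gap_mode="rank")
        genes, systems = place_systems(
            "GA", [("famA", [0, 1]), ("famB", [12, 13]), ("famC", [24])]
        )
        # rank differences of 11 break the chain under "rank" mode
        assert detect_defense_islands(genes, systems, strict) == []


class TestCircular:
    def test_wrap_around_merge(self, cfg):
        genes, systems = place_systems(
            "GA",
            [("famA", [0, 1]), ("famB", [96, 97]), ("famC", [99])],
            n_genes=100,
            circular=True,
        )
        islands = detect_defense_islands(genes, systems, cfg)
        assert len(islands) == 1
        assert islands[0].member_defense_gene_count == 5

    def test_no_wrap_on_linear(self, cfg):
        genes, systems = place_systems(
            "GA",
            [("famA", [0, 1]), ("famB", [96, 97]), ("famC", [99])],
            n_genes=100,
            circular=False,
        )
        assert detect_defense_islands(genes, systems, cfg) == []

    def test_rotation_invariance(self, cfg):
        rng = random.Random(42)
        for _ in range(20):
            n = 60
            n_def = rng.randint(5, 12)
            ranks = sorted(rng.sample(range(n), n_def))
            fams = [rng.choice("ABCD") for _ in ranks]
            placements = [(f"fam{f}_{i}", [r]) for i, (r, f) in enumerate(zip(ranks, fams))]
            # group by family letter for distinct-family counting
            by_fam = {}
            for r, f in zip(ranks, fams):
                by_fam.setdefault(f, []).append(r)
            placements = [(f"fam{f}", rs) for f, rs in by_fam.items()]
            genes, systems = place_systems("GA", placements, n_genes=n, circular=True)
            base = {
                frozenset(i.member_gene_ids)
                for i in detect_defense_islands(genes, systems, cfg)
            }
            # rotate by a random shift
            shift = rng.randint(1, n - 1)
            rot_placements = [
                (fam, [(r + shift) % n for r in rs]) for fam, rs in placements
            ]
            genes_r, systems_r = place_systems("GA", rot_placements, n_genes=n, circular=True)
            rotated = {
                frozenset(
                    genes[(int(g.rsplit("g", 1)[1]) - shift) % n].gene_id
                    for g in i.member_gene_ids
                )
                for i in detect_defense_islands(genes_r, systems_r, cfg)
            }
            assert base == rotated


class TestOracleEquivalence:
    def test_random_replicons(self, cfg):
        rng = random.Random(7)
        for _ in range(100):
            n = rng.randint(10, 60)
            circular = rng.random() < 0.5
            n_def = rng.randint(0, min(15, n))
            ranks = sorted(rng.sample(range(n), n_def))
            defense = {r: f"fam{rng.choice('ABCD')}" for r in ranks}
            by_fam = {}
            for r, f in defense.items():
                by_fam.setdefault(f, []).append(r)
            placements = [(f, sorted(rs)) for f, rs in by_fam.items()]
            genes, systems = place_systems("GA", placements, n_genes=n, circular=circular)
            got = {
                frozenset(int(g.rsplit("g", 1)[1]) for g in i.member_gene_ids)
                for i in detect_defense_islands(genes, systems, cfg)
            }
            want = brute_force_islands(
                defense, n, circular, cfg.island_max_gap_genes + 1,
                cfg.island_min_genes, cfg.island_min_families,
            )
            assert got == want


class TestProperties:
    def test_disjointness(self, cfg):
        rng = random.Random(9)
        for _ in range(30):
            n = 60
            ranks = sorted(rng.sample(range(n), rng.randint(5, 20)))
            by_fam = {}
            for r in ranks:
                by_fam.setdefault(rng.choice("ABCDE"), []).append(r)
            placements = [(f"fam{f}", sorted(rs)) for f, rs in by_fam.items()]
            genes, systems = place_systems("GA", placements, n_genes=n)
            islands = detect_defense_islands(genes, systems, cfg)
            seen = set()
            for isl in islands:
                assert not (seen & set(isl.member_gene_ids))
                seen.update(isl.member_gene_ids)

    def test_gap_monotonicity(self, cfg):
        rng = random.Random(10)
        for _ in range(20):
            n = 60
            ranks = sorted(rng.sample(range(n), 12))
            by_fam = {}
            for r in ranks:
                by_fam.setdefault(rng.choice("ABCD"), []).append(r)
            placements = [(f"fam{f}", sorted(rs)) for f, rs in by_fam.items()]
            genes, systems = place_systems("GA", placements, n_genes=n)
            sizes = []
            for gap in (12, 10, 8, 6, 4, 2, 0):
                c = dataclasses.replace(cfg, island_max_gap_genes=gap)
                total = sum(
                    i.member_defense_gene_count for i in detect_defense_islands(genes, systems, c)
                )
                sizes.append(total)
            assert sizes == sorted(sizes, reverse=True)


class TestMembership:
    def _block(self, uids, classification="core"):
        return HCADSBlock(
            block_id="B0",
            species_id="SPX",
            family="famA",
            member_system_uids=uids,
            presence_count=len(uids),
            genome_count=len(uids),
            classification=classification,
        )

    def test_inside_flagged_outside_not(self, cfg):
        genes, systems = place_systems(
            "GA",
            [("famA", [5, 6]), ("famB", [8, 9]), ("famC", [11]), ("famD", [50, 51])],
        )
        islands = detect_defense_islands(genes, systems, cfg)
        assert len(islands) == 1
        inside = self._block(["GA_s0"])
        outside = HCADSBlock("B1", "SPX", "famD", ["GA_s3"], 1, 1, "core")
        flags, frac = island_membership([inside, outside], islands, systems)
        assert flags["B0"] is True
        assert flags["B1"] is False
        assert frac == pytest.approx(0.5)

    def test_planted_fraction(self, cfg):
        # 2 of 10 instances island-resident -> 0.2
        genes_a, systems_a = place_systems(
            "GA", [("famA", [5, 6]), ("famB", [8, 9]), ("famC", [11])]
        )
        blocks = []
        systems = list(systems_a)
        # 2 in-island instances (famA, famB) + 8 far-away singletons
        blocks.append(self._block(["GA_s0"]))
        blocks.append(HCADSBlock("B1", "SPX", "famB", ["GA_s1"], 1, 1, "core"))
        extra_sys = []
        for i in range(8):
            genes_x = make_genes(f"GX{i}", 5)
            sysx = make_system(f"x{i}", f"GX{i}", "famZ", [genes_x[0].gene_id])
            extra_sys.append(sysx)
            blocks.append(HCADSBlock(f"BX{i}", "SPX", "famZ", [f"x{i}"], 1, 1, "core"))
        islands = detect_defense_islands(genes_a, systems_a, cfg)
        flags, frac = island_membership(blocks, islands, systems + extra_sys)
        assert frac == pytest.approx(0.2)
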