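import dataclasses
import random

import pytest

from defcore.models import ANIRecord
from defcore.votu import (
    build_ani_table,
    cluster_votus,
    compute_contig_ani,
    read_ani_table,
    write_ani_table,
)

NT = "ACGT"


def random_contig(rng, n):
    return "".join(rng.choice(NT) for _ in range(n))


class TestComputeAni:
    def test_identical(self):
        rng = random.Random(0)
        seq = random_contig(rng, 2000)
        rec = compute_contig_ani(seq, seq, "a", "b")
        assert rec.ani_pct == 100.0
        assert rec.query_cov_frac == 1.0 and rec.target_cov_frac == 1.0

    def test_substring_coverage(self):
        rng = random.Random(1)
        seq = random_contig(rng, 5000)
        sub = seq[1000:3000]  # 40% of the full sequence
        rec = compute_contig_ani(seq, sub, "full", "part")
        assert rec.target_cov_frac == 1.0
        assert rec.query_cov_frac == pytest.approx(0.4)
        # and with the short one as target of the definition check
        rec2 = compute_contig_ani(sub, seq, "part", "full")
        assert rec2.query_cov_frac == 1.0
        assert rec2.target_cov_frac == pytest.approx(0.4)

    def test_two_percent_substitutions(self):
        rng = random.Random(2)
        seq = random_contig(rng, 10_000)
        mutated = list(seq)
        for pos in rng.sample(range(10_000), 200):
            mutated[pos] = next(c for c in NT if c != seq[pos])
        rec = compute_contig_ani(seq, "".join(mutated), "a", "b")
        assert rec.ani_pct == pytest.approx(98.0, abs=0.5)

    def test_unrelated_no_record(self):
        rng = random.Random(3)
        a, b = random_contig(rng, 1000), random_contig(rng, 1000)
        assert compute_contig_ani(a, b, "a", "b") is None

    def test_empty_error(self):
        with pytest.raises(ValueError):
            compute_contig_ani("", "ACGT")

    def test_ani_range_validated(self):
        with pytest.raises(ValueError):
            ANIRecord("a", "b", 101.0, 1.0, 1.0)


def rec(q, t, ani=100.0, qcov=1.0, tcov=1.0):
    return ANIRecord(q, t, ani, qcov, tcov)


def greedy_oracle(lengths, records, min_ani=95.0, min_tcov=0.85, min_qcov=0.0):
    """Literal re-execution of the greedy definition."""
    lut = {}
    for r in records:
        lut[(r.query_contig, r.target_contig)] = r

    def ok(member, centroid):
        r = lut.get((member, centroid))
        if r is not None:
            mcov, ccov = r.query_cov_frac, r.target_cov_frac
        else:
            r = lut.get((centroid, member))
            if r is None:
                return False
            mcov, ccov = r.target_cov_frac, r.query_cov_frac
        return r.ani_pct >= min_ani and mcov >= min_tcov and ccov >= min_qcov

    order = sorted(lengths, key=lambda c: (-lengths[c], c))
    unassigned = list(order)
    clusters = []
    while unassigned:
        centroid = unassigned.pop(0)
        members = [centroid]
        rest = []
        for c in unassigned:
            (members if ok(c, centroid) else rest).append(c)
        unassigned = rest
        clusters.append(frozenset(members))
    return set(clusters)


class TestClusterVotus:
    def test_two_identical_contigs(self, cfg):
        lengths = {"c1": 1000, "c2": 1000}
        ani = [rec("c1", "c2"), rec("c2", "c1")]
        votus = cluster_votus(lengths, ani, cfg)
        assert len(votus) == 1
        assert votus[0].representative_contig == "c1"  # length tie -> lexicographic

    def test_singleton(self, cfg):
        votus = cluster_votus({"c1": 1000}, [], cfg)
        assert len(votus) == 1 and votus[0].member_contigs == ["c1"]

    def test_hand_built_five_contigs(self, cfg):
        lengths = {"a": 5000, "b": 4000, "c": 3000, "d": 2000, "e": 1000}
        ani = [
            rec("b", "a", 97, 0.9, 0.9),  # b joins a
            rec("c", "a", 96, 0.9, 0.5),  # c joins a (its own cov 0.9 >= 0.85)
            rec("d", "c", 99, 1.0, 1.0),  # d would join c, but c is not a centroid
            rec("e", "d", 99, 1.0, 1.0),
        ]
        votus = cluster_votus(lengths, ani, cfg)
        got = {frozenset(v.member_contigs) for v in votus}
        assert got == greedy_oracle(lengths, ani)
        assert got == {frozenset({"a", "b", "c"}), frozenset({"d", "e"})}

    def test_member_coverage_rule(self, cfg):
        # member's own coverage below 0.85 -> not recruited, even at high ANI
        lengths = {"a": 5000, "b": 1000}
        ani = [rec("b", "a", 99.0, qcov=0.5, tcov=0.1)]
        votus = cluster_votus(lengths, ani, cfg)
        assert len(votus) == 2

    def test_partition_property(self, cfg):
        rng = random.Random(4)
        for _ in range(20):
            n = rng.randint(2, 25)
            lengths = {f"c{i:02d}": rng.randint(500, 5000) for i in range(n)}
            names = list(lengths)
            records = []
            for _ in range(rng.randint(0, 3 * n)):
                q, t = rng.sample(names, 2)
                records.append(
                    rec(q, t, rng.uniform(80, 100), rng.uniform(0.3, 1.0), rng.uniform(0.3, 1.0))
                )
            votus = cluster_votus(lengths, records, cfg)
            members = [c for v in votus for c in v.member_contigs]
            assert sorted(members) == sorted(names)

    def test_random_tables_match_oracle(self, cfg):
        rng = random.Random(5)
        for _ in range(50):
            n = rng.randint(2, 30)
            lengths = {f"c{i:02d}": rng.randint(500, 5000) for i in range(n)}
            names = list(lengths)
            records = []
            for _ in range(rng.randint(0, 2 * n)):
                q, t = rng.sample(names, 2)
                records.append(
                    rec(q, t, rng.uniform(90, 100), rng.uniform(0.5, 1.0), rng.uniform(0.5, 1.0))
                )
            got = {frozenset(v.member_contigs) for v in cluster_votus(lengths, records, cfg)}
            assert got == greedy_oracle(lengths, records)

    def test_row_order_determinism(self, cfg):
        rng = random.Random(6)
        lengths = {f"c{i}": rng.randint(500, 5000) for i in range(10)}
        records = []
        names = list(lengths)
        for _ in range(20):
            q, t = rng.sample(names, 2)
            records.append(rec(q, t, rng.uniform(90, 100), rng.uniform(0.5, 1), rng.uniform(0.5, 1)))
        base = cluster_votus(lengths, records, cfg)
        shuffled = records[:]
        rng.shuffle(shuffled)
        again = cluster_votus(lengths, shuffled, cfg)
        assert [v.member_contigs for v in base] == [v.member_contigs for v in again]

    def test_all_identical_one_cluster(self, cfg):
        lengths = {f"c{i}": 1000 for i in range(6)}
        names = list(lengths)
        ani = [rec(q, t) for q in names for t in names if q != t]
        votus = cluster_votus(lengths, ani, cfg)
        assert len(votus) == 1

    def test_empty_table_all_singletons(self, cfg):
        lengths = {f"c{i}": 1000 + i for i in range(6)}
        votus = cluster_votus(lengths, [], cfg)
        assert len(votus) == 6

    def test_bad_length_fatal(self, cfg):
        with pytest.raises(ValueError):
            cluster_votus({"c1": 0}, [], cfg)


class TestAniTableIO:
    def test_round_trip(self, tmp_path):
        rng = random.Random(7)
        contigs = {f"c{i}": random_contig(rng, 1000) for i in range(3)}
        contigs["c3"] = contigs["c0"][:800]
        table = build_ani_table(contigs)
        path = tmp_path / "ani.tsv"
        write_ani_table(table, path)
        back = read_ani_table(path)
        assert len(back) == len(table)
        for x, y in zip(back, table):
            assert x.query_contig == y.query_contig
            assert x.ani_pct == pytest.approx(y.ani_pct)
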