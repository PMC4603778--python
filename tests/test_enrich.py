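"""Enrichment arithmetic, plane detection and prevalence tables."""

import numpy as np
import pytest

from clickdel.decode import CountTable, DecodeResult
from clickdel.enrich import (
    cube_coordinates,
    detect_planes,
    fold_enrichment,
    prevalence_table,
    rank_enriched,
)
from clickdel.schema import build_schema

FULL_DIVERSITY = 2259 * 222 * 667


def make_table(entries, blocks=None):
    """entries: {codes: {'selected': n, 'naive': m}}"""
    table = CountTable()
    for codes, per in entries.items():
        for pop, n in per.items():
            for _ in range(n):
                table.add(
                    pop,
                    DecodeResult(
                        "ok",
                        codes,
                        (blocks or {}).get(codes, codes),
                        (0, 0, 0),
                        (1, 1, 1),
                    ),
                )
    return table


class TestFoldEnrichment:
    def test_zero_naive_uses_library_average(self):
        """13 hits in ~1.5e5 selected reads, unseen among ~2e6 naive reads,
        against a 3.3e8-member library: about 30,000-fold."""
        fold = fold_enrichment(13, 147_885, 0, 2_037_412, FULL_DIVERSITY)
        assert fold == pytest.approx(29_404.5, abs=1)
        assert round(fold, -4) == 30_000

    @pytest.mark.parametrize(
        "args", [(5, 100, 5, 100, 1000), (20, 1000, 40, 2000, 7)]
    )
    def test_equal_frequencies_give_unity(self, args):
        assert fold_enrichment(*args) == pytest.approx(1.0)

    def test_invalid_totals_rejected(self):
        with pytest.raises(ValueError):
            fold_enrichment(1, 0, 0, 10, 10)
        with pytest.raises(ValueError):
            fold_enrichment(1, 10, 0, 10, 0)

    def test_baseline_branches_agree_at_crossover(self):
        """When naive frequency equals the library average the observed-
        and average-baseline branches coincide."""
        diversity, naive_total = 500, 50_000
        naive_count = naive_total // diversity  # frequency exactly 1/diversity
        with_counts = fold_enrichment(7, 1000, naive_count, naive_total, diversity)
        unseen = fold_enrichment(7, 1000, 0, naive_total, diversity)
        assert with_counts == pytest.approx(unseen)

    def test_population_swap_inverts_enrichment(self):
        f = fold_enrichment(30, 1000, 6, 2000, 99)
        g = fold_enrichment(6, 2000, 30, 1000, 99)
        assert f * g == pytest.approx(1.0)


class TestRankEnriched:
    def test_uniform_counts_rank_lexicographically(self):
        entries = {
            (c, "X", "Y"): {"selected": 5, "naive": 5} for c in "DCBA"
        }
        table = make_table(entries)
        results = rank_enriched(table, diversity=100)
        assert [r.fold_enrichment for r in results] == [1.0] * 4
        assert [r.codes[0] for r in results] == ["A", "B", "C", "D"]

    def test_min_count_filters_singletons(self):
        entries = {
            ("A", "B", "C"): {"selected": 4, "naive": 1},
            ("D", "E", "F"): {"selected": 1, "naive": 1},
        }
        results = rank_enriched(make_table(entries), diversity=10, min_count=2)
        assert len(results) == 1
        assert results[0].codes == ("A", "B", "C")

    def test_missing_population_rejected(self):
        table = make_table({("A", "B", "C"): {"selected": 1}})
        with pytest.raises(ValueError, match="naive"):
            rank_enriched(table, diversity=10)


def plane_entries(n_c1=6, n_c2=4, plane_block="P", sel=40, n_background=100):
    """Synthetic counts: every member carrying cycle-3 block P is strongly
    enriched over a broad, flat background."""
    entries, blocks = {}, {}
    for i in range(n_c1):
        for j in range(n_c2):
            codes = (f"A{i}", f"B{j}", "CP")
            entries[codes] = {"selected": sel, "naive": 2}
            blocks[codes] = (f"a{i}", f"b{j}", plane_block)
    # flat background: many members seen once selected, all naive-visible
    for i in range(n_background):
        codes = (f"X{i}", "B0", f"CQ{i}")
        entries[codes] = {"selected": 1, "naive": 2}
        blocks[codes] = (f"x{i}", "b0", f"q{i}")
    return entries, blocks


class TestPlaneDetection:
    def test_planted_plane_is_sole_family(self):
        entries, blocks = plane_entries()
        table = make_table(entries, blocks)
        results = rank_enriched(table, diversity=10_000)
        report = detect_planes(results)
        assert len(report.planes) == 1
        plane = report.planes[0]
        assert (plane.cycle_index, plane.block_id) == (3, "P")
        assert plane.n_members == 24

    def test_two_planes_both_reported(self):
        entries, blocks = plane_entries()
        for i in range(6):
            for j in range(4):
                codes = (f"A{i}", f"B{j}", "CR")
                entries[codes] = {"selected": 35, "naive": 2}
                blocks[codes] = (f"a{i}", f"b{j}", "R")
        table = make_table(entries, blocks)
        report = detect_planes(rank_enriched(table, diversity=10_000))
        found = {(p.cycle_index, p.block_id) for p in report.planes}
        assert found == {(3, "P"), (3, "R")}

    def test_null_data_yields_no_planes(self):
        """Label-free calibration: uniform multinomial counts over seeds
        should essentially never produce a family at default thresholds."""
        rng_detections = 0
        schema = build_schema([5, 4, 3], seed=1)
        members = list(schema.trisynthons())
        for seed in range(20):
            rng = np.random.default_rng(seed)
            sel = rng.multinomial(2000, np.full(len(members), 1 / len(members)))
            naive = rng.multinomial(4000, np.full(len(members), 1 / len(members)))
            table = CountTable()
            for m, s, n in zip(members, sel, naive):
                for pop, k in (("selected", int(s)), ("naive", int(n))):
                    for _ in range(k):
                        table.add(
                            pop, DecodeResult("ok", m.codes, m.blocks, (0,) * 3, (1,) * 3)
                        )
            results = rank_enriched(table, diversity=len(members))
            if detect_planes(results).planes:
                rng_detections += 1
        assert rng_detections <= 1

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            detect_planes([])


class TestPrevalence:
    def test_prevalence_fractions(self):
        entries, blocks = plane_entries(n_c1=2, n_c2=2)
        table = make_table(entries, blocks)
        report = detect_planes(rank_enriched(table, diversity=10_000))
        plane = report.planes[0]
        prev_c3 = prevalence_table(plane, 3)
        assert prev_c3 == {"P": 1.0}
        prev_c1 = prevalence_table(plane, 1)
        assert prev_c1 == {"a0": 0.5, "a1": 0.5}
        assert sum(prev_c1.values()) == pytest.approx(1.0)

    def test_four_member_example(self):
        """Members with cycle-1 blocks {x, x, y, z} -> {x: .5, y: .25, z: .25}."""
        entries = {
            ("A", "B1", "C"): {"selected": 9, "naive": 0},
            ("A", "B2", "C"): {"selected": 9, "naive": 0},
            ("Y", "B3", "C"): {"selected": 9, "naive": 0},
            ("Z", "B4", "C"): {"selected": 9, "naive": 0},
            ("W", "B5", "D"): {"selected": 1, "naive": 50},
        }
        blocks = {
            ("A", "B1", "C"): ("x", "b1", "c"),
            ("A", "B2", "C"): ("x", "b2", "c"),
            ("Y", "B3", "C"): ("y", "b3", "c"),
            ("Z", "B4", "C"): ("z", "b4", "c"),
            ("W", "B5", "D"): ("w", "b5", "d"),
        }
        table = make_table(entries, blocks)
        results = rank_enriched(table, diversity=10_000)
        report = detect_planes(results, min_members=4)
        plane = report.planes[0]
        assert prevalence_table(plane, 1) == {"x": 0.5, "y": 0.25, "z": 0.25}

    def test_single_member_family(self):
        from clickdel.enrich import Plane

        member = rank_enriched(
            make_table({("A", "B", "C"): {"selected": 3, "naive": 1}}),
            diversity=100,
        )[0]
        plane = Plane(3, "C", [member], -10.0)
        assert prevalence_table(plane, 1) == {"A": 1.0}

    def test_empty_family_rejected(self):
        from clickdel.enrich import Plane

        with pytest.raises(ValueError):
            prevalence_table(Plane(3, "C", [], 0.0), 1)


class TestCube:
    def test_coordinates_and_plane_structure(self, toy_schema):
        members = list(toy_schema.trisynthons())
        # members 0 and 3 share the same cycle-3 block in enumeration order
        chosen = [m for m in members if m.blocks[2] == members[0].blocks[2]][:2]
        chosen.append(next(m for m in members if m.blocks[2] != members[0].blocks[2]))
        table = CountTable()
        for m in chosen:
            for _ in range(3):
                table.add(
                    "selected", DecodeResult("ok", m.codes, m.blocks, (0,) * 3, (1,) * 3)
                )
        coords = cube_coordinates(table, toy_schema)
        assert len(coords) == 3
        assert set(coords["count"]) == {3}
        # plane membership: shared cycle-3 block -> shared cycle-3 axis index
        orders = {b: i for i, b in enumerate(toy_schema.cycle(3).blocks)}
        expected = sorted(orders[m.blocks[2]] for m in chosen)
        assert sorted(coords["cycle3_index"]) == expected
        assert len(set(coords["cycle3_index"])) == 2

    def test_missing_block_rejected(self, toy_schema):
        table = CountTable()
        table.add(
            "selected",
            DecodeResult("ok", ("x", "y", "z"), ("nope", "nope", "nope"), (0,) * 3, (1,) * 3),
        )
        with pytest.raises(ValueError):
            cube_coordinates(table, toy_schema)
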