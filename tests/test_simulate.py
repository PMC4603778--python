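"""Synthetic selection generator: count dynamics, read emission, determinism."""

import math

import numpy as np
import pytest
from scipy import stats

from clickdel.decode import TagIndex, count_reads
from clickdel.readthrough import KLENOW, EnzymeProfile
from clickdel.schema import build_schema, expected_read_layout
from clickdel.simulate import (
    AffinityModel,
    PlantedFamily,
    SelectionRun,
    emit_reads,
    expected_member_fold,
    simulate_experiment,
    simulate_selection,
)

PERFECT = EnzymeProfile("perfect", 1.0)


@pytest.fixture(scope="module")
def schema():
    return build_schema([5, 4, 3], seed=1)


@pytest.fixture(scope="module")
def layout(schema):
    return expected_read_layout(schema)


class TestSelectionDynamics:
    def test_capture_one_preserves_counts(self, schema):
        run = SelectionRun(schema, copies_per_member=7, rounds=3, seed=0)
        counts = simulate_selection(run, AffinityModel(background_capture_prob=1.0))
        assert (counts.counts == 7).all()

    def test_capture_zero_empties_after_first_round(self, schema):
        run = SelectionRun(schema, copies_per_member=7, rounds=2, seed=0)
        counts = simulate_selection(run, AffinityModel(background_capture_prob=0.0))
        assert (counts.round_counts(1) == 0).all()
        assert (counts.round_counts(2) == 0).all()

    def test_planted_retention_ratio_closed_form(self, schema):
        """Two rounds at capture 0.5 vs background 0.001 give a per-copy
        relative retention of (0.5/0.001)^2 = 250,000."""
        planted = PlantedFamily(3, "B3-0001", 0.5)
        affinity = AffinityModel(0.001, [planted])
        members = list(schema.trisynthons())
        w = np.array([affinity.capture_prob(m) ** 2 for m in members])
        is_planted = np.array([m.blocks[2] == "B3-0001" for m in members])
        ratio = w[is_planted].mean() / w[~is_planted].mean()
        assert ratio == pytest.approx(250_000)

    def test_planted_counts_track_expectation(self, schema):
        planted = PlantedFamily(3, "B3-0001", 0.5)
        run = SelectionRun(schema, copies_per_member=10_000, rounds=2, seed=3)
        counts = simulate_selection(run, AffinityModel(0.001, [planted]))
        members = counts.members
        planted_counts = [
            c
            for m, c in zip(members, counts.round_counts(2))
            if m.blocks[2] == "B3-0001"
        ]
        mean = np.mean(planted_counts)
        # E = 10,000 * 0.25; binomial chain SE per member ~ sqrt(n p (1-p))
        se = math.sqrt(10_000 * 0.25 * 0.75 / len(planted_counts))
        assert abs(mean - 2500) < 4 * se

    def test_planted_below_background_rejected(self):
        with pytest.raises(ValueError):
            AffinityModel(0.5, [PlantedFamily(3, "x", 0.001)])

    def test_empty_library_rejected(self):
        empty = SelectionRun(
            build_schema([1], seed=0), copies_per_member=1, rounds=1, seed=0
        )
        empty.schema.cycles = []
        with pytest.raises(ValueError):
            simulate_selection(empty, AffinityModel())

    def test_expected_member_fold(self, schema):
        planted = PlantedFamily(3, "B3-0001", 0.5)
        affinity = AffinityModel(0.001, [planted])
        run = SelectionRun(schema, rounds=2, seed=0)
        member = next(
            m for m in schema.trisynthons() if m.blocks[2] == "B3-0001"
        )
        n = 5 * 4 * 3
        n_planted = 5 * 4
        w_planted, w_bg = 0.25, 1e-6
        expected = w_planted * n / (n_planted * w_planted + (n - n_planted) * w_bg)
        assert expected_member_fold(run, affinity, member) == pytest.approx(expected)


class TestReadEmission:
    def test_identical_seeds_give_byte_identical_fastq(self, schema, layout, tmp_path):
        run = SelectionRun(schema, reads_naive=500, reads_selected=500, seed=17)
        affinity = AffinityModel(0.001, [PlantedFamily(3, "B3-0001", 0.5)])
        a = simulate_experiment(run, affinity, tmp_path / "a", error_rate=0.01)
        b = simulate_experiment(run, affinity, tmp_path / "b", error_rate=0.01)
        assert a.selected_fastq.read_bytes() == b.selected_fastq.read_bytes()
        assert a.naive_fastq.read_bytes() == b.naive_fastq.read_bytes()

    def test_error_free_full_readthrough_reads_decode_exactly(
        self, schema, layout, tmp_path
    ):
        members = list(schema.trisynthons())
        counts = np.full(len(members), 5)
        emitted = emit_reads(
            counts, members, layout, 600, 0.0, PERFECT, 11,
            tmp_path / "r.fastq", tmp_path / "r.tsv",
        )
        assert emitted.n_truncated == 0
        index = TagIndex(schema)
        table = count_reads({"pop": tmp_path / "r.fastq"}, layout, index)
        assert table.failure_total("pop") == 0
        assert table.decoded_total("pop") == 600
        # counts equal the truth marginals
        import pandas as pd

        truth = pd.read_csv(tmp_path / "r.tsv", sep="\t", dtype=str)
        marginals = truth.groupby(["code1", "code2", "code3"]).size()
        for codes, n in marginals.items():
            assert table.count(tuple(codes), "pop") == n

    def test_read_counts_multinomial(self, schema, layout, tmp_path):
        """Uniform population, 10,000 reads over 60 members: goodness of fit."""
        members = list(schema.trisynthons())
        counts = np.full(len(members), 100)
        emit_reads(
            counts, members, layout, 10_000, 0.0, PERFECT, 23,
            tmp_path / "m.fastq", tmp_path / "m.tsv",
        )
        import pandas as pd

        truth = pd.read_csv(tmp_path / "m.tsv", sep="\t", dtype=str)
        observed = truth.groupby(["code1", "code2", "code3"]).size()
        # include zero cells
        obs = np.zeros(len(members))
        lookup = {m.codes: i for i, m in enumerate(members)}
        for codes, n in observed.items():
            obs[lookup[tuple(codes)]] = n
        res = stats.chisquare(obs)
        assert res.pvalue > 0.001

    def test_truncation_fraction_matches_stall_model(self, schema, layout, tmp_path):
        """Reads losing tag information ~ 1 - p^3 for Klenow on the 3-tag
        layout (a stall at the final faithful junction keeps all tags)."""
        members = list(schema.trisynthons())
        counts = np.full(len(members), 10)
        n = 20_000
        emitted = emit_reads(
            counts, members, layout, n, 0.0, KLENOW, 31,
            tmp_path / "t.fastq", tmp_path / "t.tsv",
        )
        expected = 1 - 0.8**3
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(emitted.n_truncated / n - expected) <= 3 * se

    def test_truth_marginals_match_sampling_weights(self, schema, layout, tmp_path):
        """Skewed population: read marginals track the count weights."""
        members = list(schema.trisynthons())
        counts = np.zeros(len(members), dtype=int)
        counts[0], counts[1] = 300, 100
        emit_reads(
            counts, members, layout, 8_000, 0.0, PERFECT, 41,
            tmp_path / "w.fastq", tmp_path / "w.tsv",
        )
        import pandas as pd

        truth = pd.read_csv(tmp_path / "w.tsv", sep="\t", dtype=str)
        for m, frac in ((members[0], 0.75), (members[1], 0.25)):
            got = (
                (truth.code1 == m.codes[0])
                & (truth.code2 == m.codes[1])
                & (truth.code3 == m.codes[2])
            ).mean()
            se = math.sqrt(frac * (1 - frac) / 8_000)
            assert abs(got - frac) <= 4 * se

    def test_all_zero_counts_rejected(self, schema, layout, tmp_path):
        members = list(schema.trisynthons())
        with pytest.raises(ValueError):
            emit_reads(
                np.zeros(len(members)), members, layout, 10, 0.0, PERFECT, 1,
                tmp_path / "z.fastq", tmp_path / "z.tsv",
            )
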