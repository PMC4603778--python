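import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from clickdel.decode import TagIndex, count_reads, decode_fastq
from clickdel.reference import load_reference_oligos
from clickdel.schema import build_schema, expected_read_layout
from clickdel.simulate import (
    AffinityModel,
    PlantedFamily,
    SelectionRun,
    simulate_experiment,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref_oligos():
    return load_reference_oligos()


@pytest.fixture(scope="session")
def toy_schema():
    """5 x 4 x 3 schema with distance-3 codes."""
    return build_schema([5, 4, 3], seed=1)


@pytest.fixture(scope="session")
def toy_layout(toy_schema):
    return expected_read_layout(toy_schema)


@pytest.fixture(scope="session")
def toy_index(toy_schema):
    return TagIndex(toy_schema)


class PipelineRun:
    """A full desk-scale selection experiment, simulated and decoded once."""

    def __init__(self, tmp_dir):
        self.schema = build_schema([50, 20, 20], seed=101)
        self.layout = expected_read_layout(self.schema)
        self.planted_block = "B3-0001"
        self.affinity = AffinityModel(
            background_capture_prob=0.001,
            planted_families=[PlantedFamily(3, self.planted_block, 0.5)],
        )
        self.run = SelectionRun(
            schema=self.schema,
            copies_per_member=100,
            rounds=2,
            reads_naive=100_000,
            reads_selected=100_000,
            seed=424_242,
        )
        self.output = simulate_experiment(
            self.run, self.affinity, tmp_dir, error_rate=0.005
        )
        self.index = TagIndex(self.schema)
        self.results = {}  # read_id -> DecodeResult
        self.table = count_reads(
            {
                "naive": self.output.naive_fastq,
                "selected": self.output.selected_fastq,
            },
            self.layout,
            self.index,
        )
        self.truth = pd.concat(
            [
                pd.read_csv(self.output.truth_naive, sep="\t"),
                pd.read_csv(self.output.truth_selected, sep="\t"),
            ],
            ignore_index=True,
        )
        self.diversity = 50 * 20 * 20

    def decode_all(self):
        if not self.results:
            for fastq in (self.output.naive_fastq, self.output.selected_fastq):
                for rid, res in decode_fastq(fastq, self.layout, self.index):
                    self.results[rid] = res
        return self.results


@pytest.fixture(scope="session")
def pipeline(tmp_path_factory):
    return PipelineRun(tmp_path_factory.mktemp("pipeline"))
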