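"""Synthetic affinity-selection data generator.

Models the computational surface of a DEL selection experiment:

* a combinatorial library population (equal copies per member at round 0);
* affinity capture as independent Bernoulli retention per molecule copy,
  with "planted" high-affinity families defined by a fixed building block
  in one cycle (capture probability far above background);
* iterated selection rounds (binomial thinning per member);
* sequencing-read emission: reads sampled multinomially from a population's
  molecule counts, built from the schema's read layout with single-A
  junction gaps, truncated at simulated polymerase stalls, and corrupted
  with uniform per-base substitution errors.

Every emitted read is recorded in a truth table (trisynthon, stop position,
error counts), so decoding and enrichment statistics can be validated
exhaustively. PCR bias is deliberately not modelled: amplification is
uniform, and read sampling is multinomial from post-selection counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .readthrough import KLENOW, EnzymeProfile
from .schema import (
    Constant,
    JunctionGap,
    LibrarySchema,
    ReadLayout,
    TagWindow,
    Trisynthon,
    expected_read_layout,
    revcomp,
)

__all__ = [
    "PlantedFamily",
    "AffinityModel",
    "SelectionRun",
    "SelectionCounts",
    "EmittedReads",
    "simulate_selection",
    "emit_reads",
    "simulate_experiment",
    "expected_member_fold",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
#: Constant Phred 30 base quality, Phred+33 encoded.
_QUAL_CHAR = "?"


@dataclass(frozen=True)
class PlantedFamily:
    """A high-affinity plane: every trisynthon carrying ``block_id`` in
    cycle ``cycle_index`` captures with ``capture_prob``."""

    cycle_index: int
    block_id: str
    capture_prob: float


@dataclass
class AffinityModel:
    background_capture_prob: float = 0.001
    planted_families: list[PlantedFamily] = field(default_factory=list)
    overrides: dict[tuple[str, ...], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        probs = [self.background_capture_prob] + [
            f.capture_prob for f in self.planted_families
        ] + list(self.overrides.values())
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("capture probabilities must lie in [0, 1]")
        if any(
            f.capture_prob < self.background_capture_prob
            for f in self.planted_families
        ):
            raise ValueError("planted capture_prob must be >= background")

    def capture_prob(self, member: Trisynthon) -> float:
        if member.codes in self.overrides:
            return self.overrides[member.codes]
        best = self.background_capture_prob
        for fam in self.planted_families:
            if member.blocks[fam.cycle_index - 1] == fam.block_id:
                best = max(best, fam.capture_prob)
        return best


@dataclass
class SelectionRun:
    """Parameters of one synthetic selection experiment.

    Defaults are desk scale: a 50 x 20 x 20 library (20,000 trisynthons),
    100 molecule copies per member, two selection rounds, and 10^5 reads
    each for the naive and selected populations.
    """

    schema: LibrarySchema
    copies_per_member: int = 100
    rounds: int = 2
    reads_naive: int = 100_000
    reads_selected: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.reads_naive < 0 or self.reads_selected < 0:
            raise ValueError("read counts must be >= 0")


@dataclass
class SelectionCounts:
    """True molecule counts per trisynthon and round (round 0 = naive)."""

    members: list[Trisynthon]
    counts: np.ndarray  # shape (rounds + 1, n_members)

    def round_counts(self, r: int) -> np.ndarray:
        return self.counts[r]


def simulate_selection(
    run: SelectionRun, affinity: AffinityModel
) -> SelectionCounts:
    """Simulate molecule-count trajectories through the selection rounds.

    Round 0 holds ``copies_per_member`` per trisynthon; each subsequent
    round draws Binomial(count, capture_prob) independently per member.
    Deterministic for a fixed run seed.
    """
    members = list(run.schema.trisynthons())
    if not members:
        raise ValueError("empty library")
    rng = np.random.default_rng(run.seed)
    p = np.array([affinity.capture_prob(m) for m in members])
    counts = np.empty((run.rounds + 1, len(members)), dtype=np.int64)
    counts[0] = run.copies_per_member
    for r in range(1, run.rounds + 1):
        counts[r] = rng.binomial(counts[r - 1], p)
    return SelectionCounts(members=members, counts=counts)


def _layout_chunks(layout: ReadLayout) -> tuple[str, list[tuple[str, int]]]:
    """Split a layout into (prefix, per-junction chunks).

    Chunk j is the text appended to a read once the polymerase traverses
    junction j: for U^tr T junctions a single-A gap plus the next tag
    window (placeholder cycle recorded), for the final faithful junction
    the trailing constant.
    """
    segments = list(layout.segments)
    if not isinstance(segments[0], Constant):
        raise ValueError("layout must start with the hairpin constant")
    prefix = segments[0].sequence
    chunks: list[tuple[str, int]] = []
    i = 1
    while i < len(segments):
        seg = segments[i]
        if isinstance(seg, JunctionGap):
            window = segments[i + 1]
            assert isinstance(window, TagWindow)
            chunks.append(("A" * seg.min_A, window.cycle_index))
            i += 2
        elif isinstance(seg, Constant):
            chunks.append((seg.sequence, 0))
            i += 1
        else:
            raise ValueError("unexpected tag window without a junction gap")
    return prefix, chunks


@dataclass
class EmittedReads:
    fastq_path: Path
    truth_path: Path
    n_reads: int
    n_truncated: int


def emit_reads(
    counts: np.ndarray,
    members: list[Trisynthon],
    layout: ReadLayout,
    n_reads: int,
    error_rate: float,
    enzyme: EnzymeProfile,
    seed: int,
    fastq_path: str | Path,
    truth_path: str | Path,
    population: str = "selected",
    read_id_prefix: str = "read",
) -> EmittedReads:
    """Sample reads from a population and write FASTQ plus a truth table.

    Reads are multinomial in the molecule counts. Each read is built from
    the layout with deterministic single-A junction gaps; with probability
    ``1 - read_through_prob`` per junction the polymerase stalls and the
    read is truncated there (stall artifacts +/-A applied). Substitution
    errors are uniform per base at ``error_rate``. The truth table records,
    per read, the member codes/blocks, the stop junction, the number of
    errors, and the worst per-code-window error count.
    """
    counts = np.asarray(counts)
    total = counts.sum()
    if n_reads > 0 and total == 0:
        raise ValueError("cannot sample reads from an all-zero population")
    rng = np.random.default_rng(seed)
    prefix, chunks = _layout_chunks(layout)
    n_junctions = len(chunks)
    p_read = counts / total if total else counts
    per_member = rng.multinomial(n_reads, p_read)

    # per-read stop junction: first Bernoulli(1-p) failure, else full length
    draws = rng.random((n_reads, n_junctions)) < enzyme.read_through_prob
    stops = np.where(draws.all(axis=1), n_junctions, draws.argmin(axis=1))
    artifact_names = ("correct", "minus_A", "plus_A")
    weights = [enzyme.stall_artifact_weights[k] for k in artifact_names]
    artifacts = rng.choice(3, size=n_reads, p=weights)

    # code windows needed to decode: chunks holding a tag window
    tag_chunk_ids = [k for k, (_, cyc) in enumerate(chunks) if cyc > 0]
    last_tag_chunk = max(tag_chunk_ids) if tag_chunk_ids else -1

    fastq_path, truth_path = Path(fastq_path), Path(truth_path)
    n_trunc = 0
    ridx = 0
    with open(fastq_path, "w") as fq, open(truth_path, "w") as tt:
        ncyc = len(tag_chunk_ids)
        tt.write(
            "read_id\t"
            + "\t".join(f"code{c + 1}" for c in range(ncyc))
            + "\t"
            + "\t".join(f"block{c + 1}" for c in range(ncyc))
            + "\tpopulation\tstopped_at\tartifact\tn_errors\tmax_code_errors\n"
        )
        for m_idx in np.flatnonzero(per_member):
            member = members[m_idx]
            # reverse-complemented code per cycle for this member
            rc_by_cycle = {
                c + 1: revcomp(member.codes[c]) for c in range(len(member.codes))
            }
            for _ in range(per_member[m_idx]):
                stop = int(stops[ridx])
                pieces = [prefix]
                window_spans: list[tuple[int, int]] = []
                pos = len(prefix)
                for k in range(stop):
                    gap_or_const, cyc = chunks[k]
                    pieces.append(gap_or_const)
                    pos += len(gap_or_const)
                    if cyc > 0:
                        w = rc_by_cycle[cyc]
                        pieces.append(w)
                        window_spans.append((pos, pos + len(w)))
                        pos += len(w)
                seq = "".join(pieces)
                art = "none"
                if stop < n_junctions:
                    art = artifact_names[artifacts[ridx]]
                    if art == "minus_A":
                        cut = seq.rfind("A")
                        seq = seq[:cut] + seq[cut + 1 :] if cut >= 0 else seq[:-1]
                    elif art == "plus_A":
                        seq += "A"
                truncated = stop <= last_tag_chunk
                n_trunc += truncated
                # substitution errors
                n_err = rng.binomial(len(seq), error_rate) if error_rate else 0
                max_code_err = 0
                if n_err:
                    positions = rng.choice(len(seq), size=n_err, replace=False)
                    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
                    for pos_e in positions:
                        choices = _BASES[_BASES != arr[pos_e]]
                        arr[pos_e] = rng.choice(choices)
                    seq = arr.tobytes().decode()
                    for a, b in window_spans:
                        max_code_err = max(
                            max_code_err,
                            int(((positions >= a) & (positions < b)).sum()),
                        )
                rid = f"{read_id_prefix}:{population}:{ridx}"
                fq.write(f"@{rid}\n{seq}\n+\n{_QUAL_CHAR * len(seq)}\n")
                stop_label = "full" if stop == n_junctions else str(stop)
                tt.write(
                    rid
                    + "\t"
                    + "\t".join(member.codes)
                    + "\t"
                    + "\t".join(member.blocks)
                    + f"\t{population}\t{stop_label}\t{art}\t{n_err}\t{max_code_err}\n"
                )
                ridx += 1
    return EmittedReads(fastq_path, truth_path, n_reads, n_trunc)


@dataclass
class ExperimentOutput:
    naive_fastq: Path
    selected_fastq: Path
    truth_naive: Path
    truth_selected: Path
    metadata: Path
    counts: SelectionCounts


def simulate_experiment(
    run: SelectionRun,
    affinity: AffinityModel,
    out_dir: str | Path,
    error_rate: float = 0.005,
    enzyme: EnzymeProfile = KLENOW,
    layout: ReadLayout | None = None,
) -> ExperimentOutput:
    """Full synthetic experiment: selection, then naive + selected reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    layout = layout or expected_read_layout(run.schema)
    counts = simulate_selection(run, affinity)
    naive = emit_reads(
        counts.round_counts(0),
        counts.members,
        layout,
        run.reads_naive,
        error_rate,
        enzyme,
        seed=run.seed + 1,
        fastq_path=out / "naive.fastq",
        truth_path=out / "truth_naive.tsv",
        population="naive",
    )
    selected = emit_reads(
        counts.round_counts(run.rounds),
        counts.members,
        layout,
        run.reads_selected,
        error_rate,
        enzyme,
        seed=run.seed + 2,
        fastq_path=out / "selected.fastq",
        truth_path=out / "truth_selected.tsv",
        population="selected",
    )
    meta = {
        "seed": run.seed,
        "rounds": run.rounds,
        "copies_per_member": run.copies_per_member,
        "reads_naive": run.reads_naive,
        "reads_selected": run.reads_selected,
        "error_rate": error_rate,
        "enzyme": enzyme.name,
        "read_through_prob": enzyme.read_through_prob,
        "n_members": len(counts.members),
        "background_capture_prob": affinity.background_capture_prob,
        "planted_families": [
            {
                "cycle_index": f.cycle_index,
                "block_id": f.block_id,
                "capture_prob": f.capture_prob,
            }
            for f in affinity.planted_families
        ],
    }
    meta_path = out / "metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2))
    return ExperimentOutput(
        naive_fastq=naive.fastq_path,
        selected_fastq=selected.fastq_path,
        truth_naive=naive.truth_path,
        truth_selected=selected.truth_path,
        metadata=meta_path,
        counts=counts,
    )


def expected_member_fold(
    run: SelectionRun, affinity: AffinityModel, member: Trisynthon
) -> float:
    """Closed-form expected measured fold enrichment for one member.

    The measured statistic is (selected frequency) / (naive frequency);
    with equal starting copies its expectation is
    capture^rounds / mean(capture^rounds) over the library.
    """
    members = list(run.schema.trisynthons())
    w = np.array([affinity.capture_prob(m) ** run.rounds for m in members])
    return float(
        affinity.capture_prob(member) ** run.rounds / w.sum() * len(members)
    )
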