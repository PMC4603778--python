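"""Decode sequencing reads into trisynthon identifiers and tabulate counts.

A read from a chemically ligated library shows: the hairpin-derived
constant, then the reverse-complemented 13-base codes in cycle order
3 -> 2 -> 1, separated by junction gaps of 1 A (the polymerase skips one
base of the U/T pair at each U^tr T triazole junction) or 2 A (no skip),
then the headpiece complement.

Decoding anchors the constant prefix (one mismatch allowed by default),
then walks the tag windows trying every allowed gap length, matching each
code with a bounded number of substitutions. Codes are designed at pairwise
edit distance >= 3, so a 1-substitution budget can never cross-assign a
code unless two errors fall inside one window. Ties between codes are
never broken arbitrarily: equal-distance double matches are dropped as
ambiguous. Reads too short to cover all tag windows (stalled extensions)
are tallied as truncated, not counted.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .schema import CODE_ALPHABET, LibrarySchema, ReadLayout, TagWindow, revcomp

__all__ = [
    "DecodeResult",
    "CountTable",
    "TagIndex",
    "parse_read",
    "count_reads",
    "decode_fastq",
]

STATUSES = ("ok", "constant_mismatch", "tag_unmatched", "ambiguous", "truncated")

AMBIGUOUS_CODE = "__ambiguous__"


@dataclass(frozen=True)
class DecodeResult:
    status: str
    codes: tuple[str, ...] | None = None  # cycle-ordered (1, 2, 3)
    blocks: tuple[str, ...] | None = None
    mismatches: tuple[int, ...] | None = None  # per tag, cycle-ordered
    gap_lengths: tuple[int, ...] | None = None  # observed, read order


class TagIndex:
    """Per-cycle lookup from read-orientation (reverse-complemented) code
    windows to codes/blocks, with an optional 1-mismatch neighbourhood map
    for O(1) fuzzy lookup."""

    def __init__(self, schema: LibrarySchema) -> None:
        self.schema = schema
        self.code_length = schema.code_length
        self.exact: dict[int, dict[str, str]] = {}
        self.fuzzy1: dict[int, dict[str, tuple[str, int]]] = {}
        self.blocks: dict[int, dict[str, str]] = {}
        for cycle in schema.cycles:
            exact = {revcomp(t.code): t.code for t in cycle.tags}
            self.exact[cycle.index] = exact
            self.blocks[cycle.index] = dict(cycle.assignment)
            fuzzy: dict[str, tuple[str, int]] = {
                w: (c, 0) for w, c in exact.items()
            }
            for window, code in exact.items():
                for pos, alt in itertools.product(
                    range(len(window)), CODE_ALPHABET
                ):
                    if alt == window[pos]:
                        continue
                    neighbour = window[:pos] + alt + window[pos + 1 :]
                    prev = fuzzy.get(neighbour)
                    if prev is None:
                        fuzzy[neighbour] = (code, 1)
                    elif prev[1] == 1 and prev[0] != code:
                        fuzzy[neighbour] = (AMBIGUOUS_CODE, 1)
                    # exact hits (distance 0) always win over neighbours
            self.fuzzy1[cycle.index] = fuzzy

    def match(
        self, window: str, cycle_index: int, max_mismatch: int
    ) -> tuple[str, int] | None:
        """Best unique code for a read window, or None / ambiguous marker."""
        hit = self.exact[cycle_index].get(window)
        if hit is not None:
            return hit, 0
        if max_mismatch == 0:
            return None
        if max_mismatch == 1:
            return self.fuzzy1[cycle_index].get(window)
        # general (rarely used) path: scan all codes by Hamming distance
        best: tuple[str, int] | None = None
        tied = False
        for rc_code, code in self.exact[cycle_index].items():
            d = sum(a != b for a, b in zip(window, rc_code))
            if d > max_mismatch:
                continue
            if best is None or d < best[1]:
                best, tied = (code, d), False
            elif d == best[1] and code != best[0]:
                tied = True
        if best is None:
            return None
        return (AMBIGUOUS_CODE, best[1]) if tied else best

    def is_ambiguous(self, hit: tuple[str, int] | None) -> bool:
        return hit is not None and hit[0] == AMBIGUOUS_CODE


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def parse_read(
    seq: str,
    layout: ReadLayout,
    tag_index: TagIndex,
    max_mismatch_per_tag: int = 1,
    constant_max_mismatch: int = 1,
) -> DecodeResult:
    """Decode one read against the expected layout.

    Returns a status, never raises: ``truncated`` when the read cannot
    cover every tag window, ``constant_mismatch`` when the anchoring
    prefix fails, ``tag_unmatched`` / ``ambiguous`` per the matching rules.
    """
    from .schema import Constant, JunctionGap  # local to avoid cycle noise

    segments = list(layout.segments)
    anchor = segments[0].sequence  # leading hairpin constant
    if len(seq) < len(anchor):
        return DecodeResult("truncated")
    if _hamming(seq[: len(anchor)], anchor) > constant_max_mismatch:
        return DecodeResult("constant_mismatch")

    pos = len(anchor)
    codes_by_cycle: dict[int, str] = {}
    mism_by_cycle: dict[int, int] = {}
    gaps: list[int] = []
    i = 1
    while i < len(segments):
        seg = segments[i]
        if isinstance(seg, Constant):
            i += 1
            continue
        assert isinstance(seg, JunctionGap)
        window_seg = segments[i + 1]
        assert isinstance(window_seg, TagWindow)
        L = window_seg.length
        best = None  # (mismatches, gap, code); code None marks ambiguity
        tied = False
        for g in range(seg.min_A, seg.max_A + 1):
            if pos + g + L > len(seq):
                continue
            if seq[pos : pos + g] != "A" * g:
                continue
            window = seq[pos + g : pos + g + L]
            hit = tag_index.match(
                window, window_seg.cycle_index, max_mismatch_per_tag
            )
            if hit is None:
                continue
            code, d = (None, hit[1]) if tag_index.is_ambiguous(hit) else hit
            if best is None or d < best[0]:
                best, tied = (d, g, code), code is None
            elif d == best[0] and code != best[2]:
                tied = True
        if best is None:
            # no gap placement yields any window fitting in the read?
            if pos + seg.min_A + L > len(seq):
                return DecodeResult("truncated")
            return DecodeResult("tag_unmatched")
        if tied or best[2] is None:
            return DecodeResult("ambiguous")
        d, g, code = best
        codes_by_cycle[window_seg.cycle_index] = code
        mism_by_cycle[window_seg.cycle_index] = d
        gaps.append(g)
        pos += g + L
        i += 2

    order = sorted(codes_by_cycle)
    codes = tuple(codes_by_cycle[c] for c in order)
    blocks = tuple(tag_index.blocks[c][codes_by_cycle[c]] for c in order)
    mism = tuple(mism_by_cycle[c] for c in order)
    return DecodeResult("ok", codes, blocks, mism, tuple(gaps))


@dataclass
class CountTable:
    """Trisynthon read counts per population plus decode-failure tallies."""

    counts: dict[tuple[str, ...], dict[str, int]] = field(default_factory=dict)
    failures: dict[str, dict[str, int]] = field(default_factory=dict)
    totals: dict[str, int] = field(default_factory=dict)
    blocks: dict[tuple[str, ...], tuple[str, ...]] = field(default_factory=dict)

    def populations(self) -> list[str]:
        return sorted(self.totals)

    def add(
        self,
        population: str,
        result: DecodeResult,
    ) -> None:
        self.totals[population] = self.totals.get(population, 0) + 1
        if result.status == "ok":
            per = self.counts.setdefault(result.codes, {})
            per[population] = per.get(population, 0) + 1
            self.blocks.setdefault(result.codes, result.blocks)
        else:
            per = self.failures.setdefault(population, {})
            per[result.status] = per.get(result.status, 0) + 1

    def count(self, codes: tuple[str, ...], population: str) -> int:
        return self.counts.get(codes, {}).get(population, 0)

    def decoded_total(self, population: str) -> int:
        return sum(per.get(population, 0) for per in self.counts.values())

    def failure_total(self, population: str) -> int:
        return sum(self.failures.get(population, {}).values())

    def check_conservation(self) -> bool:
        return all(
            self.decoded_total(p) + self.failure_total(p) == self.totals[p]
            for p in self.totals
        )

    # -- I/O ---------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        pops = self.populations()
        rows = []
        for codes, per in sorted(self.counts.items()):
            blocks = self.blocks.get(codes, ("",) * len(codes))
            row = {
                **{f"cycle{i + 1}_code": c for i, c in enumerate(codes)},
                **{f"cycle{i + 1}_block": b for i, b in enumerate(blocks)},
            }
            for p in pops:
                row[f"count_{p}"] = per.get(p, 0)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def stats(self) -> dict:
        return {
            "totals": dict(self.totals),
            "decoded": {p: self.decoded_total(p) for p in self.totals},
            "failures": {p: dict(self.failures.get(p, {})) for p in self.totals},
        }

    def write_stats(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.stats(), indent=2))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        code_cols = sorted(c for c in df.columns if c.endswith("_code"))
        block_cols = sorted(c for c in df.columns if c.endswith("_block"))
        count_cols = [c for c in df.columns if c.startswith("count_")]
        table = cls()
        for row in df.itertuples(index=False):
            d = row._asdict()
            codes = tuple(d[c] for c in code_cols)
            table.blocks[codes] = tuple(d[c] for c in block_cols)
            per = {}
            for c in count_cols:
                pop = c[len("count_") :]
                per[pop] = int(d[c])
                table.totals[pop] = table.totals.get(pop, 0) + int(d[c])
            table.counts[codes] = per
        return table


def _fastq_records(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) from a FASTQ file, with record numbering in
    error messages for malformed input."""
    with open(path) as handle:
        try:
            for i, (title, seq, _qual) in enumerate(
                FastqGeneralIterator(handle), start=1
            ):
                yield title.split()[0], seq
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record near record {i}: {exc}") from exc


def count_reads(
    streams: dict[str, str | Path | Iterable[tuple[str, str]]],
    layout: ReadLayout,
    tag_index: TagIndex,
    max_mismatch_per_tag: int = 1,
    constant_max_mismatch: int = 1,
) -> CountTable:
    """Decode labelled FASTQ streams into a :class:`CountTable`.

    ``streams`` maps a population label to a FASTQ path (or an iterable of
    (read_id, sequence) pairs). Streaming: memory is constant in the read
    count. Totals are conserved: ok + failures == reads, per population.
    """
    if not streams:
        raise ValueError("need at least one read stream")
    table = CountTable()
    for population, source in streams.items():
        records = (
            _fastq_records(source)
            if isinstance(source, (str, Path))
            else iter(source)
        )
        for _rid, seq in records:
            result = parse_read(
                seq,
                layout,
                tag_index,
                max_mismatch_per_tag=max_mismatch_per_tag,
                constant_max_mismatch=constant_max_mismatch,
            )
            table.add(population, result)
        table.totals.setdefault(population, 0)
    return table


def decode_fastq(
    fastq: str | Path,
    layout: ReadLayout,
    tag_index: TagIndex,
    max_mismatch_per_tag: int = 1,
    reverse_complement: bool = False,
) -> Iterator[tuple[str, DecodeResult]]:
    """Yield (read_id, DecodeResult) for each read in a FASTQ file."""
    for rid, seq in _fastq_records(fastq):
        if reverse_complement:
            seq = revcomp(seq)
        yield rid, parse_read(
            seq, layout, tag_index, max_mismatch_per_tag=max_mismatch_per_tag
        )
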