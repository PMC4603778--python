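"""Encoding schema for a chemically ligated, 3-cycle DNA-encoded library.

The encoding oligo is grown 5'->3' by iterative CuAAC ligation:

    headpiece(...rG-3'-propargyl) ^tr (T code1 U) ^tr (T code2 U)
        ^tr (T code3 U) ^tr (T...hairpin)

Every tag conforms to ``5'-azido-T<13 nt code>U-3'-propargyl-TIPS``: the
leading T and trailing U flank the information-bearing 13-mer and are the
bases that sit at triazole junctions. The headpiece-tag1 junction is
``rG^tr T`` (copied faithfully by Klenow); all later junctions are
``U^tr T`` (the U/T pair is copied into a single A, so junction gaps in a
read are 1 A, or 2 A if the polymerase does not skip).

Sequencing starts from the self-priming hairpin at the 3' end, so a read
shows the hairpin-derived constant first, then the reverse-complemented
codes in cycle order 3 -> 2 -> 1, then the headpiece complement. All
coordinates are 0-based, half-open.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import edlib
import numpy as np
import pandas as pd

__all__ = [
    "Tag",
    "BuildingBlock",
    "Cycle",
    "LibrarySchema",
    "Trisynthon",
    "ReadLayout",
    "Constant",
    "TagWindow",
    "JunctionGap",
    "validate_schema",
    "library_diversity",
    "generate_tag_set",
    "expected_read_layout",
    "build_schema",
    "full_scale_schema",
    "write_schema",
    "read_schema",
    "revcomp",
    "TagInfeasibleError",
]

CODE_ALPHABET = "ACGT"
CODE_LENGTH = 13

_COMP = str.maketrans("ACGTU", "TGCAA")

Role = Literal["amine", "bromoaryl_acid", "boronate", "null"]
_CYCLE_ROLES: dict[int, set[str]] = {
    1: {"amine"},
    2: {"bromoaryl_acid"},
    3: {"boronate", "null"},
}


def revcomp(seq: str) -> str:
    """Reverse complement (U treated as T on the template strand)."""
    return seq.translate(_COMP)[::-1]


class TagInfeasibleError(RuntimeError):
    """Tag set generation could not satisfy the distance constraint."""


@dataclass(frozen=True)
class Tag:
    """One encoding tag oligo: ``5'-azido-T<code>U-3'-propargyl-TIPS``."""

    cycle_index: int
    well_id: str
    code: str
    five_prime_chem: str = "azido"
    three_prime_chem: str = "propargyl_TIPS"

    @property
    def full_sequence(self) -> str:
        return "T" + self.code + "U"


@dataclass(frozen=True)
class BuildingBlock:
    id: str
    cycle_index: int
    role: str
    display_name: str = ""


@dataclass
class Cycle:
    """One synthesis cycle: its tags and the tag->building-block assignment."""

    index: int
    tags: list[Tag]
    blocks: dict[str, BuildingBlock]  # block id -> block
    assignment: dict[str, str]  # tag code -> block id

    @property
    def codes(self) -> list[str]:
        return [t.code for t in self.tags]

    def block_for_code(self, code: str) -> BuildingBlock:
        return self.blocks[self.assignment[code]]


@dataclass
class LibrarySchema:
    """Cycles, constant oligo regions and junction-gap behaviour.

    ``headpiece_sequence`` is the 5' constant whose 3'-terminal residue is a
    ribo-G bearing the first propargyl; ``hairpin_constant`` is the
    self-priming 3' hairpin segment whose complement opens every read
    (its 5'-terminal T participates in the last junction gap).
    """

    cycles: list[Cycle]
    headpiece_sequence: str = "TCGAATGACTCCGATATG"
    hairpin_constant: str = "TGAGTCGGATCGAC"
    min_code_distance: int = 3
    gap_min: int = 1
    gap_max: int = 2
    code_length: int = CODE_LENGTH

    def cycle(self, index: int) -> Cycle:
        for c in self.cycles:
            if c.index == index:
                return c
        raise KeyError(f"no cycle {index}")

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    def junction_types(self) -> list[str]:
        """Junction types in chain order (headpiece-tag1 first)."""
        return ["rG_tr_T"] + ["U_tr_T"] * self.n_cycles

    def trisynthons(self) -> Iterable["Trisynthon"]:
        """All encoded code combinations, in deterministic schema order."""
        if not self.cycles:
            return
        for combo in itertools.product(*(c.tags for c in self.cycles)):
            codes = tuple(t.code for t in combo)
            blocks = tuple(
                c.assignment[t.code] for c, t in zip(self.cycles, combo)
            )
            yield Trisynthon(codes=codes, blocks=blocks)


@dataclass(frozen=True)
class Trisynthon:
    """One member of the combinatorial library: a code/block per cycle."""

    codes: tuple[str, ...]
    blocks: tuple[str, ...]


# ---------------------------------------------------------------------------
# Read layout
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Constant:
    sequence: str


@dataclass(frozen=True)
class TagWindow:
    cycle_index: int
    length: int = CODE_LENGTH


@dataclass(frozen=True)
class JunctionGap:
    min_A: int = 1
    max_A: int = 2


Segment = Constant | TagWindow | JunctionGap


@dataclass
class ReadLayout:
    """Expected read structure, in read orientation (hairpin end first).

    Tag windows hold reverse-complemented codes and appear in cycle order
    3 -> 2 -> 1. ``n_junctions`` counts triazole junctions a polymerase must
    traverse to produce the full read (the variable-gap U^tr T junctions
    plus the final faithful rG^tr T junction inside the trailing constant).
    """

    segments: list[Segment]
    n_junctions: int

    def tag_cycles(self) -> list[int]:
        return [s.cycle_index for s in self.segments if isinstance(s, TagWindow)]

    def min_spans(self) -> list[tuple[int, int]]:
        """0-based half-open segment coordinates at minimum gap lengths."""
        spans = []
        pos = 0
        for seg in self.segments:
            if isinstance(seg, Constant):
                n = len(seg.sequence)
            elif isinstance(seg, TagWindow):
                n = seg.length
            else:
                n = seg.min_A
            spans.append((pos, pos + n))
            pos += n
        return spans

    @property
    def min_length(self) -> int:
        return self.min_spans()[-1][1]

    def min_length_through_last_tag(self) -> int:
        """Read length needed (at min gaps) to cover every tag window."""
        spans = self.min_spans()
        last = max(
            i for i, s in enumerate(self.segments) if isinstance(s, TagWindow)
        )
        return spans[last][1]


def expected_read_layout(schema: LibrarySchema) -> ReadLayout:
    """Derive the expected sequencing-read layout from a schema.

    Read = revcomp(hairpin constant minus its junction T), then per cycle
    (descending) a 1-2 A junction gap and the 13-base reverse-complemented
    code, then the faithful tail: A (tag1's leading T), C (the headpiece's
    ribo-G, correctly transcribed) and the headpiece complement.
    """
    violations = validate_schema(schema)
    if violations:
        raise ValueError("invalid schema: " + "; ".join(violations))
    segments: list[Segment] = [Constant(revcomp(schema.hairpin_constant[1:]))]
    for cycle in sorted(schema.cycles, key=lambda c: -c.index):
        segments.append(JunctionGap(schema.gap_min, schema.gap_max))
        segments.append(TagWindow(cycle.index, schema.code_length))
    tail = "A" + revcomp(schema.headpiece_sequence)  # revcomp includes rG -> C
    segments.append(Constant(tail))
    # U^tr T junction per tag plus the faithful rG^tr T junction
    return ReadLayout(segments=segments, n_junctions=schema.n_cycles + 1)


# ---------------------------------------------------------------------------
# Validation and counting
# ---------------------------------------------------------------------------


def edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance")["editDistance"]


def validate_schema(schema: LibrarySchema) -> list[str]:
    """Check all schema invariants; return human-readable violations."""
    v: list[str] = []
    if not schema.cycles:
        return ["schema has no cycles"]
    for seq, name in (
        (schema.headpiece_sequence, "headpiece"),
        (schema.hairpin_constant, "hairpin"),
    ):
        bad = [c for c in seq if c not in "ACGTU"]
        if bad:
            v.append(f"{name} sequence has invalid characters {bad}")
    if schema.headpiece_sequence and not schema.headpiece_sequence.endswith("G"):
        v.append("headpiece must end in its propargylated ribo-G")
    if schema.hairpin_constant and not schema.hairpin_constant.startswith("T"):
        v.append("hairpin constant must start with the junction T")
    for cycle in schema.cycles:
        seen: dict[str, str] = {}
        for tag in cycle.tags:
            label = f"cycle {cycle.index} tag {tag.well_id}"
            if len(tag.code) != schema.code_length:
                v.append(f"{label}: code length != {schema.code_length}")
            bad = [c for c in tag.code if c not in CODE_ALPHABET]
            if bad:
                v.append(f"{label}: invalid characters {bad} in code")
            if tag.full_sequence != "T" + tag.code + "U":
                v.append(f"{label}: full sequence not T+code+U")
            if tag.code in seen:
                v.append(
                    f"{label}: code duplicates {seen[tag.code]} (codes must be "
                    f"unique within a cycle)"
                )
            else:
                seen[tag.code] = tag.well_id
            if tag.code not in cycle.assignment:
                v.append(f"{label}: no building block assigned")
            elif cycle.assignment[tag.code] not in cycle.blocks:
                v.append(f"{label}: assigned block not in cycle block table")
        for block in cycle.blocks.values():
            allowed = _CYCLE_ROLES.get(cycle.index)
            if allowed is not None and block.role not in allowed:
                v.append(
                    f"cycle {cycle.index} block {block.id}: role {block.role!r} "
                    f"not allowed (expected one of {sorted(allowed)})"
                )
        if schema.min_code_distance > 1:
            codes = [t.code for t in cycle.tags]
            for i in range(len(codes)):
                for j in range(i + 1, len(codes)):
                    d = edit_distance(codes[i], codes[j])
                    if d < schema.min_code_distance:
                        v.append(
                            f"cycle {cycle.index}: codes {codes[i]} and "
                            f"{codes[j]} at edit distance {d} < "
                            f"{schema.min_code_distance}"
                        )
    return v


def library_diversity(
    schema: LibrarySchema,
    count_rule: Literal["unique_products", "encoded_combinations"] = "unique_products",
) -> int:
    """Library size under either counting rule.

    ``unique_products`` multiplies the number of distinct non-null building
    blocks per cycle (a block tagged in several wells counts once);
    ``encoded_combinations`` multiplies tag counts, i.e. the number of
    distinguishable DNA barcodes.
    """
    if not schema.cycles:
        raise ValueError("schema has no cycles")
    total = 1
    for cycle in schema.cycles:
        if count_rule == "unique_products":
            n = len({b.id for b in cycle.blocks.values() if b.role != "null"})
        elif count_rule == "encoded_combinations":
            n = len(cycle.tags)
        else:
            raise ValueError(f"unknown count rule {count_rule!r}")
        if n == 0:
            raise ValueError(f"cycle {cycle.index} contributes no members")
        total *= n
    return total


def generate_tag_set(
    n: int,
    code_length: int = CODE_LENGTH,
    min_edit_distance: int = 3,
    seed: int = 0,
    cycle_index: int = 1,
    attempt_budget: int = 200_000,
) -> list[Tag]:
    """Generate ``n`` tags with pairwise code edit distance >= the minimum.

    Rejection sampling of random codes against the accepted set;
    deterministic for a fixed seed. Raises :class:`TagInfeasibleError` when
    the attempt budget is exhausted (or trivially by pigeonhole).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > 4**code_length:
        raise TagInfeasibleError(
            f"{n} codes cannot fit in a {code_length}-mer alphabet of 4"
        )
    rng = np.random.default_rng(seed)
    accepted: list[str] = []
    attempts = 0
    while len(accepted) < n:
        attempts += 1
        if attempts > attempt_budget:
            raise TagInfeasibleError(
                f"could not place {n} codes at distance "
                f">= {min_edit_distance} within {attempt_budget} attempts "
                f"(placed {len(accepted)})"
            )
        code = "".join(CODE_ALPHABET[i] for i in rng.integers(0, 4, code_length))
        if all(edit_distance(code, c) >= min_edit_distance for c in accepted):
            accepted.append(code)
    return [
        Tag(cycle_index=cycle_index, well_id=f"C{cycle_index}-W{i + 1:04d}", code=c)
        for i, c in enumerate(accepted)
    ]


# ---------------------------------------------------------------------------
# Schema construction and round-trip I/O
# ---------------------------------------------------------------------------


def _role_for_cycle(index: int) -> str:
    return {1: "amine", 2: "bromoaryl_acid", 3: "boronate"}.get(index, "amine")


def build_schema(
    tags_per_cycle: list[int],
    seed: int = 0,
    min_code_distance: int = 3,
    code_length: int = CODE_LENGTH,
    blocks_per_cycle: list[list[BuildingBlock]] | None = None,
    **schema_kwargs,
) -> LibrarySchema:
    """Build a schema with generated tags and one block per tag by default."""
    cycles: list[Cycle] = []
    for i, n in enumerate(tags_per_cycle, start=1):
        tags = generate_tag_set(
            n,
            code_length=code_length,
            min_edit_distance=min_code_distance,
            seed=seed + i,
            cycle_index=i,
        )
        if blocks_per_cycle is not None:
            blocks = {b.id: b for b in blocks_per_cycle[i - 1]}
            if len(blocks) != n:
                raise ValueError("need exactly one block per tag in build_schema")
            assignment = {t.code: b for t, b in zip(tags, blocks)}
        else:
            role = _role_for_cycle(i)
            blocks = {
                f"B{i}-{k + 1:04d}": BuildingBlock(
                    id=f"B{i}-{k + 1:04d}",
                    cycle_index=i,
                    role=role,
                    display_name=f"{role} {k + 1}",
                )
                for k in range(n)
            }
            assignment = {t.code: f"B{i}-{k + 1:04d}" for k, t in enumerate(tags)}
        cycles.append(Cycle(index=i, tags=tags, blocks=blocks, assignment=assignment))
    return LibrarySchema(
        cycles=cycles,
        min_code_distance=min_code_distance,
        code_length=code_length,
        **schema_kwargs,
    )


def full_scale_schema() -> LibrarySchema:
    """The production-scale 3-cycle design, for counting and layout work.

    2,259 amines in cycle 1; 666 tagged wells sharing 222 unique bromoaryl
    acids (each acid used in 3 wells) in cycle 2; 669 tags in cycle 3 for
    667 boronates plus 2 encoded nulls (wells that received no reagent).
    Codes are sequential placeholders (the real tag sequences are not
    public), so ``min_code_distance`` is set to 1 and this schema is for
    diversity arithmetic and layout derivation, not decoding.
    """

    def seq_codes(n: int) -> list[str]:
        out = []
        for i in range(n):
            digits = []
            x = i
            for _ in range(CODE_LENGTH):
                digits.append(CODE_ALPHABET[x % 4])
                x //= 4
            out.append("".join(reversed(digits)))
        return out

    cycles = []
    plans = [
        (1, 2259, [("amine", k + 1, 1) for k in range(2259)]),
        (2, 666, [("bromoaryl_acid", (k % 222) + 1, 1) for k in range(666)]),
        (3, 669, [("boronate", k + 1, 1) for k in range(667)] + [("null", k, 1) for k in (668, 669)]),
    ]
    for index, n_tags, block_plan in plans:
        tags = [
            Tag(cycle_index=index, well_id=f"C{index}-W{i + 1:04d}", code=c)
            for i, c in enumerate(seq_codes(n_tags))
        ]
        blocks: dict[str, BuildingBlock] = {}
        assignment: dict[str, str] = {}
        for tag, (role, num, _) in zip(tags, block_plan):
            bid = f"{role}-{num:04d}"
            blocks.setdefault(
                bid,
                BuildingBlock(
                    id=bid, cycle_index=index, role=role, display_name=bid
                ),
            )
            assignment[tag.code] = bid
        cycles.append(Cycle(index=index, tags=tags, blocks=blocks, assignment=assignment))
    return LibrarySchema(cycles=cycles, min_code_distance=1)


def write_schema(schema: LibrarySchema, directory: str | Path) -> None:
    """Write tags.tsv, blocks.tsv and config.json to ``directory``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    tag_rows, block_rows = [], []
    for cycle in schema.cycles:
        for tag in cycle.tags:
            tag_rows.append(
                {
                    "cycle": cycle.index,
                    "well_id": tag.well_id,
                    "code": tag.code,
                    "block_id": cycle.assignment.get(tag.code, ""),
                }
            )
        for block in cycle.blocks.values():
            block_rows.append(
                {
                    "cycle": cycle.index,
                    "block_id": block.id,
                    "role": block.role,
                    "display_name": block.display_name,
                }
            )
    pd.DataFrame(tag_rows).to_csv(d / "tags.tsv", sep="\t", index=False)
    pd.DataFrame(block_rows).to_csv(d / "blocks.tsv", sep="\t", index=False)
    config = {
        "headpiece_sequence": schema.headpiece_sequence,
        "hairpin_constant": schema.hairpin_constant,
        "min_code_distance": schema.min_code_distance,
        "gap_min": schema.gap_min,
        "gap_max": schema.gap_max,
        "code_length": schema.code_length,
    }
    (d / "config.json").write_text(json.dumps(config, indent=2))


def read_schema(directory: str | Path) -> LibrarySchema:
    """Parse a schema written by :func:`write_schema`."""
    d = Path(directory)
    tags_df = pd.read_csv(d / "tags.tsv", sep="\t", dtype=str)
    blocks_df = pd.read_csv(d / "blocks.tsv", sep="\t", dtype=str).fillna("")
    config = json.loads((d / "config.json").read_text())
    cycles: list[Cycle] = []
    for index in sorted(tags_df["cycle"].astype(int).unique()):
        ct = tags_df[tags_df["cycle"].astype(int) == index]
        cb = blocks_df[blocks_df["cycle"].astype(int) == index]
        tags = [
            Tag(cycle_index=index, well_id=r.well_id, code=r.code)
            for r in ct.itertuples(index=False)
        ]
        blocks = {
            r.block_id: BuildingBlock(
                id=r.block_id,
                cycle_index=index,
                role=r.role,
                display_name=r.display_name,
            )
            for r in cb.itertuples(index=False)
        }
        assignment = {r.code: r.block_id for r in ct.itertuples(index=False)}
        cycles.append(Cycle(index=index, tags=tags, blocks=blocks, assignment=assignment))
    return LibrarySchema(
        cycles=cycles,
        headpiece_sequence=config["headpiece_sequence"],
        hairpin_constant=config["hairpin_constant"],
        min_code_distance=int(config["min_code_distance"]),
        gap_min=int(config["gap_min"]),
        gap_max=int(config["gap_max"]),
        code_length=int(config["code_length"]),
    )
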