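"""Enrichment statistics and structure-family aggregation.

Fold enrichment compares a trisynthon's frequency in the selected
population with its naive-library frequency; a member never seen in the
naive reads is compared against the naive *average* (1 / library
diversity), which is how a count of 13 among ~1.5e5 selected reads and 0
among ~2e6 naive reads over a 3.3e8-member library works out to roughly a
30,000-fold enrichment.

Families are "planes": sets of enriched trisynthons sharing one fixed
building block in one cycle (a plane in the 3-axis cube visualization of a
3-cycle library). Detection is greedy: the candidate (cycle, block) with
the most significant joint Poisson evidence is extracted, its members
removed, and the search repeated -- so a real single-block plane is
reported once rather than echoed by every building block its members
happen to contain. The Poisson-tail machinery is this package's own
statistic; visual inspection of the cube plot is the classical approach.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import poisson

from .decode import CountTable
from .schema import LibrarySchema

__all__ = [
    "EnrichmentResult",
    "Plane",
    "FamilyReport",
    "fold_enrichment",
    "rank_enriched",
    "detect_planes",
    "prevalence_table",
    "cube_coordinates",
    "plot_cube",
]


@dataclass(frozen=True)
class EnrichmentResult:
    codes: tuple[str, ...]
    blocks: tuple[str, ...]
    sel_count: int
    sel_total: int
    naive_count: int
    naive_total: int
    fold_enrichment: float
    poisson_tail: float  # P(X >= sel_count) under the naive-rate null
    log10_tail: float


def fold_enrichment(
    sel_count: int,
    sel_total: int,
    naive_count: int,
    naive_total: int,
    diversity: int,
) -> float:
    """Selected frequency over the naive baseline frequency.

    The baseline is the member's naive frequency when it was observed
    naive, else the naive average ``1 / diversity`` — no pseudocounts.
    """
    if sel_total <= 0 or diversity <= 0:
        raise ValueError("sel_total and diversity must be positive")
    if naive_total <= 0:
        raise ValueError("naive_total must be positive")
    observed = sel_count / sel_total
    baseline = (
        naive_count / naive_total if naive_count > 0 else 1.0 / diversity
    )
    return observed / baseline


def _member_result(
    codes: tuple[str, ...],
    blocks: tuple[str, ...],
    sel_count: int,
    sel_total: int,
    naive_count: int,
    naive_total: int,
    diversity: int,
) -> EnrichmentResult:
    fold = fold_enrichment(sel_count, sel_total, naive_count, naive_total, diversity)
    baseline = (
        naive_count / naive_total if naive_count > 0 else 1.0 / diversity
    )
    rate = sel_total * baseline
    log_tail = float(poisson.logsf(sel_count - 1, rate)) if sel_count > 0 else 0.0
    return EnrichmentResult(
        codes=codes,
        blocks=blocks,
        sel_count=sel_count,
        sel_total=sel_total,
        naive_count=naive_count,
        naive_total=naive_total,
        fold_enrichment=fold,
        poisson_tail=math.exp(log_tail),
        log10_tail=log_tail / math.log(10),
    )


def rank_enriched(
    table: CountTable,
    diversity: int,
    min_count: int = 1,
    selected_label: str = "selected",
    naive_label: str = "naive",
) -> list[EnrichmentResult]:
    """Per-trisynthon enrichment, descending by fold.

    Stable order: fold enrichment desc, then selected count desc, then
    lexicographic codes. Members with selected count below ``min_count``
    are dropped.
    """
    for label in (selected_label, naive_label):
        if label not in table.totals:
            raise ValueError(f"population {label!r} missing from count table")
    sel_total = table.totals[selected_label]
    naive_total = table.totals[naive_label]
    results = []
    for codes, per in table.counts.items():
        sel = per.get(selected_label, 0)
        if sel < min_count:
            continue
        results.append(
            _member_result(
                codes,
                table.blocks.get(codes, ("",) * len(codes)),
                sel,
                sel_total,
                per.get(naive_label, 0),
                naive_total,
                diversity,
            )
        )
    results.sort(key=lambda r: (-r.fold_enrichment, -r.sel_count, r.codes))
    return results


@dataclass
class Plane:
    cycle_index: int
    block_id: str
    members: list[EnrichmentResult]
    joint_log10_tail: float  # Bonferroni-adjusted

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclass
class FamilyReport:
    planes: list[Plane] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = []
        for p in self.planes:
            payload.append(
                {
                    "cycle_index": p.cycle_index,
                    "block_id": p.block_id,
                    "n_members": p.n_members,
                    "joint_log10_tail": p.joint_log10_tail,
                    "members": [
                        {
                            "codes": list(m.codes),
                            "blocks": list(m.blocks),
                            "sel_count": m.sel_count,
                            "naive_count": m.naive_count,
                            "fold_enrichment": m.fold_enrichment,
                        }
                        for m in p.members
                    ],
                    "prevalence": {
                        str(c): prevalence_table(p, c)
                        for c in sorted(
                            {i + 1 for m in p.members for i in range(len(m.blocks))}
                        )
                    },
                }
            )
        Path(path).write_text(json.dumps(payload, indent=2))


def detect_planes(
    results: list[EnrichmentResult],
    min_members: int = 3,
    tail_threshold: float = 1e-6,
    member_tail: float = 1e-3,
) -> FamilyReport:
    """Detect fixed-building-block planes among enriched trisynthons.

    Members whose individual Poisson tail falls below ``member_tail`` are
    grouped by every (cycle, block) they contain; the candidate with the
    smallest joint log-tail (sum of member log-tails, Bonferroni-adjusted
    across candidates) is accepted if it has >= ``min_members`` members and
    clears ``tail_threshold``; its members are removed and the search
    repeats. Greedy extraction keeps a single causal block from being
    reported once per co-occurring building block.
    """
    if not results:
        raise ValueError("results must be nonempty")
    log10_thresh = math.log10(tail_threshold)
    remaining = [r for r in results if r.poisson_tail < member_tail]
    planes: list[Plane] = []
    while remaining:
        groups: dict[tuple[int, str], list[EnrichmentResult]] = {}
        for r in remaining:
            for i, block in enumerate(r.blocks):
                groups.setdefault((i + 1, block), []).append(r)
        candidates = {
            k: v for k, v in groups.items() if len(v) >= min_members
        }
        if not candidates:
            break
        bonferroni = math.log10(len(candidates))
        scored = []
        for (cycle, block), members in candidates.items():
            joint = sum(m.log10_tail for m in members) + bonferroni
            scored.append((joint, cycle, block, members))
        scored.sort(key=lambda t: (t[0], t[1], t[2]))
        joint, cycle, block, members = scored[0]
        if joint > log10_thresh:
            break
        planes.append(
            Plane(
                cycle_index=cycle,
                block_id=block,
                members=sorted(members, key=lambda m: -m.sel_count),
                joint_log10_tail=joint,
            )
        )
        kept = {id(m) for m in members}
        remaining = [r for r in remaining if id(r) not in kept]
    return FamilyReport(planes=planes)


def prevalence_table(plane: Plane, cycle_index: int) -> dict[str, float]:
    """Fraction of plane members carrying each building block in a cycle.

    Denominators count member trisynthons, not reads; fractions over the
    blocks present sum to 1.
    """
    if not plane.members:
        raise ValueError("empty family")
    tally: dict[str, int] = {}
    for m in plane.members:
        block = m.blocks[cycle_index - 1]
        tally[block] = tally.get(block, 0) + 1
    n = len(plane.members)
    return {b: k / n for b, k in sorted(tally.items(), key=lambda kv: -kv[1])}


def cube_coordinates(
    table: CountTable,
    schema: LibrarySchema,
    population: str = "selected",
) -> pd.DataFrame:
    """Axis coordinates for a cube plot: one row per observed trisynthon.

    Axis index = the block's position in its cycle's ordered block list
    (deterministic schema order); only members with count > 0 appear.
    """
    orders = {
        c.index: {bid: i for i, bid in enumerate(c.blocks)} for c in schema.cycles
    }
    rows = []
    for codes, per in sorted(table.counts.items()):
        n = per.get(population, 0)
        if n <= 0:
            continue
        blocks = table.blocks.get(codes)
        if blocks is None:
            raise ValueError(f"no block assignment recorded for {codes}")
        coords = {}
        for i, block in enumerate(blocks):
            order = orders[i + 1]
            if block not in order:
                raise ValueError(f"block {block!r} missing from cycle {i + 1}")
            coords[f"cycle{i + 1}_index"] = order[block]
        rows.append({**coords, "count": n})
    return pd.DataFrame(rows, columns=[*(f"cycle{i}_index" for i in (1, 2, 3)), "count"])


def plot_cube(coords: pd.DataFrame, path: str | Path, highlight: pd.Series | None = None) -> None:
    """Render cube-plot coordinates to an image file (3D scatter)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(6, 6))
    ax = fig.add_subplot(projection="3d")
    sizes = 4 + 40 * np.sqrt(coords["count"] / max(coords["count"].max(), 1))
    colors = (
        np.where(highlight, "tab:blue", "lightgray")
        if highlight is not None
        else "tab:blue"
    )
    ax.scatter(
        coords["cycle1_index"],
        coords["cycle2_index"],
        coords["cycle3_index"],
        s=sizes,
        c=colors,
        alpha=0.7,
    )
    ax.set_xlabel("cycle 1 (amine)")
    ax.set_ylabel("cycle 2 (acid)")
    ax.set_zlabel("cycle 3 (boronate)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
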