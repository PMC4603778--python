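"""Bundled reference data: the characterization oligo set and enzyme profiles."""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .oligo import OligoSpec, parse_oligo

__all__ = ["ReferenceOligo", "load_reference_oligos"]


@dataclass(frozen=True)
class ReferenceOligo:
    id: str
    notation: str
    spec: OligoSpec
    reported_mw: float
    notes: str


def load_reference_oligos() -> dict[str, ReferenceOligo]:
    """Load the bundled triazole read-through reference oligo set, parsed."""
    with resources.files("clickdel.data").joinpath("reference_oligos.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#", dtype={"id": str})
    out: dict[str, ReferenceOligo] = {}
    for row in df.itertuples(index=False):
        out[row.id] = ReferenceOligo(
            id=row.id,
            notation=row.sequence,
            spec=parse_oligo(row.sequence),
            reported_mw=float(row.reported_mw),
            notes=str(row.notes),
        )
    return out
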