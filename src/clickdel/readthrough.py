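"""Stochastic model of primer extension across triazole backbone junctions.

A polymerase walking a triazole-containing template either traverses each
junction (probability ``read_through_prob``, i.i.d. per junction) or stalls
there. Junction chemistry matters on traversal:

* ``rG^tr T`` (headpiece-side): copied faithfully -- both flanking bases
  appear in the product;
* ``U^tr T`` (tag-tag): the U/T pair is copied into a single A -- one
  template base is skipped, so a full-length product is one A short per
  such junction.

Stalled products carry artifacts: most end exactly at the junction, but a
fraction lose or gain one adenosine (``minus_A`` / ``plus_A``), as seen in
the mass spectra of stalled material. Full-length products show no such
artifacts.

Enzyme read-through probabilities come from measured stall:full product
ratios on a single-junction template; Klenow fragment (2:8, i.e. 0.8 per
junction) is the reference enzyme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .oligo import (
    DA_RESIDUE_MASS,
    ModificationTable,
    OligoSpec,
    oligo_mass,
)
from .schema import revcomp

__all__ = [
    "EnzymeProfile",
    "TemplateModel",
    "ExtensionOutcome",
    "SpectrumEntry",
    "FractionEstimate",
    "ENZYMES",
    "KLENOW",
    "enzyme_from_ratio",
    "extend_once",
    "full_length_fraction",
    "product_spectrum",
    "FULL",
]

#: Sentinel stop position for a full-length extension product.
FULL = "FULL"

#: Default stall-artifact mix: adenosine deletions are the dominant stall
#: side product and additions are rarer; the exact split is not quantified
#: experimentally, so these weights are configuration, not measurement.
DEFAULT_ARTIFACT_WEIGHTS = {"correct": 0.6, "minus_A": 0.3, "plus_A": 0.1}


@dataclass(frozen=True)
class EnzymeProfile:
    name: str
    read_through_prob: float
    stall_artifact_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ARTIFACT_WEIGHTS)
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.read_through_prob <= 1.0:
            raise ValueError("read_through_prob must be in [0, 1]")
        w = self.stall_artifact_weights
        if set(w) != {"correct", "minus_A", "plus_A"}:
            raise ValueError("artifact weights must cover correct/minus_A/plus_A")
        if any(x < 0 for x in w.values()) or not math.isclose(sum(w.values()), 1.0):
            raise ValueError("artifact weights must be nonnegative and sum to 1")


def enzyme_from_ratio(
    stall: float,
    full: float,
    name: str = "custom",
    stall_artifact_weights: dict[str, float] | None = None,
) -> EnzymeProfile:
    """Build a profile from a measured stall:full product ratio."""
    if stall < 0 or full < 0:
        raise ValueError("ratio components must be nonnegative")
    if stall + full == 0:
        raise ValueError("stall and full cannot both be zero")
    return EnzymeProfile(
        name=name,
        read_through_prob=full / (stall + full),
        stall_artifact_weights=dict(
            stall_artifact_weights or DEFAULT_ARTIFACT_WEIGHTS
        ),
    )


#: Measured single-junction stall:full ratios per enzyme.
ENZYMES: dict[str, EnzymeProfile] = {
    "E. coli DNA Pol I": enzyme_from_ratio(3, 7, "E. coli DNA Pol I"),
    "Klenow": enzyme_from_ratio(2, 8, "Klenow"),
    "Therminator": enzyme_from_ratio(4, 6, "Therminator"),
    "Superscript III": enzyme_from_ratio(6, 4, "Superscript III"),
    "9degN": enzyme_from_ratio(6, 4, "9degN"),
}
KLENOW = ENZYMES["Klenow"]


@dataclass
class TemplateModel:
    """A triazole-containing template with a primer at its 3' end.

    ``residues`` is the template base string 5'->3' (U allowed);
    ``junctions`` lists (position, type) pairs where ``position`` i means a
    triazole linkage between template residues i and i+1 and type is
    ``"rG_tr_T"`` or ``"U_tr_T"`` (the named base 5' of the junction).
    ``primer_length`` template bases at the 3' end are covered by the
    annealed primer; all junctions must lie 5' of the primer site.
    """

    residues: str
    junctions: list[tuple[int, str]]
    primer_length: int
    product_five_prime_mod: str | None = None

    def __post_init__(self) -> None:
        n = len(self.residues)
        if not 0 < self.primer_length <= n:
            raise ValueError("primer_length out of range")
        for pos, jtype in self.junctions:
            if jtype not in ("rG_tr_T", "U_tr_T"):
                raise ValueError(f"unknown junction type {jtype!r}")
            if not 0 <= pos < n - 1:
                raise ValueError("junction outside linkage range")
            if pos >= n - self.primer_length:
                raise ValueError("primer site must lie 3' of all junctions")
        self.junctions = sorted(self.junctions)

    @property
    def n_junctions(self) -> int:
        return len(self.junctions)

    @classmethod
    def from_oligo(
        cls,
        spec: OligoSpec,
        primer_length: int,
        product_five_prime_mod: str | None = None,
    ) -> "TemplateModel":
        """Derive a template from a parsed oligo spec (junction types from
        the base 5' of each triazole: ribo-G -> rG_tr_T, else U_tr_T)."""
        junctions = []
        for pos in spec.junctions:
            r = spec.residues[pos]
            jtype = "rG_tr_T" if (r.base == "G" and r.sugar == "ribo") else "U_tr_T"
            junctions.append((pos, jtype))
        return cls(
            residues=spec.sequence,
            junctions=junctions,
            primer_length=primer_length,
            product_five_prime_mod=product_five_prime_mod,
        )


@dataclass(frozen=True)
class ExtensionOutcome:
    """One simulated primer-extension product."""

    stopped_at: int | str  # junction index (0 = first met) or FULL
    artifact: str  # none | correct_stall | minus_A | plus_A
    product_sequence: str  # product 5'->3'
    skipped_A_count: int

    @property
    def full_length(self) -> bool:
        return self.stopped_at == FULL


def _product_sequence(template: TemplateModel, stop_junction: int | str) -> tuple[str, int]:
    """Complement of the traversed template, applying the single-A skip.

    Walks the template 3'->5' from its 3' end; the product is built 5'->3'.
    At a traversed ``U_tr_T`` junction the base 5' of the junction (the U)
    is skipped. Returns (product, skipped_A_count).
    """
    n = len(template.residues)
    # junctions in traversal order = descending template position
    jns = sorted(template.junctions, reverse=True)
    n_traversed = (
        len(jns) if stop_junction == FULL else int(stop_junction)
    )
    # template 5' boundary of the product (exclusive walk down to `stop_pos`)
    stop_pos = -1 if stop_junction == FULL else jns[n_traversed][0]
    skip_positions = {
        pos for pos, jtype in jns[:n_traversed] if jtype == "U_tr_T"
    }
    # walk template 3'->5'; the walk order is already product 5'->3'
    product = "".join(
        revcomp(template.residues[i])
        for i in range(n - 1, stop_pos, -1)
        if i not in skip_positions
    )
    return product, len(skip_positions)


def extend_once(
    template: TemplateModel,
    enzyme: EnzymeProfile,
    rng: np.random.Generator,
) -> ExtensionOutcome:
    """Simulate a single primer extension on ``template``."""
    stop: int | str = FULL
    for j in range(template.n_junctions):
        if rng.random() >= enzyme.read_through_prob:
            stop = j
            break
    if stop == FULL:
        seq, skipped = _product_sequence(template, FULL)
        return ExtensionOutcome(FULL, "none", seq, skipped)
    seq, skipped = _product_sequence(template, stop)
    names = ("correct", "minus_A", "plus_A")
    weights = [enzyme.stall_artifact_weights[k] for k in names]
    artifact = names[rng.choice(3, p=weights)]
    if artifact == "minus_A":
        idx = seq.rfind("A")
        seq = seq[:idx] + seq[idx + 1 :] if idx >= 0 else seq[:-1]
    elif artifact == "plus_A":
        seq = seq + "A"
    label = "correct_stall" if artifact == "correct" else artifact
    return ExtensionOutcome(stop, label, seq, skipped)


@dataclass(frozen=True)
class FractionEstimate:
    fraction: float
    ci_low: float
    ci_high: float
    n: int
    analytic: float


def full_length_fraction(
    template: TemplateModel,
    enzyme: EnzymeProfile,
    n: int = 10_000,
    seed: int = 0,
) -> FractionEstimate:
    """Monte-Carlo estimate of P(full-length) with a binomial 95% CI.

    The analytic value is ``read_through_prob ** n_junctions``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    # equivalent to running extend_once n times and counting FULL outcomes
    draws = rng.random((n, max(template.n_junctions, 1)))
    if template.n_junctions == 0:
        k = n
    else:
        k = int((draws < enzyme.read_through_prob).all(axis=1).sum())
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return FractionEstimate(
        fraction=k / n,
        ci_low=float(lo),
        ci_high=float(hi),
        n=n,
        analytic=enzyme.read_through_prob**template.n_junctions,
    )


@dataclass(frozen=True)
class SpectrumEntry:
    stopped_at: int | str
    artifact: str
    sequence: str
    mass_da: float
    probability: float


def product_spectrum(
    template: TemplateModel,
    enzyme: EnzymeProfile,
    mods: ModificationTable | None = None,
) -> list[SpectrumEntry]:
    """Exact enumeration of all extension products with probabilities.

    Closed form, no sampling: full-length with probability p^J; stall at
    junction j with probability p^j (1-p), split across artifact classes by
    the enzyme's stall weights. Probabilities sum to 1. Masses are average
    Da of the (deoxy) product strand including any primer 5' label.
    """
    p = enzyme.read_through_prob
    J = template.n_junctions
    entries: list[SpectrumEntry] = []

    def mass_of(seq: str, delta: float = 0.0) -> float:
        spec = OligoSpec.from_bases(
            seq, five_prime_mod=template.product_five_prime_mod
        )
        return oligo_mass(spec, mods) + delta

    full_seq, _ = _product_sequence(template, FULL)
    entries.append(
        SpectrumEntry(FULL, "none", full_seq, mass_of(full_seq), p**J)
    )
    for j in range(J):
        stall_p = p**j * (1 - p)
        if stall_p == 0.0:
            continue
        seq, _ = _product_sequence(template, j)
        for artifact, w in enzyme.stall_artifact_weights.items():
            if w == 0.0:
                continue
            if artifact == "correct":
                entries.append(
                    SpectrumEntry(
                        j, "correct_stall", seq, mass_of(seq), stall_p * w
                    )
                )
            elif artifact == "minus_A":
                idx = seq.rfind("A")
                s = seq[:idx] + seq[idx + 1 :] if idx >= 0 else seq[:-1]
                entries.append(
                    SpectrumEntry(
                        j, "minus_A", s, mass_of(seq, -DA_RESIDUE_MASS), stall_p * w
                    )
                )
            else:
                entries.append(
                    SpectrumEntry(
                        j, "plus_A", seq + "A", mass_of(seq, DA_RESIDUE_MASS),
                        stall_p * w,
                    )
                )
    total = sum(e.probability for e in entries)
    assert math.isclose(total, 1.0, abs_tol=1e-12), total
    return entries
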