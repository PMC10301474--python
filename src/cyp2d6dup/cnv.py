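"""Three-probe copy-number interpretation and structure enumeration.

The copy-number assay interrogates the CYP2D6 promoter, intron 6 and exon
9, normalized to a control gene.  Full gene copies contribute to all three
probes; hybrid alleles contribute the characteristic partial signatures
(1,0,0), (1,1,0) and (0,1,1) for the early-crossover CYP2D6–CYP2D7, the
exon-9-crossover CYP2D6–CYP2D7, and the CYP2D7–CYP2D6 hybrid classes
respectively.  Rounded probe triples are decomposed exhaustively into
nonnegative counts of these building blocks; half-integer plateaus across
all probes are the fingerprint of a control-gene variant suppressing one
control copy.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "AMBIGUOUS",
    "CnvConfig",
    "CopyNumberResult",
    "StructuralHypothesis",
    "round_copies",
    "enumerate_structures",
    "consistency_check",
]

AMBIGUOUS = "AMBIGUOUS"
PROBES = ("promoter", "intron6", "exon9")

#: probe contribution of each building block: (promoter, intron6, exon9)
BASIS = {
    "full": (1, 1, 1),
    "hybrid_2D6_2D7_early": (1, 0, 0),
    "hybrid_2D6_2D7_late": (1, 1, 0),
    "hybrid_2D7_2D6": (0, 1, 1),
}


@dataclass
class CnvConfig:
    #: max distance from an integer before an estimate is ambiguous
    ambiguity_halfwidth: float = 0.35
    #: upper end of the assay's validated copy-number range
    validated_max: int = 6


@dataclass
class CopyNumberResult:
    sample_id: str
    estimates: dict[str, float | None]  # per-probe replicate mean
    replicates: dict[str, list[float]]
    rounded: dict[str, int | str | None]  # int, AMBIGUOUS, or None (missing)
    flags: set[str] = field(default_factory=set)

    @property
    def consensus_copies(self) -> int | None:
        """The CYP2D6 copy number when all three probes agree on an
        integer (the plain, hybrid-free configuration); otherwise None."""
        vals = [self.rounded.get(p) for p in PROBES]
        if any(not isinstance(v, int) for v in vals) or len(set(vals)) != 1:
            return None
        return int(vals[0])

    @property
    def triple(self) -> tuple | None:
        vals = tuple(self.rounded.get(p) for p in PROBES)
        return vals if all(isinstance(v, int) for v in vals) else None


@dataclass(frozen=True)
class StructuralHypothesis:
    """Counts of full and hybrid gene copies explaining a probe triple."""

    n_full: int
    n_68like: int = 0
    n_36like: int = 0
    n_13like: int = 0
    exact: bool = True

    @property
    def n_hybrids(self) -> int:
        return self.n_68like + self.n_36like + self.n_13like

    @property
    def probe_triple(self) -> tuple[int, int, int]:
        p = self.n_full + self.n_68like + self.n_36like
        i = self.n_full + self.n_36like + self.n_13like
        e = self.n_full + self.n_13like
        return (p, i, e)


def round_copies(
    replicates: Mapping[str, Sequence[float]] | Mapping[str, float],
    sample_id: str = "",
    config: CnvConfig | None = None,
) -> CopyNumberResult:
    """Round continuous probe estimates to integer copies with flags.

    Each probe's replicate mean rounds to the nearest integer when within
    ``ambiguity_halfwidth``; otherwise it is AMBIGUOUS.  All three probes
    ambiguous at the same half-integer raise ``suspect_control_gene_variant``
    (the signature of a variant under a control-gene probe); any estimate
    above ``validated_max`` raises ``exceeds_validated_range``.
    """
    config = config or CnvConfig()
    estimates: dict[str, float | None] = {}
    reps: dict[str, list[float]] = {}
    rounded: dict[str, int | str | None] = {}
    flags: set[str] = set()
    for probe in PROBES:
        vals = replicates.get(probe)
        if vals is None:
            estimates[probe] = None
            reps[probe] = []
            rounded[probe] = None
            continue
        vals = [float(v) for v in (vals if isinstance(vals, (list, tuple, np.ndarray)) else [vals])]
        if any(v < 0 for v in vals):
            raise ValueError(f"{sample_id}/{probe}: negative copy estimate")
        mean = float(np.mean(vals))
        estimates[probe] = mean
        reps[probe] = vals
        nearest = round(mean)
        if abs(mean - nearest) <= config.ambiguity_halfwidth:
            rounded[probe] = int(nearest)
        else:
            rounded[probe] = AMBIGUOUS
            flags.add("ambiguous_half_copy")
        if mean > config.validated_max:
            flags.add("exceeds_validated_range")
    ambiguous_means = [
        estimates[p] for p in PROBES if rounded[p] == AMBIGUOUS
    ]
    if len(ambiguous_means) == 3:
        halves = {round(m * 2.0) / 2.0 for m in ambiguous_means}
        if len(halves) == 1 and next(iter(halves)) % 1 == 0.5:
            flags.add("suspect_control_gene_variant")
    return CopyNumberResult(
        sample_id=sample_id,
        estimates=estimates,
        replicates=reps,
        rounded=rounded,
        flags=flags,
    )


def enumerate_structures(
    p: int, i: int, e: int, config: CnvConfig | None = None
) -> list[StructuralHypothesis]:
    """All nonnegative-integer decompositions of a rounded probe triple.

    Solves ``(p,i,e) = n_full*(1,1,1) + n_68*(1,0,0) + n_36*(1,1,0) +
    n_13*(0,1,1)`` in closed form over the free hybrid counts.  Sorted by
    parsimony: fewest hybrid copies first, then more full copies.
    """
    config = config or CnvConfig()
    for name, v in (("promoter", p), ("intron6", i), ("exon9", e)):
        if not isinstance(v, (int, np.integer)):
            raise ValueError(f"{name} copies must be an integer, got {v!r}")
        if v < 0 or v > config.validated_max:
            raise ValueError(
                f"{name} copies {v} outside [0, {config.validated_max}]"
            )
    out = []
    # e = n_full + n_13 ; i = n_full + n_36 + n_13 ; p = n_full + n_68 + n_36
    for n_13 in range(e + 1):
        n_full = e - n_13
        n_36 = i - n_full - n_13
        if n_36 < 0:
            continue
        n_68 = p - n_full - n_36
        if n_68 < 0:
            continue
        out.append(
            StructuralHypothesis(
                n_full=n_full, n_68like=n_68, n_36like=n_36, n_13like=n_13
            )
        )
    out.sort(key=lambda h: (h.n_hybrids, -h.n_full))
    return out


def consistency_check(
    hypotheses: Sequence[StructuralHypothesis],
    full_copies: int | None = None,
) -> tuple[list[StructuralHypothesis], bool]:
    """Filter hypotheses against the SNV-derived full-copy total.

    Returns surviving hypotheses and a recommend-sequencing flag, raised
    unless exactly one hypothesis survives.
    """
    survivors = [
        h
        for h in hypotheses
        if full_copies is None or h.n_full == full_copies
    ]
    return survivors, len(survivors) != 1
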