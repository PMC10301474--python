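"""Duplicated-allele inference from endpoint-signal shifts.

The method: on each allelic-discrimination assay, 2-copy samples define
where the heterozygous cluster sits.  A 3-copy heterozygote carries its
two alleles 2:1, so its variant-signal fraction shifts away from the
balanced cluster — toward the variant axis if the variant allele gained a
copy, toward the reference axis otherwise.  Each informative (heterozygous)
assay therefore casts a vote for the duplicated haplotype; unanimous,
confident votes name the duplicated star allele, anything ambiguous defers
to sequencing.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alleles import AlleleRegistry

__all__ = [
    "CallerConfig",
    "ClusterModel",
    "ShiftCall",
    "DuplicationCall",
    "CalibrationError",
    "NoInformativeSnvError",
    "DEFER",
    "fraction_coordinate",
    "fit_clusters",
    "shift_statistic",
    "infer_allele_pair",
    "call_duplicated_allele",
    "evaluate_calls",
    "cohen_kappa",
]

DEFER = "DEFER"
CLASSES = ("hom_ref", "het", "hom_var")

DEFER_REASONS = (
    "too_few_informative_snvs",
    "low_comparator_count",
    "replicate_discordance",
    "weak_shift",
    "conflicting_votes",
    "cnv_inconsistent",
)


class CalibrationError(ValueError):
    """Cluster model cannot be fitted from the comparator samples."""


class NoInformativeSnvError(ValueError):
    """Sample is homozygous at every panel assay; the shift method is blind."""


@dataclass
class CallerConfig:
    z_min: float = 3.0
    min_votes: int = 2
    min_comparators: int = 3
    min_cluster_size: int = 2
    floor_sd: float = 0.005
    zone_halfwidth: float = 0.12


@dataclass
class ClusterModel:
    """Per-assay cluster geometry fitted from 2-copy samples."""

    assay_id: str
    run_id: str
    centers: dict[str, float]
    spreads: dict[str, float]
    counts: dict[str, int]
    zones: dict[str, tuple[float, float]]

    @property
    def het_center(self) -> float:
        return self.centers["het"]

    @property
    def het_spread(self) -> float:
        return self.spreads["het"]

    @property
    def comparator_count(self) -> int:
        return self.counts["het"]


@dataclass
class ShiftCall:
    """Signed shift of one query's replicates relative to the het cluster."""

    assay_id: str
    fractions: tuple[float, float]
    z: float
    direction: str  # toward_ref | toward_var | none
    confident: bool
    comparator_count: int
    discordant: bool = False


@dataclass
class DuplicationCall:
    sample_id: str
    result: str  # star-allele name or DEFER
    allele_pair: tuple[str, str] | None = None
    votes: dict[str, str] = field(default_factory=dict)  # assay_id -> allele
    shift_calls: list[ShiftCall] = field(default_factory=list)
    defer_reasons: list[str] = field(default_factory=list)


def fraction_coordinate(vic: float, fam: float) -> float:
    """Project a (VIC, FAM) endpoint onto the variant-signal fraction."""
    total = vic + fam
    if total <= 0:
        raise ValueError("non-amplification: vic + fam must be positive")
    return fam / total


def fit_clusters(
    points: pd.DataFrame,
    assay_id: str,
    run_id: str = "",
    config: CallerConfig | None = None,
) -> ClusterModel:
    """Fit per-class centers and robust spreads from 2-copy samples.

    ``points`` needs columns ``fraction`` and ``call`` (hom_ref/het/hom_var).
    Centers are medians, spreads MAD-based with a floor; classification
    zones are center ± zone_halfwidth.  The heterozygous class must be
    represented by at least two points.
    """
    config = config or CallerConfig()
    centers: dict[str, float] = {}
    spreads: dict[str, float] = {}
    counts: dict[str, int] = {}
    for cls in CLASSES:
        frac = points.loc[points["call"] == cls, "fraction"].to_numpy(dtype=float)
        if frac.size == 0:
            continue
        if frac.size < 2:
            raise CalibrationError(
                f"{assay_id}: class {cls} has only {frac.size} comparator point"
            )
        med = float(np.median(frac))
        mad = float(np.median(np.abs(frac - med)))
        centers[cls] = med
        spreads[cls] = max(mad * 1.4826, config.floor_sd)
        counts[cls] = int(frac.size)
    if "het" not in centers:
        raise CalibrationError(f"{assay_id}: no heterozygous comparator samples")
    ordered = [centers[c] for c in CLASSES if c in centers]
    if ordered != sorted(ordered):
        raise CalibrationError(f"{assay_id}: cluster centers out of order: {centers}")
    zones = {
        cls: (
            max(0.0, centers[cls] - config.zone_halfwidth),
            min(1.0, centers[cls] + config.zone_halfwidth),
        )
        for cls in centers
    }
    for cls in CLASSES:
        counts.setdefault(cls, 0)
    return ClusterModel(
        assay_id=assay_id,
        run_id=run_id,
        centers=centers,
        spreads=spreads,
        counts=counts,
        zones=zones,
    )


def shift_statistic(
    fractions: Sequence[float],
    model: ClusterModel,
    config: CallerConfig | None = None,
) -> ShiftCall:
    """Score a query heterozygote's displacement from the het cluster.

    z is the mean replicate fraction minus the het center, in units of the
    robust cluster spread.  The call is confident only when both replicates
    fall on the same side and each individually clears ``z_min``.
    """
    config = config or CallerConfig()
    if len(fractions) != 2:
        raise ValueError("expected exactly 2 query replicates")
    f1, f2 = float(fractions[0]), float(fractions[1])
    center, spread = model.het_center, model.het_spread
    z1, z2 = (f1 - center) / spread, (f2 - center) / spread
    z = (z1 + z2) / 2.0
    direction = "none" if z == 0 else ("toward_var" if z > 0 else "toward_ref")
    discordant = z1 * z2 < 0
    confident = (
        not discordant
        and z != 0
        and min(abs(z1), abs(z2)) >= config.z_min
    )
    return ShiftCall(
        assay_id=model.assay_id,
        fractions=(f1, f2),
        z=z,
        direction=direction,
        confident=confident,
        comparator_count=model.comparator_count,
        discordant=discordant,
    )


def infer_allele_pair(
    genotype_calls: Mapping[str, str],
    registry: AlleleRegistry | None = None,
) -> list[tuple[str, str]]:
    """Star-allele pairs consistent with the qualitative genotype calls.

    Considers full (non-hybrid, non-deletion) alleles only: hybrids do not
    change which variants are observed het/hom on the panel beyond the full
    copies, and structural content is resolved separately from CNV data.
    Pairs are sorted by numeric star order; calls of ``undetermined`` or
    ``no_amp`` are ignored as uninformative.
    """
    registry = registry or AlleleRegistry.default()
    full = sorted(registry.full_alleles(), key=lambda a: _star_key(a.name))
    matches = []
    for a, b in itertools.combinations_with_replacement(full, 2):
        ok = True
        for assay_id, call in genotype_calls.items():
            if call not in CLASSES:
                continue
            n_alt = int(assay_id in a.defining_variants) + int(
                assay_id in b.defining_variants
            )
            expected = ("hom_ref", "het", "hom_var")[n_alt]
            if call != expected:
                ok = False
                break
        if ok:
            matches.append((a.name, b.name))
    return matches


def _star_key(name: str) -> tuple:
    body = name.lstrip("*")
    digits = "".join(c for c in body if c.isdigit())
    return (int(digits) if digits else 1 << 30, body)


def call_duplicated_allele(
    sample_id: str,
    genotype_calls: Mapping[str, str],
    shift_calls: Sequence[ShiftCall],
    registry: AlleleRegistry | None = None,
    cnv_total: int | None = None,
    config: CallerConfig | None = None,
) -> DuplicationCall:
    """Vote across informative assays and name the duplicated allele.

    A confident shift toward the variant axis supports duplication of the
    haplotype carrying the variant at that assay, and vice versa.  The call
    is made only when all confident votes agree, at least ``min_votes``
    exist, and the CNV total equals three; otherwise the sample defers to
    sequencing with explicit reasons.
    """
    registry = registry or AlleleRegistry.default()
    config = config or CallerConfig()
    het_assays = [a for a, c in genotype_calls.items() if c == "het"]
    if not het_assays:
        raise NoInformativeSnvError(
            f"{sample_id}: homozygous at every assay; duplication cannot be assessed"
        )
    pairs = infer_allele_pair(genotype_calls, registry)
    if not pairs:
        raise ValueError(
            f"{sample_id}: genotype calls match no star-allele pair on the panel"
        )
    pair = pairs[0]
    a, b = (registry.allele(n) for n in pair)

    shift_by_assay = {sc.assay_id: sc for sc in shift_calls}
    votes: dict[str, str] = {}
    for assay_id in het_assays:
        sc = shift_by_assay.get(assay_id)
        if sc is None or not sc.confident:
            continue
        # exactly one of the pair carries the variant at a het assay
        alt_carrier = a.name if assay_id in a.defining_variants else b.name
        ref_carrier = b.name if alt_carrier == a.name else a.name
        votes[assay_id] = alt_carrier if sc.direction == "toward_var" else ref_carrier

    reasons: list[str] = []
    considered = [shift_by_assay[a_] for a_ in het_assays if a_ in shift_by_assay]
    if considered and all(
        sc.comparator_count < config.min_comparators for sc in considered
    ):
        reasons.append("low_comparator_count")
    targets = set(votes.values())
    if len(targets) > 1:
        reasons.append("conflicting_votes")
    elif len(votes) < config.min_votes:
        if len(het_assays) < config.min_votes:
            reasons.append("too_few_informative_snvs")
        else:
            reasons.append("weak_shift")
        if any(sc.discordant for sc in considered):
            reasons.append("replicate_discordance")
    if cnv_total != 3:
        reasons.append("cnv_inconsistent")

    result = votes and not reasons
    return DuplicationCall(
        sample_id=sample_id,
        result=next(iter(targets)) if result else DEFER,
        allele_pair=pair,
        votes=votes,
        shift_calls=list(shift_calls),
        defer_reasons=reasons,
    )


# ---------------------------------------------------------------------------
# evaluation

def cohen_kappa(a: Sequence[str], b: Sequence[str]) -> float:
    """Cohen's kappa (p_o - p_e)/(1 - p_e) between two raters' labels.

    Identical rating vectors score 1.0 (perfect agreement), covering the
    degenerate case where both raters use a single category.
    """
    if len(a) != len(b) or not a:
        raise ValueError("rating vectors must be nonempty and equal length")
    a, b = list(a), list(b)
    if a == b:
        return 1.0
    n = len(a)
    po = sum(x == y for x, y in zip(a, b)) / n
    cats = set(a) | set(b)
    pe = sum((a.count(c) / n) * (b.count(c) / n) for c in cats)
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1.0 - pe)


@dataclass
class EvaluationReport:
    accuracy: dict[str, float | None]
    n_attempted: dict[str, int]
    n_deferred: dict[str, int]
    kappa_correctness: float | None
    kappa_reporting: float | None


def evaluate_calls(
    calls_by_rater: Mapping[str, Sequence[str]],
    truth: Sequence[str],
) -> EvaluationReport:
    """Accuracy and inter-rater agreement against truth.

    ``calls_by_rater`` maps a rater id to its per-case results (a star
    allele or DEFER).  Accuracy counts only attempted (non-deferred) cases.
    Correctness agreement is the mean pairwise kappa over cases attempted
    by both raters of each pair, labels correct/incorrect; reporting
    agreement uses labels attempted/deferred over all cases.
    """
    if not calls_by_rater:
        raise ValueError("no calls to evaluate")
    truth = list(truth)
    accuracy: dict[str, float | None] = {}
    n_attempted: dict[str, int] = {}
    n_deferred: dict[str, int] = {}
    for rater, calls in calls_by_rater.items():
        if len(calls) != len(truth):
            raise ValueError(f"rater {rater}: call/truth length mismatch")
        attempted = [(c, t) for c, t in zip(calls, truth) if c != DEFER]
        n_attempted[rater] = len(attempted)
        n_deferred[rater] = len(truth) - len(attempted)
        accuracy[rater] = (
            sum(c == t for c, t in attempted) / len(attempted) if attempted else None
        )

    def mean_pairwise(label_fn, restrict_both_attempted: bool) -> float | None:
        raters = list(calls_by_rater)
        if len(raters) < 2:
            return None
        kappas = []
        for r1, r2 in itertools.combinations(raters, 2):
            c1, c2 = calls_by_rater[r1], calls_by_rater[r2]
            idx = range(len(truth))
            if restrict_both_attempted:
                idx = [i for i in idx if c1[i] != DEFER and c2[i] != DEFER]
                if not idx:
                    continue
            v1 = [label_fn(c1[i], truth[i]) for i in idx]
            v2 = [label_fn(c2[i], truth[i]) for i in idx]
            kappas.append(cohen_kappa(v1, v2))
        return float(np.mean(kappas)) if kappas else None

    return EvaluationReport(
        accuracy=accuracy,
        n_attempted=n_attempted,
        n_deferred=n_deferred,
        kappa_correctness=mean_pairwise(
            lambda c, t: "correct" if c == t else "incorrect", True
        ),
        kappa_reporting=mean_pairwise(
            lambda c, t: "deferred" if c == DEFER else "attempted", False
        ),
    )
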