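"""Star-allele definitions, diplotype grammar, activity scores and phenotypes.

CYP2D6 haplotypes are named with star nomenclature (*1, *4, *41, ...).  A
diplotype string pairs two haplotypes with ``/``; a haplotype may carry a
whole-gene multiplication (``*1×2``) or a tandem arrangement of a hybrid
allele with a full gene copy (``*68+*4``).  ``×N`` denotes a multiplication
of unknown extent (at least two copies).

The activity score of a diplotype is the sum of per-allele activity values
over all gene copies; the metabolizer phenotype follows from consensus
cutpoints (0 poor / ≤1 intermediate / ≤2.25 normal / >2.25 ultrarapid).
"""
from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

_DEFAULT_REGISTRY = None

__all__ = [
    "VariantAssay",
    "StarAllele",
    "HaplotypeTerm",
    "Diplotype",
    "ScoreBound",
    "AlleleRegistry",
    "DiplotypeParseError",
    "parse_diplotype",
    "canonical_string",
    "activity_score",
    "phenotype_from_score",
    "diplotypes_equal",
    "allele_counts_by_assay",
]

#: gene segments covered by each structural class, in genomic order.
#: "early" = promoter through exon 1, "mid" = intron 1 through intron 8,
#: "late" = exon 9 region.  Hybrid alleles amplify SNV assays only within
#: their CYP2D6-derived segment.
SEGMENTS_BY_CLASS = {
    "full": frozenset({"early", "mid", "late"}),
    "hybrid_2D6_2D7_early": frozenset({"early"}),
    "hybrid_2D6_2D7_late": frozenset({"early", "mid"}),
    "hybrid_2D7_2D6": frozenset({"mid", "late"}),
    "deletion": frozenset(),
}

PROBE_VECTOR_BY_CLASS = {
    "full": (1, 1, 1),
    "hybrid_2D6_2D7_early": (1, 0, 0),
    "hybrid_2D6_2D7_late": (1, 1, 0),
    "hybrid_2D7_2D6": (0, 1, 1),
    "deletion": (0, 0, 0),
}

PHENOTYPES = ("Poor", "Intermediate", "Normal", "Ultrarapid", "Indeterminate")


@dataclass(frozen=True)
class VariantAssay:
    """One allelic-discrimination assay on the genotyping panel."""

    assay_id: str
    legacy_name: str
    ref_allele: str
    alt_allele: str
    segment: str
    panel_index: int

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.assay_id}: ref and alt alleles must differ")


@dataclass(frozen=True)
class StarAllele:
    """A star-named haplotype restricted to the assay panel.

    ``defining_variants`` holds the assay ids at which the allele carries
    the variant base.  ``activity_value`` is the CPIC/DPWG per-copy value
    (None = uncurated, scores involving it become indeterminate).
    """

    name: str
    defining_variants: frozenset[str]
    activity_value: float | None
    structure_class: str
    probe_vector: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.structure_class not in SEGMENTS_BY_CLASS:
            raise ValueError(f"unknown structure class {self.structure_class!r}")
        expected = PROBE_VECTOR_BY_CLASS[self.structure_class]
        if tuple(self.probe_vector) != expected:
            raise ValueError(
                f"{self.name}: probe vector {self.probe_vector} inconsistent "
                f"with structure class {self.structure_class} (expected {expected})"
            )
        if self.structure_class != "full" and self.activity_value not in (0, 0.0):
            raise ValueError(f"{self.name}: hybrid/deletion alleles must have activity 0")

    @property
    def is_hybrid(self) -> bool:
        return self.structure_class.startswith("hybrid")

    @property
    def segments(self) -> frozenset[str]:
        return SEGMENTS_BY_CLASS[self.structure_class]


@dataclass(frozen=True)
class HaplotypeTerm:
    """One allele within a haplotype, with its copy count.

    ``copies=None`` encodes the ``×N`` notation: an unknown multiplicity of
    at least two.  A tandem arrangement such as ``*68+*4`` is an ordered
    tuple of terms (see :class:`Diplotype`).
    """

    allele: str
    copies: int | None = 1

    def __post_init__(self) -> None:
        if self.copies is not None and self.copies < 1:
            raise ValueError("copies must be >= 1")

    def __str__(self) -> str:
        if self.copies is None:
            return f"{self.allele}×N"
        if self.copies > 1:
            return f"{self.allele}×{self.copies}"
        return self.allele


Haplotype = tuple[HaplotypeTerm, ...]


@dataclass
class Diplotype:
    """A pair of haplotypes, each an ordered tuple of terms."""

    hap1: Haplotype
    hap2: Haplotype
    alternatives: list[str] = field(default_factory=list)

    @property
    def haplotypes(self) -> tuple[Haplotype, Haplotype]:
        return (self.hap1, self.hap2)

    def alleles(self) -> list[str]:
        return [t.allele for h in self.haplotypes for t in h]


@dataclass(frozen=True)
class ScoreBound:
    """An open lower bound on the activity score, printed ``>k``."""

    lower: float

    def __str__(self) -> str:
        return f">{_fmt(self.lower)}"


def _fmt(v: float) -> str:
    return format(v, "g")


class DiplotypeParseError(ValueError):
    """Raised for malformed diplotype strings; names the offending token."""


class AlleleRegistry:
    """The assay panel plus the star-allele definition table."""

    def __init__(self, panel: Iterable[VariantAssay], alleles: Iterable[StarAllele]):
        self.panel: dict[str, VariantAssay] = {}
        for a in panel:
            if a.assay_id in self.panel:
                raise ValueError(f"duplicate assay id {a.assay_id}")
            self.panel[a.assay_id] = a
        self.alleles: dict[str, StarAllele] = {a.name: a for a in alleles}
        for star in self.alleles.values():
            unknown = star.defining_variants - self.panel.keys()
            if unknown:
                raise ValueError(f"{star.name}: variants not on panel: {sorted(unknown)}")

    # -- construction -----------------------------------------------------
    @classmethod
    def from_files(cls, panel_path, alleles_path) -> "AlleleRegistry":
        panel_df = pd.read_csv(panel_path, sep="\t")
        panel = [
            VariantAssay(
                assay_id=r.assay_id,
                legacy_name=str(r.legacy_name),
                ref_allele=r.ref_allele,
                alt_allele=r.alt_allele,
                segment=r.segment,
                panel_index=int(r.panel_index),
            )
            for r in panel_df.itertuples()
        ]
        with open(alleles_path) as fh:
            spec = json.load(fh)
        alleles = [
            StarAllele(
                name=rec["name"],
                defining_variants=frozenset(rec["defining_variants"]),
                activity_value=rec["activity_value"],
                structure_class=rec["structure_class"],
                probe_vector=tuple(rec["probe_vector"]),
            )
            for rec in spec["alleles"]
        ]
        return cls(panel, alleles)

    @classmethod
    def default(cls) -> "AlleleRegistry":
        global _DEFAULT_REGISTRY
        if _DEFAULT_REGISTRY is None:
            data = resources.files("cyp2d6dup.data")
            with resources.as_file(data / "panel.tsv") as p, resources.as_file(
                data / "star_alleles.json"
            ) as a:
                _DEFAULT_REGISTRY = cls.from_files(p, a)
        return _DEFAULT_REGISTRY

    # -- lookups ----------------------------------------------------------
    def allele(self, name: str) -> StarAllele:
        try:
            return self.alleles[name]
        except KeyError:
            raise KeyError(f"unknown star allele {name!r}") from None

    def full_alleles(self) -> list[StarAllele]:
        return [a for a in self.alleles.values() if a.structure_class == "full"]

    def hybrid_for_class(self, structure_class: str) -> StarAllele:
        for a in self.alleles.values():
            if a.structure_class == structure_class:
                return a
        raise KeyError(f"no allele with structure class {structure_class}")

    def covers(self, allele_name: str, assay_id: str) -> bool:
        """Whether the allele's CYP2D6-derived segment spans the assay."""
        return self.panel[assay_id].segment in self.allele(allele_name).segments

    def carries_alt(self, allele_name: str, assay_id: str) -> bool:
        return assay_id in self.allele(allele_name).defining_variants

    def activity_table(self) -> dict[str, float | None]:
        return {name: a.activity_value for name, a in self.alleles.items()}


# ---------------------------------------------------------------------------
# diplotype grammar

_TERM_RE = re.compile(r"^\*?(?P<name>[0-9]+[A-Za-z]*)(?:[×xX](?P<mult>[0-9]+|N))?$")


def _parse_haplotype(text: str) -> Haplotype:
    terms = []
    for token in text.split("+"):
        token = token.strip()
        m = _TERM_RE.match(token)
        if not m or not token:
            raise DiplotypeParseError(f"malformed haplotype token {token!r}")
        mult = m.group("mult")
        if mult is None:
            copies: int | None = 1
        elif mult == "N":
            copies = None
        else:
            copies = int(mult)
            if copies < 1:
                raise DiplotypeParseError(f"malformed haplotype token {token!r}")
        terms.append(HaplotypeTerm(allele=f"*{m.group('name')}", copies=copies))
    return tuple(terms)


def parse_diplotype(text: str) -> Diplotype:
    """Parse a star-nomenclature diplotype string.

    Accepts ``×`` or ``x`` for multiplication and bare allele names inside
    tandems (``*68+4`` normalizes to ``*68+*4``).  An ``or``-joined pair of
    strings parses as a diplotype with alternatives (unresolvable phasing).
    """
    text = text.strip()
    if " or " in text:
        first, *rest = [part.strip() for part in text.split(" or ")]
        d = parse_diplotype(first)
        d.alternatives = [canonical_string(d, sort=False)] + [
            canonical_string(parse_diplotype(p), sort=False) for p in rest
        ]
        return d
    parts = text.split("/")
    if len(parts) != 2:
        raise DiplotypeParseError(
            f"expected exactly one '/' separator in {text!r}"
        )
    return Diplotype(hap1=_parse_haplotype(parts[0]), hap2=_parse_haplotype(parts[1]))


def _hap_string(hap: Haplotype) -> str:
    return "+".join(str(t) for t in hap)


def _star_sort_key(hap: Haplotype) -> tuple:
    name = hap[0].allele.lstrip("*")
    m = re.match(r"([0-9]+)([A-Za-z]*)", name)
    return (int(m.group(1)), m.group(2)) if m else (1 << 30, name)


def _hap_score(hap: Haplotype, table: Mapping[str, float | None]) -> float:
    total = 0.0
    for t in hap:
        v = table.get(t.allele)
        if v is None:
            return -1.0  # sorts last; only used for display ordering
        total += v * (t.copies if t.copies is not None else 2)
    return total


def canonical_string(
    d: Diplotype, table: Mapping[str, float | None] | None = None, sort: bool = True
) -> str:
    """Render a diplotype canonically: higher-activity haplotype first,
    ties broken by numeric star order."""
    if table is None:
        table = AlleleRegistry.default().activity_table()
    haps = list(d.haplotypes)
    if sort:
        haps.sort(key=lambda h: (-_hap_score(h, table), _star_sort_key(h)))
    return "/".join(_hap_string(h) for h in haps)


def diplotypes_equal(a: Diplotype | str, b: Diplotype | str) -> bool:
    """Order-insensitive diplotype equality (haplotype multisets)."""
    if isinstance(a, str):
        a = parse_diplotype(a)
    if isinstance(b, str):
        b = parse_diplotype(b)
    ms = lambda d: sorted(_hap_string(h) for h in d.haplotypes)
    return ms(a) == ms(b)


# ---------------------------------------------------------------------------
# scoring

def activity_score(
    d: Diplotype, table: Mapping[str, float | None] | None = None
) -> float | ScoreBound | None:
    """Sum per-copy activity values over both haplotypes.

    Returns None ("indeterminate") when any allele has an uncurated value.
    A ``×N`` term with positive activity yields an open bound: the score
    with N substituted by 3, reported as ``>k``.
    """
    if table is None:
        table = AlleleRegistry.default().activity_table()
    total = 0.0
    open_bound = False
    for hap in d.haplotypes:
        for t in hap:
            if t.allele not in table:
                raise KeyError(f"allele {t.allele} missing from activity table")
            v = table[t.allele]
            if v is None:
                return None
            if t.copies is None:
                total += v * 3
                if v > 0:
                    open_bound = True
            else:
                total += v * t.copies
    return ScoreBound(total) if open_bound else total


def phenotype_from_score(s: float | ScoreBound | None) -> str:
    """Translate an activity score to the metabolizer phenotype.

    Consensus cutpoints: 0 → Poor; (0, 1] → Intermediate; (1, 2.25] →
    Normal; > 2.25 → Ultrarapid.  Open bounds resolve only when the whole
    admissible range lies in one band.
    """
    if s is None:
        return "Indeterminate"
    if isinstance(s, ScoreBound):
        return "Ultrarapid" if s.lower >= 2.25 else "Indeterminate"
    if s < 0:
        raise ValueError("activity score cannot be negative")
    if s == 0:
        return "Poor"
    if s <= 1:
        return "Intermediate"
    if s <= 2.25:
        return "Normal"
    return "Ultrarapid"


def format_score(s: float | ScoreBound | None) -> str:
    if s is None:
        return "Indeterminate"
    if isinstance(s, ScoreBound):
        return str(s)
    return _fmt(s)


# ---------------------------------------------------------------------------
# genotype arithmetic used by the simulator and the resolver

def allele_counts_by_assay(
    d: Diplotype,
    registry: AlleleRegistry | None = None,
    expand_unknown: int = 2,
) -> dict[str, tuple[int, int]]:
    """Per-assay (n_ref, n_alt) counts implied by a diplotype.

    Counts include only gene copies whose CYP2D6-derived segment spans the
    assay (hybrid alleles amplify a subset of the panel).  ``×N`` terms are
    expanded to ``expand_unknown`` copies.
    """
    registry = registry or AlleleRegistry.default()
    counts: dict[str, tuple[int, int]] = {}
    for assay_id in registry.panel:
        n_ref = n_alt = 0
        for hap in d.haplotypes:
            for t in hap:
                copies = t.copies if t.copies is not None else expand_unknown
                if not registry.covers(t.allele, assay_id):
                    continue
                if registry.carries_alt(t.allele, assay_id):
                    n_alt += copies
                else:
                    n_ref += copies
        counts[assay_id] = (n_ref, n_alt)
    return counts


def probe_copies(d: Diplotype, registry: AlleleRegistry | None = None,
                 expand_unknown: int = 2) -> tuple[int, int, int]:
    """True (promoter, intron 6, exon 9) probe copies implied by a diplotype."""
    registry = registry or AlleleRegistry.default()
    tot = [0, 0, 0]
    for hap in d.haplotypes:
        for t in hap:
            copies = t.copies if t.copies is not None else expand_unknown
            vec = registry.allele(t.allele).probe_vector
            for i in range(3):
                tot[i] += vec[i] * copies
    return tuple(tot)


def genotype_call(n_ref: int, n_alt: int) -> str:
    """Qualitative genotype label implied by true allele counts."""
    if n_ref + n_alt == 0:
        return "no_amp"
    if n_alt == 0:
        return "hom_ref"
    if n_ref == 0:
        return "hom_var"
    return "het"
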