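"""Final diplotype assembly and clinical-style case reports.

Combines the base allele pair from genotyping, the duplication vote, and
the CNV structural decomposition into a star-nomenclature diplotype with
activity score and phenotype.  Ambiguity routes to reflex sequencing;
unphaseable extra copies are reported as an alternatives pair (both
phasings always share the same activity score, so the phenotype is
unaffected).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import alleles as am
from .alleles import AlleleRegistry, HaplotypeTerm, Diplotype
from .caller import (
    DEFER,
    CallerConfig,
    DuplicationCall,
    NoInformativeSnvError,
    call_duplicated_allele,
    fit_clusters,
    fraction_coordinate,
    shift_statistic,
)
from .cnv import CnvConfig, CopyNumberResult, consistency_check, enumerate_structures, round_copies
from .cnv import StructuralHypothesis

__all__ = ["CaseReport", "resolve", "render_report", "parse_report", "run_pipeline"]

STATUSES = ("reported", "reflex_sequencing", "indeterminate")

#: canonical tandem partner of each hybrid allele (the full allele it
#: arises with in the common duplication structures)
HYBRID_PARTNERS = {"*68": "*4", "*36": "*10"}

HYBRID_CLASS_ALLELE = {
    "hybrid_2D6_2D7_early": "*68",
    "hybrid_2D6_2D7_late": "*36",
    "hybrid_2D7_2D6": "*13",
}


@dataclass
class CaseReport:
    sample_id: str
    status: str
    diplotype: str | None = None
    alternatives: list[str] = field(default_factory=list)
    activity_score: str | None = None
    phenotype: str | None = None
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == "reflex_sequencing" and not self.evidence.get("defer_reasons"):
            raise ValueError("reflex_sequencing requires at least one defer reason")


def _term_strings(terms: Sequence[HaplotypeTerm]) -> am.Haplotype:
    return tuple(terms)


def _score_and_phenotype(d: Diplotype, registry: AlleleRegistry):
    score = am.activity_score(d, registry.activity_table())
    return score, am.phenotype_from_score(score)


def resolve(
    sample_id: str,
    allele_pair: tuple[str, str] | None,
    dup_call: DuplicationCall | None,
    cnv_result: CopyNumberResult | None,
    structures: Sequence[StructuralHypothesis] | None = None,
    registry: AlleleRegistry | None = None,
    extra_alleles: Sequence[str] | None = None,
) -> CaseReport:
    """Assemble the final case report for one sample.

    ``structures`` is the consistency-filtered hypothesis list; when it
    names hybrid copies they are attached in tandem notation to the
    haplotype of their canonical full partner (falling back to the
    duplicated haplotype).  ``extra_alleles`` supplies alleles identified
    by follow-up sequencing for >3-copy cases whose phasing the panel
    cannot resolve; these are reported as an alternatives pair.
    """
    registry = registry or AlleleRegistry.default()
    table = registry.activity_table()
    evidence: dict = {}
    if cnv_result is not None:
        evidence["cnv_rounded"] = {p: cnv_result.rounded.get(p) for p in cnv_result.rounded}
        evidence["cnv_flags"] = sorted(cnv_result.flags)
    if dup_call is not None:
        evidence["votes"] = dict(dup_call.votes)
        evidence["z"] = {
            sc.assay_id: round(sc.z, 3) for sc in dup_call.shift_calls
        }
        evidence["defer_reasons"] = list(dup_call.defer_reasons)
        evidence["allele_pair"] = list(dup_call.allele_pair or ())

    # no informative SNV: the duplication cannot be assigned in-house
    if dup_call is None:
        evidence.setdefault("note", "no informative heterozygous assay")
        return CaseReport(sample_id=sample_id, status="indeterminate", evidence=evidence)

    if dup_call.result == DEFER:
        return CaseReport(
            sample_id=sample_id, status="reflex_sequencing", evidence=evidence
        )

    if allele_pair is None:
        allele_pair = dup_call.allele_pair
    duplicated = dup_call.result
    if duplicated not in allele_pair:
        raise ValueError(
            f"{sample_id}: duplicated allele {duplicated} absent from genotype {allele_pair}"
        )
    other = allele_pair[1] if allele_pair[0] == duplicated else allele_pair[0]

    structure = None
    if structures:
        if len(structures) > 1:
            return CaseReport(
                sample_id=sample_id,
                status="reflex_sequencing",
                evidence={**evidence, "defer_reasons": ["cnv_inconsistent"],
                          "note": "multiple structural hypotheses"},
            )
        structure = structures[0]

    dup_hap: list[HaplotypeTerm] = [HaplotypeTerm(duplicated, 2)]
    other_hap: list[HaplotypeTerm] = [HaplotypeTerm(other, 1)]

    extra = list(extra_alleles or [])
    if structure is not None:
        n_extra_full = structure.n_full - 3
        if n_extra_full != len(extra):
            if n_extra_full > 0:
                # extra full copies the panel cannot attribute
                return CaseReport(
                    sample_id=sample_id,
                    status="reflex_sequencing",
                    evidence={**evidence, "defer_reasons": ["cnv_inconsistent"],
                              "note": f"{n_extra_full} unattributed full copies"},
                )
            if n_extra_full < 0:
                raise ValueError(
                    f"{sample_id}: structure has fewer full copies than the "
                    f"3 implied by a duplication call"
                )
        # attach hybrid copies in tandem with their canonical partner
        for cls, count in (
            ("hybrid_2D6_2D7_early", structure.n_68like),
            ("hybrid_2D6_2D7_late", structure.n_36like),
            ("hybrid_2D7_2D6", structure.n_13like),
        ):
            if not count:
                continue
            hybrid = HYBRID_CLASS_ALLELE[cls]
            partner = HYBRID_PARTNERS.get(hybrid)
            host = (
                other_hap
                if partner is not None and partner == other
                else dup_hap
                if partner is None or partner == duplicated
                else other_hap
            )
            host.insert(0, HaplotypeTerm(hybrid, count))

    if extra:
        # unphaseable extra copies: both placements reported
        alt_a = Diplotype(
            hap1=_term_strings(dup_hap),
            hap2=_term_strings([HaplotypeTerm(x, 1) for x in extra] + other_hap),
        )
        alt_b = Diplotype(
            hap1=_term_strings(dup_hap + [HaplotypeTerm(x, 1) for x in extra]),
            hap2=_term_strings(other_hap),
        )
        score_a, ph_a = _score_and_phenotype(alt_a, registry)
        score_b, ph_b = _score_and_phenotype(alt_b, registry)
        if am.format_score(score_a) != am.format_score(score_b):
            raise ValueError(
                f"{sample_id}: alternative phasings disagree on activity score"
            )
        alts = [
            am.canonical_string(alt_a, table, sort=False),
            am.canonical_string(alt_b, table, sort=False),
        ]
        return CaseReport(
            sample_id=sample_id,
            status="reported",
            diplotype=" or ".join(alts),
            alternatives=alts,
            activity_score=am.format_score(score_a),
            phenotype=ph_a,
            evidence=evidence,
        )

    d = Diplotype(hap1=_term_strings(dup_hap), hap2=_term_strings(other_hap))
    score, phenotype = _score_and_phenotype(d, registry)
    return CaseReport(
        sample_id=sample_id,
        status="reported",
        diplotype=am.canonical_string(d, table),
        activity_score=am.format_score(score),
        phenotype=phenotype,
        evidence=evidence,
    )


# ---------------------------------------------------------------------------
# serialization

def render_report(report: CaseReport, fmt: str = "json") -> str:
    """Serialize a case report deterministically as JSON or text."""
    if fmt == "json":
        payload = dict(
            sample_id=report.sample_id,
            status=report.status,
            diplotype=report.diplotype,
            alternatives=report.alternatives,
            activity_score=report.activity_score,
            phenotype=report.phenotype,
            evidence=report.evidence,
        )
        return json.dumps(payload, indent=2, sort_keys=True)
    if fmt == "text":
        lines = [
            f"Sample:         {report.sample_id}",
            f"Status:         {report.status}",
        ]
        if report.diplotype:
            lines.append(f"Diplotype:      {report.diplotype}")
            lines.append(f"Activity score: {report.activity_score}")
            lines.append(f"Phenotype:      {report.phenotype}")
        reasons = report.evidence.get("defer_reasons", [])
        if reasons:
            lines.append("Defer reasons:  " + ", ".join(dict.fromkeys(reasons)))
        votes = report.evidence.get("votes")
        if votes:
            lines.append("Votes:")
            for assay, allele in sorted(votes.items()):
                z = report.evidence.get("z", {}).get(assay)
                lines.append(f"  {assay}: {allele} (z={z})")
        flags = report.evidence.get("cnv_flags")
        if flags:
            lines.append("CNV flags:      " + ", ".join(flags))
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown report format {fmt!r}")


def parse_report(text: str) -> CaseReport:
    """Inverse of :func:`render_report` for the JSON format."""
    payload = json.loads(text)
    return CaseReport(
        sample_id=payload["sample_id"],
        status=payload["status"],
        diplotype=payload.get("diplotype"),
        alternatives=payload.get("alternatives") or [],
        activity_score=payload.get("activity_score"),
        phenotype=payload.get("phenotype"),
        evidence=payload.get("evidence") or {},
    )


# ---------------------------------------------------------------------------
# end-to-end pipeline

def run_pipeline(
    genotyper: pd.DataFrame,
    cnv: pd.DataFrame,
    registry: AlleleRegistry | None = None,
    caller_config: CallerConfig | None = None,
    cnv_config: CnvConfig | None = None,
) -> list[CaseReport]:
    """Run the full duplication-resolution pipeline on one run's tables.

    Fits per-assay cluster models from control and concurrent 2-copy
    samples, scores every query heterozygote's shift, aggregates votes,
    interprets the three-probe CNV result, and assembles case reports.
    """
    registry = registry or AlleleRegistry.default()
    caller_config = caller_config or CallerConfig()
    cnv_config = cnv_config or CnvConfig()

    df = genotyper.copy()
    df["fraction"] = [
        fraction_coordinate(v, f) for v, f in zip(df["vic"], df["fam"])
    ]

    reports: list[CaseReport] = []
    for run_id, run_df in df.groupby("run_id", sort=False):
        comparators = run_df[run_df["role"].isin(["control", "concurrent"])]
        models = {}
        for assay_id, adf in comparators.groupby("assay_id", sort=False):
            models[assay_id] = fit_clusters(
                adf, assay_id, run_id=str(run_id), config=caller_config
            )
        queries = run_df[run_df["role"] == "query"]
        for sample_id, sdf in queries.groupby("sample_id", sort=True):
            calls = {
                assay_id: adf["call"].iloc[0]
                for assay_id, adf in sdf.groupby("assay_id", sort=False)
            }
            shift_calls = []
            for assay_id, adf in sdf.groupby("assay_id", sort=False):
                if calls[assay_id] != "het" or assay_id not in models:
                    continue
                fracs = adf.sort_values("replicate")["fraction"].tolist()
                if len(fracs) != 2:
                    continue
                shift_calls.append(
                    shift_statistic(fracs, models[assay_id], caller_config)
                )

            cnv_sdf = cnv[cnv["sample_id"] == sample_id]
            cnv_result = round_copies(
                {
                    probe: pdf["copy_estimate"].tolist()
                    for probe, pdf in cnv_sdf.groupby("probe", sort=False)
                },
                sample_id=sample_id,
                config=cnv_config,
            )
            total = cnv_result.consensus_copies

            try:
                dup_call = call_duplicated_allele(
                    sample_id,
                    calls,
                    shift_calls,
                    registry=registry,
                    cnv_total=total,
                    config=caller_config,
                )
            except NoInformativeSnvError:
                reports.append(
                    resolve(sample_id, None, None, cnv_result, registry=registry)
                )
                continue

            # 2-copy samples are ordinary genotyping results, no duplication
            if total == 2 and dup_call.result == DEFER and not (
                cnv_result.flags & {"suspect_control_gene_variant"}
            ):
                pair = dup_call.allele_pair
                d = am.parse_diplotype(f"{pair[0]}/{pair[1]}")
                score = am.activity_score(d, registry.activity_table())
                reports.append(
                    CaseReport(
                        sample_id=sample_id,
                        status="reported",
                        diplotype=am.canonical_string(d, registry.activity_table()),
                        activity_score=am.format_score(score),
                        phenotype=am.phenotype_from_score(score),
                        evidence={"cnv_rounded": dict(cnv_result.rounded),
                                  "cnv_flags": sorted(cnv_result.flags),
                                  "note": "two copies, no duplication"},
                    )
                )
                continue

            structures = None
            if (
                dup_call.result != DEFER
                and cnv_result.triple is not None
                and "exceeds_validated_range" not in cnv_result.flags
            ):
                hyps = enumerate_structures(*cnv_result.triple, config=cnv_config)
                structures, _ = consistency_check(hyps, full_copies=3)
            reports.append(
                resolve(
                    sample_id,
                    dup_call.allele_pair,
                    dup_call,
                    cnv_result,
                    structures=structures,
                    registry=registry,
                )
            )
    return reports
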