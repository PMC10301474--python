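"""Seeded generative model of endpoint-genotyping signals and CNV estimates.

The generator emulates one real-time PCR run: control samples with known
genotypes (2 copies), concurrent 2-copy patient samples, and query samples
whose gene copy number may differ from two.  A sample's position on an
allelic-discrimination plot is summarized by the variant-signal fraction
``fam/(vic+fam)``; a full-gene duplication moves a heterozygote from 1:1
to 2:1 (fraction 1/3 or 2/3).  Noise is applied in the fraction coordinate
and mapped back to (VIC, FAM) through a radial gain, with per-run
multiplicative lot scale factors on each channel.

Copy-number estimates for the three probes (promoter, intron 6, exon 9)
are the true copies times ``2/(1 + eta_ctrl)`` plus Gaussian noise, where
``eta_ctrl`` is the relative amplification of the affected control-gene
copy: a variant under a control-gene (RPPH1) probe suppresses one of its
two copies and inflates every estimate (at ``eta_ctrl=0.6`` a 2-copy
sample reads 2.5 at all probes).  Allelic dropout is modeled the same way
on the SNV side: the efficiency ``eta`` scales one allele's effective copy
count at a chosen assay.
"""
from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .alleles import (
    AlleleRegistry,
    allele_counts_by_assay,
    genotype_call,
    parse_diplotype,
    probe_copies,
)

__all__ = [
    "SimConfig",
    "TruthRecord",
    "SimulatedRun",
    "CohortFixture",
    "allele_fraction",
    "simulate_run",
    "make_study_cohort",
    "load_study_fixture",
]

PROBES = ("promoter", "intron6", "exon9")


def allele_fraction(n_ref: int, n_alt: int) -> float:
    """Variant-signal fraction implied by allele copy counts."""
    if n_ref < 0 or n_alt < 0:
        raise ValueError("allele counts must be nonnegative")
    if n_ref + n_alt == 0:
        raise ValueError("no gene copies at locus (n_ref + n_alt == 0)")
    return n_alt / (n_ref + n_alt)


@dataclass
class SimConfig:
    """Parameters of the generative model.

    sigma_f
        Gaussian noise sd in the fraction coordinate (per replicate).
    lot_sd
        Lognormal sd of the per-run VIC/FAM lot scale factors.
    amp_sd
        Lognormal sd of the per-point radial amplitude.
    dropout
        Map assay_id -> (allele, eta): effective copies of ``allele``
        ("ref" or "alt") at that assay are scaled by eta in query samples.
    eta_ctrl
        Relative amplification of the variant-bearing control-gene copy,
        applied to samples whose truth record is interference-flagged.
    """

    seed: int = 0
    run_id: str = "R1"
    n_concurrent_het: int = 6
    n_controls_per_class: int = 4
    f_hom_ref: float = 0.08
    f_hom_var: float = 0.92
    radial_gain: float = 2000.0
    sigma_f: float = 0.02
    lot_sd: float = 0.1
    amp_sd: float = 0.1
    sigma_c: float = 0.1
    dropout: dict[str, tuple[str, float]] = dc_field(default_factory=dict)
    eta_ctrl: float = 0.6

    def __post_init__(self) -> None:
        if not (0 <= self.sigma_f < 0.15):
            raise ValueError("sigma_f must be in [0, 0.15)")
        if not (0 <= self.eta_ctrl <= 1):
            raise ValueError("eta_ctrl must be in [0, 1]")
        for assay, (which, eta) in self.dropout.items():
            if which not in ("ref", "alt"):
                raise ValueError(f"dropout[{assay}]: allele must be 'ref' or 'alt'")
            if not (0 <= eta <= 1):
                raise ValueError(f"dropout[{assay}]: eta must be in [0, 1]")
        if not (0 < self.f_hom_ref < 0.5 < self.f_hom_var < 1):
            raise ValueError("cluster geometry must satisfy f_hom_ref < 0.5 < f_hom_var")


@dataclass
class TruthRecord:
    """Simulation ground truth for one sample."""

    sample_id: str
    diplotype: str
    duplicated: str | None
    assay_counts: dict[str, tuple[int, int]]
    probe_copies: tuple[int, int, int]
    interference: bool = False
    dataset: str = ""
    table_n_het: int | None = None

    def __post_init__(self) -> None:
        for assay, (n_ref, n_alt) in self.assay_counts.items():
            if n_ref < 0 or n_alt < 0:
                raise ValueError(f"{self.sample_id}/{assay}: negative allele count")

    @property
    def n_informative(self) -> int:
        """Number of heterozygous (informative) assays."""
        return sum(1 for r, a in self.assay_counts.values() if r > 0 and a > 0)


@dataclass
class SimulatedRun:
    """Output tables of one simulated run (genotyper-export dialect)."""

    genotyper: pd.DataFrame
    cnv: pd.DataFrame
    truth: pd.DataFrame


def truth_record(
    sample_id: str,
    diplotype: str,
    registry: AlleleRegistry | None = None,
    duplicated: str | None = None,
    interference: bool = False,
    dataset: str = "",
    table_n_het: int | None = None,
    probe_triple: tuple[int, int, int] | None = None,
    expand_unknown: int = 2,
) -> TruthRecord:
    """Build a TruthRecord from a diplotype string.

    ``duplicated`` defaults to the allele of the first ×k (k ≥ 2) term.
    """
    registry = registry or AlleleRegistry.default()
    d = parse_diplotype(diplotype)
    if duplicated is None:
        for hap in d.haplotypes:
            for t in hap:
                if t.copies is None or t.copies >= 2:
                    duplicated = t.allele
                    break
            if duplicated:
                break
    counts = allele_counts_by_assay(d, registry, expand_unknown=expand_unknown)
    triple = probe_triple or probe_copies(d, registry, expand_unknown=expand_unknown)
    return TruthRecord(
        sample_id=sample_id,
        diplotype=diplotype,
        duplicated=duplicated,
        assay_counts=counts,
        probe_copies=tuple(triple),
        interference=interference,
        dataset=dataset,
        table_n_het=table_n_het,
    )


def simulate_run(
    cohort: Sequence[TruthRecord],
    cfg: SimConfig,
    registry: AlleleRegistry | None = None,
) -> SimulatedRun:
    """Simulate one run: controls, concurrent 2-copy samples, and queries.

    Deterministic under a fixed config (same seed → identical tables).
    """
    if not cohort:
        raise ValueError("cohort must be nonempty")
    registry = registry or AlleleRegistry.default()
    assays = list(registry.panel)
    for rec in cohort:
        unknown = set(rec.assay_counts) - set(assays)
        if unknown:
            raise ValueError(
                f"{rec.sample_id}: assays absent from panel: {sorted(unknown)}"
            )

    rng = np.random.default_rng(cfg.seed)
    lot_vic = float(np.exp(rng.normal(0.0, cfg.lot_sd))) if cfg.lot_sd else 1.0
    lot_fam = float(np.exp(rng.normal(0.0, cfg.lot_sd))) if cfg.lot_sd else 1.0

    geno_rows: list[dict] = []

    def emit(sample_id: str, assay_id: str, f_true: float, call: str, role: str) -> None:
        for replicate in (1, 2):
            f_obs = f_true + (rng.normal(0.0, cfg.sigma_f) if cfg.sigma_f else 0.0)
            f_obs = min(max(f_obs, 0.0), 1.0)
            amp = cfg.radial_gain * (
                float(np.exp(rng.normal(0.0, cfg.amp_sd))) if cfg.amp_sd else 1.0
            )
            vic = max(0.0, amp * (1.0 - f_obs) * lot_vic)
            fam = max(0.0, amp * f_obs * lot_fam)
            geno_rows.append(
                dict(
                    sample_id=sample_id,
                    assay_id=assay_id,
                    replicate=replicate,
                    vic=round(vic, 3),
                    fam=round(fam, 3),
                    call=call,
                    role=role,
                    run_id=cfg.run_id,
                )
            )

    # 2-copy comparator samples: controls from prior lots with known genotype
    # per class, then patient samples run concurrently (all balanced 2-copy).
    # residual background fluorescence keeps homozygous clusters off the
    # plot axes, hence the f_hom_ref / f_hom_var geometry parameters
    class_fraction = {"hom_ref": cfg.f_hom_ref, "het": 0.5, "hom_var": cfg.f_hom_var}
    for cls in ("hom_ref", "het", "hom_var"):
        f = class_fraction[cls]
        for i in range(cfg.n_controls_per_class):
            sid = f"CTRL_{cls}_{i + 1}"
            for assay_id in assays:
                emit(sid, assay_id, f, cls, "control")
    for i in range(cfg.n_concurrent_het):
        sid = f"CONC_{i + 1}"
        for assay_id in assays:
            emit(sid, assay_id, 0.5, "het", "concurrent")

    cnv_rows: list[dict] = []
    for rec in cohort:
        for assay_id in assays:
            n_ref, n_alt = rec.assay_counts.get(assay_id, (0, 0))
            if n_ref + n_alt == 0:
                continue  # no CYP2D6-derived template at this assay
            eff_ref, eff_alt = float(n_ref), float(n_alt)
            if assay_id in cfg.dropout:
                which, eta = cfg.dropout[assay_id]
                if which == "ref":
                    eff_ref *= eta
                else:
                    eff_alt *= eta
            if eff_ref + eff_alt == 0:
                continue  # full dropout of the only amplifiable allele
            f = eff_alt / (eff_ref + eff_alt)
            emit(rec.sample_id, assay_id, f, genotype_call(n_ref, n_alt), "query")
        factor = 2.0 / (1.0 + cfg.eta_ctrl) if rec.interference else 1.0
        for probe, true_c in zip(PROBES, rec.probe_copies):
            for replicate in (1, 2):
                est = true_c * factor + (
                    rng.normal(0.0, cfg.sigma_c) if cfg.sigma_c else 0.0
                )
                cnv_rows.append(
                    dict(
                        sample_id=rec.sample_id,
                        probe=probe,
                        replicate=replicate,
                        copy_estimate=round(max(0.0, est), 4),
                    )
                )

    truth_df = pd.DataFrame(
        [
            dict(
                sample_id=r.sample_id,
                diplotype=r.diplotype,
                duplicated=r.duplicated or "",
                promoter=r.probe_copies[0],
                intron6=r.probe_copies[1],
                exon9=r.probe_copies[2],
                interference=int(r.interference),
                dataset=r.dataset,
            )
            for r in cohort
        ]
    )
    return SimulatedRun(
        genotyper=pd.DataFrame(geno_rows),
        cnv=pd.DataFrame(cnv_rows),
        truth=truth_df,
    )


# ---------------------------------------------------------------------------
# packaged study cohort

@dataclass
class CohortFixture:
    """The packaged study cohort, split by dataset."""

    main: list[TruthRecord]
    exploratory: list[TruthRecord]
    ambiguous: list[TruthRecord]

    @property
    def all(self) -> list[TruthRecord]:
        return self.main + self.exploratory + self.ambiguous


def load_study_fixture() -> pd.DataFrame:
    """The packaged cohort composition table (one row per genotype)."""
    with resources.as_file(
        resources.files("cyp2d6dup.data") / "study_cohort.tsv"
    ) as path:
        return pd.read_csv(path, sep="\t", dtype={"activity_score": str})


def make_study_cohort(
    seed: int = 0, registry: AlleleRegistry | None = None
) -> CohortFixture:
    """Expand the packaged cohort table into per-case truth records.

    The main dataset holds 73 three-copy cases, the exploratory dataset 11
    hybrid/multicopy cases (×N expanded to four copies), and the ambiguous
    dataset 3 two-copy cases flagged for control-gene interference.  The
    seed only shuffles sample-id assignment within each dataset.
    """
    registry = registry or AlleleRegistry.default()
    df = load_study_fixture()
    rng = np.random.default_rng(seed)
    out: dict[str, list[TruthRecord]] = {"main": [], "exploratory": [], "ambiguous": []}
    prefixes = {"main": "M", "exploratory": "X", "ambiguous": "A"}
    for dataset, sub in df.groupby("dataset", sort=False):
        recs: list[TruthRecord] = []
        for row in sub.itertuples():
            for _ in range(int(row.n_cases)):
                recs.append(
                    truth_record(
                        sample_id="",
                        diplotype=str(row.genotype),
                        registry=registry,
                        interference=(dataset == "ambiguous"),
                        dataset=dataset,
                        table_n_het=int(row.n_het_snvs),
                        probe_triple=(
                            int(row.cnv_promoter),
                            int(row.cnv_intron6),
                            int(row.cnv_exon9),
                        ),
                        expand_unknown=4,
                    )
                )
        order = rng.permutation(len(recs))
        for i, j in enumerate(order):
            recs[j].sample_id = f"{prefixes[dataset]}{i + 1:03d}"
        out[dataset] = [recs[j] for j in np.argsort([r.sample_id for r in recs])]
    return CohortFixture(**out)
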