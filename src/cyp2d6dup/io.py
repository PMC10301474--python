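"""Readers and writers for the plain-TSV table dialects.

Dialects are defined by this package (documented headers below) rather
than mimicking proprietary instrument exports; adapt real exports by
renaming columns.

genotyper export: sample_id, assay_id, replicate, vic, fam, call, role, run_id
CNV table:       sample_id, probe, replicate, copy_estimate
truth table:     sample_id, diplotype, duplicated, promoter, intron6,
                 exon9, interference, dataset
"""
from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd

from .caller import CallerConfig
from .cnv import CnvConfig, PROBES
from .simulate import SimConfig, SimulatedRun

__all__ = [
    "SchemaError",
    "PipelineConfig",
    "read_genotyper_export",
    "read_cnv_table",
    "read_truth_table",
    "write_run",
    "load_config",
]

log = logging.getLogger("cyp2d6dup")

GENOTYPER_COLUMNS = ["sample_id", "assay_id", "replicate", "vic", "fam", "call", "role", "run_id"]
CNV_COLUMNS = ["sample_id", "probe", "replicate", "copy_estimate"]

CALL_SYNONYMS = {
    "hom_ref": "hom_ref", "ref/ref": "hom_ref", "0/0": "hom_ref",
    "het": "het", "ref/alt": "het", "0/1": "het",
    "hom_var": "hom_var", "alt/alt": "hom_var", "1/1": "hom_var",
    "no_amp": "no_amp",
}

ROLES = {"control", "concurrent", "query"}


class SchemaError(ValueError):
    """A table fails structural validation (named column or row)."""


def _read_strict_tsv(path, columns: list[str]) -> pd.DataFrame:
    """Read a TSV rejecting ragged rows rather than best-effort padding."""
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file") from None
        missing = [c for c in columns if c not in header]
        if missing:
            raise SchemaError(f"{path}: missing column(s) {missing}")
        width = len(header)
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != width:
                raise SchemaError(
                    f"{path}:{lineno}: ragged row ({len(row)} fields, expected {width})"
                )
            rows.append(row)
    return pd.DataFrame(rows, columns=header)


def read_genotyper_export(path) -> pd.DataFrame:
    """Read a genotyper-export TSV into typed records (row order kept)."""
    df = _read_strict_tsv(path, GENOTYPER_COLUMNS)
    for col in ("vic", "fam"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            lineno = int(bad.idxmax()) + 2
            raise SchemaError(
                f"{path}:{lineno}: non-numeric {col} value {df.loc[bad.idxmax(), col]!r}"
            )
        df[col] = converted.astype(float)
    df["replicate"] = pd.to_numeric(df["replicate"], errors="raise").astype(int)
    df["call"] = [
        CALL_SYNONYMS.get(str(c).strip().lower(), "undetermined") for c in df["call"]
    ]
    unknown_roles = set(df["role"]) - ROLES
    if unknown_roles:
        raise SchemaError(f"{path}: unknown role(s) {sorted(unknown_roles)}")
    return df


def read_cnv_table(path) -> pd.DataFrame:
    """Read a CNV TSV; both replicates are retained per sample and probe."""
    df = _read_strict_tsv(path, CNV_COLUMNS)
    unknown = set(df["probe"]) - set(PROBES)
    if unknown:
        raise SchemaError(f"{path}: unknown probe label(s) {sorted(unknown)}")
    df["copy_estimate"] = pd.to_numeric(df["copy_estimate"], errors="raise").astype(float)
    if (df["copy_estimate"] < 0).any():
        raise SchemaError(f"{path}: negative copy estimate")
    df["replicate"] = pd.to_numeric(df["replicate"], errors="raise").astype(int)
    for sample_id, sdf in df.groupby("sample_id"):
        missing = set(PROBES) - set(sdf["probe"])
        if missing:
            log.warning(
                "sample %s missing probe(s) %s; marked unresolved downstream",
                sample_id, sorted(missing),
            )
    return df


def read_truth_table(path) -> pd.DataFrame:
    return _read_strict_tsv(path, ["sample_id", "diplotype", "duplicated"])


def write_run(run: SimulatedRun, outdir) -> dict[str, Path]:
    """Write a simulated run's three tables; byte-deterministic."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotyper": outdir / "genotyper.tsv",
        "cnv": outdir / "cnv.tsv",
        "truth": outdir / "truth.tsv",
    }
    run.genotyper.to_csv(paths["genotyper"], sep="\t", index=False)
    run.cnv.to_csv(paths["cnv"], sep="\t", index=False)
    run.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# configuration

@dataclass
class PipelineConfig:
    """Bundle of tunables; JSON files override defaults, CLI flags override both."""

    caller: CallerConfig = field(default_factory=CallerConfig)
    cnv: CnvConfig = field(default_factory=CnvConfig)
    sim: SimConfig = field(default_factory=SimConfig)


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    cfg = PipelineConfig()
    layers = []
    if path is not None:
        with open(path) as fh:
            layers.append(json.load(fh))
    if overrides:
        layers.append(overrides)
    for layer in layers:
        for section, values in layer.items():
            target = getattr(cfg, section, None)
            if target is None:
                raise SchemaError(f"unknown config section {section!r}")
            known = {f.name for f in fields(target)}
            for key, val in values.items():
                if key not in known:
                    raise SchemaError(f"unknown config key {section}.{key}")
                if key == "dropout":
                    val = {k: tuple(v) for k, v in val.items()}
                setattr(target, key, val)
    return cfg
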