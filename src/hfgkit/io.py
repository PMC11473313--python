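"""Interchange-format readers/writers, pipeline configuration, pipeline driver.

Everything tabular is UTF-8, tab-delimited, LF-terminated, with a
mandatory header row.  Frequencies are carried exactly in machine
columns and additionally rendered rounded (percentages to two decimals,
folds to one) in the report tables, mirroring how such results are
printed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .annotation import read_annotation
from .association import FusionAssociationModel, FusionAssociationResults
from .cohort import DEFAULT_MIN_COUNT, CohortDesign
from .fusions import DEFAULT_GAP_THRESHOLD
from .scanner import DEFAULT_ANCHOR, DEFAULT_FLANK

log = logging.getLogger("hfgkit")

REQUIRED_CALL_COLUMNS = ["run_id", "patient_id", "cohort", "fusion_id"]
OPTIONAL_CALL_COLUMNS = [
    "five_prime_gene",
    "three_prime_gene",
    "five_prime_chrom",
    "five_prime_pos",
    "three_prime_chrom",
    "three_prime_pos",
    "junction_sequence",
]


class TableFormatError(ValueError):
    """Raised when an input table is structurally invalid."""


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a TSV with header, no index, LF line endings."""
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def read_fusion_calls(
    path: str | Path,
    coordinate_system: str = "0-based",
    strict: bool = False,
) -> pd.DataFrame:
    """Read and validate a per-run fusion call table.

    Required columns: run_id, patient_id, cohort, fusion_id.  Breakpoint
    positions, when present, are normalized to 0-based (pass
    ``coordinate_system="1-based"`` for 1-based input).  Malformed rows
    (unparseable positions) are logged with their line number and
    dropped; in ``strict`` mode they abort the read instead.
    """
    if coordinate_system not in ("0-based", "1-based"):
        raise TableFormatError(
            f"coordinate_system must be '0-based' or '1-based', got {coordinate_system!r}"
        )
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_CALL_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s): {missing}")
    pos_cols = [c for c in ("five_prime_pos", "three_prime_pos") if c in df.columns]
    bad_rows: list[int] = []
    for col in pos_cols:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & (df[col] != "")
        bad_rows.extend(df.index[bad].tolist())
        df[col] = parsed
    if bad_rows:
        bad_lines = sorted({i + 2 for i in bad_rows})  # +2: header + 1-based
        msg = f"{path}: unparseable breakpoint position at line(s) {bad_lines}"
        if strict:
            raise TableFormatError(msg)
        log.warning("%s; dropping %d row(s)", msg, len(set(bad_rows)))
        df = df.drop(index=sorted(set(bad_rows))).reset_index(drop=True)
    if coordinate_system == "1-based":
        for col in pos_cols:
            df[col] = df[col] - 1
    for col in pos_cols:
        df[col] = df[col].astype("Int64")
    return df


def read_cohort_design(path: str | Path) -> CohortDesign:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return CohortDesign.from_dataframe(df)


# -- report rendering --------------------------------------------------


def render_association_table(table: pd.DataFrame) -> pd.DataFrame:
    """Report view of the association table.

    Adds percentage columns rounded to two decimals and a fold rounded
    to one decimal alongside the exact machine columns.
    """
    out = table.copy()
    out["case_pct"] = (100 * out["case_freq"]).round(2)
    out["control_pct"] = (100 * out["control_freq"]).round(2)
    out["fold_rounded"] = out["fold"].round(1)
    return out


def write_results(
    results: FusionAssociationResults, out_dir: str | Path
) -> dict[str, Path]:
    """Write the standard result bundle for a fitted association model.

    Emits classification + association TSV, the unfiltered recurrence
    TSV, case/control presence matrices over the tested fusions, and a
    plain-text summary.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["association"] = out_dir / "association.tsv"
    write_table(render_association_table(results.table), paths["association"])
    paths["recurrence"] = out_dir / "recurrence.tsv"
    write_table(results.recurrence, paths["recurrence"])
    for cohort in ("case", "control"):
        key = f"matrix_{cohort}"
        paths[key] = out_dir / f"presence_matrix_{cohort}.tsv"
        mat = results.presence_matrix(cohort=cohort)
        mat.to_csv(paths[key], sep="\t", index_label="patient_id", lineterminator="\n")
    paths["summary"] = out_dir / "summary.txt"
    paths["summary"].write_text(results.summary() + "\n")
    return paths


# -- configuration and the end-to-end driver ---------------------------


@dataclass
class PipelineConfig:
    """All tunable constants of the comparison pipeline, with defaults.

    Defaults: alpha 0.01 (critical |z| 2.576), patient-recurrence
    filter 5, readthrough gap threshold 200,000 bp, somatic
    per-individual fusion rate 3.6e-2 with coincidence count 5, probe
    anchor 10 and flank 30, zero-control fold pseudo-count 1.
    """

    alpha: float = 0.01
    min_count: int = DEFAULT_MIN_COUNT
    gap_threshold_bp: int = DEFAULT_GAP_THRESHOLD
    somatic_rate: float = 3.6e-2
    somatic_k: int = 5
    probe_anchor: int = DEFAULT_ANCHOR
    probe_flank: int = DEFAULT_FLANK
    zero_pseudocount: int = 1
    seed: int = 0
    calls: Optional[str] = None
    design: Optional[str] = None
    annotation: Optional[str] = None
    out_dir: str = "hfgkit_out"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise TableFormatError(f"{path}: unknown config key(s): {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def log_effective(self) -> None:
        log.info("effective config (hash %s):", self.config_hash())
        for f in dataclasses.fields(self):
            log.info("  %s = %r", f.name, getattr(self, f.name))


def run_pipeline(config: PipelineConfig) -> tuple[FusionAssociationResults, dict[str, Path]]:
    """classify + collapse + recurrence + associate + report, from files.

    Deterministic given config and inputs.  Errors from a stage are
    re-raised with the stage name attached.
    """
    config.log_effective()
    stage = "read inputs"
    try:
        if config.calls is None or config.design is None:
            raise TableFormatError("config must set 'calls' and 'design' paths")
        calls = read_fusion_calls(config.calls)
        design = read_cohort_design(config.design)
        annotation = read_annotation(config.annotation) if config.annotation else None
        log.info("read %d call rows, %d runs", len(calls), len(design.run_to_patient))

        stage = "associate"
        model = FusionAssociationModel(
            calls,
            design,
            annotation,
            alpha=config.alpha,
            min_count=config.min_count,
            gap_threshold=config.gap_threshold_bp,
            zero_pseudocount=config.zero_pseudocount,
        )
        results = model.fit()
        log.info(
            "tested %d fusions, %d significant",
            len(results.table),
            int(results.table["significant"].sum()),
        )

        stage = "write results"
        paths = write_results(results, config.out_dir)
        return results, paths
    except Exception as exc:
        raise PipelineError(stage, exc) from exc


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {cause}")
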