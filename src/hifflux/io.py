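"""CSV readers/writers with schema validation, and the run manifest.

All tables are RFC-4180 CSV with a header row, UTF-8, locale-independent
decimal points.  Validation errors name the offending rows and columns.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable

import pandas as pd

from .finemap import ALLELE_CODES, CandidateInterval, FinemapError, GenotypeTable, MarkerMap
from .flux import FluxError

MARKER_MAP_COLUMNS = ["marker", "chrom", "pos_bp"]
GENOTYPE_FIRST_COLUMN = "line_id"
PHENOTYPE_COLUMNS = ["line_id", "allele", "replicate", "value"]
ORGAN_SAMPLE_COLUMNS = ["plant_id", "genotype", "experiment", "organ", "dw_mg", "n_pct", "a15n_pct"]
SEGREGATION_COLUMNS = ["line_id", "start_bp", "end_bp", "verdict", "p_value", "method"]
SENESCENCE_COLUMNS = ["plant_id", "genotype", "das", "n_yellow", "n_total_at_bolting"]
CHLOROPHYLL_COLUMNS = ["plant_id", "leaf_rank", "das", "chl_index", "flower_bud_das"]


class SchemaError(ValueError):
    """A table does not match its declared schema."""


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_marker_map(path) -> MarkerMap:
    df = pd.read_csv(path)
    _require_columns(df, MARKER_MAP_COLUMNS, path)
    try:
        return MarkerMap(
            (str(r.marker), str(r.chrom), int(r.pos_bp)) for r in df.itertuples()
        )
    except FinemapError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def read_genotypes(path, marker_map: MarkerMap) -> GenotypeTable:
    df = pd.read_csv(path, dtype=str)
    if df.columns[0] != GENOTYPE_FIRST_COLUMN:
        raise SchemaError(f"{path}: first column must be {GENOTYPE_FIRST_COLUMN!r}")
    expected = list(marker_map.marker_ids)
    got = list(df.columns[1:])
    if got != expected:
        raise SchemaError(
            f"{path}: marker columns do not match the map "
            f"(expected {expected[:3]}..., got {got[:3]}...)"
        )
    for col in got:
        bad = df.index[~df[col].isin(ALLELE_CODES)]
        if len(bad):
            row = int(bad[0]) + 2  # header + 1-based
            raise SchemaError(
                f"{path}: invalid allele code {df.loc[bad[0], col]!r} "
                f"at row {row}, column {col!r}"
            )
    try:
        return GenotypeTable(
            ((str(r[0]), "".join(r[1:])) for r in df.itertuples(index=False)), marker_map
        )
    except FinemapError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_genotypes(table: GenotypeTable, path) -> None:
    df = pd.DataFrame(
        [list(row) for row in table.calls],
        columns=list(table.marker_map.marker_ids),
    )
    df.insert(0, GENOTYPE_FIRST_COLUMN, list(table.line_ids))
    df.to_csv(path, index=False)


def write_marker_map(marker_map: MarkerMap, path) -> None:
    pd.DataFrame(marker_map.markers, columns=MARKER_MAP_COLUMNS).to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, PHENOTYPE_COLUMNS, path)
    bad = df.index[~df["allele"].isin({"A", "B"})]
    if len(bad):
        raise SchemaError(f"{path}: allele must be A or B (row {int(bad[0]) + 2})")
    return df


def read_organ_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ORGAN_SAMPLE_COLUMNS, path)
    neg = df.index[df["dw_mg"] <= 0]
    if len(neg):
        raise SchemaError(f"{path}: non-positive dry weight at row {int(neg[0]) + 2}")
    for col in ("n_pct", "a15n_pct"):
        bad = df.index[(df[col] < 0) | (df[col] > 100)]
        if len(bad):
            raise SchemaError(f"{path}: {col} outside [0, 100] at row {int(bad[0]) + 2}")
    dup = df.duplicated(subset=["plant_id", "experiment", "organ"])
    if dup.any():
        rows = [int(i) + 2 for i in df.index[dup]]
        raise SchemaError(f"{path}: duplicate (plant, organ) sample at row(s) {rows}")
    return df


def read_segregation_calls(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, SEGREGATION_COLUMNS, path)
    bad = df.index[~df["verdict"].isin({"segregating", "non_segregating", "inconclusive"})]
    if len(bad):
        raise SchemaError(f"{path}: unknown verdict at row {int(bad[0]) + 2}")
    return df


def read_senescence_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, SENESCENCE_COLUMNS, path)
    bad = df.index[df["n_yellow"] > df["n_total_at_bolting"]]
    if len(bad):
        raise SchemaError(
            f"{path}: n_yellow exceeds n_total_at_bolting at row {int(bad[0]) + 2}"
        )
    return df


def read_chlorophyll(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, CHLOROPHYLL_COLUMNS, path)
    return df


def parse_region(text: str) -> tuple[str, int, int]:
    """Parse ``chrom:start-end`` with 1-based closed bp bounds."""
    try:
        chrom, span = text.split(":")
        start, end = span.split("-")
        start_bp, end_bp = int(start), int(end)
    except ValueError as exc:
        raise SchemaError(f"malformed region {text!r}; expected chrom:start-end") from exc
    if start_bp >= end_bp:
        raise SchemaError(f"region {text!r}: start must be < end")
    return chrom, start_bp, end_bp


def intervals_to_json(intervals: Iterable[CandidateInterval]) -> list[dict]:
    out = []
    for iv in intervals:
        d = asdict(iv)
        d["width_bp"] = iv.width_bp
        out.append(d)
    return out


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path,
    command: str,
    inputs: dict,
    parameters: dict,
    outputs: Iterable[str | Path],
    seed: int | None = None,
) -> dict:
    """Record everything needed to reproduce a run: inputs, parameters, seed,
    package version and output checksums."""
    from . import __version__

    manifest = {
        "command": command,
        "version": __version__,
        "seed": seed,
        "inputs": {
            str(p): file_sha256(p) for p in inputs.values() if p and Path(p).exists()
        },
        "parameters": parameters,
        "outputs": {str(p): file_sha256(p) for p in outputs},
        "timestamp": pd.Timestamp.now().isoformat(),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
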