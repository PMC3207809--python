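"""Readers and writers for the pipeline's tab-separated artifacts.

Matrix files are TSV with features as rows: the first column is the
feature id, the header row holds sample ids. Clinical tables carry
``sample_id``, ``time_months`` and ``event`` columns plus optional
annotations. Lines starting with ``#`` are metadata comments (every
writer embeds the run's config hash there) and are skipped on read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .integration import FeatureMatrix
from .survival import SurvivalOutcome

__all__ = [
    "ClinicalTable",
    "read_feature_matrix",
    "write_feature_matrix",
    "read_clinical",
    "write_clinical",
    "read_pairing",
    "write_pairing",
    "write_signature",
    "read_signature",
    "write_report",
]

VALID_OUTCOME_TYPES = {"PFS", "OS", "PFI"}
VALID_PLATINUM = {"sensitive", "resistant", "unknown"}


@dataclass
class ClinicalTable:
    """Validated clinical annotations with right-censored follow-up."""

    table: pd.DataFrame

    @property
    def sample_ids(self) -> list:
        return list(self.table["sample_id"])

    def outcome(self) -> SurvivalOutcome:
        return SurvivalOutcome(
            self.table["time_months"].to_numpy(float),
            self.table["event"].to_numpy(int),
        )

    def check_platinum_consistency(self) -> pd.Series:
        """Flag rows labelled resistant whose platinum-free interval is
        not under six months (resistance requires PFI < 6 months with
        progression)."""
        t = self.table
        if "platinum_status" not in t.columns or "outcome_type" not in t.columns:
            return pd.Series(False, index=t.index)
        return (
            (t["platinum_status"] == "resistant")
            & (t["outcome_type"] == "PFI")
            & ((t["time_months"] >= 6) | (t["event"] != 1))
        )


def _comment_header(config_hash: str | None) -> str:
    return f"# omicox config_hash={config_hash}\n" if config_hash else ""


def write_feature_matrix(fm: FeatureMatrix, path, config_hash: str | None = None) -> None:
    """Write features-as-rows TSV (first column feature id, header of
    sample ids)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_comment_header(config_hash))
        fm.values.T.rename_axis("feature_id").to_csv(fh, sep="\t")


def read_feature_matrix(path, platform: str) -> FeatureMatrix:
    """Read a features-as-rows TSV into a :class:`FeatureMatrix`.

    Ragged rows, duplicate feature ids, empty files and non-numeric cells
    are errors reporting the offending line or id.
    """
    path = Path(path)
    lines = [
        (i + 1, ln) for i, ln in enumerate(path.read_text().splitlines())
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise ValueError(f"{path}: empty matrix file")
    header = lines[0][1].split("\t")
    if len(header) < 2:
        raise ValueError(f"{path}: header must list at least one sample id")
    samples = header[1:]
    ncol = len(header)
    ids, rows = [], []
    for lineno, ln in lines[1:]:
        parts = ln.split("\t")
        if len(parts) != ncol:
            raise ValueError(
                f"{path}:{lineno}: ragged row ({len(parts)} fields, expected {ncol})"
            )
        ids.append(parts[0])
        row = []
        for j, cell in enumerate(parts[1:], start=2):
            if cell in ("", "NA", "NaN", "nan"):
                row.append(np.nan)
                continue
            try:
                row.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric cell {cell!r} in column {j}"
                ) from None
        rows.append(row)
    seen = set()
    for fid in ids:
        if fid in seen:
            raise ValueError(f"{path}: duplicate feature id {fid!r}")
        seen.add(fid)
    values = pd.DataFrame(rows, index=ids, columns=samples).T
    return FeatureMatrix(values=values, platform=platform)


def write_clinical(clinical: ClinicalTable, path, config_hash: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_comment_header(config_hash))
        clinical.table.to_csv(fh, sep="\t", index=False)


def read_clinical(path) -> ClinicalTable:
    """Read and validate a clinical TSV (sample_id, time_months, event,
    optional outcome_type / platinum_status)."""
    table = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample_id", "time_months", "event"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    if table.empty:
        raise ValueError(f"{path}: empty clinical table")
    if table["sample_id"].duplicated().any():
        dups = table.loc[table["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample ids {dups[:5]}")
    if not np.issubdtype(table["time_months"].dtype, np.number) or (
        table["time_months"] <= 0
    ).any() or table["time_months"].isna().any():
        raise ValueError(f"{path}: time_months must be positive numbers")
    if not set(pd.unique(table["event"])) <= {0, 1}:
        raise ValueError(f"{path}: event must be 0 or 1")
    if "outcome_type" in table.columns:
        bad = set(table["outcome_type"].dropna()) - VALID_OUTCOME_TYPES
        if bad:
            raise ValueError(f"{path}: unknown outcome_type values {sorted(bad)}")
    if "platinum_status" in table.columns:
        bad = set(table["platinum_status"].dropna()) - VALID_PLATINUM
        if bad:
            raise ValueError(f"{path}: unknown platinum_status values {sorted(bad)}")
    return ClinicalTable(table=table)


def write_pairing(pairing: pd.DataFrame, path, config_hash: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_comment_header(config_hash))
        pairing.to_csv(fh, sep="\t", index=False)


def read_pairing(path) -> pd.DataFrame:
    pairing = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"mirna", "gene"} <= set(pairing.columns):
        raise ValueError(f"{path}: pairing table needs 'mirna' and 'gene' columns")
    return pairing


def write_signature(signature, path, config_hash: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_comment_header(config_hash))
        signature.to_frame().to_csv(fh, sep="\t", index=False)


def read_signature(path):
    from .prognosis import Signature

    df = pd.read_csv(path, sep="\t", comment="#")
    features = [
        (p, f) if isinstance(p, str) and p else f
        for p, f in zip(df["platform"].fillna(""), df["feature"])
    ]
    return Signature(
        features=tuple(features),
        betas=df["beta"].to_numpy(float),
        means=df["mean"].to_numpy(float),
        scales=df["scale"].to_numpy(float),
    )


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    return obj


def write_report(report, path, config: dict | None = None,
                 config_hash: str | None = None) -> None:
    """Serialize a PredictionReport (plus the materialized run config) as
    JSON."""
    payload = _jsonify(report.to_dict())
    if config is not None:
        payload["config"] = _jsonify(config)
    if config_hash is not None:
        payload["config_hash"] = config_hash
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
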