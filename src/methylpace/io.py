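"""CSV interchange formats shared by the CLI and library.

All files are RFC-4180 CSV, UTF-8; beta matrices may be gzipped (detected by
a ``.gz`` suffix). Writers emit a leading ``#``-comment line with the
toolkit version; readers skip comment lines. Validation errors carry the
offending row/column coordinates.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import SchemaError
from .longitudinal import LongBiomarkerPanel, PaceOfAgingScores

logger = logging.getLogger(__name__)

_HEADER_COMMENT = f"# methylpace v{__version__}\n"


def _open_write(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "wt")
    return open(path, "w")


def read_beta_matrix(path) -> pd.DataFrame:
    """Read a probes x samples beta matrix (first column ``probe_id``)."""
    df = pd.read_csv(path, comment="#", dtype={0: str}, float_precision="round_trip")
    if df.columns[0] != "probe_id":
        raise SchemaError(
            f"{path}: first column must be 'probe_id', found {df.columns[0]!r}"
        )
    df = df.set_index("probe_id")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique()[:5]
        raise SchemaError(f"{path}: duplicate probe ids, e.g. {list(dups)}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad_parse = vals.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "") \
            & ~df[col].astype(str).str.upper().isin(["NA", "NAN", "NULL"])
        if bad_parse.any():
            row = int(np.flatnonzero(bad_parse)[0])
            raise SchemaError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} at data row "
                f"{row + 1}, sample column {col!r}"
            )
        out_of_range = vals.notna() & ((vals < 0) | (vals > 1))
        if out_of_range.any():
            row = int(np.flatnonzero(out_of_range)[0])
            raise SchemaError(
                f"{path}: beta value {vals.iloc[row]} outside [0, 1] at data row "
                f"{row + 1}, sample column {col!r}"
            )
        df[col] = vals
    return df


def write_beta_matrix(m: pd.DataFrame, path) -> None:
    with _open_write(path) as fh:
        fh.write(_HEADER_COMMENT)
        m.to_csv(fh, index_label="probe_id", lineterminator="\n")


def read_long_panel(panel_path, meta_path) -> LongBiomarkerPanel:
    """Read a long-format biomarker panel and its metadata."""
    data = pd.read_csv(panel_path, comment="#", dtype={"subject_id": str, "biomarker_id": str})
    need = {"subject_id", "visit_age", "biomarker_id", "value"}
    if not need <= set(data.columns):
        raise SchemaError(f"{panel_path}: needs columns {sorted(need)}")
    meta = read_biomarker_meta(meta_path)
    panel = LongBiomarkerPanel(data[list(need)], meta)
    panel.validate()
    return panel


def read_biomarker_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, comment="#", dtype={"biomarker_id": str})
    need = {"biomarker_id", "orientation"}
    if not need <= set(meta.columns):
        missing = sorted(need - set(meta.columns))
        raise SchemaError(f"{path}: missing column(s) {missing}")
    if "name" not in meta.columns:
        meta["name"] = meta["biomarker_id"]
    meta = meta.set_index("biomarker_id")
    if not meta["orientation"].isin([1, -1]).all():
        raise SchemaError(f"{path}: orientation must be +1 or -1")
    return meta


def write_long_panel(panel: LongBiomarkerPanel, panel_path, meta_path) -> None:
    with _open_write(panel_path) as fh:
        fh.write(_HEADER_COMMENT)
        panel.data.to_csv(fh, index=False, lineterminator="\n")
    with _open_write(meta_path) as fh:
        fh.write(_HEADER_COMMENT)
        panel.meta.to_csv(fh, index_label="biomarker_id", lineterminator="\n")


def write_pace_scores(scores: PaceOfAgingScores, path) -> None:
    out = pd.DataFrame(
        {
            "subject_id": scores.pace.index,
            "pace": scores.pace.to_numpy(),
            "raw_composite": scores.raw_composite.reindex(scores.pace.index).to_numpy(),
            "n_biomarkers_observed": scores.n_biomarkers,
        }
    )
    with _open_write(path) as fh:
        fh.write(_HEADER_COMMENT)
        out.to_csv(fh, index=False, lineterminator="\n")


def read_pace_scores(path) -> pd.Series:
    df = pd.read_csv(path, comment="#", dtype={"subject_id": str}, float_precision="round_trip")
    if not {"subject_id", "pace"} <= set(df.columns):
        raise SchemaError(f"{path}: needs columns subject_id, pace")
    return pd.Series(
        df["pace"].to_numpy(float), index=pd.Index(df["subject_id"]), name="pace"
    )


def write_reliability(table: pd.DataFrame, path) -> None:
    with _open_write(path) as fh:
        fh.write(_HEADER_COMMENT)
        table.to_csv(fh, index_label="probe_id", lineterminator="\n")


def read_reliability(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", dtype={"probe_id": str}, float_precision="round_trip")
    if "probe_id" not in df.columns or "icc" not in df.columns:
        raise SchemaError(f"{path}: needs columns probe_id, icc")
    return df.set_index("probe_id")


def write_score_result(result, path) -> None:
    out = result.diagnostics.copy()
    out.insert(0, "score", result.scores)
    with _open_write(path) as fh:
        fh.write(_HEADER_COMMENT)
        out.to_csv(fh, index_label="sample_id", lineterminator="\n")
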