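"""CSV dialects: state-data tables, uptake summaries, Woods-plot export.

The state-data dialect is one row per peptide x state x exposure x
replicate with columns

    protein, start, end, sequence, max_uptake, state, exposure_s,
    bio_rep, tech_rep, centroid_da

where ``exposure_s`` holds seconds (0 = undeuterated reference) or the
literal token ``FD`` for fully-deuterated control rows.  Files are
plain UTF-8 comma-separated with a mandatory header; lines starting
with ``#`` are metadata comments (version, seed, config hash) and are
skipped on read.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ParseError
from .uptake import PEPTIDE_KEY

logger = logging.getLogger(__name__)

STATE_COLUMNS = [
    "protein",
    "start",
    "end",
    "sequence",
    "max_uptake",
    "state",
    "exposure_s",
    "bio_rep",
    "tech_rep",
    "centroid_da",
]
FD_TOKEN = "FD"


def _header_lines(meta: dict | None) -> str:
    lines = [f"# hdxkit {__version__}"]
    for k, v in (meta or {}).items():
        lines.append(f"# {k}={v}")
    return "\n".join(lines) + "\n"


def config_hash(obj) -> str:
    """Stable short hash of a configuration mapping for output headers."""
    return hashlib.sha1(repr(sorted(str(obj).split())).encode()).hexdigest()[:12]


def write_csv(df: pd.DataFrame, path, meta: dict | None = None) -> Path:
    """Write any frame with the standard metadata comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_header_lines(meta))
        df.to_csv(fh, index=False)
    return path


def write_state_csv(table: pd.DataFrame, path, meta: dict | None = None) -> Path:
    """Write a centroid table in the state-data dialect (FD sentinel)."""
    out = table.copy()
    exposure = out["exposure_s"].astype(object)
    is_fd = out["is_fd"].astype(bool)
    exposure[is_fd] = FD_TOKEN
    exposure[~is_fd] = out.loc[~is_fd, "exposure_s"].map(
        lambda v: format(float(v), "g")
    )
    out["exposure_s"] = exposure
    return write_csv(out[STATE_COLUMNS], path, meta)


def read_state_csv(path, *, return_report: bool = False):
    """Read and validate a state-data CSV.

    Returns the typed table (``exposure_s`` float with NaN on FD rows,
    plus a boolean ``is_fd`` column).  Emits a validation report through
    the logger — row counts per state/exposure, missing-control warnings
    — and returns it as a dict when ``return_report`` is true.

    Raises
    ------
    ParseError
        On missing columns, malformed exposure tokens, or duplicate
        (peptide, state, exposure, replicate) rows, with line numbers.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, comment="#", dtype={"exposure_s": str})
    except Exception as exc:  # noqa: BLE001 - normalize parser failures
        raise ParseError(f"{path}: {exc}") from exc
    missing = set(STATE_COLUMNS) - set(raw.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")

    tok = raw["exposure_s"].astype(str).str.strip()
    is_fd = tok.str.upper() == FD_TOKEN
    exposure = pd.to_numeric(tok.where(~is_fd), errors="coerce")
    bad = (~is_fd) & exposure.isna()
    if bad.any():
        lines = (raw.index[bad] + 2).tolist()[:5]  # +2: header + 1-based
        raise ParseError(
            f"{path}: malformed exposure token(s) near line(s) {lines} "
            f"(numeric seconds or '{FD_TOKEN}' expected)"
        )
    table = raw.copy()
    table["exposure_s"] = exposure.astype(float)
    table["is_fd"] = is_fd.to_numpy()
    for col in ("start", "end", "max_uptake", "bio_rep", "tech_rep"):
        table[col] = pd.to_numeric(table[col], errors="raise").astype(int)
    table["centroid_da"] = pd.to_numeric(table["centroid_da"], errors="raise")

    dup_key = PEPTIDE_KEY + ["state", "exposure_s", "is_fd", "bio_rep", "tech_rep"]
    dups = table.duplicated(dup_key, keep=False)
    if dups.any():
        lines = (table.index[dups] + 2).tolist()[:5]
        raise ParseError(f"{path}: duplicate measurement rows near line(s) {lines}")

    report = {
        "n_rows": len(table),
        "states": sorted(table["state"].unique()),
        "n_peptides": int(table[PEPTIDE_KEY].drop_duplicates().shape[0]),
        "rows_per_state": table.groupby("state").size().to_dict(),
        "missing_t0": [],
        "missing_fd": [],
    }
    key = PEPTIDE_KEY + ["state"]
    peptides = table[key].drop_duplicates()
    t0_keys = set(
        map(tuple, table[(~table["is_fd"]) & (table["exposure_s"] == 0)][key].values)
    )
    fd_keys = set(map(tuple, table[table["is_fd"]][key].values))
    for row in map(tuple, peptides.values):
        if row not in t0_keys:
            report["missing_t0"].append(row)
        if row not in fd_keys:
            report["missing_fd"].append(row)
    for kind in ("missing_t0", "missing_fd"):
        if report[kind]:
            logger.warning(
                "%s: %d peptide(s) without %s control rows, e.g. %s",
                path.name,
                len(report[kind]),
                "t=0" if kind == "missing_t0" else "FD",
                report[kind][0],
            )
    logger.info(
        "%s: %d rows, %d peptides, states %s",
        path.name,
        report["n_rows"],
        report["n_peptides"],
        report["states"],
    )
    if return_report:
        return table, report
    return table


def export_woods(
    records: pd.DataFrame, cl: float, path, meta: dict | None = None
) -> Path:
    """Write the Woods-plot data file: one row per peptide x exposure
    with span, midpoint, Δ%EX and the symmetric confidence limits —
    everything needed to redraw the peptide-level differential panel."""
    if records.empty:
        raise ParseError("no differential records to export")
    out = pd.DataFrame(
        {
            "start": records["start"],
            "end": records["end"],
            "midpoint": (records["start"] + records["end"]) / 2.0,
            "exposure_s": records["exposure_s"],
            "delta_pct": records["delta_pct"],
            "cl_pos": float(cl),
            "cl_neg": -float(cl),
            "significant": records["significant"],
            "direction": records["direction"],
        }
    )
    return write_csv(out, path, meta)


def qc_report_text(qc_by_state: dict) -> str:
    """Tabular text report of QC metrics, one column per state."""
    frame = pd.DataFrame({state: qc.as_series() for state, qc in qc_by_state.items()})
    return frame.to_string(float_format=lambda v: f"{v:.3f}")
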