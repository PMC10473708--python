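"""Replicate aggregation, percent exchange, and dataset QC metrics.

The central normalization is FD-referenced percent exchange,

    %EX = (m_t - m_0) / (m_f - m_0) * 100

with m_0 the undeuterated centroid, m_t the centroid after labeling time
t and m_f the fully-deuterated control centroid.  Because back-exchange
attenuates numerator and denominator by the same factor, %EX is robust
to deuterium loss during workup.

Replicates are aggregated nested: technical injections are averaged
within each biological replicate, then biological means are averaged;
the reported SD is across biological means (n-1 denominator), matching
an n = 3 biological design with technical triplicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    CoordinateError,
    DegenerateControlError,
    InputError,
)
from .peptides import MASS_SHIFT_PER_D

logger = logging.getLogger(__name__)

PEPTIDE_KEY = ["protein", "start", "end", "sequence", "max_uptake"]
CELL_KEY = PEPTIDE_KEY + ["state", "exposure_s"]


def percent_exchange(m_t, m_0, m_f, *, clip: bool = False):
    """FD-normalized percent exchange of a centroid measurement.

    Accepts scalars or arrays.  Values are not clipped to [0, 100] by
    default: replicate noise legitimately produces slightly negative or
    >100% values and clipping them would bias dispersion statistics.

    Raises
    ------
    DegenerateControlError
        If any ``m_f <= m_0`` (the FD control must exceed the
        undeuterated reference for the ratio to be defined).
    """
    m_t = np.asarray(m_t, dtype=float)
    m_0 = np.asarray(m_0, dtype=float)
    m_f = np.asarray(m_f, dtype=float)
    if np.any(m_f <= m_0):
        raise DegenerateControlError(
            "fully-deuterated control does not exceed undeuterated reference "
            f"(m_f={m_f!r}, m_0={m_0!r})"
        )
    out = (m_t - m_0) / (m_f - m_0) * 100.0
    if clip:
        out = np.clip(out, 0.0, 100.0)
    if out.ndim == 0:
        return float(out)
    return out


def _control_means(table: pd.DataFrame) -> pd.DataFrame:
    """Mean m_0 and m_f per peptide x state; errors if either is absent."""
    is_fd = table["is_fd"].astype(bool)
    t0 = table[(~is_fd) & (table["exposure_s"] == 0)]
    fd = table[is_fd]
    key = PEPTIDE_KEY + ["state"]
    m0 = t0.groupby(key, sort=False)["centroid_da"].mean().rename("m0")
    mf = fd.groupby(key, sort=False)["centroid_da"].mean().rename("mf")
    ctl = pd.concat([m0, mf], axis=1).reset_index()
    missing = ctl[ctl[["m0", "mf"]].isna().any(axis=1)]
    if len(missing):
        peps = missing.apply(
            lambda r: f"{r['protein']} {r['start']}-{r['end']} [{r['state']}]", axis=1
        )
        raise DegenerateControlError(
            "missing t=0 or FD control rows for: " + "; ".join(peps.head(10))
        )
    bad = ctl[ctl["mf"] <= ctl["m0"]]
    if len(bad):
        r = bad.iloc[0]
        raise DegenerateControlError(
            f"FD control <= undeuterated reference for peptide "
            f"{r['protein']} {r['start']}-{r['end']} [{r['state']}]"
        )
    return ctl


def aggregate_replicates(
    table: pd.DataFrame, *, dispersion: str = "biological"
) -> pd.DataFrame:
    """Aggregate a centroid table into per-cell uptake summaries.

    One output row per peptide x state x exposure (>0) with columns
    ``mean_uptake``/``sd_uptake`` (Da), ``mean_pct_ex``/``sd_pct_ex`` (%),
    replicate counts and the control means ``m0``/``mf`` used.

    ``dispersion="biological"`` (default) reports the SD across
    biological-replicate means; ``"technical"`` pools all individual
    measurements instead (flat SD), a sensitivity-analysis option.  The
    mean is nested in both cases (equal to the flat mean for balanced
    designs).
    """
    if dispersion not in ("biological", "technical"):
        raise InputError(f"unknown dispersion level {dispersion!r}")
    ctl = _control_means(table)
    lab = table[(~table["is_fd"].astype(bool)) & (table["exposure_s"] > 0)].copy()
    if lab.empty:
        raise InputError("no labeled (exposure > 0) rows to aggregate")

    # unbalanced-design check: warn when a biological replicate is absent
    counts = lab.groupby(CELL_KEY, sort=False)["bio_rep"].nunique()
    if counts.nunique() > 1:
        logger.warning(
            "unbalanced biological replication: %d cells have fewer "
            "biological replicates than the maximum (%d); they are "
            "aggregated over the replicates present",
            int((counts < counts.max()).sum()),
            int(counts.max()),
        )

    bio = (
        lab.groupby(CELL_KEY + ["bio_rep"], sort=False)["centroid_da"]
        .mean()
        .reset_index()
    )
    cell = (
        bio.groupby(CELL_KEY, sort=False)["centroid_da"]
        .agg(mean_mt="mean", sd_mt=lambda x: x.std(ddof=1), n_bio="count")
        .reset_index()
    )
    if dispersion == "technical":
        flat = (
            lab.groupby(CELL_KEY, sort=False)["centroid_da"]
            .agg(sd_flat=lambda x: x.std(ddof=1))
            .reset_index()
        )
        cell = cell.merge(flat, on=CELL_KEY)
        cell["sd_mt"] = cell.pop("sd_flat")
    n_total = (
        lab.groupby(CELL_KEY, sort=False)["centroid_da"].size().rename("n_total")
    )
    cell = cell.merge(n_total.reset_index(), on=CELL_KEY)
    cell = cell.merge(ctl, on=PEPTIDE_KEY + ["state"])
    span = cell["mf"] - cell["m0"]
    cell["mean_uptake"] = cell["mean_mt"] - cell["m0"]
    cell["sd_uptake"] = cell["sd_mt"]
    cell["mean_pct_ex"] = cell["mean_uptake"] / span * 100.0
    cell["sd_pct_ex"] = cell["sd_uptake"] / span * 100.0
    cols = CELL_KEY + [
        "mean_uptake",
        "sd_uptake",
        "mean_pct_ex",
        "sd_pct_ex",
        "n_bio",
        "n_total",
        "m0",
        "mf",
    ]
    return (
        cell[cols]
        .sort_values(["protein", "start", "end", "state", "exposure_s"])
        .reset_index(drop=True)
    )


def estimate_back_exchange(
    table: pd.DataFrame,
    f_D: float = 0.95,
    mass_shift_per_D: float = MASS_SHIFT_PER_D,
) -> float:
    """Dataset-level back-exchange (%) from the FD-control deficit.

    Per peptide, ``BE = 1 - (m_f - m_0) / (max_uptake * f_D *
    mass_shift_per_D)``: the fraction of theoretically incorporable
    deuterium the fully-deuterated control failed to retain.  Returns the
    unweighted mean across peptides as a percentage.
    """
    if not 0 < f_D <= 1:
        raise InputError("f_D must be in (0, 1]")
    ctl = _control_means(table)
    ctl = ctl[ctl["max_uptake"] > 0]
    if ctl.empty:
        raise DegenerateControlError("no peptides with max_uptake > 0")
    theo = ctl["max_uptake"] * f_D * mass_shift_per_D
    be = 1.0 - (ctl["mf"] - ctl["m0"]) / theo
    return float(be.mean() * 100.0)


@dataclass(frozen=True)
class QCSummary:
    """Dataset-level quality metrics (one protein state)."""

    n_peptides: int
    coverage_pct: float
    avg_peptide_length: float
    redundancy: float
    repeatability_da: float
    repeatability_pct: float
    back_exchange_pct: float

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "# of Peptides": self.n_peptides,
                "Sequence coverage (%)": self.coverage_pct,
                "Ave peptide length": self.avg_peptide_length,
                "Redundancy": self.redundancy,
                "Repeatability (Ave SD, Da)": self.repeatability_da,
                "Repeatability (Ave SD, %)": self.repeatability_pct,
                "Back-exchange (%)": self.back_exchange_pct,
            }
        )


def qc_summary(
    table: pd.DataFrame,
    protein_length: int | None = None,
    *,
    first_residue: int | None = None,
    f_D: float = 0.95,
    dispersion: str = "biological",
) -> QCSummary:
    """Compute dataset QC metrics from a centroid table.

    ``protein_length`` is the number of residues of the analyzed protein
    (or construct); ``first_residue`` anchors the numbering (defaults to
    the smallest peptide start).  A residue is covered if it lies inside
    at least one peptide span; redundancy is the mean peptide depth over
    covered residues.  Repeatability is the unweighted mean of per-cell
    replicate SDs over every peptide x state x exposure cell.
    """
    peptides = table[PEPTIDE_KEY].drop_duplicates()
    if peptides.empty:
        raise InputError("no peptides in table")
    if first_residue is None:
        first_residue = int(peptides["start"].min())
    if protein_length is None:
        protein_length = int(peptides["end"].max()) - first_residue + 1
    last_residue = first_residue + protein_length - 1
    if int(peptides["end"].max()) > last_residue:
        raise CoordinateError(
            f"protein_length {protein_length} (residues {first_residue}-"
            f"{last_residue}) shorter than peptide map end "
            f"{int(peptides['end'].max())}"
        )
    depth = np.zeros(protein_length, dtype=int)
    for _, p in peptides.iterrows():
        depth[int(p["start"]) - first_residue : int(p["end"]) - first_residue + 1] += 1
    covered = depth > 0
    coverage_pct = 100.0 * covered.sum() / protein_length
    redundancy = float(depth[covered].mean()) if covered.any() else 0.0
    lengths = peptides["end"] - peptides["start"] + 1
    summary = aggregate_replicates(table, dispersion=dispersion)
    with_rep = summary[summary["n_bio"] >= 2]
    rep_da = float(with_rep["sd_uptake"].mean()) if len(with_rep) else float("nan")
    rep_pct = float(with_rep["sd_pct_ex"].mean()) if len(with_rep) else float("nan")
    return QCSummary(
        n_peptides=len(peptides),
        coverage_pct=float(coverage_pct),
        avg_peptide_length=float(lengths.mean()),
        redundancy=redundancy,
        repeatability_da=rep_da,
        repeatability_pct=rep_pct,
        back_exchange_pct=estimate_back_exchange(table, f_D=f_D),
    )
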