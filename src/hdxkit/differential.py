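"""Differential exchange statistics: Δ%EX, the pooled-SD global
confidence limit, and significance classification.

Rather than testing each peptide separately, differential HDX commonly
uses a single dataset-wide threshold: the two states' average replicate
standard deviations s_A and s_B (the "repeatability") are pooled in
quadrature and scaled by a two-sided critical multiplier,

    CL = multiplier * sqrt(s_A**2 + s_B**2)

with 2.32 (the large-sample two-sided 98% point) as the default.  A
peptide x exposure difference Δ%EX = %EX_A - %EX_B is significant when
it strictly exceeds ±CL.  With state A the wild type, positive Δ%EX
marks regions more protected (stabilized) in state B, negative Δ%EX
regions deprotected (destabilized) in B.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, InputError, InsufficientReplicationError
from .uptake import PEPTIDE_KEY, _control_means

logger = logging.getLogger(__name__)

STABILIZED = "stabilized"
DESTABILIZED = "destabilized"
UNCHANGED = "unchanged"
MIXED = "mixed"


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings for the differential analysis.

    ``critical_multiplier`` is applied to the quadrature-pooled
    repeatabilities; 2.32 corresponds to a two-sided 98% confidence
    level in the large-sample limit.  ``units`` selects whether the
    limit and differences are expressed in percent exchange ("%") or
    mass ("da").
    """

    confidence_level: float = 98.0
    critical_multiplier: float = 2.32
    min_significant_timepoints: int = 1
    units: str = "%"

    def __post_init__(self) -> None:
        if not 50.0 < self.confidence_level < 100.0:
            raise InputError("confidence_level must be in (50, 100)")
        if self.critical_multiplier <= 0:
            raise InputError("critical_multiplier must be > 0")
        if self.min_significant_timepoints < 1:
            raise InputError("min_significant_timepoints must be >= 1")
        if self.units not in ("%", "da"):
            raise InputError("units must be '%' or 'da'")

    @classmethod
    def from_confidence(cls, confidence_level: float, **kw) -> "AnalysisConfig":
        """Derive the multiplier from the normal two-sided critical value
        for ``confidence_level`` (e.g. 98 -> 2.326)."""
        alpha = 1.0 - confidence_level / 100.0
        mult = float(stats.norm.ppf(1.0 - alpha / 2.0))
        return cls(
            confidence_level=confidence_level, critical_multiplier=mult, **kw
        )


def repeatability(summary: pd.DataFrame) -> tuple[float, float]:
    """Dataset repeatability: the unweighted mean of per-cell replicate
    SDs, in Da and in %, over all cells with >= 2 biological replicates.

    This is the noise scale the global confidence limit is built from.
    """
    cells = summary[summary["n_bio"] >= 2]
    if cells.empty:
        raise InsufficientReplicationError(
            "no peptide x exposure cell with >= 2 biological replicates"
        )
    return float(cells["sd_uptake"].mean()), float(cells["sd_pct_ex"].mean())


def global_significance_limit(
    s_a: float, s_b: float, config: AnalysisConfig | None = None
) -> float:
    """Global confidence limit for differential uptake.

    ``multiplier * sqrt(s_a**2 + s_b**2)`` with the two states' average
    replicate SDs (same units in, same units out).  Symmetric in its
    arguments and linear under a common rescaling of both SDs.
    """
    if s_a < 0 or s_b < 0:
        raise InputError("standard deviations must be >= 0")
    mult = (config or AnalysisConfig()).critical_multiplier
    return float(mult * np.hypot(s_a, s_b))


@dataclass(frozen=True)
class DifferentialResult:
    """Δ%EX records with the limit they were judged against."""

    records: pd.DataFrame
    cl: float
    s_a: float
    s_b: float
    config: AnalysisConfig
    only_in_a: pd.DataFrame = field(repr=False, default=None)
    only_in_b: pd.DataFrame = field(repr=False, default=None)


def differential_uptake(
    summary_a: pd.DataFrame,
    summary_b: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> DifferentialResult:
    """Compute per-cell differences A - B against the global limit.

    Both inputs are uptake summaries (one state each, from
    :func:`hdxkit.uptake.aggregate_replicates`).  Only the common
    peptide x exposure grid is differenced; peptides present in a single
    state are returned in the ``only_in_a`` / ``only_in_b`` mismatch
    listings rather than silently dropped.  Significance is strict:
    ``|delta| > cl``, with direction stabilized (positive, state B more
    protected) or destabilized (negative).
    """
    config = config or AnalysisConfig()
    value = "mean_pct_ex" if config.units == "%" else "mean_uptake"
    sd_col = "sd_pct_ex" if config.units == "%" else "sd_uptake"

    s_a = float(summary_a.loc[summary_a["n_bio"] >= 2, sd_col].mean())
    s_b = float(summary_b.loc[summary_b["n_bio"] >= 2, sd_col].mean())
    if np.isnan(s_a) or np.isnan(s_b):
        raise InsufficientReplicationError(
            "cannot compute repeatability: no replicated cells"
        )
    cl = global_significance_limit(s_a, s_b, config)

    key = PEPTIDE_KEY + ["exposure_s"]
    merged = summary_a.merge(
        summary_b, on=key, suffixes=("_a", "_b"), how="outer", indicator=True
    )
    only_a = merged[merged["_merge"] == "left_only"][key].drop_duplicates()
    only_b = merged[merged["_merge"] == "right_only"][key].drop_duplicates()
    both = merged[merged["_merge"] == "both"].copy()
    if both.empty:
        raise AlignmentError("states share no peptide x exposure cells")
    if len(only_a) or len(only_b):
        logger.warning(
            "peptide grid mismatch: %d cells only in state A, %d only in B",
            len(only_a),
            len(only_b),
        )

    delta = both[f"{value}_a"] - both[f"{value}_b"]
    records = both[key].copy()
    records["delta_pct"] = delta.to_numpy()
    records["cl"] = cl
    records["significant"] = np.abs(records["delta_pct"]) > cl
    records["direction"] = UNCHANGED
    records.loc[records["significant"] & (records["delta_pct"] > 0), "direction"] = (
        STABILIZED
    )
    records.loc[records["significant"] & (records["delta_pct"] < 0), "direction"] = (
        DESTABILIZED
    )
    records = records.sort_values(["protein", "start", "end", "exposure_s"]).reset_index(
        drop=True
    )
    return DifferentialResult(
        records=records,
        cl=cl,
        s_a=s_a,
        s_b=s_b,
        config=config,
        only_in_a=only_a.reset_index(drop=True),
        only_in_b=only_b.reset_index(drop=True),
    )


def classify_peptides(
    records: pd.DataFrame, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Collapse per-exposure differential records to one label per peptide.

    A peptide is stabilized (destabilized) when at least
    ``min_significant_timepoints`` exposures exceed +CL (fall below -CL);
    a peptide reaching the threshold in both directions is flagged mixed.
    """
    config = config or AnalysisConfig()
    k = config.min_significant_timepoints

    def _label(group: pd.DataFrame) -> str:
        n_pos = int(((group["delta_pct"] > group["cl"])).sum())
        n_neg = int(((group["delta_pct"] < -group["cl"])).sum())
        pos_hit, neg_hit = n_pos >= k, n_neg >= k
        if pos_hit and neg_hit:
            return MIXED
        if pos_hit:
            return STABILIZED
        if neg_hit:
            return DESTABILIZED
        return UNCHANGED

    labels = (
        records.groupby(PEPTIDE_KEY, sort=False)
        .apply(_label, include_groups=False)
        .rename("label")
        .reset_index()
    )
    mixed = labels[labels["label"] == MIXED]
    if len(mixed):
        logger.warning(
            "%d peptide(s) exceed the limit in both directions (mixed)", len(mixed)
        )
    return labels.sort_values(["protein", "start", "end"]).reset_index(drop=True)


def residue_consensus(labels: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-residue majority vote over the peptides covering each residue.

    Returns ``(per_residue, regions)``: per-residue calls (residue,
    label, depth) over the span of the peptide map, and contiguous runs
    of identical labels as (start, end, label) regions.  Ties — including
    the stabilized-vs-destabilized standoff — resolve to unchanged;
    uncovered residues inside the span are unchanged.
    """
    if labels.empty:
        raise InputError("no peptide labels")
    lo = int(labels["start"].min())
    hi = int(labels["end"].max())
    n = hi - lo + 1
    order = [STABILIZED, DESTABILIZED, MIXED, UNCHANGED]
    counts = {lab: np.zeros(n, dtype=int) for lab in order}
    for _, row in labels.iterrows():
        sl = slice(int(row["start"]) - lo, int(row["end"]) - lo + 1)
        counts[row["label"]][sl] += 1
    stack = np.vstack([counts[lab] for lab in order])
    depth = stack.sum(axis=0)
    best = stack.max(axis=0)
    ties = (stack == best).sum(axis=0) > 1
    winner = np.array(order, dtype=object)[stack.argmax(axis=0)]
    winner[ties | (depth == 0)] = UNCHANGED
    per_residue = pd.DataFrame(
        {"residue": np.arange(lo, hi + 1), "label": winner, "depth": depth}
    )
    regions = []
    run_start = lo
    for i in range(1, n + 1):
        if i == n or winner[i] != winner[i - 1]:
            regions.append(
                {"start": run_start, "end": lo + i - 1, "label": winner[i - 1]}
            )
            run_start = lo + i
    return per_residue, pd.DataFrame(regions)


def peptide_welch_test(
    table_a: pd.DataFrame, table_b: pd.DataFrame
) -> pd.DataFrame:
    """Welch two-sample test on biological-replicate %EX means.

    An optional AND-criterion ("hybrid test") alongside the global
    limit; it never replaces the limit-based classification.  Returns one
    row per common peptide x exposure with the Welch statistic and
    p-value.  Requires >= 2 biological replicates per state.
    """

    def _bio_pct(table: pd.DataFrame) -> pd.DataFrame:
        ctl = _control_means(table)
        lab = table[(~table["is_fd"].astype(bool)) & (table["exposure_s"] > 0)]
        bio = (
            lab.groupby(PEPTIDE_KEY + ["state", "exposure_s", "bio_rep"], sort=False)[
                "centroid_da"
            ]
            .mean()
            .reset_index()
            .merge(ctl, on=PEPTIDE_KEY + ["state"])
        )
        bio["pct_ex"] = (bio["centroid_da"] - bio["m0"]) / (bio["mf"] - bio["m0"]) * 100
        return bio

    a, b = _bio_pct(table_a), _bio_pct(table_b)
    key = PEPTIDE_KEY + ["exposure_s"]
    rows = []
    gb_b = dict(tuple(b.groupby(key, sort=False)))
    for cell, ga in a.groupby(key, sort=False):
        gb = gb_b.get(cell)
        if gb is None:
            continue
        xa, xb = ga["pct_ex"].to_numpy(), gb["pct_ex"].to_numpy()
        if len(xa) < 2 or len(xb) < 2:
            raise InsufficientReplicationError(
                f"cell {cell}: need >= 2 biological replicates per state"
            )
        if xa.std(ddof=1) == 0 and xb.std(ddof=1) == 0:
            t_stat, p = (0.0, 1.0) if xa.mean() == xb.mean() else (np.inf, 0.0)
        else:
            t_stat, p = stats.ttest_ind(xa, xb, equal_var=False)
        rows.append(dict(zip(key, cell)) | {"t_stat": float(t_stat), "p_value": float(p)})
    if not rows:
        raise AlignmentError("states share no peptide x exposure cells")
    return pd.DataFrame(rows)
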