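"""Synthetic EX2 exchange simulator.

Generates peptide-level HDX-MS centroid datasets from an explicit
per-residue kinetic ground truth.  In the EX2 limit each amide exchanges
independently with observed rate ``k_obs = k_intrinsic / PF`` (PF the
protection factor), so the deuterium occupancy of residue ``i`` after
labeling time ``t`` in a buffer of deuterium fraction ``f_D`` is

    D_i(t) = f_D * (1 - exp(-k_i * t))

A fraction ``b`` of incorporated deuterium is lost to back-exchange
between quench and measurement, uniformly across residues and times, so
the peptide centroid observed at time ``t`` is

    m_t = m_0 + mass_shift_per_D * (1 - b) * sum_i D_i(t)

summed over the peptide's exchangeable amides.  The fully-deuterated
(FD) control saturates every amide:

    m_f = m_0 + mass_shift_per_D * (1 - b) * max_uptake * f_D

Because the same ``f_D`` and ``(1 - b)`` factors appear in ``m_t - m_0``
and ``m_f - m_0``, FD-normalized percent exchange is independent of both
— the property the downstream analysis relies on.

Measurement noise is nested to mirror the experimental design: a
per-(peptide, biological replicate) offset (protein-prep variation) plus
independent per-injection technical noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as _ptmass

from .errors import CoordinateError, InputError
from .peptides import MASS_SHIFT_PER_D, PeptideRecord, make_peptide

logger = logging.getLogger(__name__)

# Two-component baseline for log10(k_obs / s^-1): a "fast" population that
# saturates within the first labeling times and a "slow" protected one that
# is still rising at the end of a 10 s .. 2 h schedule.
DEFAULT_RATE_MIXTURE = (
    (0.5, -1.5, 0.5),  # (weight, mean, sd) fast
    (0.5, -3.5, 0.5),  # slow
)


@dataclass(frozen=True)
class ExchangeModel:
    """Per-residue kinetic ground truth for one protein state.

    ``log10_k_obs`` has one entry per residue of ``sequence`` (construct
    coordinates); entries are NaN where the residue carries no
    exchangeable amide (position 1, prolines).
    """

    sequence: str
    log10_k_obs: np.ndarray
    residue_offset: int = 1
    f_D: float = 0.95
    b: float = 0.47
    mass_shift_per_D: float = MASS_SHIFT_PER_D
    noise_tech_da: float = 0.12
    noise_bio_da: float = 0.12
    n_term_exclusion: int = 1

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError("empty sequence")
        k = np.asarray(self.log10_k_obs, dtype=float)
        object.__setattr__(self, "log10_k_obs", k)
        if k.shape != (len(self.sequence),):
            raise InputError("log10_k_obs must have one entry per residue")
        if not 0.0 <= self.f_D <= 1.0:
            raise InputError("f_D must be in [0, 1]")
        if not 0.0 <= self.b < 1.0:
            raise InputError("back-exchange fraction b must be in [0, 1)")
        if self.noise_tech_da < 0 or self.noise_bio_da < 0:
            raise InputError("noise SDs must be >= 0")
        amide = self.exchangeable_mask()
        if np.isnan(k[amide]).any():
            raise InputError("log10_k_obs undefined at an exchangeable residue")

    def exchangeable_mask(self) -> np.ndarray:
        """Boolean mask over construct positions carrying an amide that can
        retain deuterium (position >= 2, non-proline)."""
        mask = np.array([aa != "P" for aa in self.sequence])
        mask[0] = False
        return mask

    @property
    def n_residues(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class LabelingSchedule:
    """Labeling time course and replicate design."""

    exposures: tuple[float, ...] = (10.0, 60.0, 600.0, 3600.0, 7200.0)
    includes_t0: bool = True
    includes_fd: bool = True
    n_bio: int = 3
    n_tech: int = 3

    def __post_init__(self) -> None:
        exp = tuple(float(t) for t in self.exposures)
        object.__setattr__(self, "exposures", exp)
        if any(t <= 0 for t in exp):
            raise InputError("exposures must be strictly positive")
        if any(b >= a for b, a in zip(exp, exp[1:])):
            raise InputError("exposures must be strictly increasing")
        if self.n_bio < 1 or self.n_tech < 1:
            raise InputError("replicate counts must be >= 1")


def build_exchange_model(
    sequence: str,
    region_specs: Sequence[tuple[int, int, float]] = (),
    *,
    seed: int = 0,
    rate_mixture=DEFAULT_RATE_MIXTURE,
    residue_offset: int = 1,
    **params,
) -> ExchangeModel:
    """Draw a baseline per-residue rate model and apply protection regions.

    ``region_specs`` is a list of ``(start, end, log10_pf_shift)`` in
    construct coordinates (1-based, inclusive); a positive shift makes the
    region more protected (rates ``10**shift``-fold slower).  Baseline
    ``log10_k_obs`` values are drawn i.i.d. from the two-component normal
    mixture ``rate_mixture`` (list of ``(weight, mean, sd)``).

    Deterministic for a fixed seed.  Extra keyword arguments are passed to
    :class:`ExchangeModel` (``f_D``, ``b``, noise levels, ...).
    """
    if not sequence:
        raise InputError("empty sequence")
    rng = np.random.default_rng(seed)
    L = len(sequence)
    weights = np.array([w for w, _, _ in rate_mixture], dtype=float)
    weights = weights / weights.sum()
    comp = rng.choice(len(rate_mixture), size=L, p=weights)
    means = np.array([m for _, m, _ in rate_mixture])
    sds = np.array([s for _, _, s in rate_mixture])
    k = rng.normal(means[comp], sds[comp])
    model = ExchangeModel(
        sequence=sequence,
        log10_k_obs=k,
        residue_offset=residue_offset,
        **params,
    )
    mask = model.exchangeable_mask()
    k = np.where(mask, k, np.nan)
    for start, end, shift in region_specs:
        _check_region(start, end, L)
        k = k.copy()
        k[start - 1 : end] -= shift
    return replace(model, log10_k_obs=k)


def perturb_model(
    model: ExchangeModel, region: tuple[int, int], log10_pf_delta: float
) -> ExchangeModel:
    """Return a copy of ``model`` with the region's rates shifted.

    ``log10_pf_delta > 0`` deprotects (faster exchange: the protection
    factor drops ``10**delta``-fold); negative values protect.  The input
    model is left untouched.  The region is in construct coordinates.
    """
    start, end = region
    _check_region(start, end, model.n_residues)
    k = model.log10_k_obs.copy()
    k[start - 1 : end] += log10_pf_delta
    return replace(model, log10_k_obs=k)


def _check_region(start: int, end: int, length: int) -> None:
    if not (1 <= start <= end <= length):
        raise CoordinateError(
            f"region {start}-{end} outside sequence of length {length}"
        )


def digest(
    sequence: str,
    target_mean_length: float = 13.0,
    target_redundancy: float = 5.5,
    *,
    seed: int = 0,
    spans: Sequence[tuple[int, int]] | None = None,
    protein_id: str = "protein",
    residue_offset: int = 1,
    min_length: int = 4,
    n_term_exclusion: int = 1,
) -> list[PeptideRecord]:
    """Emit a synthetic peptic map: overlapping peptides covering the
    sequence at a tunable mean length and per-residue redundancy.

    The map is built in two passes: a deterministic tiling with >= 2
    residues of overlap between neighbours (so every exchangeable amide
    sits at position >= 2 of at least one peptide, i.e. 100% coverage in
    exchange terms), then random additional peptides until the mean
    per-residue depth reaches ``target_redundancy``.  Pass ``spans`` (a
    list of 1-based inclusive ``(start, end)`` in construct coordinates)
    to bypass the random map entirely.

    Realized mean length stays within ~15% of the target; the peptide list
    is identical for identical seeds.
    """
    L = len(sequence)
    if spans is None:
        if target_mean_length < min_length:
            raise InputError(f"target_mean_length must be >= {min_length}")
        if L < target_mean_length:
            raise InputError("sequence shorter than target_mean_length")
        if target_redundancy < 1:
            raise InputError("target_redundancy must be >= 1")
        rng = np.random.default_rng(seed)
        max_len = max(min_length, min(L, int(round(2 * target_mean_length))))

        def draw_len() -> int:
            raw = rng.normal(target_mean_length, target_mean_length / 6.0)
            return int(np.clip(round(raw), min_length, max_len))

        chosen: list[tuple[int, int]] = []
        seen: set[tuple[int, int]] = set()
        # pass 1: tiling with 2-residue overlap
        start = 1
        while True:
            end = min(start + draw_len() - 1, L)
            if L - end < min_length:  # avoid a trailing stub
                end = L
            if end - start + 1 < min_length:
                start = max(1, end - min_length + 1)
            span = (start, end)
            if span not in seen:
                seen.add(span)
                chosen.append(span)
            if end >= L:
                break
            start = end - 1
        # pass 2: random peptides up to the target depth
        total = sum(e - s + 1 for s, e in chosen)
        target_total = target_redundancy * L
        attempts = 0
        while total < target_total and attempts < 100000:
            attempts += 1
            ln = draw_len()
            if ln > L:
                ln = L
            s = int(rng.integers(1, L - ln + 2))
            span = (s, s + ln - 1)
            if span in seen:
                continue
            seen.add(span)
            chosen.append(span)
            total += ln
        spans = sorted(chosen)
    else:
        for s, e in spans:
            _check_region(s, e, L)

    records = [
        make_peptide(
            protein_id,
            s + residue_offset - 1,
            sequence[s - 1 : e],
            n_term_exclusion=n_term_exclusion,
        )
        for s, e in spans
    ]
    return records


@dataclass(frozen=True)
class SimulationResult:
    """Centroid table plus the noise-free ground truth that produced it."""

    table: pd.DataFrame
    truth: pd.DataFrame
    model: ExchangeModel = field(repr=False, default=None)


def simulate_centroids(
    model: ExchangeModel,
    peptides: Sequence[PeptideRecord],
    schedule: LabelingSchedule,
    *,
    state: str = "A",
    seed: int = 0,
) -> SimulationResult:
    """Simulate one state's centroid measurements under ``schedule``.

    Emits one row per peptide x exposure x biological x technical
    replicate, plus undeuterated (t=0) and fully-deuterated control rows
    when the schedule includes them; controls carry technical noise only.
    The companion ``truth`` frame holds the noise-free uptake (Da) and
    percent exchange per peptide x exposure for oracle comparisons.
    """
    rng = np.random.default_rng(seed)
    L = model.n_residues
    k_lin = 10.0 ** model.log10_k_obs  # NaN propagates at non-amides
    exposures = np.asarray(schedule.exposures)
    n_bio, n_tech = schedule.n_bio, schedule.n_tech

    # per-(peptide, bio) offsets drawn first so row noise order is stable
    bio_off = rng.normal(0.0, model.noise_bio_da, size=(len(peptides), n_bio))
    if model.noise_bio_da == 0:
        bio_off[:] = 0.0

    rows: list[dict] = []
    truth_rows: list[dict] = []
    scale = model.mass_shift_per_D * (1.0 - model.b)
    for ip, pep in enumerate(peptides):
        cs = pep.start - model.residue_offset + 1  # construct coords
        ce = pep.end - model.residue_offset + 1
        if not (1 <= cs <= ce <= L):
            raise CoordinateError(
                f"peptide {pep.start}-{pep.end} outside model range"
            )
        if model.sequence[cs - 1 : ce] != pep.sequence:
            raise InputError(
                f"peptide {pep.start}-{pep.end} sequence does not match model"
            )
        # exchanging residues: skip the peptide's own excluded N-terminal
        # residue(s) and prolines; position 1 of the construct never has
        # an amide rate (mask handled at model construction).
        idx = [
            p - 1
            for p in range(cs + model.n_term_exclusion, ce + 1)
            if model.sequence[p - 1] != "P" and p >= 2
        ]
        if len(idx) != pep.max_uptake:
            raise InputError(
                f"peptide {pep.start}-{pep.end}: max_uptake {pep.max_uptake} "
                f"inconsistent with model convention ({len(idx)} amides)"
            )
        m0 = _ptmass.fast_mass(pep.sequence)
        mf = m0 + scale * pep.max_uptake * model.f_D
        ks = k_lin[idx]
        # occupancy sum per exposure, noise free
        occ = model.f_D * (1.0 - np.exp(-np.outer(ks, exposures))).sum(axis=0)
        uptake = scale * occ  # Da retained after back-exchange
        denom = pep.max_uptake * model.f_D
        pct_true = 100.0 * occ / denom if denom > 0 else np.zeros_like(occ)

        base = dict(
            protein=pep.protein_id,
            start=pep.start,
            end=pep.end,
            sequence=pep.sequence,
            max_uptake=pep.max_uptake,
            state=state,
        )
        for it, t in enumerate(exposures):
            truth_rows.append(
                dict(base, exposure_s=t, uptake_da=uptake[it], pct_ex=pct_true[it])
            )
        tech = rng.normal(
            0.0, model.noise_tech_da, size=(len(exposures) + 2, n_bio, n_tech)
        )
        if model.noise_tech_da == 0:
            tech[:] = 0.0
        for it, t in enumerate(exposures):
            for ib in range(n_bio):
                for jt in range(n_tech):
                    rows.append(
                        dict(
                            base,
                            exposure_s=t,
                            is_fd=False,
                            bio_rep=ib + 1,
                            tech_rep=jt + 1,
                            centroid_da=m0
                            + uptake[it]
                            + bio_off[ip, ib]
                            + tech[it, ib, jt],
                        )
                    )
        if schedule.includes_t0:
            for ib in range(n_bio):
                for jt in range(n_tech):
                    rows.append(
                        dict(
                            base,
                            exposure_s=0.0,
                            is_fd=False,
                            bio_rep=ib + 1,
                            tech_rep=jt + 1,
                            centroid_da=m0 + tech[-2, ib, jt],
                        )
                    )
        if schedule.includes_fd:
            for ib in range(n_bio):
                for jt in range(n_tech):
                    rows.append(
                        dict(
                            base,
                            exposure_s=np.nan,
                            is_fd=True,
                            bio_rep=ib + 1,
                            tech_rep=jt + 1,
                            centroid_da=mf + tech[-1, ib, jt],
                        )
                    )
    table = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    logger.info(
        "simulated state %s: %d peptides, %d rows", state, len(peptides), len(table)
    )
    return SimulationResult(table=table, truth=truth, model=model)


def ground_truth_frame(model: ExchangeModel, state: str = "A") -> pd.DataFrame:
    """Per-residue ground-truth rates in full-protein numbering, for the
    companion CSV written next to simulated datasets."""
    mask = model.exchangeable_mask()
    return pd.DataFrame(
        {
            "residue": np.arange(model.n_residues) + model.residue_offset,
            "amino_acid": list(model.sequence),
            "exchangeable": mask,
            "log10_k_obs": model.log10_k_obs,
            "state": state,
        }
    )
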