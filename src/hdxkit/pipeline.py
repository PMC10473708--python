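"""End-to-end pipeline: simulate (or read) -> uptake -> QC -> differential.

The pipeline is a convenience layer over the library; every stage is an
ordinary function call and can be run independently.  Outputs are plain
CSV/text files whose headers record the package version, the seed and a
hash of the configuration, so a run is byte-reproducible from its
config alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .differential import (
    AnalysisConfig,
    classify_peptides,
    differential_uptake,
    residue_consensus,
)
from .errors import HdxError, InputError
from .io import (
    config_hash,
    export_woods,
    qc_report_text,
    read_state_csv,
    write_csv,
    write_state_csv,
)
from .simulate import (
    LabelingSchedule,
    build_exchange_model,
    digest,
    ground_truth_frame,
    perturb_model,
    simulate_centroids,
)
from .uptake import aggregate_replicates, qc_summary

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for a full simulate-then-analyze (or analyze-only) run.

    Exactly one of the two input modes applies: ``input_csvs`` maps state
    names to existing state-data CSVs, or ``sequence`` triggers the
    simulator (two states, the second optionally perturbed in
    ``perturbation`` = (start, end, log10_pf_delta), construct
    coordinates).
    """

    outdir: str = "hdx_out"
    seed: int = 0
    # analyze-only mode
    input_csvs: dict = field(default_factory=dict)
    # simulate mode
    sequence: str = ""
    state_names: tuple = ("WT", "mutant")
    regions: list = field(default_factory=list)
    perturbation: tuple | None = None
    residue_offset: int = 1
    f_D: float = 0.95
    back_exchange: float = 0.47
    noise_tech_da: float = 0.12
    noise_bio_da: float = 0.12
    target_mean_length: float = 13.0
    target_redundancy: float = 5.5
    exposures: tuple = (10.0, 60.0, 600.0, 3600.0, 7200.0)
    n_bio: int = 3
    n_tech: int = 3
    # analysis settings
    confidence_level: float = 98.0
    critical_multiplier: float = 2.32
    min_significant_timepoints: int = 1
    units: str = "%"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("state_names", "exposures"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        if "perturbation" in data and data["perturbation"] is not None:
            data["perturbation"] = tuple(data["perturbation"])
        return cls(**data)

    def analysis_config(self) -> AnalysisConfig:
        return AnalysisConfig(
            confidence_level=self.confidence_level,
            critical_multiplier=self.critical_multiplier,
            min_significant_timepoints=self.min_significant_timepoints,
            units=self.units,
        )


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write the output bundle.

    Returns a dict with the in-memory results (tables, summaries,
    differential records, regions, QC) and the paths written.  On any
    stage failure, files already written in this run are removed and the
    error re-raised with a stage label.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # hash the scientific settings only, so the same analysis written to a
    # different directory carries the same fingerprint
    from dataclasses import asdict

    science = {k: v for k, v in asdict(config).items() if k != "outdir"}
    meta = {"seed": config.seed, "config_hash": config_hash(science)}
    written: list[Path] = []
    stage = "setup"
    try:
        tables = {}
        if config.input_csvs:
            stage = "read"
            for state, path in config.input_csvs.items():
                tables[state] = read_state_csv(path)
        else:
            stage = "simulate"
            if not config.sequence:
                raise InputError("config needs either input_csvs or a sequence")
            tables.update(_simulate_states(config, outdir, meta, written))

        stage = "uptake"
        summaries = {s: aggregate_replicates(t) for s, t in tables.items()}
        for state, summ in summaries.items():
            written.append(
                write_csv(summ, outdir / f"uptake_{state}.csv", meta)
            )

        stage = "qc"
        qc = {s: qc_summary(t, f_D=config.f_D) for s, t in tables.items()}
        report = qc_report_text(qc)
        qc_path = outdir / "qc_report.txt"
        qc_path.write_text(report + "\n", encoding="utf-8")
        written.append(qc_path)
        import pandas as pd

        qc_frame = pd.DataFrame({s: q.as_series() for s, q in qc.items()})
        written.append(
            write_csv(
                qc_frame.reset_index(names="metric"), outdir / "qc_report.csv", meta
            )
        )
        logger.info("QC report:\n%s", report)

        stage = "differential"
        states = list(tables)
        if len(states) != 2:
            raise InputError(f"differential analysis needs 2 states, got {states}")
        acfg = config.analysis_config()
        diff = differential_uptake(summaries[states[0]], summaries[states[1]], acfg)
        written.append(
            write_csv(diff.records, outdir / "differential.csv", meta)
        )

        stage = "classify"
        labels = classify_peptides(diff.records, acfg)
        per_residue, regions = residue_consensus(labels)
        written.append(write_csv(labels, outdir / "peptide_labels.csv", meta))
        written.append(write_csv(regions, outdir / "regions.csv", meta))
        written.append(
            export_woods(diff.records, diff.cl, outdir / "woods.csv", meta)
        )
        logger.info(
            "differential: cl=%.3f %s, %d/%d significant cells",
            diff.cl,
            acfg.units,
            int(diff.records["significant"].sum()),
            len(diff.records),
        )
        return {
            "tables": tables,
            "summaries": summaries,
            "qc": qc,
            "differential": diff,
            "labels": labels,
            "per_residue": per_residue,
            "regions": regions,
            "paths": written,
        }
    except HdxError as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise type(exc)(f"[stage: {stage}] {exc}") from exc


def _simulate_states(
    config: RunConfig, outdir: Path, meta: dict, written: list
) -> dict:
    """Simulate the two-state dataset described by ``config``."""
    import numpy as np

    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]
    base = build_exchange_model(
        config.sequence,
        config.regions,
        seed=seeds[0],
        residue_offset=config.residue_offset,
        f_D=config.f_D,
        b=config.back_exchange,
        noise_tech_da=config.noise_tech_da,
        noise_bio_da=config.noise_bio_da,
    )
    models = {config.state_names[0]: base}
    if config.perturbation is not None:
        s, e, delta = config.perturbation
        models[config.state_names[1]] = perturb_model(base, (s, e), delta)
    else:
        models[config.state_names[1]] = base
    peptides = digest(
        config.sequence,
        config.target_mean_length,
        config.target_redundancy,
        seed=seeds[1],
        residue_offset=config.residue_offset,
    )
    schedule = LabelingSchedule(
        exposures=config.exposures, n_bio=config.n_bio, n_tech=config.n_tech
    )
    tables = {}
    for (state, model), seed in zip(models.items(), seeds[2:]):
        sim = simulate_centroids(model, peptides, schedule, state=state, seed=seed)
        tables[state] = sim.table
        written.append(
            write_state_csv(sim.table, outdir / f"state_{state}.csv", meta)
        )
        written.append(
            write_csv(
                ground_truth_frame(model, state),
                outdir / f"ground_truth_{state}.csv",
                meta,
            )
        )
    return tables
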