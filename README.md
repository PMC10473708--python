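# hdxkit

Differential hydrogen–deuterium exchange mass spectrometry (HDX-MS)
analysis at the peptide level: percent-exchange normalization against a
fully-deuterated standard, replicate-pooled repeatability, a global
confidence limit for differential uptake, and significance
classification of peptides and sequence regions — together with an EX2
exchange simulator that generates fully ground-truthed synthetic
datasets, and two small plate-reader kinetics utilities (oxidative-burst
time-to-half-maximum, fluorometric enzyme quantification).

It is written for structural biologists and mass spectrometrists who
have peptide-level centroid tables (DynamX-style state data: one row per
peptide × state × exposure × replicate) and want a transparent,
scriptable route from centroids to "these regions are stabilized /
destabilized in the mutant", with every statistical choice inspectable.

## The analysis

For a peptic peptide with undeuterated centroid mass $m_0$, labeled
centroid $m_t$ at exposure $t$, and fully-deuterated control $m_f$,
percent exchange is

$$\%EX = \frac{m_t - m_0}{m_f - m_0} \times 100$$

Because back-exchange attenuates numerator and denominator equally, the
ratio is robust to deuterium loss during workup. Technical injections
are averaged within each biological replicate, biological means are
averaged, and the SD across biological means is the per-cell
repeatability. The dataset repeatability $\bar{s}$ (mean of per-cell
SDs) from each of two states pools into a single global confidence
limit for the difference $\Delta\%EX = \%EX_A - \%EX_B$:

$$CL = z \cdot \sqrt{\bar{s}_A^2 + \bar{s}_B^2}, \qquad z = 2.32
\text{ (two-sided 98%)}$$

A peptide × exposure cell is significant when $|\Delta\%EX| > CL$
(strict); peptides are classified stabilized / destabilized / mixed,
and a per-residue majority vote over covering peptides yields contiguous
regions. An optional Welch test on biological-replicate means is
available as an AND-criterion ("hybrid test").

The simulator draws per-residue observed exchange rates
($k_{obs} = k_{int}/PF$) from a two-component fast/slow mixture, builds
overlapping peptic maps at a target mean length and redundancy, and
emits centroid tables with nested biological/technical noise,
undeuterated references, fully-deuterated controls and a uniform
back-exchange fraction — so every downstream statistic can be checked
against known ground truth.

## Worked example

```sh
python examples/differential_analysis.py
```

simulates a 120-residue protein in two states — a wild type and a
mutant whose residues 41–55 exchange 100× faster (a deprotected loop) —
at realistic noise (~0.12 Da replicate SD), then runs the full
analysis:

```
repeatability: WT 2.92%, mutant 2.59% -> 98% confidence limit +-9.04% exchange
 start  end        label
    41   56 destabilized
```

The two states' mean replicate SDs (2.92% and 2.59% exchange) pool into
a ±9.04% confidence limit; the only region whose Δ%EX exceeds it is
called destabilized and coincides with the implanted perturbation.
`examples/qc_report.py` prints the dataset QC block (peptide count,
coverage, redundancy, repeatability, back-exchange) for a full-scale
simulated dataset; `examples/burst_halftime.py` and
`examples/gus_quantification.py` demonstrate the kinetics utilities.

The same pipeline runs from the shell on real or simulated state-data
CSVs:

```sh
hdx simulate run.yaml --seed 7 --out results/
hdx qc state_WT.csv
hdx diff state_WT.csv state_mutant.csv --level 98 --multiplier 2.32
```

outputs are plain CSVs (differential records, peptide labels, region
calls, and a Woods-plot data file with peptide spans, Δ%EX and the
±CL lines).

## Layout

- `src/hdxkit/simulate.py` — EX2 kinetic models, peptic-map digestion, centroid simulation
- `src/hdxkit/uptake.py` — %EX, nested replicate aggregation, back-exchange, QC metrics
- `src/hdxkit/differential.py` — repeatability, global confidence limit, classification, Welch option
- `src/hdxkit/kinetics.py` — burst time-to-half-maximum, standard curves, enzyme activity
- `src/hdxkit/io.py`, `pipeline.py`, `cli.py` — state-data CSV dialect, end-to-end runs, `hdx` CLI
- `docs/methods.md` — model assumptions, parameter defaults and numerical choices
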