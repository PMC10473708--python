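import numpy as np
import pandas as pd
import pytest

import hdxkit as h


@pytest.fixture(scope="session")
def small_sequence():
    return h.random_protein(60, seed=101)


@pytest.fixture(scope="session")
def small_model(small_sequence):
    return h.build_exchange_model(small_sequence, seed=102)


@pytest.fixture(scope="session")
def schedule():
    return h.LabelingSchedule()


@pytest.fixture(scope="session")
def small_peptides(small_sequence):
    return h.digest(small_sequence, 10, 2.0, seed=103)


@pytest.fixture(scope="session")
def noiseless_model(small_model):
    from dataclasses import replace

    return replace(small_model, noise_tech_da=0.0, noise_bio_da=0.0)


@pytest.fixture(scope="session")
def noisy_table(small_model, small_peptides, schedule):
    return h.simulate_centroids(
        small_model, small_peptides, schedule, state="WT", seed=104
    ).table


def make_measurement_table(
    uptakes_by_bio,
    *,
    m0=1000.0,
    mf=1010.0,
    exposure=60.0,
    state="WT",
    start=1,
    sequence="AAAAAAAAAAA",
    max_uptake=10,
    n_tech_controls=1,
):
    """Hand-built centroid table for one peptide x one exposure.

    ``uptakes_by_bio`` is a list (per biological replicate) of lists of
    technical uptake values in Da.  Control rows are exact (m0, mf).
    """
    base = dict(
        protein="p",
        start=start,
        end=start + len(sequence) - 1,
        sequence=sequence,
        max_uptake=max_uptake,
        state=state,
    )
    rows = []
    for ib, techs in enumerate(uptakes_by_bio, start=1):
        for jt, u in enumerate(techs, start=1):
            rows.append(
                dict(
                    base,
                    exposure_s=exposure,
                    is_fd=False,
                    bio_rep=ib,
                    tech_rep=jt,
                    centroid_da=m0 + u,
                )
            )
    for ib in range(1, len(uptakes_by_bio) + 1):
        for jt in range(1, n_tech_controls + 1):
            rows.append(
                dict(
                    base,
                    exposure_s=0.0,
                    is_fd=False,
                    bio_rep=ib,
                    tech_rep=jt,
                    centroid_da=m0,
                )
            )
            rows.append(
                dict(
                    base,
                    exposure_s=np.nan,
                    is_fd=True,
                    bio_rep=ib,
                    tech_rep=jt,
                    centroid_da=mf,
                )
            )
    return pd.DataFrame(rows)


def make_summary_frame(pct_means, sd_pct, *, state="A", exposures=(60.0,), sd_da=0.1):
    """Synthetic uptake-summary frame: one row per peptide x exposure.

    ``pct_means`` has shape (n_peptides, n_exposures) or (n_peptides,).
    """
    pct = np.atleast_2d(np.asarray(pct_means, dtype=float))
    if pct.shape[1] != len(exposures):
        pct = pct.reshape(-1, len(exposures))
    n_pep = pct.shape[0]
    rows = []
    for i in range(n_pep):
        start = i * 20 + 1
        for j, t in enumerate(exposures):
            rows.append(
                dict(
                    protein="p",
                    start=start,
                    end=start + 9,
                    sequence="A" * 10,
                    max_uptake=9,
                    state=state,
                    exposure_s=float(t),
                    mean_uptake=pct[i, j] / 100 * 5.0,
                    sd_uptake=sd_da,
                    mean_pct_ex=pct[i, j],
                    sd_pct_ex=sd_pct,
                    n_bio=3,
                    n_total=9,
                    m0=1000.0,
                    mf=1005.0,
                )
            )
    return pd.DataFrame(rows)
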