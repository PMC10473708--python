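"""EX2 simulator: ground-truth construction, digestion, centroid tables."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from pyteomics import mass as ptmass

import hdxkit as h
from hdxkit.errors import CoordinateError, InputError


class TestBuildExchangeModel:
    def test_uniform_when_no_regions_and_degenerate_mixture(self):
        seq = "A" * 30
        model = h.build_exchange_model(
            seq, rate_mixture=((1.0, -2.0, 0.0),), seed=0
        )
        rates = model.log10_k_obs[model.exchangeable_mask()]
        assert np.allclose(rates, -2.0)

    def test_protection_region_shifts_rates_100x(self, small_sequence):
        base = h.build_exchange_model(small_sequence, seed=7)
        shifted = h.build_exchange_model(
            small_sequence, [(10, 20, 2.0)], seed=7
        )
        mask = base.exchangeable_mask()
        inside = np.zeros(len(small_sequence), bool)
        inside[9:20] = True
        np.testing.assert_allclose(
            shifted.log10_k_obs[mask & inside],
            base.log10_k_obs[mask & inside] - 2.0,
        )
        np.testing.assert_array_equal(
            shifted.log10_k_obs[mask & ~inside], base.log10_k_obs[mask & ~inside]
        )

    def test_seeded_determinism(self, small_sequence):
        a = h.build_exchange_model(small_sequence, seed=1)
        b = h.build_exchange_model(small_sequence, seed=1)
        c = h.build_exchange_model(small_sequence, seed=2)
        np.testing.assert_array_equal(a.log10_k_obs, b.log10_k_obs)
        assert not np.array_equal(
            a.log10_k_obs[a.exchangeable_mask()],
            c.log10_k_obs[c.exchangeable_mask()],
        )

    def test_no_rate_at_position1_or_proline(self):
        model = h.build_exchange_model("MKPLSV", seed=0)
        assert np.isnan(model.log10_k_obs[0])
        assert np.isnan(model.log10_k_obs[2])  # the proline

    def test_errors(self, small_sequence):
        with pytest.raises(InputError):
            h.build_exchange_model("")
        with pytest.raises(CoordinateError):
            h.build_exchange_model(small_sequence, [(50, 100, 1.0)])


class TestPerturbModel:
    def test_zero_delta_is_identity(self, small_model):
        out = h.perturb_model(small_model, (10, 20), 0.0)
        np.testing.assert_array_equal(out.log10_k_obs, small_model.log10_k_obs)

    def test_deprotection_only_inside_region(self, small_model):
        out = h.perturb_model(small_model, (40, 55), 2.0)
        mask = small_model.exchangeable_mask()
        inside = np.zeros(small_model.n_residues, bool)
        inside[39:55] = True
        np.testing.assert_allclose(
            out.log10_k_obs[mask & inside],
            small_model.log10_k_obs[mask & inside] + 2.0,
        )
        np.testing.assert_array_equal(
            out.log10_k_obs[~inside], small_model.log10_k_obs[~inside]
        )

    def test_input_model_unmodified(self, small_model):
        before = small_model.log10_k_obs.copy()
        h.perturb_model(small_model, (10, 20), 3.0)
        np.testing.assert_array_equal(small_model.log10_k_obs, before)

    def test_chained_perturbations_add_in_log_space(self, small_model):
        twice = h.perturb_model(
            h.perturb_model(small_model, (10, 20), 1.0), (10, 20), 1.0
        )
        once = h.perturb_model(small_model, (10, 20), 2.0)
        np.testing.assert_allclose(twice.log10_k_obs, once.log10_k_obs)

    def test_out_of_bounds(self, small_model):
        with pytest.raises(CoordinateError):
            h.perturb_model(small_model, (0, 10), 1.0)


class TestDigest:
    def test_explicit_spans_hand_count(self):
        seq = h.random_protein(20, seed=5, proline_fraction=0.0)
        peps = h.digest(seq, spans=[(1, 10), (6, 15), (11, 20)])
        assert [(p.start, p.end) for p in peps] == [(1, 10), (6, 15), (11, 20)]
        assert np.mean([p.length for p in peps]) == 10.0
        covered = set()
        for p in peps:
            covered.update(range(p.start, p.end + 1))
        assert covered == set(range(1, 21))

    def test_minimal_redundancy_tiling(self):
        seq = h.random_protein(200, seed=6)
        peps = h.digest(seq, 10, 1.0, seed=7)
        # brute-force per-residue depth on the emitted map
        depth = np.zeros(200, int)
        for p in peps:
            depth[p.start - 1 : p.end] += 1
        assert depth.min() >= 1
        assert 1.0 <= depth.mean() <= 1.5

    def test_targets_hit_at_scale(self):
        seq = h.random_protein(348, seed=8)
        peps = h.digest(seq, 13, 5.5, seed=9)
        lengths = [p.length for p in peps]
        assert abs(np.mean(lengths) - 13) / 13 < 0.15
        depth = np.zeros(348, int)
        for p in peps:
            depth[p.start - 1 : p.end] += 1
        assert depth.min() >= 1  # 100% coverage
        assert 5.0 <= depth.mean() <= 6.5

    def test_exchangeable_coverage_is_complete(self, small_sequence):
        # every amide-bearing residue sits at position >= 2 of some peptide
        peps = h.digest(small_sequence, 10, 1.0, seed=11)
        ok = set()
        for p in peps:
            ok.update(range(p.start + 1, p.end + 1))
        for pos in range(2, len(small_sequence) + 1):
            if small_sequence[pos - 1] != "P":
                assert pos in ok

    def test_seeded_determinism(self, small_sequence):
        a = h.digest(small_sequence, 10, 2.0, seed=3)
        b = h.digest(small_sequence, 10, 2.0, seed=3)
        assert a == b

    def test_sequence_shorter_than_target(self):
        with pytest.raises(InputError):
            h.digest("AAAA", 10, 2.0)


class TestSimulateCentroids:
    def test_single_amide_half_life_closed_form(self):
        # one exchangeable amide with k*t = ln 2 -> f_D/2 deuterons
        seq = "AG"
        t = 100.0
        k = np.log(2) / t
        model = h.ExchangeModel(
            sequence=seq,
            log10_k_obs=np.array([np.nan, np.log10(k)]),
            f_D=0.95,
            b=0.0,
            noise_tech_da=0.0,
            noise_bio_da=0.0,
        )
        peps = [h.make_peptide("p", 1, seq)]
        sched = h.LabelingSchedule(exposures=(t,), n_bio=1, n_tech=1)
        sim = h.simulate_centroids(model, peps, sched, seed=0)
        row = sim.table[(~sim.table.is_fd) & (sim.table.exposure_s == t)].iloc[0]
        m0 = sim.table[sim.table.exposure_s == 0].iloc[0].centroid_da
        assert row.centroid_da - m0 == pytest.approx(1.00628 * 0.95 / 2, rel=1e-12)

    def test_infinite_protection_gives_zero_uptake(self, small_sequence, schedule):
        model = h.build_exchange_model(
            small_sequence,
            rate_mixture=((1.0, -30.0, 0.0),),
            noise_tech_da=0.0,
            noise_bio_da=0.0,
        )
        peps = h.digest(small_sequence, 10, 1.5, seed=1)
        sim = h.simulate_centroids(model, peps, schedule, seed=0)
        assert np.allclose(sim.truth.uptake_da, 0.0)

    def test_plateau_equals_fd(self, small_sequence):
        model = h.build_exchange_model(
            small_sequence,
            rate_mixture=((1.0, -1.0, 0.2),),
            b=0.3,
            noise_tech_da=0.0,
            noise_bio_da=0.0,
            seed=2,
        )
        peps = h.digest(small_sequence, 10, 1.5, seed=1)
        sched = h.LabelingSchedule(exposures=(10.0, 1e4), n_bio=1, n_tech=1)
        sim = h.simulate_centroids(model, peps, sched, seed=0)
        late = sim.table[(~sim.table.is_fd) & (sim.table.exposure_s == 1e4)]
        fd = sim.table[sim.table.is_fd]
        merged = late.merge(fd, on=["start", "end"], suffixes=("_t", "_f"))
        np.testing.assert_allclose(
            merged.centroid_da_t, merged.centroid_da_f, rtol=1e-9
        )

    def test_monotone_saturation_when_noiseless(
        self, noiseless_model, small_peptides, schedule
    ):
        sim = h.simulate_centroids(
            noiseless_model, small_peptides, schedule, seed=0
        )
        for _, g in sim.truth.groupby(["start", "end"]):
            u = g.sort_values("exposure_s").uptake_da.to_numpy()
            assert np.all(np.diff(u) >= -1e-12)

    @pytest.mark.parametrize("b", [0.0, 0.25, 0.49])
    def test_percent_exchange_independent_of_back_exchange(
        self, noiseless_model, small_peptides, schedule, b
    ):
        ref = h.simulate_centroids(
            replace(noiseless_model, b=0.0), small_peptides, schedule, seed=0
        )
        sim = h.simulate_centroids(
            replace(noiseless_model, b=b), small_peptides, schedule, seed=0
        )
        ref_pct = h.aggregate_replicates(ref.table)["mean_pct_ex"]
        pct = h.aggregate_replicates(sim.table)["mean_pct_ex"]
        np.testing.assert_allclose(pct, ref_pct, rtol=1e-9)

    def test_sum_rule_against_per_residue_brute_force(
        self, noiseless_model, small_peptides
    ):
        model = noiseless_model
        sched = h.LabelingSchedule(exposures=(60.0,), n_bio=1, n_tech=1)
        sim = h.simulate_centroids(model, small_peptides, sched, seed=0)
        for pep in small_peptides:
            acc = 0.0
            for pos in range(pep.start + 1, pep.end + 1):
                aa = model.sequence[pos - 1]
                if aa == "P":
                    continue
                k = 10.0 ** model.log10_k_obs[pos - 1]
                acc += model.f_D * (1 - np.exp(-k * 60.0))
            expected = acc * (1 - model.b) * model.mass_shift_per_D
            got = sim.truth[
                (sim.truth.start == pep.start) & (sim.truth.end == pep.end)
            ].uptake_da.iloc[0]
            assert got == pytest.approx(expected, rel=1e-12)

    def test_bit_reproducible(self, small_model, small_peptides, schedule):
        a = h.simulate_centroids(small_model, small_peptides, schedule, seed=42)
        b = h.simulate_centroids(small_model, small_peptides, schedule, seed=42)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_peptide_outside_model_range(self, small_model, schedule):
        bad = [h.PeptideRecord("p", 55, 70, "A" * 16, 15)]
        with pytest.raises((CoordinateError, InputError)):
            h.simulate_centroids(small_model, bad, schedule, seed=0)


def test_schedule_validation():
    with pytest.raises(InputError):
        h.LabelingSchedule(exposures=(10.0, 10.0))
    with pytest.raises(InputError):
        h.LabelingSchedule(exposures=(-1.0, 10.0))
    with pytest.raises(InputError):
        h.LabelingSchedule(n_bio=0)


def test_ground_truth_frame_numbering(small_model):
    gt = h.ground_truth_frame(small_model, "WT")
    assert gt.residue.iloc[0] == small_model.residue_offset
    assert len(gt) == small_model.n_residues
    assert not gt.loc[gt.exchangeable, "log10_k_obs"].isna().any()
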