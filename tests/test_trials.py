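"""Generator tests: roster constraints, closed-form means, censoring, I/O."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from kincontest.trials import (
    CountModelParams,
    DyadSample,
    GeneratingParams,
    LatencyParams,
    TrialDesign,
    calibrate_baseline_hazard,
    generate_activity,
    generate_aggression,
    generate_latency,
    generate_trials,
    read_trials,
    sample_dyads,
    trials_to_frames,
    write_trials,
)


def _dyad(level="non_sibling", mass_large=0.3, mass_small=0.1):
    return DyadSample(
        pair_id="p1",
        relatedness_level=level,
        r={"non_sibling": 0.0, "half_sibling": 0.25, "sibling": 0.5}[level],
        family_large="famA",
        family_small="famB",
        sire_large="sireA",
        sire_small="sireB",
        mass_large=mass_large,
        mass_small=mass_small,
    )


NO_RE = {"pair": 0.0, "family_large": 0.0, "family_small": 0.0}


class TestRoster:
    def test_default_design_yields_45_dyads(self):
        dyads = sample_dyads(TrialDesign(), 1)
        assert len(dyads) == 45
        levels = pd.Series([d.relatedness_level for d in dyads]).value_counts()
        assert set(levels) == {15}

    def test_mass_constraints_enforced(self):
        design = TrialDesign()
        for d in sample_dyads(design, 2):
            assert design.mass_range[0] <= d.mass_small < d.mass_large <= design.mass_range[1]
            assert design.mass_diff_range[0] <= d.mass_diff <= design.mass_diff_range[1]

    def test_family_structure_matches_relatedness(self):
        for d in sample_dyads(TrialDesign(n_per_level=3), 3):
            if d.relatedness_level == "sibling":
                assert d.family_large == d.family_small
            elif d.relatedness_level == "half_sibling":
                assert d.family_large != d.family_small
                assert d.sire_large == d.sire_small
            else:
                assert d.family_large != d.family_small
                assert d.sire_large != d.sire_small

    def test_deterministic_given_seed(self):
        assert sample_dyads(TrialDesign(), 7) == sample_dyads(TrialDesign(), 7)

    def test_infeasible_mass_constraints_rejected(self):
        with pytest.raises(ValueError):
            TrialDesign(mass_range=(0.04, 0.10), mass_diff_range=(0.2, 0.3))


class TestCountGenerators:
    def test_poisson_mean_matches_exposure(self, rng):
        # all coefficients zero: mean = duration * e^0
        params = CountModelParams(intercept=0.0)
        d = _dyad()
        counts = [
            generate_aggression(d, params, NO_RE, rng, duration=3600.0,
                                n_scans=10**9)[0][0]
            for _ in range(3000)
        ]
        assert np.mean(counts) == pytest.approx(3600.0, rel=0.02)

    def test_baseline_aggression_rate(self, rng):
        # intercept -8.03 over a 60-min trial implies ~1.18 expected events
        params = CountModelParams(intercept=-8.03)
        d = _dyad()
        counts = [
            generate_aggression(d, params, NO_RE, rng, duration=3600.0,
                                n_scans=240)[0][0]
            for _ in range(10_000)
        ]
        assert np.mean(counts) == pytest.approx(3600.0 * math.exp(-8.03), rel=0.03)

    def test_zero_duration_yields_zero_counts(self, rng):
        params = CountModelParams(intercept=2.0)
        out, caps = generate_aggression(_dyad(), params, NO_RE, rng, duration=0.0)
        assert out == (0, 0) and caps == 0

    def test_size_rate_ratio_recovered_in_means(self, rng):
        # experimental activity size effect: large/small mean ratio 3.46
        params = CountModelParams(
            intercept=math.log(0.005), size_large=math.log(3.46), dispersion=1.86
        )
        d = _dyad()
        draws = np.array(
            [
                generate_activity(d, params, NO_RE, rng, duration=3600.0,
                                  n_scans=10**9)[0]
                for _ in range(10_000)
            ]
        )
        ratio = draws[:, 0].mean() / draws[:, 1].mean()
        assert ratio == pytest.approx(3.46, rel=0.05)

    def test_large_dispersion_approaches_poisson(self, rng):
        params = CountModelParams(intercept=math.log(20 / 3600), dispersion=1e9)
        d = _dyad()
        counts = np.array(
            [
                generate_activity(d, params, NO_RE, rng, duration=3600.0,
                                  n_scans=10**9)[0][0]
                for _ in range(10_000)
            ]
        )
        assert counts.var() / counts.mean() == pytest.approx(1.0, rel=0.06)

    def test_counts_never_exceed_scan_budget(self):
        design = TrialDesign(n_per_level=30)
        recs = generate_trials(design, GeneratingParams.default(), 5)
        for r in recs:
            n_exp = int(r.trial_duration / design.scan_interval)
            assert max(r.activity_acclimation) <= design.acclimation_scans
            assert max(r.activity_experimental) <= n_exp
            assert max(r.aggression) <= n_exp


class TestLatencyGenerator:
    def test_exponential_mean(self, rng):
        lam = 1e-3
        params = LatencyParams(baseline_hazard=lam)
        times = [
            generate_latency(_dyad(), params, rng, trial_duration=math.inf)[0]
            for _ in range(10_000)
        ]
        assert np.mean(times) == pytest.approx(1.0 / lam, rel=0.05)

    def test_zero_baseline_censors_everything(self, rng):
        params = LatencyParams(baseline_hazard=0.0)
        t, censored, biter = generate_latency(_dyad(), params, rng)
        assert censored and t == 3600.0 and biter == "none"

    def test_interaction_hazard_ratio(self, rng):
        # only the siblings x mass-difference term: hazard ratio between
        # sibling dyads at mass_diff 0.30 vs 0.03 is e^(16.32 * 0.27)
        params = LatencyParams(siblings_mass_diff=16.32, baseline_hazard=1e-3)
        big = _dyad("sibling", 0.34, 0.04)
        small = _dyad("sibling", 0.07, 0.04)
        t_big = np.mean(
            [generate_latency(big, params, rng, math.inf)[0] for _ in range(10_000)]
        )
        t_small = np.mean(
            [generate_latency(small, params, rng, math.inf)[0] for _ in range(10_000)]
        )
        assert t_small / t_big == pytest.approx(math.exp(16.32 * 0.27), rel=0.06)

    def test_censoring_fraction_monotone_in_baseline(self):
        design = TrialDesign(n_per_level=60)
        fracs = []
        for lam in (1e-5, 1e-4, 1e-3):
            params = dataclasses.replace(
                GeneratingParams.default(),
                latency=LatencyParams(baseline_hazard=lam),
            )
            recs = generate_trials(design, params, 9)
            fracs.append(np.mean([r.censored for r in recs]))
        assert fracs[0] > fracs[1] > fracs[2]

    def test_calibrated_baseline_hits_target_event_fraction(self):
        params = GeneratingParams.default()
        design = TrialDesign(n_per_level=1500)
        lam = calibrate_baseline_hazard(params.latency, design,
                                        target_event_fraction=0.85)
        params = dataclasses.replace(
            params,
            latency=dataclasses.replace(params.latency, baseline_hazard=lam),
        )
        frac = np.mean(
            [
                not r.censored
                for seed in (13, 14)
                for r in generate_trials(design, params, seed)
            ]
        )
        assert frac == pytest.approx(0.85, abs=0.02)


class TestDatasetAndIO:
    def test_determinism_and_replicate_difference(self, default_params):
        design = TrialDesign(n_per_level=4)
        a = generate_trials(design, default_params, 21)
        b = generate_trials(design, default_params, 21)
        c = generate_trials(design, default_params, 22)
        assert a == b
        assert a != c

    def test_frame_shapes(self, default_params):
        recs = generate_trials(TrialDesign(), default_params, 1)
        counts, latency = trials_to_frames(recs)
        assert len(latency) == 45
        assert len(counts) == 180  # 2 tadpoles x 2 phases x 45 dyads
        assert (counts.groupby("phase").size() == 90).all()

    def test_round_trip(self, tmp_path, default_params):
        design = TrialDesign(n_per_level=3)
        recs = generate_trials(design, default_params, 4)
        write_trials(recs, tmp_path, design=design, meta={"seed": 4})
        counts, latency = read_trials(tmp_path)
        counts0, latency0 = trials_to_frames(recs, design.acclimation_duration)
        pd.testing.assert_frame_equal(counts, counts0, check_dtype=False)
        pd.testing.assert_frame_equal(latency, latency0, check_dtype=False)

    def test_empty_record_list_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_trials([], tmp_path)

    def test_early_termination_truncates_duration(self, default_params):
        design = TrialDesign(n_per_level=20, early_termination_prob=0.5)
        recs = generate_trials(design, default_params, 6)
        durs = {r.trial_duration for r in recs}
        assert any(d < design.experimental_duration for d in durs)
        assert all(0 < d <= design.experimental_duration for d in durs)
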