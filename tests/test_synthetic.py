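"""Synthetic cohort generator: determinism, targets, dropout, round trips."""

import numpy as np
import pandas as pd
import pytest

from paeecal.calorimetry import steady_state_mean, weir_ee
from paeecal.synthetic import (
    GroupSpec,
    NoiseConfig,
    TaskSpec,
    apply_dropout,
    default_group_specs,
    default_targets,
    default_tasks,
    default_true_models,
    generate_cohort,
    generate_dataset,
    noiseless_dataset,
    read_dataset,
    simulate_activity,
    write_dataset,
)


def _spec(**over):
    base = dict(label="control", n=4, rmr_mean=1800, rmr_sd=200, rest_hr_mean=60,
                rest_hr_sd=5, body_mass_mean=80, body_mass_sd=8)
    base.update(over)
    return GroupSpec(**base)


class TestGenerateCohort:
    def test_default_study_has_28_participants_in_three_groups(self):
        cohort = generate_cohort(default_group_specs(), seed=1)
        assert len(cohort) == 28
        sizes = pd.Series([p.group for p in cohort]).value_counts()
        assert sizes.to_dict() == {"bilateral": 10, "unilateral": 9, "control": 9}

    def test_zero_sd_gives_degenerate_profiles(self):
        spec = _spec(rmr_sd=0, rest_hr_sd=0, body_mass_sd=0)
        cohort = generate_cohort([spec], seed=3, economy_sd=0.0)
        for p in cohort:
            assert (p.rmr, p.rest_hr, p.body_mass, p.economy_factor) == (
                1800, 60, 80, 1.0,
            )

    def test_seed_determinism(self):
        a = generate_cohort(default_group_specs(), seed=5)
        b = generate_cohort(default_group_specs(), seed=5)
        c = generate_cohort(default_group_specs(), seed=6)
        assert a == b
        assert a != c

    def test_sample_means_converge_to_spec_means(self):
        spec = _spec(n=4000)
        cohort = generate_cohort([spec], seed=0)
        rmr = np.array([p.rmr for p in cohort])
        ef = np.array([p.economy_factor for p in cohort])
        assert rmr.mean() == pytest.approx(1800, abs=4 * 200 / np.sqrt(4000))
        assert ef.mean() == pytest.approx(1.0, abs=0.02)  # lognormal mean 1

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            _spec(n=0)
        with pytest.raises(ValueError):
            _spec(rmr_sd=-1)
        with pytest.raises(ValueError):
            generate_cohort([], seed=0)


class TestSimulateActivity:
    def setup_method(self):
        self.tasks = {t.name: t for t in default_tasks()}
        self.targets = default_targets()
        self.models = default_true_models()

    def _participant(self):
        return generate_cohort([_spec(n=1)], seed=2, economy_sd=0.0)[0]

    def test_noiseless_weir_round_trip_is_exact(self):
        import dataclasses

        p = self._participant()
        tm = dataclasses.replace(self.models["control"], residual_sd=0.0)
        gas, epochs = simulate_activity(
            p, self.tasks["tm_0.89"], tm, self.targets[("control", "tm_0.89")],
            seed=0, noise=NoiseConfig.zero(),
        )
        g = steady_state_mean(gas, 5.0)
        tee = weir_ee(g["vo2_l_min"], g["vco2_l_min"])
        target = self.targets[("control", "tm_0.89")]
        expected_tee = tm.paee(target.pac_mean,
                               p.rest_hr + target.hr_mean - target.rest_hr_mean
                               ) + p.rmr / 1440.0
        assert tee == pytest.approx(expected_tee, abs=1e-9)

    def test_rest_task_is_flat_at_resting_values(self):
        p = self._participant()
        gas, epochs = simulate_activity(
            p, self.tasks["rest"], self.models["control"],
            self.targets[("control", "rest")], seed=0, noise=NoiseConfig.zero(),
        )
        assert (epochs["pac_counts_min"] == 0).all()
        assert np.allclose(epochs["hr_bpm"], p.rest_hr)
        assert weir_ee(gas["vo2_l_min"].iloc[-1], gas["vco2_l_min"].iloc[-1]) == \
            pytest.approx(p.rmr / 1440.0, abs=1e-9)

    def test_epoch_grid_and_transient_shape(self):
        p = self._participant()
        gas, epochs = simulate_activity(
            p, self.tasks["tm_0.48"], self.models["control"],
            self.targets[("control", "tm_0.48")], seed=0, noise=NoiseConfig.zero(),
        )
        assert np.array_equal(epochs["t_s"], np.arange(0, 300, 30.0))
        plateau = epochs[epochs["t_s"] >= 180]["pac_counts_min"]
        assert plateau.nunique() == 1  # stationary after the onset transient
        ramp = epochs[epochs["t_s"] < 180]["pac_counts_min"]
        assert (np.diff(ramp) > 0).all()  # monotone exponential approach

    def test_dropout_yields_empty_streams(self):
        p = self._participant()
        gas, epochs = simulate_activity(
            p, self.tasks["tm_1.34"], self.models["control"],
            self.targets[("control", "tm_1.34")], seed=0, completed=False,
        )
        assert gas.empty and epochs.empty
        assert list(epochs.columns) == ["t_s", "pac_counts_min", "hr_bpm"]

    def test_monte_carlo_pac_mean_matches_configured_target(self):
        # 200 unilateral participant-tasks at 0.48 m/s: mean PAC within 2 SEM
        specs = [GroupSpec(label="unilateral", n=200, rmr_mean=1776, rmr_sd=269,
                           rest_hr_mean=66, rest_hr_sd=11, body_mass_mean=81,
                           body_mass_sd=11)]
        cohort = generate_cohort(specs, seed=42)
        noise = NoiseConfig()
        pacs = []
        for p in cohort:
            _, epochs = simulate_activity(
                p, self.tasks["tm_0.48"], self.models["unilateral"],
                self.targets[("unilateral", "tm_0.48")], seed=42, noise=noise,
            )
            pacs.append(steady_state_mean(epochs, 5.0)["pac_counts_min"])
        pacs = np.asarray(pacs)
        sem = pacs.std(ddof=1) / np.sqrt(len(pacs))
        assert abs(pacs.mean() - 2643.0) <= 2 * sem

    def test_substream_determinism(self):
        p = self._participant()
        args = (p, self.tasks["tm_0.67"], self.models["control"],
                self.targets[("control", "tm_0.67")])
        g1, e1 = simulate_activity(*args, seed=9)
        g2, e2 = simulate_activity(*args, seed=9)
        g3, _ = simulate_activity(*args, seed=10)
        pd.testing.assert_frame_equal(g1, g2)
        pd.testing.assert_frame_equal(e1, e2)
        assert not g1.equals(g3)


class TestApplyDropout:
    def _tasks(self, probs):
        return [TaskSpec(name=f"v{i}", velocity=0.5 + 0.2 * i,
                         completion_prob=probs) for i in range(4)]

    def test_certain_completion(self):
        cohort = generate_cohort([_spec(n=5)], seed=0)
        table = apply_dropout(cohort, self._tasks({}), seed=0)
        assert table.to_numpy().all()

    def test_bilateral_completion_rate_matches_probability(self):
        specs = [GroupSpec(label="bilateral", n=10, rmr_mean=1596, rmr_sd=178,
                           rest_hr_mean=67, rest_hr_sd=10, body_mass_mean=82,
                           body_mass_sd=19)]
        cohort = generate_cohort(specs, seed=0)
        task = [TaskSpec(name="tm_1.34", velocity=1.34,
                         completion_prob={"bilateral": 0.2})]
        completers = [
            apply_dropout(cohort, task, seed=s)["tm_1.34"].sum() for s in range(300)
        ]
        assert np.mean(completers) == pytest.approx(2.0, abs=0.25)

    def test_monotone_mode_never_recovers(self):
        cohort = generate_cohort([_spec(n=50)], seed=1)
        tasks = self._tasks({"control": 0.6})
        table = apply_dropout(cohort, tasks, seed=3, monotone=True)
        arr = table[[t.name for t in tasks]].to_numpy()
        for row in arr:
            if not row.all():
                first_false = np.argmin(row)
                assert not row[first_false:].any()

    def test_seed_reproducible(self):
        cohort = generate_cohort([_spec(n=10)], seed=0)
        tasks = self._tasks({"control": 0.5})
        pd.testing.assert_frame_equal(
            apply_dropout(cohort, tasks, seed=4), apply_dropout(cohort, tasks, seed=4)
        )


class TestDatasetRoundTrip:
    def test_write_read_round_trip(self, small_dataset, tmp_path):
        write_dataset(small_dataset, tmp_path)
        participants, epochs, gas = read_dataset(tmp_path)
        pd.testing.assert_frame_equal(participants, small_dataset.participants)
        pd.testing.assert_frame_equal(epochs, small_dataset.epochs)
        pd.testing.assert_frame_equal(gas, small_dataset.gas)

    def test_default_cohort_has_28_metadata_rows(self):
        ds = generate_dataset(seed=0)
        assert len(ds.participants) == 28

    def test_dropout_removes_streams_not_rows(self):
        ds = generate_dataset(seed=0)
        n_stages = ds.epochs.groupby(["id", "task"]).ngroups
        assert n_stages == int(ds.completion.to_numpy().sum())

    def test_full_dataset_is_pure_function_of_seed(self):
        a = generate_dataset(seed=13)
        b = generate_dataset(seed=13)
        pd.testing.assert_frame_equal(a.epochs, b.epochs)
        pd.testing.assert_frame_equal(a.gas, b.gas)

    def test_noiseless_dataset_group_means_hit_targets_exactly(self):
        ds = noiseless_dataset(seed=0)
        # every unilateral participant walks at exactly the target PAC
        uni = ds.epochs[(ds.epochs["task"] == "tm_0.48")
                        & ds.epochs["id"].str.startswith("uni")]
        plateau = uni[uni["t_s"] >= 180]
        assert np.allclose(plateau["pac_counts_min"], 2643.0)
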