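"""Contracts of the synthetic-data generators."""

import io

import numpy as np
import pandas as pd
import pytest

import strokerecovery as sr


def _csv_bytes(df):
    buf = io.StringIO()
    df.to_csv(buf, index=False)
    return buf.getvalue()


class TestBehaviorGenerator:
    def test_same_seed_byte_identical(self):
        cfg = sr.BehaviorSimConfig(seed=42)
        t1, u1 = sr.gen_behavior_cohort(cfg)
        t2, u2 = sr.gen_behavior_cohort(sr.BehaviorSimConfig(seed=42))
        assert _csv_bytes(t1) == _csv_bytes(t2)
        assert _csv_bytes(u1) == _csv_bytes(u2)
        t3, _ = sr.gen_behavior_cohort(sr.BehaviorSimConfig(seed=43))
        assert _csv_bytes(t1) != _csv_bytes(t3)

    def test_physical_ranges(self, default_cohort):
        trials, _ = default_cohort
        grid = trials[trials.test == "grid_walk"]
        assert (grid.foot_faults <= grid.steps).all()
        assert (grid.foot_faults >= 0).all() and (grid.steps > 0).all()
        beam = trials[trials.test == "rotating_beam"]
        assert (beam.duration_s > 0).all()
        assert (beam.hindlimb_drops >= 0).all()
        assert grid[["duration_s", "distance_cm"]].isna().all().all()
        assert beam[["steps", "foot_faults"]].isna().all().all()
        ro = sr.daily_readouts(trials)
        ff = ro[ro.readout == "foot_fault_pct"]["value"]
        assert ((ff >= 0) & (ff <= 100)).all()
        assert (ro[ro.readout == "speed_cm_s"]["value"] > 0).all()

    def test_cohort_composition_and_truth_separation(self, default_cohort):
        trials, truth = default_cohort
        per_animal = trials.groupby("animal_id")[["cohort", "latent_class"]].first()
        assert (per_animal.cohort == "stroke").sum() == 30
        assert (per_animal.cohort == "sham").sum() == 14
        stroke_truth = truth[truth.cohort == "stroke"]
        assert set(stroke_truth.latent_class) == {"good", "poor"}
        # exact allocation at frac_good = 0.5
        cls = stroke_truth[stroke_truth.readout == "foot_fault_pct"]["latent_class"]
        assert (cls == "good").sum() == 15

    def test_noiseless_speed_round_trip_exact(self, noiseless_cohort):
        trials, truth = noiseless_cohort
        ro = sr.daily_readouts(trials)
        tr = truth[(truth.readout == "speed_cm_s")].set_index("animal_id")
        sp = ro[(ro.readout == "speed_cm_s") & (ro.day == 14)]
        for row in sp.itertuples(index=False):
            t = tr.loc[row.animal_id]
            if t.cohort == "sham":
                expected = t.baseline
            else:
                expected = t.plateau + (t.initial - t.plateau) * np.exp(-t.k * 11.0)
            assert row.value == pytest.approx(expected, abs=1e-9)

    def test_noiseless_foot_faults_decay_one_phase(self):
        # all-good cohort: every stroke trajectory is an exact one-phase decay
        # of the latent percentage; integer back-derivation quantizes it by
        # at most 100 / (2 * min_steps)
        cfg = sr.BehaviorSimConfig(seed=2, frac_good=1.0, missing_rate=0.0)
        cfg = cfg.with_(trial_noise_sd={k: 0.0 for k in cfg.trial_noise_sd})
        trials, truth = sr.gen_behavior_cohort(cfg)
        ro = sr.daily_readouts(trials)
        tol = 100.0 / (2 * cfg.steps_range[0])
        tr = truth[truth.readout == "foot_fault_pct"].set_index("animal_id")
        ff = ro[(ro.cohort == "stroke") & (ro.readout == "foot_fault_pct") & (ro.day >= 3)]
        for row in ff.itertuples(index=False):
            t = tr.loc[row.animal_id]
            latent = t.plateau + (t.initial - t.plateau) * np.exp(-t.k * (row.day - 3))
            assert abs(row.value - latent) <= tol

    def test_classification_days_protected_under_missingness(self):
        cfg = sr.BehaviorSimConfig(seed=5, missing_rate=0.4)
        trials, _ = sr.gen_behavior_cohort(cfg)
        present = trials.groupby(["animal_id", "test"])["day"].apply(set)
        for days in present:
            assert {3, 7, 14} <= days
        # at 40% missingness some non-protected day must be gone
        n_expected = trials.animal_id.nunique() * len(cfg.days)
        assert trials.groupby(["animal_id", "day"]).ngroups < n_expected

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="frac_good"):
            sr.BehaviorSimConfig(frac_good=1.5)
        with pytest.raises(ValueError, match="days"):
            sr.BehaviorSimConfig(days=())
        with pytest.raises(ValueError, match="increasing"):
            sr.BehaviorSimConfig(days=(-3, 7, 3))
        with pytest.raises(ValueError, match="trial_noise_sd"):
            sr.BehaviorSimConfig(trial_noise_sd={"foot_fault_pct": -1.0,
                                                 "speed_cm_s": 0.5, "hl_drops": 0.8})


class TestQpcrGenerator:
    def test_same_seed_byte_identical(self):
        d1 = sr.gen_qpcr_dataset(sr.QpcrSimConfig(seed=9))
        d2 = sr.gen_qpcr_dataset(sr.QpcrSimConfig(seed=9))
        assert _csv_bytes(d1.cq) == _csv_bytes(d2.cq)
        assert _csv_bytes(d1.dilution) == _csv_bytes(d2.dilution)

    def test_design_layout(self):
        ds = sr.gen_qpcr_dataset(sr.QpcrSimConfig(seed=0))
        cq = ds.cq
        assert set(cq.gene) == {"Adora2a", "Pde10a", "Drd2", "Lingo1", "Atrx",
                                "BDNF", "Gapdh"}
        assert set(cq.region) == {"MOp", "SSp", "Str", "TH"}
        assert set(cq.hemisphere) == {"il", "cl"}
        assert set(cq.endpoint_day) == {14, 28, 56}
        # reference gene present for every (animal, region, hemisphere, endpoint)
        cells = cq.groupby(["animal_id", "region", "hemisphere", "endpoint_day"])
        assert all("Gapdh" in set(g.gene) for _, g in cells)
        n14 = cq[cq.endpoint_day == 14].groupby("group")["animal_id"].nunique()
        assert n14.to_dict() == {"good": 5, "poor": 4, "sham": 5}

    def test_ntc_rows_flagged(self):
        ds = sr.gen_qpcr_dataset(sr.QpcrSimConfig(seed=0))
        dil = ds.dilution
        assert ((dil.input_ng == 0) == dil.is_ntc).all()
        assert dil[dil.is_ntc]["cq"].isna().all()
        assert (dil[~dil.is_ntc]["cq"] > 0).all()

    def test_reference_gene_unregulated(self):
        ds = sr.gen_qpcr_dataset(sr.QpcrSimConfig(
            seed=1, replicate_sd=0.0, animal_sd=0.0))
        ref = ds.cq[ds.cq.gene == "Gapdh"]
        assert ref.groupby(["region", "hemisphere"])["cq"].nunique().eq(1).all()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="efficiency"):
            sr.QpcrSimConfig(efficiency_true={**sr.simulate.default_efficiencies(),
                                              "Gapdh": 2.5})
        with pytest.raises(ValueError, match="fold change"):
            sr.QpcrSimConfig(group_fold_change={("Drd2", "MOp", "cl", 14, "poor"): -1.0})
        with pytest.raises(ValueError, match="unregulated"):
            sr.QpcrSimConfig(group_fold_change={("Gapdh", "MOp", "cl", 14, "poor"): 2.0})
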