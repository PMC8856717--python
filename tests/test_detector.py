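import dataclasses

import numpy as np
import pytest

from swdpredict import (DetectorConfig, calibrate_threshold,
                        default_threshold_grid, detect_events,
                        enumerate_site_combinations, gaers_spec,
                        generate_recording, make_combination,
                        sweep_thresholds)
from swdpredict.detector import _alarm_indices, combination_group
from swdpredict.labeling import label_detections
from swdpredict.signal_io import M2_SITES, S1_SITES, THALAMIC_SITES
from swdpredict.spectral import channel_product

ALL_SITES = list(S1_SITES + THALAMIC_SITES + M2_SITES)


class TestSiteCombinations:
    def test_full_montage_counts(self):
        combos = enumerate_site_combinations(ALL_SITES)
        triples = [c for c in combos if len(c.sites) == 3]
        pairs = [c for c in combos if len(c.sites) == 2]
        assert len(triples) == 57
        assert len(pairs) == 28
        assert len(combos) == 85

    def test_group_tags(self):
        assert combination_group(["S1_L4", "S1_L5"]) == "CC"
        assert combination_group(["S1_L6", "VPM", "rRTN"]) == "CTT"
        assert combination_group(["S1_L4", "S1_L5", "Po"]) == "CCT"
        assert combination_group(M2_SITES) == "MCCC"
        assert combination_group(["VPM", "Po", "ATN"]) == "TTT"

    def test_two_sites_only(self):
        combos = enumerate_site_combinations(["S1_L4", "S1_L5"])
        assert len(combos) == 1
        assert combos[0].group == "CC"

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError):
            enumerate_site_combinations(["S1_L4", "S1_L4"])

    def test_group_counts_match_membership(self):
        combos = enumerate_site_combinations(ALL_SITES)
        by_group = {}
        for c in combos:
            by_group[c.group] = by_group.get(c.group, 0) + 1
        assert by_group == {"CCC": 1, "CCT": 15, "CTT": 30, "TTT": 10,
                            "MCCC": 1, "CC": 3, "CT": 15, "TT": 10}


class TestDetection:
    def test_zero_product_no_events(self, short_energies):
        prod = channel_product(short_energies, [0, 1, 2])
        zeroed = dataclasses.replace(prod, values=np.zeros_like(prod.values))
        events = detect_events(zeroed, short_energies,
                               DetectorConfig(threshold=0.1))
        assert events == []

    def test_sws_veto(self, short_energies):
        """Criterion 2: a dominant slow-wave product suppresses detection
        even when the precursor product clears the threshold."""
        prod = channel_product(short_energies, [0, 1, 2])
        vals = np.zeros_like(prod.values)
        bi = {b.name: i for i, b in enumerate(prod.bands)}
        vals[bi["precursor"]] = 2.0
        vals[bi["sws"]] = 6.0
        rigged = dataclasses.replace(prod, values=vals)
        assert detect_events(rigged, short_energies,
                             DetectorConfig(threshold=1.0)) == []

    def test_criteria_scale_invariance(self, short_energies, short_products):
        """Criteria 2 and 3 are threshold-free: scaling every band energy
        by the same constant changes only which criterion-1 thresholds
        fire, never the band comparisons."""
        prod = short_products
        scaled = dataclasses.replace(prod, values=4.0 * prod.values)
        cfg = DetectorConfig(threshold=0.3)
        cfg_scaled = DetectorConfig(threshold=4.0 * 0.3)
        t1 = [e.t for e in detect_events(prod, short_energies, cfg)]
        t2 = [e.t for e in detect_events(scaled, short_energies, cfg_scaled)]
        assert t1 == t2

    def test_event_features_shape(self, short_energies, short_products):
        events = detect_events(short_products, short_energies,
                               DetectorConfig(threshold=0.3))
        assert len(events) > 0
        for e in events:
            assert e.features.shape == (9,)
            assert np.all(e.features >= 0)
            assert e.products.shape == (3,)

    def test_alarm_separation_respects_refractory(self, short_energies,
                                                  short_products):
        events = detect_events(short_products, short_energies,
                               DetectorConfig(threshold=0.2,
                                              refractory_s=1.0))
        ts = np.array([e.t for e in events])
        assert np.all(np.diff(ts) >= 1.0 - 1e-9)

    def test_alarm_count_monotone_on_random_masks(self):
        """Dead-time alarm counts never increase when the super-threshold
        set shrinks (maximum-packing property), checked on random masks."""
        rng = np.random.default_rng(0)
        times = np.arange(2000) * 0.05
        x = rng.standard_normal(2000).cumsum()  # correlated series
        x -= x.min()
        for thr1, thr2 in [(1.0, 2.0), (5.0, 9.0), (0.1, 15.0)]:
            n1 = len(_alarm_indices(x > thr1, times, 1.0))
            n2 = len(_alarm_indices(x > thr2, times, 1.0))
            assert n1 >= n2

    def test_timestamp_mismatch_rejected(self, short_energies,
                                         short_products):
        shifted = dataclasses.replace(short_products,
                                      times=short_products.times + 0.5)
        with pytest.raises(ValueError):
            detect_events(shifted, short_energies,
                          DetectorConfig(threshold=0.1))


class TestSweep:
    def test_default_grid_sizes(self):
        assert len(default_threshold_grid(3)) == 14
        assert len(default_threshold_grid(2)) == 16
        with pytest.raises(ValueError):
            default_threshold_grid(4)

    def test_sweep_row_counts(self, short_gaers, short_energies, s1_triple):
        _, record, annotation = short_gaers
        sweep = sweep_thresholds(record, annotation, s1_triple,
                                 energies=short_energies)
        assert len(sweep) == 14
        assert (sweep["group"] == "CCC").all()
        pair = make_combination(["S1_L4", "S1_L5"])
        sweep2 = sweep_thresholds(record, annotation, pair,
                                  energies=short_energies)
        assert len(sweep2) == 16

    def test_sweep_monotone(self, short_gaers, short_energies, s1_triple):
        _, record, annotation = short_gaers
        sweep = sweep_thresholds(record, annotation, s1_triple,
                                 energies=short_energies)
        assert (sweep["sensitivity_pct"].diff().dropna() <= 1e-9).all()
        assert (sweep["n_fp"].diff().dropna() <= 0).all()

    def test_empty_grid_rejected(self, short_gaers, short_energies,
                                 s1_triple):
        _, record, annotation = short_gaers
        with pytest.raises(ValueError):
            sweep_thresholds(record, annotation, s1_triple, grid=[],
                             energies=short_energies)


class TestCalibration:
    def test_target_ordering(self, short_gaers, short_energies, s1_triple):
        """A lower sensitivity target admits a higher (or equal)
        threshold."""
        _, record, annotation = short_gaers
        cal60 = calibrate_threshold(record, annotation, s1_triple,
                                    target_sensitivity_pct=60,
                                    energies=short_energies)
        cal90 = calibrate_threshold(record, annotation, s1_triple,
                                    target_sensitivity_pct=90,
                                    energies=short_energies)
        assert cal60.threshold >= cal90.threshold
        assert cal60.sensitivity_pct >= 60
        assert cal90.sensitivity_pct >= 90 or not cal90.reached

    def test_calibrated_threshold_reaches_target(self, short_gaers,
                                                 short_energies, s1_triple):
        _, record, annotation = short_gaers
        cal = calibrate_threshold(record, annotation, s1_triple,
                                  target_sensitivity_pct=90,
                                  energies=short_energies)
        assert cal.reached
        prod = channel_product(short_energies, s1_triple.sites)
        events = detect_events(prod, short_energies,
                               DetectorConfig(threshold=cal.threshold))
        _, counts = label_detections(events, annotation)
        assert 100.0 * counts.n_tp_swd / counts.n_swd >= 90.0

    def test_too_few_swds_rejected(self, s1_triple):
        spec = gaers_spec(duration_s=120.0, fs=128.0,
                          base_swd_rate_per_h=0.0)
        record, annotation = generate_recording(spec, rng_seed=0)
        with pytest.raises(ValueError):
            calibrate_threshold(record, annotation, s1_triple,
                                target_sensitivity_pct=60)

    def test_invalid_target_rejected(self, short_gaers, short_energies,
                                     s1_triple):
        _, record, annotation = short_gaers
        with pytest.raises(ValueError):
            calibrate_threshold(record, annotation, s1_triple,
                                target_sensitivity_pct=0,
                                energies=short_energies)
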