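"""CNV caller: smoothing, segmentation, exchanges, siblings, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radpanel import cnvcall, dosage
from radpanel import simpanel as sp
from conftest import dosage_pipeline, truth_recovered


class TestSmooth:
    def test_constant_series_unchanged(self):
        x = np.full(40, 2.0)
        assert np.array_equal(cnvcall.smooth(x, 15), x)

    def test_single_outlier_removed(self):
        x = np.full(40, 2.0)
        x[20] = 9.0
        assert np.allclose(cnvcall.smooth(x, 15), 2.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_bruteforce_windowed_median(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(2, 0.5, 200)
        w = int(rng.choice([1, 5, 15, 31]))
        got = cnvcall.smooth(x, w)
        half = w // 2
        expect = np.array([
            np.median(x[max(0, i - half):min(len(x), i + half + 1)])
            for i in range(len(x))])
        assert np.allclose(got, expect)

    def test_even_window_and_empty_series_rejected(self):
        with pytest.raises(ValueError):
            cnvcall.smooth([1.0, 2.0], 4)
        with pytest.raises(ValueError):
            cnvcall.smooth([], 3)


def _profile_from_levels(levels_a, pair_map, sample_id="s1"):
    """Build a one-sample profile with exact integer copy levels on A."""
    pm = pair_map.sort_values(["chrom_A", "idx_A"])
    return pd.DataFrame({
        "sample_id": sample_id,
        "pair_id": pm.pair_id.to_numpy(),
        "k_A": np.asarray(levels_a, dtype=float),
        "k_C": 2.0,
        "masked": False,
    })


def _toy_pair_map(n=200):
    return pd.DataFrame({
        "pair_id": [f"p{i}" for i in range(n)],
        "gene_A": [f"ga{i}" for i in range(n)],
        "chrom_A": "A1", "idx_A": np.arange(n), "len_A_bp": 1000,
        "gene_C": [f"gc{i}" for i in range(n)],
        "chrom_C": "C1", "idx_C": np.arange(n), "len_C_bp": 1000,
    })


class TestCallSegments:
    def test_noiseless_deletion_called_exactly(self):
        pm = _toy_pair_map()
        levels = np.full(200, 2.0)
        levels[50:90] = 0.0
        calls = cnvcall.call_segments(_profile_from_levels(levels, pm), pm)
        assert len(calls) == 1
        ev = calls.iloc[0]
        assert (ev.event_class, ev.copies, ev.zygosity) == (
            "segmental_deletion", 0, "hom")
        assert (ev.start_idx, ev.end_idx) == (50, 90)

    def test_whole_chromosome_reclassified(self):
        pm = _toy_pair_map()
        calls = cnvcall.call_segments(
            _profile_from_levels(np.full(200, 1.0), pm), pm)
        assert list(calls.event_class) == ["chromosome_loss"]
        assert (calls.start_idx.iloc[0], calls.end_idx.iloc[0]) == (0, 200)

    def test_adjacent_het_hom_deletions_split(self):
        pm = _toy_pair_map()
        levels = np.full(200, 2.0)
        levels[40:80] = 1.0
        levels[80:120] = 0.0
        calls = cnvcall.call_segments(_profile_from_levels(levels, pm), pm)
        assert sorted(calls.copies) == [0, 1]

    def test_balanced_panel_false_positive_rate(self):
        """< 0.01 events/sample across 100 balanced re-sequenced plants."""
        cfg = sp.PanelConfig(n_pairs_per_chrom=200, seed=31, n_controls=100,
                             doses=(sp.DoseGroup("gamma", 0, 1, 1),),
                             he_prob_control=0.0)
        pm = sp.make_pair_map(cfg)
        samples = sp.build_sample_sheet(cfg)
        events = sp.simulate_lesions(cfg, pm, samples)
        _, profile = dosage_pipeline(pm, events, samples, sp.NoiseModel(), cfg)
        calls = cnvcall.call_panel(profile, pm)
        assert len(calls) / len(samples) < 0.01

    def test_simulated_hom_deletion_recovered(self, small_panel):
        pm, cfg, samples = (small_panel["pair_map"], small_panel["config"],
                            small_panel["samples"])
        events = pd.DataFrame(
            [("G2000_2a", "C", "C4", 5, 95, sp.SEGMENTAL_DELETION, 0, "hom")],
            columns=sp.EVENT_COLUMNS)
        _, profile = dosage_pipeline(pm, events, samples, sp.NoiseModel(), cfg)
        calls = cnvcall.call_segments(
            profile[profile.sample_id == "G2000_2a"], pm)
        assert len(calls) == 1
        ev = calls.iloc[0]
        assert ev.event_class == "segmental_deletion" and ev.copies == 0
        inter = min(ev.end_idx, 95) - max(ev.start_idx, 5)
        union = (ev.end_idx - ev.start_idx) + 90 - inter
        assert inter / union >= 0.9

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            cnvcall.CallerParams(window=4)
        with pytest.raises(ValueError):
            cnvcall.CallerParams(del_thresh=2.5)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_oracle_equivalence_on_short_chromosomes(self, seed):
        """With no smoothing, calls equal brute-force enumeration of
        maximal non-baseline runs (chromosomes of <= 50 genes)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 51))
        pm = _toy_pair_map(n)
        # piecewise-integer levels, baseline separating each aberration
        levels = np.full(n, 2.0)
        pos = 0
        truth = []
        while pos < n - 4:
            gap = int(rng.integers(1, 6))
            seg = int(rng.integers(2, 12))
            lvl = float(rng.choice([0, 1, 3, 4]))
            s, e = pos + gap, min(pos + gap + seg, n)
            if e - s > 0:
                levels[s:e] = lvl
                truth.append((s, e, lvl))
            pos = e + 1
        params = cnvcall.CallerParams(window=1, min_run=3)
        calls = cnvcall.call_segments(_profile_from_levels(levels, pm), pm,
                                      params)
        expect = [(s, e, lvl) for s, e, lvl in truth
                  if e - s >= params.min_run
                  and not (e - s >= params.whole_chrom_frac * n)]
        whole = [(s, e, lvl) for s, e, lvl in truth
                 if e - s >= params.whole_chrom_frac * n]
        got = [(c.start_idx, c.end_idx, float(c.copies))
               for c in calls.itertuples()
               if c.event_class.startswith("segmental")]
        assert sorted(got) == sorted(expect)
        assert len(calls) - len(got) == len(whole)


class TestHomoeologousExchange:
    def test_reciprocal_pair_merged_with_direction(self, small_panel):
        pm, cfg, samples = (small_panel["pair_map"], small_panel["config"],
                            small_panel["samples"])
        events = pd.DataFrame(
            [("G2000_3a", "A", "A3", 20, 80, sp.HOMOEOLOGOUS_EXCHANGE, 4, "hom")],
            columns=sp.EVENT_COLUMNS)
        _, profile = dosage_pipeline(pm, events, samples, sp.NoiseModel(), cfg)
        calls = cnvcall.call_segments(
            profile[profile.sample_id == "G2000_3a"], pm)
        exch, remaining = cnvcall.detect_homoeologous_exchange(calls, pm)
        assert len(exch) == 1
        assert exch.direction.iloc[0] == "A->C"
        assert len(remaining) == 0

    def test_isolated_deletion_not_an_exchange(self):
        pm = _toy_pair_map()
        events = pd.DataFrame(
            [("s1", "A", "A1", 10, 60, sp.SEGMENTAL_DELETION, 0, "hom")],
            columns=sp.EVENT_COLUMNS)
        exch, remaining = cnvcall.detect_homoeologous_exchange(events, pm)
        assert len(exch) == 0 and len(remaining) == 1

    def test_overlap_below_threshold_keeps_events(self):
        pm = _toy_pair_map()
        events = pd.DataFrame([
            ("s1", "A", "A1", 0, 50, sp.SEGMENTAL_DUPLICATION, 4, "hom"),
            ("s1", "C", "C1", 40, 100, sp.SEGMENTAL_DELETION, 0, "hom"),
        ], columns=sp.EVENT_COLUMNS)
        exch, remaining = cnvcall.detect_homoeologous_exchange(events, pm, 0.7)
        assert len(exch) == 0 and len(remaining) == 2


class TestGeneScan:
    def test_single_gene_duplication_is_top_candidate(self, small_panel):
        pm, cfg, samples = (small_panel["pair_map"], small_panel["config"],
                            small_panel["samples"])
        gene = pm[pm.chrom_A == "A7"].sort_values("idx_A").gene_A.iloc[40]
        events = pd.DataFrame(
            [("G2000_5b", "A", "A7", 40, 41, sp.SEGMENTAL_DUPLICATION, 4, "hom")],
            columns=sp.EVENT_COLUMNS)
        k, _ = dosage_pipeline(pm, events, samples, sp.NoiseModel(), cfg)
        hits = cnvcall.scan_gene_level(k, pd.DataFrame(columns=sp.EVENT_COLUMNS),
                                       pm)
        dups = hits[hits.kind == "duplication"]
        assert len(dups) >= 1
        assert (dups.gene.iloc[0], dups.sample_id.iloc[0]) == (gene, "G2000_5b")

    def test_balanced_matrix_no_candidates(self):
        pm = _toy_pair_map(50)
        rng = np.random.default_rng(41)
        genes = list(pm.gene_A) + list(pm.gene_C)
        k = pd.DataFrame(rng.normal(2.0, 0.1, size=(100, 25)),
                         index=genes, columns=[f"s{i}" for i in range(25)])
        hits = cnvcall.scan_gene_level(k, pd.DataFrame(columns=sp.EVENT_COLUMNS),
                                       pm)
        assert len(hits) == 0

    def test_genes_in_called_segment_suppressed(self, small_panel):
        pm, cfg, samples = (small_panel["pair_map"], small_panel["config"],
                            small_panel["samples"])
        events = pd.DataFrame(
            [("G2000_6a", "A", "A1", 10, 60, sp.SEGMENTAL_DELETION, 0, "hom")],
            columns=sp.EVENT_COLUMNS)
        k, _ = dosage_pipeline(pm, events, samples, sp.NoiseModel(), cfg)
        hits = cnvcall.scan_gene_level(k, events, pm)
        genes = set(pm[pm.chrom_A == "A1"].sort_values("idx_A").gene_A.iloc[10:60])
        inside = hits[(hits.sample_id == "G2000_6a") & hits.gene.isin(genes)]
        assert len(inside) == 0


class TestSiblingMatcher:
    def test_reciprocal_family_reported_once(self, small_panel):
        samples = small_panel["samples"]
        events = pd.DataFrame([
            ("G2000_4a", "A", "A5", 0, 60, sp.SEGMENTAL_DELETION, 1, "het"),
            ("G2000_4b", "A", "A5", 2, 61, sp.SEGMENTAL_DUPLICATION, 3, "het"),
        ], columns=sp.EVENT_COLUMNS)
        pairs = cnvcall.match_sibling_events(events, samples)
        assert len(pairs) == 1
        assert pairs.deleted_in.iloc[0] == "G2000_4a"
        assert pairs.duplicated_in.iloc[0] == "G2000_4b"

    def test_symmetric_in_sibling_order(self, small_panel):
        samples = small_panel["samples"]
        events = pd.DataFrame([
            ("G2000_4b", "A", "A5", 2, 61, sp.SEGMENTAL_DUPLICATION, 3, "het"),
            ("G2000_4a", "A", "A5", 0, 60, sp.SEGMENTAL_DELETION, 1, "het"),
        ], columns=sp.EVENT_COLUMNS)
        pairs = cnvcall.match_sibling_events(events, samples)
        assert len(pairs) == 1

    def test_unrelated_samples_not_paired(self, small_panel):
        samples = small_panel["samples"]
        events = pd.DataFrame([
            ("G2000_4a", "A", "A5", 0, 60, sp.SEGMENTAL_DELETION, 1, "het"),
            ("G2000_5b", "A", "A5", 0, 60, sp.SEGMENTAL_DUPLICATION, 3, "het"),
        ], columns=sp.EVENT_COLUMNS)
        assert len(cnvcall.match_sibling_events(events, samples)) == 0

    def test_deletion_without_partner_unpaired(self, small_panel):
        samples = small_panel["samples"]
        events = pd.DataFrame([
            ("G2000_4a", "A", "A5", 0, 60, sp.SEGMENTAL_DELETION, 1, "het"),
        ], columns=sp.EVENT_COLUMNS)
        assert len(cnvcall.match_sibling_events(events, samples)) == 0


class TestDoseResponse:
    @pytest.mark.parametrize("rates,expect", [
        ((1.5, 2.38, 0.63, 0.31), 1.21),
        ((0.38, 0.25, 0.0, 0.25), 0.22),
        ((0.5, 0.88, 0.06, 0.20), 0.41),
        ((1.31, 1.69, 0.56, 0.31), 0.97),
        ((0.75, 0.63, 0.13, 0.50), 0.50),
        ((0.75, 2.38, 1.25, 0.75), 1.28),
    ])
    def test_mean_visible_rate(self, rates, expect):
        assert cnvcall.mean_visible_rate(rates) == expect

    def test_all_zero_events_table(self, small_panel):
        table = cnvcall.summarize_dose_response(
            pd.DataFrame(columns=sp.EVENT_COLUMNS), small_panel["samples"])
        assert (table[cnvcall.DOSE_RESPONSE_COLUMNS[3:]] == 0).all().all()

    def test_per_plant_rates_and_mean_column(self, small_panel):
        samples = small_panel["samples"]
        # 16 treated plants, 24 C deletions and 8 A duplications
        rows = []
        treated = samples[samples.role == "treated"].sample_id.tolist()
        for i, s in enumerate(treated):
            rows.append((s, "C", "C2", 0, 20, sp.SEGMENTAL_DELETION, 1, "het"))
            if i < 8:
                rows.append((s, "C", "C3", 0, 20, sp.SEGMENTAL_DELETION, 0, "hom"))
                rows.append((s, "A", "A2", 0, 20, sp.SEGMENTAL_DUPLICATION, 3, "het"))
        events = pd.DataFrame(rows, columns=sp.EVENT_COLUMNS)
        table = cnvcall.summarize_dose_response(events, samples)
        row = table[table.radiation_type == "gamma"].iloc[0]
        assert row.del_C == 1.5 and row.dup_A == 0.5 and row.del_A == 0
        assert row.mean_del_dup == cnvcall.mean_visible_rate([0, 1.5, 0.5, 0])

    def test_exchanges_excluded(self, small_panel):
        samples = small_panel["samples"]
        events = pd.DataFrame(
            [("G2000_1a", "A", "A1", 0, 30, sp.HOMOEOLOGOUS_EXCHANGE, 4, "hom")],
            columns=sp.EVENT_COLUMNS)
        table = cnvcall.summarize_dose_response(events, samples)
        assert (table[cnvcall.DOSE_RESPONSE_COLUMNS[3:]] == 0).all().all()

    def test_dose_monotonicity_at_scale(self):
        """Per-plant visible rates are non-decreasing in dose under the
        linear-rate model (1000 plants per dose)."""
        cfg = sp.PanelConfig(
            n_pairs_per_chrom=60, seed=37, n_controls=3, recip_prob=0.0,
            he_prob_control=0.0,
            doses=tuple(sp.DoseGroup("gamma", d, 500, 2)
                        for d in (750, 1500, 2000)))
        pm = sp.make_pair_map(cfg)
        samples = sp.build_sample_sheet(cfg)
        events = sp.simulate_lesions(cfg, pm, samples)
        table = cnvcall.summarize_dose_response(events, samples)
        g = table[table.radiation_type == "gamma"].sort_values("dose_Gy")
        means = g.mean_del_dup.to_numpy()
        assert all(x <= y + 1e-9 for x, y in zip(means, means[1:]))


class TestSaturation:
    def test_closed_form(self):
        assert cnvcall.saturation_size(2.5, 0.002) == 1000

    def test_zero_target(self):
        assert cnvcall.saturation_size(2.5, 0.002, target_multiplicity=0) == 0

    def test_monotone_in_rate(self):
        sizes = [cnvcall.saturation_size(r, 0.002) for r in (1.0, 2.0, 4.0)]
        assert sizes == sorted(sizes, reverse=True)

    def test_zero_rate_error(self):
        with pytest.raises(ValueError):
            cnvcall.saturation_size(0.0, 0.002)
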