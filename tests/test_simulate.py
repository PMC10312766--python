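"""Forward-simulator checks: sampling laws, capture model, determinism."""

import dataclasses

import numpy as np
import pytest

from evmap.config import MOUSE_PANEL, ConfigurationError, SimulationConfig
from evmap.io import write_localizations
from evmap.simulate import (
    TrueEV,
    simulate_capture,
    simulate_ev_population,
    simulate_localizations,
)


def make_ev(i=0, diameter=80.0, copies=None):
    base = {"MmCD9": 0, "MmCD63": 0, "MmCD81": 0, "HsCD81": 0}
    base.update(copies or {})
    return TrueEV(id=i, diameter=diameter, marker_copies=base)


class TestPopulation:
    @pytest.mark.parametrize("f,expected", [(0.0, 0), (1.0, 1000)])
    def test_degenerate_tracer_fractions(self, f, expected):
        cfg = SimulationConfig(n_ev=1000, fraction_tracer_positive=f, seed=1)
        pop = simulate_ev_population(cfg)
        assert sum(ev.source_label == "tracer-positive" for ev in pop) == expected

    def test_tracer_fraction_within_binomial_bound(self):
        """Observed tracer-positive fraction stays within 3 binomial SEs."""
        n, f = 10_000, 0.15
        cfg = SimulationConfig(n_ev=n, fraction_tracer_positive=f, seed=2)
        pop = simulate_ev_population(cfg)
        obs = sum(ev.source_label == "tracer-positive" for ev in pop) / n
        assert abs(obs - f) <= 3 * np.sqrt(f * (1 - f) / n)

    def test_tracer_positive_iff_tracer_copies(self):
        cfg = SimulationConfig(n_ev=2000, fraction_tracer_positive=0.4, seed=3)
        for ev in simulate_ev_population(cfg):
            assert (ev.marker_copies["HsCD81"] >= 1) == (
                ev.source_label == "tracer-positive"
            )
            assert all(v >= 0 for v in ev.marker_copies.values())
            assert ev.diameter > 0

    def test_copy_numbers_scale_with_membrane_area(self):
        """Mean copies over the population ≈ species mean × E[(d/80)²]."""
        cfg = SimulationConfig(n_ev=20_000, fraction_tracer_positive=0.0, seed=4)
        pop = simulate_ev_population(cfg)
        scale = np.mean([(ev.diameter / 80.0) ** 2 for ev in pop])
        mean_cd9 = np.mean([ev.marker_copies["MmCD9"] for ev in pop])
        expected = cfg.marker_mean_per_species["MmCD9"] * scale
        assert mean_cd9 == pytest.approx(expected, rel=0.03)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_ev=0)
        with pytest.raises(ConfigurationError):
            SimulationConfig(fraction_tracer_positive=1.5)


class TestCapture:
    def test_zero_copies_never_captured(self, small_sim_config):
        evs = [make_ev(i) for i in range(500)]
        captured = simulate_capture(evs, "HsCD81", 0.9, 0.0, small_sim_config)
        assert captured == []

    def test_certain_capture_with_copies(self, small_sim_config):
        evs = [make_ev(i, copies={"MmCD81": 3}) for i in range(200)]
        captured = simulate_capture(evs, "MmCD81", 1.0, 0.0, small_sim_config)
        assert len(captured) == 200
        assert all(ev.captured and ev.roi_id is not None for ev in captured)

    def test_capture_frequency_matches_closed_form(self, small_sim_config):
        """P(capture | k copies) = 1 − (1−p)^k, checked by Monte Carlo."""
        n, p_cap, k = 100_000, 0.2, 5
        evs = [make_ev(i, copies={"MmCD81": k}) for i in range(n)]
        captured = simulate_capture(evs, "MmCD81", p_cap, 0.0, small_sim_config)
        expected = 1 - (1 - p_cap) ** k
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(len(captured) / n - expected) <= 3 * se

    def test_unknown_species_rejected(self, small_sim_config):
        with pytest.raises(ConfigurationError):
            simulate_capture([make_ev()], "CD47", 0.5, 0.0, small_sim_config)

    def test_nonspecific_capture_ignores_composition(self, small_sim_config):
        """With f=0 and a tracer-specific target, every capture is flagged
        non-specific; with nonspecific_rate=0 there are none at all."""
        cfg = dataclasses.replace(small_sim_config, fraction_tracer_positive=0.0)
        pop = simulate_ev_population(cfg)
        assert simulate_capture(pop, "HsCD81", 0.9, 0.0, cfg) == []
        stuck = simulate_capture(pop, "HsCD81", 0.9, 2.0, cfg)
        assert stuck and all(ev.nonspecific for ev in stuck)


class TestLocalizations:
    def test_nothing_labeled_gives_empty_tables(self, small_sim_config):
        cfg = dataclasses.replace(
            small_sim_config, label_prob=0.0, background_density=0.0
        )
        pop = simulate_ev_population(cfg)
        captured = simulate_capture(pop, "MmCD81", 1.0, 0.0, cfg)
        tables, truth = simulate_localizations(captured, MOUSE_PANEL, cfg)
        assert all(len(df) == 0 for df in tables.values())
        assert len(truth) == 0

    def test_blink_count_mean_matches_calibration(self, rng):
        """Mean localizations per antibody within 2% of L=14 over 10⁴ draws."""
        L = 14.0
        draws = rng.geometric(1.0 / L, 10_000)
        assert draws.min() >= 1
        assert abs(draws.mean() - L) / L <= 0.02

    def test_background_count_is_poisson(self):
        """1/μm² over an empty 50×50 μm ROI → N within 3·√2500 of 2500."""
        cfg = SimulationConfig(n_ev=1, n_roi=1, background_density=1.0, seed=9)
        tables, truth = simulate_localizations([], MOUSE_PANEL, cfg)
        n = len(tables["roi000"])
        assert abs(n - 2500) <= 3 * np.sqrt(2500)
        assert (truth["ev_id"] == -1).all()

    def test_truth_conservation(self, small_sim_config):
        """Every emitted localization is attributed to exactly one vesicle or
        to background."""
        cfg = small_sim_config
        pop = simulate_ev_population(cfg)
        captured = simulate_capture(pop, "MmCD81", 0.9, 0.0, cfg)
        tables, truth = simulate_localizations(captured, MOUSE_PANEL, cfg)
        for roi_id, df in tables.items():
            t = truth[truth["roi_id"] == roi_id]
            assert sorted(t["loc_id"]) == sorted(df["id"])
            assert not t["loc_id"].duplicated().any()
        valid_ids = {ev.id for ev in captured} | {-1}
        assert set(truth["ev_id"]) <= valid_ids

    def test_mean_localizations_per_ev_match_forward_model(self):
        """E[locs per vesicle] ≈ p_label × Σ stained copies × L."""
        cfg = SimulationConfig(
            n_ev=2000, fraction_tracer_positive=0.0, background_density=0.0,
            n_roi=10, seed=11,
        )
        pop = simulate_ev_population(cfg)
        captured = simulate_capture(pop, "MmCD81", 1.0, 0.0, cfg)
        tables, truth = simulate_localizations(captured, MOUSE_PANEL, cfg)
        total_copies = sum(
            sum(ev.marker_copies[sp] for sp in MOUSE_PANEL) for ev in captured
        )
        expected = cfg.label_prob * total_copies * cfg.localizations_per_antibody_mean
        observed = sum(len(df) for df in tables.values())
        # a few % of localizations fall outside the ROI near edges
        assert observed == pytest.approx(expected, rel=0.05)

    def test_empty_stain_panel_rejected(self, small_sim_config):
        with pytest.raises(ConfigurationError):
            simulate_localizations([], frozenset(), small_sim_config)

    def test_determinism_byte_identical(self, tmp_path, small_sim_config):
        """Identical configuration (incl. seed) → byte-identical output."""
        def render():
            cfg = small_sim_config
            pop = simulate_ev_population(cfg)
            captured = simulate_capture(pop, "MmCD81", 0.9, 0.5, cfg)
            tables, _ = simulate_localizations(captured, MOUSE_PANEL, cfg)
            out = {}
            for roi_id, df in tables.items():
                p = tmp_path / f"{roi_id}.csv"
                write_localizations(df, p)
                out[roi_id] = p.read_bytes()
            return out

        assert render() == render()
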