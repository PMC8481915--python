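import math

import numpy as np
import pandas as pd
import pytest

from grscreen import synthetic_data as sd
from grscreen.gr_core import compute_gr_table
from grscreen.synthetic_data import GRCurveTruth, SimConfig


def one_population(doubling=220.0, fraction=1.0):
    return [
        sd.PopulationTruth(
            "epithelial", "KRT19+", fraction, doubling,
            {m: math.log(10) for m in ("dna", "krt19", "vim", "her2")},
            {m: 0.5 for m in ("dna", "krt19", "vim", "her2")},
        )
    ]


class TestExpectedCount:
    # hand-computed with the exponential growth model, 1000 cells, 96 h
    def test_dmso_well_220h_doubling(self):
        n = sd.expected_count(
            one_population()[0], "negative_control", None, 0.0, SimConfig(noise="none")
        )
        assert n == pytest.approx(1000 * 2 ** (96 / 220))  # ~1353
        assert round(n) == 1353

    def test_growth_control_freezes_at_seeding(self):
        n = sd.expected_count(
            one_population()[0], "growth_control", None, 0.0, SimConfig(noise="none")
        )
        assert n == 1000

    def test_kill_control_is_empty(self):
        n = sd.expected_count(
            one_population()[0], "positive_control", None, 0.0, SimConfig(noise="none")
        )
        assert n == 0.0

    def test_half_effect_dose_plugin(self):
        # GRinf=0, GEC50=1, h=1 at c=1: GR=0.5, k*T = (96/220)*log2(1.5)
        curve = GRCurveTruth(0.0, 1.0, 1.0)
        n = sd.expected_count(
            one_population()[0], "treatment", curve, 1.0, SimConfig(noise="none")
        )
        expected = 1000 * 2 ** ((96 / 220) * math.log2(1.5))
        assert n == pytest.approx(expected)
        assert round(n) == 1194

    def test_expected_counts_non_increasing_in_dose(self):
        curve = GRCurveTruth(-0.5, 0.7, 1.6)
        doses = np.geomspace(0.01, 50, 40)
        ns = [
            sd.expected_count(
                one_population()[0], "treatment", curve, c, SimConfig(noise="none")
            )
            for c in doses
        ]
        assert all(b <= a + 1e-12 for a, b in zip(ns, ns[1:]))


class TestScreenLayout:
    def test_16_drugs_fit_one_plate_with_32_controls(self):
        drugs = sd.make_drug_panel(16)
        screen = sd.simulate_screen(
            drugs=drugs, cfg=SimConfig(noise="none"), include_cells=False
        )
        assert len(screen.plate_maps) == 1
        pm = screen.plate_maps[0]
        assert len(pm.wells) == 16 * 5 + 32 == 112
        assert len(pm.wells_by_role("negative_control")) == 14

    def test_193_drugs_need_three_plates(self):
        drugs = sd.make_drug_panel(193)
        screen = sd.simulate_screen(
            drugs=drugs, cfg=SimConfig(noise="none"), include_cells=False
        )
        assert len(screen.plate_maps) == 3
        assert all(len(pm.wells) <= 384 for pm in screen.plate_maps)
        n_treat = sum(len(pm.wells_by_role("treatment")) for pm in screen.plate_maps)
        assert n_treat == 193 * 5

    def test_replicate_wells_multiply_layout(self):
        drugs = sd.make_drug_panel(4)
        screen = sd.simulate_screen(
            drugs=drugs, cfg=SimConfig(noise="none", n_replicates=3),
            include_cells=False,
        )
        assert len(screen.plate_maps[0].wells_by_role("treatment")) == 4 * 5 * 3

    def test_same_seed_reproduces_byte_identical_tables(self):
        drugs = sd.make_drug_panel(4)
        a = sd.simulate_screen(drugs=drugs, cfg=SimConfig(seed=9))
        b = sd.simulate_screen(drugs=drugs, cfg=SimConfig(seed=9))
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_frame_equal(a.cells, b.cells)
        assert a.cells.to_csv() == b.cells.to_csv()


class TestGenerativeInversion:
    def test_noise_free_gr_recovers_truth_everywhere(self, noise_free_screen):
        """Eq-style GR normalization inverts the growth model exactly."""
        table = compute_gr_table(
            noise_free_screen.counts, noise_free_screen.plate_maps,
            populations=("KRT19+", "VIM+"),
        )
        merged = table.merge(
            noise_free_screen.truth_gr(),
            on=["drug_id", "population", "concentration_uM"],
        )
        assert len(merged) == len(table)
        assert np.abs(merged["gr"] - merged["gr_true"]).max() < 1e-9

    def test_kill_curve_rejected_below_total_kill(self):
        with pytest.raises(ValueError):
            GRCurveTruth(-1.5, 1.0, 1.0)


class TestMarkerSeparation:
    def test_positive_population_clears_background_quantile(self, noisy_cell_screen):
        from conftest import stain_control_cells

        stain = stain_control_cells(noisy_cell_screen)
        cutoff = np.quantile(stain["krt19"], 0.99)
        # growth-arrest wells hold the seeded composition: 77.1% epithelial,
        # essentially all of which clear the background cutoff, plus ~1%
        # false positives from the 22.9% background-intensity cells
        pm = noisy_cell_screen.plate_maps[0]
        grw = {w.well for w in pm.wells_by_role("growth_control")}
        cells = noisy_cell_screen.cells
        well_cells = cells[
            (cells["plate_id"] == pm.plate_id) & cells["well"].isin(grw)
        ]
        frac_pos = (well_cells["krt19"] > cutoff).mean()
        assert frac_pos == pytest.approx(0.771 + 0.229 * 0.01, abs=0.02)


class TestRPPASimulation:
    def test_zero_slopes_give_flat_normalized_signal(self):
        truth = {(d, m): 0.0 for d in ["d1"] for m in sd.RPPA_MARKERS}
        spots = sd.simulate_rppa(["d1"], truth, loading_sigma=0.4, seed=0)
        ratio = spots["antibody_signal"] / spots["total_signal"]
        assert np.allclose(ratio, ratio.iloc[0])

    def test_loading_factor_cancels(self):
        truth = sd.make_rppa_truth(["d1"], rng=np.random.default_rng(0))
        spots = sd.simulate_rppa(["d1"], truth, loading_sigma=0.0, seed=0)
        scaled = spots.copy()
        one = scaled["lysate_id"] == scaled["lysate_id"].iloc[0]
        scaled.loc[one, ["antibody_signal", "total_signal"]] *= 2.0
        r0 = spots["antibody_signal"] / spots["total_signal"]
        r1 = scaled["antibody_signal"] / scaled["total_signal"]
        assert np.allclose(r0, r1)

    def test_planted_decrease_is_most_negative_at_top_dose(self):
        drugs = ["d1", "d2"]
        truth = sd.make_rppa_truth(
            drugs, rng=np.random.default_rng(1), planted={("d1", "HER2"): -3.0}
        )
        spots = sd.simulate_rppa(drugs, truth, seed=1)
        her2 = spots[(spots["marker"] == "HER2") & (spots["drug_id"] == "d1")]
        log_ratio = np.log2(her2["antibody_signal"] / her2["total_signal"])
        assert (
            her2.loc[log_ratio.idxmin(), "concentration_uM"]
            == her2["concentration_uM"].max()
        )


class TestLoeweOracle:
    def test_additive_mixture_of_identical_agents_is_the_agent(self):
        # mixing a drug with itself: iso-effect dose equals the single-agent dose
        fa = sd.loewe_additive_fa(2.0, (1, 1), dm_a=2.0, m_a=1.0, dm_b=2.0, m_b=1.0)
        assert fa == pytest.approx(0.5, abs=1e-9)

    def test_additive_mixture_interpolates_potency(self):
        fa = sd.loewe_additive_fa(3.0, (1, 5), dm_a=1.0, m_a=1.0, dm_b=5.0, m_b=1.0)
        # closed form for m=1: fa/(1-fa) = D*(wa/dm_a + wb/dm_b)
        expected_ratio = 3.0 * (1 / 6 / 1.0 + 5 / 6 / 5.0)
        assert fa / (1 - fa) == pytest.approx(expected_ratio, rel=1e-9)
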