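import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from grscreen import population_compare as pc
from grscreen.gating import assign_populations, learn_thresholds
from grscreen.io_plate import dose_series

DOSES = sorted(dose_series(5, 5, 2))  # ascending; GR vectors are low-to-high dose


def gr_frame(per_drug: dict[str, tuple[list, list]], pops=("KRT19+", "VIM+")):
    rows = []
    for drug, (a, b) in per_drug.items():
        for pop, vec in zip(pops, (a, b)):
            for c, g in zip(DOSES, vec):
                rows.append(
                    {"plate_id": "p1", "well": "A01", "drug_id": drug,
                     "concentration_uM": c, "population": pop, "gr": g}
                )
    return pd.DataFrame(rows)


class TestComparePopulations:
    def test_identical_vectors_not_selective(self):
        v = [1, 0.8, 0.6, 0.5, 0.4]
        out = pc.compare_populations(gr_frame({"d": (v, v)}))
        row = out.iloc[0]
        assert row["p_value"] == 1.0
        assert not row["selective"]

    def test_hand_example_selective_for_first_population(self):
        a = [1, 0.8, 0.2, -0.4, -0.6]
        b = [1, 1, 0.9, 0.9, 0.8]
        out = pc.compare_populations(gr_frame({"d": (a, b)}))
        row = out.iloc[0]
        assert row["cytotoxic_a"] and not row["cytotoxic_b"]
        assert row["selective"] and row["selective_population"] == "KRT19+"

    def test_label_swap_symmetry(self):
        a = [1, 0.8, 0.2, -0.4, -0.6]
        b = [1, 1, 0.9, 0.9, 0.8]
        fwd = pc.compare_populations(gr_frame({"d": (a, b)}), "KRT19+", "VIM+")
        rev = pc.compare_populations(gr_frame({"d": (a, b)}), "VIM+", "KRT19+")
        assert fwd.iloc[0]["selective"] == rev.iloc[0]["selective"]
        assert fwd.iloc[0]["selective_population"] == "KRT19+"
        assert rev.iloc[0]["selective_population"] == "KRT19+"
        assert fwd.iloc[0]["p_value"] == pytest.approx(rev.iloc[0]["p_value"])

    def test_mismatched_dose_sets_rejected(self):
        frame = gr_frame({"d": ([1, 0.8, 0.6, 0.5, 0.4], [1, 1, 1, 1, 1])})
        frame = frame.drop(frame[(frame["population"] == "VIM+")].index[:1])
        with pytest.raises(pc.AlignmentError):
            pc.compare_populations(frame)

    def test_paired_t_matches_textbook_closed_form(self):
        a = [1.0, 0.6, 0.1, -0.2, -0.5]
        b = [0.9, 0.8, 0.6, 0.5, 0.45]
        out = pc.compare_populations(gr_frame({"d": (a, b)}))
        d = np.array(a) - np.array(b)
        t = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        p = 2 * stats.t.sf(abs(t), len(d) - 1)
        assert out.iloc[0]["t_stat"] == pytest.approx(t, abs=1e-10)
        assert out.iloc[0]["p_value"] == pytest.approx(p, abs=1e-10)

    def test_fdr_column_present_and_monotone_with_p(self):
        frames = {
            f"d{i}": (
                list(np.linspace(1, -0.1 * i, 5)),
                [1, 1, 0.9, 0.9, 0.8],
            )
            for i in range(1, 6)
        }
        out = pc.compare_populations(gr_frame(frames)).sort_values("p_value")
        assert (out["q_value"] >= out["p_value"] - 1e-15).all()


class TestPopulationCorrelation:
    def test_identical_profiles(self):
        f = {
            "d1": ([1, 0.9, 0.8, 0.7, 0.6], [1, 0.9, 0.8, 0.7, 0.6]),
            "d2": ([0.5, 0.4, 0.3, 0.2, 0.1], [0.5, 0.4, 0.3, 0.2, 0.1]),
            "d3": ([0.2, 0.1, 0, -0.1, -0.2], [0.2, 0.1, 0, -0.1, -0.2]),
        }
        r, _ = pc.population_correlation(gr_frame(f))
        assert r == pytest.approx(1.0)

    def test_mirrored_profiles(self):
        f = {
            "d1": ([0.8] * 5, [-0.8] * 5),
            "d2": ([0.2] * 5, [-0.2] * 5),
            "d3": ([-0.5] * 5, [0.5] * 5),
        }
        r, _ = pc.population_correlation(gr_frame(f))
        assert r == pytest.approx(-1.0)

    def test_matches_textbook_pearson_on_five_drugs(self):
        means_a = [0.9, 0.5, 0.1, -0.3, 0.7]
        means_b = [0.8, 0.6, 0.3, -0.1, 0.2]
        f = {f"d{i}": ([means_a[i]] * 5, [means_b[i]] * 5) for i in range(5)}
        r, _ = pc.population_correlation(gr_frame(f))
        x, y = np.array(means_a), np.array(means_b)
        manual = float(
            ((x - x.mean()) * (y - y.mean())).sum()
            / math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        assert r == pytest.approx(manual, abs=1e-12)

    def test_zero_variance_rejected(self):
        f = {f"d{i}": ([0.5] * 5, [0.1 * i] * 5) for i in range(4)}
        with pytest.raises(pc.AlignmentError, match="variance"):
            pc.population_correlation(gr_frame(f))


@pytest.fixture(scope="module")
def gated_screen(noisy_cell_screen):
    from conftest import stain_control_cells

    th = learn_thresholds(stain_control_cells(noisy_cell_screen), 0.99)
    return (
        assign_populations(noisy_cell_screen.cells, th,
                           noisy_cell_screen.plate_maps),
        noisy_cell_screen.plate_maps,
    )


class TestIntensityShift:
    def test_fold_change_one_against_itself(self, gated_screen):
        res, maps = gated_screen
        out = pc.intensity_shift(res.cells, maps, marker="her2")
        # treated epithelial HER2 intensities are drawn from the same
        # distribution as control wells: fold changes concentrate near 1
        assert out["fold_change"].median() == pytest.approx(1.0, abs=0.05)

    def test_welch_t_matches_closed_form(self, gated_screen):
        res, maps = gated_screen
        out = pc.intensity_shift(res.cells, maps, marker="her2")
        row = out.dropna(subset=["p_value"]).iloc[0]
        cells = res.cells
        treated = cells[
            (cells["plate_id"] == row["plate_id"])
            & (cells["well"] == row["well"])
            & (cells["population"] == "KRT19+")
        ]["her2"].to_numpy()
        neg_keys = {
            (pm.plate_id, w.well)
            for pm in maps
            for w in pm.wells_by_role("negative_control")
        }
        ctrl = cells[
            [k in neg_keys for k in zip(cells["plate_id"], cells["well"])]
        ]
        ctrl = ctrl[ctrl["population"] == "KRT19+"]["her2"].to_numpy()
        m1, m2 = treated.mean(), ctrl.mean()
        v1, v2 = treated.var(ddof=1), ctrl.var(ddof=1)
        n1, n2 = len(treated), len(ctrl)
        t = (m1 - m2) / math.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
        p = 2 * stats.t.sf(abs(t), df)
        assert row["t_stat"] == pytest.approx(t, abs=1e-10)
        assert row["p_value"] == pytest.approx(p, abs=1e-10)

    def test_planted_ratio_arithmetic(self):
        # control mean 100, treated mean 250 -> fold change 2.5
        from grscreen.io_plate import PlateMap, WellSpec

        pm = PlateMap("p1", [
            WellSpec("A01", "negative_control"),
            WellSpec("A02", "positive_control"),
            WellSpec("A03", "growth_control"),
            WellSpec("A04", "treatment", "drugX", 5.0),
        ])
        def rows(well, mean, n=50):
            return pd.DataFrame({
                "plate_id": "p1", "well": well, "cell_id": range(n),
                "dna": 1.0, "krt19": 500.0, "vim": 1.0,
                "her2": np.full(n, mean, dtype=float),
                "population": "KRT19+", "her2_pos": True,
            })
        cells = pd.concat([rows("A01", 100.0), rows("A04", 250.0)])
        out = pc.intensity_shift(cells, pm, marker="her2")
        assert out.iloc[0]["fold_change"] == pytest.approx(2.5)
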