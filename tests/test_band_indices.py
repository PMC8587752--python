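import numpy as np
import pytest

from ftirage.band_indices import (
    AMIDE_I_WINDOW,
    AMIDE_II_WINDOW,
    PeakQuery,
    compute_panel,
    peak_intensity,
    summarize_panel,
)
from ftirage.errors import RatioError, WindowError
from ftirage.io_spectra import SpectraSet
from ftirage.preprocess import (
    CANONICAL_REGIONS,
    SGParams,
    area_normalize,
    preprocess_region,
    second_derivative_sg,
)
from ftirage.synthetic_data import CohortConfig, generate_cohort

from conftest import make_spectrum


class TestPeakIntensity:
    def test_direct_window_maximum_and_argmax(self):
        x = np.arange(1600.0, 1701.0, 2.0)
        trace = np.zeros_like(x)
        trace[x == 1628.0] = -0.42  # second-derivative minimum at the band
        trace[x == 1640.0] = -0.80  # stronger band outside the window
        hit = peak_intensity(
            make_spectrum(x, trace), PeakQuery(1628.0, halfwidth=6.0)
        )
        assert hit.intensity == pytest.approx(0.42)
        assert hit.wavenumber == 1628.0

    def test_gaussian_band_height_over_sigma_squared(self, gaussian_spectrum):
        derived = second_derivative_sg(gaussian_spectrum, SGParams())
        hit = peak_intensity(derived, PeakQuery(1650.0, halfwidth=6.0))
        assert hit.intensity == pytest.approx(1.0 / 100.0, rel=0.02)

    def test_scale_invariance_after_area_normalization(self, gaussian_spectrum):
        scaled = gaussian_spectrum.with_absorbance(7.0 * gaussian_spectrum.absorbance)
        q = PeakQuery(1650.0, halfwidth=6.0)
        a = peak_intensity(second_derivative_sg(area_normalize(gaussian_spectrum)), q)
        b = peak_intensity(second_derivative_sg(area_normalize(scaled)), q)
        assert a.intensity == pytest.approx(b.intensity, abs=1e-12)

    def test_empty_window_rejected(self, gaussian_spectrum):
        with pytest.raises(WindowError):
            peak_intensity(gaussian_spectrum, PeakQuery(900.0, halfwidth=4.0))


def _panel_inputs(amide_heights, lipid_heights=None, fingerprint_heights=None,
                  amide_raw=None):
    """Hand-built 'derived' traces with prescribed inverted peak heights."""
    lipid_heights = lipid_heights or {2851: 1.0, 2922: 1.0, 2959: 1.0, 2871: 1.0,
                                      3013: 0.5}
    fingerprint_heights = fingerprint_heights or {1169: 0.3, 1045: 0.4}
    amide_raw = amide_raw or {1651: 0.6, 1540: 0.3}

    def derived_set(lo, hi, heights):
        x = np.arange(lo, hi + 1.0, 2.0)
        y = np.zeros_like(x)
        for center, h in heights.items():
            y[np.argmin(np.abs(x - center))] = -h  # inverted later
        return SpectraSet([make_spectrum(x, y)])

    def raw_set(lo, hi, heights):
        x = np.arange(lo, hi + 1.0, 2.0)
        y = np.zeros_like(x)
        for center, h in heights.items():
            y[np.argmin(np.abs(x - center))] = h
        return SpectraSet([make_spectrum(x, y)])

    return (
        derived_set(2800, 3050, lipid_heights),
        derived_set(1500, 1800, amide_heights),
        derived_set(900, 1200, fingerprint_heights),
        raw_set(1500, 1800, amide_raw),
    )


class TestComputePanel:
    def test_known_intensities_give_exact_indices(self):
        lip, ami, fin, raw = _panel_inputs(
            amide_heights={1693: 0.2, 1682: 0.3, 1628: 0.5, 1741: 0.15}
        )
        panel = compute_panel(lip, ami, fin, raw)
        row = panel.iloc[0]
        assert row["acyl_chain_length"] == pytest.approx(1.0)
        assert row["lipid_unsaturation"] == pytest.approx(0.25)
        assert row["triglycerides"] == pytest.approx(0.15)
        assert row["antiparallel_beta_fraction"] == pytest.approx(0.2)
        assert row["intermolecular_beta_fraction"] == pytest.approx(0.5)
        assert row["total_protein"] == pytest.approx(0.9)
        assert row["fibril_formation"] == pytest.approx(0.5)
        assert row["cholesterol_esters"] == pytest.approx(0.3)
        assert row["glucose"] == pytest.approx(0.4)

    def test_beta_shares_sum_to_one(self):
        heights = {1693: 0.23, 1682: 0.31, 1628: 0.46, 1741: 0.1}
        lip, ami, fin, raw = _panel_inputs(heights)
        panel = compute_panel(lip, ami, fin, raw)
        row = panel.iloc[0]
        share_1682 = 0.31 / (0.23 + 0.31 + 0.46)
        total = (
            row["antiparallel_beta_fraction"]
            + row["intermolecular_beta_fraction"]
            + share_1682
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_denominator_names_sample_and_index(self):
        lip, ami, fin, raw = _panel_inputs(
            amide_heights={1693: -0.1, 1682: -0.1, 1628: -0.1, 1741: 0.1}
        )
        with pytest.raises(RatioError, match="antiparallel_beta_fraction"):
            compute_panel(lip, ami, fin, raw)

    def test_noiseless_cohort_monotone_recovery(self, quiet_cohort):
        """Configured band slopes must surface as monotone group means."""
        sg = SGParams(window_points=11)
        regions = {}
        for name in ("lipid", "amide", "fingerprint"):
            regions[name] = preprocess_region(
                quiet_cohort, CANONICAL_REGIONS[name], "rubberband", sg
            )
        panel = compute_panel(
            regions["lipid"][1], regions["amide"][1], regions["fingerprint"][1],
            regions["amide"][0],
        )
        gm = panel.groupby(["tissue", "age_months"]).mean(numeric_only=True)
        card = gm.loc["cardiac", "intermolecular_beta_fraction"].to_numpy()
        skel = gm.loc["skeletal", "intermolecular_beta_fraction"].to_numpy()
        assert np.all(np.diff(card) > 0)
        assert np.all(np.diff(skel) < 0)
        for tissue in ("cardiac", "skeletal"):
            anti = gm.loc[tissue, "antiparallel_beta_fraction"].to_numpy()
            assert np.all(np.diff(anti) < 0)

    def test_amide_raw_windows_cover_envelope_peaks(self, quiet_cohort):
        norm, _ = preprocess_region(
            quiet_cohort, CANONICAL_REGIONS["amide"], "rubberband", SGParams()
        )
        s = norm[0]
        i_max = s.wavenumbers[np.argmax(s.absorbance)]
        assert AMIDE_I_WINDOW[0] <= i_max <= AMIDE_I_WINDOW[1]
        assert AMIDE_II_WINDOW[0] < AMIDE_II_WINDOW[1] < AMIDE_I_WINDOW[0]


class TestSummarize:
    def test_hand_arithmetic(self):
        lip, ami, fin, raw = _panel_inputs({1693: 0.2, 1682: 0.3, 1628: 0.5, 1741: 0.1})
        panel = compute_panel(lip, ami, fin, raw)
        panel = panel.loc[panel.index.repeat(3)].reset_index(drop=True)
        panel["triglycerides"] = [1.0, 2.0, 3.0]
        summary = summarize_panel(panel)
        assert summary["triglycerides_mean"].item() == pytest.approx(2.0)
        assert summary["triglycerides_sd"].item() == pytest.approx(1.0)

    def test_noiseless_cohort_zero_sd(self):
        cohort = generate_cohort(
            CohortConfig(n_bio=2, n_tech=1, noise_sd=0.0, scale_jitter_sd=0.0,
                         bio_amplitude_sd=0.0, baseline_coeffs_sd=(0, 0, 0), seed=0)
        )
        sg = SGParams(window_points=11)
        parts = {
            name: preprocess_region(cohort, CANONICAL_REGIONS[name], "rubberband", sg)
            for name in ("lipid", "amide", "fingerprint")
        }
        panel = compute_panel(
            parts["lipid"][1], parts["amide"][1], parts["fingerprint"][1],
            parts["amide"][0],
        )
        summary = summarize_panel(panel)
        sd_cols = [c for c in summary.columns if c.endswith("_sd")]
        assert np.allclose(summary[sd_cols].to_numpy(float), 0.0, atol=1e-12)

    def test_single_member_group_flagged(self):
        lip, ami, fin, raw = _panel_inputs({1693: 0.2, 1682: 0.3, 1628: 0.5, 1741: 0.1})
        panel = compute_panel(lip, ami, fin, raw)
        summary = summarize_panel(panel)
        assert not summary["sd_defined"].item()
        assert np.isnan(summary["glucose_sd"].item())
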