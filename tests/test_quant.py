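"""Extraction, natural-abundance correction and peak-list IO."""

import numpy as np
import pytest

from petrokin import (
    CentroidSpectrum,
    build_correction_matrix,
    correct_fractions,
    correct_time_course,
    extract_raw_intensities,
    fractions_to_frame,
    model_fractions,
    normalize_to_reference,
    parse_formula,
    read_peaks_csv,
    read_peaks_json,
    simulate_time_course,
    spectra_to_frame,
    write_fractions_csv,
)
from petrokin.elements import isotopes_of
from petrokin.formula import merge_centroids
from petrokin.quant import IsotopologueTimeSeries

from test_formula import brute_force_pattern


def spectrum(peaks, t=0.0, rep="r1"):
    return CentroidSpectrum(time_s=t, peaks=tuple(sorted(peaks)), replicate_id=rep)


class TestExtraction:
    def test_single_d0_peak(self, petrosamine_cation):
        r = extract_raw_intensities(spectrum([(422.0499, 1000.0)]), petrosamine_cation)
        assert r.intensities == pytest.approx([1000.0, 0.0, 0.0])
        assert not r.no_signal

    def test_window_assignment(self, petrosamine_cation):
        r = extract_raw_intensities(
            spectrum([(422.0499, 500.0), (424.0624, 200.0)]), petrosamine_cation
        )
        assert r.intensities == pytest.approx([500.0, 0.0, 200.0])

    def test_peak_outside_ppm_window_is_no_signal(self, petrosamine_cation):
        # 422.060 is ~26 ppm from the d0 channel; a 10 ppm window must miss it
        r = extract_raw_intensities(
            spectrum([(422.060, 900.0)]), petrosamine_cation, tol_ppm=10.0
        )
        assert r.intensities == pytest.approx([0.0, 0.0, 0.0])
        assert r.no_signal

    def test_max_d_limited_by_hydrogens(self):
        ec = parse_formula("CHBr").with_charge(1)
        with pytest.raises(ValueError):
            extract_raw_intensities(spectrum([(100.0, 1.0)]), ec, max_d=2)


class TestCorrectionMatrix:
    def test_lower_triangular_with_unit_bounded_columns(self, petrosamine_cation):
        M = build_correction_matrix(petrosamine_cation, max_d=2, resolving_power=20000)
        assert np.allclose(np.triu(M, k=1), 0.0)
        assert np.all(M.sum(axis=0) <= 1.0 + 1e-12)
        assert np.all(np.diag(M) > 0)

    def test_c13_satellite_lands_in_d1_channel(self, petrosamine_cation):
        """The unresolved M+1 satellite of d0 contaminates the d1 channel.

        Every +1 fine-structure peak is a single rare-isotope substitution,
        so its abundance relative to the monoisotopic peak is exactly
        sum_i n_i * p_rare_i / p_light_i over the one-mass-unit isotopes.
        """
        M = build_correction_matrix(petrosamine_cation, max_d=2, resolving_power=20000)
        h1, h2 = isotopes_of("H")[:2]
        expected = (
            21 * 0.0107 / 0.9893
            + 3 * isotopes_of("N")[1][1] / isotopes_of("N")[0][1]
            + 17 * h2[1] / h1[1]
            + 2 * isotopes_of("O")[1][1] / isotopes_of("O")[0][1]
        )
        assert M[1, 0] / M[0, 0] == pytest.approx(expected, rel=1e-6)
        # sanity: the dominant term is the 21-carbon 13C satellite, ~0.23
        assert 0.2 < M[1, 0] / M[0, 0] < 0.3

    def test_br81_satellite_lands_in_d2_channel(self, petrosamine_cation):
        """The 81Br satellite of d0 is unresolved from the d2 channel at RP 20k."""
        M = build_correction_matrix(petrosamine_cation, max_d=2, resolving_power=20000)
        assert M[2, 0] / M[0, 0] > 0.9  # ~ 0.4931/0.5069 plus 13C2 and 18O terms

    def test_matches_enumeration_oracle_small_molecule(self):
        """Full matrix against brute-force isotopologue enumeration binning."""
        ec = parse_formula("C2H5Br").with_charge(1)
        rp = 20000.0
        from petrokin import monoisotopic_mz

        centers = np.array([monoisotopic_mz(ec.with_deuterium(n)) for n in range(3)])
        widths = centers / rp
        expected = np.zeros((3, 3))
        for j in range(3):
            mz_o, ab_o = brute_force_pattern(ec.with_deuterium(j))
            mz_o = mz_o - 0.000548579909065  # cation: electron-mass shift
            # same centroiding convention as the instrument model
            mz_o, ab_o = merge_centroids(mz_o, ab_o, rp)
            for mz, ab in zip(mz_o, ab_o):
                dist = np.abs(mz - centers)
                n = int(np.argmin(dist))
                if dist[n] < widths[n]:
                    expected[n, j] += ab
        M = build_correction_matrix(ec, max_d=2, resolving_power=rp)
        assert np.max(np.abs(M - expected)) < 1e-9

    def test_near_identity_without_bromine_or_carbon(self):
        """No Br/13C satellites: only the tiny natural-2H term survives."""
        M = build_correction_matrix(parse_formula("H2O").with_charge(1), 2, 1e9)
        assert np.allclose(M, np.eye(3), atol=3e-3)

    def test_indistinguishable_channels_rejected(self, petrosamine_cation):
        with pytest.raises(ValueError, match="indistinguishable"):
            build_correction_matrix(petrosamine_cation, max_d=2, resolving_power=300)


class TestCorrectFractions:
    def test_round_trip(self, petrosamine_cation):
        M = build_correction_matrix(petrosamine_cation, 2, 20000)
        x = np.array([0.2, 0.3, 0.5])
        out = correct_fractions(M @ x, M)
        assert out.fractions == pytest.approx(x, abs=1e-10)
        assert not out.flagged

    def test_pure_d0_satellites_resolve_to_pure_d0(self, petrosamine_cation):
        """Raw intensities that are d0's own satellite pattern mean pure d0."""
        M = build_correction_matrix(petrosamine_cation, 2, 20000)
        out = correct_fractions(M[:, 0].copy(), M)
        assert out.fractions == pytest.approx([1.0, 0.0, 0.0], abs=1e-12)

    def test_negative_solution_clipped_and_flagged(self, petrosamine_cation):
        M = build_correction_matrix(petrosamine_cation, 2, 20000)
        raw = M @ np.array([0.9, 0.1, 0.0])
        raw[2] *= 0.5  # noise knocks the d2 channel well below its satellites
        out = correct_fractions(raw, M)
        assert np.all(out.fractions >= 0)
        assert out.fractions.sum() == pytest.approx(1.0, abs=1e-12)
        assert out.clipped_mass > 0
        assert out.flagged

    def test_nnls_option_agrees_when_unconstrained(self, petrosamine_cation):
        M = build_correction_matrix(petrosamine_cation, 2, 20000)
        x = np.array([0.5, 0.3, 0.2])
        out = correct_fractions(M @ x, M, method="nnls")
        assert out.fractions == pytest.approx(x, abs=1e-8)

    def test_singular_matrix_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            correct_fractions(np.ones(2), np.array([[1.0, 0.0], [0.5, 0.0]]))

    def test_hypothesis_like_round_trip_grid(self, petrosamine_cation):
        """Any probability vector survives the forward-solve round trip."""
        M = build_correction_matrix(petrosamine_cation, 2, 20000)
        rng = np.random.default_rng(7)
        for _ in range(50):
            x = rng.dirichlet([1, 1, 1])
            out = correct_fractions(M @ x, M)
            assert np.max(np.abs(out.fractions - x)) < 1e-9


class TestNormalizeToReference:
    def make_series(self):
        return IsotopologueTimeSeries(
            replicate_id="r1",
            times_s=np.array([0.0, 15.0]),
            fractions=np.array([[1.0, 0.0, 0.0], [0.5, 0.25, 0.25]]),
            raw_intensities=np.array([[100.0, 50.0, 50.0], [10.0, 5.0, 5.0]]),
        )

    def test_scaling_leaves_fractions_unchanged(self):
        s = self.make_series()
        out = normalize_to_reference(s, 200.0)
        assert np.allclose(out.fractions, s.fractions)
        assert out.raw_intensities[0] == pytest.approx([0.5, 0.25, 0.25])
        assert out.reference_intensity == 200.0

    @pytest.mark.parametrize("ref", [0.0, -5.0])
    def test_nonpositive_reference_rejected(self, ref):
        with pytest.raises(ValueError):
            normalize_to_reference(self.make_series(), ref)


class TestFullChain:
    def test_zero_noise_chain_recovers_true_fractions(self, noiseless_config):
        """extract -> correct on noiseless spectra reproduces the generator."""
        spectra = simulate_time_course(noiseless_config)
        series = correct_time_course(spectra, noiseless_config.formula)
        assert len(series) == 3
        for s in series:
            truth = model_fractions(noiseless_config.model, s.times_s)
            assert np.max(np.abs(s.fractions - truth)) < 1e-6

    def test_no_correction_biases_fractions(self, noiseless_config):
        """Skipping the correction leaves satellite cross-talk in the data."""
        spectra = simulate_time_course(noiseless_config)
        uncorr = correct_time_course(spectra, noiseless_config.formula, correction=False)
        truth = model_fractions(noiseless_config.model, uncorr[0].times_s)
        # the 81Br satellite inflates the apparent d2 fraction at early times
        assert uncorr[0].fractions[0, 2] > truth[0, 2] + 0.1


class TestIO:
    def test_csv_round_trip(self, tmp_path, noisy_config):
        spectra = simulate_time_course(noisy_config)
        path = tmp_path / "peaks.csv"
        spectra_to_frame(spectra).to_csv(path, index=False)
        back = read_peaks_csv(path)
        assert len(back) == len(spectra)
        a = sorted(spectra, key=lambda s: (s.replicate_id, s.time_s))
        b = sorted(back, key=lambda s: (s.replicate_id, s.time_s))
        for s1, s2 in zip(a, b):
            assert np.allclose(s1.mz, s2.mz)
            assert np.allclose(s1.intensity, s2.intensity)

    def test_json_reader(self, tmp_path):
        import json

        path = tmp_path / "peaks.json"
        path.write_text(json.dumps([
            {"replicate_id": "a", "time_s": 0, "peaks": [[422.05, 10.0], [423.06, 2.0]]}
        ]))
        spectra = read_peaks_json(path)
        assert spectra[0].replicate_id == "a"
        assert spectra[0].peaks[0] == (422.05, 10.0)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("mz,intensity\n422.05,1\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_peaks_csv(path)

    def test_fractions_csv(self, tmp_path, noiseless_config):
        series = correct_time_course(
            simulate_time_course(noiseless_config), noiseless_config.formula
        )
        path = tmp_path / "fractions.csv"
        write_fractions_csv(series, path)
        df = fractions_to_frame(series)
        assert set(df.columns) == {
            "replicate_id", "time_s", "f_d0", "f_d1", "f_d2", "quality_flag",
        }
        assert path.read_text().startswith("replicate_id,time_s,f_d0")
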