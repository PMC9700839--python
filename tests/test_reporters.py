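"""Reporter channel masses, extraction, impurity correction, IFI, and
diagnostic-ion detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from scpriq import (
    ACETYL_LYSINE_DIAGNOSTIC_MZ,
    ImpurityMatrix,
    Peak,
    ReporterVector,
    SpectrumRecord,
    apply_impurities,
    channel_mz,
    composition_mz,
    correct_impurities,
    detect_diagnostic_ion,
    extract_reporters,
    interference_free_index,
    packaged_channels,
    parse_formula,
)

from conftest import make_spectrum

# Independent atomic-mass oracle: CODATA/AME monoisotopic masses, hand-entered.
ORACLE_MASS = {
    "H": 1.00782503207,
    "C": 12.0,
    "13C": 13.00335483507,
    "N": 14.0030740048,
    "15N": 15.0001088989,
    "O": 15.9949146196,
}
ORACLE_ELECTRON = 0.00054857990907


def oracle_mz(formula: str) -> float:
    total = sum(ORACLE_MASS[tok] * n for tok, n in parse_formula(formula).items())
    return total - ORACLE_ELECTRON


class TestChannelMass:
    def test_tmt_126_reporter_cation(self):
        (ch,) = [c for c in packaged_channels("TMT11") if c.label == "126"]
        assert channel_mz(ch) == pytest.approx(126.12772, abs=1e-5)

    def test_acetyl_lysine_diagnostic_cation(self):
        # C7H12NO+ immonium-derived ion of acetylated lysine
        assert composition_mz(parse_formula("C7 H12 N1 O1")) == pytest.approx(
            126.0913, abs=1e-4
        )
        assert ACETYL_LYSINE_DIAGNOSTIC_MZ == pytest.approx(126.0913, abs=1e-4)

    def test_gap_between_diagnostic_and_126_reporter(self):
        (ch,) = [c for c in packaged_channels("TMTPro") if c.label == "126"]
        gap = channel_mz(ch) - ACETYL_LYSINE_DIAGNOSTIC_MZ
        assert gap == pytest.approx(0.0364, abs=1e-4)

    def test_127c_minus_127n_isotope_spacing(self):
        by = {c.label: c for c in packaged_channels("TMTPro")}
        gap = channel_mz(by["127C"]) - channel_mz(by["127N"])
        expected = (ORACLE_MASS["13C"] - ORACLE_MASS["C"]) - (
            ORACLE_MASS["15N"] - ORACLE_MASS["N"]
        )
        assert gap == pytest.approx(expected, abs=1e-6)
        assert gap == pytest.approx(0.0063, abs=1e-4)

    @pytest.mark.parametrize("plex", ["TMT11", "TMTPro"])
    def test_every_packaged_channel_matches_hand_summed_oracle(self, plex):
        import csv
        from importlib import resources

        text = resources.files("scpriq.data").joinpath("reporter_channels.tsv").read_text()
        for row in csv.DictReader(text.splitlines(), delimiter="\t"):
            if row["plex"] != plex:
                continue
            got = composition_mz(parse_formula(row["formula"]))
            assert got == pytest.approx(oracle_mz(row["formula"]), abs=1e-5), row["label"]

    def test_adjacent_nc_spacing_constant_across_plex(self):
        chans = packaged_channels("TMTPro")
        mzs = sorted(channel_mz(c) for c in chans)
        spacings = [b - a for a, b in zip(mzs, mzs[1:])]
        small = [s for s in spacings if s < 0.5]  # N/C fine-structure pairs
        assert small, "expected N/C pairs in the TMTPro table"
        for s in small:
            assert s == pytest.approx(0.0063, abs=1e-4)

    def test_unknown_element_raises(self):
        with pytest.raises(ValueError, match="element"):
            parse_formula("Xx3")


def brute_force_extract(spectrum, design, tol_value, tol_unit):
    """Exhaustive scan over all (peak, channel) pairs."""
    theo = design.theoretical_mz()
    best = {l: None for l in theo}
    for p in spectrum.peaks:
        if p.intensity <= 0:
            continue
        nearest = min(theo, key=lambda l: abs(theo[l] - p.mz))
        tol = tol_value if tol_unit == "Da" else theo[nearest] * tol_value * 1e-6
        if abs(theo[nearest] - p.mz) > tol:
            continue
        cur = best[nearest]
        if (
            cur is None
            or p.intensity > cur.intensity
            or (p.intensity == cur.intensity
                and abs(p.mz - theo[nearest]) < abs(cur.mz - theo[nearest]))
        ):
            best[nearest] = p
    return {l: (None if pk is None else (pk.intensity, pk.mz)) for l, pk in best.items()}


class TestExtractReporters:
    def test_single_peak_in_window_matched(self, std_design):
        spec = SpectrumRecord("s", 500.0, peaks=[Peak(127.1248, 1000.0)])
        vec = extract_reporters(spec, std_design, 0.005, "Da")
        assert vec.intensity["127N"] == pytest.approx(1000.0)
        assert vec.matched_mz["127N"] == pytest.approx(127.1248)

    def test_empty_spectrum_all_missing(self, std_design):
        spec = SpectrumRecord("s", 500.0, peaks=[])
        vec = extract_reporters(spec, std_design, 0.005, "Da")
        assert all(v is None for v in vec.intensity.values())

    def test_matches_exhaustive_scan_oracle_on_200_random_spectra(self, rng, std_design):
        for i in range(200):
            # peaks dense around the reporter region to stress assignment
            spec = make_spectrum(rng, n_peaks=30, spectrum_id=f"s{i}",
                                 mz_range=(125.9, 135.4))
            vec = extract_reporters(spec, std_design, 0.01, "Da")
            oracle = brute_force_extract(spec, std_design, 0.01, "Da")
            for l in oracle:
                if oracle[l] is None:
                    assert vec.intensity[l] is None
                else:
                    assert vec.intensity[l] == pytest.approx(oracle[l][0])
                    assert vec.matched_mz[l] == pytest.approx(oracle[l][1])

    def test_peak_assigned_to_single_nearest_channel(self, std_design):
        theo = std_design.theoretical_mz()
        mid_low = theo["127N"] + 0.002  # nearer 127N than 128N
        spec = SpectrumRecord("s", 500.0, peaks=[Peak(mid_low, 10.0)])
        vec = extract_reporters(spec, std_design, 0.05, "Da")
        assert vec.intensity["127N"] == pytest.approx(10.0)
        assert vec.intensity["128N"] is None

    @given(seed=st.integers(0, 50))
    @settings(max_examples=20, deadline=None)
    def test_shrinking_tolerance_never_gains_matches(self, seed):
        from scpriq import two_proteome_9plex

        design = two_proteome_9plex()
        spec = make_spectrum(np.random.default_rng(seed), n_peaks=40,
                             mz_range=(125.9, 135.4))
        wide = extract_reporters(spec, design, 0.02, "Da")
        narrow = extract_reporters(spec, design, 0.004, "Da")
        for l in wide.intensity:
            if narrow.intensity[l] is not None:
                assert wide.intensity[l] is not None


class TestImpurityCorrection:
    def test_identity_matrix_returns_input(self, std_design):
        labels = std_design.labels
        imp = ImpurityMatrix.identity(labels)
        vec = ReporterVector(
            "s",
            {l: float(i + 1) for i, l in enumerate(labels)},
            {l: 126.0 + i for i, l in enumerate(labels)},
        )
        out = correct_impurities(vec, imp)
        assert out.intensity == vec.intensity

    def test_forward_model_inversion_recovers_truth(self, rng):
        labels = [f"ch{i}" for i in range(6)]
        for _ in range(20):
            M = np.eye(6)
            for j in range(6):
                leak = rng.uniform(0.0, 0.08, size=6)
                leak[j] = 0.0
                M[:, j] += leak
                M[j, j] = 1.0 - leak.sum()
            imp = ImpurityMatrix(labels, M)
            truth = {l: float(v) for l, v in zip(labels, rng.uniform(10, 1000, 6))}
            vec = ReporterVector("s", truth, {l: 126.0 for l in labels})
            rec = correct_impurities(apply_impurities(vec, imp), imp)
            for l in labels:
                assert rec.intensity[l] == pytest.approx(truth[l], rel=1e-6)

    def test_two_channel_closed_form(self):
        # observed = [[0.9, 0.1], [0.1, 0.9]] @ true; solve by elimination:
        # true = (9*obs - flip(obs)) / 8 elementwise combination
        M = np.array([[0.9, 0.1], [0.1, 0.9]])
        true = np.array([100.0, 300.0])
        obs = M @ true
        hand = np.array(
            [(0.9 * obs[0] - 0.1 * obs[1]) / 0.8, (0.9 * obs[1] - 0.1 * obs[0]) / 0.8]
        )
        np.testing.assert_allclose(hand, true, rtol=1e-12)
        imp = ImpurityMatrix(["a", "b"], M)
        vec = ReporterVector("s", {"a": obs[0], "b": obs[1]}, {"a": 1.0, "b": 2.0})
        out = correct_impurities(vec, imp)
        assert out.intensity["a"] == pytest.approx(hand[0], rel=1e-6)
        assert out.intensity["b"] == pytest.approx(hand[1], rel=1e-6)

    def test_missing_channels_restored_to_missing(self):
        imp = ImpurityMatrix(["a", "b"], np.array([[0.95, 0.05], [0.05, 0.95]]))
        vec = ReporterVector("s", {"a": 100.0, "b": None}, {"a": 1.0, "b": None})
        out = correct_impurities(vec, imp)
        assert out.intensity["b"] is None

    def test_singular_matrix_raises(self):
        imp = ImpurityMatrix(["a", "b"], np.array([[0.5, 0.5], [0.5, 0.5]]))
        vec = ReporterVector("s", {"a": 1.0, "b": 1.0}, {"a": 1.0, "b": 2.0})
        with pytest.raises(ValueError, match="singular"):
            correct_impurities(vec, imp)

    def test_invalid_entries_rejected(self):
        with pytest.raises(ValueError):
            ImpurityMatrix(["a", "b"], np.array([[1.2, 0.0], [0.0, 1.0]]))


class TestInterferenceFreeIndex:
    def _matrix(self, rows):
        cols = pd.MultiIndex.from_tuples(
            [("r", c) for c in ["ko1", "ko2", "p1", "p2"]], names=["run", "channel"]
        )
        return pd.DataFrame(rows, columns=cols)

    def test_zero_interference_gives_one(self):
        df = self._matrix([[0.0, 0.0, 100.0, 200.0]])
        ifi = interference_free_index(df, ["ko1", "ko2"], ["p1", "p2"])
        assert ifi.iloc[0] == pytest.approx(1.0)

    def test_equal_means_give_zero(self):
        df = self._matrix([[150.0, 150.0, 100.0, 200.0]])
        ifi = interference_free_index(df, ["ko1", "ko2"], ["p1", "p2"])
        assert ifi.iloc[0] == pytest.approx(0.0)

    def test_matches_direct_formula_with_missing_as_zero(self, rng):
        raw = rng.uniform(0, 100, size=(30, 4))
        raw[rng.random(raw.shape) < 0.2] = np.nan
        df = self._matrix(raw)
        ifi = interference_free_index(df, ["ko1", "ko2"], ["p1", "p2"])
        filled = np.nan_to_num(raw)
        for i in range(len(df)):
            parent = filled[i, 2:].mean()
            if parent == 0:
                assert np.isnan(ifi.iloc[i])
            else:
                expect = np.clip(1 - filled[i, :2].mean() / parent, 0, 1)
                assert ifi.iloc[i] == pytest.approx(expect)

    def test_all_parent_zero_is_missing(self):
        df = self._matrix([[10.0, 10.0, 0.0, 0.0]])
        ifi = interference_free_index(df, ["ko1", "ko2"], ["p1", "p2"])
        assert np.isnan(ifi.iloc[0])

    def test_overlapping_sets_rejected(self):
        df = self._matrix([[1.0, 1.0, 1.0, 1.0]])
        with pytest.raises(ValueError):
            interference_free_index(df, ["ko1"], ["ko1", "p1"])


REPORTER_126 = 126.12772


class TestDiagnosticIon:
    def test_resolves_diagnostic_from_reporter(self):
        spec = SpectrumRecord(
            "s", 500.0,
            peaks=[Peak(126.0913, 500.0), Peak(126.1277, 9000.0)],
        )
        hit = detect_diagnostic_ion(spec, 126.0913, 50.0, exclusion_mz=REPORTER_126)
        assert hit is not None
        assert hit.mz == pytest.approx(126.0913)
        assert hit.intensity == pytest.approx(500.0)

    def test_absent_ion_returns_none(self):
        spec = SpectrumRecord("s", 500.0, peaks=[Peak(500.0, 10.0)])
        assert detect_diagnostic_ion(spec, 126.0913, 50.0, REPORTER_126) is None

    def test_window_reaching_exclusion_mass_raises(self):
        spec = SpectrumRecord("s", 500.0, peaks=[Peak(126.1, 1.0)])
        with pytest.raises(ValueError, match="tolerance"):
            # 0.0364 Th gap at 126 is ~289 ppm; a 400 ppm window is ambiguous
            detect_diagnostic_ion(spec, 126.0913, 400.0, REPORTER_126)

    def test_agrees_with_brute_force_nearest_peak_classification(self, rng):
        ion, excl, tol_ppm = 126.0913, REPORTER_126, 80.0
        tol = ion * tol_ppm * 1e-6
        for i in range(1000):
            spec = make_spectrum(rng, n_peaks=8, spectrum_id=f"s{i}",
                                 mz_range=(126.05, 126.17))
            got = detect_diagnostic_ion(spec, ion, tol_ppm, excl)
            eligible = [
                p for p in spec.peaks
                if abs(p.mz - ion) <= tol and abs(p.mz - ion) < abs(p.mz - excl)
            ]
            if not eligible:
                assert got is None
            else:
                best = max(eligible, key=lambda p: p.intensity)
                assert got == best
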