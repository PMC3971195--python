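"""Feature extraction: spectral fractions, modulation energies, coherence,
phase, global field synchrony, assembly and block averaging."""

import numpy as np
import pandas as pd
import pytest

from eegad import (average_blocks, extract_features, gfs_band,
                   modulation_features, msc_band, phase_coherence_band,
                   relative_band_power)
from eegad.experiment import add_bipolar_epochs
from eegad.features import FeatureTable, _epoch_features
from eegad.montage import (BAND_NAMES, DEFAULT_BANDS, SCALP_LABELS,
                           VALID_MODULATION_PAIRS)
from eegad.preprocess import segment_epochs

FS = 200.0


def _t(seconds=10.0):
    return np.arange(int(FS * seconds)) / FS


class TestRelativeBandPower:
    def test_pure_alpha_tone(self):
        rp = relative_band_power(np.sin(2 * np.pi * 10 * _t()), FS)
        assert rp["alpha"] >= 0.99
        assert all(v <= 0.01 for b, v in rp.items() if b != "alpha")

    def test_two_tone_energy_split(self):
        x = np.sin(2 * np.pi * 2 * _t()) + np.sin(2 * np.pi * 20 * _t())
        rp = relative_band_power(x, FS)
        assert rp["delta"] == pytest.approx(0.5, abs=0.02)
        assert rp["beta"] == pytest.approx(0.5, abs=0.02)

    def test_fractions_sum_to_one(self):
        x = np.random.default_rng(0).standard_normal(4000)
        rp = relative_band_power(x, FS)
        assert sum(rp.values()) == pytest.approx(1.0, abs=1e-9)

    def test_zero_signal_rejected(self):
        with pytest.raises(ValueError):
            relative_band_power(np.zeros(4000), FS)


class TestModulationFeatures:
    def test_exactly_the_14_permitted_pairs(self):
        x = np.random.default_rng(1).standard_normal(int(8 * FS))
        mf = modulation_features(x, FS)
        assert len(mf) == 14
        expected = {f"{b}_{mb}" for b, mb in VALID_MODULATION_PAIRS}
        assert set(mf) == expected
        assert "delta_m-theta" not in mf

    def test_beta_carrier_with_3hz_am(self):
        """A 25 Hz carrier 100% AM-modulated at 3 Hz puts its envelope
        energy into the m-delta band."""
        t = _t(16.0)
        x = (1 + np.sin(2 * np.pi * 3 * t)) * np.sin(2 * np.pi * 25 * t)
        mf = modulation_features(x, FS)
        beta = {k: v for k, v in mf.items() if k.startswith("beta_")}
        assert max(beta, key=beta.get) == "beta_m-delta"

    def test_normalized_and_bounded(self):
        x = np.random.default_rng(2).standard_normal(int(8 * FS))
        mf = modulation_features(x, FS)
        assert sum(mf.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(0.0 <= v <= 1.0 for v in mf.values())


class TestCoherence:
    def test_self_coherence_is_one(self):
        x = np.random.default_rng(3).standard_normal(int(8 * FS))
        for band in DEFAULT_BANDS.bands.values():
            if band[1] > 0.45 * FS:
                band = (band[0], 0.45 * FS)
            assert msc_band(x, x, FS, band) == pytest.approx(1.0, abs=1e-9)

    def test_independent_noise_low_coherence(self):
        rng = np.random.default_rng(4)
        x, y = rng.standard_normal(12000), rng.standard_normal(12000)
        assert msc_band(x, y, FS, (8, 12)) <= 0.1

    def test_pure_delay_preserves_coherence(self):
        """A 50 ms delay leaves band MSC near 1 (minus the segment-edge
        bias of the Welch estimator)."""
        rng = np.random.default_rng(5)
        x = rng.standard_normal(12000)
        y = np.roll(x, 10)
        assert msc_band(x, y, FS, (8, 12)) >= 0.95

    def test_symmetry(self):
        rng = np.random.default_rng(6)
        x, y = rng.standard_normal(4000), rng.standard_normal(4000)
        assert msc_band(x, y, FS, (4, 8)) == pytest.approx(
            msc_band(y, x, FS, (4, 8)))


class TestPhaseCoherence:
    def test_zero_for_identical_signals(self):
        x = np.random.default_rng(7).standard_normal(4000)
        assert phase_coherence_band(x, x, FS, (8, 12)) == pytest.approx(
            0.0, abs=1e-9)

    def test_quarter_pi_offset_tones(self):
        x = np.sin(2 * np.pi * 10 * _t())
        y = np.sin(2 * np.pi * 10 * _t() - np.pi / 4)   # y lags x
        assert phase_coherence_band(x, y, FS, (8, 12)) == pytest.approx(
            np.pi / 4, abs=0.02)

    def test_antiphase_is_pi(self):
        x = np.sin(2 * np.pi * 10 * _t())
        assert abs(phase_coherence_band(x, -x, FS, (8, 12))) == pytest.approx(
            np.pi, abs=1e-6)

    def test_antisymmetry(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(4000)
        y = rng.standard_normal(4000) + 0.5 * x
        a = phase_coherence_band(x, y, FS, (8, 12))
        b = phase_coherence_band(y, x, FS, (8, 12))
        assert ((a + b) % (2 * np.pi)) == pytest.approx(0.0, abs=1e-9) or \
            abs(a + b) == pytest.approx(0.0, abs=1e-9)


class TestGFS:
    def test_identical_channels_full_synchrony(self):
        x = np.sin(2 * np.pi * 10 * _t())
        X = np.outer(np.linspace(1, 3, 20), np.ones(x.size)) * x
        assert gfs_band(X, FS, (8, 12)) == pytest.approx(1.0, abs=1e-2)

    def test_random_phase_channels_low_synchrony(self):
        """Fixed-amplitude, independently phased channels sit near the
        random-phase null, far below full synchrony.

        The analytic null of the 2x2 scatter anisotropy for N=20 ideal
        coefficients is sqrt(pi*N)/2N ~ 0.20; the Hamming window of the
        spectral estimator mixes neighbouring bins and lifts the measured
        null to ~0.23-0.28 (Monte-Carlo), still a fourth of the
        full-synchrony value."""
        rng = np.random.default_rng(9)
        t = _t(60.0)
        freqs = np.arange(1.0, 90.0, 1.0)
        X = np.zeros((20, t.size))
        for c in range(20):
            phases = rng.uniform(0, 2 * np.pi, freqs.size)
            X[c] = np.sin(2 * np.pi * np.outer(freqs, t)
                          + phases[:, None]).sum(axis=0)
        assert gfs_band(X, FS, (0.5, 89.5)) <= 0.3

    def test_amplitude_rescaling_invariance(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((20, 4000))
        assert gfs_band(X, FS, (8, 12)) == pytest.approx(
            gfs_band(7.5 * X, FS, (8, 12)), abs=1e-12)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            gfs_band(np.zeros((1, 4000)), FS, (8, 12))


@pytest.fixture(scope="module")
def table(clean_subject):
    ep = add_bipolar_epochs(segment_epochs(clean_subject.clean, 8.0))
    return extract_features(ep, "S1", "N")


class TestExtractFeatures:

    def test_column_counts(self, table):
        from collections import Counter
        counts = Counter(table.set_tags.values())
        assert table.values.shape[1] == 617
        assert counts["spectral"] == 140
        assert counts["modulation"] == 392
        assert counts["coherence"] == 40
        assert counts["phase"] == 45

    def test_coherence_covers_eight_pairs_per_band(self, table):
        for band in BAND_NAMES:
            cols = [c for c in table.values.columns
                    if c.endswith(f"_{band}_cohe_mag")]
            assert len(cols) == 8

    def test_value_ranges(self, table):
        vals = table.values
        for col in table.columns_for("spectral"):
            assert vals[col].between(0, 1).all()
        for col in table.columns_for("coherence"):
            assert vals[col].between(0, 1).all()
        for col in table.columns_for("phase"):
            if col.endswith("_gfs"):
                assert vals[col].between(0, 1).all()
            else:
                assert vals[col].between(-np.pi, np.pi).all()

    def test_determinism(self, clean_subject, table):
        ep = add_bipolar_epochs(segment_epochs(clean_subject.clean, 8.0))
        again = extract_features(ep, "S1", "N")
        pd.testing.assert_frame_equal(table.values, again.values)

    def test_fast_path_matches_reference_functions(self, clean_subject):
        ep = add_bipolar_epochs(segment_epochs(clean_subject.clean, 8.0))
        scheme = DEFAULT_BANDS.capped(ep.fs)
        row = _epoch_features(ep.data[0], ep.fs, ep.labels, scheme)
        x = ep.data[0][ep.labels.index("Pz")]
        rp = relative_band_power(x, ep.fs, scheme)
        mf = modulation_features(x, ep.fs, scheme)
        for b in BAND_NAMES:
            assert row[f"Pz_{b}_pwr"] == pytest.approx(rp[b], abs=1e-12)
        for key, v in mf.items():
            b, mb = key.split("_")
            assert row[f"Pz_{b}_{mb}"] == pytest.approx(v, abs=1e-12)
        o1 = ep.data[0][ep.labels.index("O1")]
        o2 = ep.data[0][ep.labels.index("O2")]
        assert row["O1-O2_alpha_cohe_mag"] == pytest.approx(
            msc_band(o1, o2, ep.fs, scheme.bands["alpha"]), abs=1e-12)
        assert row["O1-O2_alpha_cohe_pha"] == pytest.approx(
            phase_coherence_band(o1, o2, ep.fs, scheme.bands["alpha"]),
            abs=1e-12)
        scalp = ep.data[0][[ep.labels.index(l) for l in SCALP_LABELS]]
        assert row["GFS_theta_gfs"] == pytest.approx(
            gfs_band(scalp, ep.fs, scheme.bands["theta"]), abs=1e-12)

    def test_missing_channels_rejected(self, clean_subject):
        ep = segment_epochs(clean_subject.clean, 8.0)   # no bipolar
        with pytest.raises(ValueError):
            extract_features(ep)


class TestAverageBlocks:
    @staticmethod
    def _toy_table(n_rows=12, n_cols=4, subject="A"):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(rng.standard_normal((n_rows, n_cols)),
                              columns=[f"f{i}" for i in range(n_cols)])
        meta = pd.DataFrame({"subject_id": [subject] * n_rows,
                             "group": ["N"] * n_rows,
                             "epoch_start": range(n_rows),
                             "epoch_stop": range(n_rows)})
        return FeatureTable(values=values, meta=meta,
                            set_tags={c: "spectral" for c in values.columns})

    def test_block_count(self):
        out = average_blocks(self._toy_table(12), k=5)
        assert out.n_rows == 2

    def test_constant_column_unchanged(self):
        tab = self._toy_table(10)
        tab.values["f0"] = 3.14
        out = average_blocks(tab, k=5)
        assert np.allclose(out.values["f0"], 3.14)

    def test_k1_is_identity(self):
        tab = self._toy_table(7)
        out = average_blocks(tab, k=1)
        pd.testing.assert_frame_equal(out.values, tab.values)

    def test_averaging_reduces_variance(self):
        rng = np.random.default_rng(1)
        values = pd.DataFrame(rng.standard_normal((100, 3)),
                              columns=["a", "b", "c"])
        meta = pd.DataFrame({"subject_id": ["S"] * 100, "group": ["N"] * 100,
                             "epoch_start": range(100),
                             "epoch_stop": range(100)})
        tab = FeatureTable(values=values, meta=meta,
                           set_tags={c: "spectral" for c in values.columns})
        out = average_blocks(tab, k=5)
        assert (out.values.var() <= tab.values.var()).all()

    def test_too_few_rows_warns_and_empties(self):
        tab = self._toy_table(3)
        with pytest.warns(UserWarning):
            out = average_blocks(tab, k=5)
        assert out.n_rows == 0

    def test_epoch_range_recorded(self):
        out = average_blocks(self._toy_table(10), k=5)
        assert list(out.meta["epoch_start"]) == [0, 5]
        assert list(out.meta["epoch_stop"]) == [4, 9]
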