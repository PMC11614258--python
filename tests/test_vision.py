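"""Avian visual model: receptor templates, catches, tetrahedral space,
and receptor-noise contrasts (with an independent brute-force oracle)."""

import itertools

import numpy as np
import pytest

import hyperplume as hp
from hyperplume.vision import AVERAGE_VS_LMAX, DEFAULT_GRID, RECEPTOR_NAMES


def rnl_brute_force(QA, QB, e):
    """Independent transcription of the tetrachromatic receptor-noise
    distance: sum over receptor pairs (i, j) of
    (e_k e_l)^2 (df_i - df_j)^2 with {k, l} the complementary pair,
    divided by the sum over leave-one-out triples of (e_a e_b e_c)^2."""
    df = np.log(np.asarray(QA) / np.asarray(QB))
    num = 0.0
    for i, j in itertools.combinations(range(4), 2):
        others = [m for m in range(4) if m not in (i, j)]
        num += (e[others[0]] ** 2) * (e[others[1]] ** 2) * (df[i] - df[j]) ** 2
    den = 0.0
    for trio in itertools.combinations(range(4), 3):
        den += np.prod([e[m] for m in trio]) ** 2
    return np.sqrt(num / den)


class TestReceptorTemplates:
    def test_template_peaks_at_stated_lmax(self):
        for lmax in range(400, 601, 25):
            s = hp.govardovskii_template(float(lmax))
            peak = DEFAULT_GRID[np.argmax(s)]
            assert abs(peak - lmax) <= 1.0
            assert s.max() == pytest.approx(1.0)
            assert s.min() >= 0.0

    def test_single_global_maximum(self):
        for lmax in (420.0, 500.0, 580.0):
            s = hp.govardovskii_template(lmax)
            peaks = np.flatnonzero((s[1:-1] > s[:-2]) & (s[1:-1] > s[2:]))
            # the alpha peak dominates; any beta-band bump stays well below
            assert s[peaks + 1].max() == s.max()
            assert sorted(s[peaks + 1])[-2:-1] == [] or \
                sorted(s[peaks + 1])[-2] < 0.9 * s.max()

    def test_average_vs_bird_ordering_and_coverage(self):
        rec = hp.vs_bird_receptors()
        assert rec.wavelengths[0] == 300 and rec.wavelengths[-1] == 700
        peaks = [rec.wavelengths[np.argmax(s)] for s in rec.sensitivities]
        assert peaks == sorted(peaks)  # VS < SWS < MWS < LWS
        for name, peak in zip(RECEPTOR_NAMES, peaks):
            assert abs(peak - AVERAGE_VS_LMAX[name]) <= 1.0

    def test_lmax_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            hp.govardovskii_template(250.0)


class TestQuantumCatch:
    def test_perfect_white_gives_unit_catches(self, receptors):
        wl = receptors.wavelengths
        cc = hp.quantum_catch(hp.ReflectanceSpectrum(wl, np.ones_like(wl)),
                              receptors)
        np.testing.assert_allclose(cc.Q, 1.0, atol=1e-12)
        np.testing.assert_allclose(cc.q, 0.25, atol=1e-12)
        np.testing.assert_allclose(cc.xyz, 0.0, atol=1e-12)

    def test_gray_is_brightness_invariant_in_q(self, receptors):
        wl = receptors.wavelengths
        cc = hp.quantum_catch(
            hp.ReflectanceSpectrum(wl, np.full_like(wl, 0.5)), receptors)
        np.testing.assert_allclose(cc.Q, 0.5, atol=1e-12)
        np.testing.assert_allclose(cc.q, 0.25, atol=1e-12)

    def test_narrow_box_at_lws_peak_favors_lws(self, receptors):
        wl = receptors.wavelengths
        vals = np.where(np.abs(wl - AVERAGE_VS_LMAX["lws"]) <= 5, 1.0, 0.0)
        cc = hp.quantum_catch(hp.ReflectanceSpectrum(wl, vals), receptors)
        assert np.argmax(cc.q) == 3
        # direct-summation oracle for each receptor
        S = receptors.sensitivities
        oracle = (S * vals).sum(axis=1) / S.sum(axis=1)
        np.testing.assert_allclose(cc.Q, oracle, atol=1e-14)

    def test_grid_mismatch_raises(self, receptors):
        wl = np.arange(325.0, 701.0)
        with pytest.raises(ValueError, match="grid"):
            hp.quantum_catch(hp.ReflectanceSpectrum(wl, np.ones_like(wl)),
                             receptors)


class TestTetraCoords:
    def test_equal_catches_map_to_origin(self):
        np.testing.assert_allclose(hp.tetra_coords([0.25] * 4), 0.0,
                                   atol=1e-15)

    def test_all_vertices_at_radius_075(self):
        expected = {
            0: (0.0, 1 / (2 * np.sqrt(2)) * 0 + 0.75),  # handled below
        }
        for i in range(4):
            q = np.zeros(4)
            q[i] = 1.0
            xyz = hp.tetra_coords(q)
            assert np.linalg.norm(xyz) == pytest.approx(0.75, abs=1e-12)
        # VS vertex sits on the +z axis
        np.testing.assert_allclose(hp.tetra_coords([1, 0, 0, 0]),
                                   [0.0, 0.0, 0.75], atol=1e-12)

    def test_unnormalised_q_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            hp.tetra_coords([0.5, 0.5, 0.5, 0.5])

    def test_points_never_exceed_vertex_radius(self):
        rng = np.random.default_rng(0)
        q = rng.dirichlet(np.ones(4), size=500)
        xyz = hp.tetra_coords(q)
        assert np.linalg.norm(xyz, axis=1).max() <= 0.75 + 1e-12


class TestRnlContrasts:
    def test_identical_catches_give_zero(self, receptors):
        Q = np.array([0.3, 0.5, 0.7, 0.6])
        assert hp.rnl_chromatic(Q, Q, receptors) == 0.0

    def test_brightness_scaling_invariance(self, receptors):
        rng = np.random.default_rng(1)
        QA = rng.uniform(0.1, 1.0, 4)
        QB = rng.uniform(0.1, 1.0, 4)
        base = hp.rnl_chromatic(QA, QB, receptors)
        for k in (0.1, 2.0, 37.0):
            assert hp.rnl_chromatic(QA * k, QB, receptors) == pytest.approx(
                base, abs=1e-12)
            assert hp.rnl_chromatic(QA, QB * k, receptors) == pytest.approx(
                base, abs=1e-12)
        assert hp.rnl_chromatic(QB, QA, receptors) == pytest.approx(base)

    def test_matches_brute_force_on_1000_random_quadruples(self, receptors):
        rng = np.random.default_rng(2)
        e = receptors.noise
        for _ in range(1000):
            QA = rng.uniform(0.01, 1.0, 4)
            QB = rng.uniform(0.01, 1.0, 4)
            got = hp.rnl_chromatic(QA, QB, receptors)
            want = rnl_brute_force(QA, QB, e)
            assert got == pytest.approx(want, abs=1e-10)

    def test_noise_anchored_to_most_abundant_cone(self, receptors):
        """w = 0.1 applies to the LWS (n=2) channel; the three singleton
        channels get 0.1 * sqrt(2)."""
        np.testing.assert_allclose(receptors.noise,
                                   [0.1 * np.sqrt(2)] * 3 + [0.1], atol=1e-15)

    def test_luminance_closed_form(self, receptors):
        assert hp.rnl_luminance(1.0, 1.0, receptors) == 0.0
        assert hp.rnl_luminance(1.0, 2.0, receptors) == pytest.approx(
            np.log(2) / 0.1)
        assert hp.rnl_luminance(2.0, 1.0, receptors) == pytest.approx(
            np.log(2) / 0.1)

    def test_luminance_from_scaled_reflectance(self, receptors):
        wl = receptors.wavelengths
        base = 0.2 + 0.3 * np.exp(-((wl - 550) ** 2) / 8000)
        for k in (0.5, 2.0):
            a = hp.quantum_catch(hp.ReflectanceSpectrum(wl, base), receptors)
            b = hp.quantum_catch(hp.ReflectanceSpectrum(wl, base * k),
                                 receptors)
            dl = hp.rnl_luminance(a.Q_double, b.Q_double, receptors)
            assert dl == pytest.approx(abs(np.log(k)) / 0.1, abs=1e-9)
            assert hp.rnl_chromatic(a.Q, b.Q, receptors) < 1e-9

    def test_negative_catch_rejected(self, receptors):
        with pytest.raises(ValueError, match="non-negative"):
            hp.rnl_chromatic([-0.1, 1, 1, 1], [1, 1, 1, 1], receptors)


class TestDiscriminable:
    @pytest.mark.parametrize("value,expected", [
        (3.0, True), (0.0, False), (2.999, False), (3.001, True),
    ])
    def test_threshold_inclusive_at_three(self, value, expected):
        assert hp.discriminable(value) is expected

    def test_negative_contrast_rejected(self):
        with pytest.raises(ValueError):
            hp.discriminable(-1.0)


class TestConeCatchImage:
    def test_white_cube_gives_unit_channels(self, receptors):
        wl = np.linspace(274, 812, 80)
        cube = hp.HyperCube(np.ones((4, 5, 80)), wl,
                            meta={"calibrated": True})
        img = hp.cone_catch_image(cube, receptors)
        assert img.shape == (4, 5, 4)
        np.testing.assert_allclose(img, 1.0, atol=1e-9)

    def test_per_pixel_matches_per_spectrum(self, receptors, noiseless_scene):
        """Per-patch mean channel values equal the quantum catch of the
        patch spectrum run through the same preprocessing chain."""
        cube, bright, truth = noiseless_scene
        cal = hp.calibrate_cube(cube, truth.standard, bright=bright)
        img = hp.cone_catch_image(cal, receptors)
        for name in ("breast", "back"):
            mask = truth.masks[name]
            # erode the mask so the 1-pixel patch boundary is excluded
            core = mask.copy()
            core[:-1] &= mask[1:]
            core[1:] &= mask[:-1]
            core[:, :-1] &= mask[:, 1:]
            core[:, 1:] &= mask[:, :-1]
            got = img[core].mean(axis=0)
            prepped = hp.prepare(truth.spectra[name])
            want = hp.quantum_catch(prepped, receptors).Q
            np.testing.assert_allclose(got, want, atol=1e-6)

    def test_channel_count_without_double_cone(self, receptors):
        assert receptors.double is None
        wl = np.linspace(274, 812, 60)
        cube = hp.HyperCube(np.full((2, 2, 60), 0.5), wl,
                            meta={"calibrated": True})
        assert hp.cone_catch_image(cube, receptors).shape[-1] == 4

    def test_double_cone_adds_fifth_channel(self):
        rec = hp.vs_bird_receptors(double_lmax=565.0)
        wl = np.linspace(274, 812, 60)
        cube = hp.HyperCube(np.full((2, 2, 60), 0.5), wl,
                            meta={"calibrated": True})
        assert hp.cone_catch_image(cube, rec).shape[-1] == 5

    def test_uncalibrated_cube_refused(self, receptors):
        wl = np.linspace(274, 812, 60)
        cube = hp.HyperCube(np.ones((2, 2, 60)), wl)
        with pytest.raises(ValueError, match="calibrated"):
            hp.cone_catch_image(cube, receptors)
        hp.cone_catch_image(cube, receptors, force=True)  # no raise


class TestPatchContrasts:
    def test_pairwise_table_on_synthetic_specimens(self, receptors):
        wl = np.arange(300.0, 701.0)
        green = 0.05 + 0.45 * np.exp(-((wl - 535) ** 2) / 5000)
        red = 0.05 + 0.55 / (1 + np.exp(-(wl - 600) / 25))
        rows, spectra = [], []
        for spec_id, vals in (("s1", green), ("s2", red), ("s3", green)):
            for i in range(3):
                rows.append(("syn", spec_id, "dorsal", "back", i, i))
                spectra.append(vals)
        import pandas as pd

        ss = hp.SampleSet(
            pd.DataFrame(rows, columns=["species", "specimen", "view",
                                        "patch", "row", "col"]),
            np.array(spectra), wl)
        df = hp.patch_contrasts(ss, receptors)
        assert len(df) == 3  # 3 specimen pairs, 1 patch
        same = df[(df.specimenA == "s1") & (df.specimenB == "s3")]
        diff = df[(df.specimenA == "s1") & (df.specimenB == "s2")]
        assert same.dS.iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert not same.discriminable_dS.iloc[0]
        assert diff.dS.iloc[0] > 3
        assert diff.discriminable_dS.iloc[0]


class TestUvRobustness:
    def test_ds_insensitive_to_uv_extrapolation(self, receptors):
        """Replacing the extrapolated 300-325 nm segment with a constant
        changes dS by < 0.1 for the synthetic pigment spectra (avian
        sensitivity below 325 nm is low)."""
        wl_src = np.linspace(274, 812, 294)
        kinds = [("gaussian_peak", {"l0": 535.0, "sigma": 50.0,
                                    "amplitude": 0.45, "baseline": 0.05}),
                 ("sigmoid_step", {"l0": 545.0}),
                 ("linear_ramp", {}), ("flat", {"level": 0.65})]
        prepped = [hp.prepare(hp.spectrum_model(k, p, wl_src))
                   for k, p in kinds]
        for a, b in itertools.combinations(prepped, 2):
            qa = hp.quantum_catch(a, receptors)
            qb = hp.quantum_catch(b, receptors)
            ds = hp.rnl_chromatic(qa.Q, qb.Q, receptors)
            const = []
            for s in (a, b):
                v = s.values.copy()
                v[:25] = v[25]
                const.append(hp.ReflectanceSpectrum(s.wavelengths, v))
            ds_const = hp.rnl_chromatic(
                hp.quantum_catch(const[0], receptors).Q,
                hp.quantum_catch(const[1], receptors).Q, receptors)
            assert abs(ds - ds_const) < 0.1
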