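import numpy as np
import pytest

from theradose.metrics import suv
from theradose.nuclides import decay_factor
from theradose.phantom import (
    PhantomConfig,
    PKParams,
    Shape,
    add_imaging_noise,
    build_phantom,
    default_organs,
    excretion_curves,
)


class TestKinetics:
    def test_k_up_equal_k_bio_rejected(self):
        with pytest.raises(ValueError, match="degenerate|exceed"):
            PKParams(0.1, 0.05, 0.05)

    def test_route_split_must_sum_to_one(self):
        with pytest.raises(ValueError, match="route_split"):
            PKParams(0.1, 0.5, 0.01, (0.6, 0.6))

    def test_mass_balance_closed_form(self):
        pk = PKParams(0.3, 0.25, 0.01)
        for t in (0.0, 4.0, 24.0, 73.0, 500.0):
            total = pk.precursor(t) + pk.organ_content(t) + pk.excreted(t)
            assert total == pytest.approx(0.3, rel=1e-12)


class TestBuildPhantom:
    def test_whole_body_balance_closes(self, phantom_default, zr):
        """Decay-corrected whole-body activity plus cumulative excreta must
        equal the injected activity at every frame (zero noise)."""
        injected = phantom_default.meta.injected_activity_mbq * 1e6
        for frame in phantom_default.frames:
            t = frame.timestamp
            resident = frame.total() / decay_factor(zr, t) / injected
            excreted = float(phantom_default.excreted_fraction(t))
            assert resident + excreted == pytest.approx(1.0, rel=1e-9)

    def test_frame_activity_never_exceeds_decayed_injected(self, phantom_default, zr):
        injected = phantom_default.meta.injected_activity_mbq * 1e6
        for frame in phantom_default.frames:
            assert frame.total() <= injected * decay_factor(zr, frame.timestamp) * (1 + 1e-12)

    def test_voxel_values_non_negative(self, phantom_default):
        for frame in phantom_default.frames:
            assert frame.values.min() >= 0

    def test_uptake_ordering_at_73h(self, phantom_default, zr):
        """Highest uptake in decreasing order: liver, adrenals, marrow; the
        heart (blood pool) has cleared by the last scan."""
        s = phantom_default
        frame = s.frame_at(73.0)
        val = {
            name: suv(frame, s.labels, name, s.meta, zr)
            for name in s.labels.labels
        }
        adrenals = (val["adrenal_left"], val["adrenal_right"])
        marrow = (val["marrow_spine"], val["marrow_left_shoulder"], val["marrow_right_shoulder"])
        assert val["liver"] > max(adrenals)
        assert min(adrenals) > max(marrow)
        assert min(marrow) > val["heart"]

    def test_suv_trends_marrow_up_heart_down(self, phantom_default, zr):
        s = phantom_default
        first, last = s.frame_at(4.0), s.frame_at(73.0)
        assert suv(last, s.labels, "marrow_spine", s.meta, zr) > suv(
            first, s.labels, "marrow_spine", s.meta, zr
        )
        assert suv(last, s.labels, "heart", s.meta, zr) < suv(
            first, s.labels, "heart", s.meta, zr
        )

    def test_organ_activity_matches_closed_form_at_24h(self, phantom_default, zr):
        """Voxel sum over the liver equals b(24)·A_inj·decay computed
        independently from the rate equations."""
        s = phantom_default
        frame = s.frame_at(24.0)
        pk = s.kinetics["liver"]
        # independent evaluation of the catenary solution
        f, ku, kb = pk.uptake_fraction, pk.k_up, pk.k_bio
        b24 = f * ku / (ku - kb) * (np.exp(-kb * 24) - np.exp(-ku * 24))
        expected = s.meta.injected_activity_mbq * 1e6 * decay_factor(zr, 24.0) * b24
        mask = s.labels.mask("liver")
        measured = frame.values[mask].sum() * s.grid.voxel_volume_ml
        assert measured == pytest.approx(expected, rel=1e-9)

    def test_determinism_digest(self):
        a = build_phantom(seed=7)
        b = build_phantom(seed=7)
        assert a.digest() == b.digest()

    def test_noise_changes_digest_but_seed_reproduces(self, phantom_default):
        a = add_imaging_noise(phantom_default, seed=3)
        b = add_imaging_noise(phantom_default, seed=3)
        c = add_imaging_noise(phantom_default, seed=4)
        assert a.digest() == b.digest()
        assert a.digest() != c.digest()

    def test_overlapping_organs_rejected(self):
        organs = default_organs("female")
        clone = organs[0].__class__(
            name="heart2", label=99, shape=organs[0].shape, pk=organs[0].pk
        )
        with pytest.raises(ValueError, match="overlaps"):
            build_phantom(PhantomConfig(organs=organs + (clone,)))

    def test_organ_outside_body_rejected(self):
        bad = default_organs("female")[0].__class__(
            name="outside", label=99,
            shape=Shape("ellipsoid", (10.0, 10.0, 10.0), (20.0, 20.0, 20.0)),
            pk=PKParams(0.01, 1.0, 0.01),
        )
        with pytest.raises(ValueError, match="outside"):
            build_phantom(PhantomConfig(organs=default_organs("female") + (bad,)))

    def test_testes_only_in_males(self):
        assert "testes" not in {o.name for o in default_organs("female")}
        assert "testes" in {o.name for o in default_organs("male")}


class TestImagingNoise:
    def test_zero_noise_zero_blur_is_identity(self, phantom_default):
        out = add_imaging_noise(phantom_default, psf_sigma_mm=0.0, noise_cv=0.0, seed=1)
        for a, b in zip(out.frames, phantom_default.frames):
            np.testing.assert_array_equal(a.values, b.values)

    def test_blur_conserves_total_activity(self, phantom_default):
        """Blur-only degradation loses < 0.5% to boundary truncation for the
        interior-supported body."""
        out = add_imaging_noise(phantom_default, psf_sigma_mm=4.0, noise_cv=0.0, seed=1)
        for a, b in zip(out.frames, phantom_default.frames):
            assert a.total() == pytest.approx(b.total(), rel=0.005)

    def test_negative_parameters_rejected(self, phantom_default):
        with pytest.raises(ValueError):
            add_imaging_noise(phantom_default, psf_sigma_mm=-1.0)
        with pytest.raises(ValueError):
            add_imaging_noise(phantom_default, noise_cv=-0.1)


class TestExcretion:
    def test_curves_start_at_zero_and_are_monotone(self, phantom_default):
        ec = excretion_curves(phantom_default)
        assert ec.iloc[0]["urinary"] == 0.0
        assert ec.iloc[0]["hepatobiliary"] == 0.0
        assert (np.diff(ec["urinary"]) >= -1e-15).all()
        assert (np.diff(ec["hepatobiliary"]) >= -1e-15).all()

    def test_plateau_equals_total_cleared(self, phantom_default):
        ec = excretion_curves(phantom_default, np.array([0.0, 5000.0]))
        total = ec.iloc[-1]["urinary"] + ec.iloc[-1]["hepatobiliary"]
        # every pathway eventually clears completely
        assert total == pytest.approx(1.0, abs=1e-4)

    def test_most_excretion_before_73h(self, phantom_default):
        """At default rates ≥ 80% of the one-week biological excretion has
        occurred by the last scan at 73 h."""
        ec = excretion_curves(phantom_default, np.array([73.0, 168.0])).set_index("time_h")
        frac = ec.loc[73.0].sum() / ec.loc[168.0].sum()
        assert frac >= 0.8
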