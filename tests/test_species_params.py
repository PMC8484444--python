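import hashlib
import json
from dataclasses import asdict

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tephrisim import (
    available_species,
    daily_rate_from_survival,
    dev_increment,
    dev_rate,
    fecundity_profile,
    load_species,
    mortality_rate,
    phi_RH,
    phi_T,
    symmetric_window,
)
from tephrisim.species_params import StageParams, _phi_T_raw

# guards against transcription drift in the shipped parameter files
REGISTRY_SHA256 = "17efaf5070cb2a580a53395132cf253ad70a13a7d44eea6ee7aff50fd3fe14af"


def _registry_digest():
    blob = {}
    for name in available_species():
        sp = load_species(name)
        d = {
            "stages": {k: asdict(v) for k, v in sp.stages.items()},
            "reproduction": asdict(sp.reproduction),
            "mortality": {k: asdict(v) for k, v in sp.mortality.items()},
            "rate_audit": [
                list(map(list, [[a], list(stages)])) for a, stages in sp.rate_audit
            ],
        }
        d["reproduction"].pop("phiT_norm")  # computed, not transcribed
        blob[name] = d
    canon = json.dumps(blob, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


class TestRegistry:
    def test_available(self):
        assert available_species() == ("medfly", "melon_fly", "mexfly",
                                       "oriental_fly")

    def test_unknown_species(self):
        with pytest.raises(KeyError, match="medfly"):
            load_species("tsetse")

    def test_medfly_adult_row(self, medfly):
        adult = medfly.stage("adult")
        assert adult.delta == 772.0
        assert adult.theta_L == 9.5

    def test_melon_egg_larva_row(self, melon_fly):
        el = melon_fly.stage("egg_larva")
        assert el.delta == 104.0
        assert el.theta_L == 7.95

    def test_mexfly_erlang_k(self, mexfly):
        ks = tuple(mexfly.stage(s).erlang_k for s in ("egg_larva", "pupa", "adult"))
        assert ks == (25, 40, 68)

    def test_all_stages_present(self, species):
        for sid in ("egg_larva", "pupa", "adult", "quiescent_adult"):
            assert sid in species.stages

    def test_frozen_checksum(self):
        assert _registry_digest() == REGISTRY_SHA256

    def test_stage_invariants(self, species):
        for p in species.stages.values():
            assert p.delta > 0
            assert p.theta_L < p.theta_U
            assert p.erlang_k >= 1
            assert p.b > 1

    def test_invalid_stage_params_rejected(self):
        with pytest.raises(ValueError):
            StageParams("egg_larva", delta=-1, theta_L=10, theta_U=33,
                        b=4, a=0.01, erlang_k=25)
        with pytest.raises(ValueError):
            StageParams("egg_larva", delta=100, theta_L=35, theta_U=33,
                        b=4, a=0.01, erlang_k=25)


class TestDevRate:
    def test_zero_at_threshold(self, melon_fly):
        assert dev_rate(7.95, melon_fly.stage("egg_larva")) == 0.0

    def test_melon_el_at_25(self, melon_fly):
        # frozen from direct evaluation: 0.00975*17.05/(1+4**-8.5)
        assert dev_rate(25.0, melon_fly.stage("egg_larva")) == pytest.approx(
            0.1662362, rel=1e-5
        )

    def test_medfly_adult_at_25(self, medfly):
        assert dev_rate(25.0, medfly.stage("adult")) == pytest.approx(
            0.0914499, rel=1e-5
        )

    def test_monotone_on_linear_range(self, species):
        for p in species.stages.values():
            ts = np.linspace(p.theta_L + 0.5, p.theta_U - 5, 30)
            rates = [dev_rate(t, p) for t in ts]
            assert np.all(np.diff(rates) > 0)


class TestDevIncrement:
    def test_zero_at_threshold(self, medfly):
        assert dev_increment(9.5, medfly.stage("pupa")) == 0.0

    def test_medfly_pupa_at_25(self, medfly):
        assert dev_increment(25.0, medfly.stage("pupa")) == pytest.approx(
            15.5, abs=1e-3
        )

    def test_half_linear_at_inflection(self, medfly):
        # b**0 == 1, so the increment is exactly half the linear value
        assert dev_increment(33.7, medfly.stage("pupa")) == pytest.approx(
            (33.7 - 9.5) / 2
        )

    def test_integrates_to_delta(self, species):
        # constant T in the linear range: delta/(T-thetaL) days reaches delta
        for p in species.stages.values():
            T = p.theta_L + 12.0
            dx = dev_increment(T, p)
            days = p.delta / (T - p.theta_L)
            assert days * dx == pytest.approx(p.delta, rel=0.005)


class TestRateCoefficientAudit:
    @pytest.mark.parametrize("name", ["melon_fly", "oriental_fly", "mexfly"])
    def test_printed_a_matches_inverse_delta(self, name):
        sp = load_species(name)
        assert sp.rate_audit, f"{name} should declare a rate audit"
        for a, stages in sp.rate_audit:
            delta = sum(sp.stage(s).delta for s in stages)
            assert a == pytest.approx(1.0 / delta, rel=0.10)


class TestSymmetricWindow:
    def test_midpoint_is_one(self):
        assert symmetric_window(23.5, 15.0, 32.0) == 1.0

    def test_boundary_zero(self):
        assert symmetric_window(15.0, 15.0, 32.0) == 0.0
        assert symmetric_window(32.0, 15.0, 32.0) == 0.0

    def test_bad_bounds(self):
        with pytest.raises(ValueError):
            symmetric_window(1.0, 5.0, 5.0)

    @given(st.floats(min_value=10.0, max_value=40.0))
    def test_symmetry(self, x):
        lo, hi = 15.0, 32.0
        assert symmetric_window(x, lo, hi) == pytest.approx(
            symmetric_window(lo + hi - x, lo, hi), abs=1e-12
        )


class TestPhiT:
    def test_oriental_clamped_at_16(self, oriental_fly):
        assert phi_T(16.0, oriental_fly) == 0.0

    def test_oriental_raw_cubic_at_25(self, oriental_fly):
        raw = _phi_T_raw(25.0, oriental_fly.reproduction.phiT_spec)
        assert raw == pytest.approx(0.9645, abs=1e-3)

    def test_medfly_window_edge(self, medfly):
        assert phi_T(32.0, medfly) == 0.0

    def test_normalized_sup_is_one(self, species):
        stage = species.stage("adult")
        grid = np.linspace(stage.theta_L, stage.theta_U + 5.0, 2001)
        vals = [phi_T(t, species) for t in grid]
        assert max(vals) == pytest.approx(1.0, abs=5e-4)

    @given(st.floats(min_value=-50.0, max_value=60.0))
    def test_bounded(self, T):
        for name in available_species():
            v = phi_T(T, load_species(name))
            assert 0.0 <= v <= 1.0


class TestPhiRH:
    def test_medfly_quartic_at_50(self, medfly):
        assert phi_RH(50.0, medfly) == pytest.approx(0.9622814, rel=1e-6)

    def test_melon_window_midpoint(self, melon_fly):
        assert phi_RH(67.5, melon_fly) == 1.0

    def test_mexfly_scaled_clamps(self, mexfly):
        # 1.36 * 0.962 > 1, clamped
        assert phi_RH(50.0, mexfly) == 1.0

    def test_out_of_range_errors(self, medfly):
        with pytest.raises(ValueError):
            phi_RH(-1.0, medfly)
        with pytest.raises(ValueError):
            phi_RH(101.0, medfly)

    @given(st.floats(min_value=0.0, max_value=100.0))
    def test_bounded(self, rh):
        for name in available_species():
            v = phi_RH(rh, load_species(name))
            assert 0.0 <= v <= 1.0


class TestMortality:
    def test_medfly_el_at_20(self, medfly):
        assert mortality_rate(20.0, "egg_larva", medfly) == pytest.approx(
            0.05774, abs=1e-5
        )

    def test_mexfly_cold_branch_at_0(self, mexfly):
        assert mortality_rate(0.0, "egg_larva", mexfly) == pytest.approx(0.518)

    def test_clamp_ceiling(self, species):
        for grp in ("egg_larva", "pupa_adult"):
            assert mortality_rate(-40.0, grp, species) == 1.0

    def test_alias_resolution(self, melon_fly):
        assert mortality_rate(15.0, "pupa_adult", melon_fly) == mortality_rate(
            15.0, "egg_larva", melon_fly
        )

    def test_unknown_group(self, medfly):
        with pytest.raises(KeyError):
            mortality_rate(20.0, "larva", medfly)

    @given(st.floats(min_value=-60.0, max_value=60.0))
    def test_bounded(self, T):
        for name in available_species():
            sp = load_species(name)
            for grp in ("egg_larva", "pupa_adult"):
                assert 0.0 <= mortality_rate(T, grp, sp) <= 1.0


class TestFecundity:
    def test_medfly_gate_boundary(self, medfly):
        assert fecundity_profile(3.0, medfly) == 0.0

    def test_medfly_at_10(self, medfly):
        assert fecundity_profile(10.0, medfly) == pytest.approx(24.2424, abs=1e-3)

    def test_mexfly_gate(self, mexfly):
        assert fecundity_profile(11.0, mexfly) == 0.0

    def test_zero_before_offset(self, species):
        x0 = species.reproduction.x0
        for x in np.linspace(0.0, x0, 10):
            assert fecundity_profile(x, species) == 0.0

    def test_single_interior_maximum(self, species):
        xs = np.linspace(0.0, 200.0, 4001)
        ys = np.array([fecundity_profile(x, species) for x in xs])
        assert ys.max() > 0
        d = np.diff(ys)
        # one sign change from rising to falling after the gate
        rising = d > 0
        switches = np.sum(rising[:-1] & ~rising[1:])
        assert switches == 1
        assert ys[-1] < 1e-2 * ys.max()  # decays toward 0

    def test_negative_age_errors(self, medfly):
        with pytest.raises(ValueError):
            fecundity_profile(-0.1, medfly)


class TestDailyRateFromSurvival:
    def test_cold_larvae_published_values(self):
        s, m = daily_rate_from_survival(0.079, 14)
        assert round(s, 3) == 0.834
        assert round(m, 3) == 0.166

    def test_freezing_published_values(self):
        s, m = daily_rate_from_survival(0.0016, 14)
        assert round(s, 3) == 0.631
        assert round(m, 3) == 0.369

    def test_full_survival(self):
        assert daily_rate_from_survival(1.0, 14) == (1.0, 0.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            daily_rate_from_survival(0.0, 14)
        with pytest.raises(ValueError):
            daily_rate_from_survival(0.5, 0)
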