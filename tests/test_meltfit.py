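"""Two-state melt fitting: parameter recovery, model discrimination, joint fit."""

import numpy as np
import pytest

from meltfold import factors, meltfit, presets, synth
from meltfold.equilibria import (
    EquilibriumConditions,
    ThermoParams,
    kelvin_to_celsius,
    melting_temperature,
)
from meltfold.meltfit import (
    NotSeparableError,
    ShiftProfile,
    fit_joint,
    fit_shift_profiles,
    fit_uv_scores,
    per_resonance_tm,
)

TRUE_TM_NMR = kelvin_to_celsius(melting_temperature(presets.SRESEG16_NMR_HAIRPIN))
TRUE_TM_UV = kelvin_to_celsius(melting_temperature(presets.SRESEG16_UV_HAIRPIN))


class TestUvScoreFit:
    def test_recovers_generator_tm(self, uv_series):
        dec = factors.decompose(uv_series)
        fit = fit_uv_scores(dec, 4, "hairpin", presets.COND_UV_SRESEG16)
        assert fit.tm_celsius == pytest.approx(TRUE_TM_UV, abs=0.5)
        assert fit.params.dH == pytest.approx(-137e3, rel=0.05)

    def test_noiseless_fit_is_essentially_exact(self):
        cfg = synth.SynthConfig(seed=0, uv_noise_sigma=0.0)
        dec = factors.decompose(synth.synth_uv_series(cfg))
        fit = fit_uv_scores(dec, 4, "hairpin", presets.COND_UV_SRESEG16)
        assert fit.rss < 1e-18
        assert fit.tm_celsius == pytest.approx(TRUE_TM_UV, abs=1e-6)

    def test_hairpin_and_duplex_fits_indistinguishable_at_one_concentration(
        self, uv_series
    ):
        # single-concentration melting data cannot discriminate molecularity:
        # the bimolecular fit compensates its broader intrinsic transition
        # with a larger |dH| and yields a visually unresolvable curve
        dec = factors.decompose(uv_series)
        fit_h = fit_uv_scores(dec, 4, "hairpin", presets.COND_UV_SRESEG16)
        fit_d = fit_uv_scores(dec, 4, "duplex", presets.COND_UV_SRESEG16)
        assert abs(fit_d.params.dH) > 1.4 * abs(fit_h.params.dH)
        t = np.linspace(5.0, 85.0, 200)
        for j in range(2):
            amp = np.ptp(dec.W[j] * dec.V[:, j])
            diff = np.max(np.abs(fit_h.predict(j, t) - fit_d.predict(j, t)))
            assert diff < 0.01 * amp

    def test_requires_two_scores(self, uv_series):
        dec = factors.decompose(uv_series)
        with pytest.raises(ValueError):
            fit_uv_scores(dec, 1, "hairpin", presets.COND_UV_SRESEG16)


class TestShiftProfileFit:
    def test_global_fit_recovers_table_parameters(self, shift_profiles):
        fit = fit_shift_profiles(shift_profiles, "hairpin", presets.COND_NMR_SRESEG16)
        assert fit.tm_celsius == pytest.approx(TRUE_TM_NMR, abs=0.5)
        assert fit.params.dH == pytest.approx(-137e3, rel=0.03)

    def test_replicate_recovery_statistics(self):
        # >= 20 seeded replicates at the default noise level
        errs_tm, errs_dh = [], []
        for seed in range(20):
            profs = synth.synth_shift_profiles(synth.SynthConfig(seed=seed))
            fit = fit_shift_profiles(profs, "hairpin", presets.COND_NMR_SRESEG16)
            errs_tm.append(abs(fit.tm_celsius - TRUE_TM_NMR))
            errs_dh.append(abs(fit.params.dH + 137e3) / 137e3)
        assert np.median(errs_tm) < 0.5
        assert np.median(errs_dh) < 0.05

    def test_single_noiseless_profile_exact(self):
        cfg = synth.SynthConfig(seed=0, shift_noise_sigma=0.0)
        profs = synth.synth_shift_profiles(cfg)[:1]
        fit = fit_shift_profiles(profs, "hairpin", presets.COND_NMR_SRESEG16)
        assert fit.tm_celsius == pytest.approx(TRUE_TM_NMR, abs=1e-6)
        assert fit.params.dH == pytest.approx(-137e3, rel=1e-6)

    def test_mixed_sign_amplitudes_share_one_tm(self, shift_profiles):
        # some shifts move up on melting, some down; split by the sign of
        # the generator's folded-unfolded amplitude and refit each group
        amp = {row[0]: row[3] - row[1] for row in synth.DEFAULT_RESONANCE_TABLE}
        up = [p for p in shift_profiles if amp[p.nucleus] > 0]
        down = [p for p in shift_profiles if amp[p.nucleus] <= 0]
        assert up and down
        fit_up = fit_shift_profiles(up, "hairpin", presets.COND_NMR_SRESEG16)
        fit_down = fit_shift_profiles(down, "hairpin", presets.COND_NMR_SRESEG16)
        pooled = np.hypot(fit_up.stderr["Tm"], fit_down.stderr["Tm"])
        assert abs(fit_up.tm_celsius - fit_down.tm_celsius) < 3.0 * max(pooled, 0.3)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            ShiftProfile("x", np.arange(4.0), np.zeros(4))

    def test_reparameterization_consistency(self, shift_profiles):
        # ΔS derived from the internal (Tm, ΔH) equals ΔH/Tm for the hairpin
        fit = fit_shift_profiles(shift_profiles, "hairpin", presets.COND_NMR_SRESEG16)
        assert fit.params.dS == pytest.approx(fit.params.dH / fit.Tm, rel=1e-9)
        assert melting_temperature(fit.params, "hairpin") == pytest.approx(
            fit.Tm, rel=1e-9
        )

    def test_duplex_model_recovers_octamer_tm(self):
        cond = presets.COND_NMR_CTTCGAAG
        profs = synth.synth_shift_profiles(
            synth.SynthConfig(seed=4),
            thermo=presets.CTTCGAAG_NMR_DUPLEX,
            model="duplex",
            cond=cond,
        )
        fit = fit_shift_profiles(profs, "duplex", cond)
        true_tm = kelvin_to_celsius(
            melting_temperature(presets.CTTCGAAG_NMR_DUPLEX, "duplex", cond)
        )
        assert fit.tm_celsius == pytest.approx(true_tm, abs=0.5)


class TestConcentrationDiscrimination:
    """Unimolecular Tm is concentration independent, bimolecular is not."""

    def test_hairpin_fit_tm_concentration_independent(self):
        tms = []
        for i, c in enumerate((3.08e-6, 1.14e-3)):
            cond = EquilibriumConditions(c=c)
            profs = synth.synth_shift_profiles(
                synth.SynthConfig(seed=7 + i), thermo=presets.SRESEG16_NMR_HAIRPIN,
                model="hairpin", cond=cond,
            )
            tms.append(fit_shift_profiles(profs, "hairpin", cond).tm_celsius)
        assert abs(tms[0] - tms[1]) < 0.5

    def test_duplex_data_shifts_tm_with_concentration(self):
        du = presets.CTTCGAAG_NMR_DUPLEX
        tms = []
        for i, c in enumerate((1.06e-3, 1.06e-5)):
            cond = EquilibriumConditions(c=c)
            profs = synth.synth_shift_profiles(
                synth.SynthConfig(seed=9 + i), thermo=du, model="duplex", cond=cond
            )
            tms.append(fit_shift_profiles(profs, "duplex", cond).tm_celsius)
        # dilution by 100x must lower the apparent duplex Tm
        assert tms[0] - tms[1] > 5.0


class TestPerResonance:
    def test_all_resonances_agree_with_generator_tm(self):
        # line-fit shift precision so each transition is individually sharp
        cfg = synth.SynthConfig(seed=5, shift_noise_sigma=0.0005)
        strong = tuple(
            r for r in synth.DEFAULT_RESONANCE_TABLE if abs(r[1] - r[3]) >= 0.2
        )
        per = per_resonance_tm(
            synth.synth_shift_profiles(cfg, resonance_table=strong),
            "hairpin",
            presets.COND_NMR_SRESEG16,
        )
        tms = np.array([r["Tm_celsius"] for r in per if not r["flag"]])
        errs = np.array([r["stderr"] for r in per if not r["flag"]])
        assert len(tms) == len(strong)
        assert np.max(tms) - np.min(tms) < 2.0  # strong melting cooperativity
        assert np.all(np.abs(tms - TRUE_TM_NMR) < 4.0 * np.maximum(errs, 0.1))

    def test_flat_profile_flagged_no_transition(self):
        cfg = synth.SynthConfig(seed=1)
        flat = synth.synth_shift_profiles(
            cfg, resonance_table=(("X H8", 8.0, 0.0002, 8.0, 0.0002),)
        )
        rec = per_resonance_tm(flat, "hairpin", presets.COND_NMR_SRESEG16)[0]
        assert rec["flag"] == "no transition"

    def test_two_population_mixture_detected_as_bimodal(self):
        cfg = synth.SynthConfig(seed=2, shift_noise_sigma=0.0005)
        low = ThermoParams(dH=-120e3, dS=-120e3 / 318.15)  # Tm 45 C
        strong = tuple(
            r for r in synth.DEFAULT_RESONANCE_TABLE if abs(r[1] - r[3]) >= 0.2
        )
        profs = synth.synth_shift_profiles(cfg, resonance_table=strong[:4], thermo=low)
        profs += synth.synth_shift_profiles(
            synth.SynthConfig(seed=3, shift_noise_sigma=0.0005),
            resonance_table=strong[4:8],
        )
        tms = sorted(
            r["Tm_celsius"]
            for r in per_resonance_tm(profs, "hairpin", presets.COND_NMR_SRESEG16)
            if not r["flag"]
        )
        gaps = np.diff(tms)
        assert gaps.max() > 10.0  # two clusters ~17 C apart
        assert min(tms) == pytest.approx(45.0, abs=2.0)
        assert max(tms) == pytest.approx(TRUE_TM_NMR, abs=2.0)


@pytest.fixture(scope="module")
def joint_data():
    cond_uv, cond_nmr = presets.COND_UV_SRESEG16, presets.COND_NMR_SRESEG16
    hp = presets.SRESEG16_NMR_HAIRPIN
    duplex = synth.solve_duplex_entropy(0.07, 13.0, cond_nmr, hp, -217e3)
    cfg = synth.SynthConfig(seed=3)
    series = synth.synth_uv_series(
        cfg, thermo=hp, model="combined", cond=cond_uv, duplex=duplex
    )
    profiles = synth.synth_shift_profiles(
        cfg, thermo=hp, model="combined", cond=cond_nmr, duplex=duplex
    )
    return factors.decompose(series), profiles, cond_uv, cond_nmr


class TestJointFit:
    def test_recovers_duplex_fraction_at_13C(self, joint_data):
        dec, profiles, cond_uv, cond_nmr = joint_data
        res = fit_joint((dec, 4, cond_uv), (profiles, cond_nmr))
        f_du = res.fraction_at(13.0, cond_nmr.c)[1]
        assert f_du == pytest.approx(0.07, abs=0.03)
        assert not res.non_identifiable

    def test_duplex_fraction_curve_behaviour(self, joint_data):
        dec, profiles, cond_uv, cond_nmr = joint_data
        res = fit_joint((dec, 4, cond_uv), (profiles, cond_nmr))
        grid = np.arange(5.0, 96.0, 1.0)
        high = meltfit.duplex_fraction_curve(res, grid, cond_nmr.c)
        low = meltfit.duplex_fraction_curve(res, grid, cond_uv.c)
        assert np.all((0 <= high) & (high <= 1))
        assert high.max() > low.max()  # bimolecular: more duplex when concentrated
        assert high[-1] < 0.01  # far above both transitions everything is melted
        tiny = meltfit.duplex_fraction_curve(res, np.array([13.0]), 1e-12)[0]
        assert tiny < 1e-6  # c -> 0 kills the bimolecular species

    def test_single_method_is_not_separable(self, joint_data):
        dec, profiles, cond_uv, cond_nmr = joint_data
        with pytest.raises(NotSeparableError, match="not separable"):
            fit_joint((dec, 4, cond_uv), None)
        with pytest.raises(NotSeparableError):
            fit_joint(None, (profiles, cond_nmr))
        forced = fit_joint(None, (profiles, cond_nmr), require_separable=False)
        assert forced.non_identifiable

    def test_close_concentrations_warn(self, joint_data):
        dec, profiles, _, cond_nmr = joint_data
        near = EquilibriumConditions(c=cond_nmr.c / 2)
        with pytest.warns(UserWarning, match="separable"):
            fit_joint((dec, 4, near), (profiles, cond_nmr))

    def test_null_generator_yields_negligible_duplex(self):
        cond_uv, cond_nmr = presets.COND_UV_SRESEG16, presets.COND_NMR_SRESEG16
        hp = presets.SRESEG16_NMR_HAIRPIN
        cfg = synth.SynthConfig(seed=1)
        dec = factors.decompose(
            synth.synth_uv_series(cfg, thermo=hp, model="hairpin", cond=cond_uv)
        )
        profiles = synth.synth_shift_profiles(
            cfg, thermo=hp, model="hairpin", cond=cond_nmr
        )
        res = fit_joint((dec, 4, cond_uv), (profiles, cond_nmr))
        assert res.fraction_at(13.0, cond_nmr.c)[1] < 0.01
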