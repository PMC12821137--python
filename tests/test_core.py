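"""The activity-coefficient engine: exchange energies, the segment fixed
point, the combinatorial term and ln gamma, each against independent oracles."""

import numpy as np
import pytest

from cosmosac.core import (
    MixtureState,
    ParameterSet,
    available_presets,
    exchange_energy,
    idac,
    ln_gamma,
    misfit_alpha,
    solve_segment_gammas,
    staverman_guggenheim,
)
from cosmosac.exceptions import ConfigurationError, ValidationError
from cosmosac.sigma import SigmaGrid, SigmaProfile

from conftest import HB_CONSTANT_NAMES

# ---------------------------------------------------------------------------
# independent oracles (scalar loops, written directly from the model formulas)
# ---------------------------------------------------------------------------

def oracle_segment_gammas(sigmas, classes, p, T, params, tol=1e-12, max_iter=50000):
    """Brute-force damped iteration on Gamma itself (not ln Gamma)."""
    n = len(sigmas)
    W = np.array([
        [exchange_energy(sigmas[i], sigmas[j], classes[i], classes[j], params)
         for j in range(n)]
        for i in range(n)
    ])
    RT = params.gas_constant * T
    G = np.ones(n)
    for _ in range(max_iter):
        Gnew = np.array([
            1.0 / sum(p[j] * G[j] * np.exp(-W[i][j] / RT) for j in range(n))
            for i in range(n)
        ])
        if np.max(np.abs(Gnew - G)) < tol:
            return Gnew
        G = 0.5 * (G + Gnew)
    raise AssertionError("oracle iteration did not converge")


def oracle_sg(x, r, q, z=10.0):
    x, r, q = map(np.asarray, (x, r, q))
    phi = x * r / (x @ r)
    theta = x * q / (x @ q)
    ell = z / 2 * (r - q) - (r - 1)
    out = np.empty(len(x))
    for i in range(len(x)):
        out[i] = (np.log(phi[i] / x[i]) + z / 2 * q[i] * np.log(theta[i] / phi[i])
                  + ell[i] - phi[i] / x[i] * (x @ ell))
    return out


def toy_profile(name, entries, total_area=60.0, volume=50.0,
                classes=("NONE",), grid=None):
    """SigmaProfile with areas placed at chosen (class, sigma-center) spots."""
    grid = grid or SigmaGrid()
    areas = np.zeros((len(classes), grid.n_bins))
    for cls, sig, a in entries:
        k = int(np.argmin(np.abs(grid.centers - sig)))
        areas[classes.index(cls), k] += a
    return SigmaProfile(grid=grid, classes=classes, areas=areas,
                        total_area=total_area, volume=volume, name=name)


def oracle_ln_gamma_binary(prof1, prof2, x, T, params):
    """End-to-end independent evaluation for a binary of toy profiles."""
    classes = ("NONE", "OH_DONOR", "OH_ACCEPTOR", "NH_DONOR", "N_ACCEPTOR",
               "WATER_DONOR", "WATER_ACCEPTOR", "OTHER_ACCEPTOR")

    def flat(prof):
        out = {}
        for ci, cls in enumerate(prof.classes):
            for k in range(prof.grid.n_bins):
                if prof.areas[ci, k] > 0:
                    out[(cls, prof.grid.centers[k])] = out.get(
                        (cls, prof.grid.centers[k]), 0.0) + prof.areas[ci, k]
        return out

    f1, f2 = flat(prof1), flat(prof2)
    keys = sorted(set(f1) | set(f2))
    a1 = np.array([f1.get(k, 0.0) for k in keys])
    a2 = np.array([f2.get(k, 0.0) for k in keys])
    mix = x[0] * a1 + x[1] * a2
    sig = [k[1] for k in keys]
    cls = [k[0] for k in keys]

    def lng(weights):
        p = weights / weights.sum()
        keep = p > 0
        G = oracle_segment_gammas(
            [s for s, k in zip(sig, keep) if k],
            [c for c, k in zip(cls, keep) if k],
            p[keep], T, params)
        # evaluate ln Gamma at every key against the populated set
        out = np.empty(len(keys))
        RT = params.gas_constant * T
        kept_idx = np.nonzero(keep)[0]
        for i in range(len(keys)):
            s = sum(p[j] * G[jj] * np.exp(-exchange_energy(
                sig[i], sig[j], cls[i], cls[j], params) / RT)
                for jj, j in enumerate(kept_idx))
            out[i] = -np.log(s)
        return out

    lng_mix = lng(mix)
    res = []
    for prof, a in ((prof1, a1), (prof2, a2)):
        lng_pure = lng(a)
        p = a / a.sum()
        n_i = prof.total_area / params.a_eff
        res.append(n_i * float(p @ (lng_mix - lng_pure)))
    r = np.array([prof1.volume, prof2.volume]) / params.r0_volume
    q = np.array([prof1.total_area, prof2.total_area]) / params.q0_area
    return np.array(res) + oracle_sg(x, r, q, params.z_coordination)


# ---------------------------------------------------------------------------

TABLE2 = {
    "HB2-FINE": dict(
        variant="hb2", f_pol=0.9987, r_avg=1.5000, r_eff=1.1781, sigma_hb=7.01e-3,
        c_hb={"C_HB": 8263.93, "C_HB2": 16061.92, "C_HB3": 7496.26,
              "C_HB4": 16989.74, "C_HB5": 25332.78, "C_HB6": 12882.18,
              "C_HB7": 28400.07, "C_HB8": 19668.59},
    ),
    "HB2-BP-TZVP": dict(
        variant="hb2", f_pol=0.7560, r_avg=1.5000, r_eff=1.2806, sigma_hb=7.03e-3,
        c_hb={"C_HB": 8400.52, "C_HB2": 17251.80, "C_HB3": 11123.03,
              "C_HB4": 17575.78, "C_HB5": 23721.46, "C_HB6": 12733.48,
              "C_HB7": 28538.48, "C_HB8": 12978.83},
    ),
    "COSMO-SAC-FINE": dict(
        variant="cosmosac2002", f_pol=0.8893, r_avg=1.6000, r_eff=1.2547,
        sigma_hb=1.15e-2, c_hb=181543.18,
    ),
    "HB2-HF-TZVP": dict(
        variant="hb2", f_pol=0.7817, r_avg=1.1000, r_eff=1.1567, sigma_hb=7.70e-3,
        c_hb={"C_HB": 15020.48, "C_HB2": 14171.02, "C_HB3": 9327.21,
              "C_HB4": 14171.02, "C_HB5": 14171.02, "C_HB6": 6866.67,
              "C_HB7": 4642.64, "C_HB8": 14171.02},
    ),
    "COSMO-SAC-HF-TZVP": dict(
        variant="cosmosac2002", f_pol=0.8041, r_avg=1.4000, r_eff=1.1565,
        sigma_hb=1.01e-2, c_hb=58250.49,
    ),
}


class TestParameterSets:
    def test_all_five_presets_available(self):
        assert set(available_presets()) == set(TABLE2)

    @pytest.mark.parametrize("name", sorted(TABLE2))
    def test_preset_fields_exact(self, name):
        p = ParameterSet.from_preset(name)
        ref = TABLE2[name]
        assert p.variant == ref["variant"]
        assert p.f_pol == ref["f_pol"]
        assert p.r_avg == ref["r_avg"]
        assert p.r_eff == ref["r_eff"]
        assert p.sigma_hb == ref["sigma_hb"]
        assert p.c_hb == ref["c_hb"]

    def test_alias_and_case_insensitive_lookup(self):
        assert ParameterSet.from_preset("SAC-FINE").name == "COSMO-SAC-FINE"
        assert ParameterSet.from_preset("hb2-fine").name == "HB2-FINE"

    def test_unknown_preset_lists_available(self):
        with pytest.raises(ConfigurationError, match="HB2-FINE"):
            ParameterSet.from_preset("nope")

    def test_invariants_enforced(self):
        with pytest.raises(ConfigurationError):
            ParameterSet(f_pol=2.0)
        with pytest.raises(ConfigurationError):
            ParameterSet(r_eff=-1.0)
        with pytest.raises(ConfigurationError):
            ParameterSet(variant="hb2", c_hb=100.0)  # needs a constant table


class TestMisfitAlpha:
    def test_unit_effective_area(self):
        p = ParameterSet(f_pol=1.0, r_eff=1.0 / np.sqrt(np.pi))
        assert p.a_eff == pytest.approx(1.0, abs=1e-14)
        assert misfit_alpha(p) == pytest.approx(0.3 / p.eps0, rel=1e-12)

    def test_hb2_fine_closed_form(self, hb2_params):
        a_eff = np.pi * 1.1781**2
        expected = 0.9987 * 0.3 * a_eff**1.5 / 2.395e-4
        assert misfit_alpha(hb2_params) == pytest.approx(expected, rel=1e-12)

    def test_linearity_in_f_pol(self, sac_params):
        doubled = sac_params.replace(f_pol=2 * sac_params.f_pol / 1.5, name="")
        # compare at a legal pair of f_pol values
        base = sac_params.replace(f_pol=sac_params.f_pol / 1.5)
        assert misfit_alpha(doubled) == pytest.approx(2 * misfit_alpha(base), rel=1e-12)


class TestExchangeEnergy:
    def test_zero_charge_identity(self, hb2_params):
        assert exchange_energy(0.0, 0.0, "NONE", "NONE", hb2_params) == 0.0

    def test_complementary_below_cutoff_vanishes(self, hb2_params):
        s = 0.004  # below sigma_hb = 0.00701
        assert exchange_energy(s, -s, "OH_ACCEPTOR", "OH_DONOR", hb2_params) == \
            pytest.approx(0.0, abs=1e-15)

    def test_hb2_fine_hand_evaluation(self, hb2_params):
        # complementary pair at +-0.012 with OH donor/acceptor classes:
        # misfit vanishes, HB term uses C_HB4
        s = 0.012
        shb = 7.01e-3
        expected = 16989.74 * (s - shb) * (-s + shb)
        got = exchange_energy(-s, s, "OH_DONOR", "OH_ACCEPTOR", hb2_params)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got < 0  # attractive

    def test_symmetry(self, hb2_params):
        a = exchange_energy(0.011, -0.009, "OH_ACCEPTOR", "NH_DONOR", hb2_params)
        b = exchange_energy(-0.009, 0.011, "NH_DONOR", "OH_ACCEPTOR", hb2_params)
        assert a == pytest.approx(b, abs=1e-15)

    def test_non_donor_acceptor_pair_gets_no_hb(self, hb2_params):
        # both donors: misfit only
        got = exchange_energy(-0.012, 0.012, "OH_DONOR", "NH_DONOR", hb2_params)
        assert got == pytest.approx(0.0, abs=1e-15)  # misfit cancels, no HB

    def test_missing_pair_constant_is_configuration_error(self):
        params = ParameterSet(
            variant="hb2", sigma_hb=0.007,
            c_hb={"C_HB": 1000.0},
            hb_pair_map={"OH_DONOR": {"OH_ACCEPTOR": "C_HB"}},
        )
        with pytest.raises(ConfigurationError, match="NH_DONOR"):
            exchange_energy(-0.012, 0.012, "NH_DONOR", "OH_ACCEPTOR", params)


class TestSegmentGammaSolver:
    def test_conductor_profile_gamma_is_one(self, sac_params):
        prof = toy_profile("cond", [("NONE", 0.0, 50.0)])
        field = solve_segment_gammas(prof, 298.15, sac_params)
        assert field.ln_gamma[0, 25] == pytest.approx(0.0, abs=1e-12)
        assert field.residual < 1e-8

    def test_converged_field_reproduces_itself(self, sac_params):
        prof = toy_profile("t", [("NONE", -0.01, 20.0), ("NONE", 0.0, 20.0),
                                 ("NONE", 0.012, 20.0)])
        field = solve_segment_gammas(prof, 298.15, sac_params, tol=1e-12)
        p = prof.p_sigma[0]
        keep = p > 0
        sig = prof.grid.centers[keep]
        lng = field.ln_gamma[0, keep]
        RT = sac_params.gas_constant * 298.15
        for i in range(len(sig)):
            rhs = -np.log(sum(
                p[keep][j] * np.exp(lng[j]) * np.exp(
                    -exchange_energy(sig[i], sig[j], "NONE", "NONE", sac_params) / RT)
                for j in range(len(sig))))
            assert rhs == pytest.approx(lng[i], abs=1e-10)

    @pytest.mark.parametrize("entries,classes", [
        ([("NONE", -0.012, 10.0), ("NONE", 0.0, 30.0), ("NONE", 0.012, 10.0)],
         ("NONE",)),
        ([("OH_DONOR", -0.011, 8.0), ("NONE", 0.0, 40.0), ("OH_ACCEPTOR", 0.013, 8.0)],
         ("NONE", "OH_DONOR", "OH_ACCEPTOR")),
    ])
    def test_matches_bruteforce_oracle(self, sac_params, hb2_params, entries, classes):
        params = hb2_params if len(classes) > 1 else sac_params
        prof = toy_profile("toy", entries, classes=classes)
        field = solve_segment_gammas(prof, 298.15, params, tol=1e-12)
        p = prof.p_sigma.ravel()
        keep = p > 0
        sig = np.tile(prof.grid.centers, len(classes))[keep]
        cls = np.repeat(classes, prof.grid.n_bins)[keep]
        G = oracle_segment_gammas(list(sig), list(cls), p[keep], 298.15, params)
        np.testing.assert_allclose(
            np.exp(field.ln_gamma.ravel()[keep]), G, rtol=1e-6)

    def test_unpopulated_bins_still_defined(self, sac_params):
        prof = toy_profile("t", [("NONE", 0.005, 25.0)])
        field = solve_segment_gammas(prof, 298.15, sac_params)
        assert np.all(np.isfinite(field.ln_gamma))


class TestStavermanGuggenheim:
    def test_equal_size_molecules_ideal(self):
        x = np.array([0.3, 0.45, 0.25])
        np.testing.assert_allclose(
            staverman_guggenheim(x, np.ones(3), np.ones(3)), 0.0, atol=1e-14)

    def test_pure_compound_zero(self):
        out = staverman_guggenheim([1.0, 0.0], [2.0, 1.3], [1.8, 1.2])
        assert out[0] == 0.0

    def test_binary_closed_form_hand_evaluation(self):
        x, r, q, z = np.array([0.5, 0.5]), np.array([2.0, 1.0]), np.array([1.8, 1.0]), 10.0
        got = staverman_guggenheim(x, r, q, z)
        np.testing.assert_allclose(got, oracle_sg(x, r, q, z), atol=1e-12)


class TestLnGamma:
    def test_pure_compound_exactly_zero(self, profiles_split, hb2_params):
        for prof in profiles_split.values():
            pad = profiles_split["alkane-like"]
            if pad is prof:
                pad = profiles_split["water-like"]
            lg = ln_gamma(MixtureState([prof, pad], [1.0, 0.0], 298.15), hb2_params)
            assert lg[0] == 0.0

    def test_indistinguishable_compounds_ideal(self, profiles_split, hb2_params):
        prof = profiles_split["water-like"]
        rng = np.random.default_rng(11)
        for x1 in rng.uniform(0.05, 0.95, 5):
            lg = ln_gamma(MixtureState([prof, prof], [x1, 1 - x1], 298.15), hb2_params)
            np.testing.assert_allclose(lg, 0.0, atol=1e-10)

    def test_binary_matches_independent_oracle(self, hb2_params):
        p1 = toy_profile("d", [("OH_DONOR", -0.012, 10.0), ("NONE", 0.0, 35.0),
                               ("OH_ACCEPTOR", 0.011, 10.0)],
                         classes=("NONE", "OH_DONOR", "OH_ACCEPTOR"),
                         total_area=55.0, volume=45.0)
        p2 = toy_profile("n", [("NONE", -0.004, 20.0), ("NONE", 0.004, 20.0)],
                         total_area=40.0, volume=60.0)
        x = np.array([0.3, 0.7])
        got = ln_gamma(MixtureState([p1, p2], x, 298.15), hb2_params, tol=1e-12)
        want = oracle_ln_gamma_binary(p1, p2, x, 298.15, hb2_params)
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_grid_mismatch_rejected(self, hb2_params, profiles_split, library):
        from cosmosac.sigma import build_profile
        other = build_profile(library["alkane-like"], 1.5, SigmaGrid(n_bins=101))
        with pytest.raises(ValidationError, match="grid"):
            ln_gamma(MixtureState([profiles_split["water-like"], other],
                                  [0.5, 0.5], 298.15), hb2_params)

    def test_high_temperature_limit_is_combinatorial(self, profiles_split, hb2_params):
        pair = [profiles_split["water-like"], profiles_split["alkane-like"]]
        x = np.array([0.3, 0.7])
        lg = ln_gamma(MixtureState(pair, x, 1e7), hb2_params)
        r = np.array([p.volume for p in pair]) / hb2_params.r0_volume
        q = np.array([p.total_area for p in pair]) / hb2_params.q0_area
        np.testing.assert_allclose(
            lg, staverman_guggenheim(x, r, q, hb2_params.z_coordination), atol=1e-5)

    def test_hb2_degenerates_to_single_constant_model(self):
        """With all eight constants equal and activation-matched classes,
        HB2 reproduces the 2002 model."""
        c = 5000.0
        hb2 = ParameterSet(variant="hb2", f_pol=0.9, r_avg=1.5, r_eff=1.2,
                           sigma_hb=0.007, c_hb={k: c for k in HB_CONSTANT_NAMES})
        flat = ParameterSet(variant="cosmosac2002", f_pol=0.9, r_avg=1.5,
                            r_eff=1.2, sigma_hb=0.007, c_hb=c)
        classes = ("NONE", "OH_DONOR", "OH_ACCEPTOR")
        pa = toy_profile("a", [("NONE", 0.0, 30.0), ("OH_DONOR", -0.012, 15.0),
                               ("OH_ACCEPTOR", 0.012, 15.0)], classes=classes)
        pb = toy_profile("b", [("NONE", 0.0, 50.0), ("OH_DONOR", -0.009, 5.0),
                               ("OH_ACCEPTOR", 0.009, 5.0)], classes=classes)
        x = np.array([0.4, 0.6])
        lg_hb2 = ln_gamma(MixtureState([pa, pb], x, 298.15), hb2)
        lg_flat = ln_gamma(
            MixtureState([pa.collapse_classes(), pb.collapse_classes()], x, 298.15),
            flat)
        np.testing.assert_allclose(lg_hb2, lg_flat, atol=1e-10)


class TestIdac:
    def test_identical_compounds_zero(self, profiles_split, hb2_params):
        p = profiles_split["alcohol-like"]
        assert idac(p, p, 298.15, hb2_params) == pytest.approx(0.0, abs=1e-12)

    def test_matches_finite_dilution(self, profiles_split, hb2_params):
        solute = profiles_split["water-like"]
        solvent = profiles_split["alkane-like"]
        inf = idac(solute, solvent, 298.15, hb2_params, tol=1e-12)
        eps = 1e-8
        fin = ln_gamma(MixtureState([solute, solvent], [eps, 1 - eps], 298.15),
                       hb2_params, tol=1e-12)[0]
        assert inf == pytest.approx(fin, abs=1e-5)

    def test_solute_solvent_asymmetry(self, profiles_split, hb2_params):
        a = idac(profiles_split["water-like"], profiles_split["alkane-like"],
                 298.15, hb2_params)
        b = idac(profiles_split["alkane-like"], profiles_split["water-like"],
                 298.15, hb2_params)
        assert abs(a - b) > 0.01

    def test_grid_refinement_stability(self, library, hb2_params):
        """Doubling the bin count moves ln gamma_inf by under 2%."""
        from cosmosac.sigma import build_profile
        for pair in (("water-like", "alkane-like"), ("alcohol-like", "ketone-like")):
            vals = []
            for n_bins in (51, 101):
                profs = [
                    build_profile(library[p], hb2_params.r_avg,
                                  SigmaGrid(n_bins=n_bins), split_hb=True)
                    for p in pair
                ]
                vals.append(idac(profs[0], profs[1], 298.15, hb2_params))
            assert vals[1] == pytest.approx(vals[0], rel=0.02)


class TestMixtureState:
    def test_simplex_violation_rejected(self, profiles_split):
        p = list(profiles_split.values())[:2]
        with pytest.raises(ValidationError):
            MixtureState(p, [0.5, 0.6], 298.15)
        with pytest.raises(ValidationError):
            MixtureState(p, [1.2, -0.2], 298.15)
        with pytest.raises(ValidationError):
            MixtureState(p, [0.5, 0.5], -1.0)
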