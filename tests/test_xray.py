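"""Reflection generation, structure factors against an independent
brute-force oracle, the amplitude target, and R factors."""

import cmath
import math

import numpy as np
import pytest

from denrefine import (
    StructureFactorEngine,
    UnitCell,
    assign_test_set,
    calc_structure_factors,
    generate_hkl,
    make_helix,
    make_observations,
    r_factors,
    read_reflections,
    write_reflections,
    xray_energy_forces,
)
from denrefine.elements import ELEMENTS, UnknownElementError
from denrefine.structures import Atom, Structure
from denrefine.xray import ReflectionError, ReflectionSet


# ---------------------------------------------------------------------------
# index generation
# ---------------------------------------------------------------------------

def brute_force_hkl(cell, d_min, span=6):
    """Independent full scan with explicit d-spacing and hemisphere test."""
    out = set()
    for h in range(-span, span + 1):
        for k in range(-span, span + 1):
            for l in range(-span, span + 1):
                if (h, k, l) == (0, 0, 0):
                    continue
                inv_d2 = (h / cell.a) ** 2 + (k / cell.b) ** 2 + (l / cell.c) ** 2
                if inv_d2 > 1.0 / d_min**2 + 1e-12:
                    continue
                first = next(x for x in (h, k, l) if x != 0)
                if first > 0:
                    out.add((h, k, l))
    return out


def test_hkl_matches_brute_force_scan():
    cell = UnitCell(20.0, 20.0, 20.0)
    refl = generate_hkl(cell, 10.0)
    assert {tuple(h) for h in refl.hkl} == brute_force_hkl(cell, 10.0)


def test_no_friedel_mates_present(helix20):
    refl = generate_hkl(helix20.unit_cell, 5.0)
    index_set = {tuple(h) for h in refl.hkl}
    assert all(tuple(-h for h in hkl) not in index_set for hkl in index_set)
    assert (0, 0, 0) not in index_set


def test_set_grows_with_resolution(helix20):
    n8 = len(generate_hkl(helix20.unit_cell, 8.0))
    n4 = len(generate_hkl(helix20.unit_cell, 4.0))
    assert n4 > n8


def test_all_reflections_within_resolution(helix20):
    refl = generate_hkl(helix20.unit_cell, 3.5)
    assert np.all(refl.cell.inv_d2(refl.hkl) <= 1 / 3.5**2 + 1e-9)


def test_unreachable_resolution_is_error():
    with pytest.raises(ReflectionError):
        generate_hkl(UnitCell(8.0, 8.0, 8.0), 10.0)


# ---------------------------------------------------------------------------
# structure factors vs an independent direct summation
# ---------------------------------------------------------------------------

def brute_force_structure_factors(structure, refl):
    """Per-reflection scalar loop, written independently of the engine."""
    cell = refl.cell
    out = []
    for hkl in refl.hkl:
        h, k, l = (int(x) for x in hkl)
        s2 = (h / cell.a) ** 2 + (k / cell.b) ** 2 + (l / cell.c) ** 2
        total = 0j
        for atom in structure.atoms:
            el = ELEMENTS[atom.element]
            f = el.ff_a * math.exp(-el.ff_b * s2) + el.ff_c
            dw = math.exp(-atom.b_factor * s2 / 4.0)
            x, y, z = atom.position
            phase = 2.0 * math.pi * (h * x / cell.a + k * y / cell.b + l * z / cell.c)
            total += atom.occupancy * f * dw * cmath.exp(1j * phase)
        out.append(total)
    return np.array(out)


@pytest.fixture(scope="module")
def small_fixture(rng=None):
    rng = np.random.default_rng(77)
    cell = UnitCell(18.0, 22.0, 25.0)
    elements = ["C", "N", "O", "S", "C", "C", "N", "O", "C", "C"] * 2
    atoms = [
        Atom(i + 1, el, el, i, "ALA", "A", rng.uniform(2, 15, 3),
             b_factor=float(rng.uniform(5, 60)), occupancy=1.0)
        for i, el in enumerate(elements)
    ]
    return Structure(atoms, cell)


def test_structure_factors_match_bruteforce_oracle(small_fixture):
    refl = generate_hkl(small_fixture.unit_cell, 4.0)
    ours = calc_structure_factors(small_fixture, refl)
    oracle = brute_force_structure_factors(small_fixture, refl)
    scale = np.abs(oracle).max()
    np.testing.assert_allclose(ours / scale, oracle / scale, atol=1e-8)


def test_friedel_symmetry_on_full_sphere(small_fixture):
    refl = generate_hkl(small_fixture.unit_cell, 5.0)
    mates = refl.copy()
    mates.hkl = -mates.hkl
    f_plus = brute_force_structure_factors(small_fixture, refl)
    f_minus = brute_force_structure_factors(small_fixture, mates)
    np.testing.assert_allclose(np.abs(f_plus), np.abs(f_minus), rtol=1e-10)


def test_single_carbon_at_origin_is_real_formfactor():
    cell = UnitCell(20.0, 20.0, 20.0)
    s = Structure([Atom(1, "C", "C", 0, "ALA", "A", np.zeros(3), b_factor=0.0)], cell)
    refl = generate_hkl(cell, 8.0)
    F = calc_structure_factors(s, refl)
    el = ELEMENTS["C"]
    expected = el.ff_a * np.exp(-el.ff_b * refl.cell.inv_d2(refl.hkl)) + el.ff_c
    np.testing.assert_allclose(F.real, expected, rtol=1e-12)
    np.testing.assert_allclose(F.imag, 0.0, atol=1e-12)


def test_lattice_translation_invariance(small_fixture):
    refl = generate_hkl(small_fixture.unit_cell, 4.0)
    F0 = calc_structure_factors(small_fixture, refl)
    cell = small_fixture.unit_cell
    shifted = small_fixture.with_coords(
        small_fixture.coords + np.array([cell.a, -cell.b, 2 * cell.c])
    )
    F1 = calc_structure_factors(shifted, refl)
    np.testing.assert_allclose(F1, F0, rtol=1e-10, atol=1e-10 * np.abs(F0).max())


def test_unknown_element_raises():
    cell = UnitCell(20.0, 20.0, 20.0)
    with pytest.raises(UnknownElementError):
        Atom(1, "XX", "Xx", 0, "UNK", "A", np.zeros(3))


# ---------------------------------------------------------------------------
# the amplitude least-squares target
# ---------------------------------------------------------------------------

def test_self_consistency_zero_energy(helix20, helix20_obs):
    e, f, k = xray_energy_forces(helix20, helix20_obs)
    fobs_scale = float(np.sum(helix20_obs.f_obs**2))
    assert e / fobs_scale <= 1e-10
    assert np.abs(f).max() < 1e-6
    assert k == pytest.approx(1.0, rel=1e-10)


def test_forces_match_finite_differences(helix20, helix20_obs, rng):
    pos = helix20.coords + rng.normal(0, 0.4, (len(helix20), 3))
    pert = helix20.with_coords(pos)
    engine = StructureFactorEngine(pert, helix20_obs)
    _, forces, _ = xray_energy_forces(pert, helix20_obs, engine=engine)
    eps = 1e-4
    for idx in [(3, 0), (50, 1), (99, 2)]:
        xp, xm = pos.copy(), pos.copy()
        xp[idx] += eps
        xm[idx] -= eps
        ep, _, _ = xray_energy_forces(pert, helix20_obs, engine=engine, positions=xp)
        em, _, _ = xray_energy_forces(pert, helix20_obs, engine=engine, positions=xm)
        fd = -(ep - em) / (2 * eps)
        assert fd == pytest.approx(forces[idx], rel=1e-4)


def test_energy_and_forces_linear_in_weight(helix20, helix20_obs, rng):
    pert = helix20.with_coords(helix20.coords + rng.normal(0, 0.3, (len(helix20), 3)))
    e1, f1, _ = xray_energy_forces(pert, helix20_obs, w_xray=1.0)
    e2, f2, _ = xray_energy_forces(pert, helix20_obs, w_xray=2.0)
    assert e2 == pytest.approx(2 * e1, rel=1e-12)
    np.testing.assert_allclose(f2, 2 * f1, rtol=1e-12)


def test_test_reflections_carry_no_force(helix20, helix20_obs, rng):
    """Randomizing the test-set amplitudes must not change energy or forces."""
    pert = helix20.with_coords(helix20.coords + rng.normal(0, 0.3, (len(helix20), 3)))
    e0, f0, _ = xray_energy_forces(pert, helix20_obs)
    scrambled = helix20_obs.copy()
    scrambled.f_obs = scrambled.f_obs.copy()
    scrambled.f_obs[scrambled.is_test] *= rng.uniform(0.1, 5.0, scrambled.n_test)
    e1, f1, _ = xray_energy_forces(pert, scrambled)
    assert e1 == pytest.approx(e0, rel=1e-14)
    np.testing.assert_array_equal(f0, f1)


def test_all_zero_fobs_rejected(helix20, helix20_obs):
    zeroed = helix20_obs.copy()
    zeroed.f_obs = np.zeros(len(zeroed))
    with pytest.raises(ReflectionError):
        xray_energy_forces(helix20, zeroed)


# ---------------------------------------------------------------------------
# R factors
# ---------------------------------------------------------------------------

def test_perfect_model_r_zero(helix20, helix20_obs):
    F = calc_structure_factors(helix20, helix20_obs)
    r_work, r_free = r_factors(helix20_obs, F)
    assert r_work == pytest.approx(0.0, abs=1e-12)
    assert r_free == pytest.approx(0.0, abs=1e-12)


def test_r_invariant_to_fcalc_scale(helix20, helix20_obs, rng):
    pert = helix20.with_coords(helix20.coords + rng.normal(0, 0.5, (len(helix20), 3)))
    F = calc_structure_factors(pert, helix20_obs)
    r1 = r_factors(helix20_obs, F)
    r2 = r_factors(helix20_obs, 17.3 * F)
    assert r1 == pytest.approx(r2, rel=1e-12)


def test_random_model_r_in_acentric_band(helix20, helix20_obs):
    """Wilson-statistics expectation for unrelated acentric structures:
    R ≈ 0.59; accept a generous Monte-Carlo band."""
    values = []
    for seed in range(5):
        rng = np.random.default_rng(seed)
        random_model = helix20.with_coords(
            rng.uniform(0, 1, (len(helix20), 3)) * np.array(helix20.unit_cell.lengths)
        )
        F = calc_structure_factors(random_model, helix20_obs)
        r_work, r_free = r_factors(helix20_obs, F)
        values.append(r_free)
    assert 0.45 < float(np.mean(values)) < 0.70


def test_empty_test_set_is_error(helix20, helix20_obs):
    refl = helix20_obs.copy()
    refl.is_test = None
    F = calc_structure_factors(helix20, refl)
    with pytest.raises(ReflectionError):
        r_factors(refl, F)


# ---------------------------------------------------------------------------
# test-set assignment and file round trip
# ---------------------------------------------------------------------------

def test_test_set_size_in_binomial_band(helix20):
    refl = generate_hkl(helix20.unit_cell, 3.2)
    big = refl.copy()
    big.hkl = big.hkl[:1000]
    flagged = assign_test_set(big, 0.10, seed=11)
    assert 80 <= flagged.n_test <= 120  # binomial 99% interval at n=1000


def test_test_set_deterministic(helix20):
    refl = generate_hkl(helix20.unit_cell, 4.0)
    a = assign_test_set(refl, 0.1, seed=5)
    b = assign_test_set(refl, 0.1, seed=5)
    np.testing.assert_array_equal(a.is_test, b.is_test)


def test_test_fraction_bounds(helix20):
    refl = generate_hkl(helix20.unit_cell, 4.0)
    with pytest.raises(ValueError):
        assign_test_set(refl, 0.6, seed=0)
    with pytest.raises(ValueError):
        assign_test_set(refl, 0.0, seed=0)


def test_reflection_file_roundtrip_exact(helix20, tmp_path):
    obs = make_observations(helix20, 4.0, noise_frac=0.05, seed=9)
    path = tmp_path / "obs.hkl"
    write_reflections(obs, path)
    back = read_reflections(path)
    np.testing.assert_array_equal(back.hkl, obs.hkl)
    np.testing.assert_array_equal(back.f_obs, obs.f_obs)   # exact round trip
    np.testing.assert_array_equal(back.sigma, obs.sigma)
    np.testing.assert_array_equal(back.is_test, obs.is_test)
    assert back.d_min == obs.d_min
    assert back.cell.lengths == obs.cell.lengths
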