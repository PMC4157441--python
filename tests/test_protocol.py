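"""Rigid-body pre-refinement, B-factor refinement, automatic weighting and
the macrocycle loop."""

import numpy as np
import pytest

from denrefine import (
    AnnealingSchedule,
    RefinementConfig,
    SelectionConfig,
    auto_weight_xray,
    bfactor_refine,
    build_topology,
    compare,
    make_bundle,
    make_helix,
    make_observations,
    rigid_body_refine,
    run_den_refinement,
)
from denrefine.synthetic import displace_chains_rigidly


@pytest.fixture(scope="module")
def bundle_truth():
    return make_bundle(3, 12, spacing=10.0)


@pytest.fixture(scope="module")
def bundle_obs(bundle_truth):
    return make_observations(bundle_truth, d_min=7.4, noise_frac=0.0, seed=3)


# ---------------------------------------------------------------------------
# rigid-body refinement
# ---------------------------------------------------------------------------

def test_pose_recovery(bundle_truth, bundle_obs):
    displaced = displace_chains_rigidly(bundle_truth, rot_deg=5.0, trans=2.0, seed=11)
    assert compare(displaced, bundle_truth).rmsd_all > 1.0
    refined = rigid_body_refine(displaced, bundle_obs)
    assert compare(refined, bundle_truth).rmsd_all <= 0.3


def test_start_at_optimum_stays(bundle_truth, bundle_obs):
    refined = rigid_body_refine(bundle_truth, bundle_obs)
    assert np.abs(refined.coords - bundle_truth.coords).max() <= 1e-6


def test_intra_segment_rigidity(bundle_truth, bundle_obs):
    displaced = displace_chains_rigidly(bundle_truth, 5.0, 2.0, seed=4)
    refined = rigid_body_refine(displaced, bundle_obs)
    for cid, idx in bundle_truth.chain_atom_indices().items():
        before = displaced.coords[idx]
        after = refined.coords[idx]
        d0 = np.linalg.norm(before[:, None] - before[None, :], axis=-1)
        d1 = np.linalg.norm(after[:, None] - after[None, :], axis=-1)
        assert np.abs(d1 - d0).max() < 1e-8


def test_segments_must_partition(bundle_truth, bundle_obs):
    idx = list(bundle_truth.chain_atom_indices().values())
    with pytest.raises(ValueError):
        rigid_body_refine(bundle_truth, bundle_obs, segments=idx[:2])


# ---------------------------------------------------------------------------
# B-factor refinement
# ---------------------------------------------------------------------------

def test_grouped_bfactor_recovery():
    truth = make_helix(20)
    for atom in truth.atoms:
        atom.b_factor = 40.0 if atom.name in ("N", "CA", "C", "O") else 80.0
    obs = make_observations(truth, d_min=3.5, noise_frac=0.0, seed=5)
    start = truth.copy()
    start.set_b_factors(np.full(len(truth), 20.0))
    refined = bfactor_refine(start, obs, mode="grouped")
    b = refined.b_factors
    main = np.array([a.name in ("N", "CA", "C", "O") for a in truth.atoms])
    assert np.abs(b[main].mean() - 40.0) / 40.0 < 0.15
    assert np.abs(b[~main].mean() - 80.0) / 80.0 < 0.15


def test_correct_b_unchanged_on_self_data(helix20, helix20_obs):
    refined = bfactor_refine(helix20, helix20_obs, mode="grouped")
    assert np.abs(refined.b_factors - helix20.b_factors).max() < 1.0


def test_bfactor_refine_never_moves_coordinates(helix20, helix20_obs):
    refined = bfactor_refine(helix20, helix20_obs, mode="individual", max_iter=5)
    np.testing.assert_array_equal(refined.coords, helix20.coords)


def test_grouped_mode_ties_group_members():
    truth = make_helix(8)
    obs = make_observations(truth, d_min=4.0, noise_frac=0.02, seed=8)
    start = truth.copy()
    start.set_b_factors(np.linspace(10, 90, len(truth)))
    refined = bfactor_refine(start, obs, mode="grouped")
    for res in refined.chains["A"]:
        mains = [a.b_factor for a in res if a.name in ("N", "CA", "C", "O")]
        sides = [a.b_factor for a in res if a.name not in ("N", "CA", "C", "O")]
        assert np.ptp(mains) == 0.0
        if sides:
            assert np.ptp(sides) == 0.0


def test_b_bounds_respected():
    truth = make_helix(6)
    obs = make_observations(truth, d_min=4.0, noise_frac=0.0, seed=2)
    start = truth.copy()
    start.set_b_factors(np.full(len(truth), 2.0))
    refined = bfactor_refine(start, obs, mode="individual", max_iter=50)
    assert refined.b_factors.min() >= 1.0
    assert refined.b_factors.max() <= 500.0


# ---------------------------------------------------------------------------
# automatic X-ray weighting
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def weighting_setup(rng=None):
    truth = make_helix(15)
    obs = make_observations(truth, d_min=3.5, noise_frac=0.0, seed=13)
    rng = np.random.default_rng(13)
    model = truth.with_coords(truth.coords + rng.normal(0, 0.25, (len(truth), 3)))
    return model, obs, build_topology(truth)


def test_auto_weight_balances_rms_forces(weighting_setup):
    from denrefine import geom_energy_forces, xray_energy_forces

    model, obs, topo = weighting_setup
    w = auto_weight_xray(model, obs, topo)
    assert w > 0
    _, f_mm = geom_energy_forces(model.coords, topo)
    _, f_x, _ = xray_energy_forces(model, obs, w_xray=w)
    ratio = np.sqrt(np.mean(f_x**2)) / np.sqrt(np.mean(f_mm**2))
    assert ratio == pytest.approx(1.0, rel=1e-6)


def test_auto_weight_self_normalizes_against_fobs_scale(weighting_setup):
    model, obs, topo = weighting_setup
    w1 = auto_weight_xray(model, obs, topo)
    scaled = obs.copy()
    scaled.f_obs = 10.0 * scaled.f_obs
    w2 = auto_weight_xray(model, scaled, topo)
    # energy is quadratic in amplitudes: weight must fall by 100 so that the
    # effective force ratio stays 1
    assert w2 * 100.0 == pytest.approx(w1, rel=1e-6)


def test_auto_weight_scales_with_forcefield(weighting_setup):
    model, obs, topo = weighting_setup
    w1 = auto_weight_xray(model, obs, topo)
    stiff = build_topology(make_helix(15), bond_k=2000.0, angle_k=200.0,
                           repulsion_k=200.0)
    w2 = auto_weight_xray(model, obs, stiff)
    assert w2 == pytest.approx(2.0 * w1, rel=0.05)


def test_auto_weight_fallback_on_zero_geometry_gradient(helix20, helix20_obs):
    topo = build_topology(helix20)
    # at the build geometry E_MM forces vanish identically
    assert auto_weight_xray(helix20, helix20_obs, topo) == 1.0


# ---------------------------------------------------------------------------
# the macrocycle loop
# ---------------------------------------------------------------------------

def _fast_config(**kw):
    defaults = dict(
        gamma=0.0,
        w_den=100.0,
        n_macrocycles=2,
        first_cycle_gamma_zero=True,
        release_last_two=False,
        bfactor_mode="none",
        min_steps=30,
        seed=5,
        schedule=AnnealingSchedule(t_start=600.0, dt_temp=100.0, timestep=1.0),
    )
    defaults.update(kw)
    return RefinementConfig(**defaults)


@pytest.fixture(scope="module")
def small_scenario():
    truth = make_helix(10)
    obs = make_observations(truth, d_min=3.5, noise_frac=0.0, seed=21)
    from denrefine import perturb_structure

    start = perturb_structure(truth, 1.0, seed=21, mode="torsion")
    return truth, start, obs


def test_refinement_reduces_r_free(small_scenario):
    truth, start, obs = small_scenario
    from denrefine import calc_structure_factors, r_factors

    _, r_free_start = r_factors(obs, calc_structure_factors(start, obs))
    result = run_den_refinement(start, start, obs, _fast_config())
    assert result.r_free < r_free_start


def test_wden_zero_reduces_to_unrestrained(small_scenario):
    truth, start, obs = small_scenario
    result = run_den_refinement(start, start, obs, _fast_config(w_den=0.0))
    assert all(rec.e_den_final == 0.0 for rec in result.trace)


def test_refinement_deterministic(small_scenario):
    truth, start, obs = small_scenario
    r1 = run_den_refinement(start, start, obs, _fast_config())
    r2 = run_den_refinement(start, start, obs, _fast_config())
    assert r1.r_free == r2.r_free
    np.testing.assert_array_equal(r1.model.coords, r2.model.coords)


def test_restraint_pairs_fixed_across_macrocycles(small_scenario):
    truth, start, obs = small_scenario
    from denrefine import select_restraints

    # γ>0 from macrocycle 2 on lets d0 track the model, so the equilibria
    # must change while the pair list stays the one selected at entry
    result = run_den_refinement(start, start, obs,
                                _fast_config(n_macrocycles=3, gamma=0.7))
    ss = np.random.SeedSequence(5)
    sel_seed = int(ss.spawn(4)[0].generate_state(1)[0] % 2**31)
    net0 = select_restraints(start, start, SelectionConfig(), sel_seed)
    np.testing.assert_array_equal(result.network.pairs, net0.pairs)
    assert not np.array_equal(result.network.d0, net0.d0)


def test_first_macrocycle_gamma_zero_and_release(small_scenario):
    truth, start, obs = small_scenario
    config = _fast_config(gamma=0.8, n_macrocycles=4, release_last_two=True)
    result = run_den_refinement(start, start, obs, config)
    gammas = [rec.gamma for rec in result.trace]
    w_dens = [rec.w_den for rec in result.trace]
    assert gammas[0] == 0.0 and gammas[1] == 0.8
    assert w_dens[:2] == [100.0, 100.0] and w_dens[2:] == [0.0, 0.0]
    assert result.drift_rmsd is not None and result.drift_rmsd >= 0.0
    assert len(result.trace) == 4


def test_release_requires_three_macrocycles():
    with pytest.raises(ValueError):
        RefinementConfig(n_macrocycles=2, release_last_two=True)


def test_correspondence_enforced(small_scenario):
    truth, start, obs = small_scenario
    from denrefine.den import CorrespondenceError

    other = make_helix(11)
    with pytest.raises(CorrespondenceError):
        run_den_refinement(start, other, obs, _fast_config())


def test_partial_reference_mask_limits_restraints(small_scenario):
    truth, start, obs = small_scenario
    mask = np.zeros(len(start), dtype=bool)
    mask[: len(start) // 2] = True  # restrain only the N-terminal half
    config = _fast_config()
    config.atom_mask = mask
    result = run_den_refinement(start, start, obs, config)
    assert np.all(mask[result.network.pairs[:, 0]])
    assert np.all(mask[result.network.pairs[:, 1]])
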