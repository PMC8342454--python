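import math

import numpy as np
import pytest

from crossbeta.restraints import K_B, RestraintCollection, short_fibril_protocol
from crossbeta.sampler import (CGParams, MoveParams, ReplicaLadder,
                               ReplicaState, attempt_swap, build_ladder,
                               cg_energy, compile_system, mc_sweep, run_remd,
                               swap_delta)
from crossbeta.structures import Assembly, Atom, Chain


def _two_bead(distance=3.8):
    chain = Chain("A", ["GLY", "GLY"], [
        [Atom("CA", "C", np.zeros(3))],
        [Atom("CA", "C", np.array([distance, 0.0, 0.0]))],
    ])
    return Assembly([chain])


HARMONIC = CGParams(bond_k=100.0, excluded_k=0.0, attraction_depth=0.0,
                    zipper_depth=0.0)


# ---------------------------------------------------------------------------
# ladder
# ---------------------------------------------------------------------------

def test_default_ladder_spans_300_to_450_kelvin():
    ladder = build_ladder(30)
    assert ladder.n_replicas == 30
    assert ladder.temperatures[0] == pytest.approx(300.0)
    assert ladder.temperatures[-1] == pytest.approx(450.0)
    ladder.validate()


def test_three_replica_geometric_midpoint():
    ladder = build_ladder(3, 300.0, 450.0)
    assert ladder.temperatures[1] == pytest.approx(math.sqrt(300 * 450))


def test_restraint_scale_endpoints_are_exact():
    for n in (2, 5, 30):
        ladder = build_ladder(n)
        assert ladder.k_scales[0] == 1.0
        assert ladder.k_scales[-1] == 0.0
        assert np.all(np.diff(ladder.k_scales) <= 0)


def test_ladder_shape_controls_decay():
    gentle = build_ladder(10, shape=1.0)
    steep = build_ladder(10, shape=5.0)
    assert np.all(steep.k_scales[1:-1] < gentle.k_scales[1:-1])


def test_ladder_validation_errors():
    with pytest.raises(ValueError):
        build_ladder(1)
    with pytest.raises(ValueError):
        build_ladder(5, t_min=400, t_max=300)
    with pytest.raises(ValueError):
        ReplicaLadder(np.array([300.0, 290.0]), np.array([1.0, 0.0]))
    with pytest.raises(ValueError):
        ReplicaLadder(np.array([300.0, 350.0]), np.array([0.5, 1.0]))
    bent = ReplicaLadder(np.array([300.0, 310.0, 450.0]),
                         np.array([1.0, 0.5, 0.0]))
    with pytest.raises(ValueError, match="geometric"):
        bent.validate()


# ---------------------------------------------------------------------------
# surrogate potential
# ---------------------------------------------------------------------------

def test_cg_bond_at_rest_length_is_zero():
    assert cg_energy(_two_bead(3.8), HARMONIC) == pytest.approx(0.0)


def test_cg_bond_stretched_harmonic_value():
    assert cg_energy(_two_bead(4.8), HARMONIC) == pytest.approx(50.0)


def test_cg_distant_nonbonded_beads_do_not_interact():
    chains = [
        Chain("A", ["GLY"], [[Atom("CA", "C", np.zeros(3))]]),
        Chain("B", ["GLY"], [[Atom("CA", "C", np.array([40.0, 0, 0]))]]),
    ]
    e = cg_energy(Assembly(chains), CGParams(attraction_depth=0.0,
                                             zipper_depth=0.0))
    assert abs(e) < 1e-6


def test_cg_coincident_beads_finite():
    chains = [
        Chain("A", ["GLY"], [[Atom("CA", "C", np.zeros(3))]]),
        Chain("B", ["GLY"], [[Atom("CA", "C", np.zeros(3))]]),
    ]
    e = cg_energy(Assembly(chains), CGParams(attraction_depth=0.0,
                                             zipper_depth=0.0))
    assert np.isfinite(e)
    assert e > 0


def test_backbone_fibril_is_cg_minimum_basin(toy_fibril):
    params = CGParams()
    e_ideal = cg_energy(toy_fibril, params)
    jostled = toy_fibril.with_coords(
        toy_fibril.coords()
        + np.random.default_rng(3).normal(0, 0.3, (toy_fibril.n_atoms, 3)))
    assert cg_energy(jostled, params) > e_ideal


# ---------------------------------------------------------------------------
# Metropolis sweeps
# ---------------------------------------------------------------------------

def test_zero_temperature_only_accepts_downhill():
    asm = _two_bead(4.6)  # stretched: energy decreases toward 3.8
    system = compile_system(asm, None, HARMONIC)
    ladder = ReplicaLadder(np.array([1e-9, 300.0]), np.array([1.0, 0.0]))
    state = ReplicaState.initial(system, asm.coords(), 0)
    rng = np.random.default_rng(5)
    energies = [state.e_cg]
    for _ in range(50):
        state = mc_sweep(state, RestraintCollection([]), ladder, rng,
                         system=system,
                         move_params=MoveParams(sigma_bead=0.1,
                                                sigma_trans=0.0,
                                                sigma_rot=0.0, t_ref=300.0))
        energies.append(state.e_cg)
    assert all(b <= a + 1e-12 for a, b in zip(energies, energies[1:]))


def test_harmonic_bond_equipartition_within_three_se():
    """Sampled Var(r) of a harmonic virtual bond matches the quadrature
    value kT/k (with the r^2 Jacobian) within 3 standard errors."""
    asm = _two_bead()
    system = compile_system(asm, None, HARMONIC)
    t = 300.0
    beta = 1.0 / (K_B * t)
    mv = MoveParams(sigma_bead=0.15, sigma_trans=0.0, sigma_rot=0.0)
    coords = asm.coords()
    seeds = np.random.SeedSequence(2026).generate_state(3001) % (2**31 - 1)
    system.run(coords, 2000, beta, 0.0, mv, t, int(seeds[-1]))
    samples = []
    for i in range(3000):
        system.run(coords, 50, beta, 0.0, mv, t, int(seeds[i]))
        samples.append(np.linalg.norm(coords[1] - coords[0]))
    samples = np.asarray(samples)
    r = np.linspace(2.5, 5.1, 20001)
    w = r**2 * np.exp(-beta * 0.5 * 100.0 * (r - 3.8) ** 2)
    w /= w.sum()
    var_expected = float(w @ (r - w @ r) ** 2)
    se = samples.var() * math.sqrt(2.0 / len(samples))
    assert abs(samples.var() - var_expected) < 3 * se


def test_restraint_scale_zero_ignores_restraints(toy_start, toy_collection):
    system = compile_system(toy_start, toy_collection, CGParams())
    coords_a = toy_start.coords()
    coords_b = toy_start.coords()
    mv = MoveParams()
    beta = 1.0 / (K_B * 450.0)
    system.run(coords_a, 20, beta, 0.0, mv, 450.0, 99)
    empty = compile_system(toy_start, RestraintCollection([]), CGParams())
    empty.run(coords_b, 20, beta, 0.0, mv, 450.0, 99)
    # identical trajectories: with alpha = 0 the restraints change nothing
    assert np.array_equal(coords_a, coords_b)


# ---------------------------------------------------------------------------
# replica exchange
# ---------------------------------------------------------------------------

def test_swap_identical_configurations_always_accepted(toy_start,
                                                       toy_collection):
    system = compile_system(toy_start, toy_collection, CGParams())
    ladder = build_ladder(4)
    s0 = ReplicaState.initial(system, toy_start.coords(), 0)
    s1 = ReplicaState.initial(system, toy_start.coords(), 1)
    accepted, *_ = attempt_swap(s0, s1, toy_collection, ladder,
                                np.random.default_rng(0))
    assert accepted


def test_pure_temperature_swap_hand_value():
    # U(x_i)=1, U(x_j)=2 kJ/mol at 300 / 450 K, equal restraint scales
    beta_i = 1.0 / (K_B * 300.0)
    beta_j = 1.0 / (K_B * 450.0)
    delta = swap_delta(beta_i, beta_j, 0.0, 0.0, 1.0, 0.0, 2.0, 0.0)
    assert delta == pytest.approx(0.13363, abs=1e-5)
    assert math.exp(-delta) == pytest.approx(0.8749, abs=1e-4)


def test_downhill_swap_always_accepted():
    beta_i = 1.0 / (K_B * 300.0)
    beta_j = 1.0 / (K_B * 450.0)
    delta = swap_delta(beta_i, beta_j, 0.0, 0.0, 2.0, 0.0, 1.0, 0.0)
    assert delta < 0


def test_swap_exchanges_configurations(toy_start, toy_collection, rng):
    system = compile_system(toy_start, toy_collection, CGParams())
    ladder = build_ladder(4)
    c0 = toy_start.coords()
    c1 = toy_start.coords() + 0.05
    s0 = ReplicaState.initial(system, c0, 0)
    s1 = ReplicaState.initial(system, c1, 1)
    for _ in range(50):
        accepted, n0, n1 = attempt_swap(s0, s1, toy_collection, ladder, rng)
        if accepted:
            assert np.allclose(n0.coords, c1)
            assert np.allclose(n1.coords, c0)
            assert n0.replica_index == 0 and n1.replica_index == 1
            break
    else:  # pragma: no cover
        pytest.fail("no swap accepted in 50 attempts at tiny energy gap")


def test_non_neighbour_swap_rejected(toy_start, toy_collection, rng):
    system = compile_system(toy_start, toy_collection, CGParams())
    ladder = build_ladder(4)
    s0 = ReplicaState.initial(system, toy_start.coords(), 0)
    s2 = ReplicaState.initial(system, toy_start.coords(), 2)
    with pytest.raises(ValueError, match="neighbour"):
        attempt_swap(s0, s2, toy_collection, ladder, rng)


# ---------------------------------------------------------------------------
# run_remd
# ---------------------------------------------------------------------------

def test_remd_zero_sweeps_records_initial_frames(toy_start, toy_collection):
    ladder = build_ladder(3)
    traj = run_remd(toy_start, toy_collection, ladder, 0, seed=1, stride=10)
    assert traj.n_frames == 1
    assert traj.n_replicas == 3
    assert np.allclose(traj.coords[0, 0], toy_start.coords(), atol=1e-6)


def test_remd_same_seed_is_bit_identical(toy_start, toy_collection):
    ladder = build_ladder(3)
    kwargs = dict(n_sweeps=200, swap_interval=10, seed=7, stride=50,
                  cg_params=CGParams(confine_radius=20.0))
    t1 = run_remd(toy_start, toy_collection, ladder, **kwargs)
    t2 = run_remd(toy_start, toy_collection, ladder, **kwargs)
    assert np.array_equal(t1.coords, t2.coords)
    assert np.array_equal(t1.exchange_log, t2.exchange_log)
    assert np.array_equal(t1.walker, t2.walker)


def test_remd_energy_caches_never_drift(toy_start, toy_collection):
    """Incrementally tracked energies equal from-scratch recomputation."""
    system = compile_system(toy_start, toy_collection,
                            CGParams(confine_radius=20.0))
    coords = toy_start.coords()
    mv = MoveParams()
    beta = 1.0 / (K_B * 300.0)
    for it in range(10):
        e_cg, e_rest, *_ = system.run(coords, 1000, beta, 1.0, mv, 300.0,
                                      1000 + it)
        fresh_cg, fresh_rest = system.energies(coords)
        assert e_cg == pytest.approx(fresh_cg, rel=1e-9, abs=1e-9)
        assert e_rest == pytest.approx(fresh_rest, rel=1e-9, abs=1e-9)


def test_remd_acceptance_bookkeeping(toy_start, toy_collection):
    ladder = build_ladder(4)
    traj = run_remd(toy_start, toy_collection, ladder, 300, seed=3,
                    stride=100, cg_params=CGParams(confine_radius=20.0))
    rates = traj.acceptance_rates()
    assert rates.shape == (3,)
    assert np.all((rates >= 0) & (rates <= 1))
    assert traj.exchange_log.shape[1] == 5
    # alternating even/odd phases attempt every neighbour pair
    assert traj.swap_attempted.min() > 0


def test_walkers_traverse_the_ladder():
    """With a small harmonic system every walker should visit both ends of
    the ladder in a long run (replica-flow health check)."""
    asm = _two_bead()
    col = RestraintCollection([])
    ladder = build_ladder(4, 300.0, 450.0)
    traj = run_remd(asm, col, ladder, 4000, swap_interval=5, seed=11,
                    stride=20, cg_params=HARMONIC,
                    move_params=MoveParams(sigma_bead=0.15, sigma_trans=0.2,
                                           sigma_rot=0.1))
    visited_bottom = set(traj.walker[0].tolist())
    visited_top = set(traj.walker[-1].tolist())
    assert visited_bottom == set(range(4))
    assert visited_top == set(range(4))


def test_trajectory_export_roundtrip(tmp_path, toy_start, toy_collection):
    ladder = build_ladder(3)
    traj = run_remd(toy_start, toy_collection, ladder, 100, seed=2,
                    stride=50, cg_params=CGParams(confine_radius=20.0))
    npz = tmp_path / "traj.npz"
    traj.save_npz(npz)
    data = np.load(npz)
    assert np.array_equal(data["coords"], traj.coords)
    csv = tmp_path / "exchange.csv"
    traj.exchange_log_csv(csv)
    assert csv.read_text().startswith("sweep,i,j,delta,accepted")
    pdb = tmp_path / "frames.pdb"
    traj.frames_to_pdb(pdb, replica=0, max_models=3)
    assert "MODEL" in pdb.read_text()
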