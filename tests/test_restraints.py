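import itertools
import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crossbeta.fixtures import build_ideal_fibril
from crossbeta.restraints import (DIHEDRAL_CENTERS, DihedralRestraint,
                                  DistanceRestraint, K_B, RestraintCollection,
                                  RestraintEnergyModel, RestraintGroup,
                                  central_residues, collection_energy,
                                  corresponding_pairs, density_report,
                                  load_restraint_table, long_fibril_protocol,
                                  posterior_log_weight, restraint_energy,
                                  short_fibril_protocol)
from crossbeta.structures import FibrilSpec


# ---------------------------------------------------------------------------
# protocol generation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("arrangement,phi,psi", [
    ("parallel", -119.0, 113.0),
    ("antiparallel", -139.0, 135.0),
])
def test_protocol_dihedral_centers_by_arrangement(arrangement, phi, psi):
    spec = FibrilSpec("VEALYL", 4, arrangement, [[0, 1], [2, 3]])
    col = short_fibril_protocol(spec, "S0")
    dihedrals = [r for _, _, r in col.iter_restraints()
                 if isinstance(r, DihedralRestraint)]
    assert dihedrals
    phis = [r for r in dihedrals if r.sites[1][2] == "N"]
    psis = [r for r in dihedrals if r.sites[3][2] == "N"]
    assert all(r.center == phi for r in phis)
    assert all(r.center == psi for r in psis)


def test_s0_protocol_counts_and_density(toy_spec):
    col = short_fibril_protocol(toy_spec, "S0")
    dist = [r for _, _, r in col.iter_restraints()
            if isinstance(r, DistanceRestraint)]
    dihedrals = [r for _, _, r in col.iter_restraints()
                 if isinstance(r, DihedralRestraint)]
    interstrand = [r for r in dist if abs(r.r2 - 4.6) < 1e-9]
    intersheet = [r for r in dist if r.r2 < 4.0 or r.r3 > 6.0]
    assert len(interstrand) == 12     # 2 adjacent pairs x 6 residues
    assert len(intersheet) == 18      # 2 facing pairs x 3x3 central
    assert len(dihedrals) == 32       # 4 chains x 4 interior x 2 angles
    assert col.n_restraints == 62
    rep = density_report(col, toy_spec)
    assert rep.restraints_per_residue == pytest.approx(62 / 24)
    assert not rep.sparse_data_flag


def test_level_ladder_s1_s2_s3(toy_spec):
    s1 = short_fibril_protocol(toy_spec, "S1")
    assert all(isinstance(r, DistanceRestraint)
               for _, _, r in s1.iter_restraints())
    assert s1.n_restraints == 30          # 12 interstrand + 18 intersheet
    s2 = short_fibril_protocol(toy_spec, "S2")
    assert s2.n_restraints == 24          # 2x3 central interstrand + 18
    s3 = short_fibril_protocol(toy_spec, "S3")
    assert len(s3.groups) == 1            # one group of central restraints
    assert s3.n_restraints == 2           # one per adjacent strand pair


def test_long_fibril_levels():
    spec = FibrilSpec("KLVFFAENVGS", 4, "parallel", [[0, 1, 2, 3]])
    with pytest.warns(UserWarning, match="inter-sheet"):
        l3 = long_fibril_protocol(spec, "L3")
        l2 = long_fibril_protocol(spec, "L2")
    assert l3.n_restraints == 33          # 3 adjacent pairs x 11 residues
    assert all(isinstance(r, DistanceRestraint)
               for _, _, r in l3.iter_restraints())
    dihedrals = [r for _, _, r in l2.iter_restraints()
                 if isinstance(r, DihedralRestraint)]
    assert len(dihedrals) == 4 * 9 * 2    # interior residues 2..10


def test_single_sheet_spec_warns_and_omits_intersheet():
    spec = FibrilSpec("VEALYL", 4, "parallel", [[0, 1, 2, 3]])
    with pytest.warns(UserWarning, match="inter-sheet"):
        col = short_fibril_protocol(spec, "S0")
    assert all(not g.label.startswith("intersheet") for g in col.groups)


def test_heteromeric_spec_rejected():
    spec = FibrilSpec(["VEALYL", "GGVVIA"], 2, "parallel", [[0, 1]])
    with pytest.raises(ValueError, match="homomeric"):
        short_fibril_protocol(spec, "S0")


def test_protocol_generation_is_deterministic(toy_spec):
    a = json.dumps(short_fibril_protocol(toy_spec, "S0").to_json_dict())
    b = json.dumps(short_fibril_protocol(toy_spec, "S0").to_json_dict())
    assert a == b


def test_corresponding_pairs_and_central_residues():
    assert corresponding_pairs(4, "parallel") == [(1, 1), (2, 2), (3, 3),
                                                  (4, 4)]
    assert corresponding_pairs(4, "antiparallel") == [(1, 4), (2, 3), (3, 2),
                                                      (4, 1)]
    assert corresponding_pairs(4, "parallel", registry_offset=1) == \
        [(1, 2), (2, 3), (3, 4)]
    assert central_residues(6) == [2, 3, 4]
    assert central_residues(7) == [3, 4, 5]


# ---------------------------------------------------------------------------
# restraint energies
# ---------------------------------------------------------------------------

def _two_ca_assembly(distance):
    from crossbeta.structures import Assembly, Atom, Chain
    chains = [
        Chain("A", ["GLY"], [[Atom("CA", "C", np.zeros(3))]]),
        Chain("B", ["GLY"], [[Atom("CA", "C",
                                   np.array([distance, 0.0, 0.0]))]]),
    ]
    return Assembly(chains)


DIST = DistanceRestraint((0, 1, "CA"), (1, 1, "CA"),
                         3.6, 4.6, 5.0, 6.0, k=2.5)


@pytest.mark.parametrize("d,expected", [
    (4.8, 0.0),                                   # inside the flat bottom
    (5.5, 0.5 * 2.5 * 0.5**2),                    # quadratic shoulder
    (4.0, 0.5 * 2.5 * 0.6**2),                    # lower shoulder
    (7.0, 0.5 * 2.5 * 1.0**2 + 2.5 * 1.0 * 1.0),  # linear tail beyond r4
    (2.0, 0.5 * 2.5 * 1.0**2 + 2.5 * 1.0 * 1.6),  # linear tail below r1
])
def test_distance_restraint_piecewise_profile(d, expected):
    asm = _two_ca_assembly(d)
    assert restraint_energy(DIST, asm) == pytest.approx(expected)


def test_restraint_energy_scales_with_k_scale():
    asm = _two_ca_assembly(5.5)
    full = restraint_energy(DIST, asm, k_scale=1.0)
    assert restraint_energy(DIST, asm, k_scale=0.0) == 0.0
    assert restraint_energy(DIST, asm, k_scale=0.5) == pytest.approx(full / 2)


@settings(max_examples=50, deadline=None)
@given(st.floats(min_value=0.01, max_value=20.0))
def test_distance_profile_nonnegative_zero_only_in_bottom(d):
    e = DIST.profile(d)
    assert e >= 0.0
    if 4.6 <= d <= 5.0:
        assert e == 0.0
    elif d < 4.59 or d > 5.01:
        assert e > 0.0


def test_distance_profile_is_continuous_and_smooth():
    d = np.linspace(0.5, 10.0, 20001)
    e = np.array([DIST.profile(x) for x in d])
    step = np.abs(np.diff(e))
    # max |dE/dr| is the tail slope k*(r4-r3); continuity bounds the jump
    assert step.max() <= 2.5 * 1.0 * (d[1] - d[0]) * 1.5
    de = np.diff(e) / np.diff(d)
    assert np.abs(np.diff(de)).max() < 2.5 * (d[1] - d[0]) * 2  # C1


def test_dihedral_restraint_wraps_on_the_circle():
    r = DihedralRestraint(((0, 1, "A"), (0, 1, "B"), (0, 1, "C"),
                           (0, 1, "D")), center=170.0, delta=30.0, k=0.02)
    assert r.profile(-170.0) == 0.0          # 20 deg away through the cut
    assert r.profile(120.0) == pytest.approx(0.5 * 0.02 * 20.0**2)
    assert r.profile(170.0) == 0.0


def test_unresolvable_selector_reports_location(toy_fibril):
    bad = DistanceRestraint((0, 99, "CA"), (1, 1, "CA"), 3.6, 4.6, 5.0, 6.0)
    with pytest.raises(KeyError, match="residue 99"):
        restraint_energy(bad, toy_fibril)


# ---------------------------------------------------------------------------
# activation / collection energy
# ---------------------------------------------------------------------------

def _collection_on_line(distances, n_active=None, group_split=None):
    """Restraints from a fixed origin CA to chain-B CAs at given distances;
    bottom [1,1] so the energy of restraint i is 0.5*k*(d_i-1)^2 when just
    outside, here simply controlled by d_i."""
    from crossbeta.structures import Assembly, Atom, Chain
    chains = [Chain("A", ["GLY"], [[Atom("CA", "C", np.zeros(3))]])]
    groups = []
    rs = []
    for i, d in enumerate(distances):
        chains.append(Chain("BCDEFGHIJKLM"[i], ["GLY"],
                            [[Atom("CA", "C", np.array([d, 0.0, 0.0]))]]))
        rs.append(DistanceRestraint((0, 1, "CA"), (i + 1, 1, "CA"),
                                    0.0, 0.0, 1.0, 100.0, k=2.0))
    groups.append(RestraintGroup(rs, n_active=n_active))
    asm = Assembly(chains)
    return RestraintCollection(groups), asm


def test_collection_energy_all_active_is_plain_sum(toy_fibril,
                                                   toy_collection):
    decoy = toy_fibril.with_coords(toy_fibril.coords() + np.random.default_rng(
        0).normal(0, 0.7, (toy_fibril.n_atoms, 3)))
    total = collection_energy(toy_collection, decoy).total
    plain = sum(restraint_energy(r, decoy)
                for _, _, r in toy_collection.iter_restraints())
    assert total == pytest.approx(plain, rel=1e-12)


def test_collection_energy_selects_lowest_members():
    # member energies 0.5*k*(d-1)^2 = {0, 1, 4} for d = {1, 2, 3}
    col, asm = _collection_on_line([1.0, 2.0, 3.0], n_active=2)
    out = collection_energy(col, asm)
    assert out.total == pytest.approx(1.0)
    assert out.active_restraints == [(0, 0), (0, 1)]


def test_empty_collection_energy_is_zero(toy_fibril):
    out = collection_energy(RestraintCollection([]), toy_fibril)
    assert out.total == 0.0
    assert out.active_restraints == []


def test_collection_energy_matches_brute_force_subsets(rng):
    from crossbeta.structures import Assembly, Atom, Chain
    for _ in range(25):
        n = int(rng.integers(2, 9))
        dists = rng.uniform(0.5, 4.0, n)
        n_active = int(rng.integers(1, n + 1))
        col, asm = _collection_on_line(dists, n_active=n_active)
        energies = [restraint_energy(r, asm)
                    for _, _, r in col.iter_restraints()]
        brute = min(sum(c) for c in
                    itertools.combinations(energies, n_active))
        assert collection_energy(col, asm).total == pytest.approx(brute)


def test_activation_is_monotone_in_n_active(rng):
    dists = rng.uniform(0.5, 4.0, 6)
    totals = []
    for n_active in range(1, 7):
        col, asm = _collection_on_line(dists, n_active=n_active)
        totals.append(collection_energy(col, asm).total)
    assert all(a <= b + 1e-12 for a, b in zip(totals, totals[1:]))


def test_group_level_selection():
    colA, asm = _collection_on_line([1.0, 3.0])     # energies 0, 4
    g1 = RestraintGroup([colA.groups[0].restraints[0]])  # E = 0
    g2 = RestraintGroup([colA.groups[0].restraints[1]])  # E = 4
    col = RestraintCollection([g2, g1], n_active_groups=1)
    out = collection_energy(col, asm)
    assert out.total == pytest.approx(0.0)
    assert out.active_groups == [1]


# ---------------------------------------------------------------------------
# posterior weight
# ---------------------------------------------------------------------------

def test_posterior_weight_reduces_to_prior_without_restraint_energy(
        toy_fibril, toy_collection):
    model = RestraintEnergyModel(toy_collection, temperature=300.0)
    w = posterior_log_weight(model, physical_energy=10.0,
                             assembly=toy_fibril)
    assert w == pytest.approx(-10.0 / (K_B * 300.0))


def test_posterior_weight_boltzmann_ratio(toy_fibril, toy_collection):
    model = RestraintEnergyModel(toy_collection, temperature=300.0)
    w0 = posterior_log_weight(model, 0.0, toy_fibril)
    w1 = posterior_log_weight(model, 1.0, toy_fibril)
    assert math.exp(w1 - w0) == pytest.approx(0.6697, abs=2e-4)


def test_posterior_weight_infinite_temperature_limit(toy_fibril,
                                                     toy_collection):
    model = RestraintEnergyModel(toy_collection, temperature=1e12)
    w0 = posterior_log_weight(model, 0.0, toy_fibril)
    w1 = posterior_log_weight(model, 1000.0, toy_fibril)
    assert math.exp(w1 - w0) == pytest.approx(1.0, abs=1e-6)


def test_posterior_weight_invariant_to_energy_offset(toy_fibril,
                                                     toy_collection):
    model = RestraintEnergyModel(toy_collection, temperature=300.0)
    d1 = (posterior_log_weight(model, 5.0, toy_fibril)
          - posterior_log_weight(model, 2.0, toy_fibril))
    d2 = (posterior_log_weight(model, 105.0, toy_fibril)
          - posterior_log_weight(model, 102.0, toy_fibril))
    assert d1 == pytest.approx(d2)


def test_posterior_weight_rejects_nonpositive_temperature(toy_fibril,
                                                          toy_collection):
    model = RestraintEnergyModel(toy_collection, temperature=-5.0)
    with pytest.raises(ValueError):
        posterior_log_weight(model, 0.0, toy_fibril)


# ---------------------------------------------------------------------------
# density / tables / serialization
# ---------------------------------------------------------------------------

def test_density_report_flags_sparse_protocols(toy_spec):
    sparse = RestraintCollection([RestraintGroup([DIST] * 10)])
    rep = density_report(sparse, toy_spec)
    assert rep.restraints_per_residue == pytest.approx(10 / 24)
    assert rep.sparse_data_flag
    empty = density_report(RestraintCollection([]), toy_spec)
    assert empty.restraints_per_residue == 0.0
    assert empty.sparse_data_flag


def test_load_restraint_table_grouping_and_margins(tmp_path):
    table = tmp_path / "restraints.csv"
    table.write_text(
        "chain_i,res_i,atom_i,chain_j,res_j,atom_j,r2,r3,group\n"
        "0,1,CA,1,1,CA,4.6,5.0,g1\n"
        "0,2,CA,1,2,CA,4.6,5.0,g1\n"
        "0,3,CA,1,3,CA,9.0,11.0,\n")
    col = load_restraint_table(table)
    assert len(col.groups) == 2
    grouped = next(g for g in col.groups if g.label == "g1")
    assert len(grouped) == 2
    r = grouped.restraints[0]
    assert r.r1 == pytest.approx(3.6)
    assert r.r4 == pytest.approx(6.0)


def test_load_restraint_table_empty_and_malformed(tmp_path, toy_fibril):
    empty = tmp_path / "empty.csv"
    empty.write_text("")
    col = load_restraint_table(empty)
    assert collection_energy(col, toy_fibril).total == 0.0

    bad = tmp_path / "bad.csv"
    bad.write_text(
        "chain_i,res_i,atom_i,chain_j,res_j,atom_j,r2,r3\n"
        "0,1,CA,1,1,CA,5.0,4.0\n")
    with pytest.raises(ValueError, match=":2"):
        load_restraint_table(bad)


def test_table_dihedrals_and_deferred_selector_check(tmp_path, toy_fibril):
    table = tmp_path / "dihedrals.tsv"
    table.write_text("chain\tres\tangle_name\tcenter\tdelta\n"
                     "0\t3\tphi\t-119\t30\n"
                     "7\t3\tpsi\t113\t30\n")
    col = load_restraint_table(table)   # parses fine
    assert col.n_restraints == 2
    with pytest.raises(KeyError):       # rejected at first evaluation
        collection_energy(col, toy_fibril)


def test_collection_json_round_trip(toy_collection, tmp_path):
    path = tmp_path / "collection.json"
    toy_collection.save_json(path)
    back = RestraintCollection.load_json(path)
    assert back.to_json_dict() == toy_collection.to_json_dict()
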