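"""Hamiltonian-Temperature replica exchange over a coarse-grained surrogate.

The physical engine here is deliberately simple: a C-alpha / backbone-bead
Metropolis Monte-Carlo sampler whose potential has harmonic virtual bonds,
a soft excluded volume and optional inter-strand attraction wells.  What is
implemented faithfully is the machinery around it — the per-replica
Hamiltonian U_i(x) = E_cg(x) + alpha_i * E_restraint(x), the geometric
temperature ladder with exponentially decaying restraint scales, the
lowest-energy-fraction restraint activation (re-selected at every
evaluation), and the neighbour-swap Metropolis rule

    Delta = beta_i [U_i(x_j) - U_i(x_i)] + beta_j [U_j(x_i) - U_j(x_j)]

accepted with probability min(1, exp(-Delta)).  Because the restraint scale
multiplies every restraint equally, the active-set selection is
scale-invariant and restraint energies are cached at unit scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import _kernels
from .restraints import (K_B, DihedralRestraint, DistanceRestraint,
                         RestraintCollection, corresponding_pairs)
from .structures import Assembly

__all__ = [
    "ReplicaLadder",
    "CGParams",
    "MoveParams",
    "ReplicaState",
    "TrajectorySet",
    "build_ladder",
    "compile_system",
    "cg_energy",
    "mc_sweep",
    "attempt_swap",
    "run_remd",
]

# Backbone virtual-bond rest lengths (Angstrom) by atom-name pair.
BOND_LENGTHS = {
    ("N", "CA"): 1.458,
    ("CA", "C"): 1.525,
    ("C", "N"): 1.329,
}

# Backbone bond-angle rest values (degrees) by atom-name triple.
ANGLE_REST = {
    ("N", "CA", "C"): 111.0,
    ("CA", "C", "N"): 116.6,
    ("C", "N", "CA"): 121.9,
}


@dataclass
class ReplicaLadder:
    """Per-replica temperatures (K, increasing) and restraint scales
    (dimensionless, nonincreasing)."""

    temperatures: np.ndarray
    k_scales: np.ndarray

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.k_scales = np.asarray(self.k_scales, dtype=float)
        if self.temperatures.shape != self.k_scales.shape:
            raise ValueError("temperatures and k_scales must match in length")
        if np.any(self.temperatures <= 0):
            raise ValueError("temperatures must be positive")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if np.any((self.k_scales < 0) | (self.k_scales > 1)):
            raise ValueError("k_scales must lie in [0, 1]")
        if np.any(np.diff(self.k_scales) > 1e-12):
            raise ValueError("k_scales must be nonincreasing")

    @property
    def n_replicas(self) -> int:
        return len(self.temperatures)

    def betas(self) -> np.ndarray:
        return 1.0 / (K_B * self.temperatures)

    def validate(self) -> None:
        """Check the canonical-ladder invariants: geometric temperatures
        and exact 1 -> 0 restraint-scale endpoints."""
        t = self.temperatures
        if len(t) >= 3:
            ratios = t[1:] / t[:-1]
            if np.any(np.abs(ratios - ratios[0]) > 1e-9):
                raise ValueError("temperature ladder is not geometric")
        if self.k_scales[0] != 1.0 or self.k_scales[-1] != 0.0:
            raise ValueError("restraint scales must run from exactly 1 to 0")


def build_ladder(n_replicas: int = 30, t_min: float = 300.0,
                 t_max: float = 450.0, shape: float = 3.0) -> ReplicaLadder:
    """Geometric temperature ladder with an exponential restraint-scale
    ramp: T_i = t_min (t_max/t_min)^(i/(n-1)) and
    alpha_i = (e^{shape (1 - i/(n-1))} - 1)/(e^{shape} - 1), which is
    exactly 1 at the bottom and exactly 0 at the top."""
    if n_replicas < 2:
        raise ValueError("need at least 2 replicas")
    if not t_max > t_min > 0:
        raise ValueError("require t_max > t_min > 0")
    if shape <= 0:
        raise ValueError("shape must be positive")
    x = np.arange(n_replicas) / (n_replicas - 1)
    temps = t_min * (t_max / t_min) ** x
    scales = (np.exp(shape * (1.0 - x)) - 1.0) / (np.exp(shape) - 1.0)
    scales[0] = 1.0
    scales[-1] = 0.0
    return ReplicaLadder(temps, scales)


@dataclass
class CGParams:
    """Surrogate-potential parameters (Angstrom / kJ/mol units)."""

    bond_k: float = 200.0           # kJ/mol/A^2, virtual bonds
    ca_bond_length: float = 3.8     # A, CA-CA virtual bond (CA-only mode)
    angle_k: float = 100.0          # kJ/mol/rad^2, backbone bond angles
    omega_k: float = 0.02           # kJ/mol/deg^2, planar peptide torsion
    excluded_radius: float = 3.0    # A, soft-core onset
    excluded_k: float = 2.0         # kJ/mol/A^2 (soft core: thermally
                                    # passable at high T, so chains can
                                    # re-register instead of jamming)
    attraction_depth: float = 8.0   # kJ/mol; 0 disables the wells
    attraction_r0: float = 4.8      # A, neighbour-strand CA well centre
    attraction_sigma: float = 0.5   # A
    zipper_depth: float = 6.0       # kJ/mol; sheet-packing wells, 0 = off
    zipper_sigma: float = 0.6       # A
    confine_radius: float = 0.0     # A; 0 disables the spherical wall
    confine_k: float = 1.0          # kJ/mol/A^2

    def __post_init__(self) -> None:
        if min(self.bond_k, self.excluded_k, self.attraction_depth) < 0:
            raise ValueError("strengths must be >= 0")


@dataclass
class MoveParams:
    """Monte-Carlo proposal widths at the reference temperature; widths are
    scaled by sqrt(T / t_ref) along the ladder."""

    sigma_bead: float = 0.25    # A
    sigma_trans: float = 0.6    # A
    sigma_rot: float = 0.15     # rad
    t_ref: float = 300.0


@dataclass
class CompiledSystem:
    """Assembly topology + restraint collection flattened to kernel arrays."""

    template: Assembly
    n_atoms: int
    chain_of: np.ndarray
    pos_of: np.ndarray
    chain_first: np.ndarray
    chain_last: np.ndarray
    n_excl: int
    params: CGParams
    pair_i: np.ndarray
    pair_j: np.ndarray
    pair_kind: np.ndarray
    pair_p1: np.ndarray
    pair_p2: np.ndarray
    pair_p3: np.ndarray
    apair_off: np.ndarray
    apair_id: np.ndarray
    cpair_off: np.ndarray
    cpair_id: np.ndarray
    an_i: np.ndarray
    an_j: np.ndarray
    an_k: np.ndarray
    an_t0: np.ndarray
    an_kf: np.ndarray
    aang_off: np.ndarray
    aang_id: np.ndarray
    od_idx: np.ndarray
    od_t0: np.ndarray
    od_kf: np.ndarray
    aod_off: np.ndarray
    aod_id: np.ndarray
    mem_kind: np.ndarray
    mem_param: np.ndarray
    di_a: np.ndarray
    di_b: np.ndarray
    di_r: np.ndarray
    di_k: np.ndarray
    dh_idx: np.ndarray
    dh_center: np.ndarray
    dh_delta: np.ndarray
    dh_k: np.ndarray
    grp_of_mem: np.ndarray
    grp_off: np.ndarray
    grp_nact: np.ndarray
    n_act_groups: int
    amem_off: np.ndarray
    amem_id: np.ndarray
    cmem_off: np.ndarray
    cmem_id: np.ndarray

    def energies(self, coords: np.ndarray) -> tuple[float, float]:
        """From-scratch (surrogate, unit-scale restraint) energies."""
        coords = np.ascontiguousarray(coords, dtype=float)
        out = _kernels.run_sweeps(
            coords.copy(), 0, 1.0, 1.0, 0.0, 0.0, 0.0,
            *self._kernel_args(), 0)
        return out[0], out[1]

    def _kernel_args(self):
        return (self.pair_i, self.pair_j, self.pair_kind, self.pair_p1,
                self.pair_p2, self.pair_p3, self.apair_off, self.apair_id,
                self.cpair_off, self.cpair_id,
                self.an_i, self.an_j, self.an_k, self.an_t0, self.an_kf,
                self.aang_off, self.aang_id,
                self.od_idx, self.od_t0, self.od_kf,
                self.aod_off, self.aod_id,
                self.chain_of, self.pos_of,
                self.n_excl, self.params.excluded_radius,
                self.params.excluded_k,
                self.params.confine_radius,
                self.params.confine_k if self.params.confine_radius > 0
                else 0.0,
                self.chain_first, self.chain_last,
                self.mem_kind, self.mem_param, self.di_a, self.di_b,
                self.di_r, self.di_k, self.dh_idx, self.dh_center,
                self.dh_delta, self.dh_k, self.grp_of_mem, self.grp_off,
                self.grp_nact, self.n_act_groups, self.amem_off,
                self.amem_id, self.cmem_off, self.cmem_id)

    def run(self, coords: np.ndarray, n_sweeps: int, beta: float,
            alpha: float, moves: MoveParams, temperature: float,
            seed: int):
        """Run sweeps in place on ``coords``; returns
        (e_cg, e_restraint_unit, acc_bead, att_bead, acc_chain, att_chain)."""
        scale = math.sqrt(temperature / moves.t_ref)
        return _kernels.run_sweeps(
            coords, n_sweeps, beta, alpha,
            moves.sigma_bead * scale, moves.sigma_trans * scale,
            moves.sigma_rot * scale, *self._kernel_args(), seed)


def _csr(n: int, lists: list[list[int]]):
    off = np.zeros(n + 1, dtype=np.int64)
    for i, lst in enumerate(lists):
        off[i + 1] = off[i] + len(lst)
    ids = np.array([x for lst in lists for x in lst], dtype=np.int64)
    return off, ids


def compile_system(assembly: Assembly,
                   collection: RestraintCollection | None = None,
                   params: CGParams | None = None) -> CompiledSystem:
    """Flatten an assembly and a restraint collection into kernel arrays.

    Restraint selectors that do not resolve against the assembly raise
    KeyError here — the first evaluation is the contract point for
    rejecting restraints that reference nonexistent atoms.
    """
    params = params or CGParams()
    collection = collection if collection is not None \
        else RestraintCollection([])
    names: list[str] = []
    chain_of: list[int] = []
    pos_of: list[int] = []
    chain_first: list[int] = []
    chain_last: list[int] = []
    k = 0
    for ci, chain in enumerate(assembly.chains):
        chain_first.append(k)
        p = 0
        for group in chain.atoms:
            for atom in group:
                names.append(atom.name)
                chain_of.append(ci)
                pos_of.append(p)
                p += 1
                k += 1
        chain_last.append(k)
    n_atoms = k
    ca_only = assembly.is_ca_only()
    n_excl = 1 if ca_only else 3

    # virtual bonds: consecutive beads within each chain
    pair_i: list[int] = []
    pair_j: list[int] = []
    pair_kind: list[int] = []
    pair_p1: list[float] = []
    pair_p2: list[float] = []
    pair_p3: list[float] = []
    for ci in range(len(assembly.chains)):
        for a in range(chain_first[ci], chain_last[ci] - 1):
            b = a + 1
            if ca_only:
                r0 = params.ca_bond_length
            else:
                r0 = BOND_LENGTHS.get((names[a], names[b]))
                if r0 is None:
                    r0 = float(np.linalg.norm(
                        assembly.coords()[a] - assembly.coords()[b]))
            pair_i.append(a)
            pair_j.append(b)
            pair_kind.append(_kernels.PAIR_BOND)
            pair_p1.append(r0)
            pair_p2.append(params.bond_k)
            pair_p3.append(0.0)

    # backbone bond angles and planar peptide torsions (skipped for
    # CA-only assemblies, whose surrogate is bonds + excluded volume)
    an_i: list[int] = []
    an_j: list[int] = []
    an_k_: list[int] = []
    an_t0: list[float] = []
    an_kf: list[float] = []
    od_idx: list[list[int]] = []
    od_t0: list[float] = []
    od_kf: list[float] = []
    if not ca_only:
        for ci in range(len(assembly.chains)):
            for a in range(chain_first[ci], chain_last[ci] - 2):
                rest = ANGLE_REST.get((names[a], names[a + 1], names[a + 2]))
                if rest is None or params.angle_k <= 0:
                    continue
                an_i.append(a)
                an_j.append(a + 1)
                an_k_.append(a + 2)
                an_t0.append(math.radians(rest))
                an_kf.append(params.angle_k)
            if params.omega_k > 0:
                for a in range(chain_first[ci], chain_last[ci] - 3):
                    quad = (names[a], names[a + 1], names[a + 2],
                            names[a + 3])
                    if quad == ("CA", "C", "N", "CA"):
                        od_idx.append([a, a + 1, a + 2, a + 3])
                        od_t0.append(180.0)
                        od_kf.append(params.omega_k)
    atom_angles: list[list[int]] = [[] for _ in range(n_atoms)]
    for a, (i0, i1, i2) in enumerate(zip(an_i, an_j, an_k_)):
        for x in (i0, i1, i2):
            atom_angles[x].append(a)
    aang_off, aang_id = _csr(n_atoms, atom_angles)
    atom_ods: list[list[int]] = [[] for _ in range(n_atoms)]
    for d, quad in enumerate(od_idx):
        for x in quad:
            atom_ods[x].append(d)
    aod_off, aod_id = _csr(n_atoms, atom_ods)

    index = assembly.atom_index()
    # cohesion wells (the surrogate's stand-in for backbone hydrogen
    # bonding and side-chain zipper packing, which a real force field
    # provides): neighbour-strand CA wells within sheets and facing-sheet
    # CA wells between central residues
    # Cohesion wells — the surrogate's stand-in for backbone hydrogen
    # bonding and side-chain zipper packing.  Well centres are read off the
    # ideal cross-beta lattice for the spec (a Go-style structure-based
    # parameterisation): direct plus diagonal CA pairs between adjacent
    # strands within a sheet, and same-rank plus diagonal-rank strand pairs
    # between facing sheets.  The diagonal wells give the interfaces shear
    # stiffness; distance wells alone cannot lock the register.
    spec = assembly.spec
    homomeric = (spec is not None
                 and len(set(spec.chain_sequences())) == 1)
    if homomeric and (params.attraction_depth > 0 or params.zipper_depth > 0):
        from .fixtures import build_ideal_fibril  # local import, no cycle

        ref = build_ideal_fibril(spec)
        ref_coords = ref.coords()
        L = len(spec.chain_sequences()[0])
        pairs = corresponding_pairs(L, spec.arrangement,
                                    spec.registry_offset)

        def add_well(sel_a, sel_b, depth, sigma):
            ia = index[sel_a]
            ib = index[sel_b]
            r0 = float(np.linalg.norm(ref_coords[ia] - ref_coords[ib]))
            pair_i.append(ia)
            pair_j.append(ib)
            pair_kind.append(_kernels.PAIR_WELL)
            pair_p1.append(r0)
            pair_p2.append(depth)
            pair_p3.append(sigma)

        if params.attraction_depth > 0:
            for sheet in spec.sheets:
                for a, b in zip(sheet[:-1], sheet[1:]):
                    for i, j in pairs:
                        for dj in (-1, 0, 1):
                            if 1 <= j + dj <= L:
                                add_well((a, i - 1, "CA"),
                                         (b, j + dj - 1, "CA"),
                                         params.attraction_depth,
                                         params.attraction_sigma)
        if params.zipper_depth > 0:
            for sheet_a, sheet_b in zip(spec.sheets[:-1], spec.sheets[1:]):
                links = list(zip(sheet_a, sheet_b))
                links += list(zip(sheet_a, sheet_b[1:]))
                links += list(zip(sheet_a[1:], sheet_b))
                for a, b in links:
                    for i in range(1, L + 1):
                        for dj in (-1, 0, 1):
                            if 1 <= i + dj <= L:
                                add_well((a, i - 1, "CA"),
                                         (b, i + dj - 1, "CA"),
                                         params.zipper_depth,
                                         params.zipper_sigma)

    atom_pairs: list[list[int]] = [[] for _ in range(n_atoms)]
    chain_pairs: list[list[int]] = [[] for _ in range(len(assembly.chains))]
    for b, (a, c) in enumerate(zip(pair_i, pair_j)):
        atom_pairs[a].append(b)
        atom_pairs[c].append(b)
        if chain_of[a] != chain_of[c]:
            chain_pairs[chain_of[a]].append(b)
            chain_pairs[chain_of[c]].append(b)
    apair_off, apair_id = _csr(n_atoms, atom_pairs)
    cpair_off, cpair_id = _csr(len(assembly.chains), chain_pairs)

    # restraint members, group-contiguous
    def resolve(sel):
        ci, resno, name = sel
        key = (ci, resno - 1, name)
        if key not in index:
            raise KeyError(
                f"restraint selector (chain {ci}, residue {resno}, "
                f"atom {name!r}) does not resolve in the assembly")
        return index[key]

    mem_kind: list[int] = []
    mem_param: list[int] = []
    grp_of_mem: list[int] = []
    grp_off = [0]
    grp_nact: list[int] = []
    di_a: list[int] = []
    di_b: list[int] = []
    di_r: list[list[float]] = []
    di_k: list[float] = []
    dh_idx: list[list[int]] = []
    dh_center: list[float] = []
    dh_delta: list[float] = []
    dh_k: list[float] = []
    atom_mems: list[list[int]] = [[] for _ in range(n_atoms)]
    chain_mems: list[list[int]] = [[] for _ in range(len(assembly.chains))]
    m = 0
    for gi, group in enumerate(collection.groups):
        for r in group.restraints:
            if isinstance(r, DistanceRestraint):
                ia, ib = resolve(r.site_a), resolve(r.site_b)
                mem_kind.append(0)
                mem_param.append(len(di_a))
                di_a.append(ia)
                di_b.append(ib)
                di_r.append([r.r1, r.r2, r.r3, r.r4])
                di_k.append(r.k)
                atoms = [ia, ib]
            elif isinstance(r, DihedralRestraint):
                ii = [resolve(s) for s in r.sites]
                mem_kind.append(1)
                mem_param.append(len(dh_idx))
                dh_idx.append(ii)
                dh_center.append(r.center)
                dh_delta.append(r.delta)
                dh_k.append(r.k)
                atoms = ii
            else:  # pragma: no cover
                raise TypeError(f"unknown restraint type {type(r)!r}")
            for a in set(atoms):
                atom_mems[a].append(m)
            touched = {chain_of[a] for a in atoms}
            if len(touched) > 1:
                for c in touched:
                    chain_mems[c].append(m)
            grp_of_mem.append(gi)
            m += 1
        grp_off.append(m)
        grp_nact.append(group.n_active)
    amem_off, amem_id = _csr(n_atoms, atom_mems)
    cmem_off, cmem_id = _csr(len(assembly.chains), chain_mems)

    sys = CompiledSystem(
        template=assembly,
        n_atoms=n_atoms,
        chain_of=np.array(chain_of, dtype=np.int64),
        pos_of=np.array(pos_of, dtype=np.int64),
        chain_first=np.array(chain_first, dtype=np.int64),
        chain_last=np.array(chain_last, dtype=np.int64),
        n_excl=n_excl,
        params=params,
        pair_i=np.array(pair_i, dtype=np.int64),
        pair_j=np.array(pair_j, dtype=np.int64),
        pair_kind=np.array(pair_kind, dtype=np.int64),
        pair_p1=np.array(pair_p1, dtype=float),
        pair_p2=np.array(pair_p2, dtype=float),
        pair_p3=np.array(pair_p3, dtype=float),
        apair_off=apair_off, apair_id=apair_id,
        cpair_off=cpair_off, cpair_id=cpair_id,
        an_i=np.array(an_i, dtype=np.int64),
        an_j=np.array(an_j, dtype=np.int64),
        an_k=np.array(an_k_, dtype=np.int64),
        an_t0=np.array(an_t0, dtype=float),
        an_kf=np.array(an_kf, dtype=float),
        aang_off=aang_off, aang_id=aang_id,
        od_idx=np.array(od_idx, dtype=np.int64).reshape(-1, 4),
        od_t0=np.array(od_t0, dtype=float),
        od_kf=np.array(od_kf, dtype=float),
        aod_off=aod_off, aod_id=aod_id,
        mem_kind=np.array(mem_kind, dtype=np.int64),
        mem_param=np.array(mem_param, dtype=np.int64),
        di_a=np.array(di_a, dtype=np.int64),
        di_b=np.array(di_b, dtype=np.int64),
        di_r=np.array(di_r, dtype=float).reshape(-1, 4),
        di_k=np.array(di_k, dtype=float),
        dh_idx=np.array(dh_idx, dtype=np.int64).reshape(-1, 4),
        dh_center=np.array(dh_center, dtype=float),
        dh_delta=np.array(dh_delta, dtype=float),
        dh_k=np.array(dh_k, dtype=float),
        grp_of_mem=np.array(grp_of_mem, dtype=np.int64),
        grp_off=np.array(grp_off, dtype=np.int64),
        grp_nact=np.array(grp_nact, dtype=np.int64),
        n_act_groups=collection.n_active_groups or 0,
        amem_off=amem_off, amem_id=amem_id,
        cmem_off=cmem_off, cmem_id=cmem_id,
    )
    # scratch buffer in the kernel is sized from these CSRs; empty systems
    # still need valid (length-1) offset arrays, which _csr guarantees
    return sys


def cg_energy(assembly: Assembly, params: CGParams | None = None) -> float:
    """Surrogate potential energy (kJ/mol) of an assembly."""
    system = compile_system(assembly, None, params)
    e_cg, _ = system.energies(assembly.coords())
    return e_cg


@dataclass
class ReplicaState:
    """One replica's configuration and cached energies (restraint energy at
    unit scale)."""

    coords: np.ndarray
    e_cg: float
    e_restraint: float
    replica_index: int
    walker_id: int = 0

    @classmethod
    def initial(cls, system: CompiledSystem, coords: np.ndarray,
                replica_index: int) -> "ReplicaState":
        e_cg, e_rest = system.energies(coords)
        return cls(np.array(coords, dtype=float), e_cg, e_rest,
                   replica_index, walker_id=replica_index)


def mc_sweep(state: ReplicaState, collection: RestraintCollection,
             ladder: ReplicaLadder, rng: np.random.Generator,
             system: CompiledSystem | None = None,
             assembly: Assembly | None = None,
             n_sweeps: int = 1,
             cg_params: CGParams | None = None,
             move_params: MoveParams | None = None) -> ReplicaState:
    """Run Metropolis sweeps for one replica and return the updated state.

    Each sweep attempts one local displacement per bead and one rigid
    translate+rotate move per chain, accepted at the replica's temperature
    and Hamiltonian; moves that explode the energy are simply rejected.
    """
    if system is None:
        if assembly is None:
            raise ValueError("pass either a compiled system or an assembly")
        system = compile_system(assembly, collection, cg_params)
    moves = move_params or MoveParams()
    i = state.replica_index
    if not 0 <= i < ladder.n_replicas:
        raise IndexError("replica index outside the ladder")
    beta = float(ladder.betas()[i])
    alpha = float(ladder.k_scales[i])
    t = float(ladder.temperatures[i])
    coords = np.array(state.coords, dtype=float)
    seed = int(rng.integers(0, 2**31 - 1))
    e_cg, e_rest, *_ = system.run(coords, n_sweeps, beta, alpha, moves, t,
                                  seed)
    return replace(state, coords=coords, e_cg=e_cg, e_restraint=e_rest)


def attempt_swap(state_i: ReplicaState, state_j: ReplicaState,
                 collection: RestraintCollection, ladder: ReplicaLadder,
                 rng: np.random.Generator
                 ) -> tuple[bool, ReplicaState, ReplicaState]:
    """Neighbour-replica exchange: configurations (and their cached
    energies) swap between the two replicas on acceptance."""
    i, j = state_i.replica_index, state_j.replica_index
    if abs(i - j) != 1:
        raise ValueError("replica exchange is only defined for neighbours")
    betas = ladder.betas()
    alphas = ladder.k_scales
    delta = swap_delta(betas[i], betas[j], alphas[i], alphas[j],
                       state_i.e_cg, state_i.e_restraint,
                       state_j.e_cg, state_j.e_restraint)
    accepted = delta <= 0 or rng.random() < math.exp(-min(delta, 700.0))
    if accepted:
        new_i = replace(state_i, coords=state_j.coords, e_cg=state_j.e_cg,
                        e_restraint=state_j.e_restraint,
                        walker_id=state_j.walker_id)
        new_j = replace(state_j, coords=state_i.coords, e_cg=state_i.e_cg,
                        e_restraint=state_i.e_restraint,
                        walker_id=state_i.walker_id)
        return True, new_i, new_j
    return False, state_i, state_j


def swap_delta(beta_i: float, beta_j: float, alpha_i: float, alpha_j: float,
               e_cg_i: float, e_rest_i: float,
               e_cg_j: float, e_rest_j: float) -> float:
    """Exchange exponent for U_m(x) = E_cg(x) + alpha_m E_restraint(x)."""
    return ((beta_i - beta_j) * (e_cg_j - e_cg_i)
            + (beta_i * alpha_i - beta_j * alpha_j) * (e_rest_j - e_rest_i))


@dataclass
class TrajectorySet:
    """Per-replica frame series with energies, exchange records and
    neighbour-pair acceptance statistics."""

    template: Assembly
    coords: np.ndarray          # (R, F, N, 3) float32
    e_cg: np.ndarray            # (R, F)
    e_restraint: np.ndarray     # (R, F), unit restraint scale
    sweeps: np.ndarray          # (F,)
    walker: np.ndarray          # (R, F) walker id per frame
    temperatures: np.ndarray
    k_scales: np.ndarray
    exchange_log: np.ndarray    # (n, 5): sweep, i, j, delta, accepted
    swap_attempted: np.ndarray  # (R-1,)
    swap_accepted: np.ndarray   # (R-1,)

    @property
    def n_replicas(self) -> int:
        return self.coords.shape[0]

    @property
    def n_frames(self) -> int:
        return self.coords.shape[1]

    def acceptance_rates(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(self.swap_attempted > 0,
                            self.swap_accepted / self.swap_attempted, np.nan)

    def replica_frames(self, replica: int) -> np.ndarray:
        return np.asarray(self.coords[replica], dtype=float)

    def save_npz(self, path) -> None:
        np.savez_compressed(
            path, coords=self.coords, e_cg=self.e_cg,
            e_restraint=self.e_restraint, sweeps=self.sweeps,
            walker=self.walker, temperatures=self.temperatures,
            k_scales=self.k_scales, exchange_log=self.exchange_log,
            swap_attempted=self.swap_attempted,
            swap_accepted=self.swap_accepted)

    def exchange_log_csv(self, path) -> None:
        header = "sweep,i,j,delta,accepted"
        np.savetxt(path, self.exchange_log, delimiter=",", header=header,
                   comments="", fmt=["%d", "%d", "%d", "%.8g", "%d"])

    def frames_to_pdb(self, path, replica: int = 0,
                      max_models: int = 50) -> None:
        """Write a replica's frames as a multi-MODEL PDB."""
        import os
        import tempfile

        import biotite.structure as struc
        import biotite.structure.io.pdb as pdb

        from .structures import write_structure

        frames = self.replica_frames(replica)
        step = max(1, len(frames) // max_models)
        arrays = []
        for fr in frames[::step]:
            asm = self.template.with_coords(fr)
            with tempfile.NamedTemporaryFile("w", suffix=".pdb",
                                             delete=False) as fh:
                tmp = fh.name
            write_structure(asm, tmp)
            arrays.append(pdb.PDBFile.read(tmp).get_structure(model=1))
            os.unlink(tmp)
        out = pdb.PDBFile()
        out.set_structure(struc.stack(arrays))
        out.write(str(path))


def run_remd(assembly: Assembly, collection: RestraintCollection,
             ladder: ReplicaLadder, n_sweeps: int, swap_interval: int = 10,
             seed: int = 0, stride: int = 100,
             cg_params: CGParams | None = None,
             move_params: MoveParams | None = None) -> TrajectorySet:
    """Hamiltonian-Temperature replica exchange.

    All replicas start from ``assembly``; every ``swap_interval`` sweeps,
    alternating even/odd neighbour pairs attempt an exchange.  Frames are
    recorded every ``stride`` sweeps (plus the initial state).  The run is
    fully reproducible from ``seed``: every replica draws from its own
    counter-based stream, so results do not depend on execution order.
    """
    if swap_interval < 1:
        raise ValueError("swap_interval must be >= 1")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    system = compile_system(assembly, collection, cg_params)
    moves = move_params or MoveParams()
    R = ladder.n_replicas
    betas = ladder.betas()
    alphas = ladder.k_scales
    temps = ladder.temperatures

    coords = np.repeat(assembly.coords()[None, :, :], R, axis=0)
    e_cg = np.empty(R)
    e_rest = np.empty(R)
    for r in range(R):
        e_cg[r], e_rest[r] = system.energies(coords[r])
    walker = np.arange(R)

    frame_sweeps = list(range(0, n_sweeps + 1, stride))
    F = len(frame_sweeps)
    out_coords = np.empty((R, F, system.n_atoms, 3), dtype=np.float32)
    out_ecg = np.empty((R, F))
    out_er = np.empty((R, F))
    out_walker = np.empty((R, F), dtype=np.int32)
    log: list[tuple[int, int, int, float, int]] = []
    attempted = np.zeros(R - 1, dtype=np.int64)
    accepted = np.zeros(R - 1, dtype=np.int64)

    def record(fi):
        out_coords[:, fi] = coords
        out_ecg[:, fi] = e_cg
        out_er[:, fi] = e_rest
        out_walker[:, fi] = walker

    record(0)
    next_frame = 1
    sweep = 0
    interval = 0
    swap_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(0xFFFF,)))
    while sweep < n_sweeps:
        chunk = min(swap_interval, n_sweeps - sweep)
        for r in range(R):
            ss = np.random.SeedSequence(entropy=seed,
                                        spawn_key=(r, interval))
            kseed = int(ss.generate_state(1)[0] % (2**31 - 1))
            e_cg[r], e_rest[r], *_ = system.run(
                coords[r], chunk, float(betas[r]), float(alphas[r]), moves,
                float(temps[r]), kseed)
        sweep += chunk
        interval += 1
        # alternating even/odd neighbour swap phase
        start = 0 if interval % 2 == 1 else 1
        for i in range(start, R - 1, 2):
            j = i + 1
            delta = swap_delta(betas[i], betas[j], alphas[i], alphas[j],
                               e_cg[i], e_rest[i], e_cg[j], e_rest[j])
            attempted[i] += 1
            ok = delta <= 0 or swap_rng.random() < math.exp(-min(delta,
                                                                 700.0))
            if ok:
                accepted[i] += 1
                coords[[i, j]] = coords[[j, i]]
                e_cg[[i, j]] = e_cg[[j, i]]
                e_rest[[i, j]] = e_rest[[j, i]]
                walker[[i, j]] = walker[[j, i]]
            log.append((sweep, i, j, float(delta), int(ok)))
        while next_frame < F and frame_sweeps[next_frame] <= sweep:
            record(next_frame)
            next_frame += 1

    return TrajectorySet(
        template=assembly,
        coords=out_coords,
        e_cg=out_ecg,
        e_restraint=out_er,
        sweeps=np.array(frame_sweeps),
        walker=out_walker,
        temperatures=np.array(temps),
        k_scales=np.array(alphas),
        exchange_log=np.array(log, dtype=float).reshape(-1, 5),
        swap_attempted=attempted,
        swap_accepted=accepted,
    )
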