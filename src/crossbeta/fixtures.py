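"""Deterministic generators of idealised cross-beta fibrils and test ensembles.

Everything here is synthetic: an ideal fibril built from the strand
arrangement's dihedral centers stands in for deposited structures, decoy
ensembles emulate sampled trajectory frames, and polymorph generators
produce geometrically distinct packings of the same spec.  The builder and
the restraint protocol share one pairing convention, so the ideal fibril
satisfies every protocol restraint exactly — the central consistency oracle
of the package.

Construction notes.  Each chain is grown by internal-coordinate (NeRF)
placement of N/CA/C backbone beads at the arrangement's phi/psi centers
(omega = 180), which makes every chain an exact discrete helix.  Parallel
neighbours are pure translations at the strand spacing, so in-register
CA-CA distances are exactly 4.8 A.  Antiparallel neighbours exploit the
dyad symmetry of a uniform helix: the reversed CA trace is rigidly
congruent to the forward trace, so superposing it and translating gives
exact 4.8 A distances for the i <-> L+1-i pairing.  No side chains are
built; metrics accept heavy-atom structures from users, but generated
fixtures are backbone-only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from biotite.sequence import ProteinSequence

from .metrics import kabsch
from .restraints import DIHEDRAL_CENTERS
from .structures import (Assembly, Atom, Chain, CHAIN_ALPHABET, FibrilSpec,
                         validate_spec)

__all__ = [
    "FibrilGeometry",
    "build_strand_backbone",
    "build_ideal_fibril",
    "build_separated_chains",
    "make_decoys",
    "make_polymorph",
    "replicate_seed",
]

# Standard backbone internal coordinates (Angstrom / degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.6
ANGLE_C_N_CA = 121.9
OMEGA = 180.0


@dataclass
class FibrilGeometry:
    """Geometric parameters of the ideal lattice.

    ``sheet_spacing`` defaults to the generic 10 A protocol value, inside
    the 8.8-14.6 A range observed across real fibrils.  ``rise`` and
    ``twist`` (per strand, along/about the stacking axis) default to zero:
    ideal untwisted fibrils.
    """

    strand_spacing: float = 4.8
    sheet_spacing: float = 10.0
    rise: float = 0.0
    twist: float = 0.0  # degrees per strand

    def __post_init__(self) -> None:
        if self.strand_spacing <= 0 or self.sheet_spacing <= 0:
            raise ValueError("spacings must be positive")


def _place_atom(a, b, c, bond, angle, dihedral):
    """NeRF placement of the next atom from three predecessors."""
    ang = math.radians(angle)
    # sign chosen so that the measured IUPAC torsion A-B-C-D equals
    # ``dihedral``
    dih = -math.radians(dihedral)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * math.cos(ang),
                  bond * math.cos(dih) * math.sin(ang),
                  bond * math.sin(dih) * math.sin(ang)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_strand_backbone(length: int, phi: float, psi: float,
                          omega: float = OMEGA) -> np.ndarray:
    """Backbone bead coordinates (3*length, 3) in order N, CA, C per residue
    for a chain with uniform (phi, psi)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(ANGLE_N_CA_C)
    c0 = ca0 + np.array([BOND_CA_C * math.cos(math.pi - ang),
                         BOND_CA_C * math.sin(math.pi - ang), 0.0])
    atoms = [n0, ca0, c0]
    for _ in range(1, length):
        n_prev, ca_prev, c_prev = atoms[-3], atoms[-2], atoms[-1]
        ni = _place_atom(n_prev, ca_prev, c_prev, BOND_C_N, ANGLE_CA_C_N, psi)
        cai = _place_atom(ca_prev, c_prev, ni, BOND_N_CA, ANGLE_C_N_CA, omega)
        ci = _place_atom(c_prev, ni, cai, BOND_CA_C, ANGLE_N_CA_C, phi)
        atoms += [ni, cai, ci]
    return np.array(atoms)


def _canonical_template(length: int, phi: float, psi: float) -> np.ndarray:
    """Strand backbone rotated so the CA helix axis lies along x and the
    trace is centered at the origin; deterministic axis signs."""
    coords = build_strand_backbone(length, phi, psi)
    ca = coords[1::3]
    center = ca.mean(axis=0)
    c = ca - center
    if length == 1:
        return coords - center
    _, _, vt = np.linalg.svd(c)
    axes = vt.copy()
    # chain runs in +x; right-handed frame with deterministic signs
    if (ca[-1] - ca[0]) @ axes[0] < 0:
        axes[0] = -axes[0]
    if np.linalg.det(axes) < 0:
        axes[2] = -axes[2]
    return (coords - center) @ axes.T


def _dyad_transform(ca: np.ndarray):
    """Proper rotation + translation mapping the reversed CA trace onto the
    forward trace (exact for a uniform-dihedral chain)."""
    R, t, rmsd = kabsch(ca[::-1], ca)
    return R, t, rmsd


def _residue_names(seq: str) -> list[str]:
    names = []
    for letter in seq:
        try:
            names.append(ProteinSequence.convert_letter_1to3(letter).upper())
        except KeyError:
            names.append("UNK")
    return names


def _chain_from_coords(chain_id: str, seq: str, coords: np.ndarray) -> Chain:
    names = _residue_names(seq)
    groups = []
    for i in range(len(seq)):
        n, ca, c = coords[3 * i], coords[3 * i + 1], coords[3 * i + 2]
        groups.append([Atom("N", "N", np.array(n)),
                       Atom("CA", "C", np.array(ca)),
                       Atom("C", "C", np.array(c))])
    return Chain(chain_id, names, groups)


def _rot_x(deg: float) -> np.ndarray:
    a = math.radians(deg)
    return np.array([[1, 0, 0],
                     [0, math.cos(a), -math.sin(a)],
                     [0, math.sin(a), math.cos(a)]])


def build_ideal_fibril(spec: FibrilSpec,
                       geometry: FibrilGeometry | None = None) -> Assembly:
    """Build the idealised cross-beta fibril for a spec.

    Strands are stacked at ``strand_spacing`` along y within each sheet
    (antiparallel arrangements alternate strand direction via the exact
    dyad placement); sheets are offset by ``sheet_spacing`` along z.
    """
    geometry = geometry or FibrilGeometry()
    violations = validate_spec(spec)
    if violations:
        raise ValueError(
            "invalid FibrilSpec: " + "; ".join(v.message for v in violations))
    seqs = spec.chain_sequences()
    if len(set(seqs)) != 1:
        raise ValueError("the ideal-fibril builder requires a homomeric spec")
    seq = seqs[0]
    L = len(seq)
    template = _canonical_template(L, *DIHEDRAL_CENTERS[spec.arrangement])
    ca = template[1::3]
    if spec.arrangement == "antiparallel" and L > 1:
        R_d, t_d, resid = _dyad_transform(ca)
        if resid > 1e-6:
            raise RuntimeError("dyad fit failed on a uniform helix")
        flipped = template @ R_d.T + t_d
    else:
        flipped = template

    # per-residue rise along the strand axis, for registry shifts
    rise_per_res = ((ca[-1] - ca[0])[0] / (L - 1)) if L > 1 else 0.0

    chain_coords: dict[int, np.ndarray] = {}
    for mi, sheet in enumerate(spec.sheets):
        for si, chain_idx in enumerate(sheet):
            base = template
            if spec.arrangement == "antiparallel" and si % 2 == 1:
                base = flipped
            coords = base.copy()
            if geometry.twist:
                coords = coords @ _rot_x(si * geometry.twist).T
            offset = np.array([
                si * geometry.rise
                + si * spec.registry_offset * rise_per_res,
                si * geometry.strand_spacing,
                mi * geometry.sheet_spacing,
            ])
            chain_coords[chain_idx] = coords + offset

    chains = [
        _chain_from_coords(CHAIN_ALPHABET[i], seq, chain_coords[i])
        for i in range(spec.n_chains)
    ]
    asm = Assembly(chains, metadata={
        "builder": "ideal_fibril",
        "strand_axis": [1.0, 0.0, 0.0],
        "stacking_axis": [0.0, 1.0, 0.0],
        "sheet_axis": [0.0, 0.0, 1.0],
        "strand_spacing": geometry.strand_spacing,
        "sheet_spacing": geometry.sheet_spacing,
        "rise_per_residue": rise_per_res,
    }, spec=spec)
    asm.validate()
    return asm


def build_separated_chains(spec: FibrilSpec, separation: float = 15.0,
                           ) -> Assembly:
    """Extended, well-separated monomer chains: the standard starting state
    for folding runs.  Chains are laid out on a z-line at least
    ``separation`` A apart with generic extended-strand dihedrals."""
    violations = validate_spec(spec)
    if violations:
        raise ValueError(
            "invalid FibrilSpec: " + "; ".join(v.message for v in violations))
    seqs = spec.chain_sequences()
    chains = []
    mid = 0.5 * (len(seqs) - 1)
    for i, seq in enumerate(seqs):
        template = _canonical_template(len(seq), -139.0, 135.0)
        offset = np.array([0.0, 0.0, (i - mid) * separation])
        chains.append(_chain_from_coords(CHAIN_ALPHABET[i], seq,
                                         template + offset))
    asm = Assembly(chains, metadata={"builder": "separated_chains"},
                   spec=spec)
    asm.validate()
    return asm


def make_decoys(assembly: Assembly, sigma: float, n: int,
                seed: int = 0) -> np.ndarray:
    """``n`` noisy copies of an assembly's coordinates, shape (n, N, 3):
    independent isotropic Gaussian displacement of scale ``sigma`` per axis."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    base = assembly.coords()
    return base[None, :, :] + rng.normal(0.0, sigma, size=(n, *base.shape))


def _sheet_atom_indices(assembly: Assembly, sheet: list[int]) -> np.ndarray:
    """Flat coordinate rows belonging to the chains of one sheet."""
    starts = []
    k = 0
    for chain in assembly.chains:
        starts.append(k)
        k += sum(len(g) for g in chain.atoms)
    starts.append(k)
    rows = []
    for ci in sheet:
        rows.extend(range(starts[ci], starts[ci + 1]))
    return np.array(rows, dtype=int)


def make_polymorph(assembly: Assembly, mode: str) -> Assembly:
    """A geometrically distinct packing of the same fibril.

    ``shift_register`` slides every other strand by one residue along the
    strand axis; ``flip_sheet`` rotates the second sheet 180 deg about the
    strand axis through its centroid (an involution); ``repack`` slides the
    second sheet by half a strand spacing along the stacking axis.
    """
    spec = assembly.spec
    meta = assembly.metadata
    if spec is None or meta.get("builder") != "ideal_fibril":
        raise ValueError("make_polymorph requires an ideal-fibril assembly "
                         "with an attached spec")
    coords = assembly.coords()
    strand_axis = np.array(meta["strand_axis"])
    stacking_axis = np.array(meta["stacking_axis"])
    if mode in ("flip_sheet", "repack") and len(spec.sheets) < 2:
        raise ValueError(f"{mode} requires at least two sheets")

    if mode == "shift_register":
        shift = meta["rise_per_residue"] * strand_axis
        for sheet in spec.sheets:
            for si, chain_idx in enumerate(sheet):
                if si % 2 == 1:
                    rows = _sheet_atom_indices(assembly, [chain_idx])
                    coords[rows] += shift
    elif mode == "flip_sheet":
        rows = _sheet_atom_indices(assembly, spec.sheets[1])
        centroid = coords[rows].mean(axis=0)
        a = strand_axis / np.linalg.norm(strand_axis)
        # 180-degree rotation about the strand axis: R = 2 aa^T - I
        R = 2.0 * np.outer(a, a) - np.eye(3)
        coords[rows] = (coords[rows] - centroid) @ R.T + centroid
    elif mode == "repack":
        rows = _sheet_atom_indices(assembly, spec.sheets[1])
        coords[rows] += 0.5 * meta["strand_spacing"] * stacking_axis
    else:
        raise ValueError(f"unknown polymorph mode {mode!r}")
    out = assembly.with_coords(coords)
    out.metadata["polymorph"] = mode
    return out


def replicate_seed(seed_assembly: Assembly, n_copies: int,
                   axis_spacing: float = 4.8,
                   axis: np.ndarray | None = None) -> Assembly:
    """Stack translated copies of a seed assembly along the fibril axis,
    relabelling chains — the staged build-up used to grow a fibril from a
    converged monomer or trimer."""
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    total = seed_assembly.n_chains * n_copies
    if total > len(CHAIN_ALPHABET):
        raise ValueError(
            f"{total} chains exceed the {len(CHAIN_ALPHABET)}-letter "
            "chain-id alphabet")
    if axis is None:
        axis = np.array(seed_assembly.metadata.get("stacking_axis",
                                                   [0.0, 1.0, 0.0]))
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    # the copy offset steps past the whole seed so the first strand of the
    # next copy continues the stack at one strand spacing from the last
    centroids = []
    for chain in seed_assembly.chains:
        pts = np.array([a.xyz for g in chain.atoms for a in g if
                        a.name == "CA"])
        centroids.append(float(pts.mean(axis=0) @ axis))
    extent = max(centroids) - min(centroids)
    step = extent + axis_spacing

    chains = []
    k = 0
    for copy in range(n_copies):
        offset = copy * step * axis
        for chain in seed_assembly.chains:
            groups = [[Atom(a.name, a.element, a.xyz + offset) for a in g]
                      for g in chain.atoms]
            chains.append(Chain(CHAIN_ALPHABET[k], list(chain.residues),
                                groups))
            k += 1
    spec = None
    if seed_assembly.spec is not None:
        old = seed_assembly.spec
        spec = FibrilSpec(
            sequence=old.sequence if isinstance(old.sequence, str)
            else old.chain_sequences() * n_copies,
            n_chains=total,
            arrangement=old.arrangement,
            sheets=[[c + copy * old.n_chains for copy in range(n_copies)
                     for c in sheet] for sheet in old.sheets],
            registry_offset=old.registry_offset,
        )
    meta = dict(seed_assembly.metadata)
    meta["replicated"] = n_copies
    return Assembly(chains, meta, spec)
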