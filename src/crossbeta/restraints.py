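"""Flat-bottom restraint collections and the Bayesian restrained-sampling weight.

External knowledge about a fibril (strand arrangement, inter-strand hydrogen
bonding at 4.8 A, generic sheet packing near 10 A, or user-supplied
NMR/ssNMR-style tables) enters the sampler as a two-level hierarchy of
flat-bottom restraints:

* a :class:`RestraintGroup` holds alternative restraints of which only the
  ``n_active`` lowest-energy members are enforced at any evaluation — this is
  how ambiguous or partially wrong data is tolerated;
* a :class:`RestraintCollection` holds groups of which the
  ``n_active_groups`` lowest-energy groups are enforced.

The total collection energy ``E_c(x)`` defines the data likelihood
``p(D|x) ~ exp(-E_c(x)/kT)``; multiplied by the Boltzmann prior of the
physical potential it yields the posterior sampled by the replica-exchange
machinery.  The normalisation ``p(D)`` cancels in every ratio and is never
computed.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence, Union

import numpy as np
import pandas as pd

from .structures import Assembly, FibrilSpec, validate_spec

__all__ = [
    "K_B",
    "DIHEDRAL_CENTERS",
    "DistanceRestraint",
    "DihedralRestraint",
    "RestraintGroup",
    "RestraintCollection",
    "RestraintEnergyModel",
    "CollectionEnergy",
    "DensityReport",
    "corresponding_pairs",
    "central_residues",
    "short_fibril_protocol",
    "long_fibril_protocol",
    "load_restraint_table",
    "restraint_energy",
    "collection_energy",
    "posterior_log_weight",
    "density_report",
]

#: Boltzmann constant, kJ/mol/K.
K_B = 0.0083145

#: Backbone dihedral restraint centers (phi, psi) in degrees by strand
#: arrangement, as used by the short-fibril protocol.
DIHEDRAL_CENTERS = {
    "parallel": (-119.0, 113.0),
    "antiparallel": (-139.0, 135.0),
}

#: Base force constant for protocol distance restraints, kJ/mol/A^2.
#: The conventional quote of 250 kJ/mol/nm^2 converts via
#: 1 kJ/mol/nm^2 = 0.01 kJ/mol/A^2.
DEFAULT_DISTANCE_K = 2.5

#: Dihedral restraint force constant, kJ/mol/deg^2 (a few kT at ~15 deg
#: beyond the tolerance; the source protocols do not pin this value).
DEFAULT_DIHEDRAL_K = 0.02

#: Flat-bottom half-width for sequence-registry (4.8 A) distance restraints.
DISTANCE_TOL = 0.2
#: Flat-bottom half-width for the generic 10 A inter-sheet restraints.  Wide
#: on purpose: the 3x3 central-residue pairs of a rigidly packed pair of
#: sheets span ~10-12.6 A, and real fibrils show 8.8-14.6 A sheet spacings.
INTERSHEET_TOL = 3.0
#: Quadratic shoulder width beyond the flat bottom (r1 = r2 - margin,
#: r4 = r3 + margin); linear continuation outside keeps forces bounded.
SHOULDER_MARGIN = 1.0
#: Dihedral half-width, degrees.
DIHEDRAL_DELTA = 30.0

# An atom selector: (chain index, residue number, atom name); chain indices
# are 0-based in file order, residue numbers are 1-based within the chain.
AtomSelector = tuple[int, int, str]


@dataclass(frozen=True)
class DistanceRestraint:
    """Flat-bottom distance restraint: zero on [r2, r3], quadratic on
    [r1, r2] and [r3, r4], linear (slope-matched) beyond r1 / r4."""

    site_a: AtomSelector
    site_b: AtomSelector
    r1: float
    r2: float
    r3: float
    r4: float
    k: float = DEFAULT_DISTANCE_K  # kJ/mol/A^2

    def __post_init__(self) -> None:
        if not (self.r1 <= self.r2 <= self.r3 <= self.r4):
            raise ValueError(
                f"require r1 <= r2 <= r3 <= r4, got "
                f"{self.r1}, {self.r2}, {self.r3}, {self.r4}")
        if self.k < 0:
            raise ValueError("force constant must be >= 0")

    def profile(self, d: float) -> float:
        """Energy (kJ/mol) at separation ``d`` A with unit k_scale."""
        return _flat_bottom_energy(d, self.r1, self.r2, self.r3, self.r4, self.k)


@dataclass(frozen=True)
class DihedralRestraint:
    """Flat-bottom dihedral restraint; the deviation from ``center`` is
    wrapped to (-180, 180] and penalised quadratically beyond ``delta``."""

    sites: tuple[AtomSelector, AtomSelector, AtomSelector, AtomSelector]
    center: float  # degrees, (-180, 180]
    delta: float = DIHEDRAL_DELTA  # degrees
    k: float = DEFAULT_DIHEDRAL_K  # kJ/mol/deg^2

    def __post_init__(self) -> None:
        if not (-180.0 < self.center <= 180.0):
            raise ValueError("center must lie in (-180, 180]")
        if self.delta < 0 or self.k < 0:
            raise ValueError("delta and k must be >= 0")

    def profile(self, angle: float) -> float:
        dev = _wrap_angle(angle - self.center)
        excess = max(0.0, abs(dev) - self.delta)
        return 0.5 * self.k * excess * excess


Restraint = Union[DistanceRestraint, DihedralRestraint]


@dataclass
class RestraintGroup:
    restraints: list[Restraint]
    n_active: int | None = None  # default: all members enforced
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_active is None:
            self.n_active = len(self.restraints)
        if self.restraints and not 1 <= self.n_active <= len(self.restraints):
            raise ValueError(
                f"n_active must lie in 1..{len(self.restraints)}, "
                f"got {self.n_active}")

    def __len__(self) -> int:
        return len(self.restraints)


@dataclass
class RestraintCollection:
    groups: list[RestraintGroup] = field(default_factory=list)
    n_active_groups: int | None = None

    def __post_init__(self) -> None:
        if self.n_active_groups is None:
            self.n_active_groups = len(self.groups)
        if self.groups and not 1 <= self.n_active_groups <= len(self.groups):
            raise ValueError(
                f"n_active_groups must lie in 1..{len(self.groups)}, "
                f"got {self.n_active_groups}")

    @property
    def n_restraints(self) -> int:
        return sum(len(g) for g in self.groups)

    def iter_restraints(self):
        for gi, group in enumerate(self.groups):
            for ri, r in enumerate(group.restraints):
                yield gi, ri, r

    # ---- JSON round-trip -------------------------------------------------
    def to_json_dict(self) -> dict:
        def enc(r: Restraint) -> dict:
            if isinstance(r, DistanceRestraint):
                return {"kind": "distance",
                        "site_a": list(r.site_a), "site_b": list(r.site_b),
                        "r1": r.r1, "r2": r.r2, "r3": r.r3, "r4": r.r4,
                        "k": r.k}
            return {"kind": "dihedral",
                    "sites": [list(s) for s in r.sites],
                    "center": r.center, "delta": r.delta, "k": r.k}

        return {
            "n_active_groups": self.n_active_groups,
            "groups": [
                {"label": g.label, "n_active": g.n_active,
                 "restraints": [enc(r) for r in g.restraints]}
                for g in self.groups
            ],
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "RestraintCollection":
        def dec(rd: dict) -> Restraint:
            if rd["kind"] == "distance":
                return DistanceRestraint(
                    tuple(rd["site_a"]), tuple(rd["site_b"]),
                    rd["r1"], rd["r2"], rd["r3"], rd["r4"], rd["k"])
            return DihedralRestraint(
                tuple(tuple(s) for s in rd["sites"]),
                rd["center"], rd["delta"], rd["k"])

        groups = [
            RestraintGroup([dec(rd) for rd in gd["restraints"]],
                           n_active=gd["n_active"], label=gd.get("label", ""))
            for gd in d["groups"]
        ]
        return cls(groups, n_active_groups=d["n_active_groups"])

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=1))

    @classmethod
    def load_json(cls, path: str | Path) -> "RestraintCollection":
        return cls.from_json_dict(json.loads(Path(path).read_text()))


@dataclass
class RestraintEnergyModel:
    """Posterior weight model: prior (physical Boltzmann factor) times the
    data likelihood exp(-E_c(x)/k_B T)."""

    collection: RestraintCollection
    temperature: float  # K
    k_B: float = K_B


class CollectionEnergy(NamedTuple):
    total: float
    active_restraints: list[tuple[int, int]]  # (group index, member index)
    active_groups: list[int]


class DensityReport(NamedTuple):
    restraints_per_residue: float
    sparse_data_flag: bool


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _wrap_angle(a: float) -> float:
    """Wrap an angle in degrees to (-180, 180]."""
    a = math.fmod(a, 360.0)
    if a <= -180.0:
        a += 360.0
    elif a > 180.0:
        a -= 360.0
    return a


def _flat_bottom_energy(d, r1, r2, r3, r4, k):
    if d < r1:
        return 0.5 * k * (r2 - r1) ** 2 + k * (r2 - r1) * (r1 - d)
    if d < r2:
        return 0.5 * k * (d - r2) ** 2
    if d <= r3:
        return 0.0
    if d <= r4:
        return 0.5 * k * (d - r3) ** 2
    return 0.5 * k * (r4 - r3) ** 2 + k * (r4 - r3) * (d - r4)


def measure_dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees for four points (IUPAC convention)."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    return math.degrees(math.atan2(y, x))


def corresponding_pairs(length: int, arrangement: str,
                        registry_offset: int = 0) -> list[tuple[int, int]]:
    """Residue pairing (1-based) between adjacent strands within a sheet.

    In-register parallel strands pair residue i with residue i; antiparallel
    strands pair residue i with residue L+1-i.  ``registry_offset`` shifts
    the partner index; pairs falling outside 1..L are dropped.
    """
    pairs = []
    for i in range(1, length + 1):
        if arrangement == "parallel":
            j = i + registry_offset
        else:
            j = length + 1 - i + registry_offset
        if 1 <= j <= length:
            pairs.append((i, j))
    return pairs


def central_residues(length: int) -> list[int]:
    """The three central residue numbers (1-based): positions
    ceil(L/2)-1, ceil(L/2), ceil(L/2)+1, clipped to the chain."""
    c = math.ceil(length / 2)
    return [i for i in (c - 1, c, c + 1) if 1 <= i <= length]


# ---------------------------------------------------------------------------
# protocol generation
# ---------------------------------------------------------------------------

def _protocol_guard(spec: FibrilSpec) -> str:
    violations = validate_spec(spec)
    if violations:
        raise ValueError(
            "invalid FibrilSpec: " + "; ".join(v.message for v in violations))
    seqs = spec.chain_sequences()
    if len(set(seqs)) != 1:
        raise ValueError(
            "protocol generation requires a homomeric fibril "
            "(identical chain sequences)")
    return seqs[0]


def _distance_restraint(site_a, site_b, center, tol, k) -> DistanceRestraint:
    r2, r3 = center - tol, center + tol
    return DistanceRestraint(site_a, site_b,
                             max(0.0, r2 - SHOULDER_MARGIN), r2, r3,
                             r3 + SHOULDER_MARGIN, k)


def _interstrand_groups(spec, seq, k, residues=None):
    """One group per adjacent strand pair within each sheet; members are
    CA-CA restraints centred at 4.8 A between corresponding residues."""
    L = len(seq)
    pairs = corresponding_pairs(L, spec.arrangement, spec.registry_offset)
    if residues is not None:
        keep = set(residues)
        pairs = [(i, j) for i, j in pairs if i in keep and j in keep]
    groups = []
    for sheet in spec.sheets:
        for a, b in zip(sheet[:-1], sheet[1:]):
            members = [
                _distance_restraint((a, i, "CA"), (b, j, "CA"), 4.8,
                                    DISTANCE_TOL, k)
                for i, j in pairs
            ]
            if members:
                groups.append(RestraintGroup(members,
                                             label=f"interstrand:{a}-{b}"))
    return groups


def _intersheet_groups(spec, seq, k):
    """One group per facing strand pair of adjacent sheets; members are the
    3x3 CA-CA restraints centred at 10 A between central residues."""
    L = len(seq)
    central = central_residues(L)
    groups = []
    for sheet_a, sheet_b in zip(spec.sheets[:-1], spec.sheets[1:]):
        for a, b in zip(sheet_a, sheet_b):
            members = [
                _distance_restraint((a, i, "CA"), (b, j, "CA"), 10.0,
                                    INTERSHEET_TOL, k)
                for i in central for j in central
            ]
            groups.append(RestraintGroup(members, label=f"intersheet:{a}-{b}"))
    return groups


def _dihedral_groups(spec, seq, k):
    """Per-chain phi/psi restraints for interior residues (2..L-1); terminal
    residues lack one of the two angles and are skipped."""
    L = len(seq)
    phi0, psi0 = DIHEDRAL_CENTERS[spec.arrangement]
    groups = []
    for c in range(spec.n_chains):
        members = []
        for i in range(2, L):
            members.append(DihedralRestraint(
                ((c, i - 1, "C"), (c, i, "N"), (c, i, "CA"), (c, i, "C")),
                center=phi0, delta=DIHEDRAL_DELTA, k=k))
            members.append(DihedralRestraint(
                ((c, i, "N"), (c, i, "CA"), (c, i, "C"), (c, i + 1, "N")),
                center=psi0, delta=DIHEDRAL_DELTA, k=k))
        if members:
            groups.append(RestraintGroup(members, label=f"dihedral:{c}"))
    return groups


def short_fibril_protocol(spec: FibrilSpec, level: str = "S0",
                          k: float = DEFAULT_DISTANCE_K,
                          dihedral_k: float = DEFAULT_DIHEDRAL_K,
                          ) -> RestraintCollection:
    """Generate the short-fibril restraint protocol at information level
    S0 (full), S1 (no dihedrals), S2 (central-residue distances only) or
    S3 (single group of central-residue inter-strand restraints)."""
    seq = _protocol_guard(spec)
    level = level.upper()
    if level not in ("S0", "S1", "S2", "S3"):
        raise ValueError(f"unknown short-fibril level {level!r}")
    L = len(seq)
    want_intersheet = level in ("S0", "S1", "S2")
    if want_intersheet and len(spec.sheets) < 2:
        warnings.warn(
            "single-sheet spec: inter-sheet restraints omitted",
            stacklevel=2)
        want_intersheet = False

    groups: list[RestraintGroup] = []
    if level in ("S0", "S1"):
        groups += _interstrand_groups(spec, seq, k)
    elif level == "S2":
        groups += _interstrand_groups(spec, seq, k,
                                      residues=central_residues(L))
    else:  # S3: one group, central residue of each adjacent strand pair
        c = math.ceil(L / 2)
        pairs = {i: j for i, j in
                 corresponding_pairs(L, spec.arrangement,
                                     spec.registry_offset)}
        members = []
        for sheet in spec.sheets:
            for a, b in zip(sheet[:-1], sheet[1:]):
                if c in pairs:
                    members.append(_distance_restraint(
                        (a, c, "CA"), (b, pairs[c], "CA"), 4.8,
                        DISTANCE_TOL, k))
        if members:
            groups.append(RestraintGroup(members, label="interstrand:central"))
        return RestraintCollection(groups)

    if want_intersheet:
        groups += _intersheet_groups(spec, seq, k)
    if level == "S0":
        groups += _dihedral_groups(spec, seq, dihedral_k)
    return RestraintCollection(groups)


def long_fibril_protocol(spec: FibrilSpec, level: str = "L2",
                         k: float = DEFAULT_DISTANCE_K,
                         dihedral_k: float = DEFAULT_DIHEDRAL_K,
                         ) -> RestraintCollection:
    """Long-chain protocol levels: L2 mirrors the general short-fibril
    protocol (inter-strand + inter-sheet + dihedrals); L3 keeps only the
    4.8 A inter-strand restraints between adjacent strands."""
    seq = _protocol_guard(spec)
    level = level.upper()
    if level == "L2":
        return short_fibril_protocol(spec, "S0", k=k, dihedral_k=dihedral_k)
    if level == "L3":
        return RestraintCollection(_interstrand_groups(spec, seq, k))
    raise ValueError(f"unknown long-fibril level {level!r}")


# ---------------------------------------------------------------------------
# tabular restraints
# ---------------------------------------------------------------------------

_DIST_COLS = {"chain_i", "res_i", "atom_i", "chain_j", "res_j", "atom_j",
              "r2", "r3"}
_DIH_COLS = {"chain", "res", "angle_name", "center", "delta"}


def load_restraint_table(path: str | Path,
                         k: float = DEFAULT_DISTANCE_K,
                         dihedral_k: float = DEFAULT_DIHEDRAL_K,
                         ) -> RestraintCollection:
    """Parse a delimited restraint table (CSV/TSV with header).

    Distance tables carry columns chain_i,res_i,atom_i,chain_j,res_j,atom_j,
    r2,r3; dihedral tables carry chain,res,angle_name,center,delta.  Rows
    sharing a ``group`` label form one group; ungrouped rows become
    singleton groups.  r1/r4 derive from r2/r3 via the default shoulder
    margin.  Selector validity is only checked at first evaluation against
    an assembly.
    """
    path = Path(path)
    text = path.read_text()
    first = next((ln for ln in text.splitlines()
                  if ln.strip() and not ln.startswith("#")), "")
    sep = "\t" if "\t" in first else ","
    try:
        df = pd.read_csv(path, sep=sep, skip_blank_lines=True, comment="#")
    except pd.errors.EmptyDataError:
        return RestraintCollection([])
    if df.empty:
        return RestraintCollection([])
    cols = set(df.columns)
    if _DIST_COLS <= cols:
        kind = "distance"
    elif _DIH_COLS <= cols:
        kind = "dihedral"
    else:
        raise ValueError(
            f"{path}: header must contain either {sorted(_DIST_COLS)} "
            f"or {sorted(_DIH_COLS)}")

    grouped: dict[str, list[Restraint]] = {}
    singletons: list[Restraint] = []
    for pos, (idx, row) in enumerate(df.iterrows()):
        lineno = pos + 2  # header is line 1
        try:
            if kind == "distance":
                r2, r3 = float(row["r2"]), float(row["r3"])
                if r2 > r3:
                    raise ValueError(f"r2={r2} > r3={r3}")
                r = DistanceRestraint(
                    (int(row["chain_i"]), int(row["res_i"]),
                     str(row["atom_i"]).strip()),
                    (int(row["chain_j"]), int(row["res_j"]),
                     str(row["atom_j"]).strip()),
                    max(0.0, r2 - SHOULDER_MARGIN), r2, r3,
                    r3 + SHOULDER_MARGIN,
                    float(row["k"]) if "k" in cols and pd.notna(row.get("k"))
                    else k)
            else:
                name = str(row["angle_name"]).strip().lower()
                c = int(row["chain"])
                i = int(row["res"])
                if name == "phi":
                    sites = ((c, i - 1, "C"), (c, i, "N"),
                             (c, i, "CA"), (c, i, "C"))
                elif name == "psi":
                    sites = ((c, i, "N"), (c, i, "CA"),
                             (c, i, "C"), (c, i + 1, "N"))
                else:
                    raise ValueError(f"unknown angle_name {name!r}")
                r = DihedralRestraint(sites, float(row["center"]),
                                      float(row["delta"]), dihedral_k)
        except (ValueError, KeyError, TypeError) as exc:
            raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from exc
        group = row.get("group") if "group" in cols else None
        if group is None or (isinstance(group, float) and math.isnan(group)):
            singletons.append(r)
        else:
            grouped.setdefault(str(group), []).append(r)

    groups = [RestraintGroup(rs, label=lab) for lab, rs in grouped.items()]
    groups += [RestraintGroup([r]) for r in singletons]
    return RestraintCollection(groups)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _resolve(selector: AtomSelector, index: dict, assembly: Assembly) -> int:
    ci, resno, name = selector
    key = (ci, resno - 1, name)
    if key not in index:
        raise KeyError(
            f"restraint selector (chain {ci}, residue {resno}, atom "
            f"{name!r}) does not resolve in an assembly with "
            f"{assembly.n_chains} chains")
    return index[key]


def restraint_energy(r: Restraint, assembly: Assembly,
                     k_scale: float = 1.0,
                     _index: dict | None = None,
                     _coords: np.ndarray | None = None) -> float:
    """Energy (kJ/mol) of one restraint on an assembly, scaled by the
    replica's restraint strength ``k_scale`` in [0, 1]."""
    index = _index if _index is not None else assembly.atom_index()
    coords = _coords if _coords is not None else assembly.coords()
    if isinstance(r, DistanceRestraint):
        ia = _resolve(r.site_a, index, assembly)
        ib = _resolve(r.site_b, index, assembly)
        d = float(np.linalg.norm(coords[ia] - coords[ib]))
        return k_scale * r.profile(d)
    ii = [_resolve(s, index, assembly) for s in r.sites]
    angle = measure_dihedral(*(coords[i] for i in ii))
    return k_scale * r.profile(angle)


def collection_energy(c: RestraintCollection, assembly: Assembly,
                      k_scale: float = 1.0) -> CollectionEnergy:
    """Total enforced energy of a collection and the exact active set.

    Within each group the ``n_active`` lowest-energy members are summed;
    groups are then ranked by that sum and the ``n_active_groups`` lowest
    groups are summed.  Ties break by declaration order (stable sort).
    """
    index = assembly.atom_index()
    coords = assembly.coords()
    group_sums: list[float] = []
    group_active: list[list[tuple[int, int]]] = []
    for gi, group in enumerate(c.groups):
        energies = [
            restraint_energy(r, assembly, k_scale, _index=index,
                             _coords=coords)
            for r in group.restraints
        ]
        order = sorted(range(len(energies)), key=lambda i: (energies[i], i))
        chosen = order[:group.n_active]
        group_sums.append(sum(energies[i] for i in chosen))
        group_active.append([(gi, i) for i in sorted(chosen)])
    order = sorted(range(len(group_sums)), key=lambda g: (group_sums[g], g))
    active_groups = sorted(order[:c.n_active_groups])
    total = sum(group_sums[g] for g in active_groups)
    active = [pair for g in active_groups for pair in group_active[g]]
    return CollectionEnergy(total, active, active_groups)


def posterior_log_weight(model: RestraintEnergyModel, physical_energy: float,
                         assembly: Assembly, k_scale: float = 1.0) -> float:
    """Log posterior weight -(E_phys + E_c)/(k_B T), up to the additive
    constant from the uncomputed normalisation: differences of returned
    values are exact log posterior ratios."""
    if model.temperature <= 0:
        raise ValueError("temperature must be positive")
    e_c = collection_energy(model.collection, assembly, k_scale).total
    return -(physical_energy + e_c) / (model.k_B * model.temperature)


def density_report(c: RestraintCollection, spec: FibrilSpec) -> DensityReport:
    """Restraints per residue, with an advisory flag below 0.5 — sparser
    protocols than that are empirically unreliable."""
    n_res = spec.n_residues_total
    density = c.n_restraints / n_res if n_res else 0.0
    return DensityReport(density, density < 0.5)
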