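"""Data model for multi-chain peptide assemblies and fibril specifications.

An :class:`Assembly` is the package-wide container for coordinates: an ordered
list of chains, each an ordered list of residues carrying named atoms with
positions in Angstrom.  A :class:`FibrilSpec` declares the target fibril —
peptide sequence, chain count, parallel/antiparallel strand arrangement and
the assignment of chains to beta-sheets — and is the single source of truth
for restraint-protocol generation and fixture construction.

PDB reading/writing is delegated to :mod:`biotite`; only the first model is
read by default, alternate locations other than blank/'A' are dropped and
HETATM records are ignored.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb
from biotite.sequence import ProteinSequence

__all__ = [
    "Atom",
    "Chain",
    "Assembly",
    "FibrilSpec",
    "SpecViolation",
    "read_structure",
    "write_structure",
    "validate_spec",
]

# PDB chain identifier alphabet: upper, lower, digits -> 62 chains max.
CHAIN_ALPHABET = string.ascii_uppercase + string.ascii_lowercase + string.digits


class Atom(NamedTuple):
    name: str
    element: str
    xyz: np.ndarray  # shape (3,), Angstrom


@dataclass
class Chain:
    """One peptide chain: residue names (3-letter) and per-residue atoms."""

    chain_id: str
    residues: list[str]
    atoms: list[list[Atom]]

    def __post_init__(self) -> None:
        if len(self.residues) != len(self.atoms):
            raise ValueError(
                f"chain {self.chain_id!r}: {len(self.residues)} residues but "
                f"{len(self.atoms)} atom groups"
            )

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def sequence1(self) -> str:
        """One-letter sequence ('X' for non-standard residues)."""
        out = []
        for res in self.residues:
            try:
                out.append(ProteinSequence.convert_letter_3to1(res))
            except KeyError:
                out.append("X")
        return "".join(out)


@dataclass
class Assembly:
    """Multi-chain assembly; the configuration *x* that restraint energies
    and the surrogate potential are evaluated on."""

    chains: list[Chain]
    metadata: dict = field(default_factory=dict)
    spec: "FibrilSpec | None" = None

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    @property
    def n_atoms(self) -> int:
        return sum(len(g) for c in self.chains for g in c.atoms)

    @property
    def n_residues(self) -> int:
        return sum(c.n_residues for c in self.chains)

    def iter_atoms(self) -> Iterator[tuple[int, int, Atom]]:
        """Yield (chain_index, residue_index, Atom); residue_index 0-based."""
        for ci, chain in enumerate(self.chains):
            for ri, group in enumerate(chain.atoms):
                for atom in group:
                    yield ci, ri, atom

    def coords(self) -> np.ndarray:
        """Flat (n_atoms, 3) coordinate array in iteration order."""
        return np.array([a.xyz for _, _, a in self.iter_atoms()], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "Assembly":
        """Copy of this assembly with coordinates replaced (same topology)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError(f"expected coords of shape {(self.n_atoms, 3)}")
        chains = []
        k = 0
        for chain in self.chains:
            groups = []
            for group in chain.atoms:
                new = [Atom(a.name, a.element, coords[k + i].copy())
                       for i, a in enumerate(group)]
                k += len(group)
                groups.append(new)
            chains.append(Chain(chain.chain_id, list(chain.residues), groups))
        return Assembly(chains, dict(self.metadata), self.spec)

    def atom_index(self) -> dict[tuple[int, int, str], int]:
        """Map (chain_index, residue_index, atom_name) -> flat coordinate row."""
        idx = {}
        for k, (ci, ri, atom) in enumerate(self.iter_atoms()):
            idx[(ci, ri, atom.name)] = k
        return idx

    def ca_indices(self) -> np.ndarray:
        return np.array(
            [k for k, (_, _, a) in enumerate(self.iter_atoms()) if a.name == "CA"],
            dtype=int,
        )

    def ca_coords(self) -> np.ndarray:
        return self.coords()[self.ca_indices()]

    def ca_only(self) -> "Assembly":
        """Reduced assembly keeping only the CA atom of each residue."""
        chains = []
        for chain in self.chains:
            groups = []
            for ri, group in enumerate(chain.atoms):
                cas = [a for a in group if a.name == "CA"]
                if len(cas) != 1:
                    raise ValueError(
                        f"chain {chain.chain_id!r} residue {ri + 1} has "
                        f"{len(cas)} CA atoms"
                    )
                groups.append([Atom("CA", cas[0].element, cas[0].xyz.copy())])
            chains.append(Chain(chain.chain_id, list(chain.residues), groups))
        return Assembly(chains, dict(self.metadata), self.spec)

    def is_ca_only(self) -> bool:
        return all(
            len(g) == 1 and g[0].name == "CA"
            for c in self.chains for g in c.atoms
        )

    def validate(self) -> None:
        coords = self.coords()
        if not np.all(np.isfinite(coords)):
            raise ValueError("assembly contains non-finite coordinates")
        if self.spec is not None:
            seqs = self.spec.chain_sequences()
            if len(self.chains) != self.spec.n_chains:
                raise ValueError(
                    f"assembly has {len(self.chains)} chains; spec requires "
                    f"{self.spec.n_chains}")
            for chain, seq in zip(self.chains, seqs):
                if chain.n_residues != len(seq):
                    raise ValueError(
                        f"chain {chain.chain_id!r} has {chain.n_residues} "
                        f"residues; spec requires {len(seq)}"
                    )


@dataclass
class FibrilSpec:
    """Declarative description of a target cross-beta fibril.

    ``sheets`` assigns every chain index to exactly one sheet and fixes the
    strand order within each sheet; ``arrangement`` applies to adjacent
    strands within a sheet.  ``registry_offset`` shifts the in-register
    residue pairing (0 = in-register).
    """

    sequence: "str | list[str]"  # shared sequence, or one per chain
    n_chains: int
    arrangement: str  # "parallel" | "antiparallel"
    sheets: list[list[int]]
    registry_offset: int = 0

    def chain_sequences(self) -> list[str]:
        """One-letter sequence per chain (heteromeric specs are allowed by
        the type; protocol generation enforces homomeric input)."""
        if isinstance(self.sequence, str):
            return [self.sequence] * self.n_chains
        return list(self.sequence)

    @property
    def n_residues_total(self) -> int:
        return sum(len(s) for s in self.chain_sequences())

    def to_dict(self) -> dict:
        return {
            "sequence": self.sequence,
            "n_chains": self.n_chains,
            "arrangement": self.arrangement,
            "sheets": [list(s) for s in self.sheets],
            "registry_offset": self.registry_offset,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FibrilSpec":
        return cls(
            sequence=str(d["sequence"]),
            n_chains=int(d["n_chains"]),
            arrangement=str(d["arrangement"]),
            sheets=[list(map(int, s)) for s in d["sheets"]],
            registry_offset=int(d.get("registry_offset", 0)),
        )


class SpecViolation(NamedTuple):
    code: str
    message: str


def validate_spec(spec: FibrilSpec) -> list[SpecViolation]:
    """Check FibrilSpec invariants; returns an empty list iff well-formed."""
    out: list[SpecViolation] = []
    if not spec.sequence or (not isinstance(spec.sequence, str)
                             and not all(spec.sequence)):
        out.append(SpecViolation("empty-sequence", "sequence must be non-empty"))
    if (not isinstance(spec.sequence, str)
            and len(spec.sequence) != spec.n_chains):
        out.append(SpecViolation(
            "sequence-count-mismatch",
            f"{len(spec.sequence)} per-chain sequences for "
            f"{spec.n_chains} chains"))
    if spec.n_chains < 1:
        out.append(SpecViolation("bad-chain-count",
                                 f"n_chains must be >= 1, got {spec.n_chains}"))
    if spec.arrangement not in ("parallel", "antiparallel"):
        out.append(SpecViolation(
            "bad-arrangement",
            f"arrangement must be 'parallel' or 'antiparallel', "
            f"got {spec.arrangement!r}"))
    seen: dict[int, int] = {}
    for si, sheet in enumerate(spec.sheets):
        for idx in sheet:
            seen[idx] = seen.get(idx, 0) + 1
    dupes = sorted(i for i, n in seen.items() if n > 1)
    if dupes:
        out.append(SpecViolation(
            "duplicate-assignment",
            f"chain indices assigned to more than one sheet slot: {dupes}"))
    want = set(range(spec.n_chains))
    missing = sorted(want - set(seen))
    if missing:
        out.append(SpecViolation(
            "incomplete-cover",
            f"chain indices not assigned to any sheet: {missing}"))
    extra = sorted(set(seen) - want)
    if extra:
        out.append(SpecViolation(
            "out-of-range-index",
            f"sheet entries outside 0..{spec.n_chains - 1}: {extra}"))
    return out


def _assembly_from_atom_array(array: struc.AtomArray) -> Assembly:
    chains: list[Chain] = []
    # first-occurrence order, not np.unique's sorted order
    chain_order = list(dict.fromkeys(array.chain_id.tolist()))
    for chain_id in chain_order:
        mask = array.chain_id == chain_id
        sub = array[mask]
        residues: list[str] = []
        groups: list[list[Atom]] = []
        # preserve file order of residues
        res_starts = struc.get_residue_starts(sub)
        for s, e in zip(res_starts, list(res_starts[1:]) + [len(sub)]):
            residues.append(str(sub.res_name[s]))
            group = [
                Atom(str(sub.atom_name[i]), str(sub.element[i]),
                     np.array(sub.coord[i], dtype=float))
                for i in range(s, e)
            ]
            groups.append(group)
        chains.append(Chain(str(chain_id), residues, groups))
    return Assembly(chains)


def read_structure(path: str | Path, model_index: int = 1,
                   ca_only: bool = False) -> Assembly:
    """Read a PDB file into an :class:`Assembly`.

    ``model_index`` is 1-based; only altloc blank/'A' atoms are kept and
    HETATM records are ignored.  With ``ca_only`` every residue must carry a
    CA atom and all other atoms are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    # fibril peptides never need insertion codes; reject them outright
    # rather than silently renumbering
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if line.startswith(("ATOM", "HETATM")) and len(line) > 26 \
                and line[26] != " ":
            raise ValueError(
                f"{path}:{lineno}: insertion codes are not supported")
    pdb_file = pdb.PDBFile.read(str(path))
    n_models = pdb_file.get_model_count()
    if not 1 <= model_index <= n_models:
        raise IndexError(
            f"model_index {model_index} out of range (file has {n_models})")
    array = pdb_file.get_structure(model=model_index, altloc="first",
                                   extra_fields=[])
    array = array[~array.hetero]
    if array.array_length() == 0:
        raise ValueError(f"{path}: no ATOM records")
    asm = _assembly_from_atom_array(array)
    asm.metadata["source"] = str(path)
    asm.metadata["model_index"] = model_index
    if ca_only:
        asm = asm.ca_only()
        asm.metadata["source"] = str(path)
        asm.metadata["model_index"] = model_index
    asm.validate()
    return asm


def write_structure(assembly: Assembly, path: str | Path) -> None:
    """Write an assembly as fixed-column PDB ATOM records (TER between
    chains, END terminator)."""
    if assembly.n_chains == 0 or assembly.n_atoms == 0:
        raise ValueError("cannot write an empty assembly")
    if assembly.n_chains > len(CHAIN_ALPHABET):
        raise ValueError(
            f"{assembly.n_chains} chains exceed the {len(CHAIN_ALPHABET)}"
            "-letter PDB chain-id alphabet")
    n = assembly.n_atoms
    array = struc.AtomArray(n)
    k = 0
    for ci, chain in enumerate(assembly.chains):
        cid = chain.chain_id if len(chain.chain_id) == 1 else CHAIN_ALPHABET[ci]
        for ri, (res_name, group) in enumerate(zip(chain.residues, chain.atoms)):
            for atom in group:
                array.chain_id[k] = cid
                array.res_id[k] = ri + 1
                array.res_name[k] = res_name
                array.atom_name[k] = atom.name
                array.element[k] = atom.element
                array.coord[k] = atom.xyz
                array.hetero[k] = False
                k += 1
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(array)
    pdb_file.write(str(path))
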