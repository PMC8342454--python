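"""Structure-comparison kernels for multi-chain assemblies.

All scores treat the aggregate as a single unit: one global superposition
over every mapped atom (no per-chain fitting), which is the right convention
for judging whether a predicted fibril reproduces the full quaternary
arrangement rather than just the monomer fold.

Conventions:

* GDT_TS — mean over the CASP cutoffs {1, 2, 4, 8} A of the percentage of
  CA pairs within the cutoff, after a single global Kabsch fit (the full
  LGA multi-superposition search is deliberately not performed).
* TM-score — (1/L) sum 1/(1+(d_i/d0)^2) with d0 = 1.24 (L-15)^(1/3) - 1.8
  computed from the total aggregate length and clamped to >= 0.5 A (short
  peptide aggregates would otherwise give a negative d0).  The
  superposition maximising the score is found by iterative subset
  refinement seeded from the global fit and from contiguous fragments.
* Native contacts — CA pairs within ``cutoff`` (default 8 A) in the
  reference, excluding intra-chain pairs closer than ``min_seq_sep`` in
  sequence; the score is the percentage of those also present in the model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .structures import Assembly

__all__ = [
    "KabschResult",
    "ScoreReport",
    "kabsch",
    "superpose",
    "assembly_rmsd",
    "gdt_ts",
    "tm_score",
    "tm_d0",
    "native_contact_pct",
    "score_report",
]

GDT_CUTOFFS = (1.0, 2.0, 4.0, 8.0)


class KabschResult(NamedTuple):
    rotation: np.ndarray   # (3, 3) proper rotation
    translation: np.ndarray  # (3,)
    rmsd: float


@dataclass
class ScoreReport:
    rmsd_ca: float
    gdt_ts: float
    tm_score: float
    native_contact_pct: float
    rmsd_heavy: float | None = None
    chain_mapping: tuple[int, ...] | None = None

    def to_dict(self) -> dict:
        return {
            "rmsd_ca": self.rmsd_ca,
            "rmsd_heavy": self.rmsd_heavy,
            "gdt_ts": self.gdt_ts,
            "tm_score": self.tm_score,
            "native_contact_pct": self.native_contact_pct,
            "chain_mapping": (list(self.chain_mapping)
                              if self.chain_mapping is not None else None),
        }


def kabsch(P: np.ndarray, Q: np.ndarray,
           weights: np.ndarray | None = None) -> KabschResult:
    """Optimal proper rotation + translation mapping P onto Q.

    Minimises the (weighted) RMSD of ``P @ R.T + t`` against ``Q``; the
    reflection branch of the SVD solution is sign-corrected so the result
    is always a proper rotation (det = +1).
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must both have shape (N, 3)")
    n = P.shape[0]
    if n < 3:
        raise ValueError("at least 3 points are required")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    pc = w @ P
    qc = w @ Q
    p = P - pc
    q = Q - qc
    H = (p * w[:, None]).T @ q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    fitted = p @ R.T
    rmsd = float(np.sqrt(np.sum(w[:, None] * (fitted - q) ** 2)))
    t = qc - R @ pc
    return KabschResult(R, t, rmsd)


def superpose(P: np.ndarray, Q: np.ndarray,
              weights: np.ndarray | None = None) -> np.ndarray:
    """Return P rigidly fitted onto Q."""
    R, t, _ = kabsch(P, Q, weights)
    return np.asarray(P) @ R.T + t


def _select_coords(asm: Assembly, atom_mode: str) -> np.ndarray:
    if atom_mode == "ca":
        return asm.ca_coords()
    if atom_mode == "heavy":
        coords = [a.xyz for _, _, a in asm.iter_atoms() if a.element != "H"]
        return np.array(coords, dtype=float)
    raise ValueError(f"unknown atom_mode {atom_mode!r}")


def _chain_coords(asm: Assembly, atom_mode: str) -> list[np.ndarray]:
    out = []
    for ci, chain in enumerate(asm.chains):
        pts = []
        for group in chain.atoms:
            for a in group:
                if atom_mode == "ca" and a.name != "CA":
                    continue
                if atom_mode == "heavy" and a.element == "H":
                    continue
                pts.append(a.xyz)
        out.append(np.array(pts, dtype=float))
    return out


def _mapping_rmsd(model_chains, ref_chains, perm) -> float:
    P = np.concatenate([model_chains[p] for p in perm])
    Q = np.concatenate(ref_chains)
    return kabsch(P, Q).rmsd


def assembly_rmsd(model: Assembly, ref: Assembly, atom_mode: str = "ca",
                  mapping_mode: str = "identity",
                  return_mapping: bool = False):
    """Whole-aggregate RMSD after one global superposition.

    ``best_permutation`` searches chain assignments among chains with
    identical sequences (exhaustive up to 8 chains, greedy pair-swap hill
    climbing beyond) and returns the minimum.
    """
    model_chains = _chain_coords(model, atom_mode)
    ref_chains = _chain_coords(ref, atom_mode)
    if len(model_chains) != len(ref_chains):
        raise ValueError("chain counts differ")
    for mc, rc in zip(model_chains, ref_chains):
        if mc.shape != rc.shape:
            raise ValueError("per-chain atom counts do not match")
    n = len(model_chains)
    identity = tuple(range(n))
    if mapping_mode == "identity":
        best_perm, best = identity, _mapping_rmsd(model_chains, ref_chains,
                                                  identity)
    elif mapping_mode == "best_permutation":
        seqs_m = [c.sequence1() for c in model.chains]
        seqs_r = [c.sequence1() for c in ref.chains]
        # permutations may only move a model chain to a slot whose reference
        # chain has the same sequence and atom count
        def ok(perm):
            return all(
                seqs_m[p] == seqs_r[i]
                and model_chains[p].shape == ref_chains[i].shape
                for i, p in enumerate(perm))
        if n <= 8:
            best, best_perm = np.inf, identity
            for perm in itertools.permutations(range(n)):
                if not ok(perm):
                    continue
                r = _mapping_rmsd(model_chains, ref_chains, perm)
                if r < best:
                    best, best_perm = r, perm
        else:
            perm = list(identity)
            best = _mapping_rmsd(model_chains, ref_chains, perm)
            improved = True
            while improved:
                improved = False
                for i in range(n):
                    for j in range(i + 1, n):
                        cand = list(perm)
                        cand[i], cand[j] = cand[j], cand[i]
                        if not ok(cand):
                            continue
                        r = _mapping_rmsd(model_chains, ref_chains, cand)
                        if r < best - 1e-12:
                            best, perm, improved = r, cand, True
            best_perm = tuple(perm)
    else:
        raise ValueError(f"unknown mapping_mode {mapping_mode!r}")
    if return_mapping:
        return float(best), tuple(best_perm)
    return float(best)


def _paired_ca(model: Assembly, ref: Assembly):
    P = model.ca_coords()
    Q = ref.ca_coords()
    if P.shape != Q.shape:
        raise ValueError("CA counts differ between model and reference")
    return P, Q


def gdt_ts(model: Assembly, ref: Assembly, superpose_first: bool = True
           ) -> float:
    """Global distance test (total score), 0-100."""
    P, Q = _paired_ca(model, ref)
    if superpose_first:
        P = superpose(P, Q)
    d = np.linalg.norm(P - Q, axis=1)
    fracs = [np.mean(d <= c) for c in GDT_CUTOFFS]
    return float(100.0 * np.mean(fracs))


def tm_d0(length: int) -> float:
    """TM-score normalisation distance, clamped to >= 0.5 A."""
    if length <= 15:
        return 0.5
    return max(0.5, 1.24 * (length - 15) ** (1.0 / 3.0) - 1.8)


def _tm_from_fit(P, Q, d0):
    d2 = np.sum((P - Q) ** 2, axis=1)
    return float(np.mean(1.0 / (1.0 + d2 / (d0 * d0))))


def tm_score(model: Assembly, ref: Assembly, superpose_first: bool = True,
             max_iter: int = 30) -> float:
    """Length-normalised similarity in (0, 1]; 1 means identical.

    With superposition enabled, the score-maximising fit is approximated in
    two stages: iterative subset refinement (seeded from the global Kabsch
    fit and from contiguous fragments of length L, L/2 and L/4, re-fitting
    on the residues inside the inclusion cutoff until the subset stops
    changing), followed by a direct local maximisation of the score over
    the rigid motion from the best fit found.
    """
    P, Q = _paired_ca(model, ref)
    L = len(P)
    d0 = tm_d0(L)
    if not superpose_first:
        return _tm_from_fit(P, Q, d0)

    cut = max(d0, 3.0)
    seeds: list[np.ndarray] = [np.arange(L)]
    for frag in (max(3, L // 2), max(3, L // 4)):
        for start in range(0, L - frag + 1, max(1, frag // 2)):
            seeds.append(np.arange(start, start + frag))

    best = 0.0
    fits: list[np.ndarray] = []
    for seed in seeds:
        subset = seed
        prev: set[int] = set()
        for _ in range(max_iter):
            if len(subset) < 3:
                break
            Pf = superpose(P, Q, weights=_subset_weights(L, subset))
            score = _tm_from_fit(Pf, Q, d0)
            if score > best:
                best = score
            fits.append(Pf)
            d = np.linalg.norm(Pf - Q, axis=1)
            new = np.where(d <= cut)[0]
            if len(new) < 3:
                break
            if set(new.tolist()) == prev:
                break
            prev = set(new.tolist())
            subset = new
    # polish the most promising fits directly on the score
    fits.sort(key=lambda F: -_tm_from_fit(F, Q, d0))
    for F in fits[:5]:
        best = max(best, _tm_polish(F, Q, d0))
    return best


def _tm_polish(P: np.ndarray, Q: np.ndarray, d0: float) -> float:
    """Local maximisation of the TM sum over the rigid motion of P."""
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    Pc = P - P.mean(axis=0)
    base_t = P.mean(axis=0)

    def neg_score(x):
        R = Rotation.from_rotvec(x[:3]).as_matrix()
        d2 = np.sum((Pc @ R.T + base_t + x[3:] - Q) ** 2, axis=1)
        return -np.mean(1.0 / (1.0 + d2 / (d0 * d0)))

    res = minimize(neg_score, np.zeros(6), method="Nelder-Mead",
                   options={"maxiter": 3000, "xatol": 1e-8, "fatol": 1e-12})
    return float(-res.fun)


def _subset_weights(L: int, subset: np.ndarray) -> np.ndarray:
    w = np.zeros(L)
    w[subset] = 1.0
    return w


def _contact_pairs(asm: Assembly, cutoff: float, min_seq_sep: int):
    """Set of global CA index pairs in contact, excluding short-range
    intra-chain pairs."""
    coords = asm.ca_coords()
    chain_of = []
    res_of = []
    for ci, chain in enumerate(asm.chains):
        for ri in range(chain.n_residues):
            chain_of.append(ci)
            res_of.append(ri)
    chain_of = np.array(chain_of)
    res_of = np.array(res_of)
    n = len(coords)
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt(np.sum(diff * diff, axis=-1))
    iu, ju = np.triu_indices(n, k=1)
    near = dist[iu, ju] <= cutoff
    same_chain = chain_of[iu] == chain_of[ju]
    short = same_chain & (np.abs(res_of[iu] - res_of[ju]) < min_seq_sep)
    keep = near & ~short
    return set(zip(iu[keep].tolist(), ju[keep].tolist()))


def native_contact_pct(model: Assembly, ref: Assembly, cutoff: float = 8.0,
                       min_seq_sep: int = 3) -> float:
    """Percentage of reference CA contacts preserved in the model."""
    ref_contacts = _contact_pairs(ref, cutoff, min_seq_sep)
    if not ref_contacts:
        raise ValueError("reference structure has no contacts under the "
                         "chosen criterion")
    model_contacts = _contact_pairs(model, cutoff, min_seq_sep)
    kept = len(ref_contacts & model_contacts)
    return 100.0 * kept / len(ref_contacts)


def score_report(model: Assembly, ref: Assembly,
                 mapping_mode: str = "identity",
                 heavy: bool = False) -> ScoreReport:
    """Full comparison of a model against a reference assembly."""
    rmsd_ca, mapping = assembly_rmsd(model, ref, "ca", mapping_mode,
                                     return_mapping=True)
    if mapping != tuple(range(model.n_chains)):
        model = Assembly([model.chains[p] for p in mapping],
                         dict(model.metadata), model.spec)
    rmsd_heavy = assembly_rmsd(model, ref, "heavy") if heavy else None
    return ScoreReport(
        rmsd_ca=rmsd_ca,
        rmsd_heavy=rmsd_heavy,
        gdt_ts=gdt_ts(model, ref),
        tm_score=tm_score(model, ref),
        native_contact_pct=native_contact_pct(model, ref),
        chain_mapping=mapping,
    )
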