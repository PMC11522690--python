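"""Synthetic molecules with physically consistent surrogate labels.

The generator stands in for external quantum-chemical databases. Its labels
are exactly closed under the bookkeeping sum rules by construction:

- charges from constrained electronegativity equalization (sum q = 0 exactly);
- delocalization indices decaying exponentially with distance, with
  lambda_A = N_A - 1/2 sum_B delta_AB so the electron-count sum rule holds;
- pair energies (screened Coulomb + Born-Mayer) plus quadratic self-energies
  summing exactly to the stored total.

Functional forms are exactly solvable surrogates chosen for their
qualitative structure, not for quantum-chemical accuracy. Distances enter
the a.u. energy expressions in angstrom (a documented convention of the
surrogate, not a physical unit system).

It also scripts rigid host-guest "binding" trajectories with a stored
ground-truth event table for the trajectory-analysis layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .chemsys import (
    LocalPropertyRecord,
    Molecule,
    n_pairs,
    pair_index_arrays,
    symbol_for,
)

__all__ = [
    "SurrogateParams",
    "GenerationError",
    "chon_params",
    "water_params",
    "generate_geometry",
    "surrogate_charges",
    "diatomic_charge_closed_form",
    "surrogate_electron_structure",
    "surrogate_delta",
    "surrogate_iqa",
    "label_molecule",
    "generate_dataset",
    "generate_binding_trajectory",
    "BindingEvent",
]


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SurrogateParams:
    """Parameters of the surrogate label model.

    chi: electronegativity (a.u./e); eta: hardness (a.u./e^2) — must be
    positive; s: bond-order prefactor (e); r0: per-element reference radius
    (angstrom; pair reference is the sum); kappa: bond-order decay length
    (angstrom); e0: per-element self-energy offset (a.u.).
    """

    chi: Dict[int, float]
    eta: Dict[int, float]
    s: Dict[int, float]
    r0: Dict[int, float]
    e0: Dict[int, float]
    kappa: float = 1.0
    delta_max: float = 3.0
    r_floor: float = 0.5
    pair_repulsion_a0: float = 0.2
    pair_repulsion_b: float = 2.0
    sigma_noise: float = 0.0
    box_edge: float = 7.0
    min_distance: float = 1.8
    element_pool: Tuple[Tuple[int, float], ...] = ()
    m_range: Tuple[int, int] = (4, 10)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.eta.values()):
            raise ValueError("hardness eta must be positive for all elements")
        if self.kappa <= 0:
            raise ValueError("decay length kappa must be positive")
        if self.sigma_noise < 0:
            raise ValueError("label noise must be >= 0")
        if self.min_distance <= 0:
            raise ValueError("minimum interatomic distance must be positive")
        if self.r_floor <= 0:
            raise ValueError("r_floor must be positive")

    def pair_r0(self, Z_i: int, Z_j: int) -> float:
        return self.r0[Z_i] + self.r0[Z_j]


def chon_params(seed: int = 0, sigma_noise: float = 0.0) -> SurrogateParams:
    """Default CHON-like parameter set."""
    return SurrogateParams(
        chi={1: 0.20, 6: 0.35, 7: 0.55, 8: 0.75},
        eta={1: 2.2, 6: 2.0, 7: 2.1, 8: 2.3},
        s={1: 0.45, 6: 0.90, 7: 0.90, 8: 0.80},
        r0={1: 0.35, 6: 0.75, 7: 0.70, 8: 0.65},
        e0={1: -0.5, 6: -37.8, 7: -54.6, 8: -75.1},
        element_pool=((1, 0.5), (6, 0.25), (7, 0.125), (8, 0.125)),
        sigma_noise=sigma_noise,
        seed=seed,
    )


def water_params(seed: int = 0, sigma_noise: float = 0.0) -> SurrogateParams:
    """Hydrogen/oxygen parameter set mirroring a water-cluster-like space."""
    base = chon_params(seed=seed, sigma_noise=sigma_noise)
    return replace(
        base,
        chi={1: 0.20, 8: 0.75},
        eta={1: 2.2, 8: 2.3},
        s={1: 0.45, 8: 0.80},
        r0={1: 0.35, 8: 0.65},
        e0={1: -0.5, 8: -75.1},
        element_pool=((1, 2 / 3), (8, 1 / 3)),
        m_range=(3, 9),
    )


def generate_geometry(
    params: SurrogateParams,
    seed: Optional[int] = None,
    M: Optional[int] = None,
    mol_id: str = "",
    max_tries: int = 500,
) -> Molecule:
    """Rejection-sampled random geometry in a cubic box.

    All pairwise distances are >= ``params.min_distance``; element counts
    are drawn from the configured pool proportions. Deterministic for a
    given seed.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    if M is None:
        M = int(rng.integers(params.m_range[0], params.m_range[1] + 1))
    if M < 1:
        raise ValueError("atom count must be >= 1")
    if not params.element_pool:
        raise ValueError("params.element_pool is empty")
    zs = np.array([z for z, _ in params.element_pool])
    ps = np.array([p for _, p in params.element_pool], dtype=float)
    ps = ps / ps.sum()
    Z = tuple(int(z) for z in rng.choice(zs, size=M, p=ps))
    R = np.empty((M, 3))
    for k in range(M):
        for attempt in range(max_tries):
            cand = rng.uniform(0.0, params.box_edge, size=3)
            if k == 0 or np.min(np.linalg.norm(R[:k] - cand, axis=1)) >= params.min_distance:
                R[k] = cand
                break
        else:
            raise GenerationError(
                f"could not place atom {k} with min distance "
                f"{params.min_distance} A after {max_tries} tries; "
                f"increase box_edge (currently {params.box_edge} A)"
            )
    return Molecule(Z, R, id=mol_id)


def surrogate_charges(molecule: Molecule, params: SurrogateParams) -> np.ndarray:
    """Charges from constrained electronegativity equalization.

    Minimizes sum_i (chi_i q_i + eta_i q_i^2 / 2)
    + 1/2 sum_{i != j} q_i q_j / max(r_ij, r_floor) subject to sum q = 0,
    solved exactly as the (M+1) x (M+1) KKT linear system.
    """
    M = molecule.n_atoms
    for z in set(molecule.Z):
        if z not in params.chi or z not in params.eta:
            raise ValueError(f"no chi/eta parameters for element {symbol_for(z)}")
    chi = np.array([params.chi[z] for z in molecule.Z])
    eta = np.array([params.eta[z] for z in molecule.Z])
    if M == 1:
        return np.zeros(1)
    dist = np.maximum(molecule.distance_matrix(), params.r_floor)
    J = 1.0 / dist
    np.fill_diagonal(J, 0.0)
    A = np.zeros((M + 1, M + 1))
    A[:M, :M] = J + np.diag(eta)
    A[:M, M] = 1.0
    A[M, :M] = 1.0
    b = np.concatenate([-chi, [0.0]])
    try:
        sol = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise GenerationError(f"singular electronegativity system: {exc}") from None
    q = sol[:M]
    # re-impose neutrality exactly against roundoff
    q = q - q.mean()
    return q


def diatomic_charge_closed_form(
    chi1: float, chi2: float, eta1: float, eta2: float, r12: float, r_floor: float = 0.5
) -> float:
    """Analytic q_1 for a heteronuclear diatomic (independent oracle).

    Stationarity of the constrained two-site energy with q_2 = -q_1 gives
    q_1 = (chi_2 - chi_1) / (eta_1 + eta_2 - 2 J_12), J_12 = 1/max(r, r_floor).
    """
    J = 1.0 / max(r12, r_floor)
    return (chi2 - chi1) / (eta1 + eta2 - 2.0 * J)


def surrogate_delta(molecule: Molecule, params: SurrogateParams) -> np.ndarray:
    """Pairwise delocalization indices delta_ij = s_i s_j exp(-(r-r0)/kappa),
    clipped to [0, delta_max], in canonical pair order."""
    M = molecule.n_atoms
    gi, gj = pair_index_arrays(M)
    if gi.size == 0:
        return np.zeros(0)
    dist = molecule.distance_matrix()
    r = dist[gi, gj]
    s = np.array([params.s[z] for z in molecule.Z])
    r0 = np.array(
        [params.pair_r0(molecule.Z[a], molecule.Z[b]) for a, b in zip(gi, gj)]
    )
    delta = s[gi] * s[gj] * np.exp(-(r - r0) / params.kappa)
    return np.clip(delta, 0.0, params.delta_max)


def surrogate_electron_structure(
    molecule: Molecule, params: SurrogateParams, q: Optional[np.ndarray] = None
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(N_A, lambda, delta) closed under the electron-count sum rule.

    N_A = Z_A - q_A; lambda_A = N_A - 1/2 sum_{B != A} delta_AB. A negative
    lambda is a parameterization error and raises (never silently clipped).
    """
    if q is None:
        q = surrogate_charges(molecule, params)
    Z = np.asarray(molecule.Z, dtype=float)
    N_A = Z - q
    delta = surrogate_delta(molecule, params)
    M = molecule.n_atoms
    gi, gj = pair_index_arrays(M)
    half_shared = np.zeros(M)
    np.add.at(half_shared, gi, 0.5 * delta)
    np.add.at(half_shared, gj, 0.5 * delta)
    lam = N_A - half_shared
    if np.any(lam < 0):
        k = int(np.argmin(lam))
        raise GenerationError(
            f"negative localization index {lam[k]:.4f} on atom {k} "
            f"({symbol_for(molecule.Z[k])}); retune s/r0/kappa or geometry"
        )
    return N_A, lam, delta


def surrogate_iqa(
    molecule: Molecule, params: SurrogateParams, q: Optional[np.ndarray] = None
) -> Tuple[np.ndarray, np.ndarray, float]:
    """(E_intra, E_inter, E_total) closed under additive reconstruction.

    E_inter_ij = q_i q_j / r_ij + a_ij exp(-b r_ij) with a_ij = a0 s_i s_j;
    E_intra_A = e0(Z_A) + eta_A q_A^2 / 2; total is the exact sum.
    """
    if q is None:
        q = surrogate_charges(molecule, params)
    M = molecule.n_atoms
    gi, gj = pair_index_arrays(M)
    e0 = np.array([params.e0[z] for z in molecule.Z])
    eta = np.array([params.eta[z] for z in molecule.Z])
    E_intra = e0 + 0.5 * eta * q * q
    if gi.size:
        dist = molecule.distance_matrix()
        r = dist[gi, gj]
        if np.any(r < params.r_floor):
            raise GenerationError(
                f"interatomic distance below r_floor={params.r_floor} A"
            )
        s = np.array([params.s[z] for z in molecule.Z])
        a_ij = params.pair_repulsion_a0 * s[gi] * s[gj]
        E_inter = q[gi] * q[gj] / r + a_ij * np.exp(-params.pair_repulsion_b * r)
    else:
        E_inter = np.zeros(0)
    E_total = float(E_intra.sum() + E_inter.sum())
    return E_intra, E_inter, E_total


def label_molecule(
    molecule: Molecule,
    params: SurrogateParams,
    rng: Optional[np.random.Generator] = None,
) -> LocalPropertyRecord:
    """Full surrogate labeling of one molecule.

    Noise (if configured) is added to the local labels after the exact
    totals are stored, so the sum-rule residual of noisy labels is known.
    """
    q = surrogate_charges(molecule, params)
    N_A, lam, delta = surrogate_electron_structure(molecule, params, q=q)
    E_intra, E_inter, E_total = surrogate_iqa(molecule, params, q=q)
    M = molecule.n_atoms
    props_1p = {
        "q": q.copy(),
        "N": N_A.copy(),
        "lambda": lam.copy(),
        "E_intra": E_intra.copy(),
        "E_total": np.full(M, E_total),
    }
    props_2p = {"delta": delta.copy(), "E_inter": E_inter.copy()}
    if params.sigma_noise > 0:
        if rng is None:
            rng = np.random.default_rng(params.seed)
        for key in ("q", "lambda"):
            props_1p[key] = props_1p[key] + rng.normal(0, params.sigma_noise, M)
        props_1p["E_intra"] = props_1p["E_intra"] + rng.normal(0, params.sigma_noise, M)
        for key in ("delta", "E_inter"):
            props_2p[key] = props_2p[key] + rng.normal(
                0, params.sigma_noise, n_pairs(M)
            )
    units = {
        "q": "e", "N": "e", "lambda": "e", "delta": "e",
        "E_intra": "au", "E_inter": "au", "E_total": "au",
    }
    return LocalPropertyRecord(
        molecule=molecule, props_1p=props_1p, props_2p=props_2p, units=units
    )


def generate_dataset(
    n_molecules: int, params: SurrogateParams, seed: Optional[int] = None
) -> Tuple[List[LocalPropertyRecord], Dict]:
    """n fully labeled records plus a manifest of the generation settings."""
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    base_seed = params.seed if seed is None else seed
    ss = np.random.SeedSequence(base_seed)
    children = ss.spawn(n_molecules)
    records: List[LocalPropertyRecord] = []
    for idx, child in enumerate(children):
        rng = np.random.default_rng(child)
        geom_seed = int(rng.integers(0, 2**31 - 1))
        try:
            mol = generate_geometry(params, seed=geom_seed, mol_id=f"surrogate-{idx}")
            records.append(label_molecule(mol, params, rng=rng))
        except GenerationError as exc:
            raise GenerationError(f"record {idx}: {exc}") from exc
    manifest = {
        "n_molecules": n_molecules,
        "seed": base_seed,
        "element_pool": list(params.element_pool),
        "m_range": list(params.m_range),
        "box_edge": params.box_edge,
        "min_distance": params.min_distance,
        "sigma_noise": params.sigma_noise,
    }
    return records, manifest


# ---------------------------------------------------------------------------
# Scripted binding trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BindingEvent:
    """One scheduled guest-host contact.

    ``kind`` is "approach" (translation toward the group and back; both the
    electronic and the geometric metric should fire) or "rotate" (orientation
    swing at exactly constant center-of-mass distance; only the electronic
    metric should fire). Frames index the trajectory; the scheduled
    ``contact`` frame is the ground-truth event position.
    """

    kind: str
    group: str
    start: int
    contact: int
    end: int

    def __post_init__(self) -> None:
        if self.kind not in ("approach", "rotate"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if not self.start < self.contact < self.end:
            raise ValueError("event frames must satisfy start < contact < end")


DEFAULT_HOST: Dict[str, List[Tuple[int, Tuple[float, float, float]]]] = {
    # amine-like group at the origin
    "A": [(7, (0.0, 0.0, 0.0)), (1, (0.55, 0.85, 0.0)), (1, (-0.55, 0.85, 0.0))],
    # hydroxyl-like group off to the side
    "B": [(8, (9.0, 0.0, 0.0)), (1, (9.55, 0.8, 0.0))],
}

# linear O=C=O-like rigid guest: (Z, offset along the guest axis)
DEFAULT_GUEST: Tuple[Tuple[int, float], ...] = ((8, -1.16), (6, 0.0), (8, 1.16))

# guest rest position: on the station sphere around group B so that rotate
# events keep |R|(guest, B) exactly constant
DEFAULT_BASE = np.array([6.4, 2.0, 0.0])
APPROACH_DISTANCE = 2.5  # angstrom from the target group's anchor atom


def generate_binding_trajectory(
    n_frames: int,
    events: Sequence[BindingEvent],
    host: Optional[Dict[str, List[Tuple[int, Tuple[float, float, float]]]]] = None,
    guest: Sequence[Tuple[int, float]] = DEFAULT_GUEST,
    base_position: Optional[np.ndarray] = None,
    dt_fs: float = 1.0,
    min_clearance: float = 0.9,
) -> Tuple[List[Molecule], Dict[str, List[int]], List[Dict]]:
    """Rigid-guest scripted trajectory.

    Returns (frames, groups, truth) where ``groups`` maps group names
    (host groups plus "guest") to atom index lists in every frame, and
    ``truth`` is the ground-truth event table: one entry per scheduled
    event with its contact frame and the expected detection class.
    """
    host = DEFAULT_HOST if host is None else host
    base = DEFAULT_BASE if base_position is None else np.asarray(base_position, float)
    spans = sorted((e.start, e.end, e) for e in events)
    for (s1, e1, _), (s2, e2, _) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError("event windows must not overlap")
    group_names = list(host)
    host_Z: List[int] = []
    host_R: List[Tuple[float, float, float]] = []
    groups: Dict[str, List[int]] = {}
    for name in group_names:
        groups[name] = []
        for z, pos in host[name]:
            groups[name].append(len(host_Z))
            host_Z.append(z)
            host_R.append(pos)
    guest_idx = list(range(len(host_Z), len(host_Z) + len(guest)))
    groups["guest"] = guest_idx
    host_R_arr = np.asarray(host_R, dtype=float)
    anchors = {name: host_R_arr[groups[name][0]] for name in group_names}

    frames: List[Molecule] = []
    truth: List[Dict] = []
    for ev in events:
        if ev.group not in anchors:
            raise ValueError(f"event references unknown group {ev.group!r}")
        if not 0 <= ev.start and ev.end < n_frames:
            raise ValueError("event window outside trajectory")
        truth.append(
            {
                "kind": ev.kind,
                "group": ev.group,
                "frame": ev.contact,
                "time_fs": ev.contact * dt_fs,
                "expected": "both" if ev.kind == "approach" else "electronic-only",
            }
        )

    perp_axis = np.array([0.0, 0.0, 1.0])
    for f in range(n_frames):
        com = base.copy()
        axis = perp_axis
        for ev in events:
            if not ev.start <= f <= ev.end:
                continue
            if f <= ev.contact:
                frac = (f - ev.start) / max(ev.contact - ev.start, 1)
            else:
                frac = (ev.end - f) / max(ev.end - ev.contact, 1)
            if ev.kind == "approach":
                anchor = anchors[ev.group]
                away = base - anchor
                target = anchor + away / np.linalg.norm(away) * APPROACH_DISTANCE
                com = base + frac * (target - base)
            else:  # rotate: COM fixed, axis swings toward the group anchor
                toward = anchors[ev.group] - base
                toward = toward / np.linalg.norm(toward)
                angle = frac * (np.pi / 2.0)
                axis = np.cos(angle) * perp_axis + np.sin(angle) * toward
        Z = tuple(host_Z) + tuple(z for z, _ in guest)
        R = np.vstack([host_R_arr, np.array([com + off * axis for _, off in guest])])
        mol = Molecule(Z, R, id=f"t={f * dt_fs:.1f}fs")
        dmat = mol.distance_matrix()
        np.fill_diagonal(dmat, np.inf)
        if dmat.min() < min_clearance:
            raise GenerationError(
                f"frame {f}: atoms closer than {min_clearance} A "
                f"(min {dmat.min():.3f} A); adjust the schedule"
            )
        frames.append(mol)
    return frames, groups, truth
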