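"""Per-atom environment vectors from (Z, R) via embedding plus
continuous-filter interaction blocks.

The map is: learned element embedding, then ``n_interactions`` residual
updates ``x_i <- x_i + W_out(sum_{j!=i} W_in(x_j) * F(r_ij))`` where the
filter ``F`` is a two-layer feed-forward map of a Gaussian distance
expansion multiplied by a cosine cutoff. The output depends on geometry
only through interatomic distances, so it is invariant under rigid
isometries and equivariant under atom relabeling.

Gradients are hand-written reverse mode (see :func:`backward`); parameters
live in a flat ``{name: ndarray}`` dictionary under a configurable prefix so
the representation and readout heads can share one optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._nn import Params, init_dense, ssp, ssp_grad
from .chemsys import Molecule, symbol_for

__all__ = [
    "RepresentationConfig",
    "AtomEnvironments",
    "MoleculeEncoding",
    "gaussian_expansion",
    "cosine_cutoff",
    "init_representation",
    "encode_molecule",
    "forward",
    "backward",
    "compute_environments",
]


@dataclass(frozen=True)
class RepresentationConfig:
    """Hyperparameters of the representation block.

    Defaults are sized for desk-scale CPU training; keep the feature width
    moderate to avoid excessively large pair descriptors downstream.
    """

    n: int = 64
    n_interactions: int = 3
    r_cut: float = 5.0
    n_rbf: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"feature width n must be >= 1, got {self.n}")
        if self.n_interactions < 0:
            raise ValueError("n_interactions must be >= 0")
        if self.r_cut <= 0:
            raise ValueError(f"r_cut must be positive, got {self.r_cut}")
        if self.n_rbf < 2:
            raise ValueError(f"n_rbf must be >= 2, got {self.n_rbf}")

    def to_dict(self) -> Dict:
        return {
            "n": self.n,
            "n_interactions": self.n_interactions,
            "r_cut": self.r_cut,
            "n_rbf": self.n_rbf,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Dict) -> "RepresentationConfig":
        return cls(
            n=int(d["n"]),
            n_interactions=int(d["n_interactions"]),
            r_cut=float(d["r_cut"]),
            n_rbf=int(d["n_rbf"]),
            seed=int(d.get("seed", 0)),
        )


@dataclass(frozen=True)
class AtomEnvironments:
    """M x n matrix of per-atom environment vectors."""

    values: np.ndarray
    config: RepresentationConfig

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape[1] != self.config.n:
            raise ValueError(f"environment matrix must be M x {self.config.n}")
        if not np.all(np.isfinite(vals)):
            raise ValueError("environment matrix contains non-finite entries")
        object.__setattr__(self, "values", vals)


def gaussian_expansion(d, config: RepresentationConfig) -> np.ndarray:
    """Expand distances on ``n_rbf`` Gaussians equally spaced on [0, r_cut].

    Component k is exp(-gamma (d - mu_k)^2) with gamma = 1/(2 dmu^2).
    Accepts a scalar or an array of distances; returns shape (..., n_rbf).
    """
    d = np.asarray(d, dtype=float)
    centers = np.linspace(0.0, config.r_cut, config.n_rbf)
    dmu = centers[1] - centers[0]
    gamma = 1.0 / (2.0 * dmu * dmu)
    diff = d[..., None] - centers
    return np.exp(-gamma * diff * diff)


def cosine_cutoff(d, r_cut: float) -> np.ndarray:
    """0.5 (cos(pi d / r_cut) + 1) below r_cut, exactly 0 at and beyond."""
    if r_cut <= 0:
        raise ValueError(f"r_cut must be positive, got {r_cut}")
    d = np.asarray(d, dtype=float)
    out = 0.5 * (np.cos(np.pi * d / r_cut) + 1.0)
    return np.where(d < r_cut, out, 0.0)


def init_representation(
    config: RepresentationConfig,
    elements: Sequence[int],
    params: Optional[Params] = None,
    prefix: str = "rep",
) -> Tuple[Params, Dict[int, int]]:
    """Seeded parameter initialization.

    Returns the (possibly shared) parameter dictionary and the mapping from
    atomic number to embedding row. Only listed elements are representable.
    """
    if params is None:
        params = {}
    elements = sorted({int(z) for z in elements})
    if not elements:
        raise ValueError("element coverage must be non-empty")
    z_to_row = {z: k for k, z in enumerate(elements)}
    rng = np.random.default_rng(config.seed)
    n = config.n
    params[f"{prefix}.embed"] = rng.normal(0.0, 0.5, size=(len(elements), n))
    for t in range(config.n_interactions):
        for name, shape in (
            ("in", (n, n)),
            ("f1", (config.n_rbf, n)),
            ("f2", (n, n)),
            ("o1", (n, n)),
            ("o2", (n, n)),
        ):
            W, b = init_dense(rng, *shape)
            params[f"{prefix}.int{t}.{name}.W"] = W
            params[f"{prefix}.int{t}.{name}.b"] = b
    return params, z_to_row


@dataclass
class MoleculeEncoding:
    """Geometry-derived, parameter-free inputs to the network.

    ``pi``/``pj`` list ordered within-cutoff neighbor pairs (message j -> i);
    ``rbf`` and ``fc`` are the expanded distances and cutoff values for those
    pairs. Encodings of several molecules can be concatenated with shifted
    atom indices to form a packed batch.
    """

    n_atoms: int
    z_rows: np.ndarray
    pi: np.ndarray
    pj: np.ndarray
    rbf: np.ndarray
    fc: np.ndarray


def encode_molecule(
    molecule: Molecule, z_to_row: Dict[int, int], config: RepresentationConfig
) -> MoleculeEncoding:
    M = molecule.n_atoms
    try:
        z_rows = np.array([z_to_row[z] for z in molecule.Z], dtype=np.intp)
    except KeyError as exc:
        z = exc.args[0]
        raise ValueError(
            f"element {symbol_for(z)} (Z={z}) was not seen at model construction"
        ) from None
    if M == 1:
        pi = pj = np.empty(0, dtype=np.intp)
        d = np.empty(0)
    else:
        dist = molecule.distance_matrix()
        mask = (dist < config.r_cut) & ~np.eye(M, dtype=bool)
        pi, pj = np.nonzero(mask)
        d = dist[pi, pj]
        # canonical aggregation order (receiver, distance, neighbor element):
        # makes the neighbor sum independent of atom labeling, so relabeling
        # permutes environments bit-exactly despite float non-associativity
        order = np.lexsort((z_rows[pj], d, pi))
        pi, pj, d = pi[order], pj[order], d[order]
    return MoleculeEncoding(
        n_atoms=M,
        z_rows=z_rows,
        pi=pi.astype(np.intp),
        pj=pj.astype(np.intp),
        rbf=gaussian_expansion(d, config),
        fc=cosine_cutoff(d, config.r_cut),
    )


def pack_encodings(encodings: Sequence[MoleculeEncoding]) -> Tuple[MoleculeEncoding, np.ndarray]:
    """Concatenate molecule encodings into one batch; returns atom offsets."""
    offsets = np.zeros(len(encodings) + 1, dtype=np.intp)
    for k, enc in enumerate(encodings):
        offsets[k + 1] = offsets[k] + enc.n_atoms
    packed = MoleculeEncoding(
        n_atoms=int(offsets[-1]),
        z_rows=np.concatenate([e.z_rows for e in encodings]),
        pi=np.concatenate([e.pi + offsets[k] for k, e in enumerate(encodings)]),
        pj=np.concatenate([e.pj + offsets[k] for k, e in enumerate(encodings)]),
        rbf=np.concatenate([e.rbf for e in encodings], axis=0),
        fc=np.concatenate([e.fc for e in encodings]),
    )
    return packed, offsets


def forward(
    params: Params, enc: MoleculeEncoding, config: RepresentationConfig, prefix: str = "rep"
) -> Tuple[np.ndarray, list]:
    """Environment matrix for a (packed) encoding plus the backward cache."""
    x = params[f"{prefix}.embed"][enc.z_rows]
    cache = []
    for t in range(config.n_interactions):
        p = f"{prefix}.int{t}"
        h = x @ params[f"{p}.in.W"] + params[f"{p}.in.b"]
        g1 = enc.rbf @ params[f"{p}.f1.W"] + params[f"{p}.f1.b"]
        a1 = ssp(g1)
        f = (a1 @ params[f"{p}.f2.W"] + params[f"{p}.f2.b"]) * enc.fc[:, None]
        m = np.zeros_like(x)
        np.add.at(m, enc.pi, h[enc.pj] * f)
        u1h = m @ params[f"{p}.o1.W"] + params[f"{p}.o1.b"]
        u1 = ssp(u1h)
        u = u1 @ params[f"{p}.o2.W"] + params[f"{p}.o2.b"]
        cache.append((x, h, g1, a1, f, m, u1h, u1))
        x = x + u
    return x, cache


def backward(
    params: Params,
    enc: MoleculeEncoding,
    config: RepresentationConfig,
    cache: list,
    dx: np.ndarray,
    grads: Params,
    prefix: str = "rep",
) -> None:
    """Accumulate parameter gradients given d(loss)/d(environments)."""
    dx = dx.copy()
    for t in range(config.n_interactions - 1, -1, -1):
        p = f"{prefix}.int{t}"
        x, h, g1, a1, f, m, u1h, u1 = cache[t]
        du = dx  # residual: gradient flows to both the update and the input
        grads[f"{p}.o2.W"] = grads.get(f"{p}.o2.W", 0.0) + u1.T @ du
        grads[f"{p}.o2.b"] = grads.get(f"{p}.o2.b", 0.0) + du.sum(axis=0)
        du1h = (du @ params[f"{p}.o2.W"].T) * ssp_grad(u1h)
        grads[f"{p}.o1.W"] = grads.get(f"{p}.o1.W", 0.0) + m.T @ du1h
        grads[f"{p}.o1.b"] = grads.get(f"{p}.o1.b", 0.0) + du1h.sum(axis=0)
        dm = du1h @ params[f"{p}.o1.W"].T
        dcontrib = dm[enc.pi]
        df = dcontrib * h[enc.pj]
        dh = np.zeros_like(h)
        np.add.at(dh, enc.pj, dcontrib * f)
        df_lin = df * enc.fc[:, None]
        grads[f"{p}.f2.W"] = grads.get(f"{p}.f2.W", 0.0) + a1.T @ df_lin
        grads[f"{p}.f2.b"] = grads.get(f"{p}.f2.b", 0.0) + df_lin.sum(axis=0)
        dg1 = (df_lin @ params[f"{p}.f2.W"].T) * ssp_grad(g1)
        grads[f"{p}.f1.W"] = grads.get(f"{p}.f1.W", 0.0) + enc.rbf.T @ dg1
        grads[f"{p}.f1.b"] = grads.get(f"{p}.f1.b", 0.0) + dg1.sum(axis=0)
        grads[f"{p}.in.W"] = grads.get(f"{p}.in.W", 0.0) + x.T @ dh
        grads[f"{p}.in.b"] = grads.get(f"{p}.in.b", 0.0) + dh.sum(axis=0)
        dx = dx + dh @ params[f"{p}.in.W"].T
    key = f"{prefix}.embed"
    dembed = np.zeros_like(params[key])
    np.add.at(dembed, enc.z_rows, dx)
    grads[key] = grads.get(key, 0.0) + dembed


def compute_environments(
    molecule: Molecule,
    params: Params,
    z_to_row: Dict[int, int],
    config: RepresentationConfig,
    prefix: str = "rep",
) -> AtomEnvironments:
    """Environment vectors for one molecule (inference convenience)."""
    enc = encode_molecule(molecule, z_to_row, config)
    x, _ = forward(params, enc, config, prefix=prefix)
    return AtomEnvironments(values=x, config=config)
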