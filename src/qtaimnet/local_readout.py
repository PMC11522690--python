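"""Per-atom (1P) and per-pair (2P) property heads on top of the
environment vectors, with no cumulative pooling.

Four modes are supported:

- ``AIMwise-1P`` / ``AIMwise-2P``: one universal head for every atom / pair;
- ``ElementalAIMwise``: one head per element (1P);
- ``ElementalPairAIMwise``: one head per unordered element pair (2P), routed
  by the symmetric injective :func:`pair_type_id` encoding.

2P heads consume the concatenation ``[AE_i | AE_j | r_ij]`` (length 2n+1)
and are always evaluated on both concatenation orders and averaged, which
makes pair predictions exactly invariant under i <-> j regardless of the
head weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._nn import Params, init_mlp, mlp_backward, mlp_forward
from .chemsys import Molecule, n_pairs, pair_index_arrays, symbol_for
from . import representation as rep
from .representation import MoleculeEncoding, RepresentationConfig

__all__ = [
    "MODES",
    "ReadoutConfig",
    "LocalModel",
    "build_pair_descriptor",
    "pair_type_id",
    "count_heads",
    "build_model",
    "predict_1p",
    "predict_2p",
    "save_model",
    "load_model",
]

MODES = ("AIMwise-1P", "AIMwise-2P", "ElementalAIMwise", "ElementalPairAIMwise")
MODES_1P = ("AIMwise-1P", "ElementalAIMwise")
MODES_2P = ("AIMwise-2P", "ElementalPairAIMwise")

CHECKPOINT_FORMAT = "qtaimnet-model/1"


@dataclass(frozen=True)
class ReadoutConfig:
    mode: str
    hidden_sizes: Tuple[int, ...] = (32, 16)
    elements: Tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown readout mode {self.mode!r}; expected one of {MODES}")
        object.__setattr__(self, "hidden_sizes", tuple(int(h) for h in self.hidden_sizes))
        object.__setattr__(self, "elements", tuple(sorted({int(z) for z in self.elements})))
        if any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be >= 1")
        if not self.elements:
            raise ValueError("element coverage must be non-empty")
        if any(z < 1 for z in self.elements):
            raise ValueError("atomic numbers must be >= 1")

    @property
    def is_2p(self) -> bool:
        return self.mode in MODES_2P

    def to_dict(self) -> Dict:
        return {
            "mode": self.mode,
            "hidden_sizes": list(self.hidden_sizes),
            "elements": list(self.elements),
        }

    @classmethod
    def from_dict(cls, d: Dict) -> "ReadoutConfig":
        return cls(
            mode=str(d["mode"]),
            hidden_sizes=tuple(d["hidden_sizes"]),
            elements=tuple(d["elements"]),
        )


def build_pair_descriptor(AE_i: np.ndarray, AE_j: np.ndarray, r_ij: float) -> np.ndarray:
    """Concatenate [AE_i | AE_j | r_ij]; length 2n+1."""
    AE_i = np.asarray(AE_i, dtype=float).ravel()
    AE_j = np.asarray(AE_j, dtype=float).ravel()
    if AE_i.shape != AE_j.shape:
        raise ValueError(
            f"environment vectors differ in length: {AE_i.size} vs {AE_j.size}"
        )
    if r_ij <= 0:
        raise ValueError(f"pair distance must be positive, got {r_ij}")
    return np.concatenate([AE_i, AE_j, [float(r_ij)]])


def pair_type_id(Z_i: int, Z_j: int) -> int:
    """Symmetric injective integer id of the unordered element pair.

    With a = min(Z_i, Z_j) and b = max(Z_i, Z_j): id = b(b-1)/2 + a.
    """
    Z_i, Z_j = int(Z_i), int(Z_j)
    if Z_i < 1 or Z_j < 1:
        raise ValueError(f"atomic numbers must be >= 1, got ({Z_i}, {Z_j})")
    a, b = (Z_i, Z_j) if Z_i <= Z_j else (Z_j, Z_i)
    return b * (b - 1) // 2 + a


def count_heads(mode: str, elements: Sequence[int]) -> int:
    """Number of heads K: 1, T, or T(T+1)/2."""
    if mode not in MODES:
        raise ValueError(f"unknown readout mode {mode!r}")
    if mode in ("AIMwise-1P", "AIMwise-2P"):
        return 1
    elements = {int(z) for z in elements}
    if not elements:
        raise ValueError(f"mode {mode!r} requires a non-empty element set")
    T = len(elements)
    return T if mode == "ElementalAIMwise" else T * (T + 1) // 2


def _head_ids(config: ReadoutConfig) -> List[str]:
    if config.mode in ("AIMwise-1P", "AIMwise-2P"):
        return ["shared"]
    if config.mode == "ElementalAIMwise":
        return [f"Z{z}" for z in config.elements]
    ids = sorted(
        {pair_type_id(a, b) for a in config.elements for b in config.elements}
    )
    return [f"P{t}" for t in ids]


@dataclass
class LocalModel:
    """Trained (or freshly initialized) representation + readout."""

    rep_config: RepresentationConfig
    readout_config: ReadoutConfig
    property_name: str
    unit: str
    params: Params
    z_to_row: Dict[int, int]

    @property
    def is_2p(self) -> bool:
        return self.readout_config.is_2p

    @property
    def elements(self) -> Tuple[int, ...]:
        return self.readout_config.elements

    def head_ids(self) -> List[str]:
        return _head_ids(self.readout_config)

    def atom_head_id(self, Z: int) -> str:
        if self.readout_config.mode == "AIMwise-1P":
            return "shared"
        if self.readout_config.mode == "ElementalAIMwise":
            if Z not in self.elements:
                raise ValueError(f"element {symbol_for(Z)} (Z={Z}) not covered by model")
            return f"Z{Z}"
        raise ValueError(f"1P routing requested on a 2P model ({self.readout_config.mode})")

    def pair_head_id(self, Z_i: int, Z_j: int) -> str:
        if self.readout_config.mode == "AIMwise-2P":
            return "shared"
        if self.readout_config.mode == "ElementalPairAIMwise":
            if Z_i not in self.elements or Z_j not in self.elements:
                raise ValueError(
                    f"pair ({symbol_for(Z_i)}, {symbol_for(Z_j)}) not covered by model"
                )
            return f"P{pair_type_id(Z_i, Z_j)}"
        raise ValueError(f"2P routing requested on a 1P model ({self.readout_config.mode})")


def build_model(
    rep_config: RepresentationConfig,
    readout_config: ReadoutConfig,
    property_name: str,
    unit: str = "",
) -> LocalModel:
    """Seeded construction of all parameters (representation + heads)."""
    params: Params = {}
    params, z_to_row = rep.init_representation(rep_config, readout_config.elements, params)
    d_in = 2 * rep_config.n + 1 if readout_config.is_2p else rep_config.n
    sizes = [d_in, *readout_config.hidden_sizes, 1]
    rng = np.random.default_rng([rep_config.seed, 0x6EAD])
    for hid in _head_ids(readout_config):
        init_mlp(rng, sizes, params, f"head.{hid}")
    return LocalModel(
        rep_config=rep_config,
        readout_config=readout_config,
        property_name=property_name,
        unit=unit,
        params=params,
        z_to_row=dict(z_to_row),
    )


# ---------------------------------------------------------------------------
# Batched forward / backward over packed encodings (used for both inference
# and training; caches are returned so gradients can be pushed back).
# ---------------------------------------------------------------------------

def _unify_duplicate_rows(inputs: np.ndarray, out: np.ndarray) -> np.ndarray:
    """Give bitwise-identical (pre-sorted, hence adjacent) input rows the
    same output.

    BLAS may round the same row differently depending on its position in the
    batch; symmetry-equivalent particles must nevertheless score identically.
    """
    if out.shape[0] < 2:
        return out
    dup = np.all(inputs[1:] == inputs[:-1], axis=1)
    if not dup.any():
        return out
    first = np.concatenate([[True], ~dup])
    rep = np.maximum.accumulate(np.where(first, np.arange(out.shape[0]), 0))
    return out[rep]

def forward_1p(
    model: LocalModel, enc: MoleculeEncoding, Z_flat: np.ndarray
) -> Tuple[np.ndarray, dict]:
    """Per-atom predictions for a packed batch; returns values + cache."""
    if model.is_2p:
        raise ValueError(
            f"1P prediction requested on a 2P model ({model.readout_config.mode})"
        )
    x, rep_cache = rep.forward(model.params, enc, model.rep_config)
    y = np.zeros(enc.n_atoms)
    head_caches = {}
    for hid in model.head_ids():
        if hid == "shared":
            idx = np.arange(enc.n_atoms)
        else:
            z = int(hid[1:])
            idx = np.nonzero(Z_flat == z)[0]
        if idx.size == 0:
            continue
        # canonical row order (by feature content, which is label-invariant)
        # so BLAS sees an identical batch matrix under atom relabeling and
        # predictions are exactly permutation-consistent
        idx = idx[np.lexsort(x[idx].T)]
        out, cache = mlp_forward(model.params, f"head.{hid}", x[idx])
        out = _unify_duplicate_rows(x[idx], out)
        y[idx] = out[:, 0]
        head_caches[hid] = (idx, cache)
    for z in np.unique(Z_flat):
        model.atom_head_id(int(z))  # raises on uncovered elements
    return y, {"x": x, "rep_cache": rep_cache, "heads": head_caches, "enc": enc}


def backward_1p(model: LocalModel, cache: dict, dy: np.ndarray, grads: Params) -> None:
    x = cache["x"]
    dx = np.zeros_like(x)
    for hid, (idx, mlp_cache) in cache["heads"].items():
        d_in = mlp_backward(model.params, f"head.{hid}", mlp_cache, dy[idx, None], grads)
        dx[idx] += d_in
    rep.backward(model.params, cache["enc"], model.rep_config, cache["rep_cache"], dx, grads)


def forward_2p(
    model: LocalModel,
    enc: MoleculeEncoding,
    Z_flat: np.ndarray,
    gi: np.ndarray,
    gj: np.ndarray,
    r: np.ndarray,
) -> Tuple[np.ndarray, dict]:
    """Pair predictions for labeled pairs (global indices gi < gj).

    Each head is evaluated on both concatenation orders and averaged, so the
    output is exactly symmetric in (i, j).
    """
    if not model.is_2p:
        raise ValueError(
            f"2P prediction requested on a 1P model ({model.readout_config.mode})"
        )
    x, rep_cache = rep.forward(model.params, enc, model.rep_config)
    n = model.rep_config.n
    # orient each pair by lexicographic comparison of its environment rows:
    # the (i, j) storage order depends on atom labels, this does not, so the
    # evaluated batches are identical under relabeling
    xi, xj = x[gi], x[gj]
    neq = xi != xj
    anydiff = neq.any(axis=1)
    first = np.where(anydiff, neq.argmax(axis=1), 0)
    rows = np.arange(len(gi))
    swap = anydiff & (xi[rows, first] > xj[rows, first])
    ga = np.where(swap, gj, gi)
    gb = np.where(swap, gi, gj)
    desc_a = np.concatenate([x[ga], x[gb], r[:, None]], axis=1)
    desc_b = np.concatenate([x[gb], x[ga], r[:, None]], axis=1)
    tids = np.array(
        [pair_type_id(int(Z_flat[a]), int(Z_flat[b])) for a, b in zip(gi, gj)],
        dtype=np.intp,
    ) if model.readout_config.mode == "ElementalPairAIMwise" else None
    y = np.zeros(len(gi))
    head_caches = {}
    for hid in model.head_ids():
        if hid == "shared":
            idx = np.arange(len(gi))
        else:
            idx = np.nonzero(tids == int(hid[1:]))[0]
        if idx.size == 0:
            continue
        # canonical row order by descriptor content (see forward_1p)
        idx = idx[np.lexsort(desc_a[idx].T)]
        out_a, cache_a = mlp_forward(model.params, f"head.{hid}", desc_a[idx])
        out_b, cache_b = mlp_forward(model.params, f"head.{hid}", desc_b[idx])
        out_a = _unify_duplicate_rows(desc_a[idx], out_a)
        out_b = _unify_duplicate_rows(desc_a[idx], out_b)
        y[idx] = 0.5 * (out_a[:, 0] + out_b[:, 0])
        head_caches[hid] = (idx, cache_a, cache_b)
    if model.readout_config.mode == "ElementalPairAIMwise":
        covered = {pair_type_id(a, b) for a in model.elements for b in model.elements}
        for a, b in zip(gi, gj):
            t = pair_type_id(int(Z_flat[a]), int(Z_flat[b]))
            if t not in covered:
                raise ValueError(
                    f"pair type ({symbol_for(int(Z_flat[a]))}, "
                    f"{symbol_for(int(Z_flat[b]))}) not covered by model"
                )
    cache = {
        "x": x, "rep_cache": rep_cache, "heads": head_caches,
        "enc": enc, "gi": ga, "gj": gb, "n": n,
    }
    return y, cache


def backward_2p(model: LocalModel, cache: dict, dy: np.ndarray, grads: Params) -> None:
    x = cache["x"]
    n = cache["n"]
    gi, gj = cache["gi"], cache["gj"]
    dx = np.zeros_like(x)
    for hid, (idx, cache_a, cache_b) in cache["heads"].items():
        half = 0.5 * dy[idx, None]
        d_a = mlp_backward(model.params, f"head.{hid}", cache_a, half, grads)
        d_b = mlp_backward(model.params, f"head.{hid}", cache_b, half, grads)
        np.add.at(dx, gi[idx], d_a[:, :n] + d_b[:, n : 2 * n])
        np.add.at(dx, gj[idx], d_a[:, n : 2 * n] + d_b[:, :n])
    rep.backward(model.params, cache["enc"], model.rep_config, cache["rep_cache"], dx, grads)


# ---------------------------------------------------------------------------
# Single-molecule inference
# ---------------------------------------------------------------------------

def predict_1p(molecule: Molecule, model: LocalModel) -> np.ndarray:
    """Per-atom property vector (length M); no pooling."""
    enc = rep.encode_molecule(molecule, model.z_to_row, model.rep_config)
    y, _ = forward_1p(model, enc, np.asarray(molecule.Z))
    return y


def predict_2p(molecule: Molecule, model: LocalModel) -> np.ndarray:
    """Per-pair property vector in canonical pair order (length M(M-1)/2)."""
    enc = rep.encode_molecule(molecule, model.z_to_row, model.rep_config)
    M = molecule.n_atoms
    gi, gj = pair_index_arrays(M)
    if gi.size == 0:
        return np.zeros(0)
    dist = molecule.distance_matrix()
    r = dist[gi, gj]
    y, _ = forward_2p(model, enc, np.asarray(molecule.Z), gi, gj, r)
    return y


# ---------------------------------------------------------------------------
# Checkpoint I/O (JSON, versioned)
# ---------------------------------------------------------------------------

def save_model(model: LocalModel, path) -> None:
    obj = {
        "format": CHECKPOINT_FORMAT,
        "rep_config": model.rep_config.to_dict(),
        "readout_config": model.readout_config.to_dict(),
        "property": model.property_name,
        "unit": model.unit,
        "z_to_row": {str(k): int(v) for k, v in model.z_to_row.items()},
        "params": {k: v.tolist() for k, v in model.params.items()},
    }
    with open(path, "w") as fh:
        json.dump(obj, fh)


def load_model(path) -> LocalModel:
    with open(path) as fh:
        obj = json.load(fh)
    fmt = obj.get("format")
    if fmt != CHECKPOINT_FORMAT:
        raise ValueError(
            f"checkpoint format {fmt!r} not supported (expected {CHECKPOINT_FORMAT!r})"
        )
    return LocalModel(
        rep_config=RepresentationConfig.from_dict(obj["rep_config"]),
        readout_config=ReadoutConfig.from_dict(obj["readout_config"]),
        property_name=obj["property"],
        unit=obj["unit"],
        params={k: np.asarray(v, dtype=float) for k, v in obj["params"].items()},
        z_to_row={int(k): int(v) for k, v in obj["z_to_row"].items()},
    )
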