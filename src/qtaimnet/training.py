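"""Model fitting with a composite local + global (sum-rule) loss, and
evaluation metrics.

The local term is the mean squared per-particle error; the optional global
term penalizes the squared error of the reconstructed molecular quantity
(total charge for charge models, electron count for joint lambda/delta
labels, total energy for energy labels). ``w_global = 0`` reduces exactly
to the plain local loss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._nn import Adam, Params
from .chemsys import LocalPropertyRecord, pair_index_arrays, symbol_for
from .local_readout import (
    LocalModel,
    ReadoutConfig,
    build_model,
    backward_1p,
    backward_2p,
    forward_1p,
    forward_2p,
    pair_type_id,
)
from .qct_properties import reconstruct_N
from .representation import (
    MoleculeEncoding,
    RepresentationConfig,
    encode_molecule,
    pack_encodings,
)

__all__ = [
    "TrainConfig",
    "EvalReport",
    "split_dataset",
    "composite_loss",
    "train",
    "evaluate",
    "predictions_for_records",
]

GLOBAL_KINDS = ("charge", "electron_count", "energy", "none")


@dataclass(frozen=True)
class TrainConfig:
    property_name: str = "q"
    mode: str = "ElementalAIMwise"
    w_local: float = 1.0
    w_global: float = 0.2
    global_kind: str = "charge"
    batch_size: int = 32
    learning_rate: float = 2e-3
    epochs: int = 60
    patience: int = 15
    splits: Tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.w_local <= 1 and 0 <= self.w_global <= 1):
            raise ValueError("loss weights must lie in [0, 1]")
        if self.w_local + self.w_global <= 0:
            raise ValueError("w_local + w_global must be positive")
        if self.global_kind not in GLOBAL_KINDS:
            raise ValueError(f"unknown global loss kind {self.global_kind!r}")
        if self.w_global > 0 and self.global_kind == "none":
            raise ValueError("w_global > 0 requires a global loss kind")
        if any(f <= 0 for f in self.splits):
            raise ValueError("split fractions must be positive")
        if abs(sum(self.splits) - 1.0) > 1e-8:
            raise ValueError(f"split fractions must sum to 1, got {self.splits}")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")


def split_dataset(
    records: Sequence, fractions: Tuple[float, float, float], seed: int
) -> Tuple[list, list, list]:
    """Seeded, disjoint, exhaustive molecule-level split."""
    n = len(records)
    if n < 3:
        raise ValueError("need at least 3 records to split")
    if any(f <= 0 for f in fractions):
        raise ValueError("split fractions must be positive")
    if abs(sum(fractions) - 1.0) > 1e-8:
        raise ValueError(f"split fractions must sum to 1, got {fractions}")
    order = np.random.default_rng(seed).permutation(n)
    raw = [f * n for f in fractions]
    counts = [int(math.floor(v)) for v in raw]
    # distribute the rounding remainder by largest fractional part
    rema = sorted(range(3), key=lambda k: raw[k] - counts[k], reverse=True)
    k = 0
    while sum(counts) < n:
        counts[rema[k % 3]] += 1
        k += 1
    parts = []
    start = 0
    for c in counts:
        parts.append([records[i] for i in order[start : start + c]])
        start += c
    return tuple(parts)


def composite_loss(
    predictions: Sequence[np.ndarray],
    labels: Sequence[np.ndarray],
    Z: Sequence[Sequence[int]],
    w_local: float,
    w_global: float,
    global_kind: str = "charge",
    predictions_2p: Optional[Sequence[np.ndarray]] = None,
    total_refs: Optional[Sequence[float]] = None,
) -> float:
    """w_local * MSE(local) + w_global * MSE(molecular reconstruction).

    ``predictions``/``labels`` are per-molecule arrays. The global term is,
    per molecule: (sum q_hat)^2 for ``charge``; (N(lambda_hat, delta_hat) -
    sum Z)^2 for ``electron_count`` (pass lambda in ``predictions`` and
    delta in ``predictions_2p``); (E_hat - E_ref)^2 for ``energy`` (pass
    E_intra in ``predictions``, E_inter in ``predictions_2p`` and reference
    totals in ``total_refs``).
    """
    if global_kind not in GLOBAL_KINDS:
        raise ValueError(f"unknown global loss kind {global_kind!r}")
    se = 0.0
    n_vals = 0
    for p, t in zip(predictions, labels):
        p = np.asarray(p, float)
        t = np.asarray(t, float)
        se += float(np.sum((p - t) ** 2))
        n_vals += p.size
    local = se / max(n_vals, 1)
    if w_global == 0.0:
        return w_local * local
    gse = 0.0
    n_mol = len(predictions)
    for m in range(n_mol):
        if global_kind == "charge":
            resid = float(np.sum(predictions[m]))
        elif global_kind == "electron_count":
            if predictions_2p is None:
                raise ValueError("electron_count global loss needs predictions_2p (delta)")
            resid = reconstruct_N(predictions[m], predictions_2p[m]) - float(
                np.sum(Z[m])
            )
        elif global_kind == "energy":
            if predictions_2p is None or total_refs is None:
                raise ValueError(
                    "energy global loss needs predictions_2p (E_inter) and total_refs"
                )
            resid = (
                float(np.sum(predictions[m]) + np.sum(predictions_2p[m]))
                - total_refs[m]
            )
        else:
            raise ValueError("w_global > 0 with global_kind 'none'")
        gse += resid * resid
    return w_local * local + w_global * gse / max(n_mol, 1)


@dataclass
class EvalReport:
    """MAE/RMSE plus per-particle-type breakdown and per-molecule residuals."""

    property_name: str
    unit: str
    mae: float
    rmse: float
    n_values: int
    per_type: Dict[str, Dict[str, float]] = field(default_factory=dict)
    reconstruction_residuals: List[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.rmse >= self.mae >= 0 or math.isclose(self.rmse, self.mae)):
            raise ValueError("RMSE must be >= MAE >= 0")

    def in_kcalmol(self) -> "EvalReport":
        """Energy metrics converted with 1 a.u. = 627.5 kcal/mol."""
        if self.unit != "au":
            raise ValueError(f"unit conversion defined for 'au', not {self.unit!r}")
        factor = 627.5
        return EvalReport(
            property_name=self.property_name,
            unit="kcal/mol",
            mae=self.mae * factor,
            rmse=self.rmse * factor,
            n_values=self.n_values,
            per_type={
                k: {m: v * factor for m, v in d.items()} for k, d in self.per_type.items()
            },
            reconstruction_residuals=[r * factor for r in self.reconstruction_residuals],
        )

    def to_dict(self) -> Dict:
        return {
            "property": self.property_name,
            "unit": self.unit,
            "mae": self.mae,
            "rmse": self.rmse,
            "n_values": self.n_values,
            "per_type": self.per_type,
            "reconstruction_residuals": self.reconstruction_residuals,
        }


# ---------------------------------------------------------------------------
# Batch assembly
# ---------------------------------------------------------------------------

@dataclass
class _Prepared:
    """Cached per-record network inputs (geometry never changes)."""

    enc: MoleculeEncoding
    Z: np.ndarray
    labels: np.ndarray
    li: np.ndarray  # local label-pair indices (2P only)
    lj: np.ndarray
    lr: np.ndarray  # label-pair distances


def _prepare(records, model: LocalModel, property_name: str) -> List[_Prepared]:
    prepared = []
    for rec in records:
        mol = rec.molecule
        enc = encode_molecule(mol, model.z_to_row, model.rep_config)
        if model.is_2p:
            labels = rec.props_2p[property_name]
            li, lj = pair_index_arrays(mol.n_atoms)
            lr = (
                mol.distance_matrix()[li, lj] if li.size else np.zeros(0)
            )
        else:
            labels = rec.props_1p[property_name]
            li = lj = lr = np.zeros(0)
        prepared.append(
            _Prepared(
                enc=enc,
                Z=np.asarray(mol.Z),
                labels=np.asarray(labels, float),
                li=li,
                lj=lj,
                lr=lr,
            )
        )
    return prepared


def _batch_forward(model: LocalModel, batch: List[_Prepared]):
    """Forward pass over a packed batch; returns (y, labels, cache, slices)."""
    enc, offsets = pack_encodings([p.enc for p in batch])
    Z_flat = np.concatenate([p.Z for p in batch])
    labels = np.concatenate([p.labels for p in batch])
    if model.is_2p:
        gi = np.concatenate([p.li + offsets[k] for k, p in enumerate(batch)])
        gj = np.concatenate([p.lj + offsets[k] for k, p in enumerate(batch)])
        r = np.concatenate([p.lr for p in batch])
        y, cache = forward_2p(model, enc, Z_flat, gi, gj, r)
        sizes = [p.labels.size for p in batch]
    else:
        y, cache = forward_1p(model, enc, Z_flat)
        sizes = [p.Z.size for p in batch]
    bounds = np.cumsum([0] + sizes)
    slices = [slice(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]
    return y, labels, cache, slices, offsets


def _loss_and_grad_dy(
    y: np.ndarray,
    labels: np.ndarray,
    slices: List[slice],
    w_local: float,
    w_global: float,
    global_kind: str,
) -> Tuple[float, np.ndarray]:
    n_vals = y.size
    n_mol = len(slices)
    resid = y - labels
    loss = w_local * float(np.mean(resid**2))
    dy = (2.0 * w_local / n_vals) * resid
    if w_global > 0:
        if global_kind != "charge":
            raise ValueError(
                "trainable global loss is implemented for the total-charge "
                "reconstruction of 1P charge models"
            )
        for sl in slices:
            g = float(np.sum(y[sl]))
            loss += w_global * g * g / n_mol
            dy[sl] += (2.0 * w_global / n_mol) * g
    return loss, dy


def train(
    records: Sequence[LocalPropertyRecord],
    config: TrainConfig,
    rep_config: RepresentationConfig,
    readout_config: Optional[ReadoutConfig] = None,
    unit: str = "",
) -> Tuple[LocalModel, List[Dict]]:
    """Fit a LocalModel; returns the best-validation model and the log.

    Fully deterministic given the seeds in the configs. The training loss is
    squared-error based; the log tracks per-epoch train/val loss, val MAE
    and the median |molecular reconstruction| on validation.
    """
    train_set, val_set, test_set = split_dataset(records, config.splits, config.seed)
    elements = sorted({z for rec in train_set for z in rec.molecule.Z})
    for name, part in (("validation", val_set), ("test", test_set)):
        extra = {z for rec in part for z in rec.molecule.Z} - set(elements)
        if extra:
            raise ValueError(
                f"{name} set contains elements unseen in training: "
                f"{sorted(symbol_for(z) for z in extra)}"
            )
    if readout_config is None:
        readout_config = ReadoutConfig(mode=config.mode, elements=tuple(elements))
    if not unit:
        unit = train_set[0].units.get(config.property_name, "")
    model = build_model(rep_config, readout_config, config.property_name, unit)
    prepared = _prepare(train_set, model, config.property_name)
    prepared_val = _prepare(val_set, model, config.property_name)
    opt = Adam(model.params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    backward = backward_2p if model.is_2p else backward_1p

    log: List[Dict] = []
    best_val = math.inf
    best_params: Optional[Params] = None
    bad_epochs = 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(prepared))
        train_loss = 0.0
        n_batches = 0
        for start in range(0, len(order), config.batch_size):
            batch = [prepared[i] for i in order[start : start + config.batch_size]]
            y, labels, cache, slices, _ = _batch_forward(model, batch)
            loss, dy = _loss_and_grad_dy(
                y, labels, slices, config.w_local, config.w_global, config.global_kind
            )
            if not math.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; reduce the "
                    f"learning rate (currently {config.learning_rate})"
                )
            grads: Params = {}
            backward(model, cache, dy, grads)
            opt.step(model.params, grads)
            train_loss += loss
            n_batches += 1
        val_loss, val_mae, val_recon = _validation_metrics(model, prepared_val, config)
        log.append(
            {
                "epoch": epoch,
                "train_loss": train_loss / max(n_batches, 1),
                "val_loss": val_loss,
                "val_mae": val_mae,
                "val_reconstruction": val_recon,
            }
        )
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_params = {k: v.copy() for k, v in model.params.items()}
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > config.patience:
                break
    if best_params is not None:
        model.params = best_params
    return model, log


def _validation_metrics(model, prepared_val, config) -> Tuple[float, float, float]:
    if not prepared_val:
        return math.nan, math.nan, math.nan
    losses = []
    abs_errs = []
    recons = []
    for start in range(0, len(prepared_val), 64):
        batch = prepared_val[start : start + 64]
        y, labels, _, slices, _ = _batch_forward(model, batch)
        loss, _ = _loss_and_grad_dy(
            y, labels, slices, config.w_local, config.w_global, config.global_kind
        )
        losses.append(loss * len(batch))
        abs_errs.append(np.abs(y - labels))
        if not model.is_2p:
            recons.extend(abs(float(np.sum(y[sl]))) for sl in slices)
    val_loss = float(np.sum(losses) / len(prepared_val))
    val_mae = float(np.mean(np.concatenate(abs_errs)))
    val_recon = float(np.median(recons)) if recons else math.nan
    return val_loss, val_mae, val_recon


def predictions_for_records(
    model: LocalModel, records: Sequence[LocalPropertyRecord]
) -> List[np.ndarray]:
    """Per-record prediction arrays (batched for speed)."""
    prepared = _prepare(records, model, model.property_name)
    out: List[np.ndarray] = []
    for start in range(0, len(prepared), 64):
        batch = prepared[start : start + 64]
        y, _, _, slices, _ = _batch_forward(model, batch)
        out.extend(y[sl].copy() for sl in slices)
    return out


def evaluate(
    model: LocalModel, records: Sequence[LocalPropertyRecord]
) -> EvalReport:
    """MAE/RMSE over all particles or pairs, with per-type breakdown and
    per-molecule reconstruction residuals (sum of predictions; equals the
    molecular-charge residual for charge models)."""
    if not records:
        raise ValueError("cannot evaluate on an empty record set")
    preds = predictions_for_records(model, records)
    all_err: List[np.ndarray] = []
    type_errs: Dict[str, List[float]] = {}
    residuals: List[float] = []
    for rec, y in zip(records, preds):
        t = rec.property_values(model.property_name)
        err = y - t
        all_err.append(err)
        residuals.append(float(np.sum(y)))
        if model.is_2p:
            gi, gj = pair_index_arrays(rec.molecule.n_atoms)
            for k in range(err.size):
                a, b = sorted(
                    (rec.molecule.Z[gi[k]], rec.molecule.Z[gj[k]])
                )
                key = f"{symbol_for(a)}-{symbol_for(b)}"
                type_errs.setdefault(key, []).append(float(err[k]))
        else:
            for k, z in enumerate(rec.molecule.Z):
                type_errs.setdefault(symbol_for(z), []).append(float(err[k]))
    flat = np.concatenate(all_err)
    per_type = {
        key: {
            "mae": float(np.mean(np.abs(v))),
            "rmse": float(np.sqrt(np.mean(np.square(v)))),
            "n": len(v),
        }
        for key, v in sorted(type_errs.items())
    }
    return EvalReport(
        property_name=model.property_name,
        unit=model.unit,
        mae=float(np.mean(np.abs(flat))),
        rmse=float(np.sqrt(np.mean(flat**2))),
        n_values=int(flat.size),
        per_type=per_type,
        reconstruction_residuals=residuals,
    )
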