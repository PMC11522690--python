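"""Real-space electron and energy bookkeeping: atomic charges,
localization/delocalization indices, their electron-count sum rule, the
additive intra/inter energy decomposition, and the reconstruction-based
uncertainty score for predicted records.

All systems in scope are neutral, so exact per-atom populations satisfy
sum(q) = 0 and exact lambda/delta reconstruct the molecular electron count
N = sum(Z).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np

from .chemsys import LocalPropertyRecord, n_pairs

__all__ = [
    "ElectronBookkeeping",
    "IqaBookkeeping",
    "atomic_charge",
    "localization_index",
    "delocalization_index",
    "reconstruct_N",
    "iqa_intra",
    "iqa_inter",
    "reconstruct_E",
    "uncertainty_from_reconstruction",
    "sumrule_report",
]


@dataclass
class ElectronBookkeeping:
    """Electron-count descriptors of one molecule.

    ``delta`` follows the canonical pair enumeration. Physical (generator)
    records satisfy lambda >= 0 and delta >= 0; model predictions may
    violate these bounds, which is itself a reportable diagnostic.
    """

    Z: np.ndarray
    N_A: np.ndarray
    Q: np.ndarray
    lam: Optional[np.ndarray] = None
    delta: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        self.N_A = np.asarray(self.N_A, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        if not np.allclose(self.Q, self.Z - self.N_A, atol=1e-9):
            raise ValueError("Q must equal Z - N_A elementwise")
        M = self.Z.size
        if self.lam is not None:
            self.lam = np.asarray(self.lam, dtype=float)
            if self.lam.size != M:
                raise ValueError("lambda must have one entry per atom")
        if self.delta is not None:
            self.delta = np.asarray(self.delta, dtype=float)
            if self.delta.size != n_pairs(M):
                raise ValueError("delta must have one entry per unordered pair")


@dataclass
class IqaBookkeeping:
    """Additive energy decomposition of one molecule (atomic units)."""

    E_intra: np.ndarray
    E_inter: np.ndarray

    def __post_init__(self) -> None:
        self.E_intra = np.asarray(self.E_intra, dtype=float)
        self.E_inter = np.asarray(self.E_inter, dtype=float)
        if self.E_inter.size != n_pairs(self.E_intra.size):
            raise ValueError("E_inter must have one entry per unordered pair")


def atomic_charge(Z_A, N_A):
    """q_A = Z_A - N_A (electrons)."""
    Z_A = np.asarray(Z_A, dtype=float)
    N_A = np.asarray(N_A, dtype=float)
    if np.any(N_A < 0):
        raise ValueError("electron populations must be non-negative")
    if np.any(Z_A < 1):
        raise ValueError("atomic numbers must be >= 1")
    return Z_A - N_A


def localization_index(N_A, var_A):
    """lambda(A) = N_A - sigma^2_A (electrons)."""
    var_A = np.asarray(var_A, dtype=float)
    if np.any(var_A < 0):
        raise ValueError("population variance must be non-negative")
    return np.asarray(N_A, dtype=float) - var_A


def delocalization_index(cov_AB):
    """delta(A, B) = -2 sigma_{A,B} (electrons)."""
    return -2.0 * np.asarray(cov_AB, dtype=float)


def reconstruct_N(lam: Sequence[float], delta: Sequence[float]) -> float:
    """Electron count from the sum rule: N = sum(lambda) + sum_{i<j} delta.

    The half double-sum over ordered pairs equals the plain sum over the
    canonical unordered pairs.
    """
    lam = np.asarray(lam, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if delta.size != n_pairs(lam.size):
        raise ValueError(
            f"delta length {delta.size} inconsistent with M={lam.size} atoms "
            f"(expected {n_pairs(lam.size)})"
        )
    return float(lam.sum() + delta.sum())


def iqa_intra(T_A, Vee_A, VNe_A):
    """E_intra^A = T^A + V_ee^A + V_Ne^A."""
    return np.asarray(T_A, float) + np.asarray(Vee_A, float) + np.asarray(VNe_A, float)


def iqa_inter(Vee, VNN, VNe, VeN):
    """E_inter^{A,B} = V_ee + V_NN + V_Ne + V_eN.

    The two electron-nucleus terms are distinct: density of A with nucleus
    of B and vice versa.
    """
    return (
        np.asarray(Vee, float)
        + np.asarray(VNN, float)
        + np.asarray(VNe, float)
        + np.asarray(VeN, float)
    )


def reconstruct_E(E_intra: Sequence[float], E_inter: Sequence[float]) -> float:
    """Total energy E = sum(E_intra) + sum_{i<j} E_inter (a.u.)."""
    E_intra = np.asarray(E_intra, dtype=float)
    E_inter = np.asarray(E_inter, dtype=float)
    if E_inter.size != n_pairs(E_intra.size):
        raise ValueError(
            f"E_inter length {E_inter.size} inconsistent with M={E_intra.size} atoms"
        )
    return float(E_intra.sum() + E_inter.sum())


def uncertainty_from_reconstruction(
    record: LocalPropertyRecord,
    charge_property: str = "q",
    lam_property: str = "lambda",
    delta_property: str = "delta",
) -> Dict[str, float]:
    """Per-molecule reconstruction-error scores for predicted properties.

    Two routes, both in electrons, reported when their inputs are present:

    - ``"charge"``: |sum(q_hat)| (true molecular charge is 0 in scope);
    - ``"electron_count"``: |N(lambda_hat, delta_hat) - sum(Z)|.

    Raises if neither route has its properties available.
    """
    scores: Dict[str, float] = {}
    if charge_property in record.props_1p:
        scores["charge"] = float(abs(record.props_1p[charge_property].sum()))
    if lam_property in record.props_1p and delta_property in record.props_2p:
        N_hat = reconstruct_N(
            record.props_1p[lam_property], record.props_2p[delta_property]
        )
        scores["electron_count"] = float(abs(N_hat - sum(record.molecule.Z)))
    if not scores:
        raise ValueError(
            "record has neither predicted charges nor predicted lambda/delta; "
            "cannot compute a reconstruction uncertainty"
        )
    return scores


def sumrule_report(
    record: LocalPropertyRecord,
    charge_property: str = "q",
    lam_property: str = "lambda",
    delta_property: str = "delta",
    intra_property: str = "E_intra",
    inter_property: str = "E_inter",
    total_energy_property: str = "E_total",
) -> Dict[str, float]:
    """Residuals of every sum rule whose inputs the record carries.

    Keys (present when computable): ``charge_sum`` = sum(q);
    ``N_residual`` = N(lambda, delta) - sum(Z); ``E_residual`` =
    E(E_intra, E_inter) - stored total.
    """
    out: Dict[str, float] = {}
    if charge_property in record.props_1p:
        out["charge_sum"] = float(record.props_1p[charge_property].sum())
    if lam_property in record.props_1p and delta_property in record.props_2p:
        out["N_residual"] = reconstruct_N(
            record.props_1p[lam_property], record.props_2p[delta_property]
        ) - float(sum(record.molecule.Z))
    if intra_property in record.props_1p and inter_property in record.props_2p:
        E = reconstruct_E(
            record.props_1p[intra_property], record.props_2p[inter_property]
        )
        stored = record.props_1p.get(total_energy_property)
        if stored is not None:
            out["E_residual"] = E - float(stored[0])
    return out
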