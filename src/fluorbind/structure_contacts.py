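"""Accessible-surface-area bookkeeping for docked protein-ligand poses.

Consumes per-residue ASA tables (free vs complexed protein, e.g. NACCESS
output) and docked atom-pair distance tables.  A residue is classified as
binding-involved when it loses more than 10 A^2 of accessible surface on
complexation.  Internally a loss is positive (free minus complex); the
published sign convention (losses printed negative) is applied only at
report time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import DomainError

__all__ = [
    "AsaTable",
    "delta_asa",
    "binding_residues",
    "total_asa_loss",
    "min_trp_distance",
    "ASA_BINDING_THRESHOLD",
]

ASA_BINDING_THRESHOLD = 10.0  # A^2, strict inequality


class AsaTable:
    """Per-residue accessible surface area, free and in complex.

    Rows carry either the (asa_free, asa_complex) pair or, where only the
    change was published, the loss directly.  ``loss`` is always available
    and positive for buried surface.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"residue", "loss"}
        if not required.issubset(frame.columns):
            raise DomainError(f"ASA table needs columns {sorted(required)}")
        if frame["residue"].duplicated().any():
            raise DomainError("residue identifiers must be unique")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_pairs(cls, residues, asa_free, asa_complex) -> "AsaTable":
        asa_free = np.asarray(asa_free, dtype=float)
        asa_complex = np.asarray(asa_complex, dtype=float)
        if np.any(asa_free < 0) or np.any(asa_complex < 0):
            raise DomainError("ASA values must be non-negative")
        return cls(
            pd.DataFrame(
                {
                    "residue": list(residues),
                    "asa_free": asa_free,
                    "asa_complex": asa_complex,
                    "loss": asa_free - asa_complex,
                }
            )
        )

    @classmethod
    def from_losses(cls, residues, losses) -> "AsaTable":
        """Build from per-residue losses (positive = surface buried)."""
        return cls(
            pd.DataFrame({"residue": list(residues), "loss": np.asarray(losses, float)})
        )

    @classmethod
    def from_printed_deltas(cls, residues, printed_deltas) -> "AsaTable":
        """Build from published deltas where losses carry a negative sign."""
        return cls.from_losses(residues, -np.asarray(printed_deltas, dtype=float))

    def __len__(self) -> int:
        return len(self.frame)

    def report_frame(self) -> pd.DataFrame:
        """Published sign convention: losses negative."""
        out = self.frame.copy()
        out["delta_asa"] = -out["loss"]
        return out.drop(columns=["loss"])


def delta_asa(asa_free: float, asa_complex: float) -> float:
    """Surface lost on complexation, free minus complex (positive = buried)."""
    if asa_free < 0 or asa_complex < 0:
        raise DomainError("ASA values must be non-negative")
    return asa_free - asa_complex


def binding_residues(t: AsaTable, threshold: float = ASA_BINDING_THRESHOLD) -> list[str]:
    """Residues losing strictly more than ``threshold`` A^2 of surface.

    Order follows the input table.
    """
    mask = t.frame["loss"] > threshold
    return t.frame.loc[mask, "residue"].tolist()


def total_asa_loss(t: AsaTable) -> float:
    """Signed total surface change, sum of (complex - free), in A^2.

    Negative when surface is buried overall, matching the published
    convention.
    """
    if len(t) == 0:
        return 0.0
    return float(-t.frame["loss"].sum())


def min_trp_distance(d: pd.DataFrame, trp_id: str) -> float:
    """Shortest tabulated atom-pair distance from a tryptophan to the ligand.

    ``d`` has columns (trp, atom_pair, distance_A) with one row per
    measured pair.
    """
    rows = d[d["trp"] == trp_id]
    if rows.empty:
        raise KeyError(f"no distance rows for tryptophan {trp_id!r}")
    if (rows["distance_A"] <= 0).any():
        raise DomainError("distances must be positive")
    return float(rows["distance_A"].min())
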