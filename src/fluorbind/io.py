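"""Delimited-text readers and deterministic JSON writers.

All tabular inputs are plain delimited text (comma, tab or whitespace —
sniffed automatically) with a header row; ``#`` starts a comment.  JSON
output is byte-stable: keys sorted, fixed float representation.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .binding import QuenchingSeries, TitrationSeries
from .decay import AnisotropyDecayPair, DecayCurve
from .exceptions import DomainError
from .steady_state import EmissionSpectrum
from .structure_contacts import AsaTable

__all__ = [
    "read_table",
    "read_decay",
    "read_anisotropy_pair",
    "read_titration",
    "read_quenching",
    "read_spectrum",
    "read_asa_table",
    "write_json",
]


def read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if df.empty:
        raise DomainError(f"{path}: no data rows")
    return df


def read_decay(path) -> DecayCurve:
    """Decay histogram: columns time_ns, counts[, irf_counts]."""
    df = read_table(path)
    cols = list(df.columns)
    if len(cols) < 2:
        raise DomainError(f"{path}: need at least (time_ns, counts) columns")
    time = df.iloc[:, 0].to_numpy(float)
    counts = df.iloc[:, 1].to_numpy(float)
    if len(cols) >= 3:
        irf = df.iloc[:, 2].to_numpy(float)
    else:
        # no IRF recorded: treat the excitation as a delta at the first channel
        irf = np.zeros_like(counts)
        irf[0] = 1.0
    return DecayCurve(time=time, counts=counts, irf_counts=irf)


def read_anisotropy_pair(path, g_factor: float = 1.0) -> AnisotropyDecayPair:
    """Polarized pair: columns time_ns, ivv, ivh, irf_counts."""
    df = read_table(path)
    if df.shape[1] < 4:
        raise DomainError(f"{path}: need columns time_ns, ivv, ivh, irf_counts")
    return AnisotropyDecayPair(
        time=df.iloc[:, 0].to_numpy(float),
        ivv=df.iloc[:, 1].to_numpy(float),
        ivh=df.iloc[:, 2].to_numpy(float),
        g_factor=g_factor,
        irf_counts=df.iloc[:, 3].to_numpy(float),
    )


def read_titration(
    path, ligand_conc_uM: float = 25.0, observable_kind: str = "intensity"
) -> TitrationSeries:
    """Titration: columns protein_conc_uM, observable."""
    df = read_table(path)
    return TitrationSeries(
        protein_conc_uM=df.iloc[:, 0].to_numpy(float),
        observable=df.iloc[:, 1].to_numpy(float),
        ligand_conc_uM=ligand_conc_uM,
        observable_kind=observable_kind,
    )


def read_quenching(path) -> QuenchingSeries:
    """Quenching series: columns quencher_conc_M, f0_over_f."""
    df = read_table(path)
    return QuenchingSeries(
        quencher_conc_M=df.iloc[:, 0].to_numpy(float),
        f0_over_f=df.iloc[:, 1].to_numpy(float),
    )


def read_spectrum(path) -> EmissionSpectrum:
    """Spectrum: columns wavelength_nm, intensity."""
    df = read_table(path)
    return EmissionSpectrum(
        wavelength=df.iloc[:, 0].to_numpy(float),
        intensity=df.iloc[:, 1].to_numpy(float),
    )


def read_asa_table(path) -> AsaTable:
    """Per-residue ASA: columns residue, asa_free_A2, asa_complex_A2 or
    residue, delta_asa_A2 (published sign convention, losses negative)."""
    df = read_table(path)
    cols = {c.lower() for c in df.columns}
    if {"asa_free_a2", "asa_complex_a2"} <= cols:
        return AsaTable.from_pairs(
            df.iloc[:, 0], df["asa_free_A2"], df["asa_complex_A2"]
        )
    if "delta_asa_a2" in cols:
        return AsaTable.from_printed_deltas(df.iloc[:, 0], df["delta_asa_A2"])
    raise DomainError(
        f"{path}: need (asa_free_A2, asa_complex_A2) or delta_asa_A2 columns"
    )


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_json(obj, path) -> None:
    """Deterministic JSON: sorted keys, newline-terminated."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonify(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")
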