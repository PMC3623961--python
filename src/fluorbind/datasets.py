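"""Bundled reference tables for the tetracycline / serum-albumin study.

The package ships, as plain CSV, the published summary tables for the
tetracycline (TC) + HSA / BSA / alkaline-phosphatase system: lifetime
titrations, binding constants, per-residue accessible-surface-area changes,
tryptophan-to-ligand docking distances, FRET summaries, low-temperature
phosphorescence band metrics and solvent photophysics.  They serve both as
worked-example inputs and as ground truth for the test suite.
"""

from importlib import resources

import pandas as pd

__all__ = [
    "load_lifetime_titration",
    "load_binding_constants",
    "load_asa_changes",
    "load_trp_distances",
    "load_trp_asa",
    "load_fret_summary",
    "load_phosphorescence_bands",
    "load_solvent_photophysics",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("fluorbind.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_lifetime_titration() -> pd.DataFrame:
    """Biexponential lifetime components and quantum yields of 25 uM TC
    titrated with BSA/HSA (lambda_exc 370 nm, 298 K).

    ``f1``/``f2`` are the instrument-reported fractional contributions
    (printed as percentages); ``tau_av_ns`` is the printed mean lifetime.
    """
    return _read("tc_lifetime_titration.csv")


def load_binding_constants() -> pd.DataFrame:
    """Association constants (M^-1) and free energies (kcal/mol) for the
    three protein-TC systems by three methods at 298 K."""
    return _read("binding_constants.csv")


def load_asa_changes() -> pd.DataFrame:
    """Per-residue accessible-surface-area changes (A^2, printed sign
    convention: losses negative) for the docked HSA-TC and BSA-TC poses."""
    return _read("asa_changes.csv")


def load_trp_distances() -> pd.DataFrame:
    """Docked atom-pair distances (A) from each tryptophan to TC."""
    return _read("trp_distances.csv")


def load_trp_asa() -> pd.DataFrame:
    """Tryptophan accessible surface area (A^2) free and in complex."""
    return _read("trp_asa.csv")


def load_fret_summary() -> pd.DataFrame:
    """Energy-transfer efficiencies and rate constants (1e8 s^-1) for
    HSA-TC and BSA-TC by donor quenching, acceptor enhancement and
    phosphorescence quenching, with the HSA/BSA rate ratios."""
    return _read("fret_summary.csv")


def load_phosphorescence_bands() -> pd.DataFrame:
    """77 K tryptophan phosphorescence (0,0) band position (nm) and width
    at half maximum (cm^-1) for free albumins and their TC complexes."""
    return _read("phosphorescence_bands.csv")


def load_solvent_photophysics() -> pd.DataFrame:
    """TC photophysics in pure solvents and protein complexes: emission
    maximum, quantum yield, lifetime components, rotational correlation
    time, radiative/non-radiative rates and Kamlet-Taft solvent
    parameters (pi*, alpha, beta) plus dielectric constant."""
    return _read("solvent_photophysics.csv")
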