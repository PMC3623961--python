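"""Forster resonance energy transfer: efficiencies, rates and rate ratios.

Efficiency estimators
---------------------
* donor quenching:        E = 1 - F_DA / F_D
* acceptor enhancement:   E = (eps_A / eps_AD) (F_AD / F_A - 1)
* phosphorescence areas:  E = 1 - I_DA / I_D   (77 K triplet emission)

Rates
-----
* from efficiency and the unquenched donor lifetime:  k_ET = E / tau_D
* from the lifetime pair:  k_ET = 1/tau_DA - 1/tau_D

Because the Forster rate scales as tau_D^-1 r^-6, the rate ratio of two
systems sharing the overlap integral J, refractive index n, donor yield phi
and orientation factor kappa^2 depends only on their donor lifetimes and
donor-acceptor distances:  k1/k2 = (tau_D2 / tau_D1) (r2 / r1)^6.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .exceptions import DataQualityWarning, DomainError

__all__ = [
    "FretSteadyState",
    "FretLifetimes",
    "ForsterGeometry",
    "PhosphorescenceAreas",
    "efficiency_donor",
    "efficiency_acceptor",
    "efficiency_phosphorescence",
    "efficiency_from_lifetimes",
    "ket_from_efficiency",
    "ket_from_lifetimes",
    "ket_ratio_experimental",
    "ket_ratio_theoretical",
]


@dataclass
class FretSteadyState:
    """Steady-state intensities and extinction coefficients for one pair."""

    f_d: float  # donor alone
    f_da: float  # donor with acceptor
    f_a: float  # acceptor alone
    f_ad: float  # acceptor with donor
    eps_a: float  # acceptor extinction at donor excitation, M^-1 cm^-1
    eps_ad: float  # same, in the complex

    def __post_init__(self):
        for name in ("f_d", "f_a", "eps_a", "eps_ad"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")


@dataclass
class FretLifetimes:
    """Mean donor lifetimes without (tau_d) and with (tau_da) the acceptor, ns."""

    tau_d: float
    tau_da: float

    def __post_init__(self):
        if self.tau_da <= 0:
            raise DomainError("tau_da must be positive")
        if self.tau_da > self.tau_d:
            warnings.warn(
                "tau_da exceeds tau_d: negative transfer rate",
                DataQualityWarning,
                stacklevel=2,
            )


@dataclass
class ForsterGeometry:
    """Distances and donor lifetimes for a two-system rate-ratio comparison.

    The ratio assumes the overlap integral J, refractive index n, donor
    quantum yield phi and orientation factor kappa^2 are common to both
    systems; ``shared_context`` records that assumption.
    """

    r1: float  # donor-acceptor distance, system 1 (any common unit)
    r2: float  # system 2, same unit
    tau_d1: float  # donor lifetime, system 1, ns
    tau_d2: float  # system 2, ns
    shared_context: tuple = ("J", "n", "phi", "kappa2")

    def __post_init__(self):
        if min(self.r1, self.r2, self.tau_d1, self.tau_d2) <= 0:
            raise DomainError("distances and lifetimes must be positive")


@dataclass
class PhosphorescenceAreas:
    """Integrated phosphorescence of the free protein and the complex."""

    area_d: float
    area_da: float

    def __post_init__(self):
        if self.area_d <= 0 or self.area_da <= 0:
            raise DomainError("areas must be positive")


def _flag_out_of_range(e: float, label: str) -> float:
    if not 0.0 <= e <= 1.0:
        warnings.warn(
            f"{label} efficiency {e:.3f} outside [0, 1] "
            "(enhancement rather than transfer if negative)",
            DataQualityWarning,
            stacklevel=3,
        )
    return e


def efficiency_donor(f_d: float, f_da: float) -> float:
    """Transfer efficiency from donor quenching, E = 1 - F_DA/F_D."""
    if f_d <= 0:
        raise DomainError("f_d must be positive")
    return _flag_out_of_range(1.0 - f_da / f_d, "donor-quenching")


def efficiency_acceptor(
    f_a: float, f_ad: float, eps_a: float, eps_ad: float
) -> float:
    """Transfer efficiency from acceptor enhancement.

    E = (eps_A / eps_AD) * (F_AD / F_A - 1), with the extinction ratio
    normalizing the direct-excitation contribution of the acceptor.
    """
    if min(f_a, f_ad, eps_a, eps_ad) <= 0:
        raise DomainError("all intensities and extinctions must be positive")
    return _flag_out_of_range((eps_a / eps_ad) * (f_ad / f_a - 1.0), "acceptor")


def efficiency_phosphorescence(p: PhosphorescenceAreas) -> float:
    """Transfer efficiency from 77 K phosphorescence areas, E = 1 - I_DA/I_D."""
    return _flag_out_of_range(1.0 - p.area_da / p.area_d, "phosphorescence")


def efficiency_from_lifetimes(l: FretLifetimes) -> float:
    """E = 1 - tau_DA / tau_D (purely dynamic quenching)."""
    if l.tau_d <= 0:
        raise DomainError("tau_d must be positive")
    return _flag_out_of_range(1.0 - l.tau_da / l.tau_d, "lifetime")


def ket_from_efficiency(e: float, tau_d_ns: float) -> float:
    """Transfer rate k_ET = E / tau_D in s^-1 (tau_D given in ns)."""
    if tau_d_ns <= 0:
        raise DomainError("tau_d must be positive")
    if e >= 1.0:
        raise DomainError("E = 1 implies an infinite transfer rate")
    return e / (tau_d_ns * 1e-9)


def ket_from_lifetimes(l: FretLifetimes) -> float:
    """Transfer rate k_ET = 1/tau_DA - 1/tau_D in s^-1 (lifetimes in ns)."""
    rate = 1.0 / (l.tau_da * 1e-9) - 1.0 / (l.tau_d * 1e-9)
    if rate < 0:
        warnings.warn("negative transfer rate", DataQualityWarning, stacklevel=2)
    return rate


def ket_ratio_experimental(k1: float, k2: float, ndigits: int | None = None) -> float:
    """Ratio k1/k2 of two measured transfer rates, optionally rounded."""
    if k2 <= 0:
        raise DomainError("k2 must be positive")
    ratio = k1 / k2
    return round(ratio, ndigits) if ndigits is not None else ratio


def ket_ratio_theoretical(g: ForsterGeometry) -> float:
    """Forster r^-6 rate ratio of system 1 to system 2.

    k1/k2 = (tau_d2 / tau_d1) * (r2 / r1)^6; invariant under a common
    change of distance units.
    """
    return (g.tau_d2 / g.tau_d1) * (g.r2 / g.r1) ** 6
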