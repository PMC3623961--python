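"""Kamlet-Taft solvatochromic analysis and radiative-rate decomposition.

The fluorophore's quantum yield phi and mean lifetime tau measured across
solvents are regressed on the empirical solvent scales pi* (dipolarity /
polarizability), alpha (hydrogen-bond donating ability) and beta
(hydrogen-bond accepting ability):

    response = c0 + c_pi * pi* + c_alpha * alpha + c_beta * beta

The excited-state decay rate 1/tau is split into radiative and
non-radiative channels via the quantum yield: k_r = phi/tau,
k_nr = (1 - phi)/tau.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import spearmanr

from .exceptions import DomainError, FitError

__all__ = [
    "SolventRecord",
    "RateConstants",
    "rate_constants",
    "KamletTaftModel",
    "KamletTaftResults",
    "kamlet_taft_fit",
    "trend_correlation",
    "records_from_frame",
    "filter_protic",
]


@dataclass
class SolventRecord:
    """Photophysics of the fluorophore in one solvent."""

    name: str
    pi_star: float
    alpha: float
    beta: float
    epsilon: float
    phi: float
    tau_mean: float  # ns
    lambda_em: float | None = None  # nm

    def __post_init__(self):
        if self.epsilon <= 1:
            raise DomainError("dielectric constant must exceed 1")
        if not 0 < self.phi < 1:
            raise DomainError("quantum yield must lie in (0, 1)")
        if self.tau_mean <= 0:
            raise DomainError("mean lifetime must be positive")

    @property
    def protic(self) -> bool:
        """Hydrogen-bond donating solvent (alpha > 0)."""
        return self.alpha > 0


@dataclass
class RateConstants:
    """Radiative and non-radiative decay rates, s^-1."""

    k_r: float
    k_nr: float

    @property
    def total(self) -> float:
        return self.k_r + self.k_nr


def rate_constants(phi: float, tau_mean_ns: float) -> RateConstants:
    """Decompose 1/tau into k_r = phi/tau and k_nr = (1-phi)/tau.

    ``tau_mean_ns`` is in ns; rates come back in s^-1 and satisfy
    k_r + k_nr = 1/tau exactly.
    """
    if not 0 < phi < 1:
        raise DomainError("phi must lie strictly in (0, 1)")
    if tau_mean_ns <= 0:
        raise DomainError("tau must be positive")
    tau_s = tau_mean_ns * 1e-9
    return RateConstants(k_r=phi / tau_s, k_nr=(1.0 - phi) / tau_s)


def records_from_frame(df: pd.DataFrame, phi_scale: float = 1e-3) -> list[SolventRecord]:
    """Build solvent records from the bundled photophysics table.

    Rows lacking any Kamlet-Taft parameter (the protein complexes) are
    dropped.  ``phi_scale`` converts the table's phi x 10^3 column.
    """
    out = []
    for _, row in df.iterrows():
        if pd.isna(row.get("pi_star")) or pd.isna(row.get("alpha")):
            continue
        out.append(
            SolventRecord(
                name=str(row["system"]),
                pi_star=float(row["pi_star"]),
                alpha=float(row["alpha"]),
                beta=float(row["beta"]),
                epsilon=float(row["epsilon"]),
                phi=float(row["phi_x1e3"]) * phi_scale,
                tau_mean=float(row["tau_av_ns"]),
                lambda_em=float(row["lambda_em_nm"]),
            )
        )
    return out


def filter_protic(records: list[SolventRecord], protic: bool = True) -> list[SolventRecord]:
    """Subset of hydrogen-bond donating (or non-donating) solvents."""
    return [r for r in records if r.protic == protic]


@dataclass
class KamletTaftResults:
    """Coefficients and diagnostics of the three-parameter solvent regression."""

    params: pd.Series  # c0, c_pi, c_alpha, c_beta
    bse: pd.Series
    r_squared: float
    resid: np.ndarray
    response: str
    n_obs: int

    @property
    def c0(self) -> float:
        return float(self.params["c0"])

    @property
    def c_pi(self) -> float:
        return float(self.params["c_pi"])

    @property
    def c_alpha(self) -> float:
        return float(self.params["c_alpha"])

    @property
    def c_beta(self) -> float:
        return float(self.params["c_beta"])

    def summary(self) -> str:
        lines = [
            f"Kamlet-Taft regression of {self.response} ({self.n_obs} solvents)",
            "-" * 50,
        ]
        for name in ("c0", "c_pi", "c_alpha", "c_beta"):
            lines.append(
                f"{name:8s} = {self.params[name]: .5g}  (se {self.bse[name]:.3g})"
            )
        lines.append(f"R^2 = {self.r_squared:.4f}")
        return "\n".join(lines)


class KamletTaftModel:
    """OLS of a photophysical response on the pi*, alpha, beta solvent scales."""

    def __init__(self, records: list[SolventRecord], response: str = "phi"):
        if len(records) < 5:
            raise DomainError("at least 5 solvent records required")
        if response not in ("phi", "tau_mean"):
            raise ValueError("response must be 'phi' or 'tau_mean'")
        self.records = list(records)
        self.response = response

    def design(self) -> tuple[np.ndarray, np.ndarray]:
        X = np.array([[r.pi_star, r.alpha, r.beta] for r in self.records])
        y = np.array([getattr(r, self.response) for r in self.records])
        return X, y

    def fit(self) -> KamletTaftResults:
        X, y = self.design()
        names = ["c0", "c_pi", "c_alpha", "c_beta"]
        Xc = sm.add_constant(X, has_constant="add")
        rank = np.linalg.matrix_rank(Xc)
        if rank < Xc.shape[1]:
            # identify which predictor columns are collinear with the rest
            collinear = []
            for j, nm in enumerate(names):
                keep = [k for k in range(Xc.shape[1]) if k != j]
                if np.linalg.matrix_rank(Xc[:, keep]) == rank:
                    collinear.append(nm)
            raise FitError(
                f"rank-deficient design matrix; collinear columns: {collinear}"
            )
        res = sm.OLS(y, Xc).fit()
        return KamletTaftResults(
            params=pd.Series(res.params, index=names),
            bse=pd.Series(res.bse, index=names),
            r_squared=float(res.rsquared),
            resid=np.asarray(res.resid),
            response=self.response,
            n_obs=len(y),
        )


def kamlet_taft_fit(
    records: list[SolventRecord], response: str = "phi"
) -> KamletTaftResults:
    """Convenience wrapper: ``KamletTaftModel(records, response).fit()``."""
    return KamletTaftModel(records, response=response).fit()


def trend_correlation(
    records: list[SolventRecord], x: str = "epsilon", response: str = "phi"
) -> tuple[float, float]:
    """Spearman rank correlation of a response against one solvent scale.

    Sign-level check for monotone trends (e.g. phi increasing with the
    dielectric constant); ties get mid-ranks.  Returns (rho, p-value).
    """
    if len(records) < 4:
        raise DomainError("at least 4 records required for a rank correlation")
    if x not in ("epsilon", "pi_star", "alpha", "beta"):
        raise ValueError(f"unknown solvent scale {x!r}")
    xv = np.array([getattr(r, x) for r in records])
    yv = np.array([getattr(r, response) for r in records])
    rho, p = spearmanr(xv, yv)
    return float(rho), float(p)
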