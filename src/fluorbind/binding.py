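"""Association-constant estimation from fluorescence titrations.

Three routes, mirroring how enhanced-ligand-emission and tryptophan
quenching experiments are usually analysed:

* modified Benesi-Hildebrand linearization of the 1:1 isotherm
  (observable: ligand emission intensity or quantum yield),
* anisotropy titration, (r - r_f) / [R (r_b - r)] vs protein concentration,
* combined static + dynamic Stern-Volmer quenching,
  F0/F = (1 + K_sv [L]) exp(K_static [L]).

Concentrations are stored in uM and converted to M inside the fits;
association constants are always reported in M^-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.optimize import curve_fit

from .exceptions import DataQualityWarning, DomainError, FitError, FitQualityWarning

__all__ = [
    "TitrationSeries",
    "AnisotropyTitration",
    "QuenchingSeries",
    "BindingFit",
    "SternVolmerFit",
    "BenesiHildebrandModel",
    "fit_benesi_hildebrand",
    "fit_anisotropy_binding",
    "fit_stern_volmer",
    "free_energy",
    "GAS_CONSTANT_KCAL",
]

GAS_CONSTANT_KCAL = 1.987e-3  # kcal mol^-1 K^-1


@dataclass
class TitrationSeries:
    """Ligand observable vs added protein at fixed ligand concentration."""

    protein_conc_uM: np.ndarray
    observable: np.ndarray
    ligand_conc_uM: float = 25.0
    observable_kind: str = "intensity"  # intensity | quantum_yield | anisotropy

    def __post_init__(self):
        self.protein_conc_uM = np.asarray(self.protein_conc_uM, dtype=float)
        self.observable = np.asarray(self.observable, dtype=float)
        if np.any(np.diff(self.protein_conc_uM) <= 0) or np.any(
            self.protein_conc_uM < 0
        ):
            raise DomainError("protein concentrations must be non-negative, increasing")
        if len(self.protein_conc_uM) != len(self.observable):
            raise DomainError("concentration and observable lengths differ")
        if not np.all(np.isfinite(self.observable)):
            raise DomainError("observable must be finite")
        if len(self.protein_conc_uM) < 5:
            raise DomainError("at least 5 titration points required for fitting")


@dataclass
class AnisotropyTitration:
    """Steady-state anisotropy titration with limiting values and yield ratio.

    ``quantum_yield_ratio`` is R = Q_bound / Q_free, the enhancement factor
    that weights the bound-fraction estimate from anisotropy.
    """

    protein_conc_uM: np.ndarray
    r_obs: np.ndarray
    r_f: float
    r_b: float
    quantum_yield_ratio: float

    def __post_init__(self):
        self.protein_conc_uM = np.asarray(self.protein_conc_uM, dtype=float)
        self.r_obs = np.asarray(self.r_obs, dtype=float)
        if self.quantum_yield_ratio <= 0:
            raise DomainError("quantum_yield_ratio must be positive")
        if self.r_b <= self.r_f:
            raise DomainError("r_b must exceed r_f")
        if np.any(np.diff(self.r_obs) < 0):
            warnings.warn(
                "anisotropy series is not monotone increasing",
                DataQualityWarning,
                stacklevel=2,
            )


@dataclass
class QuenchingSeries:
    """Stern-Volmer data: F0/F versus quencher concentration in M."""

    quencher_conc_M: np.ndarray
    f0_over_f: np.ndarray
    fractional_site: float = 1.0

    def __post_init__(self):
        self.quencher_conc_M = np.asarray(self.quencher_conc_M, dtype=float)
        self.f0_over_f = np.asarray(self.f0_over_f, dtype=float)
        if np.any(np.diff(self.quencher_conc_M) <= 0):
            raise DomainError("quencher concentrations must be strictly increasing")
        if len(self.quencher_conc_M) < 5:
            raise DomainError("at least 5 points required")
        if np.any(np.diff(self.f0_over_f) < 0):
            warnings.warn(
                "F0/F decreases along the series", DataQualityWarning, stacklevel=2
            )


@dataclass
class BindingFit:
    """A fitted 1:1 association constant with its provenance."""

    k_assoc: float  # M^-1
    stderr_k: float | None
    f0: float
    f_inf: float
    method: str
    r_squared: float | None = None
    intercept: float | None = None
    extra: dict = field(default_factory=dict)

    def free_energy(self, temperature: float = 298.0) -> float:
        """Binding free energy -RT ln K in kcal/mol at ``temperature``."""
        return free_energy(self.k_assoc, temperature)

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "k_assoc_M": self.k_assoc,
            "stderr_k_M": self.stderr_k,
            "f0": self.f0,
            "f_inf": self.f_inf,
            "r_squared": self.r_squared,
            "intercept": self.intercept,
        }
        d.update(self.extra)
        return d

    def summary(self) -> str:
        se = f" +/- {self.stderr_k:.3g}" if self.stderr_k is not None else ""
        r2 = f"   R^2 = {self.r_squared:.5f}" if self.r_squared is not None else ""
        return (
            f"Binding fit ({self.method})\n"
            f"K = {self.k_assoc:.4g}{se} M^-1{r2}\n"
            f"dG(298 K) = {self.free_energy():.3f} kcal/mol\n"
            f"F0 = {self.f0:.4g}   F_inf = {self.f_inf:.4g}"
        )


def _hyperbola(P, K, f0, f_inf):
    return f0 + (f_inf - f0) * K * P / (1.0 + K * P)


def _mass_balance_bound_fraction(P_tot, L_tot, K):
    """Exact 1:1 bound-ligand fraction from the mass-balance quadratic."""
    b = P_tot + L_tot + 1.0 / K
    PL = 0.5 * (b - np.sqrt(b * b - 4.0 * P_tot * L_tot))
    return PL / L_tot


class BenesiHildebrandModel:
    """1:1 association model for an enhanced-ligand-emission titration.

    ``fit(mode="linear")`` regresses (F_inf - F0)/(F_x - F0) on 1/[L]
    (ordinary least squares; K = 1/slope, intercept expected ~ 1) using a
    fixed F_inf — by default the largest-concentration observable.
    ``fit(mode="nonlinear")`` fits the hyperbola directly, returning both
    F_inf and K; ``mass_balance=True`` replaces the excess-protein
    hyperbola by the exact 1:1 mass-balance solution.
    """

    def __init__(self, series: TitrationSeries):
        self.series = series
        if np.any(np.diff(series.observable) < 0):
            warnings.warn(
                "observable is not monotone in protein concentration",
                DataQualityWarning,
                stacklevel=2,
            )

    def _f0(self) -> float:
        s = self.series
        if s.protein_conc_uM[0] == 0:
            return float(s.observable[0])
        raise DomainError(
            "series lacks a zero-protein point; supply f0 via the nonlinear mode"
        )

    def fit_linear(self, f_inf: float | None = None) -> BindingFit:
        s = self.series
        f0 = self._f0()
        if f_inf is None:
            f_inf = float(s.observable[-1])
        nonzero = s.protein_conc_uM > 0
        Fx = s.observable[nonzero]
        P = s.protein_conc_uM[nonzero] * 1e-6  # M
        dF = Fx - f0
        if np.all(np.abs(Fx - f_inf) < 1e-12 * max(abs(f_inf), 1.0)):
            raise FitError("observable saturated at F_inf everywhere; K unidentifiable")
        usable = np.abs(dF) > 0
        usable &= np.abs(Fx - f_inf) > 1e-12 * max(abs(f_inf), 1.0)
        if usable.sum() < 3:
            raise FitError("too few usable points strictly between F0 and F_inf")
        y = (f_inf - f0) / dF[usable]
        x = 1.0 / P[usable]
        res = sm.OLS(y, sm.add_constant(x)).fit()
        slope = res.params[1]
        if slope <= 0:
            raise FitError(
                "non-positive Benesi-Hildebrand slope", diagnostics={"slope": slope}
            )
        K = 1.0 / slope
        stderr = res.bse[1] / slope**2  # delta method for 1/slope
        return BindingFit(
            k_assoc=float(K),
            stderr_k=float(stderr),
            f0=f0,
            f_inf=float(f_inf),
            method="benesi_hildebrand",
            r_squared=float(res.rsquared),
            intercept=float(res.params[0]),
        )

    def fit_nonlinear(self, mass_balance: bool = False) -> BindingFit:
        s = self.series
        f0 = self._f0()
        P = s.protein_conc_uM * 1e-6
        F = s.observable
        span = F[-1] - f0
        if abs(span) < 1e-12 * max(abs(f0), 1.0):
            raise FitError("flat titration; K unidentifiable")

        if mass_balance:
            L = s.ligand_conc_uM * 1e-6

            def model(P, K, f_inf):
                return f0 + (f_inf - f0) * _mass_balance_bound_fraction(P, L, K)

        else:

            def model(P, K, f_inf):
                return _hyperbola(P, K, f0, f_inf)

        K0 = 1.0 / max(P[len(P) // 2], 1e-9)
        try:
            popt, pcov = curve_fit(
                model,
                P,
                F,
                p0=[K0, f0 + 2 * span],
                bounds=([0.0, min(f0, F.min())], [np.inf, np.inf]),
                maxfev=20000,
            )
        except RuntimeError as exc:  # pragma: no cover - optimiser failure path
            raise FitError(f"nonlinear 1:1 fit failed: {exc}") from exc
        K, f_inf = popt
        if K <= 0:
            raise FitError("non-positive fitted K")
        perr = np.sqrt(np.diag(pcov))
        pred = model(P, *popt)
        ss_res = np.sum((F - pred) ** 2)
        ss_tot = np.sum((F - F.mean()) ** 2)
        return BindingFit(
            k_assoc=float(K),
            stderr_k=float(perr[0]),
            f0=f0,
            f_inf=float(f_inf),
            method="benesi_hildebrand",
            r_squared=float(1 - ss_res / ss_tot) if ss_tot > 0 else None,
            extra={"mode": "mass_balance" if mass_balance else "hyperbola"},
        )

    def fit(self, mode: str = "nonlinear", **kwargs) -> BindingFit:
        if mode == "linear":
            return self.fit_linear(**kwargs)
        if mode == "nonlinear":
            return self.fit_nonlinear(**kwargs)
        raise ValueError(f"unknown mode {mode!r}")


def fit_benesi_hildebrand(
    t: TitrationSeries, f_inf_mode: str = "fit", f_inf: float | None = None
) -> BindingFit:
    """Benesi-Hildebrand association constant.

    ``f_inf_mode="fixed"`` uses the linear reciprocal plot with F_inf held
    at ``f_inf`` (default: the largest-concentration observable);
    ``"fit"`` refines F_inf together with K on the 1:1 hyperbola.
    """
    model = BenesiHildebrandModel(t)
    if f_inf_mode == "fixed":
        return model.fit_linear(f_inf=f_inf)
    if f_inf_mode == "fit":
        return model.fit_nonlinear()
    raise ValueError(f"unknown f_inf_mode {f_inf_mode!r}")


def fit_anisotropy_binding(a: AnisotropyTitration) -> BindingFit:
    """Association constant from an anisotropy titration.

    Regresses y = (r - r_f) / [R (r_b - r)] on protein concentration in M;
    the slope is K.  Points with r outside (r_f, r_b) are excluded with a
    warning.
    """
    P = a.protein_conc_uM * 1e-6
    r = a.r_obs
    inside = (r >= a.r_f) & (r <= a.r_b)
    if not inside.all():
        warnings.warn(
            f"{int((~inside).sum())} anisotropy point(s) outside [r_f, r_b] excluded",
            DataQualityWarning,
            stacklevel=2,
        )
    P, r = P[inside], r[inside]
    y = (r - a.r_f) / (a.quantum_yield_ratio * (a.r_b - r))
    res = sm.OLS(y, sm.add_constant(P)).fit()
    slope = res.params[1]
    if slope <= 0:
        raise FitError(
            "non-positive anisotropy-binding slope", diagnostics={"slope": slope}
        )
    return BindingFit(
        k_assoc=float(slope),
        stderr_k=float(res.bse[1]),
        f0=a.r_f,
        f_inf=a.r_b,
        method="anisotropy",
        r_squared=float(res.rsquared),
        intercept=float(res.params[0]),
    )


@dataclass
class SternVolmerFit:
    """Static + dynamic quenching constants."""

    k_sv: float  # dynamic, M^-1
    k_static: float  # static, M^-1
    stderr_sv: float | None
    stderr_static: float | None
    r_squared: float | None
    static_term: bool
    static_unresolved: bool = False

    def to_dict(self) -> dict:
        return {
            "method": "stern_volmer",
            "k_sv_M": self.k_sv,
            "k_static_M": self.k_static,
            "stderr_sv_M": self.stderr_sv,
            "stderr_static_M": self.stderr_static,
            "r_squared": self.r_squared,
            "static_term": self.static_term,
            "static_unresolved": self.static_unresolved,
        }

    def summary(self) -> str:
        lines = [
            "Stern-Volmer quenching fit",
            f"K_sv     = {self.k_sv:.4g} M^-1",
        ]
        if self.static_term:
            flag = "   [unresolved: CI includes 0]" if self.static_unresolved else ""
            lines.append(f"K_static = {self.k_static:.4g} M^-1{flag}")
        if self.r_squared is not None:
            lines.append(f"R^2 = {self.r_squared:.5f}")
        return "\n".join(lines)


def fit_stern_volmer(q: QuenchingSeries, static_term: bool = True) -> SternVolmerFit:
    """Fit F0/F = (1 + K_sv [L]) exp(K_static [L]) for a single 1:1 site.

    With ``static_term=False`` the exponential factor is dropped and the
    classic linear Stern-Volmer slope is returned (OLS of F0/F on [L]).
    """
    L = q.quencher_conc_M
    y = q.f0_over_f
    if np.any(y < 1.0 - 1e-9):
        warnings.warn("F0/F below 1 encountered", DataQualityWarning, stacklevel=2)

    if not static_term:
        res = sm.OLS(y, sm.add_constant(L)).fit()
        return SternVolmerFit(
            k_sv=float(res.params[1]),
            k_static=0.0,
            stderr_sv=float(res.bse[1]),
            stderr_static=None,
            r_squared=float(res.rsquared),
            static_term=False,
        )

    def model(L, ksv, kst):
        return (1.0 + ksv * L) * np.exp(kst * L)

    # linear slope seeds both constants
    slope0 = max((y[-1] - y[0]) / (L[-1] - L[0] + 1e-300), 1.0)
    popt, pcov = curve_fit(
        model, L, y, p0=[slope0, 0.1 * slope0], bounds=(0.0, np.inf), maxfev=20000
    )
    perr = np.sqrt(np.diag(pcov))
    pred = model(L, *popt)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = float(1 - np.sum((y - pred) ** 2) / ss_tot) if ss_tot > 0 else None
    unresolved = bool(1.96 * perr[1] >= popt[1])  # 95% CI includes zero
    if unresolved:
        warnings.warn(
            "static quenching constant not resolved (CI includes 0)",
            FitQualityWarning,
            stacklevel=2,
        )
    return SternVolmerFit(
        k_sv=float(popt[0]),
        k_static=float(popt[1]),
        stderr_sv=float(perr[0]),
        stderr_static=float(perr[1]),
        r_squared=r2,
        static_term=True,
        static_unresolved=unresolved,
    )


def free_energy(
    k_assoc: float, temperature: float = 298.0, gas_constant: float = GAS_CONSTANT_KCAL
) -> float:
    """Standard binding free energy dG = -RT ln K in kcal/mol."""
    if k_assoc <= 0:
        raise DomainError("association constant must be positive")
    if temperature <= 0:
        raise DomainError("temperature must be positive")
    return -gas_constant * temperature * float(np.log(k_assoc))
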