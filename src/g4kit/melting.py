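"""UV-melting analysis with the two-state linear-baseline model.

An intramolecular unfolding equilibrium F <-> U with van't Hoff enthalpy
``dH0`` (J/mol, enthalpy of unfolding, positive) and midpoint ``Tm`` (K) has
equilibrium constant

    K(T) = exp(-dH0 * (1 - T/Tm) / (R*T)),        R = 8.314 J K^-1 mol^-1,

so the folded fraction is theta(T) = 1 / (1 + K(T)), with theta(Tm) = 0.5 by
construction.  The observed absorbance mixes two linear baselines:

    A(T) = (aF*T + bF) * theta(T) + (aU*T + bU) * (1 - theta(T)).

``fit_two_state`` estimates the six parameters (Tm, dH0, aF, bF, aU, bU) by
trust-region non-linear least squares, automating the notoriously imprecise
manual baseline method.  When the data do not contain both baselines the fit
is meaningless; ``normalize_curve`` provides the documented [0, 1] fallback
with no thermodynamic quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.constants import R as GAS_CONSTANT  # 8.314... J K^-1 mol^-1

__all__ = [
    "MeltingCurve",
    "MeltingFit",
    "absorbance_to_epsilon",
    "fit_two_state",
    "folded_fraction",
    "theta_at_25",
    "normalize_curve",
    "two_state_model",
    "read_curve",
]

CELSIUS_OFFSET = 273.15
MIN_POINTS = 20


@dataclass
class MeltingCurve:
    """One UV-melting ramp: absorbance (or epsilon) versus temperature."""

    temperature_C: np.ndarray
    absorbance: np.ndarray
    wavelength_nm: float = 295.0
    ramp: str = "heating"  # heating | cooling
    buffer: str = ""
    oligo: str = ""
    concentration_M: float | None = None
    pathlength_cm: float | None = None
    unit: str = "absorbance"  # absorbance | epsilon | normalized

    def __post_init__(self) -> None:
        self.temperature_C = np.asarray(self.temperature_C, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.temperature_C.size != self.absorbance.size:
            raise ValueError("temperature and absorbance must have equal length")
        d = np.diff(self.temperature_C)
        if self.temperature_C.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("temperature must be strictly monotonic within a ramp")
        if self.ramp not in ("heating", "cooling"):
            raise ValueError(f"ramp must be 'heating' or 'cooling', got {self.ramp!r}")

    @property
    def temperature_K(self) -> np.ndarray:
        return self.temperature_C + CELSIUS_OFFSET


@dataclass
class MeltingFit:
    """Six-parameter two-state fit result.

    ``Tm_K`` and ``dH0_J_mol`` are the thermodynamic parameters (dH0 is the
    enthalpy of unfolding, positive); ``a_F``/``b_F`` and ``a_U``/``b_U`` are
    the folded and unfolded baseline slopes (per K) and intercepts.  Standard
    errors come from the covariance of the least-squares fit; ``converged``
    is False when the optimizer did not meet tolerance, and ``baselines_ok``
    is False when the data did not contain both baselines (in which case the
    [0,1] normalization fallback applies and no thermodynamics are reported).
    """

    Tm_K: float
    dH0_J_mol: float
    a_F: float
    b_F: float
    a_U: float
    b_U: float
    stderr: dict | None = None
    residual_norm: float = float("nan")
    converged: bool = False
    baselines_ok: bool = True
    no_thermodynamics: bool = False

    @property
    def Tm_C(self) -> float:
        return self.Tm_K - CELSIUS_OFFSET

    def as_dict(self) -> dict:
        return {
            "Tm_K": self.Tm_K,
            "Tm_C": self.Tm_C,
            "dH0_J_mol": self.dH0_J_mol,
            "a_F": self.a_F,
            "b_F": self.b_F,
            "a_U": self.a_U,
            "b_U": self.b_U,
            "stderr": self.stderr,
            "residual_norm": self.residual_norm,
            "converged": self.converged,
            "baselines_ok": self.baselines_ok,
            "no_thermodynamics": self.no_thermodynamics,
        }


def absorbance_to_epsilon(curve: MeltingCurve) -> MeltingCurve:
    """Convert absorbance to molar extinction coefficient, eps = A/(l*C)."""
    C, l = curve.concentration_M, curve.pathlength_cm
    if C is None or l is None:
        raise ValueError("concentration and path length are required")
    if not (C > 0 and l > 0):
        raise ValueError("concentration and path length must be > 0")
    return replace(curve, absorbance=curve.absorbance / (l * C), unit="epsilon")


def _theta(T_K: np.ndarray | float, Tm_K: float, dH0: float):
    """Folded fraction of the two-state model; numerically safe exp."""
    arg = -dH0 * (1.0 - np.asarray(T_K, dtype=float) / Tm_K) / (GAS_CONSTANT * np.asarray(T_K, dtype=float))
    arg = np.clip(arg, -700.0, 700.0)
    return 1.0 / (1.0 + np.exp(arg))


def two_state_model(
    T_K: np.ndarray, Tm_K: float, dH0: float, a_F: float, b_F: float, a_U: float, b_U: float
) -> np.ndarray:
    """Evaluate the baseline-mixing model A(T) at temperatures in K."""
    th = _theta(T_K, Tm_K, dH0)
    return (a_F * T_K + b_F) * th + (a_U * T_K + b_U) * (1.0 - th)


def _initial_guess(T_K: np.ndarray, y: np.ndarray) -> dict:
    """Deterministic initialization: Tm from the extremum of a smoothed
    dA/dT, baselines from OLS on the first/last 15% of points."""
    n = T_K.size
    # moving-average smoothing over ~5% of points (odd width >= 3)
    w = max(3, (n // 20) | 1)
    kernel = np.ones(w) / w
    ys = np.convolve(y, kernel, mode="same")
    dy = np.gradient(ys, T_K)
    interior = slice(w, n - w) if n > 2 * w + 2 else slice(None)
    idx = int(np.argmax(np.abs(dy[interior])))
    Tm0 = float(T_K[interior][idx])

    k = max(2, int(round(0.15 * n)))
    lo_c = np.polyfit(T_K[:k], y[:k], 1)
    hi_c = np.polyfit(T_K[-k:], y[-k:], 1)
    # low-T segment is the folded baseline
    return {
        "Tm_K": Tm0,
        "dH0": 200e3,
        "a_F": float(lo_c[0]),
        "b_F": float(lo_c[1]),
        "a_U": float(hi_c[0]),
        "b_U": float(hi_c[1]),
        "n_baseline": k,
    }


def has_both_baselines(curve: MeltingCurve, margin_fraction: float = 0.10) -> bool:
    """Heuristic baseline-presence criterion.

    The transition midpoint (initialization estimate) must not fall within
    ``margin_fraction`` of the temperature span of either extreme, and each
    baseline segment must contain at least 5 points.
    """
    T = np.sort(curve.temperature_K)
    y = curve.absorbance[np.argsort(curve.temperature_K)]
    guess = _initial_guess(T, y)
    span = T[-1] - T[0]
    if guess["n_baseline"] < 5:
        return False
    margin = margin_fraction * span
    return bool(T[0] + margin < guess["Tm_K"] < T[-1] - margin)


def fit_two_state(curve: MeltingCurve, check_baselines: bool = True) -> MeltingFit:
    """Least-squares fit of the six-parameter two-state baseline model.

    Temperatures are handled internally in K.  Non-convergence yields a
    flagged result, not an exception; fewer than 20 points is an error.
    When ``check_baselines`` and the baseline criterion fails, the returned
    fit carries ``baselines_ok=False`` and ``no_thermodynamics=True`` — use
    :func:`normalize_curve` for such data.
    """
    import lmfit

    if curve.temperature_C.size < MIN_POINTS:
        raise ValueError(
            f"need at least {MIN_POINTS} points, got {curve.temperature_C.size}"
        )
    order = np.argsort(curve.temperature_K)
    T = curve.temperature_K[order]
    y = curve.absorbance[order]

    guess = _initial_guess(T, y)
    baselines_ok = True
    if check_baselines:
        baselines_ok = has_both_baselines(curve)

    params = lmfit.Parameters()
    params.add("Tm_K", value=guess["Tm_K"], min=T[0] - 20.0, max=T[-1] + 20.0)
    params.add("dH0", value=guess["dH0"], min=1e3, max=5e6)
    params.add("a_F", value=guess["a_F"])
    params.add("b_F", value=guess["b_F"])
    params.add("a_U", value=guess["a_U"])
    params.add("b_U", value=guess["b_U"])

    def residual(p):
        return two_state_model(
            T, p["Tm_K"], p["dH0"], p["a_F"], p["b_F"], p["a_U"], p["b_U"]
        ) - y

    result = lmfit.minimize(
        residual,
        params,
        method="least_squares",
        xtol=1e-10,
        ftol=1e-10,
        gtol=1e-10,
        max_nfev=5000,
    )
    p = result.params
    stderr = {name: (p[name].stderr if p[name].stderr is not None else float("nan"))
              for name in p}
    return MeltingFit(
        Tm_K=float(p["Tm_K"].value),
        dH0_J_mol=float(p["dH0"].value),
        a_F=float(p["a_F"].value),
        b_F=float(p["b_F"].value),
        a_U=float(p["a_U"].value),
        b_U=float(p["b_U"].value),
        stderr=stderr,
        residual_norm=float(np.sqrt(np.sum(np.asarray(result.residual) ** 2))),
        converged=bool(result.success),
        baselines_ok=baselines_ok,
        no_thermodynamics=not baselines_ok,
    )


def folded_fraction(fit: MeltingFit, T_K: np.ndarray | float):
    """theta(T) of the fitted two-state model; theta(Tm) = 0.5 exactly."""
    if fit.no_thermodynamics:
        raise ValueError("no thermodynamic parameters: baseline criterion failed")
    if np.any(np.asarray(T_K) <= 0):
        raise ValueError("temperature must be > 0 K")
    return _theta(T_K, fit.Tm_K, fit.dH0_J_mol)


def theta_at_25(fit: MeltingFit) -> float:
    """Folded fraction at 25 C (298.15 K), the cross-technique benchmark."""
    return float(folded_fraction(fit, 25.0 + CELSIUS_OFFSET))


def normalize_curve(curve: MeltingCurve) -> MeltingCurve:
    """Min-max normalize a melting curve to [0, 1] (fallback when the data
    lack one of the baselines); no thermodynamic quantities are implied."""
    y = curve.absorbance
    lo, hi = float(np.min(y)), float(np.max(y))
    if hi == lo:
        raise ValueError("constant curve cannot be normalized")
    return replace(curve, absorbance=(y - lo) / (hi - lo), unit="normalized")


def hysteresis(fit_heat: MeltingFit, fit_cool: MeltingFit, threshold_K: float = 1.0) -> bool:
    """Flag heating/cooling hysteresis when |Tm_heat - Tm_cool| > threshold."""
    return abs(fit_heat.Tm_K - fit_cool.Tm_K) > threshold_K


def read_curve(path, **metadata) -> MeltingCurve:
    """Read a two-column (temperature_C, absorbance) CSV/TSV file."""
    from .cd import load_xy_columns

    t, a = load_xy_columns(path)
    return MeltingCurve(t, a, **metadata)
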