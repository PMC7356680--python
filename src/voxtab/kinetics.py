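"""Noyes-Whitney first-order dissolution kinetics.

The dissolution of a solid into a stirred medium follows
dC/dt = (D S / h) (Cs - C), whose solution from C(0) = 0 is
C(t) = Cs (1 - exp(-k t)) with k = D S / h.  Here C is the released
fraction of the dose (% w/v), Cs the plateau/solubility (% w/v), D the
diffusivity (cm^2/s), h the unstirred-layer thickness (cm) and S the
specific surface available for dissolution contact (cm^2/g).

S is the sole fitted coefficient: D, h and Cs are held fixed, so only
the product D*S/h is identifiable and comparisons between fits are
meaningful exactly when D and h are shared.  The ratio of two fitted
surfaces then measures how much dissolution contact area one geometry
loses relative to another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import DegenerateFitError, ValidationError

__all__ = [
    "DEFAULT_DIFFUSIVITY_CM2_S",
    "DEFAULT_UNSTIRRED_LAYER_CM",
    "NWParams",
    "ReleaseProfile",
    "NWFit",
    "nw_release",
    "fit_specific_surface",
    "surface_reduction_ratio",
]

# Literature-typical values for a small-molecule API in aqueous buffer at
# 37 C; placeholders, not measured quantities.  Only D*S/h is identifiable,
# so any fixed choice gives identical ratios and goodness of fit.
DEFAULT_DIFFUSIVITY_CM2_S = 7.0e-6
DEFAULT_UNSTIRRED_LAYER_CM = 30e-4  # 30 um


@dataclass(frozen=True)
class NWParams:
    """Parameters of the first-order dissolution law."""

    Cs: float  # plateau, % of dose
    S: float  # specific surface, cm^2/g
    D: float = DEFAULT_DIFFUSIVITY_CM2_S
    h: float = DEFAULT_UNSTIRRED_LAYER_CM

    def __post_init__(self) -> None:
        for name in ("Cs", "S", "D", "h"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")

    @property
    def rate_constant(self) -> float:
        """k = D S / h, 1/s."""
        return self.D * self.S / self.h


@dataclass
class ReleaseProfile:
    """Cumulative release of one species: % of dose against time (s)."""

    times: np.ndarray
    released: np.ndarray
    species: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.released = np.asarray(self.released, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.released.shape:
            raise ValidationError("times and released must be 1-D and equal length")
        if (self.times < 0).any():
            raise ValidationError("times must be >= 0")
        if not np.all(np.diff(self.times) > 0):
            raise ValidationError("times must be strictly increasing")
        if (self.released < -1e-9).any() or (self.released > 105.0 + 1e-9).any():
            raise ValidationError("released values must lie in [0, 105] (% of dose)")

    def __len__(self) -> int:
        return len(self.times)


def nw_release(t, params: NWParams):
    """Closed-form released fraction C(t) = Cs (1 - exp(-D S t / h))."""
    t = np.asarray(t, dtype=float)
    if (t < 0).any():
        raise ValidationError("t must be >= 0")
    return params.Cs * (1.0 - np.exp(-params.rate_constant * t))


@dataclass
class NWFit:
    """Result of fitting the specific surface to a release profile."""

    S_hat: float  # cm^2/g
    k_hat: float  # D * S_hat / h, 1/s
    r_squared: float
    residuals: np.ndarray
    Cs: float
    D: float
    h: float
    species: str = ""


_LOG10_S_BOUNDS = (-6.0, 8.0)


def fit_specific_surface(
    profile: ReleaseProfile,
    D: float = DEFAULT_DIFFUSIVITY_CM2_S,
    h: float = DEFAULT_UNSTIRRED_LAYER_CM,
    Cs: float = 100.0,
) -> NWFit:
    """Least-squares fit of S, holding D, h and Cs fixed.

    Minimizes sum((C_obs - Cs(1 - exp(-D S t / h)))^2) over S alone by
    bounded scalar minimization on log10(S), which is deterministic and
    insensitive to the scale of S.
    """
    if len(profile) < 3:
        raise ValidationError("need at least 3 time points to fit")
    if np.allclose(profile.released, 0.0):
        raise DegenerateFitError("profile carries no signal (all zero)")
    if profile.released.min() > 0.95 * Cs:
        raise DegenerateFitError(
            "profile is at its plateau over the whole sampled window, so S "
            "is unidentifiable (infinite); sample earlier time points"
        )

    t, c = profile.times, profile.released

    def sse(log10_s: float) -> float:
        k = D * 10.0**log10_s / h
        model = Cs * (1.0 - np.exp(-k * t))
        return float(np.sum((c - model) ** 2))

    res = minimize_scalar(
        sse,
        bounds=_LOG10_S_BOUNDS,
        method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:
        raise DegenerateFitError(f"specific-surface fit did not converge: {res.message}")
    log10_s = float(res.x)
    if log10_s > _LOG10_S_BOUNDS[1] - 0.5:
        raise DegenerateFitError(
            "fit ran into the upper bound for S: the profile is already at "
            "its plateau from t=0, so S is unidentifiable (infinite)"
        )
    s_hat = 10.0**log10_s
    params = NWParams(Cs=Cs, S=s_hat, D=D, h=h)
    residuals = c - nw_release(t, params)
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((c - c.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return NWFit(
        S_hat=s_hat,
        k_hat=params.rate_constant,
        r_squared=r_squared,
        residuals=residuals,
        Cs=Cs,
        D=D,
        h=h,
        species=profile.species,
    )


def surface_reduction_ratio(fit_reference: NWFit, fit_test: NWFit) -> float:
    """Ratio S_ref / S_test of two fits sharing the same fixed D, h, Cs.

    A ratio above 1 means the test geometry exposes less dissolution
    contact surface than the reference.
    """
    for attr in ("D", "h", "Cs"):
        a, b = getattr(fit_reference, attr), getattr(fit_test, attr)
        if not np.isclose(a, b, rtol=1e-12):
            raise ValidationError(
                f"fits were made with different fixed {attr}: {a} vs {b}; "
                "the surface ratio is not comparable"
            )
    return fit_reference.S_hat / fit_test.S_hat
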