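"""Deterministic mathematical core of the EPA-growth analysis.

Juvenile somatic growth of *Daphnia* on an EPA-supplemented diet is modelled
with a Monod-like (hyperbolic) saturation function with a shift parameter:

    g(S) = g0 + (ginf - g0) * S / (S + KS)

where ``g0`` is the growth rate without EPA supplementation (day^-1),
``ginf`` the asymptotic rate at saturating EPA (day^-1), ``S`` the dietary
EPA concentration (ug EPA mg C^-1) and ``KS`` the half-saturation constant
(ug EPA mg C^-1).  The half-saturation constant may itself depend linearly
on body size at first reproduction, ``KS(L) = K0 + KL * L``.

All functions here are pure and accept scalars or numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MonodParams",
    "SizeLaw",
    "juvenile_growth_rate",
    "monod_growth",
    "saturation_threshold",
    "ks_from_size",
    "arcsin_sqrt_transform",
    "inverse_arcsin_sqrt_transform",
]


@dataclass(frozen=True)
class MonodParams:
    """Parameters of the saturating growth response of one clone (or the
    population): baseline ``g0``, asymptote ``ginf`` (both day^-1) and
    half-saturation constant ``KS`` (ug EPA mg C^-1)."""

    g0: float
    ginf: float
    KS: float

    def validate(self) -> None:
        if not self.KS > 0:
            raise ValueError(f"KS must be positive, got {self.KS}")
        if self.ginf < self.g0:
            raise ValueError(
                f"ginf ({self.ginf}) must not be below g0 ({self.g0}) "
                "for a saturating increase"
            )


@dataclass(frozen=True)
class SizeLaw:
    """Linear body-size dependence of the half-saturation constant,
    ``KS = K0 + KL * L`` with ``L`` in mm."""

    K0: float
    KL: float

    def validate_over(self, body_sizes) -> None:
        ks = self.K0 + self.KL * np.asarray(body_sizes, dtype=float)
        if np.any(ks <= 0):
            bad = np.asarray(body_sizes, dtype=float)[ks <= 0]
            raise ValueError(
                f"size law K0={self.K0}, KL={self.KL} yields non-positive "
                f"KS at body size(s) {bad.tolist()}"
            )


def juvenile_growth_rate(mass_initial, mass_final, duration):
    """Mass-specific juvenile growth rate g = (ln Wt - ln W0) / t.

    Parameters
    ----------
    mass_initial, mass_final
        Individual dry masses W0 and Wt (ug dwt), strictly positive.
    duration
        Experiment duration t in days, strictly positive.

    Returns
    -------
    Growth rate in day^-1; negative values indicate mass loss.
    """
    w0 = np.asarray(mass_initial, dtype=float)
    wt = np.asarray(mass_final, dtype=float)
    t = np.asarray(duration, dtype=float)
    if np.any(w0 <= 0) or np.any(wt <= 0):
        raise ValueError("dry masses must be strictly positive")
    if np.any(t <= 0):
        raise ValueError("duration must be strictly positive")
    out = (np.log(wt) - np.log(w0)) / t
    return out.item() if out.ndim == 0 else out


def monod_growth(S, params: MonodParams):
    """Monod-like growth response g0 + (ginf - g0) * S / (S + KS).

    ``S`` is the dietary EPA concentration (ug EPA mg C^-1, >= 0).
    Strictly increasing and concave in S for ginf > g0, bounded in
    [g0, ginf).
    """
    s = np.asarray(S, dtype=float)
    if np.any(s < 0):
        raise ValueError("EPA concentration S must be non-negative")
    out = params.g0 + (params.ginf - params.g0) * s / (s + params.KS)
    return out.item() if out.ndim == 0 else out


def saturation_threshold(KS, p_frac):
    """EPA concentration at which growth reaches the fraction ``p_frac`` of
    its asymptotic increment above baseline.

    Solving g(S) - g0 = p_frac * (ginf - g0) for the Monod response gives

        S_p = KS * p_frac / (1 - p_frac),

    independent of g0 and ginf.  At p_frac = 0.5 this is KS itself; at
    p_frac = 0.75 it is exactly 3 * KS.  Diverges as p_frac -> 1.
    """
    ks = np.asarray(KS, dtype=float)
    if np.any(ks <= 0):
        raise ValueError("KS must be positive")
    p = np.asarray(p_frac, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("p_frac must lie strictly between 0 and 1")
    out = ks * p / (1.0 - p)
    return out.item() if out.ndim == 0 else out


def ks_from_size(law: SizeLaw, L):
    """Half-saturation constant implied by the size law, K0 + KL * L.

    Raises if the result is not strictly positive (an invalid parameter
    combination for the body size supplied).
    """
    l_arr = np.asarray(L, dtype=float)
    out = law.K0 + law.KL * l_arr
    if np.any(out <= 0):
        raise ValueError(
            f"size law gives non-positive KS ({out!r}) at L={L!r}"
        )
    return out.item() if out.ndim == 0 else out


def arcsin_sqrt_transform(c):
    """Variance-stabilising transform c' = 2 arcsin(sqrt(c)) / pi.

    Maps [0, 1] onto [0, 1] with fixed points 0, 1/2 and 1; strictly
    increasing.  Used on clutch sizes after rescaling them into [0, 1].
    """
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr < 0) or np.any(c_arr > 1):
        raise ValueError("arcsin-sqrt transform requires values in [0, 1]")
    out = 2.0 * np.arcsin(np.sqrt(c_arr)) / np.pi
    return out.item() if out.ndim == 0 else out


def inverse_arcsin_sqrt_transform(cprime):
    """Inverse of :func:`arcsin_sqrt_transform`: c = sin(pi * c' / 2)^2."""
    cp = np.asarray(cprime, dtype=float)
    if np.any(cp < 0) or np.any(cp > 1):
        raise ValueError("inverse transform requires values in [0, 1]")
    out = np.sin(np.pi * cp / 2.0) ** 2
    return out.item() if out.ndim == 0 else out
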