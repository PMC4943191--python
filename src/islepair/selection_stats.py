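"""Selection-efficiency and adaptive-evolution statistics.

Undefined values (zero denominators) propagate as ``None`` rather than zero,
so that downstream paired analyses can exclude them and report honest sample
sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "SelectionSummary",
    "pn_fraction",
    "dn_fraction",
    "dos",
    "ne_proxy",
    "ne_ratio_from_omega",
    "DEFAULT_GAMMA_SHAPE",
]

#: Default gamma-DFE shape parameter for the omega-ratio -> Ne-ratio conversion.
DEFAULT_GAMMA_SHAPE = 0.5


@dataclass(frozen=True)
class SelectionSummary:
    """Per-lineage selection statistics; ``None`` marks undefined values."""

    pn_fraction: float | None
    dn_fraction: float | None
    dos: float | None
    ne_proxy: float | None
    beta: float = DEFAULT_GAMMA_SHAPE


def _fraction(numer: float, denom_other: float, name: str) -> float | None:
    if numer < 0 or denom_other < 0:
        raise ValueError(f"{name} requires nonnegative inputs, got ({numer}, {denom_other})")
    total = numer + denom_other
    if total == 0:
        return None
    return numer / total


def pn_fraction(pi_N: float, pi_S: float) -> float | None:
    """pi_N / (pi_N + pi_S); ``None`` when both diversities are zero."""
    return _fraction(pi_N, pi_S, "pn_fraction")


def dn_fraction(dN: float, dS: float) -> float | None:
    """dN / (dN + dS); ``None`` when both divergences are zero."""
    return _fraction(dN, dS, "dn_fraction")


def dos(dN: float, dS: float, pi_N: float, pi_S: float) -> float | None:
    """Direction-of-selection statistic dN/(dN+dS) - piN/(piN+piS).

    Positive values indicate a predominance of positive selection; negative
    values a predominance of segregating slightly deleterious mutations.
    Undefined (``None``) unless there is at least one substitution and one
    polymorphism.
    """
    d = dn_fraction(dN, dS)
    p = pn_fraction(pi_N, pi_S)
    if d is None or p is None:
        return None
    return d - p


def ne_proxy(pi_S: float, d_S: float) -> float | None:
    """Effective-population-size proxy pi_S / d_S.

    Uses synonymous divergence as a mutation-rate surrogate; comparable only
    between the members of one comparison.  ``None`` when d_S is zero.
    """
    if pi_S < 0 or d_S < 0:
        raise ValueError(f"ne_proxy requires nonnegative inputs, got ({pi_S}, {d_S})")
    if d_S == 0:
        return None
    return pi_S / d_S


def ne_ratio_from_omega(omega_ratio: float, beta: float = DEFAULT_GAMMA_SHAPE) -> float:
    """Invert omega1/omega2 = (N1/N2)^(-beta) for the Ne ratio N1/N2.

    Under a gamma-distributed DFE with shape ``beta``, an observed ratio of
    omega values implies ``N1/N2 = (omega1/omega2)^(-1/beta)``.
    """
    if omega_ratio <= 0:
        raise ValueError(f"omega_ratio must be positive, got {omega_ratio}")
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    return omega_ratio ** (-1.0 / beta)
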