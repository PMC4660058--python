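"""Closed-form kinetics of the barbed-end / formin / capping-protein cycle.

An actin filament barbed end (``B``) can be occupied by a processive formin
(``BF``), by heterodimeric capping protein (``BC``), or by both proteins at
once in a ternary complex (``BFC``).  Association steps are bimolecular
(rates in µM⁻¹·s⁻¹, concentrations in µM); dissociation steps are
unimolecular (s⁻¹).  Primed rate constants refer to a barbed end that is
already occupied by the *other* protein::

        B + F  <-- k+F / k-F  -->  BF
        B + C  <-- k+C / k-C  -->  BC
        BF + C <-- k'+C / k'-C --> BFC
        BC + F <-- k'+F / k'-F --> BFC

The ternary complex decays with overall rate ``k'-C + k'-F`` and partitions
between its two products in proportion to the branch rates: a fraction
``k'-C / (k'-C + k'-F)`` loses CP and resumes fast formin-driven elongation
(BF), the remainder loses formin and stays capped (BC).  All closed-form
expressions used by the simulator and the inference chain live here:
exponential survival/appearance curves of the ternary complex, the plateau
equation for formin titrations on capped filaments, pseudo-first-order
observed rates, equilibrium dissociation constants and the
detailed-balance (thermodynamic cycle) ratio.

Unit convention: concentrations are µM everywhere in computation;
equilibrium dissociation constants are *reported* in nM, matching how
they are conventionally tabulated.  This asymmetry is deliberate — it
avoids silent thousand-fold errors when comparing against published
affinities.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from enum import Enum
from typing import Union

import numpy as np

__all__ = [
    "BarbedEndState",
    "RateSet",
    "EquilibriumSet",
    "bfc_survival",
    "partition_fractions",
    "bf_cdf",
    "bc_cdf",
    "plateau_fraction",
    "pseudo_first_order_kobs",
    "equilibrium_Kd",
    "detailed_balance_ratio",
    "fold_change",
]

ArrayLike = Union[float, np.ndarray]


class BarbedEndState(Enum):
    """Occupancy state of a single filament barbed end.

    ``BFC`` denotes the ternary complex irrespective of assembly order:
    the complex formed by capping a formin-bound end (B → BF → BFC) is
    kinetically equivalent to the one formed by formin binding a capped
    end (B → BC → BCF), so both orders map onto the single ``BFC``
    label.  The order of formation, where wanted for bookkeeping, is
    recoverable from a trace's transition history
    (:meth:`~bfckinetics.simulator.FilamentTrace.ternary_formation_order`);
    it never enters any rate computation.
    """

    B = "B"
    BC = "BC"
    BF = "BF"
    BFC = "BFC"

    @property
    def has_formin(self) -> bool:
        return self in (BarbedEndState.BF, BarbedEndState.BFC)

    @property
    def has_cp(self) -> bool:
        return self in (BarbedEndState.BC, BarbedEndState.BFC)

    @property
    def is_capped(self) -> bool:
        """CP arrests elongation whenever it is bound, including in BFC."""
        return self.has_cp

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def _require_positive(name: str, value: float) -> None:
    if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
        raise ValueError(f"{name} must be a finite positive number, got {value!r}")


def _require_nonnegative(name: str, value: ArrayLike) -> None:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr < 0):
        raise ValueError(f"{name} must be finite and non-negative, got {value!r}")


@dataclass(frozen=True)
class RateSet:
    """The eight rate constants of the cycle for one formin species.

    Association constants (``k_plus_*``, ``k_prime_plus_*``) are in
    µM⁻¹·s⁻¹, dissociation constants (``k_minus_*``, ``k_prime_minus_*``)
    in s⁻¹.  Primed constants describe binding to / release from a barbed
    end already occupied by the other protein.
    """

    k_plus_C: float
    k_minus_C: float
    k_prime_plus_C: float
    k_prime_minus_C: float
    k_plus_F: float
    k_minus_F: float
    k_prime_plus_F: float
    k_prime_minus_F: float
    formin_name: str = "formin"

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if f.name == "formin_name":
                continue
            _require_positive(f.name, getattr(self, f.name))

    def replace(self, **changes) -> "RateSet":
        """Return a copy with the given rate constants replaced."""
        return dataclasses.replace(self, **changes)

    def equilibria(self) -> "EquilibriumSet":
        """Equilibrium dissociation constants (nM) implied by the rates."""
        return EquilibriumSet(
            K_C=equilibrium_Kd(self.k_minus_C, self.k_plus_C),
            K_prime_C=equilibrium_Kd(self.k_prime_minus_C, self.k_prime_plus_C),
            K_F=equilibrium_Kd(self.k_minus_F, self.k_plus_F),
            K_prime_F=equilibrium_Kd(self.k_prime_minus_F, self.k_prime_plus_F),
        )


@dataclass(frozen=True)
class EquilibriumSet:
    """Equilibrium dissociation constants of the cycle, all in nM."""

    K_C: float
    K_prime_C: float
    K_F: float
    K_prime_F: float

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            _require_positive(f.name, getattr(self, f.name))


def _check_branch_rates(k_prime_minus_C: float, k_prime_minus_F: float) -> None:
    _require_positive("k_prime_minus_C", k_prime_minus_C)
    _require_positive("k_prime_minus_F", k_prime_minus_F)


def bfc_survival(t: ArrayLike, k_prime_minus_C: float, k_prime_minus_F: float) -> ArrayLike:
    """Fraction of ternary complexes still intact after time ``t``.

    The ternary complex decays through two parallel first-order channels
    (loss of CP at ``k'-C``, loss of formin at ``k'-F``), so its survival
    is a single exponential with the *sum* of the branch rates:
    ``exp(-(k'-C + k'-F) * t)``.

    Parameters
    ----------
    t : float or array
        Time since removal of free proteins, seconds.  Must be >= 0.
    k_prime_minus_C, k_prime_minus_F : float
        Branch dissociation rates, s⁻¹.  Must be > 0.
    """
    _check_branch_rates(k_prime_minus_C, k_prime_minus_F)
    _require_nonnegative("t", t)
    out = np.exp(-(k_prime_minus_C + k_prime_minus_F) * np.asarray(t, dtype=float))
    return float(out) if np.isscalar(t) or np.ndim(t) == 0 else out


def partition_fractions(k_prime_minus_C: float, k_prime_minus_F: float) -> tuple[float, float]:
    """Branch fractions of ternary-complex decay, ``(f_BF, f_BC)``.

    ``f_BF = k'-C / (k'-C + k'-F)`` is the probability that the complex
    resolves by losing CP (the filament resumes fast processive growth);
    ``f_BC`` is the complement (formin is lost, the end stays capped).
    The two fractions sum to exactly 1.
    """
    _check_branch_rates(k_prime_minus_C, k_prime_minus_F)
    total = k_prime_minus_C + k_prime_minus_F
    f_bf = k_prime_minus_C / total
    return f_bf, 1.0 - f_bf


def bf_cdf(t: ArrayLike, k_prime_minus_C: float, k_prime_minus_F: float) -> ArrayLike:
    """Cumulative fraction of filaments that have resolved BFC → BF by ``t``.

    Equals ``f_BF * (1 - exp(-(k'-C + k'-F) t))``: it rises from 0 with
    the overall decay rate and plateaus at the BF branch fraction.
    """
    f_bf, _ = partition_fractions(k_prime_minus_C, k_prime_minus_F)
    surv = bfc_survival(t, k_prime_minus_C, k_prime_minus_F)
    return f_bf * (1.0 - surv)


def bc_cdf(t: ArrayLike, k_prime_minus_C: float, k_prime_minus_F: float) -> ArrayLike:
    """Cumulative fraction of filaments that have resolved BFC → BC by ``t``."""
    _, f_bc = partition_fractions(k_prime_minus_C, k_prime_minus_F)
    surv = bfc_survival(t, k_prime_minus_C, k_prime_minus_F)
    return f_bc * (1.0 - surv)


def plateau_fraction(
    F_conc: float,
    T_expo: float,
    k_prime_plus_F: float,
    k_prime_minus_C: float,
    k_prime_minus_F: float,
) -> float:
    """Final BF fraction after a transient formin exposure of capped filaments.

    Capped (BC) filaments exposed to formin at concentration ``[F]`` for a
    time ``T_expo`` convert to the ternary complex with pseudo-first-order
    rate ``k'+F · [F]``; after washout and re-exposure to profilin–actin
    the ternary complexes partition, so the fraction of the initial capped
    population that ends up elongating fast plateaus at::

        (1 - exp(-k'+F [F] T_expo)) * k'-C / (k'-C + k'-F)

    The expression neglects spontaneous uncapping (BC → B) and
    ternary-complex resolution during the exposure itself, which is
    accurate when ``T_expo`` is short compared with 1/(k'-C + k'-F).
    """
    _check_branch_rates(k_prime_minus_C, k_prime_minus_F)
    _require_positive("k_prime_plus_F", k_prime_plus_F)
    _require_nonnegative("F_conc", F_conc)
    _require_nonnegative("T_expo", T_expo)
    f_bf, _ = partition_fractions(k_prime_minus_C, k_prime_minus_F)
    converted = -np.expm1(-k_prime_plus_F * F_conc * T_expo)
    return float(converted * f_bf)


def pseudo_first_order_kobs(k_on: float, conc: float) -> float:
    """Observed pseudo-first-order rate ``k_obs = k_on · [X]`` (s⁻¹).

    ``k_on`` in µM⁻¹·s⁻¹, ``conc`` in µM.  Linear and homogeneous in the
    concentration; this is the quantity an exponential fit to a
    switching-time CDF estimates when binding is a simple bimolecular
    reaction.
    """
    _require_positive("k_on", k_on)
    _require_nonnegative("conc", conc)
    return k_on * conc


def equilibrium_Kd(k_off: float, k_on: float) -> float:
    """Equilibrium dissociation constant in nM from ``k_off`` (s⁻¹) and ``k_on`` (µM⁻¹·s⁻¹).

    ``Kd = k_off / k_on`` is in µM; the factor 1000 converts to nM.
    Homogeneous of degree zero: scaling both rates by the same factor
    leaves the affinity unchanged.
    """
    _require_positive("k_off", k_off)
    _require_positive("k_on", k_on)
    return 1000.0 * k_off / k_on


def detailed_balance_ratio(eq: EquilibriumSet) -> float:
    """Thermodynamic-cycle closure ratio ``(K_C · K'_F) / (K_F · K'_C)``.

    Around the four-state cycle B ↔ BF ↔ BFC ↔ BC ↔ B detailed balance
    requires the product of dissociation constants along the two paths to
    the ternary complex to agree; the ratio is exactly 1 for a perfectly
    balanced cycle.  Values within roughly a factor of two of unity are
    what measured rate constants with independent errors typically
    achieve.
    """
    return (eq.K_C * eq.K_prime_F) / (eq.K_F * eq.K_prime_C)


def fold_change(a: float, b: float, rounding: str = "none") -> float:
    """Ratio ``a / b`` with optional rounding for reporting.

    ``rounding`` is one of ``"none"``, ``"nearest_int"``, ``"nearest_ten"``.
    An explicit rounding mode is exposed because fold-change comparisons
    are quoted at different precisions in different contexts.
    """
    _require_positive("a", a)
    _require_positive("b", b)
    ratio = a / b
    if rounding == "none":
        return ratio
    if rounding == "nearest_int":
        return float(round(ratio))
    if rounding == "nearest_ten":
        return float(10 * round(ratio / 10))
    raise ValueError(f"unknown rounding mode {rounding!r}")
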