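"""Rate-constant inference from per-filament switching-time tables.

The estimation chain mirrors how single-filament microfluidics data are
analysed in practice:

1. :func:`build_cdf` — empirical cumulative distribution of switching
   times for one condition, with explicit right-censoring (every
   monitored filament is counted, so a CDF normalized ``by_total``
   plateaus below 1 when some filaments never switch or switch the other
   way).
2. :func:`fit_single_exponential` — least-squares fit of
   ``A·(1 − e^{−k_obs·t})`` to the CDF steps, amplitude free or fixed.
3. :func:`fit_association_rate` — weighted linear regression of ``k_obs``
   versus concentration (through the origin by default) giving a
   bimolecular association constant in µM⁻¹·s⁻¹.
4. :func:`split_branch_rates` — decomposition of an overall ternary-complex
   decay rate into its two branch rates using the observed branch
   fraction, ``k'-C = f_BF·k_obs`` and ``k'-F = (1−f_BF)·k_obs``, with
   first-order (delta-method) error propagation.
5. :func:`fit_plateau_surface` — weighted fit of the exposure-titration
   plateau equation ``p = (1 − e^{−k'+F·[F]·T}) · f_BF`` over a grid of
   formin concentrations × exposure times.
6. :func:`bootstrap_se` — nonparametric bootstrap standard errors,
   resampling *filaments* (the independent experimental unit), not
   individual time points.

Fitting default: unweighted least squares on the CDF step values at the
event times.  A censored-likelihood alternative (``method="mle"``) is
provided for cross-checking; for well-sampled exponentials the two agree
closely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "CdfDataset",
    "FitResult",
    "build_cdf",
    "fit_single_exponential",
    "fit_association_rate",
    "split_branch_rates",
    "fit_plateau_surface",
    "bootstrap_se",
]


@dataclass
class FitResult:
    """Point estimates with uncertainties and fit diagnostics.

    ``params``/``stderr`` are keyed by parameter name; units follow the
    package convention (s⁻¹ for rates, µM⁻¹·s⁻¹ for association
    constants, dimensionless fractions).  Estimates should only be
    consumed when ``converged`` is true.
    """

    params: dict = field(default_factory=dict)
    stderr: dict = field(default_factory=dict)
    n_used: int = 0
    model_name: str = ""
    rss: Optional[float] = None
    converged: bool = True

    def __post_init__(self) -> None:
        for name, se in self.stderr.items():
            if np.isfinite(se) and se < 0:
                raise ValueError(f"standard error for {name} must be >= 0")

    def __getitem__(self, key: str) -> float:
        return self.params[key]


@dataclass
class CdfDataset:
    """Empirical switching-time CDF for one condition.

    ``times`` are the sorted uncensored event times (s); ``censored_times``
    the observation-window ends of filaments that showed no qualifying
    event.  ``n_total = len(times) + n_censored`` always, because every
    monitored filament is counted.
    """

    condition_label: str
    times: np.ndarray
    n_total: int
    n_censored: int
    censored_times: np.ndarray = field(default_factory=lambda: np.array([]))
    normalization: str = "by_total"

    def __post_init__(self) -> None:
        self.times = np.sort(np.asarray(self.times, dtype=float))
        self.censored_times = np.asarray(self.censored_times, dtype=float)
        if np.any(self.times < 0) or np.any(self.censored_times < 0):
            raise ValueError("switching times must be non-negative")
        if self.n_total != len(self.times) + self.n_censored:
            raise ValueError(
                "n_total must equal number of event times plus number censored"
            )
        if self.normalization not in ("by_total", "by_responders"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    @property
    def _denominator(self) -> int:
        return self.n_total if self.normalization == "by_total" else max(len(self.times), 1)

    def step_values(self) -> np.ndarray:
        """CDF value attained *at* each sorted event time (i/denominator)."""
        return np.arange(1, len(self.times) + 1) / self._denominator

    def evaluate(self, t) -> Union[float, np.ndarray]:
        """Right-continuous step function: fraction switched by time ``t``."""
        t_arr = np.asarray(t, dtype=float)
        vals = np.searchsorted(self.times, t_arr, side="right") / self._denominator
        return float(vals) if np.ndim(t) == 0 else vals


def build_cdf(
    events: pd.DataFrame,
    condition_label: Optional[str] = None,
    event_type: Optional[Union[str, Sequence[str]]] = None,
    normalization: str = "by_total",
) -> CdfDataset:
    """Empirical CDF from switching-event rows.

    Filters the event table to one condition (if given) and to the event
    types of interest (default: any uncensored event), takes the *first*
    qualifying event per filament, and counts every other monitored
    filament as censored at its observation-window end.  ``by_total``
    divides by all monitored filaments (the convention when 100% of the
    filaments in the field of view are counted); ``by_responders``
    rescales so the CDF plateaus at 1.
    """
    df = events
    if condition_label is not None:
        df = df[df["condition_label"] == condition_label]
    if len(df) == 0:
        raise ValueError(f"no rows for condition {condition_label!r}")
    n_total = int(df["filament_id"].nunique())

    ev = df[~df["censored"].astype(bool)]
    if event_type is not None:
        wanted = {event_type} if isinstance(event_type, str) else set(event_type)
        ev = ev[ev["event_type"].isin(wanted)]
    first = (
        ev.sort_values("time_s", kind="stable").groupby("filament_id", sort=True)["time_s"].first()
    )
    times = first.to_numpy(dtype=float)

    responders = set(first.index)
    others = df[~df["filament_id"].isin(responders)]
    # censor non-responders at the latest time they were observed in this table
    censored_times = others.groupby("filament_id")["time_s"].max().to_numpy(dtype=float)

    label = condition_label if condition_label is not None else "all"
    return CdfDataset(
        condition_label=label,
        times=times,
        n_total=n_total,
        n_censored=n_total - len(times),
        censored_times=censored_times,
        normalization=normalization,
    )


def _exp_model(t, k, amplitude):
    return amplitude * -np.expm1(-k * t)


def fit_single_exponential(
    cdf: CdfDataset,
    fix_amplitude: Optional[float] = None,
    method: str = "ls",
    min_events: int = 5,
    grid_points: int = 200,
) -> FitResult:
    """Fit ``A·(1 − e^{−k_obs t})`` to a switching-time CDF.

    ``fix_amplitude`` pins the plateau (use 1.0 when every filament is
    known to switch); otherwise the amplitude is free, which is the
    appropriate choice when the CDF plateaus at a branch fraction.
    ``method="ls"`` (default) performs least squares on the empirical
    CDF evaluated on a uniform time grid spanning the whole observation
    window (``grid_points`` points) — i.e. it fits the *plotted* curve,
    plateau included, which avoids the small-sample bias of fitting only
    the top-of-step values at the event times.  ``method="mle"``
    maximizes the censored exponential likelihood of the waiting times
    themselves (amplitude is then taken as fixed at 1, i.e. all
    filaments eventually switch).

    Non-convergence is reported via ``converged=False`` with no usable
    estimates rather than by raising.
    """
    m = len(cdf.times)
    if m < min_events:
        raise ValueError(f"need at least {min_events} events, got {m}")

    if method == "mle":
        total_time = float(cdf.times.sum() + cdf.censored_times.sum())
        if total_time <= 0:
            return FitResult(model_name="exponential_mle", n_used=m, converged=False)
        k = m / total_time
        return FitResult(
            params={"k_obs": k, "amplitude": 1.0},
            stderr={"k_obs": k / math.sqrt(m), "amplitude": 0.0},
            n_used=m,
            model_name="exponential_mle",
            converged=True,
        )
    if method != "ls":
        raise ValueError(f"unknown fitting method {method!r}")

    # fit the curve as plotted: the empirical step function over the whole
    # observation window, including the post-rise plateau
    t_end = float(max(cdf.times.max(), cdf.censored_times.max() if len(cdf.censored_times) else 0.0))
    t = np.linspace(0.0, t_end, int(grid_points))
    y = cdf.evaluate(t)
    mean_t = float(np.mean(cdf.times))
    k0 = 1.0 / mean_t if mean_t > 0 else 1.0
    try:
        if fix_amplitude is not None:
            popt, pcov = curve_fit(
                lambda tt, k: _exp_model(tt, k, fix_amplitude),
                t,
                y,
                p0=[k0],
                bounds=(1e-12, np.inf),
                maxfev=10000,
            )
            k, a = float(popt[0]), float(fix_amplitude)
            se_k, se_a = float(np.sqrt(pcov[0, 0])), 0.0
        else:
            popt, pcov = curve_fit(
                _exp_model,
                t,
                y,
                p0=[k0, min(max(y.max(), 1e-6), 1.0)],
                bounds=([1e-12, 1e-9], [np.inf, 1.5]),
                maxfev=10000,
            )
            k, a = float(popt[0]), float(popt[1])
            se_k, se_a = (float(x) for x in np.sqrt(np.diag(pcov)))
    except RuntimeError:
        return FitResult(model_name="exponential_cdf_ls", n_used=m, converged=False)

    resid = _exp_model(t, k, a) - y
    return FitResult(
        params={"k_obs": k, "amplitude": a},
        stderr={"k_obs": se_k, "amplitude": se_a},
        n_used=m,
        model_name="exponential_cdf_ls",
        rss=float(np.sum(resid**2)),
        converged=True,
    )


def fit_association_rate(
    pairs: Iterable[Sequence[float]],
    through_origin: bool = True,
) -> FitResult:
    """Bimolecular association constant from ``k_obs`` versus concentration.

    ``pairs`` holds ``(conc_uM, k_obs)`` or ``(conc_uM, k_obs, se)``
    tuples.  Points with standard errors are weighted by 1/se²;
    otherwise the regression is unweighted.  The regression passes
    through the origin by default — at the concentrations where pseudo-
    first-order rates are measurable, the dissociation contribution to
    the intercept is orders of magnitude below ``k_obs`` — with a
    free-intercept option for checking that assumption.
    """
    rows = [tuple(p) for p in pairs]
    x = np.array([r[0] for r in rows], dtype=float)
    y = np.array([r[1] for r in rows], dtype=float)
    se = np.array([r[2] if len(r) > 2 else np.nan for r in rows], dtype=float)
    n_distinct = len(np.unique(x))
    if not through_origin and n_distinct < 2:
        raise ValueError("free-intercept regression needs >= 2 distinct concentrations")
    if len(x) < 1:
        raise ValueError("no data points")

    if np.all(np.isfinite(se)) and np.all(se > 0):
        w = 1.0 / se**2
        weighted = True
    else:
        w = np.ones_like(x)
        weighted = False

    if through_origin:
        sxx = float(np.sum(w * x * x))
        if sxx <= 0:
            raise ValueError("all concentrations are zero")
        slope = float(np.sum(w * x * y)) / sxx
        if weighted:
            var = 1.0 / sxx
        else:
            dof = max(len(x) - 1, 1)
            var = float(np.sum((y - slope * x) ** 2)) / dof / sxx
        resid = y - slope * x
        return FitResult(
            params={"k_on": slope},
            stderr={"k_on": math.sqrt(var)},
            n_used=len(x),
            model_name="kobs_vs_conc_through_origin",
            rss=float(np.sum(w * resid**2)),
        )

    coeffs, cov = np.polyfit(x, y, 1, w=np.sqrt(w), cov="unscaled" if weighted else True)
    slope, intercept = (float(c) for c in coeffs)
    se_slope, se_int = (float(s) for s in np.sqrt(np.diag(cov)))
    resid = y - (slope * x + intercept)
    return FitResult(
        params={"k_on": slope, "intercept": intercept},
        stderr={"k_on": se_slope, "intercept": se_int},
        n_used=len(x),
        model_name="kobs_vs_conc_free_intercept",
        rss=float(np.sum(w * resid**2)),
    )


def split_branch_rates(
    k_obs: float,
    f_BF: float,
    k_obs_se: float = 0.0,
    f_BF_se: float = 0.0,
) -> FitResult:
    """Split an overall ternary-complex decay rate into its two branches.

    Given the fitted overall rate ``k_obs = k'-C + k'-F`` and the
    observed fraction ``f_BF`` of filaments resolving to the fast-growing
    BF state, the branch rates are ``k'-C = f_BF·k_obs`` and
    ``k'-F = (1 − f_BF)·k_obs`` (their ratio equals the ratio of final
    populations, N_BF/N_BC).  Errors propagate to first order assuming
    independent inputs.  The outputs sum to ``k_obs`` exactly.
    """
    if not (0.0 < f_BF < 1.0):
        raise ValueError(f"f_BF must lie strictly inside (0, 1), got {f_BF}")
    if k_obs <= 0:
        raise ValueError(f"k_obs must be positive, got {k_obs}")
    k_c = f_BF * k_obs
    k_f = k_obs - k_c  # guarantees the two branches sum exactly to k_obs
    se_c = math.hypot(f_BF * k_obs_se, k_obs * f_BF_se)
    se_f = math.hypot((1.0 - f_BF) * k_obs_se, k_obs * f_BF_se)
    return FitResult(
        params={"k_prime_minus_C": k_c, "k_prime_minus_F": k_f},
        stderr={"k_prime_minus_C": se_c, "k_prime_minus_F": se_f},
        n_used=1,
        model_name="branch_rate_split",
    )


def fit_plateau_surface(
    grid: Iterable[Sequence[float]],
    fix_f_BF: Optional[float] = None,
) -> FitResult:
    """Fit the exposure-titration plateau equation over an ([F], T_expo) grid.

    ``grid`` rows are ``(F_conc_uM, T_expo_s, plateau)`` or
    ``(F_conc_uM, T_expo_s, plateau, se)``.  The model
    ``p = (1 − e^{−k'+F·[F]·T}) · f_BF`` has two parameters: the
    association constant of formin to capped ends (µM⁻¹·s⁻¹) and the BF
    branch fraction (bounded to (0, 1]).  Fixing ``f_BF = 1`` reduces the
    model to a plain single-exponential saturation in the dose ``[F]·T``.
    Needs at least three grid points spanning at least two distinct
    ``[F]·T`` products; an all-zero response is reported as
    non-converged.
    """
    rows = [tuple(r) for r in grid]
    if len(rows) < 3:
        raise ValueError("need at least 3 grid points")
    F = np.array([r[0] for r in rows], dtype=float)
    T = np.array([r[1] for r in rows], dtype=float)
    p = np.array([r[2] for r in rows], dtype=float)
    se = np.array([r[3] if len(r) > 3 else np.nan for r in rows], dtype=float)
    dose = F * T
    if len(np.unique(np.round(dose, 12))) < 2:
        raise ValueError("degenerate grid: need >= 2 distinct [F]*T_expo products")
    if np.max(p) <= 0:
        return FitResult(model_name="plateau_surface", n_used=len(rows), converged=False)

    sigma = se if np.all(np.isfinite(se)) and np.all(se > 0) else None

    if fix_f_BF is not None:
        if not (0.0 < fix_f_BF <= 1.0):
            raise ValueError("fix_f_BF must lie in (0, 1]")

        def model(d, k):
            return fix_f_BF * -np.expm1(-k * d)

        p0 = [1.0]
        bounds = (1e-9, np.inf)
    else:

        def model(d, k, f_bf):
            return f_bf * -np.expm1(-k * d)

        p0 = [1.0, min(max(float(np.max(p)), 0.05), 0.99)]
        bounds = ([1e-9, 1e-6], [np.inf, 1.0])

    try:
        popt, pcov = curve_fit(
            model, dose, p, p0=p0, sigma=sigma, absolute_sigma=sigma is not None,
            bounds=bounds, maxfev=20000,
        )
    except RuntimeError:
        return FitResult(model_name="plateau_surface", n_used=len(rows), converged=False)

    perr = np.sqrt(np.diag(pcov))
    params = {"k_prime_plus_F": float(popt[0])}
    stderr = {"k_prime_plus_F": float(perr[0])}
    if fix_f_BF is None:
        params["f_BF"] = float(popt[1])
        stderr["f_BF"] = float(perr[1])
    else:
        params["f_BF"] = float(fix_f_BF)
        stderr["f_BF"] = 0.0
    resid = model(dose, *popt) - p
    return FitResult(
        params=params,
        stderr=stderr,
        n_used=len(rows),
        model_name="plateau_surface",
        rss=float(np.sum(resid**2)),
        converged=True,
    )


def bootstrap_se(
    events: pd.DataFrame,
    estimator: Callable[[pd.DataFrame], Union[float, dict]],
    n_boot: int = 200,
    seed: int = 0,
) -> Union[float, dict]:
    """Nonparametric bootstrap standard errors, resampling whole filaments.

    The independent experimental unit is the filament, so each bootstrap
    replicate draws filament ids with replacement and concatenates their
    event rows before re-running ``estimator`` (a callable mapping an
    event table to a float or a dict of floats).  Replicates where the
    estimator raises (e.g. a fit with too few events) are skipped; the
    standard error is the standard deviation over the surviving
    replicates.  Reproducible for a fixed ``seed``.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    ids = events["filament_id"].unique()
    if len(ids) < 5:
        raise ValueError(f"need at least 5 filaments to bootstrap, got {len(ids)}")
    groups = {i: g for i, g in events.groupby("filament_id")}
    rng = np.random.default_rng(seed)
    samples: list[Union[float, dict]] = []
    for _ in range(n_boot):
        chosen = rng.choice(ids, size=len(ids), replace=True)
        parts = []
        for new_id, fid in enumerate(chosen):
            g = groups[fid].copy()
            g["filament_id"] = new_id  # keep resampled duplicates distinct
            parts.append(g)
        table = pd.concat(parts, ignore_index=True)
        try:
            samples.append(estimator(table))
        except (ValueError, RuntimeError):
            continue
    if len(samples) < max(2, n_boot // 4):
        raise RuntimeError("estimator failed on too many bootstrap replicates")
    if isinstance(samples[0], dict):
        keys = samples[0].keys()
        return {k: float(np.std([s[k] for s in samples], ddof=1)) for k in keys}
    return float(np.std(np.asarray(samples, dtype=float), ddof=1))
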