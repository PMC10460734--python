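"""Secondary metrics of the tumor-in-host DEB-TGI model.

The DEB-TGI model describes tumor growth and host body-weight dynamics in
xenograft experiments under cytotoxic treatment, grounded in Dynamic Energy
Budget theory.  Three model-derived metrics are exposed here:

* ``lambda`` — exponential tumor growth rate governing the initial tumor
  dynamics, ``lambda = m*g*mu_u/g_u - m_u`` (host maintenance/growth costs
  ``m``, ``g``; tumor gluttony ``mu_u``; tumor growth/maintenance costs
  ``g_u``, ``m_u``).
* ``TVDT`` — tumor volume doubling time, ``ln 2 / lambda``.
* ``C_T`` — minimal constant drug concentration beyond which tumor
  eradication is asymptotically reached, ``lambda / k2`` with drug potency
  ``k2``.

A fourth metric, ``DeltaT_dVmax``, is the delay between the control and
treated arms in first reaching the maximum structural-biomass degradation
rate; it has no closed form and is extracted from simulated trajectories
supplied by the user (e.g. exported from any ODE simulator on a fine time
grid; 0.1 day is the recommended resolution).  A positive value means the
treated host degrades earlier, i.e. net treatment toxicity.

The full DEB-TGI ODE system (host energy reserves, tumor mortality chain,
drug PK, anorexia) is intentionally not implemented: every metric here is
either closed-form or an operator over externally supplied trajectories.

Draws with ``lambda <= 0`` describe a non-growing tumor for which TVDT and
C_T are undefined; they propagate as NaN and are dropped (and counted) by
the sensitivity estimator rather than clamped, which would create density
atoms distorting the kernel estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "DebParameters",
    "FixedHostConstants",
    "DerivedMetrics",
    "BodyTrajectory",
    "DEB_PARAMETER_NAMES",
    "lambda_rate",
    "tvdt",
    "c_threshold",
    "rho_b",
    "time_of_max_degradation",
    "delta_t_dvmax",
    "ct_model",
    "tvdt_model",
    "load_host_constants",
]

LN2 = np.log(2.0)

DEB_PARAMETER_NAMES = (
    "mu_u", "g_u", "m_u", "delta_Vmax", "Vu10", "W0",
    "Rb", "IVu50", "k1", "k2", "IC50",
)


@dataclass(frozen=True)
class DebParameters:
    """The eleven DEB-TGI parameters identified on xenograft data."""

    mu_u: float        # tumor gluttony (dimensionless)
    g_u: float         # tumor growth energy-investment ratio
    m_u: float         # tumor maintenance-growth rate ratio (1/day)
    delta_Vmax: float  # max structural-biomass degradation rate (cm3/day)
    Vu10: float        # initial tumor volume (g)
    W0: float          # initial host body weight (g)
    Rb: float          # food-supply reparametrization (dimensionless)
    IVu50: float       # half-maximal inhibitory tumor volume (cm3)
    k1: float          # tumor mortality chain transit rate (1/day)
    k2: float          # drug potency (ml/(ng day))
    IC50: float        # half-maximal inhibitory concentration (ng/ml)

    def __post_init__(self):
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be strictly positive")


@dataclass(frozen=True)
class FixedHostConstants:
    """Host maintenance (m, 1/day) and growth (g) costs, fixed during fitting.

    Only the product ``m*g`` enters the derived metrics.  The packaged
    default calibrates that product so the tumor volume doubling time at the
    typical parameter values equals 1.31 day, the center of the doubling
    times observed for the reference xenograft data; see docs/methods.md.
    """

    m: float
    g: float

    def __post_init__(self):
        if self.m <= 0 or self.g <= 0:
            raise ValueError("host constants m and g must be positive")

    @property
    def mg(self) -> float:
        return self.m * self.g


@dataclass(frozen=True)
class DerivedMetrics:
    """Closed-form metrics for one parameter set."""

    lam: float
    tvdt: float
    c_t: float
    rho_b: float


def load_host_constants(path=None) -> FixedHostConstants:
    """Load host constants from YAML (packaged calibrated defaults if None)."""
    if path is None:
        text = (
            resources.files("corrdelta.data")
            .joinpath("host_constants.yaml")
            .read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    cfg = yaml.safe_load(text)
    return FixedHostConstants(m=float(cfg["m"]), g=float(cfg["g"]))


def _get(params, name):
    if isinstance(params, DebParameters):
        return getattr(params, name)
    try:
        return np.asarray(params[name], dtype=float)
    except (KeyError, IndexError) as exc:
        raise KeyError(f"parameter {name!r} missing from input table") from exc


def lambda_rate(params, host: FixedHostConstants):
    """Exponential tumor growth rate ``m*g*mu_u/g_u - m_u``.

    May be <= 0 for extreme draws (a non-growing tumor); that is a valid
    value, not an error.
    """
    g_u = _get(params, "g_u")
    if np.any(np.asarray(g_u) <= 0):
        raise ValueError("g_u must be strictly positive")
    return host.mg * _get(params, "mu_u") / g_u - _get(params, "m_u")


def tvdt(lam):
    """Tumor volume doubling time ``ln 2 / lambda``; NaN where lambda <= 0."""
    lam = np.asarray(lam, dtype=float)
    out = np.where(lam > 0, LN2 / np.where(lam > 0, lam, 1.0), np.nan)
    return float(out) if out.ndim == 0 else out


def c_threshold(lam, k2):
    """Eradication concentration threshold ``lambda / k2``; NaN for lambda <= 0."""
    k2 = np.asarray(k2, dtype=float)
    if np.any(k2 <= 0):
        raise ValueError("k2 must be strictly positive")
    lam = np.asarray(lam, dtype=float)
    out = np.where(lam > 0, lam / k2, np.nan)
    return float(out) if out.ndim == 0 else out


def rho_b(Rb):
    """Food-supply coefficient ``1 / (1 + Rb)``, in (0, 1] for Rb >= 0."""
    Rb = np.asarray(Rb, dtype=float)
    if np.any(Rb < 0):
        raise ValueError("Rb must be non-negative")
    out = 1.0 / (1.0 + Rb)
    return float(out) if out.ndim == 0 else out


def derived_metrics(params, host: FixedHostConstants) -> DerivedMetrics:
    """All closed-form metrics for a single parameter set."""
    lam = float(lambda_rate(params, host))
    return DerivedMetrics(
        lam=lam,
        tvdt=tvdt(lam),
        c_t=c_threshold(lam, _get(params, "k2")),
        rho_b=rho_b(_get(params, "Rb")),
    )


# -- trajectory-based metric ------------------------------------------------

@dataclass(frozen=True)
class BodyTrajectory:
    """Structural-biomass degradation rate over time for one arm."""

    times: np.ndarray             # days, strictly increasing
    degradation_rate: np.ndarray  # cm3/day

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float).ravel()
        r = np.asarray(self.degradation_rate, dtype=float).ravel()
        if t.size == 0:
            raise ValueError("trajectory must be non-empty")
        if t.size != r.size:
            raise ValueError("times and degradation_rate lengths differ")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "degradation_rate", r)


def time_of_max_degradation(
    traj: BodyTrajectory, tolerance: float = 0.0
) -> float:
    """Earliest time at which the degradation rate first reaches its maximum.

    ``tolerance`` lets the caller treat attainment of ``max - tolerance`` as
    reaching the maximum (useful when the trajectory approaches an asymptote
    without touching it on the grid).
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    r = traj.degradation_rate
    idx = int(np.argmax(r >= r.max() - tolerance))
    return float(traj.times[idx])


def delta_t_dvmax(
    control: BodyTrajectory,
    treated: BodyTrajectory,
    tolerance: float = 0.0,
) -> float:
    """Delay ``T_max(control) - T_max(treated)`` in reaching max degradation.

    Positive values mean the treated arm degrades earlier (drug toxicity
    outweighs the cachexia relief from tumor inhibition); negative values
    mean the drug controls the tumor without strongly reducing host
    assimilation.
    """
    return time_of_max_degradation(control, tolerance) - time_of_max_degradation(
        treated, tolerance
    )


# -- row-wise model callables for the GSA engine ----------------------------

def ct_model(host: FixedHostConstants):
    """Row-wise model: parameter table -> C_T (ng/ml) per row."""

    def model(df):
        return c_threshold(lambda_rate(df, host), _get(df, "k2"))

    model.__name__ = "ct"
    return model


def tvdt_model(host: FixedHostConstants):
    """Row-wise model: parameter table -> TVDT (day) per row."""

    def model(df):
        return tvdt(lambda_rate(df, host))

    model.__name__ = "tvdt"
    return model
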