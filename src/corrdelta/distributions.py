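"""Joint input distributions for global sensitivity analysis.

Parameters are described by a typical value and a coefficient of variation
(CV) and modelled with lognormal (default) or normal marginals.  Statistical
dependence is expressed through a correlation matrix on the underlying
Gaussian scale (a Gaussian copula), which is valid for any positive-definite
matrix; natural-scale lognormal correlations would have restricted attainable
ranges.

Conventions
-----------
* For a lognormal marginal the typical value ``theta`` is the *median*:
  the Gaussian location is ``mu = ln(theta)`` and the Gaussian scale is
  ``sigma = sqrt(ln(1 + cv**2))`` so the natural-scale CV equals ``cv``.
  This is the standard pharmacometric parametrization.
* A partially known correlation matrix (``NaN`` marks unknown entries) is
  completed by initializing unknowns at zero and, when needed, running an
  alternating-projection nearest-positive-definite adjustment that keeps the
  known entries fixed whenever a feasible completion exists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ParameterSpec",
    "CorrelationTemplate",
    "JointInputDistribution",
    "InputSampleMatrix",
    "build_joint",
    "complete_correlation",
    "draw_samples",
    "append_noise_column",
]

_EIG_FLOOR = 1e-8
NOISE_NAME = "Noise"


@dataclass(frozen=True)
class ParameterSpec:
    """One model parameter: name, typical value, fractional CV and family."""

    name: str
    typical_value: float
    cv: float
    family: str = "lognormal"
    units: str = ""

    def __post_init__(self):
        if self.family not in ("lognormal", "normal"):
            raise ValueError(f"unknown family {self.family!r} for {self.name}")
        if self.cv < 0:
            raise ValueError(f"cv must be >= 0 for {self.name}")
        if self.family == "lognormal" and self.typical_value <= 0:
            raise ValueError(
                f"lognormal parameter {self.name} needs typical_value > 0"
            )


@dataclass(frozen=True)
class CorrelationTemplate:
    """Square correlation pattern with known entries and NaN for unknown."""

    names: tuple[str, ...]
    values: np.ndarray  # p x p, NaN marks unknown

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        p = len(self.names)
        if v.shape != (p, p):
            raise ValueError("template dimension does not match names")
        if len(set(self.names)) != p:
            raise ValueError("duplicate parameter names in template")
        if not np.allclose(np.diag(v), 1.0, equal_nan=False):
            raise ValueError("template diagonal must be 1")
        known = np.isfinite(v)
        if not np.array_equal(known, known.T):
            raise ValueError("known/unknown pattern must be symmetric")
        if not np.allclose(v[known], v.T[known]):
            raise ValueError("known entries must be symmetric")
        if np.any(np.abs(v[known]) > 1.0):
            raise ValueError("known correlations must lie in [-1, 1]")

    @property
    def n_unknown(self) -> int:
        return int(np.isnan(self.values).sum() // 2)


@dataclass(frozen=True)
class JointInputDistribution:
    """Gaussian-copula joint distribution with lognormal/normal marginals."""

    names: tuple[str, ...]
    log_location: np.ndarray  # ln(theta) for lognormal, theta for normal
    log_scale: np.ndarray     # Gaussian-scale sigma per parameter
    correlation: np.ndarray   # p x p on the Gaussian scale
    families: tuple[str, ...] = ()
    independent_mode: bool = False

    def __post_init__(self):
        p = len(self.names)
        loc = np.asarray(self.log_location, dtype=float)
        scale = np.asarray(self.log_scale, dtype=float)
        corr = np.asarray(self.correlation, dtype=float)
        fams = self.families or ("lognormal",) * p
        object.__setattr__(self, "log_location", loc)
        object.__setattr__(self, "log_scale", scale)
        object.__setattr__(self, "correlation", corr)
        object.__setattr__(self, "families", tuple(fams))
        if loc.shape != (p,) or scale.shape != (p,):
            raise ValueError("location/scale dimension mismatch")
        if np.any(scale < 0):
            raise ValueError("log_scale must be non-negative")
        _check_correlation(corr, p)

    @property
    def p(self) -> int:
        return len(self.names)

    def typical_values(self) -> np.ndarray:
        """Natural-scale typical values (medians for lognormal marginals)."""
        out = np.empty(self.p)
        for i, fam in enumerate(self.families):
            out[i] = (
                np.exp(self.log_location[i])
                if fam == "lognormal"
                else self.log_location[i]
            )
        return out


@dataclass
class InputSampleMatrix:
    """Monte Carlo draws: an ``n x p`` named table plus seed provenance."""

    data: pd.DataFrame
    seed: int
    distribution: JointInputDistribution | None = field(
        default=None, repr=False
    )

    def __post_init__(self):
        if len(self.data) == 0:
            raise ValueError("sample matrix must have n > 0 rows")
        if self.data.isna().any().any():
            raise ValueError("sample matrix contains missing values")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def names(self) -> list[str]:
        return list(self.data.columns)


def _check_correlation(corr: np.ndarray, p: int, floor: float = 1e-10):
    if corr.shape != (p, p):
        raise ValueError("correlation dimension mismatch")
    if not np.allclose(corr, corr.T, atol=1e-12):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0):
        raise ValueError("correlation diagonal must be 1")
    w = np.linalg.eigvalsh(corr)
    if w.min() <= floor:
        raise ValueError(
            f"correlation matrix is not positive definite "
            f"(smallest eigenvalue {w.min():.3e})"
        )


def build_joint(
    specs: list[ParameterSpec],
    correlation: np.ndarray | None = None,
) -> JointInputDistribution:
    """Build the joint distribution from parameter specs and a correlation.

    ``correlation`` acts on the underlying Gaussian scale; ``None`` means
    independence (identity matrix).
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    names = tuple(s.name for s in specs)
    if len(set(names)) != len(names):
        raise ValueError("parameter names must be unique")
    p = len(specs)
    loc = np.empty(p)
    scale = np.empty(p)
    for i, s in enumerate(specs):
        if s.family == "lognormal":
            loc[i] = np.log(s.typical_value)
            scale[i] = np.sqrt(np.log1p(s.cv**2))
        else:
            loc[i] = s.typical_value
            scale[i] = s.cv * abs(s.typical_value)
    corr = np.eye(p) if correlation is None else np.asarray(correlation, float)
    return JointInputDistribution(
        names=names,
        log_location=loc,
        log_scale=scale,
        correlation=corr,
        families=tuple(s.family for s in specs),
    )


def complete_correlation(
    template: CorrelationTemplate,
    max_iter: int = 1000,
    tol: float = 1e-10,
    eig_floor: float = _EIG_FLOOR,
) -> np.ndarray:
    """Complete a partially known correlation matrix to a PD matrix.

    Unknown entries start at zero.  If the resulting matrix is not positive
    definite, alternating projections move it onto the PSD cone (eigenvalue
    floor ``eig_floor``) while re-imposing known entries and the unit
    diagonal.  If no completion with the known entries exists, the fixed-entry
    constraint is relaxed and the maximal perturbation is reported in a
    warning.
    """
    known = np.isfinite(template.values)
    target = np.where(known, template.values, 0.0)
    np.fill_diagonal(target, 1.0)

    w = np.linalg.eigvalsh(target)
    if w.min() >= eig_floor:
        return target

    x = target.copy()
    for _ in range(max_iter):
        # project onto PSD cone with eigenvalue floor
        w, v = np.linalg.eigh(x)
        y = (v * np.maximum(w, eig_floor)) @ v.T
        y = (y + y.T) / 2.0
        # re-impose known entries and unit diagonal
        y[known] = target[known]
        np.fill_diagonal(y, 1.0)
        if np.linalg.norm(y - x, "fro") < tol:
            x = y
            break
        x = y

    w = np.linalg.eigvalsh(x)
    if w.min() >= eig_floor * 0.5:
        return x

    # no PD completion with the known entries fixed: relax and report
    w, v = np.linalg.eigh(x)
    y = (v * np.maximum(w, eig_floor)) @ v.T
    d = np.sqrt(np.diag(y))
    y = y / np.outer(d, d)
    y = (y + y.T) / 2.0
    np.fill_diagonal(y, 1.0)
    perturb = np.max(np.abs(y[known] - target[known]))
    warnings.warn(
        "no positive-definite completion preserves the known correlations "
        f"exactly; known entries perturbed by up to {perturb:.4g}",
        UserWarning,
        stacklevel=2,
    )
    return y


def draw_samples(
    joint: JointInputDistribution,
    n: int,
    seed: int,
    independent: bool = False,
) -> InputSampleMatrix:
    """Draw ``n`` correlated (or independent) samples from the joint pdf.

    ``independent=True`` keeps the marginals identical but ignores the
    off-diagonal correlation structure.  The same seed reuses the same
    underlying Gaussian quantiles in both modes.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, joint.p))
    if not (independent or joint.independent_mode):
        chol = np.linalg.cholesky(joint.correlation)
        z = z @ chol.T
    g = joint.log_location + joint.log_scale * z
    cols = {}
    for i, (name, fam) in enumerate(zip(joint.names, joint.families)):
        cols[name] = np.exp(g[:, i]) if fam == "lognormal" else g[:, i]
    return InputSampleMatrix(
        data=pd.DataFrame(cols), seed=int(seed), distribution=joint
    )


def append_noise_column(
    samples: InputSampleMatrix, seed: int
) -> InputSampleMatrix:
    """Append an independent standard-normal 'Noise' negative-control column.

    The spurious input does not belong to the model and is uncorrelated from
    every true parameter; its estimated sensitivity calibrates the numerical
    bias of the given-data estimator.
    """
    if NOISE_NAME in samples.data.columns:
        raise ValueError(f"sample matrix already has a {NOISE_NAME!r} column")
    rng = np.random.default_rng(seed)
    data = samples.data.copy()
    data[NOISE_NAME] = rng.standard_normal(samples.n)
    return InputSampleMatrix(
        data=data, seed=samples.seed, distribution=samples.distribution
    )
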