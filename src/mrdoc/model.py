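"""Structural model of the MR-DoC design: parameters, constraint patterns,
and model-implied covariance matrices.

The MR-DoC model embeds a Mendelian-randomization instrument (a polygenic
score, PGS) in the bivariate direction-of-causation twin model.  For twin
``j`` of pair ``i`` the structural equations are::

    X_ij = a_x A_Xij + c_x C_Xij + e_x E_Xij + b1 PGS_ij + g2 Y_ij
    Y_ij = a_y A_Yij + c_y C_Yij + e_y E_Yij + b2 PGS_ij + g1 X_ij

with latent additive-genetic (A), shared-environment (C) and
unique-environment (E) factors of unit variance, a standardized latent
polygenic score (the observed score is ``x`` times the standardized one),
a causal path ``g1`` (exposure -> outcome), an optional reverse path ``g2``
(zero in the MR-DoC variant), an instrument path ``b1`` and a direct
(pleiotropic) instrument-outcome path ``b2``.

Cross-twin structure: A factors correlate 1 (MZ) / 0.5 (DZ) within trait and
``ra`` / ``0.5 ra`` across traits; C factors correlate 1 within trait and
``rc`` across traits in both zygosities; E factors never correlate across
twins; the polygenic score correlates 1 (MZ) / 0.5 (DZ) across twins.

Because monozygotic twins carry identical genotypes, the model-implied MZ
covariance matrix of (PGS1, X1, Y1, PGS2, X2, Y2) is singular by
construction (PGS1 = PGS2).  Model fitting therefore uses the reduced
5-variate MZ system (PGS, X1, Y1, X2, Y2); see :mod:`mrdoc.estimate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "PARAM_NAMES",
    "VARIABLES",
    "MZ_KEEP",
    "ParameterVector",
    "ModelSpec",
    "expected_covariance",
    "implied_moments_unrelated",
    "make_candidate_spec",
    "mrdoc_spec",
]

#: Canonical parameter order used throughout the package.
PARAM_NAMES = (
    "ra", "rc", "re",
    "a_x", "c_x", "e_x",
    "a_y", "c_y", "e_y",
    "g1", "g2", "b1", "b2", "x",
)

#: Observed-variable order of the 6x6 twin-pair covariance matrices.
VARIABLES = ("pgs_1", "x_1", "y_1", "pgs_2", "x_2", "y_2")

#: Indices of the non-redundant MZ variables (PGS2 duplicates PGS1).
MZ_KEEP = (0, 1, 2, 4, 5)

_PATHS = ("a_x", "c_x", "e_x", "a_y", "c_y", "e_y")
_CORRS = ("ra", "rc", "re")
_IDX = {name: i for i, name in enumerate(PARAM_NAMES)}


class StructuralModelError(ValueError):
    """Raised when the simultaneous system is unsolvable (g1*g2 == 1)."""


@dataclass(frozen=True)
class ParameterVector:
    """Full parameter set theta of the MR-DoC / DoC model.

    Correlations ``ra``, ``rc``, ``re`` are unitless in [-1, 1]; the path
    coefficients are in SD units of the respective trait; ``x`` is the
    standard deviation of the observed polygenic score (> 0).
    """

    ra: float = 0.0
    rc: float = 0.0
    re: float = 0.0
    a_x: float = 0.0
    c_x: float = 0.0
    e_x: float = 1.0
    a_y: float = 0.0
    c_y: float = 0.0
    e_y: float = 1.0
    g1: float = 0.0
    g2: float = 0.0
    b1: float = 0.0
    b2: float = 0.0
    x: float = 1.0

    def __post_init__(self) -> None:
        if not self.x > 0:
            raise ValueError(f"PGS standard deviation x must be > 0, got {self.x}")
        for name in _CORRS:
            v = getattr(self, name)
            if abs(v) > 1 + 1e-12:
                raise ValueError(f"correlation {name}={v} outside [-1, 1]")
        if abs(self.g1 * self.g2 - 1.0) < 1e-12:
            raise StructuralModelError("g1 * g2 = 1: reciprocal system has no reduced form")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: np.ndarray) -> "ParameterVector":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected {len(PARAM_NAMES)} parameters, got shape {values.shape}")
        return cls(**dict(zip(PARAM_NAMES, values)))

    def replace(self, **updates: float) -> "ParameterVector":
        return replace(self, **updates)


@dataclass(frozen=True)
class ModelSpec:
    """Free/fixed pattern over the parameter vector defining one testable model.

    ``fixed`` maps parameter names to the value they are constrained to;
    every other parameter is estimated freely.
    """

    fixed: Mapping[str, float] = field(default_factory=dict)
    label: str = "custom"

    def __post_init__(self) -> None:
        for name, value in self.fixed.items():
            if name not in PARAM_NAMES:
                raise ValueError(f"unknown parameter {name!r}")
            if not np.isfinite(value):
                raise ValueError(f"fixed value for {name} must be finite")
        object.__setattr__(self, "fixed", dict(self.fixed))

    @property
    def free_names(self) -> tuple[str, ...]:
        return tuple(n for n in PARAM_NAMES if n not in self.fixed)

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def is_free(self, name: str) -> bool:
        return name not in self.fixed

    def constrain(self, label: str | None = None, **fixed: float) -> "ModelSpec":
        """Return a spec with additional parameters fixed."""
        merged = {**self.fixed, **fixed}
        return ModelSpec(fixed=merged, label=label or f"{self.label}+constraints")

    def is_nested_in(self, other: "ModelSpec") -> bool:
        """True if this spec is a constrained version of ``other``."""
        for name, value in other.fixed.items():
            if name not in self.fixed or self.fixed[name] != value:
                return False
        return True

    def full_theta(self, free_values: np.ndarray) -> ParameterVector:
        """Assemble a ParameterVector from values for the free parameters."""
        values = dict(self.fixed)
        values.update(zip(self.free_names, np.asarray(free_values, dtype=float)))
        return ParameterVector(**values)


def _reduced_loadings(theta: ParameterVector) -> np.ndarray:
    """Per-twin loadings of (X, Y) on (P, A_X, C_X, E_X, A_Y, C_Y, E_Y)."""
    B = np.array([[0.0, theta.g2], [theta.g1, 0.0]])
    G = np.array([
        [theta.b1, theta.a_x, theta.c_x, theta.e_x, 0.0, 0.0, 0.0],
        [theta.b2, 0.0, 0.0, 0.0, theta.a_y, theta.c_y, theta.e_y],
    ])
    det = 1.0 - theta.g1 * theta.g2
    if abs(det) < 1e-12:
        raise StructuralModelError("g1 * g2 = 1: reciprocal system has no reduced form")
    return np.linalg.solve(np.eye(2) - B, G)


def expected_covariance(theta: ParameterVector, zygosity: str) -> np.ndarray:
    """Model-implied 6x6 covariance matrix over (PGS1, X1, Y1, PGS2, X2, Y2).

    Parameters
    ----------
    theta
        Admissible parameter vector.
    zygosity
        ``"MZ"`` or ``"DZ"``.

    Notes
    -----
    For MZ pairs the returned matrix is singular because the twins' polygenic
    scores are identical (cross-twin PGS correlation 1).
    """
    zygosity = str(zygosity).upper()
    if zygosity not in ("MZ", "DZ"):
        raise ValueError(f"zygosity must be 'MZ' or 'DZ', got {zygosity!r}")
    m = 1.0 if zygosity == "MZ" else 0.5

    # Latent order per twin: P, A_X, C_X, E_X, A_Y, C_Y, E_Y (unit variances).
    W = np.eye(7)
    W[1, 4] = W[4, 1] = theta.ra
    W[2, 5] = W[5, 2] = theta.rc
    W[3, 6] = W[6, 3] = theta.re
    C = np.zeros((7, 7))  # cross-twin latent covariance
    C[0, 0] = m
    C[1, 1] = C[4, 4] = m
    C[1, 4] = C[4, 1] = m * theta.ra
    C[2, 2] = C[5, 5] = 1.0
    C[2, 5] = C[5, 2] = theta.rc

    L = _reduced_loadings(theta)  # (X, Y) on the 7 latents of one twin
    within = L @ W @ L.T
    cross = L @ C @ L.T
    x = theta.x
    sigma = np.empty((6, 6))
    # PGS covariances: the score is independent of the residual A/C/E factors.
    sigma[0, 0] = sigma[3, 3] = x * x
    sigma[0, 3] = sigma[3, 0] = m * x * x
    sigma[0, 1:3] = sigma[1:3, 0] = sigma[3, 4:6] = sigma[4:6, 3] = x * L[:, 0]
    sigma[0, 4:6] = sigma[4:6, 0] = sigma[3, 1:3] = sigma[1:3, 3] = m * x * L[:, 0]
    sigma[1:3, 1:3] = sigma[4:6, 4:6] = within
    sigma[1:3, 4:6] = cross
    sigma[4:6, 1:3] = cross.T
    return (sigma + sigma.T) / 2.0


def implied_moments_unrelated(theta: ParameterVector) -> np.ndarray:
    """Model-implied 3x3 covariance over (PGS, X, Y) for unrelated individuals.

    Equals the within-twin block of :func:`expected_covariance`; this is the
    moment structure used by the standard-MR-as-SEM baseline.
    """
    lam2 = _reduced_loadings(theta)
    W = np.eye(7)
    W[1, 4] = W[4, 1] = theta.ra
    W[2, 5] = W[5, 2] = theta.rc
    W[3, 6] = W[6, 3] = theta.re
    lam = np.zeros((3, 7))
    lam[0, 0] = theta.x
    lam[1:3] = lam2
    sigma = lam @ W @ lam.T
    return (sigma + sigma.T) / 2.0


#: Constraint patterns of the seven candidate identification models.
_CANDIDATE_CONSTRAINTS: dict[int, dict[str, float]] = {
    1: {},
    2: {"re": 0.0},
    3: {"b2": 0.0},
    4: {"rc": 0.0},
    5: {"c_x": 0.0, "c_y": 0.0, "rc": 0.0},
    6: {"c_y": 0.0, "rc": 0.0},
    7: {"c_x": 0.0, "rc": 0.0},
}


def make_candidate_spec(model_id: int) -> ModelSpec:
    """Constraint pattern of one of the seven candidate MR-DoC models.

    Model 1 frees all 13 parameters; models 2-4 fix one of re, b2, rc to
    zero; models 5-7 remove shared-environment sources from one or both
    traits.  The reverse causal path g2 is fixed at zero in all of them
    (unidirectional MR-DoC).
    """
    if model_id not in _CANDIDATE_CONSTRAINTS:
        raise ValueError(f"model_id must be in 1..7, got {model_id}")
    fixed = {"g2": 0.0, **_CANDIDATE_CONSTRAINTS[model_id]}
    return ModelSpec(fixed=fixed, label=f"candidate_model{model_id}")


def mrdoc_spec(re_zero: bool = True) -> ModelSpec:
    """The MR-DoC working model: g2 = 0, optionally re = 0 (the identifying
    constraint used for the main power analyses)."""
    fixed = {"g2": 0.0}
    label = "mrdoc"
    if re_zero:
        fixed["re"] = 0.0
        label = "mrdoc_re0"
    return ModelSpec(fixed=fixed, label=label)
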