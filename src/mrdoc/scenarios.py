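"""Effect-size bookkeeping for power scenarios.

A scenario is described on the scale of the regression (reduced-form) model
for unrelated individuals::

    X = b1 * PGS + xi_X          Var(X) = 1,  Var(PGS) = 1
    Y = g1 * X + b2 * PGS + xi_Y Var(Y) = 1

with residuals xi_X, xi_Y whose correlation r_xiX_xiY encodes the
(genetic + environmental) confounding between exposure and outcome.  Given
the instrument strength b1^2, the pleiotropic path b2, the residual
correlation, and the total explained variance of Y, the causal path g1 is
the positive root of::

    g1^2 + b2^2 + 2 g1 b1 b2 + 2 g1 sigma_xiXxiY = total_r2_y

The explained variance splits into five path-tracing components involving
g1 and b2 (C1..C5 below) plus the residual variance of Y.

The scenario is then mapped onto a full twin-model parameter vector: the
declared ACE proportions are applied to the residual variance of each trait
and the residual covariance is allocated across the additive-genetic and
shared-environment channels (plus the unique-environment channel when re is
not constrained to zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

from .model import ParameterVector, implied_moments_unrelated

__all__ = [
    "ScenarioSpec",
    "VarianceBudget",
    "solve_effect_size",
    "theta_from_scenario",
    "variance_budget",
    "vary_instrument_strength",
    "recovery_scenario",
]

_ATOL = 1e-12


def _check_ace(name: str, triple) -> tuple[float, float, float]:
    t = tuple(float(v) for v in triple)
    if len(t) != 3 or any(v < 0 for v in t):
        raise ValueError(f"{name} must be three nonnegative proportions, got {triple}")
    if abs(sum(t) - 1.0) > 1e-12:
        raise ValueError(f"{name} must sum to 1, got sum {sum(t)!r}")
    return t


@dataclass(frozen=True)
class ScenarioSpec:
    """Generating conditions for one power/recovery scenario.

    Parameters
    ----------
    instrument_r2
        Proportion of Var(X) explained by the polygenic score (b1^2).
    resid_corr
        Correlation between the residuals of X and Y (confounding).
    ace_x, ace_y
        ACE variance proportions of the residual part of each trait.
    b2
        Direct (pleiotropic) path from the standardized PGS to Y.
    total_r2_y
        Total explained variance of the standardized outcome.
    re_zero
        If true (default), generation puts no confounding through the
        unique-environment channel (re = 0), matching the identifying
        constraint of the main MR-DoC analyses.
    resid_split
        ``"proportional"`` (default) divides the residual covariance over
        the A and C channels (and E if ``re_zero`` is false) proportionally
        to the products of the corresponding path coefficients — which makes
        the channel correlations equal; ``"a_only"`` and ``"c_only"`` put it
        all in one channel.
    x
        Standard deviation of the observed polygenic score.
    """

    instrument_r2: float
    resid_corr: float
    ace_x: tuple[float, float, float]
    ace_y: tuple[float, float, float]
    b2: float = 0.0
    total_r2_y: float = 0.10
    re_zero: bool = True
    resid_split: str = "proportional"
    x: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.instrument_r2 < 1.0:
            raise ValueError(f"instrument_r2 must be in [0, 1), got {self.instrument_r2}")
        if not abs(self.resid_corr) < 1.0:
            raise ValueError(f"|resid_corr| must be < 1, got {self.resid_corr}")
        if not 0.0 < self.total_r2_y < 1.0:
            raise ValueError(f"total_r2_y must be in (0, 1), got {self.total_r2_y}")
        if self.resid_split not in ("proportional", "a_only", "c_only"):
            raise ValueError(f"unknown resid_split {self.resid_split!r}")
        object.__setattr__(self, "ace_x", _check_ace("ace_x", self.ace_x))
        object.__setattr__(self, "ace_y", _check_ace("ace_y", self.ace_y))


@dataclass(frozen=True)
class VarianceBudget:
    """Decomposition of Var(Y) = 1 into explained components and residual.

    c1 = g1^2 b1^2        causal effect of the instrumented part of X
    c2 = g1^2 s2_xi_x     causal effect of the residual part of X
    c3 = b2^2             direct (pleiotropic) instrument effect
    c4 = 2 g1 b1 b2       instrument acting through both routes
    c5 = 2 g1 s_xi_xy     causal path times residual confounding
    """

    c1: float
    c2: float
    c3: float
    c4: float
    c5: float
    sigma2_xi_y: float

    @property
    def explained(self) -> float:
        return self.c1 + self.c2 + self.c3 + self.c4 + self.c5

    @property
    def components(self) -> tuple[float, float, float, float, float]:
        return (self.c1, self.c2, self.c3, self.c4, self.c5)

    def __post_init__(self) -> None:
        total = self.explained + self.sigma2_xi_y
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"budget components must sum to 1, got {total!r}")


def solve_effect_size(
    b1: float,
    b2: float,
    resid_corr: float,
    total_r2_y: float = 0.10,
) -> tuple[float, float]:
    """Solve for the causal path g1 given the rest of the variance budget.

    Returns ``(g1, sigma2_xi_y)`` where ``sigma2_xi_y = 1 - total_r2_y`` and
    g1 is the positive root of the explained-variance equation (see module
    docstring).  Raises if |b1| >= 1 or if no real root exists.
    """
    if abs(b1) >= 1.0:
        raise ValueError(f"|b1| must be < 1 so that Var(X) = 1 is attainable, got {b1}")
    if not 0.0 < total_r2_y < 1.0:
        raise ValueError(f"total_r2_y must be in (0, 1), got {total_r2_y}")
    s2_xi_x = 1.0 - b1 * b1
    s2_xi_y = 1.0 - total_r2_y
    s_xi_xy = resid_corr * math.sqrt(s2_xi_x * s2_xi_y)
    half_b = b1 * b2 + s_xi_xy
    disc = half_b * half_b - (b2 * b2 - total_r2_y)
    if disc < 0:
        raise ValueError(
            f"no real causal path: discriminant {disc:.3e} < 0 for "
            f"b1={b1}, b2={b2}, resid_corr={resid_corr}, total_r2_y={total_r2_y}"
        )
    g1 = -half_b + math.sqrt(disc)
    return g1, s2_xi_y


def theta_from_scenario(spec: ScenarioSpec) -> ParameterVector:
    """Translate a scenario into generating twin-model parameters.

    ``b1 = sqrt(instrument_r2)``; g1 comes from :func:`solve_effect_size`;
    ACE proportions are applied to each trait's residual variance so that
    Var(X) = Var(Y) = 1; the residual covariance is allocated across the
    latent channels according to ``spec.resid_split``.
    """
    b1 = math.sqrt(spec.instrument_r2)
    g1, s2_xi_y = solve_effect_size(b1, spec.b2, spec.resid_corr, spec.total_r2_y)
    s2_xi_x = 1.0 - b1 * b1
    s_xi_xy = spec.resid_corr * math.sqrt(s2_xi_x * s2_xi_y)

    a_x, c_x, e_x = (math.sqrt(p * s2_xi_x) for p in spec.ace_x)
    a_y, c_y, e_y = (math.sqrt(p * s2_xi_y) for p in spec.ace_y)

    prods = {"a": a_x * a_y, "c": c_x * c_y, "e": 0.0 if spec.re_zero else e_x * e_y}
    if spec.resid_split == "proportional":
        weights = prods
    elif spec.resid_split == "a_only":
        weights = {"a": prods["a"], "c": 0.0, "e": 0.0}
    else:  # c_only
        weights = {"a": 0.0, "c": prods["c"], "e": 0.0}
    total_w = sum(weights.values())
    corrs = {"a": 0.0, "c": 0.0, "e": 0.0}
    if abs(s_xi_xy) > _ATOL:
        if total_w <= _ATOL:
            raise ValueError(
                "residual covariance cannot be allocated: every available "
                "channel has a zero path-coefficient product"
            )
        for ch, w in weights.items():
            if w > 0:
                corrs[ch] = s_xi_xy * (w / total_w) / prods[ch]
    for ch, label in (("a", "ra"), ("c", "rc"), ("e", "re")):
        if abs(corrs[ch]) > 1.0:
            raise ValueError(
                f"infeasible allocation: |{label}| = {abs(corrs[ch]):.4f} > 1 "
                f"(residual covariance {s_xi_xy:.4f} too large for the "
                f"{ch.upper()}-channel path product {prods[ch]:.4f})"
            )
    return ParameterVector(
        ra=corrs["a"], rc=corrs["c"], re=corrs["e"],
        a_x=a_x, c_x=c_x, e_x=e_x,
        a_y=a_y, c_y=c_y, e_y=e_y,
        g1=g1, g2=0.0, b1=b1, b2=spec.b2, x=spec.x,
    )


def variance_budget(theta: ParameterVector, atol: float = 1e-8) -> VarianceBudget:
    """Path-tracing decomposition of Var(Y) for an admissible theta.

    Requires Var(X) = Var(Y) = 1 on the implied moments (the scale on which
    the budget is defined).
    """
    m = implied_moments_unrelated(theta)
    if abs(m[1, 1] - 1.0) > atol or abs(m[2, 2] - 1.0) > atol:
        raise ValueError(
            f"variance budget requires standardized traits; implied "
            f"Var(X) = {m[1, 1]:.6f}, Var(Y) = {m[2, 2]:.6f}"
        )
    s2_xi_x = theta.a_x**2 + theta.c_x**2 + theta.e_x**2
    s2_xi_y = theta.a_y**2 + theta.c_y**2 + theta.e_y**2
    s_xi_xy = (
        theta.ra * theta.a_x * theta.a_y
        + theta.rc * theta.c_x * theta.c_y
        + theta.re * theta.e_x * theta.e_y
    )
    g1, b1, b2 = theta.g1, theta.b1, theta.b2
    return VarianceBudget(
        c1=g1 * g1 * b1 * b1,
        c2=g1 * g1 * s2_xi_x,
        c3=b2 * b2,
        c4=2.0 * g1 * b1 * b2,
        c5=2.0 * g1 * s_xi_xy,
        sigma2_xi_y=s2_xi_y,
    )


def vary_instrument_strength(theta: ParameterVector, instrument_r2: float) -> ParameterVector:
    """Rescale the instrument path so the PGS explains ``instrument_r2`` of
    Var(X), holding every other generating parameter fixed.

    This is how instrument strength is varied across power-grid cells: the
    residual (non-instrument) structure of the exposure, the causal path g1
    and the pleiotropy path b2 are untouched, so only b1 changes (and with
    it, slightly, the total variances of X and Y).  Under this variation the
    power to detect g1 in the pleiotropic MR-DoC model (b2 estimated) is
    exactly invariant to instrument strength — the information about g1
    comes from the non-instrument channels, which are held fixed.
    """
    if not 0.0 <= instrument_r2 < 1.0:
        raise ValueError(f"instrument_r2 must be in [0, 1), got {instrument_r2}")
    s2_resid = theta.a_x**2 + theta.c_x**2 + theta.e_x**2
    b1 = math.sqrt(instrument_r2 / (1.0 - instrument_r2) * s2_resid)
    return theta.replace(b1=b1)


#: Generating values of the three parameter-recovery scenarios: a valid
#: instrument, a pleiotropic instrument with a true causal effect, and a
#: pleiotropic instrument with no causal effect (b2 carries all 10% of the
#: explained outcome variance).  Shared ACE structure: exposure (.5,.2,.3),
#: outcome (.2,.1,.7), residual correlation .2, instrument R^2 = .10.
_RECOVERY_B2 = {1: 0.0, 2: 0.1599, 3: math.sqrt(0.10)}


def recovery_scenario(scenario_id: int) -> ScenarioSpec:
    """The three published parameter-recovery scenarios (1, 2, 3)."""
    if scenario_id not in _RECOVERY_B2:
        raise ValueError(f"scenario_id must be 1, 2 or 3, got {scenario_id}")
    return ScenarioSpec(
        instrument_r2=0.10,
        resid_corr=0.2,
        ace_x=(0.5, 0.2, 0.3),
        ace_y=(0.2, 0.1, 0.7),
        b2=_RECOVERY_B2[scenario_id],
        total_r2_y=0.10,
        re_zero=True,
    )
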