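"""Noncentrality-based power machinery for MR-DoC and standard MR.

Power for a likelihood-ratio test is computed in the classical SEM way:
exact data are generated at the alternative (sample covariances equal the
model-implied ones), the true model is fitted (zero misfit, parameters
recovered exactly), the tested parameters are dropped, and the resulting
misfit is the noncentrality parameter (NCP, lambda) of the test's
noncentral chi-square distribution.  Equivalent sample sizes for standard
MR come from the per-individual NCP of the trivariate MR-as-SEM model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimate import fit_ml, lrt
from .model import ModelSpec, ParameterVector, expected_covariance, implied_moments_unrelated
from .mr_baselines import mr_sem_fit
from .simulate import simulate_twin_study

__all__ = [
    "PowerResult",
    "Type1Result",
    "ncp_for_test",
    "power_from_ncp",
    "power_analysis",
    "equivalent_n_unrelated",
    "type1_error_mc",
]

_EXACT_TOL = 1e-6


@dataclass(frozen=True)
class PowerResult:
    """NCP, degrees of freedom, test size and resulting power."""

    ncp: float
    df: int
    alpha: float
    power: float
    n_equivalent: int | None = None


@dataclass(frozen=True)
class Type1Result:
    """Monte-Carlo rejection rate under the null with its exact binomial CI."""

    rate: float
    ci: tuple[float, float]
    n_reps: int
    n_rejected: int
    n_nonconverged: int
    alpha: float


def power_from_ncp(ncp: float, df: int, alpha: float = 0.05) -> float:
    """P(chi2(df, ncp) exceeds the central chi-square alpha-critical value)."""
    if ncp < 0:
        raise ValueError(f"ncp must be nonnegative, got {ncp}")
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    crit = stats.chi2.ppf(1.0 - alpha, df)
    if ncp == 0:
        return float(alpha)
    return float(stats.ncx2.sf(crit, df, ncp))


def _exact_groups(theta: ParameterVector, n_mz: int, n_dz: int) -> dict:
    """Population covariance matrices presented as exact data of given size."""
    groups = {}
    if n_mz > 0:
        groups["MZ"] = (expected_covariance(theta, "MZ"), n_mz)
    if n_dz > 0:
        groups["DZ"] = (expected_covariance(theta, "DZ"), n_dz)
    return groups


def _null_starts(theta: ParameterVector, null_spec: ModelSpec) -> ParameterVector:
    return theta.replace(**{k: v for k, v in null_spec.fixed.items()})


def ncp_for_test(
    theta: ParameterVector,
    full_spec: ModelSpec,
    null_spec: ModelSpec,
    n_mz: int,
    n_dz: int,
) -> float:
    """NCP of the LRT of ``null_spec`` against ``full_spec`` at sample sizes
    (n_mz, n_dz), with data generated exactly from ``theta``.

    The full model must reproduce the generating covariance structure
    (misfit below 1e-6); otherwise the specification is inconsistent with
    theta and an error is raised.
    """
    if not null_spec.is_nested_in(full_spec):
        raise ValueError("null_spec must be nested in full_spec")
    groups = _exact_groups(theta, n_mz, n_dz)
    full = fit_ml(groups, full_spec, starts=theta, compute_se=False)
    if full.minus2ll > _EXACT_TOL:
        raise ValueError(
            f"full model does not reproduce the generating structure "
            f"(misfit {full.minus2ll:.3g}); check that full_spec is consistent "
            f"with theta"
        )
    # Constrained null models fitted far from their generating values can
    # present distinct local optima; explore several starts and keep the best.
    null = fit_ml(groups, null_spec, starts=_null_starts(theta, null_spec),
                  compute_se=False, n_multistart=6)
    return max(0.0, null.minus2ll - full.minus2ll)


def power_analysis(
    theta: ParameterVector,
    full_spec: ModelSpec,
    null_spec: ModelSpec,
    n_mz: int,
    n_dz: int,
    alpha: float = 0.05,
    with_equivalent_n: bool = False,
) -> PowerResult:
    """NCP, power and (optionally) the equivalent standard-MR sample size
    for the LRT of ``null_spec`` against ``full_spec`` under ``theta``."""
    ncp = ncp_for_test(theta, full_spec, null_spec, n_mz, n_dz)
    df = full_spec.n_free - null_spec.n_free
    n_eq = None
    if with_equivalent_n and ncp > 0:
        n_eq = equivalent_n_unrelated(ncp, theta, alpha)
    return PowerResult(ncp=ncp, df=df, alpha=alpha,
                       power=power_from_ncp(ncp, df, alpha), n_equivalent=n_eq)


def equivalent_n_unrelated(
    ncp_target: float,
    theta: ParameterVector,
    alpha: float = 0.05,
) -> int:
    """Number of unrelated individuals standard MR needs to match a target NCP.

    Computes the per-individual NCP lambda_1 for dropping the causal path g1
    in the trivariate MR-as-SEM model fitted to the exact (population)
    moments of (PGS, X, Y) implied by ``theta``, then returns
    ``ceil(ncp_target / lambda_1)``.  ``alpha`` is carried for reporting
    only: equal NCP at equal df means equal power at any test size.
    """
    if ncp_target <= 0:
        raise ValueError(f"ncp_target must be positive, got {ncp_target}")
    moments = implied_moments_unrelated(theta)
    sem_starts = _sem_truth_starts(theta)
    full = mr_sem_fit(moments, n=1, starts=sem_starts, compute_se=False)
    null = mr_sem_fit(
        moments, n=1, starts=sem_starts.replace(g1=0.0), compute_se=False,
        g1_fixed=0.0, n_multistart=4,
    )
    lam1 = null.minus2ll - full.minus2ll
    if lam1 <= 1e-14:
        raise ValueError(
            "per-individual NCP is zero (theta implies no causal signal for "
            "standard MR); no finite sample size achieves the target"
        )
    return math.ceil(ncp_target / lam1)


def _sem_truth_starts(theta: ParameterVector) -> ParameterVector:
    """Map twin-model truth onto the trivariate SEM parametrization."""
    s_x = math.sqrt(theta.a_x**2 + theta.c_x**2 + theta.e_x**2)
    s_y = math.sqrt(theta.a_y**2 + theta.c_y**2 + theta.e_y**2)
    cov = (
        theta.ra * theta.a_x * theta.a_y
        + theta.rc * theta.c_x * theta.c_y
        + theta.re * theta.e_x * theta.e_y
    )
    re = cov / (s_x * s_y) if s_x > 0 and s_y > 0 else 0.0
    return ParameterVector(
        re=re, e_x=s_x, e_y=s_y, g1=theta.g1, b1=theta.b1, b2=0.0, x=theta.x,
    )


def type1_error_mc(
    theta_null: ParameterVector,
    spec: ModelSpec,
    reps: int = 1000,
    n_mz: int = 1000,
    n_dz: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    test_param: str = "g1",
) -> Type1Result:
    """Monte-Carlo type-I error of the LRT for ``test_param`` under the null.

    Simulates ``reps`` random twin studies from ``theta_null`` (which must
    satisfy the null, e.g. g1 = 0), fits ``spec`` with and without the
    tested parameter, and reports the empirical rejection rate at ``alpha``
    with its exact (Clopper-Pearson) 95% confidence interval.  Replicates
    whose fits do not converge are excluded and counted separately.
    """
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    if abs(getattr(theta_null, test_param)) > 1e-12:
        raise ValueError(f"theta_null must satisfy the null: {test_param} != 0")
    if not spec.is_free(test_param):
        raise ValueError(f"{test_param!r} is fixed in the fitted spec")
    null_spec = spec.constrain(label=f"{spec.label}|{test_param}=0", **{test_param: 0.0})
    rng = np.random.default_rng(seed)
    rejected = 0
    used = 0
    nonconv = 0
    for _ in range(reps):
        data = simulate_twin_study(theta_null, n_mz, n_dz, mode="random", seed=rng)
        full = fit_ml(data, spec, starts=theta_null, compute_se=False, n_restarts=3)
        null = fit_ml(
            data, null_spec, starts=full.estimates.replace(**{test_param: 0.0}),
            compute_se=False, n_restarts=3, n_multistart=2,
        )
        if null.minus2ll < full.minus2ll:
            # The less constrained fit stalled in a worse basin: restart it
            # from the null solution, which is feasible under the full spec.
            refit = fit_ml(data, spec, starts=null.estimates, compute_se=False,
                           n_restarts=3)
            if refit.minus2ll < full.minus2ll:
                full = refit
        if not (full.converged and null.converged):
            nonconv += 1
            continue
        _, _, p = lrt(full, null)
        used += 1
        if p < alpha:
            rejected += 1
    if used == 0:
        raise RuntimeError("no replicate converged")
    ci = stats.binomtest(rejected, used).proportion_ci(confidence_level=0.95, method="exact")
    return Type1Result(
        rate=rejected / used,
        ci=(float(ci.low), float(ci.high)),
        n_reps=used,
        n_rejected=rejected,
        n_nonconverged=nonconv,
        alpha=alpha,
    )
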