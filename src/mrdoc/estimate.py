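"""Multi-group normal-theory maximum-likelihood fitting of MR-DoC models.

The fit minimizes the standard ML discrepancy summed over zygosity groups::

    F(theta) = sum_g N_g [ ln det Sigma_g(theta) + tr(S_g Sigma_g(theta)^-1)
                           - ln det S_g - p_g ]

where ``S_g`` is the (n-1)-divisor sample covariance and ``N_g`` the pair
count of group ``g``.  ``F`` equals the likelihood-ratio statistic against
the saturated model, so a saturated fit scores 0 and differences of
``minus2ll`` between nested fits are chi-square test statistics.

MZ pairs are fitted on the 5-variate system (PGS, X1, Y1, X2, Y2): the
model implies identical polygenic scores for MZ co-twins, so the full
6-variate MZ covariance matrix is singular by construction and carries no
additional information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.linalg import cho_solve

from .model import (
    MZ_KEEP,
    PARAM_NAMES,
    ModelSpec,
    ParameterVector,
    expected_covariance,
    implied_moments_unrelated,
)
from .simulate import TwinDataset

__all__ = ["FitResult", "fit_ml", "lrt", "wald"]

_PATH_NAMES = ("a_x", "c_x", "e_x", "a_y", "c_y", "e_y")
_CORR_NAMES = ("ra", "rc", "re")
_PENALTY = 1e12


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit.

    ``minus2ll`` is the minimized discrepancy F, i.e. the -2 log-likelihood
    relative to the saturated model (0 for a perfectly fitting model).
    Standard errors cover free parameters only.
    """

    estimates: ParameterVector
    minus2ll: float
    converged: bool
    spec: ModelSpec
    n_free: int
    se: dict[str, float] = field(default_factory=dict)
    vcov: np.ndarray | None = None
    n_restarts_used: int = 0

    def estimate(self, name: str) -> float:
        return getattr(self.estimates, name)


class _Group:
    """One data group reduced to its informative variables.

    ``zygosity`` is ``"MZ"``, ``"DZ"`` or ``"U"`` (unrelated individuals,
    whose moment structure is the 3x3 within-person block).
    """

    def __init__(self, zygosity: str, sample_cov: np.ndarray, n: int):
        if zygosity == "MZ":
            keep = list(MZ_KEEP)
        elif zygosity == "DZ":
            keep = list(range(6))
        elif zygosity == "U":
            keep = list(range(3))
        else:
            raise ValueError(f"unknown group {zygosity!r}")
        s = np.asarray(sample_cov, dtype=float)
        if s.shape[0] == 6:
            s = s[np.ix_(keep, keep)]
        elif s.shape != (len(keep), len(keep)):
            raise ValueError(
                f"sample covariance for group {zygosity} must be 6x6 "
                f"or {len(keep)}x{len(keep)}, got {s.shape}"
            )
        sign, logdet = np.linalg.slogdet(s)
        if sign <= 0 or not np.isfinite(logdet):
            raise np.linalg.LinAlgError(
                f"{zygosity} sample covariance is singular on the informative "
                f"variables; cannot fit"
            )
        self.zygosity = zygosity
        self.keep = keep
        self.s = s
        self.n = n
        self.logdet_s = logdet
        self.p = len(keep)

    def _implied(self, theta: ParameterVector) -> np.ndarray:
        if self.zygosity == "U":
            return implied_moments_unrelated(theta)
        return expected_covariance(theta, self.zygosity)[np.ix_(self.keep, self.keep)]

    def discrepancy(self, theta: ParameterVector) -> float:
        try:
            c = np.linalg.cholesky(self._implied(theta))
        except np.linalg.LinAlgError:
            return _PENALTY
        logdet = 2.0 * np.log(np.diag(c)).sum()
        inv_s = cho_solve((c, True), self.s)
        return self.n * (logdet + np.trace(inv_s) - self.logdet_s - self.p)


def _groups_from_data(data) -> list[_Group]:
    if isinstance(data, TwinDataset):
        groups = []
        if data.n_mz > 1:
            groups.append(_Group("MZ", data.cov("MZ"), data.n_mz))
        if data.n_dz > 1:
            groups.append(_Group("DZ", data.cov("DZ"), data.n_dz))
    elif isinstance(data, dict):
        groups = [
            _Group(z.upper(), cov, n)
            for z, (cov, n) in data.items()
            if n and n > 0
        ]
    else:
        raise TypeError(
            "data must be a TwinDataset or a mapping {'MZ': (cov6, n), 'DZ': (cov6, n)}"
        )
    if not groups:
        raise ValueError("no usable zygosity group in the data")
    return groups


def _moment_starts(groups: list[_Group], spec: ModelSpec) -> dict[str, float] | None:
    """Data-driven starting values from sample moments.

    Uses the instrument-ratio estimate for g1, the first-stage slope for b1,
    and Falconer-style ACE decompositions of the traits' cross-twin
    covariances for the path coefficients.
    """
    mz = next((g for g in groups if g.zygosity == "MZ"), None)
    dz = next((g for g in groups if g.zygosity == "DZ"), None)
    ref = dz or mz
    if ref is None or ref.p < 3:
        return None
    s = ref.s
    x = np.sqrt(s[0, 0])
    b1 = s[0, 1] / x if spec.is_free("b1") else 0.0
    g1 = s[0, 2] / s[0, 1] if spec.is_free("g1") and abs(s[0, 1]) > 1e-8 else 0.0
    out = {"x": x, "b1": np.clip(b1, -5, 5), "g1": np.clip(g1, -5, 5),
           "g2": 0.0, "b2": 0.0, **{n: 0.0 for n in _CORR_NAMES}}

    def ace(var, cov_mz, cov_dz):
        a2 = np.clip(2.0 * (cov_mz - cov_dz), 0.02 * var, 0.95 * var)
        c2 = np.clip(2.0 * cov_dz - cov_mz, 0.02 * var, 0.95 * var)
        e2 = max(var - a2 - c2, 0.02 * var)
        return np.sqrt([a2, c2, e2])

    # Cross-twin covariances of each trait (indices in the full 6-var order).
    if mz is not None and dz is not None and mz.p == 5 and dz.p == 6:
        cov_mz_x, cov_dz_x = mz.s[1, 3], dz.s[1, 4]
        cov_mz_y, cov_dz_y = mz.s[2, 4], dz.s[2, 5]
    else:
        cov_mz_x = cov_dz_x = s[1, 1] / 3.0
        cov_mz_y = cov_dz_y = s[2, 2] / 3.0
    vx_resid = max(s[1, 1] - b1**2, 0.1 * s[1, 1])
    vy_resid = max(s[2, 2] - g1**2 * s[1, 1], 0.1 * s[2, 2])
    shrink_x = vx_resid / s[1, 1]
    shrink_y = vy_resid / s[2, 2]
    out["a_x"], out["c_x"], out["e_x"] = ace(vx_resid, cov_mz_x * shrink_x, cov_dz_x * shrink_x)
    out["a_y"], out["c_y"], out["e_y"] = ace(vy_resid, cov_mz_y * shrink_y, cov_dz_y * shrink_y)
    return out


def _bounds_and_starts(
    spec: ModelSpec, groups: list[_Group], starts
) -> tuple[list, list[np.ndarray]]:
    sd_pgs = float(np.sqrt(np.mean([g.s[0, 0] for g in groups])))
    heuristic = {
        **{n: 0.5 for n in _PATH_NAMES},
        **{n: 0.0 for n in _CORR_NAMES},
        "g1": 0.0, "g2": 0.0, "b1": 0.1, "b2": 0.0,
        "x": sd_pgs,
    }
    bounds = []
    for name in spec.free_names:
        if name in _PATH_NAMES:
            bounds.append((0.0, 10.0))
        elif name in _CORR_NAMES:
            bounds.append((-0.999, 0.999))
        elif name == "x":
            bounds.append((1e-6, 1e3))
        else:  # g1, g2, b1, b2
            bounds.append((-10.0, 10.0))

    def pack(values: dict) -> np.ndarray:
        return np.array([
            np.clip(values[n], lo, hi)
            for n, (lo, hi) in zip(spec.free_names, bounds)
        ])

    candidates = []
    if starts is not None:
        candidates.append(pack({n: getattr(starts, n) for n in PARAM_NAMES}))
    moment = _moment_starts(groups, spec)
    if moment is not None:
        candidates.append(pack(moment))
    candidates.append(pack(heuristic))
    return bounds, candidates


def fit_ml(
    data,
    spec: ModelSpec,
    starts: ParameterVector | None = None,
    n_restarts: int = 10,
    n_multistart: int | None = None,
    compute_se: bool = True,
    seed: int = 0,
    ftol: float = 1e-12,
) -> FitResult:
    """Fit a model specification to twin data by maximum likelihood.

    Parameters
    ----------
    data
        A :class:`~mrdoc.simulate.TwinDataset` or a mapping
        ``{"MZ": (cov6, n_mz), "DZ": (cov6, n_dz)}`` of (n-1)-divisor
        sample covariances and pair counts.  Groups with fewer than two
        pairs are dropped.  Means are ignored throughout.
    spec
        Free/fixed pattern to estimate.
    starts
        Optional starting parameter values; defaults to a mid-range
        heuristic (paths 0.5, correlations 0, x from the sample SD).
    n_restarts
        Jittered restarts attempted when the first optimization fails to
        converge or lands on the infeasibility penalty.
    n_multistart
        Minimum number of starting points explored even when the first
        attempt converges (the supplied, moment-based and heuristic starts
        first, then jittered versions); the best optimum found is kept.
        Defaults to 1 when ``starts`` is given and to 8 for cold fits,
        whose 12-parameter likelihood surface has distinct local optima.

    Notes
    -----
    Path coefficients and the PGS scale are constrained nonnegative (their
    sign is not identified: a, c, e enter the covariance only through
    squares and products with the cross-trait correlations).
    """
    groups = _groups_from_data(data)
    bounds, start_candidates = _bounds_and_starts(spec, groups, starts)
    free = spec.free_names
    if not free:
        theta = spec.full_theta(np.empty(0))
        f0 = sum(g.discrepancy(theta) for g in groups)
        return FitResult(theta, float(f0), True, spec, 0)

    def objective(p: np.ndarray) -> float:
        try:
            theta = spec.full_theta(p)
        except ValueError:
            return _PENALTY
        return sum(g.discrepancy(theta) for g in groups)

    options = {"ftol": ftol, "gtol": 1e-10, "maxiter": 2000, "maxfun": 200000}

    def run(p0):
        return optimize.minimize(objective, p0, method="L-BFGS-B", bounds=bounds,
                                 options=options)

    def run_polished(p0):
        # L-BFGS-B occasionally reports a line-search failure while sitting
        # at the optimum (common with exact data).  A solution counts as
        # converged when refitting from it improves F by less than 1e-8.
        res = run(p0)
        for _ in range(3):
            if res.fun >= _PENALTY / 2:
                return res, False
            if res.success:
                return res, True
            res2 = run(res.x)
            if res.fun - res2.fun < 1e-8:
                return (res2 if res2.fun < res.fun else res), True
            res = res2
        return res, False

    rng = np.random.default_rng(seed)
    n_cand = len(start_candidates)
    if n_multistart is None:
        n_multistart = 1 if starts is not None else 12
    n_attempts = max(n_cand + max(0, n_restarts), n_multistart)

    def random_start() -> np.ndarray:
        vals = {}
        for name in spec.free_names:
            if name in _PATH_NAMES:
                vals[name] = rng.uniform(0.05, 1.2)
            elif name in _CORR_NAMES:
                vals[name] = rng.uniform(-0.7, 0.7)
            elif name == "x":
                vals[name] = start_candidates[-1][spec.free_names.index("x")]
            else:
                vals[name] = rng.uniform(-0.8, 0.8)
        return np.array([
            np.clip(vals[n], lo, hi) for n, (lo, hi) in zip(spec.free_names, bounds)
        ])

    best = None
    converged = False
    used = 0
    for attempt in range(n_attempts):
        if attempt < n_cand:
            p0 = start_candidates[attempt]
        elif attempt % 2 == 0:
            p0 = random_start()
        else:
            base = start_candidates[attempt % n_cand]
            jitter = rng.uniform(-0.3, 0.3, size=len(base))
            p0 = np.array([
                np.clip(v + j, lo, hi)
                for v, j, (lo, hi) in zip(base, jitter, bounds)
            ])
        res, ok = run_polished(p0)
        used = attempt
        if best is None or res.fun < best.fun - 1e-10:
            best = res
            converged = ok
        if converged and attempt + 1 >= n_multistart:
            break
    theta_hat = spec.full_theta(best.x)
    se: dict[str, float] = {}
    vcov = None
    if compute_se and converged:
        vcov, se = _wald_vcov(objective, best.x, free)
    return FitResult(
        estimates=theta_hat,
        minus2ll=float(best.fun),
        converged=converged,
        spec=spec,
        n_free=len(free),
        se=se,
        vcov=vcov,
        n_restarts_used=used,
    )


def _wald_vcov(objective, x_opt: np.ndarray, free: tuple[str, ...]):
    """Parameter covariance from the numerical Hessian of F (vcov = 2 H^-1)."""
    k = len(x_opt)
    h = np.maximum(1e-4, 1e-4 * np.abs(x_opt))
    hess = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            pp = x_opt.copy(); pp[i] += h[i]; pp[j] += h[j]; fpp = objective(pp)
            pm = x_opt.copy(); pm[i] += h[i]; pm[j] -= h[j]; fpm = objective(pm)
            mp = x_opt.copy(); mp[i] -= h[i]; mp[j] += h[j]; fmp = objective(mp)
            mm = x_opt.copy(); mm[i] -= h[i]; mm[j] -= h[j]; fmm = objective(mm)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    try:
        vcov = 2.0 * np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return None, {}
    diag = np.diag(vcov)
    se = {
        name: float(np.sqrt(d)) if d > 0 else float("nan")
        for name, d in zip(free, diag)
    }
    return vcov, se


def lrt(full: FitResult, nested: FitResult) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested model against a fuller one.

    Returns ``(delta_chi2, df, p)``; ``delta_chi2`` is clipped at zero
    (tiny negative values arise from optimizer tolerance only).
    """
    if not nested.spec.is_nested_in(full.spec):
        raise ValueError(
            f"spec {nested.spec.label!r} is not nested in {full.spec.label!r}"
        )
    if not (full.converged and nested.converged):
        raise ValueError("both fits must have converged for a likelihood-ratio test")
    delta = nested.minus2ll - full.minus2ll
    if delta < -1e-6:
        raise ValueError(
            f"nested model fits better by {-delta:.3g}; refit the full model "
            f"(local optimum suspected)"
        )
    delta = max(delta, 0.0)
    df = full.n_free - nested.n_free
    p = 1.0 if df == 0 else float(stats.chi2.sf(delta, df))
    return delta, df, p


def wald(fit: FitResult, param_name: str) -> tuple[float, float]:
    """Wald z test of a single free parameter against zero."""
    if not fit.spec.is_free(param_name):
        raise ValueError(f"parameter {param_name!r} is fixed in this model")
    if param_name not in fit.se:
        raise ValueError(f"no standard error available for {param_name!r}")
    se = fit.se[param_name]
    if not np.isfinite(se) or se <= 0:
        raise ValueError(f"degenerate standard error for {param_name!r}: {se}")
    z = fit.estimate(param_name) / se
    return float(z), float(2.0 * stats.norm.sf(abs(z)))
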