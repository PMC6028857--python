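"""Standard Mendelian-randomization estimators on unrelated individuals.

These are the comparison baselines for MR-DoC: two-stage least squares,
the ratio of regression coefficients, and the MR model fitted in one step
as a trivariate structural equation model over (PGS, X, Y) by maximum
likelihood.  With a single instrument all three yield the same causal-effect
point estimate; all three are biased by b2/b1 when the instrument has a
direct (pleiotropic) effect b2 on the outcome.
"""

from __future__ import annotations

import numpy as np

from .estimate import FitResult, fit_ml
from .model import ModelSpec, ParameterVector

__all__ = ["tsls", "ratio_estimate", "mr_sem_fit", "unrelated_from_twins"]


def _check_vectors(outcome, exposure, instrument) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    y = np.asarray(outcome, dtype=float).ravel()
    x = np.asarray(exposure, dtype=float).ravel()
    z = np.asarray(instrument, dtype=float).ravel()
    if not (len(y) == len(x) == len(z)):
        raise ValueError("outcome, exposure and instrument must have equal length")
    if len(y) < 3:
        raise ValueError("need at least 3 observations")
    return y, x, z


def tsls(outcome, exposure, instrument) -> tuple[float, float]:
    """Two-stage least squares with a single instrument (intercept included).

    Stage one regresses the exposure on the instrument; stage two regresses
    the outcome on the fitted exposure.  Returns ``(estimate, se)`` with the
    conventional IV standard error (2SLS residuals evaluated at the observed
    exposure).
    """
    y, x, z = _check_vectors(outcome, exposure, instrument)
    n = len(y)
    zc = z - z.mean()
    xc = x - x.mean()
    yc = y - y.mean()
    szx = zc @ xc
    if abs(szx) < 1e-12 * n:
        raise ValueError("instrument has (near-)zero sample covariance with the exposure")
    beta = (zc @ yc) / szx
    resid = yc - beta * xc
    sigma2 = (resid @ resid) / (n - 2)
    se = float(np.sqrt(sigma2 * (zc @ zc) / szx**2))
    return float(beta), se


def ratio_estimate(outcome, exposure, instrument) -> float:
    """Ratio-of-coefficients IV estimate:
    slope(outcome ~ instrument) / slope(exposure ~ instrument)."""
    y, x, z = _check_vectors(outcome, exposure, instrument)
    zc = z - z.mean()
    szx = zc @ (x - x.mean())
    if abs(szx) < 1e-12 * len(y):
        raise ValueError("instrument has (near-)zero sample covariance with the exposure")
    return float((zc @ (y - y.mean())) / szx)


def _sem_spec(pleiotropy_free: bool, resid_corr_fixed: float | None) -> ModelSpec:
    # The trivariate MR SEM is the within-person model with all residual
    # variance routed through the E channel: e_x, e_y are the residual SDs
    # and re the residual correlation.
    fixed = {"ra": 0.0, "rc": 0.0, "a_x": 0.0, "c_x": 0.0, "a_y": 0.0, "c_y": 0.0, "g2": 0.0}
    if pleiotropy_free:
        if resid_corr_fixed is None:
            raise ValueError(
                "b2 and g1 are not jointly identified in the trivariate MR model "
                "when the residual correlation is free: pass resid_corr_fixed "
                "to fix the X-Y residual correlation"
            )
        fixed["re"] = float(resid_corr_fixed)
        label = "mr_sem_pleiotropic"
    else:
        fixed["b2"] = 0.0
        label = "mr_sem"
    return ModelSpec(fixed=fixed, label=label)


def mr_sem_fit(
    data,
    n: int | None = None,
    pleiotropy_free: bool = False,
    resid_corr_fixed: float | None = None,
    starts: ParameterVector | None = None,
    g1_fixed: float | None = None,
    **fit_kwargs,
) -> FitResult:
    """Fit the standard MR model as a trivariate SEM by maximum likelihood.

    Parameters
    ----------
    data
        Either an (n, 3) observation array over (PGS, X, Y) or a 3x3 sample
        covariance matrix (then ``n`` must be given).
    pleiotropy_free
        Estimate the direct instrument-outcome path b2.  This requires
        fixing the residual X-Y correlation (``resid_corr_fixed``), because
        b2 and g1 are not jointly identified otherwise; the default model
        fixes b2 = 0 instead and estimates the residual correlation.

    Returns a :class:`~mrdoc.estimate.FitResult`; in the returned estimates
    ``e_x`` / ``e_y`` are the residual standard deviations of X and Y and
    ``re`` their residual correlation.
    """
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 2 and arr.shape == (3, 3) and n is not None:
        cov3, n_obs = arr, int(n)
    elif arr.ndim == 2 and arr.shape[1] == 3:
        cov3, n_obs = np.cov(arr.T, ddof=1), arr.shape[0]
    else:
        raise ValueError(
            "data must be an (n, 3) table over (PGS, X, Y) or a 3x3 covariance "
            "with n given"
        )
    spec = _sem_spec(pleiotropy_free, resid_corr_fixed)
    if g1_fixed is not None:
        spec = spec.constrain(label=f"{spec.label}|g1={g1_fixed}", g1=g1_fixed)
    return fit_ml({"U": (cov3, n_obs)}, spec, starts=starts, **fit_kwargs)


def unrelated_from_twins(dataset) -> np.ndarray:
    """(n, 3) table of (PGS, X, Y) built from the twin-1 records of every
    pair — effectively a sample of unrelated individuals."""
    blocks = [b[:, :3] for b in (dataset.mz, dataset.dz) if b is not None]
    if not blocks:
        raise ValueError("empty twin dataset")
    return np.vstack(blocks)
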