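"""Twin-study data generation: exact-data simulation and Monte-Carlo sampling.

Exact-data simulation produces a finite sample whose sample covariance
(n - 1 divisor) equals a target matrix to machine precision, so that
maximum-likelihood fits of the generating model recover the generating
parameters without sampling noise.  This mirrors the ``empirical = TRUE``
style of multivariate-normal simulation used in twin-model power studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import MZ_KEEP, ParameterVector, VARIABLES, expected_covariance

__all__ = ["TwinDataset", "exact_mvn_sample", "simulate_twin_study"]

_RANK_TOL = 1e-10


@dataclass
class TwinDataset:
    """Per-zygosity twin-pair observations over (PGS, X, Y) for both twins.

    Either member may be empty (``None`` with a zero count).  Column order
    is fixed to :data:`mrdoc.model.VARIABLES`.
    """

    mz: np.ndarray | None
    dz: np.ndarray | None

    def __post_init__(self) -> None:
        for name in ("mz", "dz"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.ndim != 2 or arr.shape[1] != 6:
                    raise ValueError(f"{name} block must be (n, 6), got {arr.shape}")
                setattr(self, name, arr)

    @property
    def n_mz(self) -> int:
        return 0 if self.mz is None else self.mz.shape[0]

    @property
    def n_dz(self) -> int:
        return 0 if self.dz is None else self.dz.shape[0]

    def cov(self, zygosity: str) -> np.ndarray:
        """Sample covariance (n - 1 divisor) of one zygosity group."""
        arr = self.mz if zygosity.upper() == "MZ" else self.dz
        if arr is None or arr.shape[0] < 2:
            raise ValueError(f"no data (or a single pair) for zygosity {zygosity}")
        return np.cov(arr.T, ddof=1)

    def to_frame(self) -> pd.DataFrame:
        """Long table with family_id and zygosity columns (MZ rows first)."""
        blocks = []
        offset = 1
        for zyg, arr in (("MZ", self.mz), ("DZ", self.dz)):
            if arr is None or arr.shape[0] == 0:
                continue
            df = pd.DataFrame(arr, columns=list(VARIABLES))
            df.insert(0, "zygosity", zyg)
            df.insert(0, "family_id", np.arange(offset, offset + len(df)))
            offset += len(df)
            blocks.append(df)
        if not blocks:
            return pd.DataFrame(columns=["family_id", "zygosity", *VARIABLES])
        return pd.concat(blocks, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TwinDataset":
        missing = [c for c in ("zygosity", *VARIABLES) if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        bad = ~df["zygosity"].astype(str).str.upper().isin(["MZ", "DZ"])
        if bad.any():
            lines = (df.index[bad] + 2).tolist()  # 1-based + header
            raise ValueError(f"unknown zygosity token(s) at file line(s) {lines}")
        zyg = df["zygosity"].astype(str).str.upper()
        mz = df.loc[zyg == "MZ", list(VARIABLES)].to_numpy(dtype=float)
        dz = df.loc[zyg == "DZ", list(VARIABLES)].to_numpy(dtype=float)
        return cls(mz=mz if len(mz) else None, dz=dz if len(dz) else None)


def _psd_factor(cov: np.ndarray) -> np.ndarray:
    """Factor L (p x r) with L @ L.T == cov, allowing rank deficiency."""
    cov = np.asarray(cov, dtype=float)
    vals, vecs = np.linalg.eigh((cov + cov.T) / 2.0)
    tol = _RANK_TOL * max(vals.max(initial=0.0), 1.0)
    if vals.min() < -tol:
        raise np.linalg.LinAlgError(
            f"target covariance is not positive semi-definite (min eigenvalue {vals.min():.3e})"
        )
    keep = vals > tol
    return vecs[:, keep] * np.sqrt(vals[keep])


def exact_mvn_sample(
    target_cov: np.ndarray,
    n: int,
    seed: int | np.random.Generator = 0,
    mean: np.ndarray | None = None,
) -> np.ndarray:
    """Draw ``n`` observations whose sample covariance equals ``target_cov`` exactly.

    Normal deviates are drawn, centered, empirically whitened, then colored
    by a factor of the target; the (n - 1)-divisor sample covariance of the
    result matches the target to ~1e-12.  Rank-deficient targets (e.g. the
    MZ twin-pair matrix, where both twins carry the same polygenic score)
    are supported via an eigenvalue factorization.

    Parameters
    ----------
    target_cov : (p, p) positive semi-definite matrix.
    n : number of observations; must exceed the rank of the target.
    seed : int seed or a Generator (advanced; consumed).
    """
    target_cov = np.asarray(target_cov, dtype=float)
    p = target_cov.shape[0]
    if target_cov.shape != (p, p):
        raise ValueError("target_cov must be square")
    L = _psd_factor(target_cov)
    r = L.shape[1]
    if n <= r:
        raise ValueError(f"need n > rank(target) = {r}, got n = {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = rng.standard_normal((n, r))
    z -= z.mean(axis=0)
    s = np.cov(z.T, ddof=1).reshape(r, r)
    w = np.linalg.solve(np.linalg.cholesky(s), z.T).T  # exact unit sample covariance
    out = w @ L.T
    if mean is not None:
        out = out + np.asarray(mean, dtype=float)
    return out


def simulate_twin_study(
    theta: ParameterVector,
    n_mz: int,
    n_dz: int,
    mode: str = "exact",
    seed: int | np.random.Generator = 0,
) -> TwinDataset:
    """Simulate a twin study of ``n_mz`` MZ and ``n_dz`` DZ pairs from theta.

    ``mode="exact"`` makes each group's sample covariance equal the
    model-implied matrix exactly; ``mode="random"`` draws ordinary
    multivariate-normal samples.  Phenotypic means are zero.  Either pair
    count may be zero, yielding an empty group.
    """
    if mode not in ("exact", "random"):
        raise ValueError(f"mode must be 'exact' or 'random', got {mode!r}")
    if n_mz < 0 or n_dz < 0:
        raise ValueError("pair counts must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    blocks: dict[str, np.ndarray | None] = {}
    for key, zyg, n in (("mz", "MZ", n_mz), ("dz", "DZ", n_dz)):
        if n == 0:
            blocks[key] = None
            continue
        sigma = expected_covariance(theta, zyg)
        if mode == "exact":
            blocks[key] = exact_mvn_sample(sigma, n, rng)
        else:
            L = _psd_factor(sigma)
            blocks[key] = rng.standard_normal((n, L.shape[1])) @ L.T
    return TwinDataset(mz=blocks["mz"], dz=blocks["dz"])
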