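"""Data and configuration I/O: twin tables, scenario configs, fixtures."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import VARIABLES
from .scenarios import ScenarioSpec, recovery_scenario, theta_from_scenario
from .simulate import TwinDataset, simulate_twin_study

__all__ = [
    "read_twin_table",
    "write_twin_table",
    "read_scenario",
    "write_scenario",
    "generate_fixtures",
]

_COLUMNS = ("family_id", "zygosity", *VARIABLES)


def _sniff_sep(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    for sep in ("\t", ";", ","):
        if sep in header:
            return sep
    return r"\s+"


def read_twin_table(path) -> TwinDataset:
    """Read a delimited twin table (header: family_id, zygosity, pgs_1, x_1,
    y_1, pgs_2, x_2, y_2; zygosity MZ or DZ).  Tab, comma, semicolon or
    whitespace separated; floats are parsed at full round-trip precision."""
    sep = _sniff_sep(path)
    kwargs = {"float_precision": "round_trip"} if len(sep) == 1 else {"engine": "python"}
    df = pd.read_csv(path, sep=sep, **kwargs)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    for col in VARIABLES:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(df.index[bad][0]) + 2
            raise ValueError(
                f"{path}: non-numeric value {df.loc[df.index[bad][0], col]!r} "
                f"in column {col!r} (file line {row})"
            )
        df[col] = pd.to_numeric(df[col])
    try:
        return TwinDataset.from_frame(df)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_twin_table(dataset: TwinDataset, path) -> None:
    """Write a twin dataset as tab-separated text at full precision."""
    df = dataset.to_frame()
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_scenario(spec: ScenarioSpec, path) -> None:
    """Write a scenario spec as a flat key/value YAML file."""
    payload = {
        "instrument_r2": spec.instrument_r2,
        "resid_corr": spec.resid_corr,
        "ace_x": list(spec.ace_x),
        "ace_y": list(spec.ace_y),
        "b2": spec.b2,
        "total_r2_y": spec.total_r2_y,
        "re_zero": spec.re_zero,
        "resid_split": spec.resid_split,
        "x": spec.x,
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_scenario(path) -> ScenarioSpec:
    """Read a scenario spec from a flat key/value YAML file."""
    payload = yaml.safe_load(Path(path).read_text())
    if not isinstance(payload, dict):
        raise ValueError(f"{path}: expected a mapping of scenario fields")
    for key in ("ace_x", "ace_y"):
        if key in payload:
            payload[key] = tuple(payload[key])
    try:
        return ScenarioSpec(**payload)
    except TypeError as exc:
        raise ValueError(f"{path}: {exc}") from None


def generate_fixtures(out_dir, seed: int = 0, n_mz: int = 250, n_dz: int = 250) -> list[Path]:
    """Emit small self-contained datasets and their scenario configs.

    Writes exact-mode and random-mode twin tables for the three
    parameter-recovery scenarios plus one null (g1 = 0, non-pleiotropic)
    scenario; deterministic given the seed.  Returns the paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    bundles: dict[str, tuple[ScenarioSpec, bool]] = {
        f"recovery_s{i}": (recovery_scenario(i), False) for i in (1, 2, 3)
    }
    # Null bundle: the valid-instrument scenario with the causal path removed
    # (traits then explain slightly less than unit variance of Y).
    bundles["null_g1"] = (recovery_scenario(1), True)
    paths = []
    for name, (spec, null_g1) in bundles.items():
        theta = theta_from_scenario(spec)
        if null_g1:
            theta = theta.replace(g1=0.0)
        for mode in ("exact", "random"):
            data = simulate_twin_study(theta, n_mz, n_dz, mode=mode, seed=rng)
            p = out / f"{name}_{mode}.tsv"
            write_twin_table(data, p)
            paths.append(p)
        p = out / f"{name}.yaml"
        write_scenario(spec, p)
        paths.append(p)
    return paths
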