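"""Reading and writing the package's plain-text formats.

Pair data travel as CSV with header ``zygosity,x1,y1,x2,y2``; scenario
configurations as JSON or YAML; fit results and study reports as JSON.
Malformed pair files are rejected with the 1-based line number of the first
offending row.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import PAIR_COLUMNS, TwinDataset, ZYGOSITIES
from .estimation import FitResult
from .likelihood import MixtureWeights
from .model_core import CholeskyParams, DoCParams, ModelSpec
from .simulate import ScenarioConfig, make_params

__all__ = [
    "read_pairs",
    "write_pairs",
    "read_scenario",
    "write_fit_result",
    "read_fit_result",
    "write_report",
]


def read_pairs(path) -> TwinDataset:
    """Read a pair-level CSV, validating zygosity codes and numeric values."""
    df = pd.read_csv(path, dtype={"zygosity": str}, float_precision="round_trip")
    missing = [c for c in ("zygosity", *PAIR_COLUMNS) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    bad = ~df["zygosity"].isin(ZYGOSITIES)
    if bad.any():
        line = int(df.index[bad][0]) + 2  # header is line 1
        raise ValueError(
            f"{path}:{line}: unknown zygosity code {df['zygosity'][bad].iloc[0]!r}"
        )
    values = np.empty((len(df), 4))
    for j, col in enumerate(PAIR_COLUMNS):
        numeric = pd.to_numeric(df[col], errors="coerce")
        invalid = numeric.isna() & df[col].notna()
        if invalid.any():
            line = int(df.index[invalid][0]) + 2
            raise ValueError(f"{path}:{line}: non-numeric value in column {col!r}")
        values[:, j] = numeric.to_numpy(dtype=float)
    return TwinDataset(values=values, zygosity=df["zygosity"].to_numpy(dtype=object))


def write_pairs(data: TwinDataset, path) -> None:
    # %.17g round-trips IEEE doubles exactly
    data.to_frame().to_csv(path, index=False, float_format="%.17g")


def _load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yml", ".yaml"):
        return yaml.safe_load(text)
    return json.loads(text)


def read_scenario(path) -> ScenarioConfig:
    """Build a ScenarioConfig from a JSON/YAML file.

    Schema: ``n_mz``, ``n_dz`` (ints), optional ``family``, ``seed``,
    ``fixed_quota``, ``weights`` (``{"MZ": [4 floats], "DZ": [4 floats]}``),
    and either ``params`` (raw DoCParams fields) or ``design`` (arguments of
    :func:`mixdoc.simulate.make_params`, e.g. ``var_x``, ``b_xy``,
    ``mean_diff_x``).
    """
    cfg = _load_config(path)
    if "params" in cfg and "design" in cfg:
        raise ValueError(f"{path}: give either 'params' or 'design', not both")
    if "params" in cfg:
        params = DoCParams(**cfg["params"])
    elif "design" in cfg:
        design = dict(cfg["design"])
        for key in ("var_x", "var_y", "base_mean"):
            if key in design:
                design[key] = tuple(design[key])
        params = make_params(**design)
    else:
        raise ValueError(f"{path}: scenario needs a 'params' or 'design' block")
    kw = dict(
        n_mz=int(cfg["n_mz"]), n_dz=int(cfg["n_dz"]), params=params,
        family=cfg.get("family", "mix4"), seed=int(cfg.get("seed", 0)),
        fixed_quota=bool(cfg.get("fixed_quota", False)),
    )
    if "weights" in cfg:
        w = cfg["weights"]
        kw["weights"] = MixtureWeights(tuple(w["MZ"]), tuple(w["DZ"]))
    return ScenarioConfig(**kw)


def write_fit_result(result: FitResult, path) -> None:
    Path(path).write_text(json.dumps(result.to_dict(), indent=2) + "\n")


def read_fit_result(path) -> FitResult:
    """Rebuild a FitResult (estimates + spec) from its JSON form."""
    d = json.loads(Path(path).read_text())
    spec = ModelSpec(
        family=d["family"], confound_ra_free=d.get("confound_ra_free", False)
    )
    est = d["estimates"]
    if spec.family == "cholesky":
        params = CholeskyParams(
            l_a=np.asarray(est["l_a"]), l_c=np.asarray(est["l_c"]),
            l_e=np.asarray(est["l_e"]), mu=np.asarray(est["mu"]),
        )
    else:
        params = DoCParams(**est)
    weights = None
    if "weights" in d:
        weights = MixtureWeights(tuple(d["weights"]["MZ"]), tuple(d["weights"]["DZ"]))
    return FitResult(
        spec=spec, params=params, weights=weights,
        minus2ll=d["minus2ll"], k=d["k"], df=d["df"], aic=d["aic"],
        converged=d["converged"], n_starts_used=d.get("n_starts_used", 0),
        best_start=d.get("best_start", 0), n_iter=0, start_minus2lls=(),
    )


def write_report(report, path, fmt: str = "json") -> None:
    """Write a StudyReport (json) or a DataFrame (csv or json)."""
    path = Path(path)
    if isinstance(report, pd.DataFrame):
        if fmt == "csv":
            report.to_csv(path, index=False)
        else:
            path.write_text(report.to_json(orient="records", indent=2))
        return
    if fmt != "json":
        raise ValueError("full study reports are written as JSON")
    path.write_text(report.to_json() + "\n")
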