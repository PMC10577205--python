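"""Report serialisation and the end-to-end runner.

Every output table carries a provenance header (config hash, seed, package
version) as ``#``-prefixed comment lines; the machine-readable summary is a
single JSON file whose bytes are identical across runs with the same config
and seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, is_dataclass

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .group_stats import run_full_analysis
from .pipeline import simulate_and_extract_cohort


def write_table(df: pd.DataFrame, path: str, config: RunConfig) -> None:
    """Tab-separated table with a provenance comment header."""
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    with open(path, "w") as f:
        f.write(f"# burnout-erp {__version__}\n")
        f.write(f"# config={config.digest()} seed={config.seed}\n")
        df.to_csv(f, sep="\t", index=False)


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, pd.DataFrame):
        return [_jsonable(r) for r in obj.to_dict(orient="records")]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        if np.isnan(v):
            return None
        if np.isinf(v):
            return "inf" if v > 0 else "-inf"
        return round(v, 10)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj


def report_to_json(report: dict, path: str) -> None:
    with open(path, "w") as f:
        json.dump(_jsonable(report), f, sort_keys=True, indent=1)
        f.write("\n")


def run_end_to_end(config: RunConfig) -> dict:
    """simulate -> extract -> analyze; writes all tables plus summary.json.

    Returns the in-memory report.  Identical (config, seed) produce
    byte-identical ``summary.json``.
    """
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    config.to_yaml(os.path.join(out, "config.yaml"))

    res = simulate_and_extract_cohort(
        config.n_burnout, config.n_non_burnout, config.seed,
        dispersed=config.dispersed, min_epochs=config.min_epochs,
        threshold_uv=config.threshold_uv)
    for name in ("profiles", "measurements", "behavior", "rejections",
                 "generative"):
        write_table(res[name], os.path.join(out, f"{name}.tsv"), config)
    if res["outcomes"] is not None:
        write_table(res["outcomes"], os.path.join(out, "outcomes.tsv"), config)

    report = run_full_analysis(res["measurements"], res["profiles"],
                               outcomes=res["outcomes"],
                               behavior=res["behavior"])
    report["config"] = {"digest": config.digest(), "seed": config.seed,
                        "version": __version__}
    report_to_json(report, os.path.join(out, "summary.json"))
    return report
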