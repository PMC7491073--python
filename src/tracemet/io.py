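"""CSV/YAML helpers for the command-line interface.

Tidy-table schemas:

* samples/standards: (group, line, tracer,) metabolite, isotopologue,
  replicate, abundance
* traces: well, time_min, measurement in {ECAR, OCR}, value, phase
* injections: well, label, time_min
* flat YAML-compatible key-value configs for flux parameters
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .instruments import FluxTrace
from .propagate import FluxParameterSet

__all__ = [
    "write_traces_csv",
    "read_traces_csv",
    "params_to_dict",
    "params_from_dict",
    "save_config",
    "load_config",
]


def write_traces_csv(traces: list[FluxTrace], trace_path, injection_path) -> None:
    frames, inj_rows = [], []
    for tr in traces:
        df = tr.data.copy()
        df.insert(0, "well", tr.well)
        df["protein_mg"] = tr.protein_mg
        frames.append(df)
        for label, t in tr.injections:
            inj_rows.append({"well": tr.well, "label": label, "time_min": t})
    pd.concat(frames, ignore_index=True).to_csv(trace_path, index=False)
    pd.DataFrame(inj_rows).to_csv(injection_path, index=False)


def read_traces_csv(trace_path, injection_path) -> list[FluxTrace]:
    data = pd.read_csv(trace_path)
    inj = pd.read_csv(injection_path)
    traces = []
    for well, sub in data.groupby("well", sort=False):
        inj_sub = inj[inj["well"] == well].sort_values("time_min")
        injections = list(zip(inj_sub["label"], inj_sub["time_min"].astype(float)))
        protein = float(sub["protein_mg"].iloc[0]) if "protein_mg" in sub else 1.0
        tr = FluxTrace(
            well=str(well),
            data=sub.drop(columns=[c for c in ("well", "protein_mg") if c in sub]).reset_index(drop=True),
            injections=injections,
            protein_mg=protein,
        )
        tr.validate()
        traces.append(tr)
    return traces


def params_to_dict(params: FluxParameterSet) -> dict:
    d = {
        k: getattr(params, k)
        for k in (
            "f_glycolysis",
            "f_accoa_dilution",
            "w_cit",
            "w_glu_in",
            "w_dil",
            "f_pag",
            "f_glu_from_akg",
            "f_uptake_glu",
            "f_uptake_gln",
            "f_got",
            "f_gs",
            "n_turns",
        )
    }
    rho = params.rho
    if isinstance(rho, dict):
        d.update({f"rho.{k}": v for k, v in sorted(rho.items())})
    else:
        d["rho"] = rho
    d.update({f"pool.{k}": v for k, v in sorted(params.pool_sizes.items())})
    return d


def params_from_dict(d: dict) -> FluxParameterSet:
    rho_items = {k.split(".", 1)[1]: v for k, v in d.items() if k.startswith("rho.")}
    pools = {k.split(".", 1)[1]: v for k, v in d.items() if k.startswith("pool.")}
    plain = {k: v for k, v in d.items() if "." not in k}
    if rho_items:
        plain["rho"] = rho_items
    return FluxParameterSet(**plain, pool_sizes=pools)


def save_config(params: FluxParameterSet, path) -> None:
    Path(path).write_text(yaml.safe_dump(params_to_dict(params), sort_keys=True))


def load_config(path) -> FluxParameterSet:
    return params_from_dict(yaml.safe_load(Path(path).read_text()))
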