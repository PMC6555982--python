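"""CSV/JSON/YAML input-output for traces, summaries and configurations.

CSV dialect: comma-separated, '.' decimal, UTF-8, mandatory header row, times
in ms. Pacing metadata (BCL, beat count) rides in '#'-prefixed comment lines
ahead of the header so every trace file is self-describing and stages can
interoperate through files alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import CaTransient, PacedTraces
from .metrics import AlternansThresholds
from .myofilament import LoadCondition, MechTraces
from .protocol import CellRun, SweepConfig, SweepResult

ELECTRICAL_COLUMNS = ["time_ms", "Vm_mV", "Cai_uM", "CaSR_mM", "Cass_mM"]
MECH_COLUMNS = ["time_ms", "tension_kPa", "force_norm", "ATP_norm", "SL_um",
                "eq_length"]
CA_COLUMNS = ["time_ms", "Cai_uM"]


def _write_csv(path, df: pd.DataFrame, meta: dict):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for k, v in meta.items():
            fh.write(f"# {k} = {v}\n")
        # %.17g round-trips float64 exactly (stage hand-off stays bit-identical)
        df.to_csv(fh, index=False, lineterminator="\n", float_format="%.17g")


def _read_meta(path) -> dict:
    meta = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].partition("=")
            meta[key.strip()] = val.strip()
    return meta


def _read_csv(path, required_columns) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = _read_meta(path)
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:
        raise ValueError(f"{path}: malformed CSV ({exc})") from exc
    missing = set(required_columns) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    df = df.apply(pd.to_numeric, errors="coerce")
    if df.isna().any().any():
        bad = int(df.isna().any(axis=1).idxmax()) + 2  # +header +1-based
        raise ValueError(f"{path}: non-numeric or missing value near line {bad}")
    return df, meta


def write_electrical_csv(path, tr: PacedTraces):
    df = pd.DataFrame({"time_ms": tr.time, "Vm_mV": tr.vm,
                       "Cai_uM": tr.cai * 1e3, "CaSR_mM": tr.casr,
                       "Cass_mM": tr.cass})
    _write_csv(path, df, {"bcl_ms": tr.bcl, "n_beats": tr.n_beats})


def read_electrical_csv(path) -> PacedTraces:
    df, meta = _read_csv(path, ELECTRICAL_COLUMNS)
    t = df["time_ms"].to_numpy()
    dt = float(t[1] - t[0])
    return PacedTraces(dt=dt, vm=df["Vm_mV"].to_numpy(),
                       cai=df["Cai_uM"].to_numpy() / 1e3,
                       casr=df["CaSR_mM"].to_numpy(),
                       cass=df["Cass_mM"].to_numpy(),
                       bcl=float(meta["bcl_ms"]), n_beats=int(meta["n_beats"]))


def write_ca_csv(path, ca: CaTransient):
    df = pd.DataFrame({"time_ms": ca.time, "Cai_uM": ca.ca})
    _write_csv(path, df, {"bcl_ms": ca.bcl, "n_beats": ca.n_beats})


def read_ca_csv(path) -> CaTransient:
    df, meta = _read_csv(path, CA_COLUMNS)
    t = df["time_ms"].to_numpy()
    return CaTransient(dt=float(t[1] - t[0]), ca=df["Cai_uM"].to_numpy(),
                       bcl=float(meta["bcl_ms"]), n_beats=int(meta["n_beats"]))


def write_mech_csv(path, m: MechTraces):
    df = pd.DataFrame({"time_ms": m.time, "tension_kPa": m.tension,
                       "force_norm": m.force_norm, "ATP_norm": m.atp,
                       "SL_um": m.sl, "eq_length": m.eq_length})
    _write_csv(path, df, {"bcl_ms": m.bcl, "n_beats": m.n_beats})


def read_mech_csv(path) -> MechTraces:
    df, meta = _read_csv(path, MECH_COLUMNS)
    t = df["time_ms"].to_numpy()
    return MechTraces(dt=float(t[1] - t[0]),
                      tension=df["tension_kPa"].to_numpy(),
                      force_norm=df["force_norm"].to_numpy(),
                      atp=df["ATP_norm"].to_numpy(), sl=df["SL_um"].to_numpy(),
                      eq_length=df["eq_length"].to_numpy(),
                      bcl=float(meta["bcl_ms"]), n_beats=int(meta["n_beats"]))


def summary_frame(sweep: SweepResult) -> pd.DataFrame:
    """Flat per-(variant, BCL, load, beat) table of all metrics."""
    rows = []
    for (variant, bcl), rec in sweep.electrical_records():
        for b, m in sorted(rec["metrics"].items()):
            rows.append({"variant": variant, "bcl": bcl, "load_kPa": np.nan,
                         "stage": "electrical", **m.as_dict()})
    for (variant, bcl, load), rec in sweep.mechanical_records():
        for b, m in sorted(rec["metrics"].items()):
            rows.append({"variant": variant, "bcl": bcl, "load_kPa": load,
                         "stage": "mechanical", **m.as_dict()})
    return pd.DataFrame(rows)


def alternans_report_dict(sweep: SweepResult) -> dict:
    out = {"thresholds": asdict(sweep.config.thresholds), "electrical": [],
           "mechanical": []}
    for (variant, bcl), rec in sweep.electrical_records():
        out["electrical"].append({"variant": variant, "bcl": bcl,
                                  **rec["alternans"].as_dict()})
    for (variant, bcl, load), rec in sweep.mechanical_records():
        out["mechanical"].append({"variant": variant, "bcl": bcl,
                                  "load_kPa": load, **rec["alternans"].as_dict()})
    return out


# -- configuration ------------------------------------------------------------

def config_to_dict(config: SweepConfig) -> dict:
    return {
        "cell_variants": list(config.cell_variants),
        "bcl_list": [float(b) for b in config.bcl_list],
        "n_beats": config.n_beats,
        "record_beats": list(config.record_beats),
        "loads": [{"mode": l.mode, "afterload": l.afterload,
                   "preload": l.preload} for l in config.loads],
        "stim_amplitude": config.stim_amplitude,
        "stim_duration": config.stim_duration,
        "solver": config.solver,
        "dt": config.dt,
        "dt_out": config.dt_out,
        "mech_dt": config.mech_dt,
        "apd_fraction": config.apd_fraction,
        "thresholds": {"apd_ms": config.thresholds.apd_ms,
                       "rel_amplitude": config.thresholds.rel_amplitude},
        "seed": config.seed,
    }


def config_from_dict(d: dict) -> SweepConfig:
    d = dict(d)
    kwargs = {}
    simple = ("n_beats", "stim_amplitude", "stim_duration", "solver", "dt",
              "dt_out", "mech_dt", "apd_fraction", "seed")
    for key in simple:
        if key in d:
            kwargs[key] = d[key]
    if "cell_variants" in d:
        kwargs["cell_variants"] = tuple(d["cell_variants"])
    if "bcl_list" in d:
        kwargs["bcl_list"] = tuple(float(b) for b in d["bcl_list"])
    if "record_beats" in d:
        kwargs["record_beats"] = tuple(int(b) for b in d["record_beats"])
    if "loads" in d:
        kwargs["loads"] = tuple(
            LoadCondition(mode=l.get("mode", "isotonic"),
                          afterload=float(l.get("afterload", 10.0)),
                          preload=l.get("preload")) for l in d["loads"])
    if "thresholds" in d:
        kwargs["thresholds"] = AlternansThresholds(**d["thresholds"])
    known = set(simple) | {"cell_variants", "bcl_list", "record_beats",
                           "loads", "thresholds"}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown config field(s): {sorted(unknown)}")
    return SweepConfig(**kwargs)


def load_config(path) -> SweepConfig:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return config_from_dict(data)


def save_config(path, config: SweepConfig):
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def config_hash(config: SweepConfig) -> str:
    blob = json.dumps(config_to_dict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# -- run persistence ----------------------------------------------------------

def trace_paths(outdir, variant: str, bcl: float) -> dict:
    stem = f"{variant}_bcl{bcl:g}"
    outdir = Path(outdir)
    return {"electrical": outdir / f"{stem}_electrical.csv",
            "ca": outdir / f"{stem}_ca.csv",
            "mech": lambda load: outdir / f"{stem}_load{load:g}_mech.csv"}


def write_cell_run(outdir, run: CellRun) -> list[str]:
    """Persist one combination's traces; returns the files written."""
    paths = trace_paths(outdir, run.variant, run.bcl)
    write_electrical_csv(paths["electrical"], run.electrical)
    write_ca_csv(paths["ca"], run.ca)
    written = [str(paths["electrical"]), str(paths["ca"])]
    for load, m in run.mechanics.items():
        p = paths["mech"](load)
        write_mech_csv(p, m)
        written.append(str(p))
    return written


def write_manifest(path, config: SweepConfig, files: list[str], status: dict):
    from . import __version__
    manifest = {
        "code_version": __version__,
        "config_hash": config_hash(config),
        "config": config_to_dict(config),
        "files": sorted(files),
        "status": status,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
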