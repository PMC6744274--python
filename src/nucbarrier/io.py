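"""File formats, configuration and run manifests.

Everything on disk is tab-separated text with unit-bearing column names
and a ``# key: value`` metadata comment block, chosen for inspectability
over binary formats.  Configurations are YAML mappings; a run's config
plus seed reproduces its outputs bit-for-bit for the deterministic
stages.
"""

from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ValidationError
from .hopping import EnergyLandscape
from .trace import Trace, TxnTrace
from .unzip import ResidenceMap

__all__ = [
    "read_trace", "write_trace", "read_txn_trace", "write_txn_trace",
    "read_landscape", "write_landscape", "read_residence_map",
    "write_residence_map", "load_config", "run_pipeline",
    "template_sequence",
]

TRACE_COLUMNS = ["time_s", "force_pN", "extension_nm"]
TXN_COLUMNS = ["time_s", "position_nm", "force_pN"]


def _parse_meta_value(v: str):
    for cast in (int, float):
        try:
            return cast(v)
        except ValueError:
            pass
    return v


def _read_tsv(path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    meta = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = _parse_meta_value(v.strip())
    try:
        df = pd.read_csv(path, sep="\t", skiprows=skip,
                         float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    return df, meta


def _write_tsv(path, df: pd.DataFrame, meta: dict) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing column(s) {missing}; expected header {cols}")


def read_trace(path) -> Trace:
    """Read a force-spectroscopy trace TSV (time_s, force_pN, extension_nm)."""
    df, meta = _read_tsv(path)
    _require_columns(df, TRACE_COLUMNS, path)
    return Trace(time=df["time_s"].to_numpy(),
                 force=df["force_pN"].to_numpy(),
                 extension=df["extension_nm"].to_numpy(),
                 sample_rate=float(meta.get("sample_rate_hz", 800.0)),
                 protocol=str(meta.get("protocol", "constant_velocity")),
                 metadata=meta)


def write_trace(path, trace: Trace) -> None:
    meta = {k: v for k, v in trace.metadata.items()
            if isinstance(v, (str, int, float))}
    meta["sample_rate_hz"] = trace.sample_rate
    meta["protocol"] = trace.protocol
    df = pd.DataFrame({"time_s": trace.time, "force_pN": trace.force,
                       "extension_nm": trace.extension})
    _write_tsv(path, df, meta)


def read_txn_trace(path) -> TxnTrace:
    """Read a transcription trace TSV (time_s, position_nm, force_pN)."""
    df, meta = _read_tsv(path)
    _require_columns(df, TXN_COLUMNS, path)
    return TxnTrace(time=df["time_s"].to_numpy(),
                    position=df["position_nm"].to_numpy(),
                    force=float(df["force_pN"].iloc[0]),
                    sample_rate=float(meta.get("sample_rate_hz", 800.0)),
                    metadata=meta)


def write_txn_trace(path, trace: TxnTrace) -> None:
    meta = {k: v for k, v in trace.metadata.items()
            if isinstance(v, (str, int, float))}
    meta["sample_rate_hz"] = trace.sample_rate
    df = pd.DataFrame({"time_s": trace.time, "position_nm": trace.position,
                       "force_pN": np.full(len(trace), trace.force)})
    _write_tsv(path, df, meta)


def write_landscape(path, landscape: EnergyLandscape) -> None:
    df = pd.DataFrame({
        "N_bp": landscape.positions,
        "per_bp_kBT": landscape.per_bp_energy,
        "cumulative_kBT": landscape.cumulative_energy,
        "n_support": landscape.support_counts,
    })
    _write_tsv(path, df, {"provenance": landscape.provenance,
                          **{k: v for k, v in landscape.metadata.items()
                             if isinstance(v, (str, int, float))}})


def read_landscape(path) -> EnergyLandscape:
    df, meta = _read_tsv(path)
    _require_columns(df, ["N_bp", "per_bp_kBT"], path)
    return EnergyLandscape(
        positions=df["N_bp"].to_numpy(),
        per_bp_energy=df["per_bp_kBT"].to_numpy(),
        cumulative_energy=(df["cumulative_kBT"].to_numpy()
                           if "cumulative_kBT" in df else None),
        support_counts=(df["n_support"].to_numpy()
                        if "n_support" in df else None),
        provenance=str(meta.get("provenance", "bare")), metadata=meta)


def write_residence_map(path, rmap: ResidenceMap) -> None:
    df = pd.DataFrame({"position_bp": rmap.positions, "value": rmap.values,
                       "n": np.full(len(rmap.positions), rmap.n_traces)})
    _write_tsv(path, df, {"mode": rmap.mode, "bin_width_bp": rmap.bin_width,
                          "aggregation": rmap.aggregation})


def read_residence_map(path) -> ResidenceMap:
    df, meta = _read_tsv(path)
    _require_columns(df, ["position_bp", "value"], path)
    return ResidenceMap(df["position_bp"].to_numpy(),
                        df["value"].to_numpy(),
                        bin_width=float(meta.get("bin_width_bp", 1.0)),
                        mode=str(meta.get("mode", "force_weighted")),
                        aggregation=str(meta.get("aggregation", "single")),
                        n_traces=int(df["n"].iloc[0]) if "n" in df else 1)


def template_sequence(which: str = "unzipping") -> str:
    """Shipped template sequence: 'unzipping' stem or 'transcription'."""
    from importlib.resources import files

    name = {"unzipping": "unzipping_template.fasta",
            "transcription": "transcription_template.fasta"}.get(which)
    if name is None:
        raise ValidationError(f"unknown template {which!r}")
    text = (files("nucbarrier") / "data" / name).read_text()
    return "".join(line.strip() for line in text.splitlines()
                   if not line.startswith(">"))


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValidationError("config must be a YAML mapping")
    return cfg


KNOWN_STAGES = ("synth-unzip", "unzip-map", "synth-txn", "txn-map",
                "polii-dwell", "polii-fit")


def run_pipeline(config: dict, out_dir) -> dict:
    """Run the selected stages in dependency order; returns a manifest.

    The manifest records package version, python version, seed, the
    config hash and per-stage artifact paths; it suffices to re-run any
    stage identically.  A stage failure is recorded and stops the run.
    """
    from . import __version__
    from .ratchet import InteractionProfile, mean_dwell_profile
    from .synth import (LandscapeSpec, gen_landscape, gen_txn_trace,
                        gen_unzip_trace, wt_interaction_peaks)
    from .polymer import PolymerParams, TetherComposition
    from .txn import detect_ruler, dwell_map, register_bp
    from .unzip import residence_histogram, to_bp_coordinates

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", [])
    for s in stages:
        if s not in KNOWN_STAGES:
            raise ValidationError(f"unknown stage {s!r}; known: {KNOWN_STAGES}")
    seed = int(config.get("seed", 0))
    n_traces = int(config.get("n_traces", 3))
    manifest = {
        "version": __version__,
        "python": sys.version.split()[0],
        "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()).hexdigest(),
        "stages": {},
    }
    params = PolymerParams.preset("hopping")
    comp = TetherComposition(n_ds_bp=1850)
    state: dict = {}
    try:
        for stage in stages:
            if stage == "synth-unzip":
                peaks = [(p + 248, h, w) for p, h, w in
                         wt_interaction_peaks(config.get("peak_height_kbt", 3.0))]
                land = gen_landscape(LandscapeSpec(peaks=peaks))
                paths = []
                for i in range(n_traces):
                    tr = gen_unzip_trace(land, comp=comp, params=params,
                                         seed=seed + i)
                    p = out_dir / f"unzip_trace_{i:03d}.tsv"
                    write_trace(p, tr)
                    paths.append(str(p))
                state["unzip_traces"] = paths
                manifest["stages"][stage] = {"artifacts": paths}
            elif stage == "unzip-map":
                maps = []
                for p in state.get("unzip_traces", []):
                    tr = read_trace(p)
                    pos = to_bp_coordinates(tr, comp, params)
                    maps.append(residence_histogram(
                        pos, tr.force, mode="force_weighted",
                        bin_width=1.0, sample_rate=tr.sample_rate,
                        pos_range=(-250.0, 190.0)))
                from .unzip import aggregate_maps
                agg = aggregate_maps(maps, stat="mean")
                p = out_dir / "unzip_map.tsv"
                write_residence_map(p, agg)
                manifest["stages"][stage] = {"artifacts": [str(p)]}
            elif stage == "synth-txn":
                phi = InteractionProfile(
                    np.full(147, float(config.get("phi_kbt", 1.0))))
                paths = []
                for i in range(n_traces):
                    tr = gen_txn_trace(phi, seed=seed + i)
                    p = out_dir / f"txn_trace_{i:03d}.tsv"
                    write_txn_trace(p, tr)
                    paths.append(str(p))
                state["txn_traces"] = paths
                manifest["stages"][stage] = {"artifacts": paths}
            elif stage == "txn-map":
                traces = []
                for p in state.get("txn_traces", []):
                    tr = read_txn_trace(p)
                    period, phase, _ = detect_ruler(tr)
                    traces.append(register_bp(tr, period, phase))
                dm = dwell_map(traces)
                p = out_dir / "txn_dwell_map.tsv"
                write_residence_map(p, dm)
                state["dwell_map"] = str(p)
                manifest["stages"][stage] = {"artifacts": [str(p)]}
            elif stage == "polii-dwell":
                phi = InteractionProfile(
                    np.full(147, float(config.get("phi_kbt", 1.0))))
                pos, dw = mean_dwell_profile(phi)
                p = out_dir / "model_dwell.tsv"
                _write_tsv(p, pd.DataFrame({"j_bp": pos, "dwell_s": dw}), {})
                manifest["stages"][stage] = {"artifacts": [str(p)]}
            elif stage == "polii-fit":
                from .ratchet import fit_interaction_energies
                rmap = read_residence_map(state["dwell_map"])
                fit = fit_interaction_energies(
                    rmap.positions.astype(int), rmap.values,
                    max_nfev=int(config.get("fit_max_nfev", 30)))
                p = out_dir / "fitted_phi.tsv"
                _write_tsv(p, pd.DataFrame(
                    {"i_bp": np.arange(1, len(fit.profile.phi) + 1),
                     "phi_kBT": fit.profile.phi}), {})
                manifest["stages"][stage] = {
                    "artifacts": [str(p)],
                    "residual_rms_s": fit.residual_rms,
                }
    except Exception as exc:
        manifest["failure"] = {"stage": stage, "error": str(exc)}
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
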