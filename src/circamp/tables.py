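"""Deterministic CSV + JSON-sidecar output for analysis artifacts.

Every artifact (response curve, amplitude-response map, metric report)
writes a CSV in its documented column format plus a ``*.meta.json``
sidecar recording the model, parameters, seed and software version, so a
written table can be reloaded exactly and traced to its run."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import __version__
from .actogram import AmplitudeResponseMap
from .light import PulseProtocol
from .metrics import ProfileMetrics, RelativeChange
from .response import ResponseCurve

__all__ = ["write_tables", "read_response_curve"]


def _sidecar(meta: dict, csv_path: Path) -> Path:
    path = csv_path.with_suffix(".meta.json")
    meta = dict(meta)
    meta["software_version"] = __version__
    path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path


def write_tables(artifact, outdir, stem: str = None, extra_meta: dict = None) -> list:
    """Write ``artifact`` under ``outdir``; returns the created paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    extra = extra_meta or {}

    if isinstance(artifact, ResponseCurve):
        name = stem or f"response_{artifact.model_name}"
        csv_path = outdir / f"{name}.csv"
        artifact.to_frame().to_csv(csv_path, index=False)
        meta = artifact.metadata()
        meta.update(extra)
        return [csv_path, _sidecar(meta, csv_path)]

    if isinstance(artifact, AmplitudeResponseMap):
        name = stem or f"actogram_map_{artifact.model_name}"
        csv_path = outdir / f"{name}.csv"
        artifact.to_csv(csv_path)
        meta = dict(artifact.metadata)
        meta.update(extra)
        return [csv_path, _sidecar(meta, csv_path)]

    if isinstance(artifact, (ProfileMetrics, RelativeChange)):
        name = stem or (
            "profile_metrics" if isinstance(artifact, ProfileMetrics) else "relative_change"
        )
        d = artifact.as_dict()
        csv_path = outdir / f"{name}.csv"
        pd.json_normalize(d).to_csv(csv_path, index=False)
        json_path = outdir / f"{name}.json"
        json_path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")
        return [csv_path, json_path, _sidecar(extra, csv_path)]

    raise TypeError(f"don't know how to write a {type(artifact).__name__}")


def read_response_curve(csv_path) -> ResponseCurve:
    """Reload a response curve written by :func:`write_tables`."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta = json.loads(csv_path.with_suffix(".meta.json").read_text())
    proto = meta["protocol"]
    return ResponseCurve(
        model_name=meta["model"],
        protocol=PulseProtocol(
            duration=proto["duration_h"],
            intensity=proto["intensity_lux"],
            background=proto["background_lux"],
            reference=proto["reference"],
        ),
        phases_cbtmin=df["phase_rel_cbtmin_h"].to_numpy(),
        phases_dlmo=df["phase_rel_dlmo_h"].to_numpy(),
        delta_phi=df["delta_phi_h"].to_numpy(),
        pct_amp_change=df["pct_amp_change"].to_numpy(),
        drift_applied=meta["drift_applied_h"],
        dlmo_offset=meta["dlmo_offset_h"],
    )
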