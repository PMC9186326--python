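"""Text-format readers/writers, run configuration, and reporting.

Survey data travel in the de facto SECR text layout: a detector file
(id, x, y), a capture file with one row per detection (session, individual
id, occasion 1-based, detector id, sex), and an optional usage CSV
(detector x occasion effort in [0, 1]; defaults to all ones).  All files
are comma-separated UTF-8 with a mandatory header row.  Occasions are
1-based in files and 0-based internally.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import CaptureHistories, TrapArray

log = logging.getLogger("scrpath")


@dataclass
class RunConfig:
    """Configuration for a full fit/compare run."""

    trap_file: str = ""
    capture_file: str = ""
    usage_file: str | None = None
    raster_files: dict = field(default_factory=dict)
    buffer: float = 15_000.0
    mesh_spacing: float = 1_000.0
    resolutions: list = field(default_factory=lambda: [30, 60, 120, 240, 480, 960])
    covariates: list = field(default_factory=lambda: ["roads", "ruggedness", "water"])
    alpha: float = 0.05
    directions: int = 16
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(**data)

    def validate_paths(self) -> None:
        for p in [self.trap_file, self.capture_file, self.usage_file,
                  *self.raster_files.values()]:
            if p and not Path(p).exists():
                raise FileNotFoundError(p)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Survey I/O
# ---------------------------------------------------------------------------

def read_survey(trapfile, capturefile, usagefile=None,
                sex_column: str = "sex") -> tuple[TrapArray, CaptureHistories]:
    """Read detector, capture, and optional usage files.

    Detections referencing unknown detectors or out-of-range occasions, and
    detections at zero-usage trap-occasions, are rejected with the
    offending row number.  A missing usage file defaults to full effort
    with a logged warning.
    """
    traps_df = pd.read_csv(trapfile)
    if traps_df["id"].duplicated().any():
        dups = traps_df["id"][traps_df["id"].duplicated()].tolist()
        raise ValueError(f"duplicate detector ids: {dups}")
    ids = traps_df["id"].astype(str).tolist()
    xy = traps_df[["x", "y"]].to_numpy(dtype=float)

    caps = pd.read_csv(capturefile)
    if sex_column not in caps.columns:
        raise ValueError(f"capture file lacks a {sex_column!r} column")
    n_occ = int(caps["occasion"].max())

    if usagefile is not None:
        usage_df = pd.read_csv(usagefile)
        usage = usage_df.set_index("id").loc[ids].to_numpy(dtype=float)
        n_occ = usage.shape[1]   # the usage file defines the occasion count
    else:
        log.warning("no usage file given; assuming full effort everywhere")
        usage = np.ones((len(ids), n_occ))
    traps = TrapArray(ids=ids, xy=xy, usage=usage)

    trap_index = {t: i for i, t in enumerate(ids)}
    indiv = list(dict.fromkeys(caps["individual"].astype(str)))
    ind_index = {a: i for i, a in enumerate(indiv)}
    omega = np.zeros((len(indiv), n_occ, len(ids)), dtype=np.uint8)
    sex = np.full(len(indiv), "", dtype="<U1")
    for rownum, row in caps.iterrows():
        det = str(row["detector"])
        if det not in trap_index:
            raise ValueError(f"row {rownum}: unknown detector {det!r}")
        occ = int(row["occasion"])
        if not 1 <= occ <= n_occ:
            raise ValueError(f"row {rownum}: occasion {occ} out of range 1..{n_occ}")
        k, s = trap_index[det], occ - 1
        if usage[k, s] <= 0:
            raise ValueError(
                f"row {rownum}: detection at zero-usage detector/occasion")
        i = ind_index[str(row["individual"])]
        omega[i, s, k] = 1
        sx = str(row[sex_column]).strip().upper()[:1]
        if sx not in ("F", "M"):
            raise ValueError(f"row {rownum}: individual without valid sex")
        sex[i] = sx
    if (sex == "").any():
        raise ValueError("individual with no sex label")
    return traps, CaptureHistories(omega, sex, ids=indiv)


def write_survey(traps: TrapArray, data: CaptureHistories, outdir,
                 session: str = "sim") -> dict:
    """Write detector/capture/usage CSVs; inverse of :func:`read_survey`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "traps": outdir / "traps.csv",
        "captures": outdir / "captures.csv",
        "usage": outdir / "usage.csv",
    }
    pd.DataFrame({"id": traps.ids, "x": traps.xy[:, 0],
                  "y": traps.xy[:, 1]}).to_csv(paths["traps"], index=False)
    usage_df = pd.DataFrame(traps.usage,
                            columns=[f"occ{s+1}" for s in range(traps.n_occasions)])
    usage_df.insert(0, "id", traps.ids)
    usage_df.to_csv(paths["usage"], index=False)

    ids = data.ids or [f"A{i+1:04d}" for i in range(data.n_individuals)]
    rows = []
    for i, s, k in zip(*np.nonzero(data.omega)):
        rows.append({"session": session, "individual": ids[i],
                     "occasion": s + 1, "detector": traps.ids[k],
                     "sex": data.sex[i]})
    pd.DataFrame(rows, columns=["session", "individual", "occasion",
                                "detector", "sex"]).to_csv(
        paths["captures"], index=False)
    return paths


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def write_report(records, summary_df, outdir, base_fit=None,
                 config_hash: str = "", seed: int | None = None) -> dict:
    """Write the per-model CSV, summary CSV, full JSON, and a run log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = [r.to_row() for r in records]
    columns = ["model", "loglik", "converged", "density", "rse", "lrt_stat",
               "lrt_df", "lrt_p", "significant", "delta_density_pct",
               "delta_rse_pct", "flag_density", "flag_precision"]
    per_model = pd.DataFrame(rows) if rows else pd.DataFrame(columns=columns)
    paths = {
        "models": outdir / "models.csv",
        "summary": outdir / "summary.csv",
        "fits": outdir / "fits.json",
        "log": outdir / "run.log",
    }
    per_model.to_csv(paths["models"], index=False)
    summary_df.to_csv(paths["summary"], index=False)
    payload = {
        "config_hash": config_hash,
        "seed": seed,
        "base_fit": base_fit.to_dict() if base_fit is not None else None,
        "records": rows,
    }
    paths["fits"].write_text(json.dumps(payload, indent=2, default=_jsonify))
    paths["log"].write_text(
        f"config_hash={config_hash}\nseed={seed}\n"
        f"n_records={len(records)}\n")
    return paths


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
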