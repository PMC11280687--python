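"""Frozen plain-text file dialects tying the pipeline stages together.

Everything is CSV/JSON: per-subject trajectory CSVs plus a cohort
metadata CSV and a JSON manifest for cohorts; a long-format cycle CSV for
segmented cycles; a tidy per-row feature CSV; prediction CSVs; and a
manifest (input checksums, config hash, seed, package version) next to
every artifact set.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cyclogram import FEATURE_NAMES, cycle_feature_vector
from .events import N_CHANNELS, N_POINTS, GaitCycle
from .synthetic import CLINICAL_FIELDS, CHANNEL_ORDER, JointTrajectory, SubjectRecord, ValidationError

METADATA_COLUMNS = ("subject_id", "group", "age", "weight", "height", "cobb1")


def sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir: Path, config: dict, seed: int,
                   artifacts: list[Path]) -> Path:
    config_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config": config,
        "config_sha256": config_hash,
        "artifacts": {str(p.relative_to(outdir)): sha256_file(p) for p in artifacts},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


# -- cohort ----------------------------------------------------------------

def write_cohort(subjects: list[SubjectRecord], outdir: Path,
                 config: dict | None = None, seed: int = 0) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts = []
    meta_rows = []
    for s in subjects:
        df = pd.DataFrame({"time_s": s.trajectory.time_s})
        for name in sorted(s.trajectory.channels):
            df[name] = s.trajectory.channels[name]
        p = outdir / f"{s.subject_id}.csv"
        df.to_csv(p, index=False, float_format="%.6f")
        artifacts.append(p)
        meta_rows.append({
            "subject_id": s.subject_id, "group": s.group,
            **{k: s.clinical[k] for k in CLINICAL_FIELDS},
        })
        ev = {
            "heel_strikes": {k: list(v) for k, v in s.heel_strikes.items()},
            "toe_offs": {k: list(v) for k, v in s.toe_offs.items()},
        }
        pe = outdir / f"{s.subject_id}.events.json"
        pe.write_text(json.dumps(ev, indent=2))
        artifacts.append(pe)
    meta = outdir / "metadata.csv"
    pd.DataFrame(meta_rows)[list(METADATA_COLUMNS)].to_csv(meta, index=False)
    artifacts.append(meta)
    write_manifest(outdir, config or {}, seed, artifacts)
    return outdir


def read_cohort_metadata(outdir: Path) -> pd.DataFrame:
    df = pd.read_csv(Path(outdir) / "metadata.csv")
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"metadata.csv missing columns {sorted(missing)}")
    return df


def read_trajectory(path: Path, sampling_rate: float = 100.0) -> JointTrajectory:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValidationError(f"{path}: missing time_s column")
    channels = {c: df[c].to_numpy() for c in df.columns if c != "time_s"}
    return JointTrajectory(
        time_s=df["time_s"].to_numpy(), channels=channels,
        sampling_rate=sampling_rate,
    )


# -- segmented cycles ------------------------------------------------------

def write_cycles(cycles: list[GaitCycle], path: Path) -> Path:
    """Long-format CSV: one row per time point per cycle."""
    frames = []
    for c in cycles:
        df = pd.DataFrame(c.angles, columns=list(CHANNEL_ORDER))
        df.insert(0, "point", np.arange(N_POINTS))
        df.insert(0, "cycle_id", f"{c.subject_id}_{c.side}{c.cycle_index:03d}")
        df["subject_id"] = c.subject_id
        df["side"] = c.side
        df["cycle_index"] = c.cycle_index
        df["stance_boundary"] = c.stance_boundary
        df["duration_s"] = c.duration_s
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False, float_format="%.6f")
    return path


def read_cycles(path: Path) -> list[GaitCycle]:
    df = pd.read_csv(path)
    cycles = []
    for cid, grp in df.groupby("cycle_id", sort=True):
        grp = grp.sort_values("point")
        if len(grp) != N_POINTS:
            raise ValidationError(f"cycle {cid} has {len(grp)} points, expected {N_POINTS}")
        cycles.append(GaitCycle(
            angles=grp[list(CHANNEL_ORDER)].to_numpy(),
            stance_boundary=int(grp["stance_boundary"].iloc[0]),
            subject_id=str(grp["subject_id"].iloc[0]),
            side=str(grp["side"].iloc[0]),
            cycle_index=int(grp["cycle_index"].iloc[0]),
            duration_s=float(grp["duration_s"].iloc[0]),
        ))
    return cycles


# -- features --------------------------------------------------------------

def features_table(
    cycles: list[GaitCycle],
    metadata: pd.DataFrame,
    per_cycle: bool = True,
) -> pd.DataFrame:
    """Tidy feature CSV content: per-cycle rows (default) or per-subject means."""
    meta = metadata.set_index("subject_id")
    rows = []
    for c in cycles:
        vec = cycle_feature_vector(c)
        m = meta.loc[c.subject_id]
        rows.append({
            "subject_id": c.subject_id,
            "cycle_id": f"{c.side}{c.cycle_index:03d}",
            "label": m["group"],
            **dict(zip(FEATURE_NAMES, vec)),
            **{f: m[f] for f in CLINICAL_FIELDS},
        })
    df = pd.DataFrame(rows)
    if not per_cycle:
        agg = {f: "mean" for f in FEATURE_NAMES + tuple(CLINICAL_FIELDS)}
        agg["label"] = "first"
        df = df.groupby("subject_id", as_index=False).agg(agg)
        df.insert(1, "cycle_id", "mean")
    return df
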