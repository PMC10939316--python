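"""Readers, writers, configuration and provenance for the command line tools.

All on-disk formats are plain text (CSV, JSON) except movies (multi-page
TIFF with a JSON metadata sidecar).  Every output is accompanied by a
provenance block carrying the package version, a configuration hash and the
seed, and contains no timestamps so identical runs are hash-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .laminar import BoundaryPolyline, NeuronMark
from .trackstats import Track
from .undrift import Movie

__all__ = [
    "InputError",
    "InvariantError",
    "DEFAULT_TRACK_COLUMNS",
    "provenance_block",
    "read_tracks",
    "write_tracks",
    "read_marks",
    "write_marks",
    "read_boundaries",
    "write_boundaries",
    "read_movie",
    "write_movie",
    "write_results",
    "load_config",
]


class InputError(ValueError):
    """Malformed or missing input; maps to exit code 2."""


class InvariantError(RuntimeError):
    """A violated internal contract; maps to exit code 3."""


DEFAULT_TRACK_COLUMNS = {
    "track_id": "TRACK_ID",
    "x": "POSITION_X",
    "y": "POSITION_Y",
    "t": "POSITION_T",
    "frame": "FRAME",
    "channel": "channel",
}


def provenance_block(config: dict | None, seed: int | None) -> dict:
    cfg_json = json.dumps(config or {}, sort_keys=True)
    return {
        "package": "corticowalk",
        "version": __version__,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": seed,
    }


# ---------------------------------------------------------------------------
# Track tables
# ---------------------------------------------------------------------------


def read_tracks(
    path: str | Path,
    column_map: dict | None = None,
    frame_interval_min: float = 15.0,
) -> list[Track]:
    """Read a TrackMate-style CSV into a list of tracks.

    Time comes from the ``t`` column (minutes) when present, otherwise from
    ``frame`` * ``frame_interval_min``.  Rows are sorted by time within each
    track; duplicate timestamps are an error.  Yellow-channel tracks are
    retained (downstream analyses decide about exclusion).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"track file not found: {path}")
    cols = {**DEFAULT_TRACK_COLUMNS, **(column_map or {})}
    df = pd.read_csv(path, float_precision="round_trip")
    for key in ("track_id", "x", "y"):
        if cols[key] not in df.columns:
            raise InputError(f"{path}: missing required column {cols[key]!r}")
    if cols["t"] in df.columns:
        t = pd.to_numeric(df[cols["t"]], errors="coerce")
    elif cols["frame"] in df.columns:
        t = pd.to_numeric(df[cols["frame"]], errors="coerce") * frame_interval_min
    else:
        raise InputError(
            f"{path}: need a time column ({cols['t']!r}) or frame column ({cols['frame']!r})"
        )
    x = pd.to_numeric(df[cols["x"]], errors="coerce")
    y = pd.to_numeric(df[cols["y"]], errors="coerce")
    for name, series in (("time", t), ("x", x), ("y", y)):
        bad = series.isna()
        if bad.any():
            row = int(bad.idxmax())
            raise InputError(f"{path}: non-numeric {name} value at row {row}")
    channel = (
        df[cols["channel"]].astype(str)
        if cols["channel"] in df.columns
        else pd.Series(["green"] * len(df))
    )
    work = pd.DataFrame(
        {"tid": df[cols["track_id"]], "t": t, "x": x, "y": y, "channel": channel}
    )
    tracks = []
    for tid, grp in work.groupby("tid", sort=True):
        grp = grp.sort_values("t")
        if grp["t"].duplicated().any():
            raise InputError(f"{path}: duplicate timestamps in track {tid}")
        chans = grp["channel"].unique()
        tracks.append(
            Track(
                track_id=str(tid),
                samples=grp[["t", "x", "y"]].to_numpy(dtype=float),
                channel=str(chans[0]),
            )
        )
    return tracks


def write_tracks(tracks: list[Track], path: str | Path) -> None:
    rows = []
    for tr in tracks:
        for t, x, y in tr.samples:
            rows.append(
                {
                    "TRACK_ID": tr.track_id,
                    "POSITION_T": t,
                    "POSITION_X": x,
                    "POSITION_Y": y,
                    "channel": tr.channel,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Laminar marks and boundaries
# ---------------------------------------------------------------------------


def read_marks(path: str | Path) -> list[NeuronMark]:
    path = Path(path)
    if not path.exists():
        raise InputError(f"marks file not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"x_um", "y_um", "marker", "genotype", "animal_id", "hemisphere_id"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    return [
        NeuronMark(
            x=float(r.x_um),
            y=float(r.y_um),
            marker=str(r.marker),
            genotype=str(r.genotype),
            animal_id=str(r.animal_id),
            hemisphere_id=str(r.hemisphere_id),
        )
        for r in df.itertuples()
    ]


def write_marks(marks: list[NeuronMark], path: str | Path) -> None:
    pd.DataFrame(
        {
            "x_um": [m.x for m in marks],
            "y_um": [m.y for m in marks],
            "marker": [m.marker for m in marks],
            "genotype": [m.genotype for m in marks],
            "animal_id": [m.animal_id for m in marks],
            "hemisphere_id": [m.hemisphere_id for m in marks],
        }
    ).to_csv(path, index=False)


def read_boundaries(path: str | Path) -> dict[str, BoundaryPolyline]:
    path = Path(path)
    if not path.exists():
        raise InputError(f"boundaries file not found: {path}")
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as err:
        raise InputError(f"{path}: invalid JSON ({err})") from err
    out = {}
    for item in payload.get("boundaries", payload if isinstance(payload, list) else []):
        try:
            poly = BoundaryPolyline(
                vertices=np.asarray(item["vertices"], dtype=float), role=item["role"]
            )
        except (KeyError, ValueError) as err:
            raise InputError(f"{path}: bad boundary entry ({err})") from err
        out[poly.role] = poly
    if set(out) != {"ventricular", "pial"}:
        raise InputError(f"{path}: need exactly one ventricular and one pial boundary")
    return out


def write_boundaries(
    boundaries: dict[str, BoundaryPolyline] | tuple[BoundaryPolyline, ...],
    path: str | Path,
) -> None:
    items = boundaries.values() if isinstance(boundaries, dict) else boundaries
    payload = {
        "boundaries": [
            {"role": b.role, "vertices": b.vertices.tolist()} for b in items
        ]
    }
    Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# Movies
# ---------------------------------------------------------------------------


def read_movie(path: str | Path) -> Movie:
    path = Path(path)
    if not path.exists():
        raise InputError(f"movie file not found: {path}")
    data = tifffile.imread(path)
    meta_path = path.with_suffix(path.suffix + ".json")
    pixel_size, interval = 1.0, 15.0
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        pixel_size = float(meta.get("pixel_size_um", pixel_size))
        interval = float(meta.get("frame_interval_min", interval))
    return Movie(data=data, pixel_size_um=pixel_size, frame_interval_min=interval)


def write_movie(
    movie: Movie, path: str | Path, provenance: dict | None = None
) -> None:
    path = Path(path)
    data = movie.data
    if data.shape[1] == 1:
        data = data[:, 0]
    tifffile.imwrite(path, data)
    meta = {
        "pixel_size_um": movie.pixel_size_um,
        "frame_interval_min": movie.frame_interval_min,
        "provenance": provenance or {},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


# ---------------------------------------------------------------------------
# Generic results and configuration
# ---------------------------------------------------------------------------


def write_results(
    out_dir: str | Path,
    tables: dict[str, pd.DataFrame],
    summary: dict,
    config: dict | None,
    seed: int | None,
) -> None:
    """Write CSV tables plus a JSON summary carrying the provenance block."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out_dir / f"{name}.csv", index=False)
    payload = {"provenance": provenance_block(config, seed), **summary}
    (out_dir / "summary.json").write_text(json.dumps(payload, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


_CONFIG_SECTIONS = {
    "model.control",
    "model.ko",
    "field.control",
    "field.ko",
    "population",
    "sweep",
    "seed",
}
_MODEL_KEYS = {"rho", "alpha", "k_spring", "dt", "step_force_jitter", "theta_max", "seed"}
_FIELD_KEYS = {"height", "boundaries", "magnitudes"}
_POPULATION_KEYS = {"n_control", "n_mutant", "coupling", "environment", "n_steps"}
_SWEEP_KEYS = {"fractions", "reps", "n_steps", "n_cells", "n_bins"}


def load_config(path: str | Path) -> dict:
    """Load and validate a simulator configuration (JSON); unknown keys reject."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"config file not found: {path}")
    try:
        cfg = json.loads(path.read_text())
    except json.JSONDecodeError as err:
        raise InputError(f"{path}: invalid JSON ({err})") from err
    unknown = set(cfg) - _CONFIG_SECTIONS
    if unknown:
        raise InputError(f"{path}: unknown config sections {sorted(unknown)}")
    for section, allowed in (
        ("model.control", _MODEL_KEYS),
        ("model.ko", _MODEL_KEYS),
        ("field.control", _FIELD_KEYS),
        ("field.ko", _FIELD_KEYS),
        ("population", _POPULATION_KEYS),
        ("sweep", _SWEEP_KEYS),
    ):
        extra = set(cfg.get(section, {})) - allowed
        if extra:
            raise InputError(f"{path}: unknown keys in [{section}]: {sorted(extra)}")
    return cfg
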