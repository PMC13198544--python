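"""Trial tables and result files.

Trials interchange as plain CSV with a versioned comment header; one row per
trial carrying the condition, the three stimulus colour/location angles, the
three response pairs in report order, the cue selections (cued trials only)
and, for simulated data, the ground-truth latent state.  Angles are degrees in
[0, 360); object indices are 1-based in files and 0-based in memory.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path

import pandas as pd

from misbind.core import PROBE_CONDITIONS, Condition, Permutation
from misbind.forward import LatentTrialState, TrialRecord
from misbind.taskgen import StimulusArray

__all__ = ["read_trials", "write_trials", "FORMAT_VERSION", "config_hash"]

FORMAT_VERSION = "misbind-trials-v1"

_ANGLE_COLS = (
    [f"stim_colour_{i}" for i in (1, 2, 3)]
    + [f"stim_location_{i}" for i in (1, 2, 3)]
    + [f"resp_colour_{i}" for i in (1, 2, 3)]
    + [f"resp_location_{i}" for i in (1, 2, 3)]
)

_GT_COLS = (
    ["gt_report_order", "gt_error_kind", "gt_swap_pair", "gt_cyclic_direction",
     "gt_error_dim"]
    + [f"gt_guess_colour_{i}" for i in (1, 2, 3)]
    + [f"gt_guess_location_{i}" for i in (1, 2, 3)]
    + [f"gt_object_guess_{i}" for i in (1, 2, 3)]
)


def config_hash(obj) -> str:
    """Short deterministic hash of a JSON-serializable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _record_row(t: TrialRecord, i: int) -> dict:
    row = {
        "trial": t.trial_id if t.trial_id is not None else i,
        "subject": t.subject,
        "condition": t.condition.probe,
        "presentation": t.stimuli.presentation,
    }
    for k in range(3):
        row[f"stim_colour_{k + 1}"] = t.stimuli.colours[k]
        row[f"stim_location_{k + 1}"] = t.stimuli.locations[k]
        row[f"resp_colour_{k + 1}"] = t.response_colours[k]
        row[f"resp_location_{k + 1}"] = t.response_locations[k]
        row[f"cue_selection_{k + 1}"] = (
            t.cue_selection[k] + 1 if t.cue_selection is not None else ""
        )
    if t.latent is not None:
        lat = t.latent
        row["gt_report_order"] = "".join(str(o + 1) for o in lat.permutation.mapping)
        row["gt_error_kind"] = lat.error_kind
        row["gt_swap_pair"] = (
            "".join(str(o + 1) for o in lat.swap_pair) if lat.swap_pair else ""
        )
        row["gt_cyclic_direction"] = (
            lat.cyclic_direction if lat.cyclic_direction is not None else ""
        )
        row["gt_error_dim"] = lat.error_dim
        for k in range(3):
            row[f"gt_guess_colour_{k + 1}"] = int(lat.guess_flags[k][0])
            row[f"gt_guess_location_{k + 1}"] = int(lat.guess_flags[k][1])
            row[f"gt_object_guess_{k + 1}"] = int(lat.object_guess[k])
    return row


def write_trials(
    records: list[TrialRecord],
    path,
    seed: int | None = None,
    config_digest: str | None = None,
) -> None:
    """Write trials as versioned CSV (metadata in ``#`` comment lines)."""
    from misbind import __version__

    path = Path(path)
    df = pd.DataFrame([_record_row(t, i) for i, t in enumerate(records)])
    header = [
        f"# {FORMAT_VERSION}",
        f"# package_version={__version__}",
    ]
    if seed is not None:
        header.append(f"# seed={seed}")
    if config_digest is not None:
        header.append(f"# config_hash={config_digest}")
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        # shortest round-trip float representation so read/write cycles are
        # byte-stable
        df.to_csv(fh, index=False, float_format=lambda v: repr(float(v)))


def _fail(row: int, column: str, message: str):
    raise ValueError(f"invalid trial table at row {row}, column {column!r}: {message}")


def _angle(value, row: int, column: str) -> float:
    v = float(value)
    if not math.isfinite(v) or not 0.0 <= v < 360.0:
        _fail(row, column, f"angle {v} outside [0, 360)")
    return v


def read_trials(path) -> list[TrialRecord]:
    """Read a trial table, validating the schema row by row."""
    path = Path(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if df.empty:
        import warnings

        warnings.warn(f"empty trial table {path}", stacklevel=2)
        return []
    required = ["trial", "subject", "condition", "presentation"] + _ANGLE_COLS
    for col in required:
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in {path}")
    has_gt = all(c in df.columns for c in _GT_COLS)

    records = []
    for i, row in df.iterrows():
        probe = row["condition"]
        if probe not in PROBE_CONDITIONS:
            _fail(i, "condition", f"unknown condition {probe!r}")
        cond = Condition(probe)
        angles = {c: _angle(row[c], i, c) for c in _ANGLE_COLS}
        stim = StimulusArray(
            colours=tuple(angles[f"stim_colour_{k}"] for k in (1, 2, 3)),
            locations=tuple(angles[f"stim_location_{k}"] for k in (1, 2, 3)),
            presentation=row["presentation"],
        )
        cue = None
        if cond.is_cued:
            try:
                cue = tuple(int(row[f"cue_selection_{k}"]) - 1 for k in (1, 2, 3))
            except (TypeError, ValueError):
                _fail(i, "cue_selection_1", "cued rows need integer cue selections")
            if sorted(cue) != [0, 1, 2]:
                _fail(i, "cue_selection_1", f"{cue} is not a permutation")
        latent = _read_latent(row, i) if has_gt and isinstance(
            row["gt_error_kind"], str
        ) else None
        records.append(
            TrialRecord(
                subject=int(row["subject"]),
                condition=cond,
                stimuli=stim,
                response_colours=tuple(angles[f"resp_colour_{k}"] for k in (1, 2, 3)),
                response_locations=tuple(
                    angles[f"resp_location_{k}"] for k in (1, 2, 3)
                ),
                cue_selection=cue,
                latent=latent,
                trial_id=int(row["trial"]),
            )
        )
    return records


def _digits(value) -> str:
    """Digit string from a CSV cell that pandas may have read as a number."""
    s = str(value)
    return s[:-2] if s.endswith(".0") else s


def _read_latent(row, i: int) -> LatentTrialState:
    order = _digits(row["gt_report_order"])
    if sorted(order) != ["1", "2", "3"]:
        _fail(i, "gt_report_order", f"{order!r} is not a report order")
    kind = row["gt_error_kind"]
    pair = None
    direction = None
    if kind == "swap":
        pair = tuple(int(c) - 1 for c in _digits(row["gt_swap_pair"]))
    elif kind == "cyclic":
        direction = int(float(row["gt_cyclic_direction"]))
    return LatentTrialState(
        permutation=Permutation(tuple(int(c) - 1 for c in order)),
        error_kind=kind,
        swap_pair=pair,
        cyclic_direction=direction,
        guess_flags=tuple(
            (bool(row[f"gt_guess_colour_{k + 1}"]), bool(row[f"gt_guess_location_{k + 1}"]))
            for k in range(3)
        ),
        object_guess=tuple(bool(row[f"gt_object_guess_{k + 1}"]) for k in range(3)),
        error_dim=row["gt_error_dim"],
    )
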