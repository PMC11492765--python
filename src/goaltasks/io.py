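"""Trial-log CSV format, YAML configuration schema, and run manifests.

Trial logs are plain CSV, one row per trial, with the execution-variable
columns named per task (``chest_norm, draw_norm`` / ``vx, vy, vz`` /
``vx, vz, d``) plus ``task_id, condition, block_index, misfire, excluded,
error``.  Floats serialize at full precision (repr), so write-then-read is
bit-exact.  Files may mix tasks/conditions/blocks; reading groups rows into
one :class:`TrialBlock` per (task_id, condition, block_index).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (
    CONDITION_FRACTIONS,
    InputError,
    TASK_IDS,
    TrialBlock,
    VARIABLE_NAMES,
)

META_COLUMNS = ("task_id", "condition", "block_index", "misfire", "excluded")


class SchemaError(InputError):
    """A file does not match the expected schema."""


# ---------------------------------------------------------------------------
# trial logs
# ---------------------------------------------------------------------------


def write_trial_log(blocks, path) -> None:
    """Write blocks (a TrialBlock or list of them) to CSV.

    Mixed tasks produce the union of execution columns; cells not belonging
    to a row's task are left empty.
    """
    if isinstance(blocks, TrialBlock):
        blocks = [blocks]
    frames = []
    for b in blocks:
        df = pd.DataFrame(b.U, columns=list(b.variable_names))
        df.insert(0, "task_id", b.task_id)
        df.insert(1, "condition", b.condition)
        df.insert(2, "block_index", b.block_index)
        df["misfire"] = b.misfire.astype(int)
        df["excluded"] = b.excluded.astype(int)
        df["error"] = b.errors
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, index=False)


def read_trial_log(path) -> list[TrialBlock]:
    """Parse a trial-log CSV into blocks keyed by (task, condition, block).

    Raises :class:`SchemaError` naming the offending row/column on missing
    columns, unknown tasks/conditions, or non-numeric cells.
    """
    try:
        # round_trip parsing keeps write->read bit-exact for float64
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise SchemaError(f"cannot parse {path}: {exc}") from exc
    for col in META_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    blocks = []
    for (task, cond, bidx), sub in df.groupby(
        ["task_id", "condition", "block_index"], sort=True
    ):
        if task not in TASK_IDS:
            raise SchemaError(f"{path}: unknown task_id {task!r}")
        if cond not in CONDITION_FRACTIONS:
            raise SchemaError(f"{path}: unknown condition {cond!r}")
        names = VARIABLE_NAMES[task]
        for name in names:
            if name not in sub.columns:
                raise SchemaError(
                    f"{path}: task {task} needs column {name!r}"
                )
        U = np.empty((len(sub), len(names)))
        for j, name in enumerate(names):
            col = pd.to_numeric(sub[name], errors="coerce")
            bad = col.isna()
            if bad.any():
                row = sub.index[bad.argmax()]
                raise SchemaError(
                    f"{path}: non-numeric value in column {name!r}, row {row}"
                )
            U[:, j] = col.to_numpy()
        errors = None
        if "error" in sub.columns:
            errors = pd.to_numeric(sub["error"], errors="coerce").to_numpy()
        blocks.append(
            TrialBlock(
                U=U,
                task_id=task,
                condition=str(cond),
                block_index=int(bidx),
                misfire=sub["misfire"].to_numpy().astype(bool),
                excluded=sub["excluded"].to_numpy().astype(bool),
                errors=errors,
            )
        )
    if not blocks:
        raise SchemaError(f"{path}: no trials")
    return blocks


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

CONFIG_SCHEMA = {
    "task": {"id", "condition", "k", "d_target", "target_radius",
             "theta_bow_max_deg", "theta_des_deg", "phi_des_deg"},
    "subject": {"height", "upper_limb_length", "handedness",
                "chest_limits", "hand_limits", "neutral_hmd_height"},
    "adjustment": {"v_min", "e_max", "policy"},
    "tnc": {"grid", "t_mode"},
    "seed": None,
    "output_dir": None,
    "log_level": None,
}


def load_config(path) -> dict:
    """Load and schema-validate a YAML run configuration.

    Unknown keys are rejected (a typo should fail loudly, not silently run
    with defaults).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    for key, val in cfg.items():
        if key not in CONFIG_SCHEMA:
            raise SchemaError(f"{path}: unknown config key {key!r}")
        allowed = CONFIG_SCHEMA[key]
        if allowed is not None:
            if not isinstance(val, dict):
                raise SchemaError(f"{path}: section {key!r} must be a mapping")
            for sub in val:
                if sub not in allowed:
                    raise SchemaError(
                        f"{path}: unknown key {key}.{sub!r}"
                    )
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# run manifests
# ---------------------------------------------------------------------------


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, command: str, inputs: list, seed=None,
                   options: dict | None = None) -> dict:
    """Record everything needed to reproduce a run bit-exactly: the command,
    input file hashes, seed, resolved options and package version."""
    manifest = {
        "command": command,
        "version": __version__,
        "seed": seed,
        "inputs": {str(p): _sha256(p) for p in inputs if Path(p).is_file()},
        "options": options or {},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest
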