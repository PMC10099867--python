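"""CSV round-tripping and run manifests.

Schemas
-------
Incubation table: ``id,source,q10,ln_r0`` (header required, UTF-8,
"." decimal). Reaction table:
``id,name,catalysed,pair_id,ea_kj_mol,dh_kj_mol,t_ref_k,ln_k25`` with
empty cells for absent optional fields. Numeric output is serialized in
scientific notation with 16 significant digits so a write/read cycle
preserves every field to at least 15 significant digits, including ln k
values down to e^(−46).
"""

from __future__ import annotations

import datetime
import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import SchemaError
from .incubation import IncubationRecord, SweepResult
from .kinetics import T_REF_DEFAULT
from .reactions import ArrheniusReaction, CqtProfiles

__all__ = [
    "read_incubations",
    "write_incubations",
    "read_reactions",
    "write_reactions",
    "write_sweep",
    "write_cqt_profiles",
    "write_manifest",
]

FLOAT_FMT = "%.15e"

INCUBATION_COLUMNS = ["id", "source", "q10", "ln_r0"]
REACTION_COLUMNS = [
    "id",
    "name",
    "catalysed",
    "pair_id",
    "ea_kj_mol",
    "dh_kj_mol",
    "t_ref_k",
    "ln_k25",
]

_TRUE = {"true", "1", "yes", "y"}
_FALSE = {"false", "0", "no", "n", ""}


def _check_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def _require_number(value, column: str, row: int, path) -> float:
    try:
        out = float(value)
    except (TypeError, ValueError):
        raise SchemaError(
            f"{path}: row {row}: column {column!r} is not numeric: {value!r}"
        ) from None
    if pd.isna(out):
        raise SchemaError(f"{path}: row {row}: column {column!r} is empty")
    return out


def read_incubations(path) -> list[IncubationRecord]:
    """Read an incubation CSV; schema violations name column and row."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_columns(df, INCUBATION_COLUMNS, path)
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        records.append(
            IncubationRecord(
                id=str(row.id),
                source=str(row.source),
                q10=_require_number(row.q10, "q10", i, path),
                ln_r0=_require_number(row.ln_r0, "ln_r0", i, path),
            )
        )
    return records


def write_incubations(records: Sequence[IncubationRecord], path) -> None:
    df = pd.DataFrame([asdict(r) for r in records], columns=INCUBATION_COLUMNS)
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def _parse_bool(value, row: int, path) -> bool:
    text = str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise SchemaError(f"{path}: row {row}: column 'catalysed' not boolean: {value!r}")


def _optional_number(value, column: str, row: int, path) -> float | None:
    if str(value).strip() == "":
        return None
    return _require_number(value, column, row, path)


def read_reactions(path) -> list[ArrheniusReaction]:
    """Read a reaction CSV; empty cells stand for absent optional fields."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_columns(df, REACTION_COLUMNS, path)
    reactions = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        t_ref = _optional_number(row.t_ref_k, "t_ref_k", i, path)
        pair = str(row.pair_id).strip()
        reactions.append(
            ArrheniusReaction(
                id=str(row.id),
                name=str(row.name),
                catalysed=_parse_bool(row.catalysed, i, path),
                pair_id=pair or None,
                ea=_optional_number(row.ea_kj_mol, "ea_kj_mol", i, path),
                dh=_optional_number(row.dh_kj_mol, "dh_kj_mol", i, path),
                t_ref=T_REF_DEFAULT if t_ref is None else t_ref,
                ln_k25=_optional_number(row.ln_k25, "ln_k25", i, path),
            )
        )
    return reactions


def write_reactions(reactions: Sequence[ArrheniusReaction], path) -> None:
    rows = [
        {
            "id": r.id,
            "name": r.name,
            "catalysed": r.catalysed,
            "pair_id": "" if r.pair_id is None else r.pair_id,
            "ea_kj_mol": "" if r.ea is None else FLOAT_FMT % r.ea,
            "dh_kj_mol": "" if r.dh is None else FLOAT_FMT % r.dh,
            "t_ref_k": FLOAT_FMT % r.t_ref,
            "ln_k25": "" if r.ln_k25 is None else FLOAT_FMT % r.ln_k25,
        }
        for r in reactions
    ]
    pd.DataFrame(rows, columns=REACTION_COLUMNS).to_csv(path, index=False)


def write_sweep(result: SweepResult, path) -> None:
    """Serialize a sweep as ``t_celsius,r,p,n``."""
    df = pd.DataFrame(
        {
            "t_celsius": result.temperatures,
            "r": result.r,
            "p": result.p,
            "n": result.n,
        }
    )
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def write_cqt_profiles(profiles: CqtProfiles, path) -> None:
    """Serialize CQT profiles as ``t_celsius,set,r_mean,se,n`` rows."""
    rows = []
    for t, est in zip(profiles.temperatures, profiles.uncatalysed):
        rows.append(("uncatalysed", t, est.r_mean, est.se, est.n))
    if profiles.catalysed is not None:
        for t, est in zip(profiles.temperatures, profiles.catalysed):
            rows.append(("catalysed", t, est.r_mean, est.se, est.n))
    df = pd.DataFrame(rows, columns=["set", "t_celsius", "r_mean", "se", "n"])
    df = df[["t_celsius", "set", "r_mean", "se", "n"]]
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def write_manifest(out_path, command: str, **settings) -> Path:
    """Write a JSON manifest next to ``out_path`` recording everything
    needed to reproduce the run (command, inputs/config, seed, grid,
    tool version, timestamp). Returns the manifest path."""
    from . import __version__

    manifest = {
        "command": command,
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        **{k: v for k, v in settings.items() if v is not None},
    }
    out_path = Path(out_path)
    manifest_path = out_path.with_suffix(out_path.suffix + ".manifest.json")
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest_path
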