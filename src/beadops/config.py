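"""Structured-text configuration files (INI sections, key = value).

Three kinds of file share one format:

* chip layout — ``[grid]`` (rows, cols, pitch_mm, side_mm, current_a),
  ``[chip]`` (chamber cell, chamber height, carryover) and
  ``[reservoirs]`` where each entry is
  ``name = row,col,volume_ul[,species:amount;...][,beads]``;
* mechanics parameters — ``[mechanics]`` with k_mag, k_int, k_fric;
* assay parameters — ``[assay]`` mirroring AssayParams fields, and an
  optional ``[drift]`` section mirroring DriftModel fields.
"""

from __future__ import annotations

import configparser
import hashlib
import json
from pathlib import Path

from . import biochip as chip_mod
from . import emgrid
from .assay import AssayParams
from .errors import ConfigError
from .mechanics import ForceParams
from .readout import DriftModel


def _read(path: str | Path) -> configparser.ConfigParser:
    parser = configparser.ConfigParser()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        parser.read_string(path.read_text())
    except configparser.Error as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    return parser


def load_grid(path: str | Path) -> emgrid.CoilGrid:
    parser = _read(path)
    if "grid" not in parser:
        raise ConfigError(f"{path}: missing [grid] section")
    return emgrid.build_default_grid(dict(parser["grid"]))


def _parse_reservoir(name: str, value: str) -> chip_mod.Reservoir:
    fields = [f.strip() for f in value.split(",")]
    if len(fields) < 3:
        raise ConfigError(f"reservoir {name!r}: need row,col,volume_ul")
    row, col, vol = int(fields[0]), int(fields[1]), float(fields[2])
    contents: dict[str, float] = {}
    with_beads = False
    for extra in fields[3:]:
        if not extra:
            continue
        if extra == "beads":
            with_beads = True
            continue
        for pair in extra.split(";"):
            if not pair:
                continue
            if ":" not in pair:
                raise ConfigError(f"reservoir {name!r}: malformed contents {pair!r}")
            sp, amt = pair.split(":", 1)
            contents[sp.strip()] = float(amt)
    return chip_mod.Reservoir(
        name=name, cell=(row, col), volume_ul=vol, contents=contents, with_beads=with_beads
    )


def load_layout(path: str | Path) -> chip_mod.ChipLayout:
    parser = _read(path)
    if "reservoirs" not in parser or "chip" not in parser:
        raise ConfigError(f"{path}: missing [reservoirs] or [chip] section")
    reservoirs = {
        name: _parse_reservoir(name, value) for name, value in parser["reservoirs"].items()
    }
    chip = parser["chip"]
    try:
        r, c = (int(v) for v in chip["chamber"].split(","))
    except (KeyError, ValueError) as exc:
        raise ConfigError(f"{path}: [chip] chamber must be 'row,col'") from exc
    return chip_mod.ChipLayout(
        reservoirs=reservoirs,
        detection_chamber=(r, c),
        chamber_height_mm=float(chip.get("chamber_height_mm", chip_mod.DEFAULT_CHAMBER_HEIGHT_MM)),
        carryover=float(chip.get("carryover", chip_mod.DEFAULT_CARRYOVER)),
    )


def load_force_params(path: str | Path) -> ForceParams:
    parser = _read(path)
    if "mechanics" not in parser:
        raise ConfigError(f"{path}: missing [mechanics] section")
    sec = parser["mechanics"]
    return ForceParams(
        k_mag=float(sec.get("k_mag", 1.0)),
        k_int=float(sec.get("k_int", 1.0)),
        k_fric=float(sec.get("k_fric", 1.0)),
    )


def load_assay_params(path: str | Path) -> AssayParams:
    parser = _read(path)
    if "assay" not in parser:
        raise ConfigError(f"{path}: missing [assay] section")
    sec = parser["assay"]
    kwargs = {
        name: float(sec[name])
        for name in (
            "site_capacity_per_mg",
            "k_cap",
            "half_saturation",
            "label_efficiency",
            "signal_gain",
            "background",
            "noise_sd",
        )
        if name in sec
    }
    return AssayParams(**kwargs)


def load_drift(path: str | Path) -> DriftModel:
    parser = _read(path)
    if "drift" not in parser:
        return DriftModel()
    sec = parser["drift"]
    kwargs = {
        name: float(sec[name])
        for name in ("i0", "amplitude", "period_s", "phase", "noise_sd")
        if name in sec
    }
    return DriftModel(**kwargs)


def write_manifest(out_dir: str | Path, seed: int, config_paths: list[str | Path]) -> Path:
    """Write a replay manifest: config content hashes, seed, version."""
    from . import __version__

    digest = hashlib.sha256()
    entries = {}
    for p in config_paths:
        p = Path(p)
        data = p.read_bytes()
        digest.update(data)
        entries[p.name] = hashlib.sha256(data).hexdigest()
    manifest = {
        "seed": seed,
        "version": __version__,
        "config_sha256": entries,
        "combined_sha256": digest.hexdigest(),
    }
    out = Path(out_dir) / "manifest.json"
    out.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
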