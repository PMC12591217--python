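"""Programmatic generation of the default configuration set.

Everything the simulator needs is emitted as small structured-text files:
the 165-coil matrix layout, the biochip reagent layout (one 8 ul bead
droplet, four 50 ul wash droplets, 50 ul each of labelling conjugate, TMB
substrate and stop buffer — 358 ul in eight reagent droplets), the default
six-step assay program, mechanics/assay parameter files, and an example
noiseless calibration CSV spanning 0-50 pg/ml.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import biochip as chip_mod
from . import emgrid, protocol
from .assay import AssayParams

#: Default reservoir placement on the 11 x 15 coil lattice (row, col).
DEFAULT_RESERVOIRS: dict[str, tuple[tuple[int, int], float, str]] = {
    # name: (cell, volume_ul, contents-spec)
    "beads": ((5, 1), 8.0, ""),
    "sample": ((5, 3), 100.0, ""),
    "wash1": ((3, 3), 50.0, ""),
    "label": ((3, 5), 50.0, "hrp_ab:50000"),
    "wash2": ((3, 7), 50.0, ""),
    "wash3": ((3, 9), 50.0, ""),
    "wash4": ((3, 11), 50.0, ""),
    "chamber": ((5, 11), 50.0, "tmb:50000"),
    "stop": ((7, 11), 50.0, "stop:50000"),
}

CALIBRATION_CONCENTRATIONS = (0.0, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0)  # pg/ml


def default_layout() -> chip_mod.ChipLayout:
    """Build the default biochip layout in memory."""
    reservoirs = {}
    for name, (cell, vol, spec) in DEFAULT_RESERVOIRS.items():
        contents = {}
        for pair in spec.split(";"):
            if pair:
                sp, amt = pair.split(":")
                contents[sp] = float(amt)
        reservoirs[name] = chip_mod.Reservoir(
            name=name,
            cell=cell,
            volume_ul=vol,
            contents=contents,
            with_beads=(name == "stop"),
        )
    return chip_mod.ChipLayout(
        reservoirs=reservoirs, detection_chamber=DEFAULT_RESERVOIRS["chamber"][0]
    )


def layout_text() -> str:
    lines = [
        "# default chip layout: 165-coil matrix + biochip reservoirs",
        "[grid]",
        f"rows = {emgrid.DEFAULT_ROWS}",
        f"cols = {emgrid.DEFAULT_COLS}",
        f"pitch_mm = {emgrid.DEFAULT_PITCH_MM}",
        f"side_mm = {emgrid.DEFAULT_SIDE_MM}",
        f"current_a = {emgrid.DEFAULT_CURRENT_A}",
        "",
        "[chip]",
        "chamber = {},{}".format(*DEFAULT_RESERVOIRS["chamber"][0]),
        f"chamber_height_mm = {chip_mod.DEFAULT_CHAMBER_HEIGHT_MM}",
        f"carryover = {chip_mod.DEFAULT_CARRYOVER}",
        "",
        "[reservoirs]",
    ]
    for name, (cell, vol, spec) in DEFAULT_RESERVOIRS.items():
        entry = f"{name} = {cell[0]},{cell[1]},{vol}"
        if spec:
            entry += f",{spec}"
        if name == "stop":
            entry += ",beads"
        lines.append(entry)
    return "\n".join(lines) + "\n"


def mechanics_text() -> str:
    return "[mechanics]\nk_mag = 1.0\nk_int = 1.0\nk_fric = 1.0\n"


def assay_text() -> str:
    p = AssayParams()
    lines = ["[assay]"]
    for name in (
        "site_capacity_per_mg",
        "k_cap",
        "half_saturation",
        "label_efficiency",
        "signal_gain",
        "background",
        "noise_sd",
    ):
        lines.append(f"{name} = {getattr(p, name)}")
    lines += ["", "[drift]", "i0 = 1000.0", "amplitude = 0.05", "period_s = 300.0", "noise_sd = 2.0"]
    return "\n".join(lines) + "\n"


def calibration_frame(params: AssayParams | None = None) -> pd.DataFrame:
    """Noiseless example calibration: signal vs concentration via the
    closed-form assay chain at the default capture/label/develop times."""
    params = params or AssayParams()
    conc = np.asarray(CALIBRATION_CONCENTRATIONS)
    capacity = params.site_capacity_per_mg * 2.0
    q_eq = capacity * conc / (conc + params.half_saturation)
    captured = q_eq * (1.0 - np.exp(-params.k_cap * protocol.DEFAULT_CAPTURE_MIN))
    hrp = params.label_efficiency * captured * (
        1.0 - np.exp(-params.k_cap * protocol.DEFAULT_LABEL_MIN)
    )
    signal = params.background + params.signal_gain * hrp * protocol.DEFAULT_DEVELOP_MIN
    return pd.DataFrame({"concentration_pg_ml": conc, "signal": signal})


def generate_fixtures(out_dir: str | Path) -> dict[str, Path]:
    """Write the full default configuration set; returns name -> path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "layout": out / "layout.ini",
        "mechanics": out / "mechanics.ini",
        "assay": out / "assay.ini",
        "program": out / "ime_assay.prot",
        "calibration": out / "calibration.csv",
    }
    files["layout"].write_text(layout_text())
    files["mechanics"].write_text(mechanics_text())
    files["assay"].write_text(assay_text())
    program = protocol.default_ime_program(default_layout())
    files["program"].write_text(protocol.format_program(program))
    calibration_frame().to_csv(files["calibration"], index=False)
    return files
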