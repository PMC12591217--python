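"""Phenomenological chemistry of the bead-based sandwich immunoassay.

The assay targets exosome-bound amyloid-beta 1-42 (Exo-Ab42) through two
marker sites: streptavidin magnetic beads functionalised with biotinylated
anti-CD63 antibody capture exosomes by their membrane CD63, and an
HRP-conjugated anti-Ab42 antibody then labels only those captured exosomes
that carry membrane-bound Ab42.  Free Ab42 (no CD63) and bare exosomes
(no Ab42) pass through unlabelled, which is the dual-site specificity the
assay relies on.  Oxidation of the TMB substrate by bead-bound HRP
generates the colorimetric signal, frozen by an acid stop buffer.

Model choices (simplest forms consistent with saturating optimisation
curves of capture vs incubation time and antibody concentration):

* capture follows first-order Langmuir kinetics toward an equilibrium load
  ``Q_eq = capacity * C / (C + K)``:  ``Q(t) = Q_eq * (1 - exp(-k_cap t))``,
  accumulated memorylessly over mixing intervals;
* labelling converts captured Exo-Ab42 to HRP-labelled sites with a fixed
  efficiency;
* signal development is linear in bound HRP and reaction time:
  ``S = background + gain * HRP * t`` plus optional Gaussian noise.

Calibration uses the standard four-parameter logistic (4PL)
``y = d + (a - d) / (1 + (x / c)**b)`` and the blank + 3 SD convention for
the limit of detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit

from .errors import ConfigError, FitError, StateError

#: Species keys understood by the capture/label steps.
CAPTURABLE = ("exo_ab42", "cd63_exo")  # CD63-bearing -> bead-capturable
LABELLED = "exo_ab42"  # only Ab42-bearing captured exosomes get HRP


@dataclass(frozen=True)
class AssayParams:
    """Tunable assay constants.

    site_capacity_per_mg : antibody binding sites per mg of beads [pg-equivalents/mg]
    k_cap                : first-order capture rate constant [1/min]
    half_saturation      : analyte concentration at half-maximal equilibrium
                           load K [pg/ml]
    label_efficiency     : fraction of captured Exo-Ab42 that acquires an
                           HRP label (0..1]
    signal_gain          : absorbance-equivalent signal per pg bound HRP per
                           minute of development
    background           : signal at zero bound HRP (sensor baseline offset)
    noise_sd             : Gaussian signal noise SD (0 disables)
    """

    site_capacity_per_mg: float = 500.0
    k_cap: float = 0.15
    half_saturation: float = 25.0
    label_efficiency: float = 0.8
    signal_gain: float = 2.0e-3
    background: float = 0.05
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "site_capacity_per_mg",
            "k_cap",
            "half_saturation",
            "label_efficiency",
            "signal_gain",
            "background",
            "noise_sd",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ConfigError(f"{name} must be finite and >= 0, got {v}")


@dataclass
class BeadSurface:
    """Bound species on a bead cluster's surface."""

    capacity: float  # total binding sites [pg-equivalents]
    captured: dict[str, float] = field(default_factory=dict)  # species -> pg
    bound_hrp: float = 0.0  # pg of HRP label

    @property
    def total_captured(self) -> float:
        return sum(self.captured.values())


def capture(
    surface: BeadSurface,
    composition: dict[str, float],
    volume_ul: float,
    duration_min: float,
    params: AssayParams,
) -> tuple[BeadSurface, dict[str, float]]:
    """Advance CD63 capture kinetics for one mixing interval.

    Only CD63-bearing species (Exo-Ab42 and bare exosomes) are capturable;
    each relaxes toward its own Langmuir equilibrium share of the surface
    capacity at rate ``k_cap``, so two t/2 intervals equal one t interval.
    Returns the updated surface and the amounts (pg) removed from the
    droplet per species.
    """
    if duration_min < 0:
        raise ConfigError("duration must be >= 0")
    if volume_ul <= 0:
        raise ConfigError("droplet volume must be > 0")
    if surface.capacity <= 0:
        raise StateError("bead surface has no anti-CD63 sites")
    removed: dict[str, float] = {}
    decay = math.exp(-params.k_cap * duration_min)
    vol_ml = volume_ul / 1000.0
    for sp in CAPTURABLE:
        free = composition.get(sp, 0.0)
        already = surface.captured.get(sp, 0.0)
        total = free + already
        if total <= 0:
            continue
        conc = total / vol_ml  # pg/ml, of total available analyte
        q_eq = surface.capacity * conc / (conc + params.half_saturation)
        q_eq = min(q_eq, total)
        # first-order relaxation toward q_eq; memoryless across intervals
        q_new = q_eq - (q_eq - already) * decay
        q_new = min(max(q_new, already), total)
        delta = q_new - already
        surface.captured[sp] = q_new
        if delta > 0:
            removed[sp] = delta
    return surface, removed


def label(
    surface: BeadSurface,
    composition: dict[str, float],
    duration_min: float,
    params: AssayParams,
) -> BeadSurface:
    """Bind HRP-conjugated anti-Ab42 antibody to captured Exo-Ab42.

    The label attaches only to captured exosomes carrying membrane Ab42
    (dual-site requirement); free Ab42 in solution and bare captured
    exosomes gain no label.  Binding saturates toward
    ``label_efficiency * captured Exo-Ab42`` with the capture rate
    constant; the labelling droplet must actually contain the conjugate.
    """
    if duration_min < 0:
        raise ConfigError("duration must be >= 0")
    if composition.get("hrp_ab", 0.0) <= 0:
        return surface
    target = params.label_efficiency * surface.captured.get(LABELLED, 0.0)
    decay = math.exp(-params.k_cap * duration_min)
    surface.bound_hrp = target - (target - surface.bound_hrp) * decay
    return surface


@dataclass
class SignalState:
    """Colorimetric development state of the detection-chamber droplet."""

    signal: float = 0.0
    stopped: bool = False


def develop_signal(
    state: SignalState,
    bound_hrp: float,
    reaction_time_min: float,
    params: AssayParams,
    rng: np.random.Generator | None = None,
    stop: bool = False,
) -> SignalState:
    """Accumulate absorbance-equivalent signal from HRP/TMB turnover.

    Signal grows linearly in bound HRP and reaction time on top of the
    background; a stop event freezes it permanently (developing after a
    stop is a state error).  Optional Gaussian noise (``params.noise_sd``)
    is added once, on the accumulated signal.
    """
    if state.stopped and reaction_time_min > 0:
        raise StateError("signal development resumed after stop buffer was added")
    if reaction_time_min < 0:
        raise ConfigError("reaction time must be >= 0")
    base = state.signal if state.signal > 0 else params.background
    signal = base + params.signal_gain * bound_hrp * reaction_time_min
    if rng is not None and params.noise_sd > 0:
        signal += rng.normal(0.0, params.noise_sd)
    return SignalState(signal=max(signal, 0.0), stopped=state.stopped or stop)


@dataclass(frozen=True)
class CalibCurve:
    """Fitted 4PL calibration: y = d + (a - d) / (1 + (x/c)**b).

    ``a`` is the response at zero dose, ``d`` the response at infinite
    dose; ``c`` [pg/ml] the inflection and ``b`` the slope factor.
    """

    a: float
    b: float
    c: float
    d: float
    r_squared: float
    lod_pg_ml: float | None = None

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        return _four_pl(np.asarray(x, dtype=float), self.a, self.b, self.c, self.d)

    @property
    def increasing(self) -> bool:
        """True if the response rises with concentration."""
        return (self.d > self.a) == (self.b > 0)

    def invert(self, y: float) -> float:
        """Concentration at which the fitted curve predicts signal ``y``."""
        lo, hi = sorted((self.a, self.d))
        if not (lo < y < hi):
            raise ConfigError(f"signal {y} outside fitted response range ({lo}, {hi})")
        ratio = (self.a - y) / (y - self.d)
        return self.c * ratio ** (1.0 / self.b)


def _four_pl(x, a, b, c, d):
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        t = np.where(x > 0, (x / c) ** b, np.inf if b < 0 else 0.0)
    return d + (a - d) / (1.0 + t)


def fit_4pl(concentrations, signals) -> CalibCurve:
    """Least-squares 4PL fit of signal vs concentration.

    Requires at least five distinct concentrations including a blank (0).
    Initialisation is deterministic: ``a``/``d`` from the signals at the
    lowest/highest concentration, ``c`` from the concentration whose signal
    is nearest the mid-response, ``b = 1``.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(signals, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigError("concentrations and signals must be equal-length 1-D arrays")
    if len(np.unique(x)) < 5:
        raise FitError("need at least 5 distinct concentrations")
    if 0.0 not in x:
        raise FitError("calibration must include a blank (concentration 0)")
    if np.ptp(y) <= 0:
        raise FitError("degenerate calibration data: signals are constant")

    order = np.argsort(x)
    xs, ys = x[order], y[order]
    a0 = float(ys[0])  # zero-dose response
    d0 = float(ys[-1])  # high-dose response
    mid = 0.5 * (a0 + d0)
    pos = xs > 0
    c0 = float(xs[pos][np.argmin(np.abs(ys[pos] - mid))])
    if c0 <= 0:
        c0 = float(np.median(xs[pos]))
    p0 = (a0, 1.0, c0, d0)
    try:
        popt, _ = curve_fit(
            _four_pl,
            x,
            y,
            p0=p0,
            bounds=([-np.inf, -50.0, 1e-12, -np.inf], [np.inf, 50.0, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"4PL fit did not converge: {exc}") from exc
    a, b, c, d = (float(v) for v in popt)
    resid = y - _four_pl(x, a, b, c, d)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return CalibCurve(a=a, b=b, c=c, d=d, r_squared=r2)


def lod(curve: CalibCurve, blanks) -> float:
    """Limit of detection from blank replicates: blank mean +/- 3 SD.

    The detection threshold is ``mean(blank) + 3*SD`` for a curve that
    rises with concentration and ``mean(blank) - 3*SD`` for one that
    falls; the threshold signal is inverted through the fitted 4PL.
    Requires >= 3 blank replicates.
    """
    blanks = np.asarray(blanks, dtype=float)
    if blanks.size < 3:
        raise ConfigError("need >= 3 blank replicates")
    sign = 1.0 if curve.increasing else -1.0
    threshold = float(blanks.mean() + sign * 3.0 * blanks.std(ddof=1))
    value = curve.invert(threshold)  # ConfigError if outside curve range
    if value <= 0:
        raise ConfigError("LOD threshold maps to non-positive concentration")
    return float(value)
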