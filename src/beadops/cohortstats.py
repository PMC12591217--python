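"""Synthetic diagnostic cohorts and rank-based group statistics.

The clinical question is whether the on-chip readout separates Alzheimer's
disease (AD), mild cognitive impairment (MCI) and healthy control (CON)
groups.  Exosome-bound Ab42 concentration rises with disease stage, and
because the colorimetric readout is a transmitted-light intensity it falls
as analyte rises — so *low* readout indicates disease and diagnostic
cutoffs are of the "<= cutoff" form.

Cohorts are drawn from per-group log-normal concentration distributions
(non-negative, right-skewed, the standard shape for plasma biomarker
levels) and pushed through the assay + readout simulation to a per-subject
readout score.  Default group sizes are AD = 20, MCI = 10, CON = 30; the
default group separations are calibrated so the binormal (log-scale) AUC
is 0.94 for AD vs CON and 0.82 for MCI vs CON.

The Mann-Whitney U test, empirical ROC/AUC and Youden-J cutoff selection
are implemented here from first principles (rank summation with midranks,
exact p by enumeration for small samples, normal approximation with tie
and continuity corrections otherwise, trapezoidal AUC over the threshold
sweep); the identity AUC = U / (n1*n2) holds exactly, ties included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from . import assay as assay_mod
from . import readout as readout_mod
from .errors import ConfigError

_Z_094 = float(norm.ppf(0.94))
_Z_082 = float(norm.ppf(0.82))
_DEFAULT_SDLOG = 0.5
_DELTA_SCALE = math.sqrt(2.0) * _DEFAULT_SDLOG  # sqrt(sd1^2 + sd2^2)


@dataclass(frozen=True)
class GroupSpec:
    """Log-normal concentration distribution for one diagnostic group."""

    name: str
    n: int
    meanlog: float
    sdlog: float = _DEFAULT_SDLOG

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigError(f"group {self.name}: size must be >= 1")
        if self.sdlog <= 0:
            raise ConfigError(f"group {self.name}: sdlog must be > 0")


@dataclass(frozen=True)
class CohortSpec:
    """Study design: group sizes, concentration distributions, noise.

    Defaults reproduce the study conditions: 20 AD / 10 MCI / 30 CON, with
    log-scale group separations placing the binormal AD-vs-CON AUC at 0.94
    and MCI-vs-CON at 0.82.  ``score_mode`` selects how a subject's score
    is produced: ``"pipeline"`` pushes the concentration through the assay
    and optical readout simulation (low score = disease), ``"normal"``
    draws Gaussian scores directly from (meanlog, sdlog) — the binormal
    reference case with a known analytic AUC.
    """

    groups: tuple[GroupSpec, ...] = (
        GroupSpec("CON", 30, math.log(5.0)),
        GroupSpec("MCI", 10, math.log(5.0) + _Z_082 * _DELTA_SCALE),
        GroupSpec("AD", 20, math.log(5.0) + _Z_094 * _DELTA_SCALE),
    )
    score_mode: str = "pipeline"
    assay_params: assay_mod.AssayParams = field(default_factory=assay_mod.AssayParams)
    drift: readout_mod.DriftModel = field(
        default_factory=lambda: readout_mod.DriftModel(noise_sd=0.0)
    )
    develop_min: float = 10.0
    bead_mass_mg: float = 2.0
    sample_volume_ul: float = 100.0

    def group(self, name: str) -> GroupSpec:
        for g in self.groups:
            if g.name == name:
                return g
        raise ConfigError(f"no group named {name!r}")


@dataclass
class CohortResult:
    """Per-subject scores plus the downstream diagnostic statistics."""

    subjects: pd.DataFrame  # columns: subject, group, concentration_pg_ml, score
    pairwise: dict[tuple[str, str], tuple[float, float]]  # (U, p) per pair
    roc: pd.DataFrame  # columns: threshold, fpr, tpr
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    seed: int

    def summary(self) -> dict:
        return {
            "seed": self.seed,
            "n": int(len(self.subjects)),
            "auc": self.auc,
            "cutoff": self.cutoff,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "pairwise": {
                f"{a}_vs_{b}": {"U": u, "p": p} for (a, b), (u, p) in self.pairwise.items()
            },
        }


# ---------------------------------------------------------------------------
# end-to-end scoring

def end_to_end_readout(
    concentrations_pg_ml: np.ndarray,
    spec: CohortSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Push analyte concentrations through capture -> label -> develop ->
    optical readout, one subject at a time, returning I_readout scores.

    Uses the same closed-form kinetics as the chip simulation: Langmuir
    capture toward ``capacity * C / (C + K)`` over the default capture
    time, labelling at the configured efficiency, linear signal
    development, then a Beer-Lambert transmittance read with drift
    compensation.
    """
    ap = spec.assay_params
    conc = np.asarray(concentrations_pg_ml, dtype=float)
    capacity = ap.site_capacity_per_mg * spec.bead_mass_mg
    amount = conc * spec.sample_volume_ul / 1000.0  # pg available per sample
    from .protocol import DEFAULT_CAPTURE_MIN, DEFAULT_LABEL_MIN

    q_eq = np.minimum(capacity * conc / (conc + ap.half_saturation), amount)
    captured = q_eq * (1.0 - np.exp(-ap.k_cap * DEFAULT_CAPTURE_MIN))
    hrp = ap.label_efficiency * captured * (1.0 - np.exp(-ap.k_cap * DEFAULT_LABEL_MIN))
    signal = ap.background + ap.signal_gain * hrp * spec.develop_min
    if ap.noise_sd > 0:
        signal = np.maximum(signal + rng.normal(0.0, ap.noise_sd, size=signal.shape), 0.0)
    scores = np.empty_like(signal)
    for i, s in enumerate(signal):
        res = readout_mod.measure_chamber(
            None,
            float(s),
            drift=spec.drift,
            rng=rng if spec.drift.noise_sd > 0 else None,
            t_read=600.0,
        )
        scores[i] = res.i_readout
    return scores


def simulate_cohort(spec: CohortSpec, seed: int = 0) -> pd.DataFrame:
    """Draw a cohort and score every subject.

    Returns a tidy frame (subject, group, concentration_pg_ml, score).  In
    pipeline mode higher concentration gives a lower optical score; in
    normal mode the score *is* the Gaussian draw (and the concentration
    column repeats it) for closed-form AUC checks.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for g in spec.groups:
        if spec.score_mode == "normal":
            draws = rng.normal(g.meanlog, g.sdlog, size=g.n)
            conc = draws
            scores = draws
        elif spec.score_mode == "pipeline":
            conc = np.exp(rng.normal(g.meanlog, g.sdlog, size=g.n))
            scores = end_to_end_readout(conc, spec, rng)
        else:
            raise ConfigError(f"unknown score_mode {spec.score_mode!r}")
        for c, s in zip(conc, scores):
            rows.append({"group": g.name, "concentration_pg_ml": float(c), "score": float(s)})
    df = pd.DataFrame(rows)
    df.insert(0, "subject", [f"S{i:05d}" for i in range(len(df))])
    return df


# ---------------------------------------------------------------------------
# Mann-Whitney U

def _u_statistic(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """(U_x, U_y, tie correction term) by midrank summation."""
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks for ties
    r_x = float(ranks[:nx].sum())
    u_x = r_x - nx * (nx + 1) / 2.0
    u_y = nx * ny - u_x
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    return u_x, u_y, tie_term


def _u_counts(n1: int, n2: int) -> np.ndarray:
    """Null distribution of U1 for tie-free samples: counts[u] is the
    number of the C(n1+n2, n1) equally likely labelings with U1 = u
    (the classic two-term recursion over the largest pooled value)."""
    cache: dict[tuple[int, int], np.ndarray] = {}

    def rec(a: int, b: int) -> np.ndarray:
        if (a, b) in cache:
            return cache[(a, b)]
        if a == 0 or b == 0:
            out = np.ones(1)
        else:
            out = np.zeros(a * b + 1)
            left = rec(a - 1, b)  # largest value is an x: adds b to U1
            out[b : b + len(left)] += left
            right = rec(a, b - 1)  # largest value is a y
            out[: len(right)] += right
        cache[(a, b)] = out
        return out

    return rec(n1, n2)


def _exact_p(nx: int, ny: int, u_min: float) -> float:
    """Two-sided exact p: 2 * P(U <= u_min) under the permutation null."""
    counts = _u_counts(nx, ny)
    u = int(round(u_min))
    p = 2.0 * counts[: u + 1].sum() / counts.sum()
    return min(1.0, float(p))


def mann_whitney_u(x, y, exact_threshold: int = 8) -> tuple[float, float]:
    """Mann-Whitney U test (two-sided), midranks for ties.

    Returns ``(U, p)`` with U the smaller of the two one-sided statistics.
    The p-value is exact (full enumeration of labelings) when the smaller
    sample has at most ``exact_threshold`` observations and the pooled
    data are tie-free; otherwise the normal approximation with tie and
    continuity corrections is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ConfigError("both samples must be non-empty")
    nx, ny = len(x), len(y)
    u_x, u_y, tie_term = _u_statistic(x, y)
    u_min = min(u_x, u_y)
    has_ties = tie_term > 0
    if min(nx, ny) <= exact_threshold and not has_ties:
        return u_min, _exact_p(nx, ny, u_min)
    n = nx + ny
    mu = nx * ny / 2.0
    var = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all observations identical
        return u_min, 1.0
    z = (abs(u_x - mu) - 0.5) / math.sqrt(var)  # continuity correction
    z = max(z, 0.0)
    return u_min, float(2.0 * norm.sf(z))


# ---------------------------------------------------------------------------
# ROC

def empirical_roc(
    scores, labels, direction: str = "low"
) -> tuple[pd.DataFrame, float]:
    """Empirical ROC by threshold sweep plus trapezoidal AUC.

    ``labels`` are truthy for diseased subjects.  ``direction="low"``
    declares that low scores indicate disease (the platform's transmitted
    intensity falls with analyte), so a subject is called positive when
    ``score <= threshold``; ``"high"`` flips the rule to ``>=``.  The
    returned AUC satisfies AUC = U / (n1*n2) with midrank ties.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if direction not in ("low", "high"):
        raise ConfigError("direction must be 'low' or 'high'")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ConfigError("both classes must be present")
    # orient so that larger oriented score = more disease-like
    oriented = -scores if direction == "low" else scores
    order = np.argsort(-oriented, kind="mergesort")
    s_sorted = oriented[order]
    l_sorted = labels[order]
    tp = np.cumsum(l_sorted)
    fp = np.cumsum(~l_sorted)
    distinct = np.r_[np.diff(s_sorted) != 0, True]  # last sample of each tie block
    tpr = np.r_[0.0, tp[distinct] / n_pos]
    fpr = np.r_[0.0, fp[distinct] / n_neg]
    thr_oriented = s_sorted[distinct]
    thresholds = np.r_[np.nan, -thr_oriented if direction == "low" else thr_oriented]
    auc = float(np.trapezoid(tpr, fpr))
    roc = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})
    return roc, auc


def choose_cutoff(roc: pd.DataFrame) -> tuple[float, float, float]:
    """Operating point maximising Youden's J = sensitivity + specificity - 1.

    Ties break toward higher specificity (lower FPR).  Returns
    ``(cutoff, sensitivity, specificity)``; the cutoff is in original
    score units with the sweep's calling rule.
    """
    pts = roc.dropna(subset=["threshold"])
    if pts.empty:
        raise ConfigError("degenerate ROC: no thresholds")
    j = pts["tpr"] - pts["fpr"]
    best_j = j.max()
    candidates = pts[np.isclose(j, best_j)]
    row = candidates.loc[candidates["fpr"].idxmin()]
    return float(row["threshold"]), float(row["tpr"]), float(1.0 - row["fpr"])


# ---------------------------------------------------------------------------
# full analysis

def analyze_cohort(
    subjects: pd.DataFrame,
    disease_group: str = "AD",
    control_group: str = "CON",
    direction: str = "low",
    seed: int = 0,
) -> CohortResult:
    """Pairwise rank tests plus ROC/AUC/cutoff for disease vs control."""
    groups = list(dict.fromkeys(subjects["group"]))
    pairwise = {}
    for a, b in combinations(groups, 2):
        xa = subjects.loc[subjects["group"] == a, "score"].to_numpy()
        xb = subjects.loc[subjects["group"] == b, "score"].to_numpy()
        pairwise[(a, b)] = mann_whitney_u(xa, xb)
    mask = subjects["group"].isin([disease_group, control_group])
    sub = subjects[mask]
    labels = (sub["group"] == disease_group).to_numpy()
    roc, auc = empirical_roc(sub["score"].to_numpy(), labels, direction=direction)
    cutoff, sens, spec = choose_cutoff(roc)
    return CohortResult(
        subjects=subjects,
        pairwise=pairwise,
        roc=roc,
        auc=auc,
        cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
        seed=seed,
    )


def binormal_auc(mu1: float, sd1: float, mu0: float, sd0: float) -> float:
    """Closed-form AUC for two normal score distributions:
    Phi(delta / sqrt(sd1^2 + sd0^2))."""
    return float(norm.cdf((mu1 - mu0) / math.hypot(sd1, sd0)))
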