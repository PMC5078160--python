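"""Per-window phase-space overlap diagnostics and lambda refinement.

A perturbation window converges only when the forward and backward
perturbation-energy distributions overlap.  Six measures quantify this:

* **Omega** — Bhattacharyya coefficient of the forward and negated-backward
  energy distributions (0 = no overlap, 1 = perfect);
* **K_AB** — overlap measure on the Wu–Kofke scale: 0 = no overlap,
  about 1 = full overlap, approaching 2 when the first distribution lies
  completely inside the second;
* **Pi** — bias metric on the Wu–Kofke scale: negative values flag an
  unreliable window, values below 0.5 are alarming;
* **w_max** — largest normalized weight in the exponential average (values
  above 0.3 mean a single snapshot dominates);
* **ddG_EA** — hysteresis of the forward and backward exponential-average
  estimates;
* **ddG_TI** — absolute difference between the BAR and TI estimates.

``assess_window`` applies the acceptance thresholds (0.7 / 0.7 / 0.5 / 0.3 /
4 kJ/mol / 4 kJ/mol) and proposes an intermediate lambda (the window
midpoint) when two measures fail or Pi is negative.

Formulation notes.  The original Wu–Kofke equations are not reprinted here;
this module uses formulations chosen to reproduce the documented limiting
behaviour of their scale.  K_AB is a histogram coverage product
``c_A * (2 - c_B)`` where ``c_X`` is the probability mass of distribution X
lying in bins populated by the other distribution: disjoint supports give
0, matched supports give about 1, and a narrow first distribution nested in
a much wider second gives values above 1 approaching 2.  Pi is the
sample-adequacy criterion ``sqrt(2 ln N) - sqrt(2 s)`` with ``s`` the
Kullback–Leibler divergence of the target from the sampled work
distribution in a Gaussian-moment approximation, taken over the worse of
the two perturbation directions; it goes negative exactly when the
dissimilarity outruns what ``N`` samples can cover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import kt_kj_per_mol
from .estimators import (
    WindowSamples,
    bar_estimate,
    ea_estimate,
    ti_estimate,
)
from .exceptions import InputError

__all__ = [
    "OverlapThresholds",
    "OverlapReport",
    "RefinementDecision",
    "bhattacharyya_overlap",
    "wu_kofke_measures",
    "max_weight",
    "ea_hysteresis",
    "bar_ti_discrepancy",
    "compute_overlap_report",
    "assess_window",
]

#: Measures with a "small is bad" threshold; the rest fail when large.
_LOWER_BOUNDED = ("omega", "kab", "pi")


@dataclass(frozen=True)
class OverlapThresholds:
    """Acceptance thresholds for the six overlap measures."""

    omega: float = 0.7
    kab: float = 0.7
    pi: float = 0.5
    wmax: float = 0.3
    ddg_ea: float = 4.0
    ddg_ti: float = 4.0


@dataclass
class OverlapReport:
    """The six convergence measures for one lambda window.

    ``flags`` maps measure name to True when the measure fails its
    threshold; ``ddg_ti`` is None when no dU/dlambda samples were supplied.
    ``low_sample_warning`` is set when either sample list has fewer than 10
    entries, where the Wu–Kofke measures are unreliable.
    """

    lambda_low: float
    lambda_high: float
    omega: float
    kab: float
    pi: float
    wmax: float
    ddg_ea: float
    ddg_ti: float | None
    flags: dict = field(default_factory=dict)
    low_sample_warning: bool = False

    def __post_init__(self):
        if not 0.0 <= self.omega <= 1.0 + 1e-9:
            raise InputError(f"omega out of [0,1]: {self.omega}")
        if not 0.0 <= self.kab <= 2.0 + 1e-9:
            raise InputError(f"kab out of [0,2]: {self.kab}")
        if self.ddg_ea < 0 or (self.ddg_ti is not None and self.ddg_ti < 0):
            raise InputError("hysteresis/discrepancy magnitudes must be >= 0")


@dataclass(frozen=True)
class RefinementDecision:
    """Whether a window needs an intermediate lambda, and where."""

    refine: bool
    proposed_lambda: float | None
    reasons: tuple[str, ...]

    def __post_init__(self):
        if self.refine and not self.reasons:
            raise InputError("refine=True requires at least one reason")


def _shared_histograms(a: np.ndarray, b: np.ndarray, bins: int):
    """Probability-mass histograms of two samples on their union range."""
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi == lo:
        # Degenerate single-bin case: all samples of both lists identical.
        return np.array([1.0]), np.array([1.0])
    edges = np.linspace(lo, hi, bins + 1)
    p, _ = np.histogram(a, bins=edges)
    q, _ = np.histogram(b, bins=edges)
    return p / p.sum(), q / q.sum()


def bhattacharyya_overlap(window: WindowSamples, bins: int = 50) -> float:
    """Bhattacharyya coefficient of the window's two energy distributions.

    The backward samples are negated so both distributions live on the
    forward energy axis, then ``sum_i sqrt(p_i q_i)`` is taken over shared
    equal-width bins spanning the union range.
    """
    if bins < 2:
        raise InputError("bhattacharyya_overlap: bins must be >= 2")
    fwd = window.dU_forward
    bwd = -window.dU_backward
    p, q = _shared_histograms(fwd, bwd, bins)
    return float(np.clip(np.sum(np.sqrt(p * q)), 0.0, 1.0))


def _gaussian_kl(mu_t, sd_t, mu_s, sd_s) -> float:
    """KL divergence KL(target || sampled) between two normals (nats)."""
    if sd_s == 0.0:
        return 0.0 if (sd_t == 0.0 and mu_t == mu_s) else np.inf
    if sd_t == 0.0:
        # Point-mass target: only the displacement term survives.
        return float((mu_t - mu_s) ** 2 / (2.0 * sd_s**2))
    return float(
        np.log(sd_s / sd_t)
        + (sd_t**2 + (mu_t - mu_s) ** 2) / (2.0 * sd_s**2)
        - 0.5
    )


def wu_kofke_measures(window: WindowSamples, bins: int = 50) -> tuple[float, float]:
    """Overlap (K_AB) and bias (Pi) metrics on the Wu–Kofke scale.

    See the module docstring for the exact formulation used.  Returns
    ``(kab, pi)``; callers should treat results from fewer than 10 samples
    per direction as indicative only.
    """
    fwd = window.dU_forward
    bwd = -window.dU_backward

    p, q = _shared_histograms(fwd, bwd, bins)
    cov_a = float(p[q > 0].sum())   # mass of the forward dist covered by the backward
    cov_b = float(q[p > 0].sum())
    kab = float(np.clip(cov_a * (2.0 - cov_b), 0.0, 2.0))

    pis = []
    for sampled, target in ((fwd, bwd), (bwd, fwd)):
        s = _gaussian_kl(
            float(target.mean()), float(target.std(ddof=1)),
            float(sampled.mean()), float(sampled.std(ddof=1)),
        )
        n = sampled.size
        pis.append(np.sqrt(2.0 * np.log(n)) - np.sqrt(2.0 * s) if np.isfinite(s)
                   else -np.inf)
    pi = float(min(pis))
    return kab, pi


def max_weight(dU, temperature: float) -> float:
    """Largest normalized Boltzmann weight in the exponential average."""
    dU = np.asarray(dU, dtype=float).ravel()
    if dU.size == 0:
        raise InputError("max_weight: empty sample list")
    if not np.all(np.isfinite(dU)):
        raise InputError("max_weight: non-finite samples")
    kt = kt_kj_per_mol(temperature)
    x = -dU / kt
    w = np.exp(x - x.max())
    return float(w.max() / w.sum())


def ea_hysteresis(window: WindowSamples, temperature: float) -> float:
    """|forward EA + backward EA|: the cycle-closure error of the window.

    An exact estimator gives zero because the backward estimate is the
    negated forward free energy; finite sampling leaves a positive
    hysteresis that shrinks with sample size.
    """
    fwd = ea_estimate(window.dU_forward, temperature).value
    bwd = ea_estimate(window.dU_backward, temperature).value
    return float(abs(fwd + bwd))


def bar_ti_discrepancy(window: WindowSamples, temperature: float) -> float:
    """|BAR - TI| for one window; requires dU/dlambda samples."""
    if not window.has_dudl:
        raise InputError("bar_ti_discrepancy: window carries no dudl samples")
    bar = bar_estimate(window, temperature).value
    ti = ti_estimate(
        [window.lambda_low, window.lambda_high],
        [float(np.mean(window.dudl_low)), float(np.mean(window.dudl_high))],
    ).value
    return float(abs(bar - ti))


def compute_overlap_report(
    window: WindowSamples,
    temperature: float,
    bins: int = 50,
    thresholds: OverlapThresholds | None = None,
) -> OverlapReport:
    """Evaluate all six overlap measures and their pass/fail flags."""
    thresholds = thresholds or OverlapThresholds()
    omega = bhattacharyya_overlap(window, bins=bins)
    kab, pi = wu_kofke_measures(window, bins=bins)
    wmax = max(
        max_weight(window.dU_forward, temperature),
        max_weight(window.dU_backward, temperature),
    )
    ddg_ea = ea_hysteresis(window, temperature)
    ddg_ti = (
        bar_ti_discrepancy(window, temperature) if window.has_dudl else None
    )
    report = OverlapReport(
        lambda_low=window.lambda_low,
        lambda_high=window.lambda_high,
        omega=omega, kab=kab, pi=pi, wmax=wmax,
        ddg_ea=ddg_ea, ddg_ti=ddg_ti,
        low_sample_warning=(
            window.dU_forward.size < 10 or window.dU_backward.size < 10
        ),
    )
    report.flags = _evaluate_flags(report, thresholds)
    return report


def _evaluate_flags(report: OverlapReport, thresholds: OverlapThresholds) -> dict:
    values = {
        "omega": report.omega, "kab": report.kab, "pi": report.pi,
        "wmax": report.wmax, "ddg_ea": report.ddg_ea, "ddg_ti": report.ddg_ti,
    }
    flags = {}
    for name, value in values.items():
        if value is None:
            continue
        limit = getattr(thresholds, name)
        flags[name] = value < limit if name in _LOWER_BOUNDED else value > limit
    return flags


def assess_window(
    report: OverlapReport,
    thresholds: OverlapThresholds | None = None,
) -> RefinementDecision:
    """Decide whether the window needs an extra intermediate lambda.

    Refinement is proposed when at least two measures fail their thresholds
    or when Pi is negative (the latter alone suffices).  The proposed new
    lambda is the window midpoint.  Flag evaluation is deterministic and
    independent of measure ordering.
    """
    flags = (
        report.flags
        if thresholds is None and report.flags
        else _evaluate_flags(report, thresholds or OverlapThresholds())
    )
    reasons = sorted(name for name, failed in flags.items() if failed)
    refine = len(reasons) >= 2 or report.pi < 0.0
    if refine and report.pi < 0.0 and "pi" not in reasons:
        reasons.append("pi")
        reasons.sort()
    midpoint = 0.5 * (report.lambda_low + report.lambda_high)
    return RefinementDecision(
        refine=refine,
        proposed_lambda=midpoint if refine else None,
        reasons=tuple(reasons) if refine else (),
    )
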