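"""Quality metrics for predicted vs experimental binding affinities.

Implements the benchmark statistics used to judge binding-affinity methods:
mean absolute deviation (MAD), MAD after removing the systematic error
(MADtr), maximum error, Pearson correlation (plain, and an antisymmetrized
mode that augments each relative affinity with its sign-flipped duplicate
so the result does not depend on the direction chosen for each
perturbation), regression slope, and Kendall's tau-b.  A parametric
bootstrap propagates the uncertainties of both the calculated and the
experimental values into every metric.  IC50 values convert to absolute
binding free energies via ``dG = RT ln(IC50 / 1 M)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .constants import DEFAULT_TEMPERATURE, kt_kj_per_mol
from .exceptions import InputError, UndefinedMetricError

__all__ = [
    "AffinityPairs",
    "BootstrapConfig",
    "PearsonResult",
    "MetricReport",
    "mad",
    "madtr",
    "max_error",
    "pearson",
    "kendall_tau",
    "ic50_to_dg",
    "bootstrap_metrics",
    "METRIC_NAMES",
]


@dataclass
class AffinityPairs:
    """Matched calculated/experimental affinities (kJ/mol).

    ``relative`` marks pairwise ddG data (as opposed to absolute dG), which
    enables the antisymmetrized correlation mode.  Optional per-point
    standard errors feed the parametric bootstrap.
    """

    labels: list[str]
    calculated: np.ndarray
    experimental: np.ndarray
    calc_se: np.ndarray | None = None
    exp_se: np.ndarray | None = None
    relative: bool = False

    def __post_init__(self):
        self.calculated = np.asarray(self.calculated, dtype=float)
        self.experimental = np.asarray(self.experimental, dtype=float)
        n = self.calculated.size
        if n < 2:
            raise InputError("AffinityPairs: need at least 2 points")
        if self.experimental.size != n or len(self.labels) != n:
            raise InputError("AffinityPairs: length mismatch")
        if not (np.all(np.isfinite(self.calculated))
                and np.all(np.isfinite(self.experimental))):
            raise InputError("AffinityPairs: non-finite values")
        for name in ("calc_se", "exp_se"):
            se = getattr(self, name)
            if se is not None:
                se = np.asarray(se, dtype=float)
                if se.size != n or np.any(se < 0) or not np.all(np.isfinite(se)):
                    raise InputError(f"AffinityPairs: bad {name}")
                setattr(self, name, se)

    def __len__(self) -> int:
        return self.calculated.size


@dataclass(frozen=True)
class BootstrapConfig:
    """Parametric-bootstrap settings: 500 replicates and a 1.7 kJ/mol
    experimental uncertainty by default."""

    n_samples: int = 500
    exp_sigma: float = 1.7
    seed: int | None = None

    def __post_init__(self):
        if self.n_samples < 2:
            raise InputError("BootstrapConfig: n_samples must be >= 2")
        if self.exp_sigma < 0:
            raise InputError("BootstrapConfig: exp_sigma must be >= 0")


def mad(pairs: AffinityPairs) -> float:
    """Mean absolute deviation of calculated from experimental."""
    return float(np.mean(np.abs(pairs.calculated - pairs.experimental)))


def max_error(pairs: AffinityPairs) -> float:
    """Largest absolute deviation."""
    return float(np.max(np.abs(pairs.calculated - pairs.experimental)))


def madtr(pairs: AffinityPairs) -> float:
    """MAD after subtracting the mean signed error from the calculated
    values (translated MAD): insensitive to a uniform offset."""
    err = pairs.calculated - pairs.experimental
    return float(np.mean(np.abs(err - err.mean())))


@dataclass(frozen=True)
class PearsonResult:
    r: float
    r_squared: float
    slope: float


def pearson(pairs: AffinityPairs, antisymmetrize: bool = False) -> PearsonResult:
    """Pearson correlation and regression slope of calculated on experimental.

    In antisymmetrized mode every point (x, y) is augmented with (-x, -y)
    before the centered computation (whose mean is then exactly zero), so
    relative affinities correlate independently of the direction assigned
    to each perturbation; the slope is then the through-origin regression
    slope.
    """
    x = pairs.experimental
    y = pairs.calculated
    if antisymmetrize:
        if len(pairs) < 2:
            raise InputError("pearson: need >= 2 pairs when antisymmetrized")
        sxx = float(np.sum(x * x)) * 2.0
        syy = float(np.sum(y * y)) * 2.0
        sxy = float(np.sum(x * y)) * 2.0
        if sxx == 0.0 or syy == 0.0:
            raise UndefinedMetricError("pearson: zero variance series")
        r = sxy / np.sqrt(sxx * syy)
        slope = sxy / sxx
        return PearsonResult(float(r), float(r**2), float(slope))
    if len(pairs) < 3:
        raise InputError("pearson: need >= 3 points in plain mode")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise UndefinedMetricError("pearson: zero variance series")
    r = stats.pearsonr(x, y).statistic
    slope = stats.linregress(x, y).slope
    return PearsonResult(float(r), float(r**2), float(slope))


def kendall_tau(pairs: AffinityPairs) -> float:
    """Kendall's rank correlation, tie-corrected (tau-b)."""
    res = stats.kendalltau(pairs.experimental, pairs.calculated)
    if np.isnan(res.statistic):
        raise UndefinedMetricError("kendall_tau: undefined (all ties?)")
    return float(res.statistic)


def ic50_to_dg(ic50: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Binding free energy from an IC50: ``RT ln(IC50 / 1 M)`` in kJ/mol."""
    if ic50 <= 0:
        raise InputError(f"ic50 must be positive, got {ic50}")
    return float(kt_kj_per_mol(temperature) * np.log(ic50))


METRIC_NAMES = ("mad", "madtr", "max", "r", "slope", "tau")


def _evaluate_metrics(pairs: AffinityPairs, names, antisymmetrize: bool) -> dict:
    out = {}
    for name in names:
        if name == "mad":
            out[name] = mad(pairs)
        elif name == "madtr":
            out[name] = madtr(pairs)
        elif name == "max":
            out[name] = max_error(pairs)
        elif name in ("r", "slope"):
            res = pearson(pairs, antisymmetrize=antisymmetrize)
            out[name] = res.r if name == "r" else res.slope
        elif name == "tau":
            out[name] = kendall_tau(pairs)
        else:
            raise InputError(f"unknown metric {name!r}")
    return out


@dataclass
class MetricReport:
    """Point estimates plus bootstrap means and standard errors per metric."""

    point: dict
    bootstrap_mean: dict = field(default_factory=dict)
    bootstrap_se: dict = field(default_factory=dict)
    n_dropped: int = 0
    n_samples: int = 0

    @property
    def mad(self):
        return self.point.get("mad")

    @property
    def madtr(self):
        return self.point.get("madtr")

    @property
    def max_error(self):
        return self.point.get("max")

    @property
    def pearson_r(self):
        return self.point.get("r")

    @property
    def r_squared(self):
        r = self.point.get("r")
        return None if r is None else r**2

    @property
    def slope(self):
        return self.point.get("slope")

    @property
    def kendall_tau(self):
        return self.point.get("tau")


def bootstrap_metrics(
    pairs: AffinityPairs,
    cfg: BootstrapConfig | None = None,
    metric_set=METRIC_NAMES,
    antisymmetrize: bool = False,
) -> MetricReport:
    """Parametric bootstrap of the quality metrics.

    Each replicate adds independent Gaussian noise to the calculated values
    (per-point SE, zero when absent) and to the experimental values
    (``cfg.exp_sigma``), then recomputes every requested metric.  Replicates
    where a metric is undefined are dropped and counted.  Deterministic
    under a fixed seed; with all SEs zero the bootstrap mean equals the
    point estimate and the SE is exactly zero.
    """
    cfg = cfg or BootstrapConfig()
    point = _evaluate_metrics(pairs, metric_set, antisymmetrize)
    rng = np.random.default_rng(cfg.seed)
    calc_se = pairs.calc_se if pairs.calc_se is not None else np.zeros(len(pairs))
    samples: dict[str, list] = {name: [] for name in metric_set}
    n_dropped = 0
    for _ in range(cfg.n_samples):
        noisy = AffinityPairs(
            labels=pairs.labels,
            calculated=pairs.calculated + rng.normal(0.0, 1.0, len(pairs)) * calc_se,
            experimental=pairs.experimental
            + rng.normal(0.0, 1.0, len(pairs)) * cfg.exp_sigma,
            relative=pairs.relative,
        )
        try:
            values = _evaluate_metrics(noisy, metric_set, antisymmetrize)
        except UndefinedMetricError:
            n_dropped += 1
            continue
        for name, value in values.items():
            samples[name].append(value)
    boot_mean = {}
    boot_se = {}
    for name in metric_set:
        vals = np.asarray(samples[name])
        if vals.size >= 2:
            if np.all(vals == vals[0]):  # degenerate: no noise injected
                boot_mean[name] = float(vals[0])
                boot_se[name] = 0.0
            else:
                boot_mean[name] = float(vals.mean())
                boot_se[name] = float(vals.std(ddof=1))
    return MetricReport(
        point=point, bootstrap_mean=boot_mean, bootstrap_se=boot_se,
        n_dropped=n_dropped, n_samples=cfg.n_samples,
    )
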