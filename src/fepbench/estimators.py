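"""Free-energy estimators for alchemical transformations.

Given per-state samples of potential energies (or per-window perturbation
energies), this module computes the free-energy difference between the two
endpoint states with four standard estimators:

* **EA** — one-sided exponential averaging (Zwanzig),
  ``dG = -kT ln <exp(-dU/kT)>``;
* **BAR** — the Bennett acceptance ratio, the minimum-variance two-state
  estimator, solved self-consistently in its Fermi-function form including
  the sample-size ratio term;
* **TI** — thermodynamic integration, a trapezoidal quadrature of
  ``<dU/dlambda>`` over the coupling grid;
* **MBAR** — the multistate Bennett acceptance ratio, the self-consistent
  multistate generalisation that uses every snapshot evaluated at every
  state.

All energies are kJ/mol; temperatures kelvin.  Exponential averages are
evaluated with log-sum-exp shifting so arbitrarily large perturbation
energies cannot overflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .constants import kt_kj_per_mol
from .exceptions import ConvergenceError, InputError

__all__ = [
    "ReducedPotentialSet",
    "WindowSamples",
    "FreeEnergyEstimate",
    "MbarResult",
    "BootstrapSE",
    "ea_estimate",
    "bar_estimate",
    "ti_estimate",
    "mbar_estimate",
    "mbar_bootstrap_se",
    "windows_from_potentials",
]


def _as_finite_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if arr.size == 0:
        raise InputError(f"{name}: empty sample list")
    if not np.all(np.isfinite(arr)):
        raise InputError(f"{name}: non-finite samples present")
    return arr


@dataclass(frozen=True)
class FreeEnergyEstimate:
    """A free-energy difference in kJ/mol with an optional standard error.

    ``direction`` names the ordered state (or ligand) pair the value refers
    to; ``meta`` carries estimator-specific annotations such as the kind of
    standard error ("asymptotic" vs "bootstrap") or the quadrature rule.
    """

    value: float
    se: float | None
    method: str
    direction: tuple[str, str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.se is not None and self.se < 0:
            raise InputError(f"standard error must be >= 0, got {self.se}")


@dataclass
class WindowSamples:
    """Forward/backward perturbation energies for one lambda window.

    ``dU_forward`` holds samples of U(high) - U(low) collected in the low
    ensemble; ``dU_backward`` holds U(low) - U(high) collected in the high
    ensemble (i.e. the reverse work).  Optional ``dudl_low``/``dudl_high``
    are dU/dlambda samples at the two window edges, needed only for the
    BAR-vs-TI convergence check.
    """

    lambda_low: float
    lambda_high: float
    dU_forward: np.ndarray
    dU_backward: np.ndarray
    dudl_low: np.ndarray | None = None
    dudl_high: np.ndarray | None = None

    def __post_init__(self):
        if not self.lambda_low < self.lambda_high:
            raise InputError(
                f"lambda_low ({self.lambda_low}) must be < lambda_high "
                f"({self.lambda_high})"
            )
        self.dU_forward = _as_finite_array(self.dU_forward, "dU_forward")
        self.dU_backward = _as_finite_array(self.dU_backward, "dU_backward")
        for name in ("dU_forward", "dU_backward"):
            if getattr(self, name).size < 2:
                raise InputError(f"{name}: at least 2 samples required")
        for name in ("dudl_low", "dudl_high"):
            val = getattr(self, name)
            if val is not None:
                arr = _as_finite_array(val, name)
                if arr.size < 2:
                    raise InputError(f"{name}: at least 2 samples required")
                setattr(self, name, arr)

    @property
    def has_dudl(self) -> bool:
        return self.dudl_low is not None and self.dudl_high is not None


@dataclass
class ReducedPotentialSet:
    """Per-state samples of potentials evaluated at every state.

    ``u[k, n]`` is the potential (kJ/mol) of snapshot ``n`` evaluated at
    state ``k``; ``origin[n]`` is the state the snapshot was sampled from.
    ``lambdas`` must be strictly increasing from 0 to 1 and every state must
    have at least one snapshot.
    """

    lambdas: np.ndarray
    u: np.ndarray
    origin: np.ndarray
    temperature: float

    def __post_init__(self):
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.origin = np.asarray(self.origin, dtype=int)
        lam = self.lambdas
        if lam.ndim != 1 or lam.size < 2:
            raise InputError("lambdas: need at least two coupling values")
        if np.any(np.diff(lam) <= 0):
            raise InputError("lambdas must be strictly increasing")
        if lam[0] != 0.0 or lam[-1] != 1.0:
            raise InputError("lambda schedule must start at 0.0 and end at 1.0")
        if self.u.ndim != 2 or self.u.shape[0] != lam.size:
            raise InputError(
                f"u must be (n_states, n_snapshots); got {self.u.shape} for "
                f"{lam.size} states"
            )
        if not np.all(np.isfinite(self.u)):
            raise InputError("u: non-finite entries present")
        if self.origin.shape != (self.u.shape[1],):
            raise InputError("origin must have one entry per snapshot")
        if self.origin.min(initial=0) < 0 or self.origin.max(initial=0) >= lam.size:
            raise InputError("origin contains an invalid state index")
        counts = self.state_counts()
        if np.any(counts < 1):
            empty = np.nonzero(counts < 1)[0].tolist()
            raise InputError(f"states without samples: {empty}")
        if self.temperature <= 0:
            raise InputError(f"temperature must be positive, got {self.temperature}")

    @property
    def n_states(self) -> int:
        return self.lambdas.size

    @property
    def n_snapshots(self) -> int:
        return self.u.shape[1]

    def state_counts(self) -> np.ndarray:
        return np.bincount(self.origin, minlength=self.lambdas.size)


def ea_estimate(
    dU,
    temperature: float,
    direction: tuple[str, str] | None = None,
) -> FreeEnergyEstimate:
    """Exponential-averaging (Zwanzig) estimate from one-sided samples.

    Returns ``-kT ln <exp(-dU/kT)>`` with a delta-method standard error.
    The log-sum-exp contract guarantees no overflow for any sample scale.
    """
    dU = _as_finite_array(dU, "dU")
    kt = kt_kj_per_mol(temperature)
    x = -dU / kt
    value = -kt * (logsumexp(x) - np.log(x.size))
    # Relative spread of the Boltzmann weights is shift-invariant, so the
    # delta-method SE can be formed from shifted weights safely.
    w = np.exp(x - x.max())
    mean_w = w.mean()
    se = kt * w.std(ddof=1) / (mean_w * np.sqrt(w.size)) if w.size > 1 else 0.0
    return FreeEnergyEstimate(
        value=float(value), se=float(se), method="EA", direction=direction,
        meta={"n": int(dU.size), "se_kind": "delta-method"},
    )


def _bar_residual(dg: float, w_f: np.ndarray, w_r: np.ndarray, kt: float) -> float:
    """Bennett self-consistency residual; strictly increasing in ``dg``.

    Root of ``sum_F fermi(-(M + (w_F - dG)/kT)) - sum_R fermi(-( -M +
    (w_R + dG)/kT))`` with ``M = ln(n_F/n_R)``, the Fermi-function form of
    Bennett's equation including the sample-size ratio term.
    """
    m = np.log(w_f.size / w_r.size)
    # 1/(1+exp(t)) computed stably for any t.
    def fermi_sum(t):
        out = np.empty_like(t)
        pos = t >= 0
        out[pos] = np.exp(-t[pos]) / (1.0 + np.exp(-t[pos]))
        out[~pos] = 1.0 / (1.0 + np.exp(t[~pos]))
        return out.sum()

    lhs = fermi_sum(m + (w_f - dg) / kt)
    rhs = fermi_sum(-m + (w_r + dg) / kt)
    return lhs - rhs


def bar_estimate(
    window: WindowSamples,
    temperature: float,
    tol: float = 1e-6,
    max_iter: int = 500,
    direction: tuple[str, str] | None = None,
) -> FreeEnergyEstimate:
    """Bennett acceptance-ratio estimate for one window.

    The self-consistent equation is solved by bisection on its monotone
    residual; the initial bracket comes from the forward and (negated)
    backward exponential averages.  The standard error is the standard
    asymptotic expression evaluated at the solution and is flagged
    ``"asymptotic"`` in ``meta``.
    """
    w_f = window.dU_forward
    w_r = window.dU_backward
    kt = kt_kj_per_mol(temperature)

    ea_f = ea_estimate(w_f, temperature).value
    ea_r = -ea_estimate(w_r, temperature).value
    lo = min(ea_f, ea_r) - 10.0 * kt
    hi = max(ea_f, ea_r) + 10.0 * kt
    r_lo = _bar_residual(lo, w_f, w_r, kt)
    r_hi = _bar_residual(hi, w_f, w_r, kt)
    expand = 0
    while r_lo > 0 or r_hi < 0:
        span = hi - lo
        if r_lo > 0:
            lo -= span
            r_lo = _bar_residual(lo, w_f, w_r, kt)
        if r_hi < 0:
            hi += span
            r_hi = _bar_residual(hi, w_f, w_r, kt)
        expand += 1
        if expand > 60:
            raise ConvergenceError(
                "BAR: could not bracket the Bennett root",
                {"lo": lo, "hi": hi, "residual_lo": r_lo, "residual_hi": r_hi},
            )

    it = 0
    while hi - lo > tol:
        it += 1
        if it > max_iter:
            raise ConvergenceError(
                "BAR: bisection did not converge",
                {"lo": lo, "hi": hi, "iterations": it, "tol": tol},
            )
        mid = 0.5 * (lo + hi)
        if _bar_residual(mid, w_f, w_r, kt) < 0:
            lo = mid
        else:
            hi = mid
    dg = 0.5 * (lo + hi)

    # Bennett's asymptotic variance from the Fermi weights at the solution.
    m = np.log(w_f.size / w_r.size)
    f_f = 1.0 / (1.0 + np.exp(np.clip(m + (w_f - dg) / kt, -700, 700)))
    f_r = 1.0 / (1.0 + np.exp(np.clip(-m + (w_r + dg) / kt, -700, 700)))
    var = 0.0
    for f, n in ((f_f, w_f.size), (f_r, w_r.size)):
        mean = f.mean()
        if mean > 0:
            var += (np.mean(f**2) / mean**2 - 1.0) / n
    se = kt * np.sqrt(max(var, 0.0))
    return FreeEnergyEstimate(
        value=float(dg), se=float(se), method="BAR", direction=direction,
        meta={
            "n_forward": int(w_f.size), "n_backward": int(w_r.size),
            "se_kind": "asymptotic", "tol": tol,
        },
    )


def ti_estimate(
    lambdas,
    mean_dudl,
    se_dudl=None,
    direction: tuple[str, str] | None = None,
) -> FreeEnergyEstimate:
    """Thermodynamic integration: trapezoid rule on the lambda grid.

    The trapezoid rule is the package's fixed quadrature choice and is
    recorded in the estimate metadata.  Optional per-lambda standard errors
    of the mean derivative are combined in quadrature with the trapezoid
    weights.
    """
    lam = np.asarray(lambdas, dtype=float)
    means = np.asarray(mean_dudl, dtype=float)
    if lam.ndim != 1 or lam.size < 2:
        raise InputError("ti_estimate: need at least two lambda points")
    if means.shape != lam.shape:
        raise InputError("ti_estimate: lambdas and mean_dudl lengths differ")
    if np.any(np.diff(lam) <= 0):
        raise InputError("ti_estimate: lambdas must be strictly increasing")
    if not (np.all(np.isfinite(lam)) and np.all(np.isfinite(means))):
        raise InputError("ti_estimate: non-finite values")
    value = float(np.trapezoid(means, lam))
    se = None
    if se_dudl is not None:
        ses = np.asarray(se_dudl, dtype=float)
        if ses.shape != lam.shape:
            raise InputError("ti_estimate: se_dudl length mismatch")
        weights = np.zeros_like(lam)
        dl = np.diff(lam)
        weights[:-1] += dl / 2.0
        weights[1:] += dl / 2.0
        se = float(np.sqrt(np.sum((weights * ses) ** 2)))
    return FreeEnergyEstimate(
        value=value, se=se, method="TI", direction=direction,
        meta={"quadrature": "trapezoid", "n_lambda": int(lam.size)},
    )


@dataclass(frozen=True)
class MbarResult:
    """Self-consistent MBAR solution.

    ``free_energies`` are per-state values in kJ/mol with the first state
    pinned to zero; ``endpoint`` is the last-minus-first difference with the
    asymptotic standard error.
    """

    free_energies: np.ndarray
    endpoint: FreeEnergyEstimate
    n_iterations: int


#: Temperature at which kT equals exactly 1 kJ/mol; lets window helpers run
#: on already-reduced energies.
_UNIT_KT_TEMPERATURE = 1.0 / 8.31446e-3


def _stagewise_bar_seed(u_red: np.ndarray, origin: np.ndarray) -> np.ndarray:
    """Initial reduced free energies from adjacent-window BAR estimates."""
    n_states = u_red.shape[0]
    f = np.zeros(n_states)
    for k in range(n_states - 1):
        sel_lo = origin == k
        sel_hi = origin == k + 1
        w_f = u_red[k + 1, sel_lo] - u_red[k, sel_lo]
        w_r = u_red[k, sel_hi] - u_red[k + 1, sel_hi]
        try:
            window = WindowSamples(k, k + 1, w_f, w_r)
            df = bar_estimate(window, _UNIT_KT_TEMPERATURE, tol=1e-4).value
        except (ConvergenceError, InputError):
            # Crude fallback: midpoint of the two one-sided mean works.
            df = float(0.5 * w_f.mean() - 0.5 * w_r.mean()) if (
                w_f.size and w_r.size) else 0.0
        f[k + 1] = f[k] + df
    return f


def mbar_estimate(
    rps: ReducedPotentialSet,
    tol: float = 1e-8,
    max_iter: int = 50000,
    compute_se: bool = True,
    direction: tuple[str, str] | None = None,
) -> MbarResult:
    """Solve the MBAR equations by self-consistent iteration.

    The iteration is seeded by stagewise BAR estimates and stops when the
    largest per-state change is below ``tol`` (kJ/mol).  The endpoint
    standard error comes from the standard asymptotic covariance of the
    estimated reduced free energies (SVD form).
    """
    if tol <= 0:
        raise InputError("mbar_estimate: tol must be positive")
    kt = kt_kj_per_mol(rps.temperature)
    u_red = rps.u / kt
    origin = rps.origin
    counts = rps.state_counts().astype(float)
    log_n = np.log(counts)

    f = _stagewise_bar_seed(u_red, origin)
    f -= f[0]
    tol_red = tol / kt
    n_iter = 0
    delta = np.inf
    while True:
        n_iter += 1
        if n_iter > max_iter:
            raise ConvergenceError(
                "MBAR: self-consistent iteration did not converge",
                {"iterations": n_iter - 1, "tol_kj_mol": tol,
                 "last_delta_kj_mol": float(delta * kt)},
            )
        # log denominator per snapshot: log sum_l N_l exp(f_l - u_ln)
        log_denom = logsumexp(log_n[:, None] + f[:, None] - u_red, axis=0)
        f_new = -logsumexp(-u_red - log_denom[None, :], axis=1)
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol_red:
            break

    se = None
    if compute_se:
        log_denom = logsumexp(log_n[:, None] + f[:, None] - u_red, axis=0)
        log_w = f[:, None] - u_red - log_denom[None, :]  # (K, N)
        w = np.exp(log_w).T  # (N, K); columns sum to 1
        var = _endpoint_variance(w, counts)
        se = kt * np.sqrt(max(var, 0.0))

    endpoint = FreeEnergyEstimate(
        value=float((f[-1] - f[0]) * kt),
        se=None if se is None else float(se),
        method="MBAR",
        direction=direction,
        meta={"iterations": n_iter, "se_kind": "asymptotic", "tol": tol},
    )
    return MbarResult(free_energies=f * kt, endpoint=endpoint, n_iterations=n_iter)


def _endpoint_variance(w: np.ndarray, counts: np.ndarray) -> float:
    """Variance of f_last - f_first (reduced units) from the MBAR weights.

    Uses the SVD form of the asymptotic covariance of the reduced free
    energies, Theta = V S (I - S V' N V S)^+ S V', with N the diagonal
    matrix of state sample counts.
    """
    u_svd, s, vt = np.linalg.svd(w, full_matrices=False)
    v = vt.T
    s_mat = np.diag(s)
    inner = np.eye(s.size) - s_mat @ v.T @ (counts[:, None] * v) @ s_mat
    theta = v @ s_mat @ np.linalg.pinv(inner, rcond=1e-10) @ s_mat @ v.T
    return float(theta[0, 0] + theta[-1, -1] - 2.0 * theta[0, -1])


@dataclass(frozen=True)
class BootstrapSE:
    """Bootstrap standard error with the number of failed replicates."""

    se: float
    n_failed: int
    n_boot: int

    def __float__(self) -> float:
        return self.se


def mbar_bootstrap_se(
    rps: ReducedPotentialSet,
    n_boot: int = 100,
    seed: int | None = None,
    tol: float = 1e-6,
) -> BootstrapSE:
    """Nonparametric bootstrap SE of the MBAR endpoint free energy.

    Snapshots are resampled with replacement within each state; the MBAR
    endpoint is recomputed for each replicate and the standard deviation
    over replicates is returned.  Replicates whose MBAR solve fails are
    dropped and counted.  Deterministic under a fixed seed.
    """
    if n_boot < 2:
        raise InputError("mbar_bootstrap_se: n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    by_state = [np.nonzero(rps.origin == k)[0] for k in range(rps.n_states)]
    values = []
    n_failed = 0
    for _ in range(n_boot):
        cols = np.concatenate([
            rng.choice(idx, size=idx.size, replace=True) for idx in by_state
        ])
        boot = ReducedPotentialSet(
            lambdas=rps.lambdas,
            u=rps.u[:, cols],
            origin=rps.origin[cols],
            temperature=rps.temperature,
        )
        try:
            res = mbar_estimate(boot, tol=tol, compute_se=False)
        except ConvergenceError:
            n_failed += 1
            continue
        values.append(res.endpoint.value)
    if len(values) < 2:
        raise ConvergenceError(
            "mbar_bootstrap_se: fewer than 2 successful replicates",
            {"n_failed": n_failed, "n_boot": n_boot},
        )
    se = float(np.std(values, ddof=1))
    return BootstrapSE(se=se, n_failed=n_failed, n_boot=n_boot)


def windows_from_potentials(rps: ReducedPotentialSet) -> list[WindowSamples]:
    """Split a multistate potential set into adjacent-window samples.

    For window (k, k+1): forward samples are ``u[k+1] - u[k]`` over the
    snapshots originating in state k, backward samples ``u[k] - u[k+1]``
    over those originating in state k+1.
    """
    windows = []
    for k in range(rps.n_states - 1):
        sel_lo = rps.origin == k
        sel_hi = rps.origin == k + 1
        windows.append(
            WindowSamples(
                lambda_low=float(rps.lambdas[k]),
                lambda_high=float(rps.lambdas[k + 1]),
                dU_forward=rps.u[k + 1, sel_lo] - rps.u[k, sel_lo],
                dU_backward=rps.u[k, sel_hi] - rps.u[k + 1, sel_hi],
            )
        )
    return windows
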