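"""Free-energy estimation from per-window energy-difference samples.

The unit of work is a :class:`WindowPair`: the alchemical energy
difference ΔU = U_j − U_i between two adjacent λ windows, sampled in
both bracketing ensembles.  The Bennett acceptance ratio (BAR) solves
the self-consistency

    ⟨f(+β(ΔU − C))⟩_i  =  ⟨f(−β(ΔU − C))⟩_j,      f(x) = 1/(1 + e^x)

for the constant C; at the fixed point the free-energy difference is
ΔG = C.  We find C as the root of the monotone log-ratio of the two
averages with Brent's method, which converges deterministically
whenever the two ΔU distributions overlap.

Per-leg free energies are accumulated per replica (sum of window-pair
ΔG along the λ schedule) and reported as mean ± SEM over independent
replicas, mirroring how replicated FEP simulations are analysed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from fepcycles.errors import ConvergenceError, FepInputError

#: Gas constant in kcal/(mol·K).
R_KCAL = 1.9872e-3

#: Default simulation temperature (K).
DEFAULT_TEMPERATURE = 298.0

DEFAULT_TOLERANCE = 1e-8
DEFAULT_MAX_ITERATIONS = 200


@dataclass(frozen=True)
class WindowPair:
    """ΔU samples for one adjacent λ pair, from both ensembles.

    ``du_from_i`` holds ΔU = U_j − U_i evaluated on configurations
    sampled at λ_i; ``du_from_j`` holds the same quantity evaluated on
    configurations sampled at λ_j.  The sign convention is global:
    j is always the higher-λ window.
    """

    lambda_i: float
    lambda_j: float
    du_from_i: np.ndarray
    du_from_j: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "du_from_i",
                           np.asarray(self.du_from_i, dtype=float))
        object.__setattr__(self, "du_from_j",
                           np.asarray(self.du_from_j, dtype=float))
        if self.lambda_i == self.lambda_j:
            raise FepInputError("lambda_i and lambda_j must differ")
        for name in ("du_from_i", "du_from_j"):
            arr = getattr(self, name)
            if arr.size == 0:
                raise FepInputError(f"{name} is empty; BAR needs both ensembles")
            if not np.all(np.isfinite(arr)):
                raise FepInputError(f"{name} contains non-finite values")


@dataclass(frozen=True)
class PairEstimate:
    """BAR result for one window pair."""

    dg: float
    c_final: float
    n_iterations: int
    converged: bool
    overlap: float


@dataclass
class FEPLeg:
    """One FEP transformation: an ordered λ schedule of window pairs,
    replicated across independent runs.

    ``windows[r]`` is the ordered list of :class:`WindowPair` for
    replica ``r``; every replica must follow the same schedule.
    Annotations (receptor state, environment, transformation label)
    are what the cycle layer validates against.
    """

    windows: list[list[WindowPair]]
    temperature: float = DEFAULT_TEMPERATURE
    state_label: str = "R"            # "R" (inactive) or "Rstar" (active)
    environment: str = "apo"          # "apo" or "bound"
    transformation: str = ""
    schedule_mode: str = "linear"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.temperature <= 0:
            raise FepInputError("temperature must be positive")
        if not self.windows or not self.windows[0]:
            raise FepInputError("leg has no window pairs")
        ref = [(w.lambda_i, w.lambda_j) for w in self.windows[0]]
        for r, rep in enumerate(self.windows):
            sched = [(w.lambda_i, w.lambda_j) for w in rep]
            if sched != ref:
                raise FepInputError(
                    f"replica {r} schedule differs from replica 0")
        if self.state_label not in ("R", "Rstar"):
            raise FepInputError(f"unknown state label {self.state_label!r}")
        if self.environment not in ("apo", "bound"):
            raise FepInputError(f"unknown environment {self.environment!r}")

    @property
    def n_replicas(self) -> int:
        return len(self.windows)


@dataclass(frozen=True)
class LegEstimate:
    """Per-leg ΔG: per-replica values, mean and SEM over replicas.

    ``sem_dg`` is ``None`` for a single replica (a standard error over
    one value is undefined, not zero).  Leg annotations are carried
    along so cycle composition can validate them.
    """

    per_replica_dg: tuple
    mean_dg: float
    sem_dg: float | None
    n_replicas: int
    state_label: str = "R"
    environment: str = "apo"
    transformation: str = ""
    temperature: float = DEFAULT_TEMPERATURE

    @classmethod
    def from_replicas(cls, per_replica_dg, **annotations) -> "LegEstimate":
        vals = np.asarray(list(per_replica_dg), dtype=float)
        if vals.size == 0:
            raise FepInputError("no replica estimates")
        mean = float(vals.mean())
        sem = (float(vals.std(ddof=1) / np.sqrt(vals.size))
               if vals.size > 1 else None)
        return cls(per_replica_dg=tuple(float(v) for v in vals),
                   mean_dg=mean, sem_dg=sem, n_replicas=int(vals.size),
                   **annotations)


def _log_mean_fermi(du: np.ndarray, beta: float, c: float, sign: float) -> float:
    # log⟨1/(1+exp(sign·β(ΔU−C)))⟩ computed via log-sum-exp;
    # log f(x) = −log(1+e^x) = −logaddexp(0, x)
    x = sign * beta * (du - c)
    return float(logsumexp(-np.logaddexp(0.0, x)) - np.log(du.size))


def bar_pair_estimate(pair: WindowPair,
                      temperature: float = DEFAULT_TEMPERATURE,
                      tolerance: float = DEFAULT_TOLERANCE,
                      max_iterations: int = DEFAULT_MAX_ITERATIONS
                      ) -> PairEstimate:
    """BAR free-energy estimate for one window pair.

    Solves the Bennett self-consistency by bracketed root-finding on
    the monotone function g(C) = log⟨f(+β(ΔU−C))⟩_i − log⟨f(−β(ΔU−C))⟩_j,
    whose unique zero satisfies ΔG = C.

    Parameters
    ----------
    pair
        ΔU samples from both ensembles (kcal/mol).
    temperature
        Kelvin; sets β = 1/RT with R = 1.9872e-3 kcal/(mol·K).
    tolerance
        Absolute tolerance on C (kcal/mol).
    max_iterations
        Iteration cap for the root finder.

    Raises
    ------
    ConvergenceError
        If no sign change of g is found within an expanded bracket
        (ensembles do not overlap); carries the two ensemble means.
    """
    if tolerance <= 0:
        raise FepInputError("tolerance must be positive")
    if temperature <= 0:
        raise FepInputError("temperature must be positive")
    beta = 1.0 / (R_KCAL * temperature)
    di, dj = pair.du_from_i, pair.du_from_j
    overlap = overlap_diagnostic(pair)

    # Degenerate case: both ensembles constant at the same value c.
    # Then ΔG = c exactly; the root finder would see a flat g.
    if (di.min() == di.max() and dj.min() == dj.max()
            and di[0] == dj[0]):
        c = float(di[0])
        return PairEstimate(dg=c, c_final=c, n_iterations=0,
                            converged=True, overlap=overlap)

    def g(c: float) -> float:
        return (_log_mean_fermi(di, beta, c, +1.0)
                - _log_mean_fermi(dj, beta, c, -1.0))

    mean_i, mean_j = float(di.mean()), float(dj.mean())
    spread = float(np.sqrt((di.var() + dj.var()) / 2.0))
    if spread == 0.0:
        spread = 1.0
    lo = min(mean_i, mean_j) - 10.0 * spread
    hi = max(mean_i, mean_j) + 10.0 * spread

    # g is increasing in C; expand the bracket a few times if needed.
    for _ in range(8):
        if g(lo) < 0.0 < g(hi):
            break
        width = hi - lo
        lo -= width
        hi += width
    else:
        raise ConvergenceError(
            "BAR self-consistency has no bracketed root; the two ΔU "
            f"ensembles do not overlap (mean_i={mean_i:.4g}, "
            f"mean_j={mean_j:.4g})", mean_i=mean_i, mean_j=mean_j)

    root, res = brentq(g, lo, hi, xtol=tolerance, maxiter=max_iterations,
                       full_output=True)

    # Disjoint ensembles leave a flat plateau where both Fermi averages
    # are numerically 1 and any C "solves" the self-consistency; such a
    # root carries no statistical information, so refuse it.
    log_fi = _log_mean_fermi(di, beta, root, +1.0)
    log_fj = _log_mean_fermi(dj, beta, root, -1.0)
    if max(log_fi, log_fj) > -1e-12:
        raise ConvergenceError(
            "BAR self-consistency is degenerate: the two ΔU ensembles "
            f"do not overlap (mean_i={mean_i:.4g}, mean_j={mean_j:.4g})",
            mean_i=mean_i, mean_j=mean_j)
    return PairEstimate(dg=float(root), c_final=float(root),
                        n_iterations=int(res.iterations),
                        converged=bool(res.converged), overlap=overlap)


def bar_pair_standard_error(pair: WindowPair, c: float,
                            temperature: float = DEFAULT_TEMPERATURE
                            ) -> float:
    """Asymptotic (delta-method) standard error of the BAR estimate.

    Evaluated at the converged constant ``c``.  Diagnostic only: leg
    results report replicate SEM, never this analytic variance.
    """
    beta = 1.0 / (R_KCAL * temperature)
    se2 = 0.0
    for du, sign in ((pair.du_from_i, +1.0), (pair.du_from_j, -1.0)):
        f = 1.0 / (1.0 + np.exp(np.clip(sign * beta * (du - c), -700, 700)))
        m = f.mean()
        se2 += f.var(ddof=1) / (du.size * m * m)
    return float(np.sqrt(se2) / beta)


def exponential_estimate(samples, direction: str,
                         temperature: float = DEFAULT_TEMPERATURE) -> float:
    """One-sided exponential (Zwanzig) free-energy average.

    ``forward`` uses ensemble-i samples: −RT·ln⟨exp(−βΔU)⟩;
    ``reverse`` uses ensemble-j samples: +RT·ln⟨exp(+βΔU)⟩.
    Both are computed with a log-sum-exp guard.  Used as a diagnostic
    bracketing the BAR estimate; BAR is what leg results are built on.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.size == 0:
        raise FepInputError("exponential_estimate needs at least one sample")
    if not np.all(np.isfinite(arr)):
        raise FepInputError("samples contain non-finite values")
    rt = R_KCAL * temperature
    if direction == "forward":
        return float(-rt * (logsumexp(-arr / rt) - np.log(arr.size)))
    if direction == "reverse":
        return float(rt * (logsumexp(arr / rt) - np.log(arr.size)))
    raise FepInputError(f"direction must be 'forward' or 'reverse', "
                        f"got {direction!r}")


def overlap_diagnostic(pair: WindowPair) -> float:
    """Histogram Bhattacharyya coefficient of the two ΔU sample sets.

    Shared bin edges span both sets; the bin count is
    ceil(sqrt(min(n_i, n_j))) with a floor of 10.  Returns a value in
    [0, 1]; 1 for identical distributions in the infinite-sample limit,
    0 for disjoint supports.
    """
    di, dj = pair.du_from_i, pair.du_from_j
    lo = min(di.min(), dj.min())
    hi = max(di.max(), dj.max())
    if lo == hi:                       # all samples identical
        return 1.0
    nbins = max(10, int(np.ceil(np.sqrt(min(di.size, dj.size)))))
    edges = np.linspace(lo, hi, nbins + 1)
    pi, _ = np.histogram(di, bins=edges)
    pj, _ = np.histogram(dj, bins=edges)
    pi = pi / di.size
    pj = pj / dj.size
    return float(np.clip(np.sum(np.sqrt(pi * pj)), 0.0, 1.0))


def estimate_leg(leg: FEPLeg,
                 tolerance: float = DEFAULT_TOLERANCE,
                 max_iterations: int = DEFAULT_MAX_ITERATIONS
                 ) -> LegEstimate:
    """Accumulate BAR over the λ schedule, independently per replica.

    Each replica's ΔG is the sum of :func:`bar_pair_estimate` over its
    adjacent window pairs; the leg result is mean ± SEM over replicas
    (SEM undefined for a single replica).

    Raises
    ------
    ConvergenceError
        Naming the replica and window index of the first pair that
        fails to converge.
    """
    per_replica = []
    for r, rep in enumerate(leg.windows):
        total = 0.0
        for w, pair in enumerate(rep):
            try:
                total += bar_pair_estimate(pair, leg.temperature,
                                           tolerance, max_iterations).dg
            except ConvergenceError as exc:
                raise ConvergenceError(
                    f"replica {r}, window {w} "
                    f"(λ {pair.lambda_i:.4g}→{pair.lambda_j:.4g}): {exc}",
                    mean_i=exc.mean_i, mean_j=exc.mean_j) from exc
        per_replica.append(total)
    return LegEstimate.from_replicas(
        per_replica,
        state_label=leg.state_label, environment=leg.environment,
        transformation=leg.transformation, temperature=leg.temperature)
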