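"""One-dimensional two-basin receptor model with exact free energies.

The receptor coordinate x distinguishes an active basin (x < 0, "R*")
from an inactive basin (x > 0, "R") of a quartic double well

    U_rec(x) = barrier·((x/a)² − 1)² + basin_bias·(x/a)

with half-width a.  Positive ``basin_bias`` lowers the active basin;
negative values lower the inactive basin (how a constitutively
inactive mutation acts).  Ligands couple harmonically,
V_s(x) = k_s·(x − x_s)²/2 + c_s: an agonist-like species sits in the
active basin (x_s < 0), a neutral species couples symmetrically.
Simulating "within one receptor conformation" — the end-state
assumption behind two-state FEP cycles — is a reflecting wall at
x = 0 restricting sampling to one basin.

Alchemical legs interpolate U_λ = (1−λ)·U_start + λ·U_end over a λ
schedule (linear, or staged like side-chain annihilation protocols),
sampled by Metropolis Monte Carlo per window.  Because the model is
one-dimensional, every leg free energy is also available exactly by
numerical quadrature of the partition function, which makes the model
a ground-truth oracle for the whole estimation pipeline.

Energies are kcal/mol throughout; temperature in kelvin.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

from fepcycles.energetics import (
    DEFAULT_TEMPERATURE,
    FEPLeg,
    R_KCAL,
    WindowPair,
)
from fepcycles.errors import FepInputError

#: Half-width multiple defining the finite integration/sampling domain.
DOMAIN_HALFWIDTHS = 6.0

_SEED_MASK = 0x7FFFFFFF


@dataclass(frozen=True)
class LigandTerm:
    """Harmonic ligand coupling V(x) = k·(x − x0)²/2 + c."""

    k: float
    x0: float
    c: float = 0.0

    def __post_init__(self):
        if self.k < 0:
            raise FepInputError("ligand force constant must be >= 0")


@dataclass(frozen=True)
class ToyModelSpec:
    """Parameters of the one-dimensional receptor Hamiltonian.

    Attributes
    ----------
    barrier
        Height of the quartic double-well barrier (kcal/mol), > 0.
    half_width
        Basin separation parameter a (the minima sit near ±a), > 0.
    basin_bias
        Linear tilt b·(x/a); positive stabilizes the active (x<0) basin.
    ligand_terms
        Harmonic ligand couplings, empty for the apo receptor.
    restraint
        "active_basin", "inactive_basin" or "none": reflecting wall at
        x = 0 confining sampling/integration to one conformation.
    temperature
        Kelvin.
    """

    barrier: float = 4.0
    half_width: float = 1.0
    basin_bias: float = 0.0
    ligand_terms: tuple[LigandTerm, ...] = ()
    restraint: str = "none"
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        if self.barrier <= 0:
            raise FepInputError("barrier must be positive")
        if self.half_width <= 0:
            raise FepInputError("half_width must be positive")
        if self.restraint not in ("active_basin", "inactive_basin", "none"):
            raise FepInputError(f"unknown restraint {self.restraint!r}")
        if self.temperature <= 0:
            raise FepInputError("temperature must be positive")
        object.__setattr__(self, "ligand_terms", tuple(self.ligand_terms))

    # -- potential -----------------------------------------------------
    def potential(self, x):
        """Total potential U(x), vectorized (kcal/mol)."""
        x = np.asarray(x, dtype=float)
        z = x / self.half_width
        u = self.barrier * (z * z - 1.0) ** 2 + self.basin_bias * z
        for t in self.ligand_terms:
            u = u + 0.5 * t.k * (x - t.x0) ** 2 + t.c
        return u

    def domain(self) -> tuple[float, float]:
        """Finite sampling/integration interval imposed by the restraint."""
        d = DOMAIN_HALFWIDTHS * self.half_width
        if self.restraint == "active_basin":
            return (-d, 0.0)
        if self.restraint == "inactive_basin":
            return (0.0, d)
        return (-d, d)

    # -- derived specs -------------------------------------------------
    def with_mutation(self, d_barrier: float, d_basin_bias: float
                      ) -> "ToyModelSpec":
        """Apply a mutation as an additive change of (barrier, bias)."""
        return dataclasses.replace(self, barrier=self.barrier + d_barrier,
                                   basin_bias=self.basin_bias + d_basin_bias)

    def with_ligands(self, terms) -> "ToyModelSpec":
        return dataclasses.replace(self, ligand_terms=tuple(terms))

    def restrained(self, restraint: str) -> "ToyModelSpec":
        return dataclasses.replace(self, restraint=restraint)

    def same_receptor(self, other: "ToyModelSpec") -> bool:
        """True when the two specs differ at most in ligand terms."""
        return (self.barrier == other.barrier
                and self.half_width == other.half_width
                and self.basin_bias == other.basin_bias
                and self.restraint == other.restraint
                and self.temperature == other.temperature)


@dataclass(frozen=True)
class LambdaSchedule:
    """λ schedule of an alchemical leg.

    ``linear`` mode uses ``windows`` evenly spaced λ states from 0 to 1
    (like 50-window ligand transformations).  ``staged`` mode takes an
    ordered list of per-stage window counts (like 4-stage × 20-window
    side-chain annihilation); each stage's local λ runs 0→1 and stage s
    of S maps onto the global path as λ_glob = (s + λ_loc)/S, with
    shared stage boundaries deduplicated.
    """

    mode: str
    windows: int = 0
    stages: tuple[int, ...] | None = None

    def __post_init__(self):
        if self.mode == "linear":
            if self.windows < 2:
                raise FepInputError("linear schedule needs >= 2 windows")
        elif self.mode == "staged":
            if not self.stages:
                raise FepInputError("staged schedule needs a stage list")
            if any(n < 2 for n in self.stages):
                raise FepInputError("each stage needs >= 2 windows")
            object.__setattr__(self, "stages", tuple(self.stages))
        else:
            raise FepInputError(f"unknown schedule mode {self.mode!r}")

    @classmethod
    def linear(cls, windows: int = 50) -> "LambdaSchedule":
        """Linear ligand-transformation schedule (default 50 windows)."""
        return cls(mode="linear", windows=windows)

    @classmethod
    def staged(cls, stages=(20, 20, 20, 20)) -> "LambdaSchedule":
        """Staged annihilation schedule (default 4 stages × 20 windows)."""
        return cls(mode="staged", stages=tuple(stages))

    def global_lambdas(self) -> np.ndarray:
        if self.mode == "linear":
            return np.linspace(0.0, 1.0, self.windows)
        out = []
        n_stages = len(self.stages)
        for s, n in enumerate(self.stages):
            loc = np.linspace(0.0, 1.0, n)
            glob = (s + loc) / n_stages
            out.append(glob if s == 0 else glob[1:])
        return np.concatenate(out)


# ---------------------------------------------------------------------
# Exact free energies by quadrature
# ---------------------------------------------------------------------

def _log_partition(spec: ToyModelSpec) -> float:
    """log ∫ exp(−βU) dx over the restraint domain (adaptive quadrature)."""
    beta = 1.0 / (R_KCAL * spec.temperature)
    lo, hi = spec.domain()
    grid = np.linspace(lo, hi, 4001)
    u0 = float(spec.potential(grid).min())

    def integrand(x):
        return np.exp(-beta * (spec.potential(x) - u0))

    val, _ = quad(integrand, lo, hi, limit=400, epsabs=1e-13, epsrel=1e-10)
    if not np.isfinite(val) or val <= 0.0:
        raise FepInputError("partition function is not integrable")
    return float(np.log(val) - beta * u0)


def _check_compatible(spec_start: ToyModelSpec, spec_end: ToyModelSpec):
    if spec_start.restraint != spec_end.restraint:
        raise FepInputError("leg end states must share the restraint")
    if spec_start.temperature != spec_end.temperature:
        raise FepInputError("leg end states must share the temperature")


def exact_leg_dg(spec_start: ToyModelSpec, spec_end: ToyModelSpec) -> float:
    """Exact ΔG = −RT·ln(Z_end/Z_start) for one alchemical leg."""
    _check_compatible(spec_start, spec_end)
    rt = R_KCAL * spec_start.temperature
    return float(-rt * (_log_partition(spec_end) - _log_partition(spec_start)))


def exact_selectivity(agonist_spec: ToyModelSpec,
                      antagonist_spec: ToyModelSpec,
                      base_spec: ToyModelSpec) -> float:
    """Exact conformational selectivity ΔΔG_cs for a ligand pair.

    ΔG(agonist→antagonist) in the active basin minus the same in the
    inactive basin.  Positive values mean the agonist prefers the
    active state.  All three specs must share the receptor parameters
    (they differ only in ligand terms).
    """
    for s in (agonist_spec, antagonist_spec):
        if not dataclasses.replace(s, ligand_terms=()).same_receptor(
                dataclasses.replace(base_spec, ligand_terms=())):
            raise FepInputError("specs must differ only in ligand terms")
    dg_active = exact_leg_dg(agonist_spec.restrained("active_basin"),
                             antagonist_spec.restrained("active_basin"))
    dg_inactive = exact_leg_dg(agonist_spec.restrained("inactive_basin"),
                               antagonist_spec.restrained("inactive_basin"))
    return dg_active - dg_inactive


# ---------------------------------------------------------------------
# Metropolis sampling
# ---------------------------------------------------------------------

def _replica_rng(seed: int, replica: int) -> np.random.Generator:
    # replica streams derived from the user seed by XOR
    return np.random.default_rng((int(seed) ^ int(replica)) & _SEED_MASK)


def _window_chain_samples(spec_start, spec_end, lambdas, n_samples, rng,
                          stride, burn_factor, step_scale):
    """Run one Metropolis chain per λ window (vectorized across windows).

    Returns (diffs, acceptance): ``diffs[k, t]`` is
    U_end(x) − U_start(x) for the t-th recorded sample of window k, and
    ``acceptance[k]`` the post-burn-in acceptance rate.
    """
    lam = np.asarray(lambdas, dtype=float)
    n_windows = lam.size
    beta = 1.0 / (R_KCAL * spec_start.temperature)
    lo, hi = spec_start.domain()
    a = spec_start.half_width
    step = step_scale * a

    # start every chain at the minimum of its own window Hamiltonian
    grid = np.linspace(lo, hi, 1201)
    us_g, ue_g = spec_start.potential(grid), spec_end.potential(grid)
    u_grid = (1.0 - lam[:, None]) * us_g[None, :] + lam[:, None] * ue_g[None, :]
    x = grid[np.argmin(u_grid, axis=1)].copy()

    us_cur = spec_start.potential(x)
    ue_cur = spec_end.potential(x)
    u_cur = (1.0 - lam) * us_cur + lam * ue_cur

    n_burn = burn_factor * n_samples
    n_steps = n_burn + n_samples * stride
    diffs = np.empty((n_windows, n_samples))
    accepted = np.zeros(n_windows)
    rec = 0
    for t in range(n_steps):
        prop = x + rng.normal(0.0, step, n_windows)
        ok = (prop > lo) & (prop < hi)
        us_p = spec_start.potential(prop)
        ue_p = spec_end.potential(prop)
        u_p = (1.0 - lam) * us_p + lam * ue_p
        log_acc = -beta * (u_p - u_cur)
        take = ok & (np.log(rng.random(n_windows)) < log_acc)
        x[take] = prop[take]
        us_cur[take] = us_p[take]
        ue_cur[take] = ue_p[take]
        u_cur[take] = u_p[take]
        if t >= n_burn:
            accepted += take
            if (t - n_burn) % stride == stride - 1:
                diffs[:, rec] = ue_cur - us_cur
                rec += 1
    acceptance = accepted / (n_steps - n_burn)
    return diffs, acceptance


def sample_leg(spec_start: ToyModelSpec, spec_end: ToyModelSpec,
               schedule: LambdaSchedule, n_samples: int, n_replicas: int,
               seed: int, stride: int = 5, burn_factor: int = 10,
               step_scale: float = 0.3) -> FEPLeg:
    """Sample an alchemical leg with per-window Metropolis Monte Carlo.

    Per replica and λ window, a Metropolis chain (Gaussian proposals of
    width ``step_scale``·a, burn-in of ``burn_factor``·n_samples steps,
    every ``stride``-th step recorded) samples U_λ = (1−λ)U_start +
    λU_end; the energy difference to the adjacent higher-λ window is
    recorded from both bracketing ensembles, exactly the layout real
    FEP output has.  Replica r draws from an independent stream seeded
    with ``seed XOR r``, so the result is deterministic given ``seed``.

    Windows whose post-burn-in acceptance rate falls outside
    [0.05, 0.95] are listed in ``leg.metadata["acceptance_warnings"]``.
    """
    _check_compatible(spec_start, spec_end)
    if n_samples < 1 or n_replicas < 1:
        raise FepInputError("n_samples and n_replicas must be >= 1")
    lam = schedule.global_lambdas()
    dlam = np.diff(lam)
    replicas = []
    warnings = []
    for r in range(n_replicas):
        rng = _replica_rng(seed, r)
        diffs, acc = _window_chain_samples(
            spec_start, spec_end, lam, n_samples, rng,
            stride, burn_factor, step_scale)
        for k, rate in enumerate(acc):
            if not 0.05 <= rate <= 0.95:
                warnings.append({"replica": r, "window": k,
                                 "acceptance": float(rate)})
        pairs = [WindowPair(lambda_i=float(lam[k]), lambda_j=float(lam[k + 1]),
                            du_from_i=dlam[k] * diffs[k],
                            du_from_j=dlam[k] * diffs[k + 1])
                 for k in range(lam.size - 1)]
        replicas.append(pairs)
    state = {"active_basin": "Rstar", "inactive_basin": "R",
             "none": "R"}[spec_start.restraint]
    env = "bound" if (spec_start.ligand_terms or spec_end.ligand_terms) \
        else "apo"
    leg = FEPLeg(windows=replicas, temperature=spec_start.temperature,
                 state_label=state, environment=env,
                 transformation="toy", schedule_mode=schedule.mode,
                 metadata={"acceptance_warnings": warnings, "seed": int(seed)})
    return leg


def sample_equilibrium(spec: ToyModelSpec, n_samples: int, n_chains: int,
                       seed: int, stride: int = 5, burn_factor: int = 10,
                       step_scale: float = 0.3) -> np.ndarray:
    """Equilibrium x samples at fixed potential (for sampler validation).

    Runs ``n_chains`` independent Metropolis chains started at random
    positions in the domain and returns the pooled
    ``n_chains · n_samples`` coordinates.
    """
    beta = 1.0 / (R_KCAL * spec.temperature)
    lo, hi = spec.domain()
    rng = np.random.default_rng(int(seed) & _SEED_MASK)
    x = rng.uniform(lo, hi, n_chains)
    u_cur = spec.potential(x)
    step = step_scale * spec.half_width
    n_burn = burn_factor * n_samples
    out = np.empty((n_chains, n_samples))
    rec = 0
    for t in range(n_burn + n_samples * stride):
        prop = x + rng.normal(0.0, step, n_chains)
        ok = (prop > lo) & (prop < hi)
        u_p = spec.potential(prop)
        take = ok & (np.log(rng.random(n_chains)) < -beta * (u_p - u_cur))
        x[take] = prop[take]
        u_cur[take] = u_p[take]
        if t >= n_burn and (t - n_burn) % stride == stride - 1:
            out[:, rec] = x
            rec += 1
    return out.ravel()


def gaussian_leg(dg_per_window, sigma: float, n_samples: int,
                 n_replicas: int,
                 temperature: float = DEFAULT_TEMPERATURE,
                 seed: int = 0) -> FEPLeg:
    """Synthetic leg with Crooks-consistent Gaussian ΔU distributions.

    For a window of true free energy ΔG_w and width σ, the forward
    ensemble draws ΔU ~ N(ΔG_w + σ²/2RT, σ²) and the reverse ensemble
    ΔU ~ N(ΔG_w − σ²/2RT, σ²); this pair satisfies the Crooks relation
    p_i(ΔU)/p_j(ΔU) = exp(β(ΔU − ΔG_w)) exactly, so BAR recovers ΔG_w
    up to sampling noise.  The leg total is sum(dg_per_window).
    """
    dgs = np.asarray(list(dg_per_window), dtype=float)
    if dgs.size == 0:
        raise FepInputError("need at least one window")
    if sigma <= 0:
        raise FepInputError("sigma must be positive")
    rt = R_KCAL * temperature
    shift = sigma * sigma / (2.0 * rt)
    lam = np.linspace(0.0, 1.0, dgs.size + 1)
    replicas = []
    for r in range(n_replicas):
        rng = _replica_rng(seed, r)
        pairs = []
        for w, dg in enumerate(dgs):
            pairs.append(WindowPair(
                lambda_i=float(lam[w]), lambda_j=float(lam[w + 1]),
                du_from_i=rng.normal(dg + shift, sigma, n_samples),
                du_from_j=rng.normal(dg - shift, sigma, n_samples)))
        replicas.append(pairs)
    return FEPLeg(windows=replicas, temperature=temperature,
                  state_label="R", environment="apo",
                  transformation="gaussian", schedule_mode="linear",
                  metadata={"seed": int(seed), "sigma": float(sigma),
                            "true_dg": float(dgs.sum())})


# ---------------------------------------------------------------------
# Scripted constitutively-inactive-mutation scenario
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class CimScenario:
    """A wild-type receptor, a CIM-like mutation and two agonists.

    The mutation tilts the double well toward the inactive basin
    (negative basin-bias change), lowering basal activity.  The "deep"
    agonist binds at the bottom of the active basin, where the tilt
    also costs binding affinity — basal and affinity effects add up
    (amplification).  The "shallow" agonist binds nearer the barrier,
    where the mutation costs less than it costs the apo active state —
    the affinity term opposes the basal term (compensation).
    """

    wt: ToyModelSpec
    mutation_delta: tuple[float, float]
    ligands: dict = field(default_factory=dict)

    def mutant(self, spec: ToyModelSpec) -> ToyModelSpec:
        return spec.with_mutation(*self.mutation_delta)

    def mutation_leg_specs(self, restraint: str, ligand: str | None = None
                           ) -> tuple[ToyModelSpec, ToyModelSpec]:
        """(wt, mutant) end states for one mutation-perturbation leg."""
        start = self.wt.restrained(restraint)
        if ligand is not None:
            start = start.with_ligands(self.ligands[ligand])
        return start, self.mutant(start)


def cim_scenario(temperature: float = DEFAULT_TEMPERATURE) -> CimScenario:
    """Default scripted CIM scenario used by tests and the CLI demo."""
    wt = ToyModelSpec(barrier=4.0, half_width=1.0, basin_bias=0.0,
                      temperature=temperature)
    return CimScenario(
        wt=wt,
        mutation_delta=(0.0, -3.0),
        ligands={
            "deep_agonist": (LigandTerm(k=8.0, x0=-1.2),),
            "shallow_agonist": (LigandTerm(k=8.0, x0=-0.4),),
        })
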