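"""Stochastic pulsed-resource microcosm simulator.

The simulator emulates the experimental design the analysis pipeline
assumes: five treatment arms x eight replicate microcosms, each holding
five resident green algae and five resident protozoa, challenged by four
invader species introduced two weeks in; nutrient pulses that differ in
magnitude, duration and timing but are equal in total input; daily 1.4%
medium replacement; and weekly censuses of a 0.32 mL subsample.

Dynamics are a discrete-day Euler consumer-resource chain:

* a single lumped nutrient pool R (units of standard-medium nutrient/mL)
  replenished by dilution and by pulses of concentrated medium,
* algae growing on R with Monod kinetics and drawing it down via a yield
  coefficient,
* protozoa converting (lumped linear) grazing on algae into growth.

Species updates are multiplicative, ``x <- x * exp(net rate + noise)``,
which keeps densities non-negative.  Process noise is lognormal with two
components: an independent per-species baseline, and a pulse-driven shock
whose magnitude scales with the day's pulse volume and whose cross-species
correlation is ``rho_env`` — species respond to a nutrient pulse in a
partially shared way, which is what synchronises the community and inflates
the variability of pulsed arms.

The five arms: Control (no concentrate), Early / Coincident / Late
(1.155 mL of concentrate on two consecutive days, placed before / at /
after the invader introduction on day 14), and MultiPulses (the same
2.31 mL total dripped as 0.055 mL/day over all 42 days).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import scipy.optimize

from .domain_model import (
    CommunityTimeSeries,
    Origin,
    PulseSchedule,
    Treatment,
    TrophicGroup,
    ValidationError,
)

__all__ = [
    "AlgaTraits",
    "ProtozoanTraits",
    "ModelParams",
    "SimulationConfig",
    "default_config",
    "build_treatment_schedules",
    "find_fixed_point",
    "simulate_microcosm",
    "observe",
    "simulate_experiment",
]


@dataclass(frozen=True)
class AlgaTraits:
    """Monod growth traits of one algal species.

    growth_rate : maximum per-capita growth rate (1/day)
    half_saturation : nutrient level at half-maximal growth (units/mL)
    nutrient_yield : algal cells produced per unit of nutrient consumed
    """

    growth_rate: float
    half_saturation: float
    nutrient_yield: float

    def __post_init__(self) -> None:
        if self.growth_rate < 0 or self.half_saturation <= 0 or self.nutrient_yield <= 0:
            raise ValidationError(f"invalid algal traits: {self}")


@dataclass(frozen=True)
class ProtozoanTraits:
    """Grazing traits of one protozoan species.

    attack_rates : mL swept per individual per day, per algal prey species
    efficiency : conversion of grazed algal density into protozoan growth, in (0, 1]
    mortality : per-capita death rate (1/day)
    """

    attack_rates: Mapping[str, float]
    efficiency: float
    mortality: float

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.attack_rates.values()):
            raise ValidationError(f"negative attack rate in {self}")
        if not (0 < self.efficiency <= 1):
            raise ValidationError(f"efficiency must be in (0, 1]: {self.efficiency}")
        if self.mortality < 0:
            raise ValidationError(f"negative mortality: {self.mortality}")


@dataclass(frozen=True)
class ModelParams:
    """Dynamics parameters for the whole species pool.

    ``noise_sd`` is the SD of the independent per-species daily lognormal
    growth shock; ``pulse_noise_sd`` is the SD of the extra shock on a day
    receiving one reference high-magnitude pulse volume (scaled linearly
    with the day's volume); ``rho_env`` in [0, 1] is the cross-species
    correlation of that pulse-driven shock.
    """

    algae: Mapping[str, AlgaTraits]
    protozoa: Mapping[str, ProtozoanTraits]
    medium_nutrient: float = 1.0
    noise_sd: float = 0.05
    pulse_noise_sd: float = 0.5
    rho_env: float = 0.7

    def __post_init__(self) -> None:
        if not (0 <= self.rho_env <= 1):
            raise ValidationError(f"rho_env must be in [0, 1]: {self.rho_env}")
        if self.noise_sd < 0 or self.pulse_noise_sd < 0:
            raise ValidationError("noise SDs must be >= 0")
        for p in self.protozoa.values():
            missing = set(self.algae) - set(p.attack_rates)
            if missing:
                raise ValidationError(f"protozoan attack map missing algal prey: {missing}")


@dataclass(frozen=True)
class SimulationConfig:
    """Full experiment blueprint: species pools, schedules, noise, seed."""

    params: ModelParams
    resident_algae: tuple[str, ...]
    resident_protozoa: tuple[str, ...]
    invader_algae: tuple[str, ...]
    invader_protozoa: tuple[str, ...]
    n_replicates: int = 8
    horizon_days: int = 42
    sampling_days: tuple[int, ...] = (7, 14, 21, 28, 35, 42)
    invader_day: int = 14
    invader_inoculum: float = 10.0  # ind/mL added per invader species
    dilution_rate: float = 0.014  # fraction of medium replaced per day
    subsample_volume: float = 0.32  # mL counted per census
    microcosm_volume: float = 100.0  # mL
    pulse_volume: float = 1.155  # mL concentrate per high-magnitude pulse day
    pulse_days: Mapping[Treatment, tuple[int, ...]] = field(
        default_factory=lambda: {
            Treatment.EARLY: (10, 11),
            Treatment.COINCIDENT: (14, 15),
            Treatment.LATE: (18, 19),
        }
    )
    multi_pulse_volume: float = 0.055  # mL concentrate per day, MultiPulses arm
    concentrate_strength: float = 56.5  # standard-medium nutrient units per mL concentrate
    extinction_threshold: float = 1e-3  # ind/mL below which a population is extinct
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        days = np.asarray(self.sampling_days)
        if np.any(days < 1) or np.any(days > self.horizon_days):
            raise ValidationError("sampling_days must lie within [1, horizon_days]")
        if np.any(np.diff(days) <= 0):
            raise ValidationError("sampling_days must be strictly increasing")
        all_names = self.species_names
        if len(set(all_names)) != len(all_names):
            raise ValidationError("species names must be unique")

    @property
    def algae(self) -> tuple[str, ...]:
        return tuple(self.resident_algae) + tuple(self.invader_algae)

    @property
    def protozoa(self) -> tuple[str, ...]:
        return tuple(self.resident_protozoa) + tuple(self.invader_protozoa)

    @property
    def species_names(self) -> tuple[str, ...]:
        return self.algae + self.protozoa

    def trophic_map(self) -> dict[str, TrophicGroup]:
        out = {s: TrophicGroup.ALGA for s in self.algae}
        out.update({s: TrophicGroup.PROTOZOAN for s in self.protozoa})
        return out

    def origin_map(self) -> dict[str, Origin]:
        invaders = set(self.invader_algae) | set(self.invader_protozoa)
        return {s: (Origin.INVADER if s in invaders else Origin.RESIDENT) for s in self.species_names}


# ---------------------------------------------------------------------------
# shipped default parameterisation
# ---------------------------------------------------------------------------

_RESIDENT_ALGAE = (
    "Chlorella sp.",
    "Scenedesmus opoliensis",
    "Cosmarium sportella",
    "Micrasterias sp.",
    "Volvox aureus",
)
_RESIDENT_PROTOZOA = (
    "Colpidium striatum",
    "Paramecium aurelia",
    "Euplotes eurystomus",
    "Blepharisma americanum",
    "Spirostomum sp.",
)
_INVADER_ALGAE = ("Chlamydomonas reinhardtii", "Closterium libellula")
_INVADER_PROTOZOA = ("Tetrahymena pyriformis", "Paramecium bursaria")

_ALGA_MU = (0.50, 0.55, 0.60, 0.52, 0.58)
_ALGA_K = (0.50, 0.60, 0.70, 0.55, 0.65)
_PROTO_MORT = (0.050, 0.060, 0.055, 0.065, 0.045)


def default_params() -> ModelParams:
    """Shipped default dynamics parameters.

    Resident trait values are spread modestly around field-plausible
    magnitudes for freshwater microcosms (algal max growth ~0.5-0.6/day,
    protozoan mortality ~0.05/day, clearance rates ~1e-4 mL/ind/day).
    Each resident protozoan grazes one resident alga preferentially and
    all other algae weakly, which yields a unique interior equilibrium
    the communities are initialised at.
    """
    all_alga_names = _RESIDENT_ALGAE + _INVADER_ALGAE
    algae = {
        name: AlgaTraits(growth_rate=mu, half_saturation=k, nutrient_yield=2.5e5)
        for name, mu, k in zip(_RESIDENT_ALGAE, _ALGA_MU, _ALGA_K)
    }
    for name in _INVADER_ALGAE:
        algae[name] = AlgaTraits(growth_rate=0.50, half_saturation=0.60, nutrient_yield=2.5e5)

    protozoa = {}
    for j, (name, mort) in enumerate(zip(_RESIDENT_PROTOZOA, _PROTO_MORT)):
        attack = {a: 2e-5 for a in all_alga_names}
        attack[_RESIDENT_ALGAE[j]] = 2e-4  # preferred prey
        protozoa[name] = ProtozoanTraits(attack_rates=attack, efficiency=0.35, mortality=mort)
    for name in _INVADER_PROTOZOA:
        attack = {a: 6e-5 for a in all_alga_names}
        protozoa[name] = ProtozoanTraits(attack_rates=attack, efficiency=0.35, mortality=0.06)

    return ModelParams(algae=algae, protozoa=protozoa)


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Shipped default experiment blueprint (5 arms x 8 replicates)."""
    cfg = SimulationConfig(
        params=default_params(),
        resident_algae=_RESIDENT_ALGAE,
        resident_protozoa=_RESIDENT_PROTOZOA,
        invader_algae=_INVADER_ALGAE,
        invader_protozoa=_INVADER_PROTOZOA,
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# treatment schedules
# ---------------------------------------------------------------------------


def build_treatment_schedules(config: SimulationConfig) -> dict[Treatment, PulseSchedule]:
    """Per-day concentrate volumes for each arm; pulsed arms share one total.

    Control adds nothing; each high-magnitude arm adds ``pulse_volume`` on
    its two scheduled days; MultiPulses adds ``multi_pulse_volume`` on every
    day 1..horizon.  With the defaults, 2 x 1.155 mL = 42 x 0.055 mL =
    2.31 mL for every pulsed arm.
    """
    conc = config.concentrate_strength
    schedules = {Treatment.CONTROL: PulseSchedule({}, concentration=conc)}
    for arm, days in config.pulse_days.items():
        if max(days) > config.horizon_days:
            raise ValidationError(f"{arm.value}: pulse day {max(days)} beyond horizon {config.horizon_days}")
        schedules[arm] = PulseSchedule({d: config.pulse_volume for d in days}, concentration=conc)
    schedules[Treatment.MULTI_PULSES] = PulseSchedule(
        {d: config.multi_pulse_volume for d in range(1, config.horizon_days + 1)}, concentration=conc
    )
    pulsed = [t for t in schedules if t is not Treatment.CONTROL]
    ref = schedules[pulsed[0]]
    for t in pulsed[1:]:
        if not schedules[t].equal_total(ref, tol=1e-9):
            raise ValidationError(
                f"unequal total concentrate: {t.value} adds {schedules[t].total_volume} mL, "
                f"{pulsed[0].value} adds {ref.total_volume} mL"
            )
    return schedules


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------


class _Arrays:
    """Parameter vectors/matrices aligned with config species ordering."""

    def __init__(self, config: SimulationConfig):
        p = config.params
        self.mu = np.array([p.algae[a].growth_rate for a in config.algae])
        self.K = np.array([p.algae[a].half_saturation for a in config.algae])
        self.Y = np.array([p.algae[a].nutrient_yield for a in config.algae])
        self.attack = np.array(
            [[p.protozoa[z].attack_rates[a] for a in config.algae] for z in config.protozoa]
        )  # shape (n_protozoa, n_algae)
        self.eff = np.array([p.protozoa[z].efficiency for z in config.protozoa])
        self.mort = np.array([p.protozoa[z].mortality for z in config.protozoa])
        self.n_algae = len(config.algae)
        self.n_protozoa = len(config.protozoa)


def _step(R, A, P, pulse_nutrient, arr: _Arrays, config: SimulationConfig,
          eps_A=None, eps_P=None):
    """Advance the state one day; returns (R', A', P').

    Order of operations: pulse input and dilution refresh the nutrient
    pool; algal growth/uptake and protozoan grazing are computed from the
    refreshed pool and pre-update densities; species then update
    multiplicatively.
    """
    d = config.dilution_rate
    R_in = R + pulse_nutrient + d * (config.params.medium_nutrient - R)

    monod = arr.mu * R_in / (arr.K + R_in)  # algal per-capita growth
    grazing_on = arr.attack.T @ P  # per-alga loss rate, Σ_j a_ji P_j
    r_A = monod - grazing_on - d
    intake = arr.attack @ A  # per-protozoan intake rate, Σ_i a_ji A_i
    r_P = arr.eff * intake - arr.mort - d

    uptake = float((monod * A / arr.Y).sum())
    R_new = max(R_in - uptake, 0.0)
    if eps_A is None:
        A_new = A * np.exp(r_A)
        P_new = P * np.exp(r_P)
    else:
        A_new = A * np.exp(r_A + eps_A)
        P_new = P * np.exp(r_P + eps_P)
    return R_new, A_new, P_new


def find_fixed_point(config: SimulationConfig) -> tuple[float, np.ndarray, np.ndarray]:
    """Interior fixed point of the deterministic resident-only daily map.

    Solves ``step(x) = x`` for the nutrient pool and the resident species
    (no pulses, no invaders, no noise) by Newton iteration in log space,
    starting from the quasi-diagonal analytic guess (each protozoan pinned
    by its preferred prey).  Used to initialise every simulated microcosm
    so that an unperturbed community sits at equilibrium.

    Returns (R*, resident_algae_densities, resident_protozoa_densities).
    """
    resident = replace(config, invader_algae=(), invader_protozoa=())
    arr = _Arrays(resident)
    d = resident.dilution_rate

    # analytic guess: protozoan balance fixes A, algal balance then fixes P
    A0 = np.linalg.solve(arr.attack, (arr.mort + d) / arr.eff)
    R0 = 0.3 * resident.params.medium_nutrient
    monod0 = arr.mu * R0 / (arr.K + R0)
    P0, *_ = np.linalg.lstsq(arr.attack.T, monod0 - d, rcond=None)
    x0 = np.log(np.clip(np.concatenate([[R0], A0, P0]), 1e-6, None))

    nA = arr.n_algae

    def residual(logx):
        x = np.exp(logx)
        R, A, P = x[0], x[1 : 1 + nA], x[1 + nA :]
        Rn, An, Pn = _step(R, A, P, 0.0, arr, resident)
        return np.concatenate([[Rn - R], An - A, Pn - P])

    sol = scipy.optimize.root(residual, x0, method="hybr", tol=1e-13)
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-8:
        raise RuntimeError(f"fixed-point search failed: {sol.message}")
    x = np.exp(sol.x)
    return float(x[0]), x[1 : 1 + nA], x[1 + nA :]


def _initial_state(config: SimulationConfig) -> tuple[float, np.ndarray, np.ndarray]:
    """Initial state: residents at the interior fixed point, invaders at 0."""
    R, A_res, P_res = find_fixed_point(config)
    A = np.concatenate([A_res, np.zeros(len(config.invader_algae))])
    P = np.concatenate([P_res, np.zeros(len(config.invader_protozoa))])
    return R, A, P


def simulate_microcosm(
    config: SimulationConfig,
    treatment: Treatment,
    rng: np.random.Generator,
    schedule: PulseSchedule | None = None,
    microcosm_id: str | None = None,
    initial_state: tuple[float, np.ndarray, np.ndarray] | None = None,
    return_nutrient: bool = False,
):
    """Simulate one microcosm's latent daily trajectory.

    Returns a CommunityTimeSeries on days 1..horizon with exact (free of
    counting error) densities; pass it to :func:`observe` for the
    subsample census.  Invaders receive their inoculum at the start of
    ``invader_day``.  With ``return_nutrient=True`` also returns the daily
    nutrient-pool trajectory (units/mL, days 1..horizon).
    """
    if schedule is None:
        schedule = build_treatment_schedules(config)[treatment]
    arr = _Arrays(config)
    R, A, P = initial_state if initial_state is not None else _initial_state(config)
    A, P = A.copy(), P.copy()
    n_days = config.horizon_days
    n_sp = arr.n_algae + arr.n_protozoa
    traj = np.empty((n_sp, n_days + 1))
    traj[:, 0] = np.concatenate([A, P])
    nutrient = np.empty(n_days)

    p = config.params
    n_inv_A = len(config.invader_algae)
    n_inv_P = len(config.invader_protozoa)

    for t in range(1, n_days + 1):
        if t == config.invader_day:
            if n_inv_A:
                A[arr.n_algae - n_inv_A :] += config.invader_inoculum
            if n_inv_P:
                P[arr.n_protozoa - n_inv_P :] += config.invader_inoculum

        vol = schedule.volume_on(t)
        pulse_nutrient = vol * schedule.concentration / config.microcosm_volume

        # per-species baseline shock + correlated pulse-driven shock
        eps = p.noise_sd * rng.standard_normal(n_sp)
        if vol > 0 and p.pulse_noise_sd > 0:
            scale = p.pulse_noise_sd * vol / config.pulse_volume
            shared = rng.standard_normal()
            own = rng.standard_normal(n_sp)
            eps = eps + scale * (np.sqrt(p.rho_env) * shared + np.sqrt(1 - p.rho_env) * own)

        R, A, P = _step(R, A, P, pulse_nutrient, arr, config,
                        eps_A=eps[: arr.n_algae], eps_P=eps[arr.n_algae :])
        A[A < config.extinction_threshold] = 0.0
        P[P < config.extinction_threshold] = 0.0
        state = np.concatenate([A, P])
        if not np.all(np.isfinite(state)) or not np.isfinite(R):
            bad = np.nonzero(~np.isfinite(state))[0]
            name = config.species_names[bad[0]] if bad.size else "<nutrient>"
            raise RuntimeError(f"non-finite state on day {t} for {name}")
        traj[:, t] = state
        nutrient[t - 1] = R

    series = CommunityTimeSeries(
        microcosm_id=microcosm_id or f"{treatment.value}-latent",
        treatment=treatment,
        sampling_days=tuple(range(1, n_days + 1)),
        species_names=config.species_names,
        trophic_group=config.trophic_map(),
        origin=config.origin_map(),
        density=traj[:, 1:],
    )
    return (series, nutrient) if return_nutrient else series


def observe(
    latent: CommunityTimeSeries, config: SimulationConfig, rng: np.random.Generator
) -> CommunityTimeSeries:
    """Subsample census: Poisson counts in ``subsample_volume`` mL, per mL.

    Each observed density is ``Poisson(latent * v) / v`` with v the
    subsample volume, so observed values are multiples of 1/v and their
    expectation equals the latent density.
    """
    v = config.subsample_volume
    cols = [latent.sampling_days.index(d) for d in config.sampling_days]
    lam = latent.density[:, cols] * v
    counts = rng.poisson(lam)
    return CommunityTimeSeries(
        microcosm_id=latent.microcosm_id,
        treatment=latent.treatment,
        sampling_days=tuple(config.sampling_days),
        species_names=latent.species_names,
        trophic_group=latent.trophic_group,
        origin=latent.origin,
        density=counts / v,
    )


def _microcosm_rng(seed: int, treatment_index: int, replicate: int) -> np.random.Generator:
    """Deterministic per-microcosm substream keyed by (arm, replicate)."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(treatment_index, replicate))
    )


def simulate_experiment(config: SimulationConfig) -> list[CommunityTimeSeries]:
    """Simulate and census the full design: every arm x replicate.

    Replicate substreams are derived deterministically from ``config.seed``
    so each arm can be re-run independently; microcosm ids are
    ``"<Treatment>-<replicate>"``.
    """
    schedules = build_treatment_schedules(config)
    init = _initial_state(config)
    out: list[CommunityTimeSeries] = []
    for ti, treatment in enumerate(Treatment):
        for rep in range(config.n_replicates):
            rng = _microcosm_rng(config.seed, ti, rep)
            mid = f"{treatment.value}-{rep + 1:02d}"
            latent = simulate_microcosm(
                config, treatment, rng, schedule=schedules[treatment],
                microcosm_id=mid, initial_state=init,
            )
            out.append(observe(latent, config, rng))
    return out
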