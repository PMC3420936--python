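"""Deterministic twin-domain supercoiling kinetics on a circular chromosome.

The chromosome is a ring of ~10 kb topological domains, each carrying a
diffusible supercoil density sigma_i.  An elongating transcription unit
rotates the template through its own inertial mass, driving one negative
supercoil per helical repeat into the domain behind it (upstream) and one
positive supercoil into the domain ahead (downstream) — the twin-domain
flux.  Three topoisomerase activities oppose this flux with
linear-saturating rate laws:

* gyrase introduces negative supercoils at up to ``k_gyrase`` sc/s per
  domain, ramping down linearly to zero at its setpoint ``sigma_setpoint``;
* Topo I removes negative supercoils at up to ``k_topo1`` sc/s, engaging
  only below ``sigma_topo1_threshold`` (hypernegative upstream DNA);
* Topo IV removes positive supercoils at up to ``k_topo4`` sc/s, acting
  only where sigma > 0.

Supercoil density equilibrates between adjacent domains at
``diffusion_rate`` per second, except across actively transcribed units,
which are barriers.  The rate laws are model assumptions consistent with the
measured catalytic speeds (gyrase 4-5 sc/s, Topo I comparable); population
means are the observable, so updating is deterministic forward Euler
(stable for dt <= 0.01 s at default rates).

With all topoisomerase rates zero, the twin-domain fluxes are equal and
opposite on a closed circle, so total linking difference is conserved
exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .calibration import CalibrationCurve, efficiency_at

__all__ = [
    "TranscriptionUnit", "TopoisomeraseParams", "ChromosomeModel",
    "SimState", "PRESETS", "build_model", "step", "run_to_steady_state",
    "rif_experiment", "predicted_efficiency_profile", "load_scenario",
]

SIGMA_ABORT = 0.5        # |sigma| beyond which integration is unphysical
DEFAULT_DT = 0.01        # s; documented stability bound at default rates


@dataclass(frozen=True)
class TranscriptionUnit:
    """A highly expressed operon driving twin-domain supercoil flux."""

    position: float              # centisome of the unit's span
    orientation: int = 1         # +1/-1 along the circle
    elongation_rate: float = 52.5   # nt/s
    activity: float = 0.9        # fraction of time the unit is elongating
    is_barrier: bool = True      # active units block supercoil diffusion

    def __post_init__(self):
        if not 0.0 <= self.activity <= 1.0:
            raise ValueError("activity must be in [0, 1]")
        if self.elongation_rate < 0:
            raise ValueError("elongation rate must be >= 0")
        if self.orientation not in (-1, 1):
            raise ValueError("orientation must be +1 or -1")


@dataclass(frozen=True)
class TopoisomeraseParams:
    """Maximal catalytic rates (supercoils/s per domain) and setpoints."""

    k_gyrase: float = 4.5
    sigma_setpoint: float = -0.038
    k_topo1: float = 4.5
    sigma_topo1_threshold: float = -0.045
    k_topo4: float = 0.5

    def __post_init__(self):
        if min(self.k_gyrase, self.k_topo1, self.k_topo4) < 0:
            raise ValueError("topoisomerase rates must be >= 0")
        if self.sigma_setpoint >= 0:
            raise ValueError("gyrase setpoint must be negative")
        if self.sigma_topo1_threshold >= self.sigma_setpoint:
            raise ValueError("Topo I threshold must lie below the gyrase "
                             "setpoint")


@dataclass(frozen=True)
class ChromosomeModel:
    """Circular domain-partitioned chromosome with transcription units."""

    n_domains: int = 450
    domain_size_bp: float = 10000.0
    units: tuple[TranscriptionUnit, ...] = ()
    topo: TopoisomeraseParams = field(default_factory=TopoisomeraseParams)
    diffusion_rate: float = 0.1      # 1/s, between adjacent domains
    helical_repeat: float = 10.5     # bp/turn

    def __post_init__(self):
        if self.n_domains < 3:
            raise ValueError("need at least 3 domains on the circle")
        if self.diffusion_rate < 0:
            raise ValueError("diffusion rate must be >= 0")

    @property
    def lk0_domain(self) -> float:
        """Relaxed linking number of one domain (turns)."""
        return self.domain_size_bp / self.helical_repeat

    def domain_of(self, position_cs: float) -> int:
        if not 0.0 <= position_cs < 100.0:
            raise ValueError("position must be a centisome in [0, 100)")
        return int(position_cs / 100.0 * self.n_domains) % self.n_domains


@dataclass
class SimState:
    """Per-domain sigma_D and elapsed time."""

    sigma: np.ndarray
    time: float = 0.0
    converged: bool | None = None

    @property
    def total_linking_difference(self):
        raise AttributeError("use linking_difference(model) — the conversion "
                             "needs the domain size")

    def linking_difference(self, model: ChromosomeModel) -> float:
        """Sum over domains of sigma_i * Lk0 per domain (turns)."""
        return float(self.sigma.sum() * model.lk0_domain)


def _compiled(model: ChromosomeModel):
    """Precompute index arrays for the derivative evaluation."""
    n = model.n_domains
    upos = np.array([model.domain_of(u.position) for u in model.units],
                    dtype=int)
    ori = np.array([u.orientation for u in model.units], dtype=int)
    flux = np.array([u.activity * u.elongation_rate / model.helical_repeat
                     for u in model.units]) / model.lk0_domain
    up = (upos - ori) % n
    dn = (upos + ori) % n
    gate = np.ones(n)
    for u, d in zip(model.units, upos):
        if u.is_barrier and u.activity > 0:
            gate[d] = 0.0             # edge (d, d+1)
            gate[(d - 1) % n] = 0.0   # edge (d-1, d)
    return upos, up, dn, flux, gate


def _derivative(model, sigma, up, dn, flux, gate):
    """d(sigma)/dt for every domain."""
    topo = model.topo
    aset = abs(topo.sigma_setpoint)
    lk0 = model.lk0_domain
    d = np.zeros_like(sigma)
    if len(flux):
        np.add.at(d, up, -flux)
        np.add.at(d, dn, flux)
    d -= (topo.k_gyrase / lk0) * np.clip(
        (sigma - topo.sigma_setpoint) / aset, 0.0, 1.0)
    d += (topo.k_topo1 / lk0) * np.clip(
        (topo.sigma_topo1_threshold - sigma) / aset, 0.0, 1.0)
    d -= (topo.k_topo4 / lk0) * np.clip(sigma / aset, 0.0, 1.0)
    if model.diffusion_rate > 0:
        f = model.diffusion_rate * (np.roll(sigma, -1) - sigma) * gate
        d += f - np.roll(f, 1)
    return d


def step(model: ChromosomeModel, state: SimState, dt: float) -> SimState:
    """Advance one forward-Euler step of length dt (dt <= 0.01 s at default
    rates for stability)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    up_, up, dn, flux, gate = _compiled(model)
    sigma = state.sigma + dt * _derivative(model, state.sigma, up, dn, flux,
                                           gate)
    if np.abs(sigma).max() > SIGMA_ABORT:
        raise RuntimeError("integration unstable: |sigma| exceeded "
                           f"{SIGMA_ABORT}; reduce dt or fluxes")
    return SimState(sigma=sigma, time=state.time + dt)


def run_to_steady_state(model: ChromosomeModel, dt: float = DEFAULT_DT,
                        tol: float = 1e-6, t_max: float = 2000.0,
                        state: SimState | None = None) -> SimState:
    """Iterate until max |dsigma/dt| < tol (1/s) or t_max is reached.

    Non-convergence is flagged on the returned state, not raised.
    """
    if state is None:
        state = SimState(sigma=np.full(model.n_domains,
                                       model.topo.sigma_setpoint))
    _, up, dn, flux, gate = _compiled(model)
    sigma = state.sigma.copy()
    t = state.time
    n_steps = int(np.ceil(t_max / dt))
    check_every = 100
    for i in range(n_steps):
        d = _derivative(model, sigma, up, dn, flux, gate)
        sigma += dt * d
        t += dt
        if i % check_every == 0:
            if np.abs(sigma).max() > SIGMA_ABORT:
                raise RuntimeError("integration unstable: |sigma| exceeded "
                                   f"{SIGMA_ABORT}")
            if np.abs(d).max() < tol:
                return SimState(sigma=sigma, time=t, converged=True)
    return SimState(sigma=sigma, time=t,
                    converged=bool(np.abs(d).max() < tol))


def rif_experiment(model: ChromosomeModel, state: SimState,
                   **run_kwargs) -> SimState:
    """Rebound after rifampicin: initiation blocked, so all transcription
    activities drop to 0 and barriers dissolve; relax to the new steady
    state from the supplied state."""
    rif_model = _apply_rif(model)
    return run_to_steady_state(rif_model, state=SimState(
        sigma=state.sigma.copy(), time=state.time), **run_kwargs)


def _apply_rif(model: ChromosomeModel) -> ChromosomeModel:
    units = tuple(replace(u, activity=0.0, is_barrier=False)
                  for u in model.units)
    return replace(model, units=units)


def predicted_efficiency_profile(model: ChromosomeModel, state: SimState,
                                 curve: CalibrationCurve,
                                 positions) -> np.ndarray:
    """Resolution efficiencies a sensor would report at the given centisome
    positions under the simulated sigma profile.

    Domains driven to positive sigma (downstream of strong units in
    gyrase-impaired chromosomes) are treated as relaxed: efficiency 0.
    """
    out = []
    for pos in positions:
        sig = state.sigma[model.domain_of(float(pos))]
        out.append(efficiency_at(curve, min(sig, 0.0)))
    return np.array(out)


# -- scenario presets -------------------------------------------------------

def _default_units(n_units=45, n_domains=450, elongation_rate=52.5,
                   activity=0.9):
    """Evenly spaced, replication-co-oriented highly transcribed units."""
    return tuple(
        TranscriptionUnit(position=(i * n_domains // n_units)
                          * 100.0 / n_domains,
                          orientation=1,
                          elongation_rate=elongation_rate,
                          activity=activity)
        for i in range(n_units)
    )


PRESETS = {
    # catalytic scalings relative to wild type; the severe gyrB alleles have
    # low k_cat, the Topo IV ParE mutant halves positive-supercoil removal,
    # the slow-polymerase rpoC deletion reduces elongation speed.
    "wt":       {"gyrase_scale": 1.0},
    "gyrA209":  {"gyrase_scale": 0.5},
    "gyrB652":  {"gyrase_scale": 0.1},
    "gyrB1820": {"gyrase_scale": 0.1},
    "parE206":  {"topo4_scale": 0.5},
    "rpoC":     {"elongation_scale": 0.6},
}


def build_model(scenario, rif: bool = False) -> ChromosomeModel:
    """Build a chromosome model from a preset name or a config mapping.

    A mapping may name a ``preset`` plus overrides (n_domains,
    diffusion_rate, topoisomerase rates, unit layout) and ``rif: true``.
    """
    if isinstance(scenario, str):
        config = {"preset": scenario}
    else:
        config = dict(scenario)
    preset_name = config.pop("preset", "wt")
    if preset_name not in PRESETS:
        raise ValueError(f"unknown preset {preset_name!r}; available: "
                         f"{sorted(PRESETS)}")
    preset = PRESETS[preset_name]
    rif = bool(config.pop("rif", rif))

    n_domains = int(config.pop("n_domains", 450))
    topo = TopoisomeraseParams(
        k_gyrase=config.pop("k_gyrase", 4.5) * preset.get("gyrase_scale", 1.0),
        sigma_setpoint=config.pop("sigma_setpoint", -0.038),
        k_topo1=config.pop("k_topo1", 4.5),
        sigma_topo1_threshold=config.pop("sigma_topo1_threshold", -0.045),
        k_topo4=config.pop("k_topo4", 0.5) * preset.get("topo4_scale", 1.0),
    )
    units = _default_units(
        n_units=int(config.pop("n_units", 45)),
        n_domains=n_domains,
        elongation_rate=config.pop("elongation_rate", 52.5)
        * preset.get("elongation_scale", 1.0),
        activity=config.pop("activity", 0.9),
    )
    model = ChromosomeModel(
        n_domains=n_domains,
        domain_size_bp=config.pop("domain_size_bp", 10000.0),
        units=units, topo=topo,
        diffusion_rate=config.pop("diffusion_rate", 0.1),
        helical_repeat=config.pop("helical_repeat", 10.5),
    )
    if config:
        raise ValueError(f"unknown scenario keys: {sorted(config)}")
    return _apply_rif(model) if rif else model


def load_scenario(path) -> ChromosomeModel:
    """Build a model from a JSON scenario file."""
    with open(path) as fh:
        return build_model(json.load(fh))
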