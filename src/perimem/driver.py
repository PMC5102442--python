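"""Run a full rupture simulation from configuration to trajectory.

The pipeline: build the circular lattice and bond network, place the pins,
then loop {impose boundary driving → implicit trapezoidal step (retrying
with an adapted Δt) → break over-stretched bonds → update damage →
snapshot at the configured cadence} until the membrane has expanded to the
target diameter ratio D/D₀ (or a wall of simulated time is hit).
"""

from __future__ import annotations

import configparser
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .constitutive import (ForceEvaluator, MaterialModel, damage_field,
                           update_broken_bonds)
from .discretization import (Membrane, BondNetwork, PinningSet,
                             assign_pinning, build_bond_network,
                             build_circular_membrane)
from .integrator import (IntegratorSettings, SimulationState,
                         TimestepUnderflowError, _ConstraintProjector,
                         adapt_dt, trapezoidal_step)

logger = logging.getLogger(__name__)


@dataclass
class GeometryConfig:
    """Membrane geometry; defaults are the study conditions (μm)."""

    diameter: float = 200.0
    spacing_h: float = 1.0
    horizon_delta: float = 3.0
    thickness: float = 0.005
    layer_width: float = 10.0


@dataclass
class PinningConfig:
    n: int = 0
    seed: int | None = None
    region: tuple[float, float, float] | None = None  # (cx, cy, radius)
    coordinates: list[tuple[float, float]] | None = None


@dataclass
class RunConfig:
    """Everything needed to reproduce a simulation.

    Defaults equal the study conditions: 200 μm diameter, h = 1 μm,
    δ = 3 μm, 5 nm thickness, 10 μm driven layer, K = 10 MPa,
    ρ = 1000 kg/m³ with mass scale 10⁸, s_c = 0.15, contact scale
    2.7e-8, rim speed 200 μm/s.
    """

    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    material: MaterialModel = field(default_factory=MaterialModel)
    pinning: PinningConfig = field(default_factory=PinningConfig)
    integrator: IntegratorSettings = field(default_factory=IntegratorSettings)
    loading_rate: float = 200.0        # μm/s, radial speed of the rim layer
    loading_ramp: float = 2e-3         # s, rim-speed spin-up (shock mitigation)
    target_expansion: float = 1.4      # stop when D/D0 reaches this
    max_time: float | None = None      # optional wall of simulated time, s
    snapshot_interval: float = 3e-3    # simulated seconds between snapshots
    master_seed: int = 0

    def to_file(self, path) -> None:
        cp = configparser.ConfigParser()
        cp.optionxform = str        # field names are case-sensitive
        cp["geometry"] = {k: repr(v) for k, v in asdict(self.geometry).items()}
        cp["material"] = {k: repr(v) for k, v in asdict(self.material).items()}
        pin = asdict(self.pinning)
        if pin["coordinates"] is not None:
            pin["coordinates"] = ";".join(f"{x},{y}" for x, y in pin["coordinates"])
        if pin["region"] is not None:
            pin["region"] = ",".join(str(v) for v in pin["region"])
        cp["pinning"] = {k: repr(v) if not isinstance(v, str) else v
                         for k, v in pin.items()}
        cp["integrator"] = {k: repr(v) for k, v in asdict(self.integrator).items()}
        cp["run"] = {
            "loading_rate": repr(self.loading_rate),
            "loading_ramp": repr(self.loading_ramp),
            "target_expansion": repr(self.target_expansion),
            "max_time": repr(self.max_time),
            "snapshot_interval": repr(self.snapshot_interval),
            "master_seed": repr(self.master_seed),
        }
        with open(path, "w") as fh:
            cp.write(fh)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        cp = configparser.ConfigParser()
        cp.optionxform = str
        with open(path) as fh:
            cp.read_file(fh)

        def section(name, factory):
            kwargs = {}
            for k, v in cp[name].items():
                kwargs[k] = None if v == "None" else eval(v, {"__builtins__": {}})
            return factory(**kwargs)

        pin_kwargs = dict(cp["pinning"])
        coords = pin_kwargs.pop("coordinates", "None")
        region = pin_kwargs.pop("region", "None")
        pinning = PinningConfig(
            n=int(pin_kwargs.get("n", 0)),
            seed=None if pin_kwargs.get("seed", "None") == "None"
            else int(pin_kwargs["seed"]),
            region=None if region == "None"
            else tuple(float(v) for v in region.strip("'\"").split(",")),
            coordinates=None if coords == "None"
            else [tuple(float(v) for v in pt.split(","))
                  for pt in coords.strip("'\"").split(";")],
        )
        run = cp["run"]
        return cls(
            geometry=section("geometry", GeometryConfig),
            material=section("material", MaterialModel),
            pinning=pinning,
            integrator=section("integrator", IntegratorSettings),
            loading_rate=float(run["loading_rate"]),
            loading_ramp=float(run.get("loading_ramp", "0.0")),
            target_expansion=float(run["target_expansion"]),
            max_time=None if run["max_time"] == "None" else float(run["max_time"]),
            snapshot_interval=float(run["snapshot_interval"]),
            master_seed=int(run["master_seed"]),
        )


@dataclass
class Snapshot:
    time: float
    positions: np.ndarray
    velocities: np.ndarray
    damage: np.ndarray
    expansion: float            # D/D0
    broken_bonds_total: int


@dataclass
class Trajectory:
    """Ordered snapshots plus the per-run bookkeeping the analysis needs."""

    config: RunConfig
    membrane: Membrane
    network: BondNetwork
    pins: PinningSet
    snapshots: list[Snapshot] = field(default_factory=list)
    first_damage_crossing: np.ndarray | None = None  # time each particle first
    #   exceeded damage 0.5; inf if never
    status: str = "completed"
    accepted_steps: int = 0
    rejected_steps: int = 0
    dt_history: list[tuple[float, float]] = field(default_factory=list)
    settings_used: IntegratorSettings | None = None

    @property
    def final(self) -> Snapshot:
        return self.snapshots[-1]

    def snapshot_at(self, expansion: float) -> Snapshot:
        """Snapshot whose D/D₀ is closest to ``expansion``."""
        return min(self.snapshots, key=lambda s: abs(s.expansion - expansion))


def expansion_ratio(positions: np.ndarray, diameter_0: float) -> float:
    """D/D₀ = 2·max_i ‖y_i‖ / D₀ — the expansion progress coordinate."""
    return 2.0 * float(np.max(np.linalg.norm(positions, axis=1))) / diameter_0


def rim_expansion_ratio(config: RunConfig, t: float) -> float:
    """D/D₀ from the exact rim kinematics at time ``t``.

    The driven rim moves by construction, so this ratio is monotone in time
    and immune to stray recoiling debris that would distort the max-radius
    measure late in a rupture run.
    """
    from .integrator import rim_kinematics
    disp, _ = rim_kinematics(config.loading_rate, t, config.loading_ramp)
    radius = config.geometry.diameter / 2.0
    return (radius + max(disp, 0.0)) / radius


def resolve_integrator_settings(config: RunConfig) -> IntegratorSettings:
    """Concrete integrator settings for a run.

    A ``dt_max`` of None becomes the wave-resolution cap ``0.5·h/c`` with
    ``c = sqrt((K + 2G)/ρ_scaled)`` the fastest elastic wave speed;
    ``dt_initial`` is clipped under the cap.
    """
    s = config.integrator
    if s.dt_max is not None:
        return s
    mat = config.material
    c = np.sqrt((mat.bulk_K + 2.0 * mat.shear_G) / mat.scaled_density)
    dt_cap = 0.5 * config.geometry.spacing_h / c
    return IntegratorSettings(
        max_fp_iterations=s.max_fp_iterations, fp_tolerance=s.fp_tolerance,
        dt_initial=min(s.dt_initial, dt_cap), dt_min=s.dt_min, dt_max=dt_cap,
        dt_grow=s.dt_grow, dt_shrink=s.dt_shrink,
        easy_iterations=s.easy_iterations)


def build_from_config(config: RunConfig):
    """Construct (membrane, network, pins) for a RunConfig."""
    g = config.geometry
    membrane = build_circular_membrane(g.diameter, g.spacing_h, g.thickness,
                                       g.layer_width)
    network = build_bond_network(membrane, g.horizon_delta)
    p = config.pinning
    seed = p.seed if p.seed is not None else config.master_seed
    coords = (np.asarray(p.coordinates, dtype=float)
              if p.coordinates is not None else None)
    pins = assign_pinning(membrane, p.n, seed=seed, region=p.region,
                          coordinates=coords)
    return membrane, network, pins


def run_simulation(config: RunConfig,
                   damage_crossing_level: float = 0.5) -> Trajectory:
    """Run the time loop to the target expansion ratio.

    All randomness (pin placement) is tied to the configured seeds, so an
    identical config reproduces an identical trajectory.  Time-step
    underflow or non-finite positions abort the run with the last good
    snapshot flushed (``trajectory.status`` records the reason).
    """
    membrane, network, pins = build_from_config(config)
    material = config.material
    settings = resolve_integrator_settings(config)
    evaluator = ForceEvaluator(membrane, network, material)
    projector = _ConstraintProjector(membrane, config.loading_rate,
                                     config.loading_ramp)

    state = SimulationState.initial(membrane, settings.dt_initial)
    projector.project(state.positions, state.velocities, 0.0)
    state.accelerations = evaluator.accel(state.positions).copy()

    n = membrane.n_particles
    broken_count = np.zeros(n, dtype=np.int64)
    first_cross = np.full(n, np.inf)
    total_broken = 0

    traj = Trajectory(config=config, membrane=membrane, network=network,
                      pins=pins, first_damage_crossing=first_cross)

    def take_snapshot(st: SimulationState):
        dmg = damage_field(network, broken_count).phi
        traj.snapshots.append(Snapshot(
            time=st.time, positions=st.positions.copy(),
            velocities=st.velocities.copy(), damage=dmg,
            expansion=rim_expansion_ratio(config, st.time),
            broken_bonds_total=total_broken))

    take_snapshot(state)
    next_snap = config.snapshot_interval
    init_counts = network.initial_bond_count.astype(float)
    init_counts[init_counts == 0] = 1.0

    while True:
        ratio = rim_expansion_ratio(config, state.time)
        if ratio >= config.target_expansion:
            break
        if config.max_time is not None and state.time >= config.max_time:
            break

        try:
            new_state, converged, iters = trapezoidal_step(
                state, evaluator.accel, settings, membrane,
                rate=config.loading_rate, projector=projector)
            new_dt = adapt_dt(settings, converged, iters, state.dt)
        except TimestepUnderflowError as exc:
            logger.error("aborting: %s", exc)
            traj.status = f"aborted: {exc}"
            break

        if not converged:
            state.dt = new_dt
            traj.rejected_steps += 1
            continue

        if not np.all(np.isfinite(new_state.positions)):
            logger.error("aborting: non-finite positions at t=%g", new_state.time)
            traj.status = "aborted: non-finite positions"
            break

        state = new_state
        state.dt = new_dt
        traj.accepted_steps += 1

        newly = update_broken_bonds(state.positions, network, material,
                                    broken_count)
        if newly:
            total_broken += newly
            crossed = ((broken_count / init_counts >= damage_crossing_level)
                       & np.isinf(first_cross))
            first_cross[crossed] = state.time

        traj.dt_history.append((state.time, state.dt))
        if state.time >= next_snap:
            take_snapshot(state)
            next_snap += config.snapshot_interval

    if not traj.snapshots or traj.snapshots[-1].time < state.time:
        take_snapshot(state)
    traj.settings_used = settings
    logger.info("run finished: %s after %d accepted steps (t=%.4g s, D/D0=%.3f)",
                traj.status, traj.accepted_steps, state.time,
                traj.final.expansion)
    return traj


@dataclass
class FirstRupture:
    """Where rupture first localized in the bulk interior."""

    onset_time: float
    particle_ids: np.ndarray
    distances_to_pins: np.ndarray   # μm, per onset particle


def first_rupture_sites(trajectory: Trajectory, window: float = 0.0,
                        rim_margin_mult: float = 2.0) -> FirstRupture | None:
    """Particles whose damage first crossed 0.5, at the onset of rupture.

    The statistic covers the *bulk interior*: particles more than
    ``rim_margin_mult`` horizons (default two, matching the margin the
    fixture generator keeps between pins and the driven layer) inside the
    driven layer.  The driven layer is the loading apparatus, and the
    detachment band that forms against it — observed to extend roughly 1.5
    horizons inward — is the same "circular rim" artifact that is removed
    from the rupture masks, so neither belongs in the nucleation statistic.  ``window`` (s)
    optionally widens the onset from the single first accepted step.
    Returns None when nothing in the bulk ruptured.
    """
    mb = trajectory.membrane
    cut = (mb.diameter_0 / 2.0 - mb.layer_width
           - rim_margin_mult * trajectory.network.horizon_delta)
    radii = np.linalg.norm(mb.positions_ref, axis=1)
    fc = trajectory.first_damage_crossing
    bulk = np.nonzero(radii <= cut)[0]
    crossed = bulk[np.isfinite(fc[bulk])]
    if crossed.size == 0:
        return None
    t_on = float(fc[crossed].min())
    onset = crossed[fc[crossed] <= t_on + window]
    pins = trajectory.pins.coordinates
    if pins.shape[0]:
        d = np.min(np.linalg.norm(
            mb.positions_ref[onset][:, None, :] - pins[None, :, :], axis=2),
            axis=1)
    else:
        d = np.full(onset.shape[0], np.inf)
    return FirstRupture(onset_time=t_on, particle_ids=onset,
                        distances_to_pins=d)
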