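"""Seeded synthetic-data generators with attached ground truth.

Every generator draws from an independent, splittable random stream
derived from one global seed, so adding a generator never shifts another
generator's draws and the same (seed, parameters) pair reproduces its
output exactly.

The generators emulate the statistical structure of opto-HPF inner-hair-
cell experiments: per-shot mechanical delays of 25–42 ms, light-evoked
EPSC transients of −100 to −700 pA at 10–25 ms latency on noisy
baselines, and ribbon-synapse annotation models with ~10–15 membrane-
proximal vesicles of ~49 nm diameter at 0–50 nm membrane distance with
docked/tethered/non-tethered sub-structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .ephys import EphysTrace, LightPulse
from .errors import InvalidKinetics, PlacementError
from .geometry import Surface, segment_intersects_sphere
from .hpf_timing import SensorShot, TimingConstants, specimen_freeze_offset
from .tomo_quant import SynapseModel, Vesicle

__all__ = [
    "gen_sensor_shot",
    "gen_epsc_trace",
    "gen_synapse_model",
    "gen_group_data",
    "double_exp_waveform",
    "double_exp_charge",
    "double_exp_peak",
    "band_reentry_time",
]

# stream tags so each generator owns an independent substream of the seed
_STREAM = {"shot": 11, "epsc": 23, "synapse": 37, "groups": 53}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAM[stream]]))


# ---------------------------------------------------------------------------
# Freezing-shot sensor traces
# ---------------------------------------------------------------------------

def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3 - 2 * x)


def gen_sensor_shot(
    seed: int,
    T_mechanics_ms: float,
    noise_rel: float = 0.0,
    sampling_khz: float = 10.0,
    stim_start_ms: float = 390.0,
    constants: TimingConstants = TimingConstants(),
    dip_depth_bar: float = 0.3,
    dip_halfwidth_ms: float = 1.5,
    plateau_bar: float = 5.0,
    peak_bar: float = 7.0,
    shot_id: str | None = None,
) -> tuple[SensorShot, dict]:
    """Synthesize one freezing shot's sensor traces.

    The pneumatic trace rises to a plateau while the LN2 pressurizes,
    shows the valve-opening dip at ``T_N2_pressurized + T_mechanics``,
    builds up steadily and drops suddenly; the internal chamber pressure
    rises sigmoidally to 2100 bar from the valve opening and the chamber
    temperature declines through 0 °C at ``T_chamber_at_0`` after the
    build-up starts.  Additive Gaussian noise has SD = ``noise_rel`` ×
    the noiseless pneumatic signal range.

    Returns ``(shot, truth)`` where ``truth`` carries the planted dip
    time, T_mechanics, T_HPM_delay and stimulation duration.
    """
    if T_mechanics_ms <= 0:
        raise ValueError("T_mechanics_ms must be > 0")
    rng = _rng(seed, "shot")
    dt = 1.0 / sampling_khz
    t_dip = constants.T_N2_pressurized + T_mechanics_ms
    t_rise_end = t_dip + dip_halfwidth_ms
    t_drop = t_dip + 60.0
    t_end = t_drop + 25.0
    t = np.arange(0.0, t_end, dt)

    p = plateau_bar * _smoothstep(t / 380.0)
    in_dip = np.abs(t - t_dip) <= dip_halfwidth_ms
    p[in_dip] -= dip_depth_bar * np.cos(
        math.pi * (t[in_dip] - t_dip) / (2 * dip_halfwidth_ms)
    ) ** 2
    in_rise = (t > t_rise_end) & (t <= t_drop)
    frac = (t[in_rise] - t_rise_end) / (t_drop - t_rise_end)
    p[in_rise] = plateau_bar + (peak_bar - plateau_bar) * (1 - np.cos(math.pi * frac)) / 2
    in_drop = t > t_drop
    p[in_drop] = np.maximum(0.5, peak_bar - (peak_bar - 0.5) * (t[in_drop] - t_drop) / 4.0)

    rng_range = p.max() - p.min()
    if noise_rel > 0:
        p = p + rng.normal(0.0, noise_rel * rng_range, size=p.size)

    # internal channels on the relative clock (0 = pressure build-up start)
    t_rel = np.arange(0.0, 40.0, dt)
    pressure = 2100.0 / (1.0 + np.exp(-(t_rel - 4.0) / 1.2))
    temp = 20.0 - (20.0 / constants.T_chamber_at_0) * t_rel
    temp = np.maximum(temp, -196.0)
    if noise_rel > 0:
        pressure = pressure + rng.normal(0.0, noise_rel * 2100.0, size=t_rel.size)
        temp = temp + rng.normal(0.0, noise_rel * 216.0, size=t_rel.size)

    shot = SensorShot(
        shot_id=shot_id or f"shot-{seed}",
        pneumatic=np.column_stack([t, p]),
        internal_pressure=np.column_stack([t_rel, pressure]),
        internal_temperature=np.column_stack([t_rel, temp]),
        stim_start_ms=stim_start_ms,
    )
    T_delay = constants.T_N2_pressurized + T_mechanics_ms + specimen_freeze_offset(constants)
    truth = {
        "t_dip_ms": t_dip,
        "T_mechanics_ms": T_mechanics_ms,
        "T_HPM_delay_ms": T_delay,
        "stim_start_ms": stim_start_ms,
        "stim_duration_ms": max(0.0, T_delay - stim_start_ms),
        "noise_sd_bar": noise_rel * rng_range,
        "dip_depth_bar": dip_depth_bar,
    }
    return shot, truth


# ---------------------------------------------------------------------------
# EPSC traces
# ---------------------------------------------------------------------------

def double_exp_waveform(
    s: np.ndarray, A: float, tau_rise: float, tau_decay: float
) -> np.ndarray:
    """A·(exp(−s/τd) − exp(−s/τr)) for s ≥ 0 (0 before)."""
    s = np.asarray(s, dtype=float)
    out = np.zeros_like(s)
    pos = s >= 0
    out[pos] = A * (np.exp(-s[pos] / tau_decay) - np.exp(-s[pos] / tau_rise))
    return out


def double_exp_charge(
    A: float, tau_rise: float, tau_decay: float, t_end: float | None = None
) -> float:
    """Closed-form ∫ waveform ds (pA·ms) from 0 to ``t_end`` (∞ default)."""
    if t_end is None:
        return A * (tau_decay - tau_rise)
    return A * (
        tau_decay * (1 - math.exp(-t_end / tau_decay))
        - tau_rise * (1 - math.exp(-t_end / tau_rise))
    )


def double_exp_peak(A: float, tau_rise: float, tau_decay: float) -> tuple[float, float]:
    """(time of peak, peak value) of the double exponential."""
    t_pk = (tau_rise * tau_decay / (tau_decay - tau_rise)) * math.log(tau_decay / tau_rise)
    v_pk = A * (math.exp(-t_pk / tau_decay) - math.exp(-t_pk / tau_rise))
    return t_pk, v_pk


def band_reentry_time(
    A: float, tau_rise: float, tau_decay: float, level: float
) -> float | None:
    """Time after event start at which the clean |waveform| decays back
    to ``level`` (None if the peak never exceeds it)."""
    t_pk, v_pk = double_exp_peak(A, tau_rise, tau_decay)
    if abs(v_pk) <= level or level <= 0:
        return None
    f = lambda s: abs(double_exp_waveform(np.array([s]), A, tau_rise, tau_decay)[0]) - level
    hi = t_pk + tau_decay * max(10.0, math.log(abs(A) / level) + 10.0)
    return float(brentq(f, t_pk, hi))


def gen_epsc_trace(
    seed: int,
    events: list[tuple[float, float, float, float]],
    noise_sd_pA: float,
    light: LightPulse,
    duration_ms: float = 200.0,
    sampling_khz: float = 50.0,
    baseline_pA: float = 0.0,
    cell_type: str = "bouton",
) -> tuple[EphysTrace, dict]:
    """Synthesize a light-evoked EPSC sweep.

    ``events`` is a list of ``(latency_ms, amplitude_pA, tau_rise_ms,
    tau_decay_ms)``; each contributes a double-exponential transient
    starting at ``light.onset + latency`` on a Gaussian baseline.  Truth
    records the analytic per-event charge A·(τd − τr) plus peak times
    and values.
    """
    rng = _rng(seed, "epsc")
    t = np.arange(0.0, duration_ms, 1.0 / sampling_khz)
    v = np.full(t.size, baseline_pA)
    truth_events = []
    for latency, A, tau_r, tau_d in events:
        if latency < 0:
            raise ValueError("event latency must be >= 0")
        if tau_d <= tau_r:
            raise InvalidKinetics(f"tau_decay ({tau_d}) must exceed tau_rise ({tau_r})")
        start = light.onset_ms + latency
        v = v + double_exp_waveform(t - start, A, tau_r, tau_d)
        t_pk, v_pk = double_exp_peak(A, tau_r, tau_d)
        truth_events.append(
            {
                "latency_ms": latency,
                "amplitude_pA": A,
                "tau_rise_ms": tau_r,
                "tau_decay_ms": tau_d,
                "charge_pAms": double_exp_charge(A, tau_r, tau_d),
                "peak_time_ms": start + t_pk,
                "peak_pA": v_pk,
            }
        )
    if noise_sd_pA > 0:
        v = v + rng.normal(0.0, noise_sd_pA, size=t.size)
    trace = EphysTrace(
        time_ms=t,
        values=v,
        mode="voltage_clamp",
        cell_type=cell_type,
        trace_id=f"epsc-{seed}",
    )
    truth = {
        "events": truth_events,
        "noise_sd_pA": noise_sd_pA,
        "baseline_pA": baseline_pA,
        "light_onset_ms": light.onset_ms,
    }
    return trace, truth


# ---------------------------------------------------------------------------
# Synapse annotation models
# ---------------------------------------------------------------------------

def _plane_mesh(half_extent: float = 300.0, step: float = 60.0) -> Surface:
    xs = np.arange(-half_extent, half_extent + step / 2, step)
    ys = np.arange(-half_extent, half_extent + step / 2, step)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    verts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(xx.size)])
    n = xs.size
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            faces.append([a, a + 1, a + n])
            faces.append([a + 1, a + n + 1, a + n])
    return Surface(verts, np.array(faces))


def _ellipsoid_mesh(
    center: np.ndarray, radii: np.ndarray, n_theta: int = 24, n_phi: int = 12
) -> Surface:
    theta = np.linspace(0, 2 * math.pi, n_theta, endpoint=False)
    phi = np.linspace(0, math.pi, n_phi + 1)[1:-1]
    verts = [center + radii * np.array([0.0, 0.0, 1.0])]
    for ph in phi:
        for th in theta:
            verts.append(
                center
                + radii
                * np.array(
                    [math.sin(ph) * math.cos(th), math.sin(ph) * math.sin(th), math.cos(ph)]
                )
            )
    verts.append(center + radii * np.array([0.0, 0.0, -1.0]))
    verts = np.array(verts)
    faces = []
    # top cap
    for j in range(n_theta):
        faces.append([0, 1 + j, 1 + (j + 1) % n_theta])
    # bands
    for i in range(len(phi) - 1):
        row0 = 1 + i * n_theta
        row1 = 1 + (i + 1) * n_theta
        for j in range(n_theta):
            jn = (j + 1) % n_theta
            faces.append([row0 + j, row1 + j, row0 + jn])
            faces.append([row0 + jn, row1 + j, row1 + jn])
    # bottom cap
    last = verts.shape[0] - 1
    row = 1 + (len(phi) - 1) * n_theta
    for j in range(n_theta):
        faces.append([last, row + (j + 1) % n_theta, row + j])
    return Surface(verts, np.array(faces))


def _pd_points(
    half_x: float = 60.0, half_y: float = 20.0, height: float = 30.0
) -> Surface:
    xs = np.arange(-half_x, half_x + 1, 6.0)
    ys = np.arange(-half_y, half_y + 1, 5.0)
    zs = np.arange(0.0, height + 1, 6.0)
    pts = np.array([[x, y, z] for x in xs for y in ys for z in zs])
    return Surface(pts, None)


def _pd_lateral_2d(xy: np.ndarray, pd_xy: np.ndarray) -> float:
    return float(np.min(np.linalg.norm(pd_xy - xy, axis=1)))


@dataclass
class _Placed:
    vesicle: Vesicle
    segment: tuple[np.ndarray, np.ndarray] | None  # first-row sight line


def _clear_of_segments(v: Vesicle, placed: list[_Placed]) -> bool:
    for p in placed:
        if p.segment is None:
            continue
        if segment_intersects_sphere(p.segment[0], p.segment[1], v.center_nm, v.radius_nm):
            return False
    return True


def gen_synapse_model(
    seed: int,
    n_mp: int = 12,
    docked_fraction: float = 0.01,
    tethered_fraction: float = 0.75,
    n_ra: int = 10,
    diameter_mean_nm: float = 49.0,
    diameter_sd_nm: float = 3.0,
    distance_profile: str = "uniform",
    n_docked: int | None = None,
    n_random: int = 0,
    n_cc: int = 0,
    condition: str = "custom",
    model_id: str | None = None,
    max_retries: int = 10_000,
) -> tuple[SynapseModel, dict]:
    """Synthesize one ribbon-synapse annotation model with planted truth.

    A planar AZ mesh carries a PD patch and an ellipsoidal ribbon above
    it.  MP vesicles are placed at membrane distances drawn from the
    sub-pool's interval (docked [0, 2] nm, others (2, 50] nm; the
    ``table2`` profile uses a truncated normal with ~21 nm mean) within
    100 nm lateral PD distance; RA vesicles at ribbon distances within
    (0, 80] nm on the upper ribbon hemisphere.  Diameters are
    Normal(mean, sd) truncated > 0.  Placement is rejection sampling
    with overlap and line-of-sight (first-row) verification; exceeding
    ``max_retries`` raises :class:`PlacementError`.

    ``n_docked`` overrides the binomial docked draw with an exact count.
    ``n_random`` adds unconstrained scatter vesicles (truth pool None)
    that are kept clear of the planted sight lines.  Truth maps
    vesicle id → (pool, subpool).
    """
    if not 0 <= docked_fraction <= 1 or not 0 <= tethered_fraction <= 1:
        raise ValueError("fractions must lie in [0, 1]")
    if docked_fraction + tethered_fraction > 1 + 1e-12:
        raise ValueError("docked_fraction + tethered_fraction must be <= 1")
    rng = _rng(seed, "synapse")

    membrane = _plane_mesh()
    pd_surface = _pd_points()
    pd_xy = pd_surface.vertices[:, :2]
    ribbon_center = np.array([0.0, 0.0, 160.0])
    ribbon_radii = np.array([60.0, 45.0, 85.0])
    ribbon = _ellipsoid_mesh(ribbon_center, ribbon_radii)

    placed: list[_Placed] = []
    truth: dict[str, dict] = {}
    retries = 0

    def draw_radius() -> float:
        for _ in range(100):
            d = rng.normal(diameter_mean_nm, diameter_sd_nm)
            if d > 2.0:
                return d / 2.0
        raise PlacementError("could not draw a positive diameter")

    def try_place(candidate: Vesicle, segment) -> bool:
        nonlocal retries
        for p in placed:
            gap = np.linalg.norm(p.vesicle.center_nm - candidate.center_nm)
            if gap <= p.vesicle.radius_nm + candidate.radius_nm + 0.5:
                return False
        if segment is not None:
            for p in placed:
                if segment_intersects_sphere(
                    segment[0], segment[1], p.vesicle.center_nm, p.vesicle.radius_nm
                ):
                    return False
        if not _clear_of_segments(candidate, placed):
            return False
        placed.append(_Placed(candidate, segment))
        return True

    # --- sub-pool labels for MP vesicles ---
    if n_docked is None:
        n_docked_eff = int(rng.binomial(n_mp, docked_fraction)) if n_mp else 0
    else:
        n_docked_eff = int(n_docked)
    if n_docked_eff > n_mp:
        raise ValueError("n_docked cannot exceed n_mp")
    rest = n_mp - n_docked_eff
    p_teth = (
        tethered_fraction / (1 - docked_fraction) if docked_fraction < 1 else 0.0
    )
    p_teth = min(1.0, p_teth)
    sub_labels = ["docked"] * n_docked_eff + [
        "tethered" if rng.random() < p_teth else "non_tethered" for _ in range(rest)
    ]
    rng.shuffle(sub_labels)

    def mp_distance(sub: str) -> float:
        if sub == "docked":
            return float(rng.uniform(0.05, 1.95))
        if distance_profile == "table2":
            while True:
                d = rng.normal(21.0, 12.0)
                if 2.1 < d < 49.9:
                    return float(d)
        return float(rng.uniform(2.1, 49.9))

    # --- place MP vesicles ---
    for i, sub in enumerate(sub_labels):
        ok = False
        while not ok:
            if retries > max_retries:
                raise PlacementError("MP placement exceeded retry cap")
            retries += 1
            r = draw_radius()
            d = mp_distance(sub)
            xy = rng.uniform(-170.0, 170.0, size=2)
            lat = _pd_lateral_2d(xy, pd_xy) - r
            if lat > 95.0:
                continue
            center = np.array([xy[0], xy[1], r + d])
            # keep sight lines vertical and mutually clear
            horizontal_ok = all(
                np.linalg.norm(p.vesicle.center_nm[:2] - xy)
                > p.vesicle.radius_nm + r + 1.0
                for p in placed
            )
            if not horizontal_ok:
                continue
            if sub == "docked":
                tethers = ["membrane"] if rng.random() < 0.5 else []
            elif sub == "tethered":
                cat = rng.choice(
                    ["m", "pd", "v", "multi"], p=[0.45, 0.2, 0.1, 0.25]
                )
                tethers = {
                    "m": ["membrane"],
                    "pd": ["pd"],
                    "v": ["vesicle"],
                    "multi": ["membrane", "pd"],
                }[cat]
            else:
                tethers = []
            v = Vesicle(id=f"mp{i}", center_nm=center, radius_nm=r, tethers=tethers)
            segment = (np.array([xy[0], xy[1], d]), np.array([xy[0], xy[1], 0.0]))
            ok = try_place(v, segment)
        truth[v.id] = {"pool": "MP", "mp_subpool": sub}

    # --- place RA vesicles on the upper ribbon hemisphere ---
    ra_subpools = ["no_filaments", "ribbon_attached", "interconnected", "attached_and_interconnected"]
    ra_probs = [0.25, 0.45, 0.2, 0.1]
    ra_tethers = {
        "no_filaments": [],
        "ribbon_attached": ["ribbon"],
        "interconnected": ["vesicle"],
        "attached_and_interconnected": ["ribbon", "vesicle"],
    }
    for i in range(n_ra):
        sub = str(rng.choice(ra_subpools, p=ra_probs))
        ok = False
        while not ok:
            if retries > max_retries:
                raise PlacementError("RA placement exceeded retry cap")
            retries += 1
            r = draw_radius()
            u = rng.normal(size=3)
            u[2] = abs(u[2]) + 0.3  # upper hemisphere, away from the membrane
            u = u / np.linalg.norm(u)
            gap = float(rng.uniform(1.0, 75.0))
            # point on the ellipsoid along u (support in direction u)
            scale = 1.0 / math.sqrt(float(np.sum((u / ribbon_radii) ** 2)))
            surf_pt = ribbon_center + u * scale
            center = surf_pt + u * (gap + r)
            if center[2] - r < 60.0:  # never encroach on the MP band
                continue
            v = Vesicle(id=f"ra{i}", center_nm=center, radius_nm=r, tethers=ra_tethers[sub])
            closest, dist = ribbon.closest_points(center[None, :])
            d_rib = float(dist[0]) - r
            if not 0.5 < d_rib < 78.0:
                continue
            seg_start = center + (closest[0] - center) * (r / float(dist[0]))
            ok = try_place(v, (seg_start, closest[0]))
        truth[v.id] = {"pool": "RA", "ra_subpool": sub}

    # --- unconstrained scatter vesicles (classification stress) ---
    for i in range(n_random):
        ok = False
        while not ok:
            if retries > max_retries:
                raise PlacementError("scatter placement exceeded retry cap")
            retries += 1
            r = draw_radius()
            center = np.array(
                [
                    rng.uniform(-280.0, 280.0),
                    rng.uniform(-280.0, 280.0),
                    rng.uniform(r + 0.5, 320.0),
                ]
            )
            tethers = ["vesicle"] if rng.random() < 0.3 else []
            v = Vesicle(id=f"x{i}", center_nm=center, radius_nm=r, tethers=tethers)
            ok = try_place(v, None)
        truth[v.id] = {"pool": None}

    # --- clathrin-coated structures, far from the pools ---
    for i in range(n_cc):
        ok = False
        while not ok:
            if retries > max_retries:
                raise PlacementError("CC placement exceeded retry cap")
            retries += 1
            diam = rng.uniform(63.0, 120.0)
            r = diam / 2.0
            center = np.array(
                [
                    rng.uniform(-280.0, 280.0),
                    rng.uniform(-280.0, 280.0),
                    rng.uniform(r + 8.0, r + 78.0),
                ]
            )
            v = Vesicle(
                id=f"cc{i}", center_nm=center, radius_nm=r, clathrin_coated=True
            )
            ok = try_place(v, None)
        truth[v.id] = {"pool": "CC"}

    model = SynapseModel(
        model_id=model_id or f"synapse-{seed}",
        az_membrane=membrane,
        pd=pd_surface,
        ribbon=ribbon,
        vesicles=[p.vesicle for p in placed],
        condition=condition,
    )
    return model, {
        "labels": truth,
        "n_mp": n_mp,
        "n_docked": n_docked_eff,
        "n_ra": n_ra,
        "docked_fraction": docked_fraction,
    }


# ---------------------------------------------------------------------------
# Group data
# ---------------------------------------------------------------------------

def gen_group_data(
    seed: int,
    group_means,
    group_sds=None,
    n_per_group: int = 12,
    design: str = "one_way",
    distribution: str = "normal",
    labels=None,
    outcome: str = "outcome",
):
    """Synthesize grouped samples for the comparison gate.

    ``distribution`` is ``normal`` (parametric by construction) or
    ``cauchy`` (heavy-tailed, non-parametric by construction; the
    ``group_sds`` act as scale parameters).  Truth records the branch a
    correct gate should take.
    """
    from .group_stats import GroupData

    rng = _rng(seed, "groups")
    means = list(group_means)
    if group_sds is None:
        group_sds = [1.0] * len(means)
    sds = list(group_sds)
    if labels is None:
        labels = [f"G{i + 1}" for i in range(len(means))]
    groups = []
    for label, mu, sd in zip(labels, means, sds):
        if distribution == "normal":
            vals = rng.normal(mu, sd, size=n_per_group)
        elif distribution == "cauchy":
            vals = mu + sd * rng.standard_cauchy(size=n_per_group)
        else:
            raise ValueError(f"unknown distribution {distribution!r}")
        groups.append((label, vals))
    data = GroupData(outcome=outcome, groups=groups, design=design)
    truth = {
        "branch": "parametric" if distribution == "normal" else "nonparametric",
        "means": means,
        "sds": sds,
        "distribution": distribution,
    }
    return data, truth
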