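"""Synthetic myotome data generator.

Produces ground-truthed inputs with the statistical structure the analysis
pipeline assumes: a stochastic fiber-population time series (hyperplasia,
nuclear-domain hypertrophy, growth-rate-modulated elimination with in-situ
replacement), multichannel cross-section renders of myotomes, and qPCR Ct
tables whose recombined-cassette signal decays with fiber elimination and is
diluted by whole-animal growth.

The population model: each myotome holds a set of fast myofibers. Between
observation times, per-fiber per-day elimination follows a Bernoulli hazard
that depends on the rearing condition (fast growth drives near-complete
larval-cohort turnover, slow growth roughly half). Every elimination draws a
replacement count from a categorical distribution over {0,1,2,3,4,>=5}, and
newborn fibers are seeded inside the dead fiber's footprint. Surviving fibers
accrete nuclei and grow in volume along the nuclear-domain law V = s*N, with
multiplicative Gaussian noise of a configurable coefficient of variation;
volume growth stops after a configurable cap day.

Randomness: a single root seed is split via ``numpy.random.SeedSequence``
into named child streams, consumed in a fixed order: population dynamics,
color assignment, rendering, qPCR. Identical (config, seed) inputs produce
bit-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "SceneSpec",
    "GroundTruth",
    "FiberState",
    "NUCLEAR_DOMAIN_SLOPES",
    "REPLACEMENT_DIST",
    "MEDIAL_EDGE_BIAS",
    "simulate_population",
    "assign_brainbow_colors",
    "render_myotome_image",
    "simulate_qpcr",
    "elimination_hazard_for_condition",
]

# Nuclear-domain slopes s (µm³ per nucleus) by rearing condition and age.
# Fast-grown fish maintain roughly twice the cytoplasmic volume per nucleus
# of slow-grown siblings at matched ages.
NUCLEAR_DOMAIN_SLOPES: dict[tuple[str, int], float] = {
    ("FG", 10): 1.9e3,
    ("SG", 10): 1.0e3,
    ("FG", 14): 3.2e3,
    ("SG", 14): 1.5e3,
}

# Replacement-count distribution over {0, 1, 2, 3, 4, >=5} for dissolution
# events: 11% no birth, 29/21/18/13% for one-to-four births; the residual 8%
# mass is carried by the >=5 category (configurable).
REPLACEMENT_DIST: tuple[float, ...] = (0.11, 0.29, 0.21, 0.18, 0.13, 0.08)

# Probability that a dissolution event sits at the medial edge of its
# compartment (dorsal / ventral).
MEDIAL_EDGE_BIAS: dict[str, float] = {"dorsal": 0.53, "ventral": 0.68}

# Cohort elimination endpoints by 28 dpf used to calibrate the hazard:
# ~99% of larval fibers eliminated under fast growth, ~55% under slow growth.
_ELIMINATION_ENDPOINT = {"FG": 0.99, "SG": 0.55}
_ENDPOINT_WINDOW_DAYS = 14.0  # 14 dpf cohort -> 28 dpf endpoint


def elimination_hazard_for_condition(growth_condition: str,
                                     window_days: float = _ENDPOINT_WINDOW_DAYS) -> float:
    """Per-fiber per-day Bernoulli hazard calibrated to the cohort endpoint.

    Solves (1 - h)**window = 1 - endpoint for the condition's endpoint
    elimination fraction. This is the logistic-in-condition hazard reduced to
    its two calibration points.
    """
    p = _ELIMINATION_ENDPOINT[growth_condition]
    return 1.0 - (1.0 - p) ** (1.0 / window_days)


@dataclass
class SimulationConfig:
    """All generative parameters for the population simulator.

    Parameters
    ----------
    seed:
        Root seed; all child streams derive from it.
    n_myotomes:
        Myotomes per animal (zebrafish trunk has ~34).
    t_grid:
        Strictly increasing observation times, days post-fertilization.
    growth_condition:
        ``"SG"`` (slow growth, 1 fish/20 ml) or ``"FG"`` (fast growth,
        1 fish/200 ml). Selects hazard and nuclear-domain slope defaults.
    hyperplasia_rate:
        New fibers per myotome per day (growth-front additions, independent
        of replacement births).
    nuclear_domain_slope:
        Mapping (condition, dpf) -> µm³/nucleus. Missing ages use the
        nearest tabulated age for the condition.
    volume_noise_cv:
        Coefficient of variation of the multiplicative Gaussian volume noise.
    hypertrophy_cap_day:
        Day after which per-fiber volume and nucleus accretion stop.
    elimination_hazard:
        Per-fiber per-day death probability. ``None`` -> calibrated from
        growth_condition.
    replacement_dist:
        Probability vector over replacement counts {0,1,2,3,4,>=5}.
    medial_edge_bias:
        P(event at medial edge) per compartment.
    cassette_copies:
        Independent recombination cassette copies per tagged fiber.
    fluorophore_probs:
        Per-copy categorical probabilities of the three fluorophore outcomes.
    deformed_puncta_prob / normal_puncta_prob:
        P(autophagic puncta) in deformed vs normal fibers.
    labeling_fraction:
        Fraction of fibers color-tagged at induction.
    """

    seed: int = 0
    n_myotomes: int = 34
    t_grid: tuple[float, ...] = (6.0, 8.0, 10.0, 14.0)
    growth_condition: str = "FG"
    hyperplasia_rate: float = 4.5
    nuclear_domain_slope: Mapping[tuple[str, int], float] = field(
        default_factory=lambda: dict(NUCLEAR_DOMAIN_SLOPES))
    volume_noise_cv: float = 0.1
    hypertrophy_cap_day: float = math.inf
    elimination_hazard: float | None = None
    replacement_dist: tuple[float, ...] = REPLACEMENT_DIST
    medial_edge_bias: Mapping[str, float] = field(
        default_factory=lambda: dict(MEDIAL_EDGE_BIAS))
    cassette_copies: int = 10
    fluorophore_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    deformed_puncta_prob: float = 0.80
    normal_puncta_prob: float = 0.001
    labeling_fraction: float = 1.0
    initial_fibers_per_myotome: int = 57  # ~1942 fibers / 34 myotomes
    deformation_lead_steps: int = 1  # deformation precedes death by 1-2 steps

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.t_grid)
        if len(t) < 1 or any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("t_grid must be strictly increasing")
        self.t_grid = t
        rd = tuple(float(p) for p in self.replacement_dist)
        if abs(sum(rd) - 1.0) > 1e-12:
            raise ValueError("replacement_dist must sum to 1")
        if any(p < 0 or p > 1 for p in rd):
            raise ValueError("replacement_dist entries must be in [0,1]")
        self.replacement_dist = rd
        fp = tuple(float(p) for p in self.fluorophore_probs)
        if abs(sum(fp) - 1.0) > 1e-9 or any(p < 0 for p in fp):
            raise ValueError("fluorophore_probs must be nonnegative and sum to 1")
        self.fluorophore_probs = fp
        if self.growth_condition not in ("SG", "FG"):
            raise ValueError("growth_condition must be 'SG' or 'FG'")
        h = self.elimination_hazard
        if h is not None and not (0.0 <= h <= 1.0):
            raise ValueError("elimination_hazard must be in [0,1]")
        for name in ("deformed_puncta_prob", "normal_puncta_prob",
                     "labeling_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1]")
        if self.cassette_copies < 1:
            raise ValueError("cassette_copies must be >= 1")
        if self.volume_noise_cv < 0:
            raise ValueError("volume_noise_cv must be >= 0")

    @property
    def hazard(self) -> float:
        if self.elimination_hazard is not None:
            return self.elimination_hazard
        return elimination_hazard_for_condition(self.growth_condition)

    def slope_at(self, t: float) -> float:
        """Nuclear-domain slope for this condition at time t (nearest age)."""
        ages = sorted({a for (c, a) in self.nuclear_domain_slope
                       if c == self.growth_condition})
        if not ages:
            raise ValueError("no slope entries for condition "
                             f"{self.growth_condition!r}")
        age = min(ages, key=lambda a: (abs(a - t), a))
        return float(self.nuclear_domain_slope[(self.growth_condition, age)])

    def to_json(self) -> str:
        d = asdict(self)
        d["nuclear_domain_slope"] = {f"{c}:{a}": v for (c, a), v
                                     in self.nuclear_domain_slope.items()}
        return json.dumps(d, indent=2, default=float)


@dataclass
class FiberState:
    """Ground-truth state of one fiber across its lifetime."""

    fiber_id: int
    myotome_id: int
    compartment: str            # 'dorsal' | 'ventral'
    medial_edge: bool
    x: float                    # centroid, µm (myotome-local cross-section)
    y: float
    birth_time: float
    death_time: float | None = None
    tagged: bool = True
    color_fractions: tuple[float, float, float] | None = None
    nucleus_counts: dict[float, int] = field(default_factory=dict)
    volumes: dict[float, float] = field(default_factory=dict)
    deformed_at: list[float] = field(default_factory=list)
    puncta: bool = False


@dataclass
class GroundTruth:
    """Complete generative record of one simulated animal cohort."""

    fibers: dict[int, FiberState]
    events: list[dict]          # parent fiber id -> newborn fiber ids, time
    config: SimulationConfig

    def alive_at(self, t: float) -> list[FiberState]:
        return [f for f in self.fibers.values()
                if f.birth_time <= t and (f.death_time is None
                                          or f.death_time > t)]

    def bookkeeping_ok(self) -> bool:
        """Fibers alive at each time = born so far - died so far, exactly."""
        for t in self.config.t_grid:
            born = sum(1 for f in self.fibers.values() if f.birth_time <= t)
            died = sum(1 for f in self.fibers.values()
                       if f.death_time is not None and f.death_time <= t)
            if len(self.alive_at(t)) != born - died:
                return False
        return True


# ---------------------------------------------------------------------------
# Population dynamics
# ---------------------------------------------------------------------------

_MYOTOME_W = 120.0   # µm, cross-section extent used for centroid placement
_MYOTOME_H = 160.0


def _place_fiber(rng: np.random.Generator) -> tuple[float, float, str]:
    """Uniform centroid inside the myotome cross-section; y<H/2 is ventral."""
    x = float(rng.uniform(0.0, _MYOTOME_W))
    y = float(rng.uniform(0.0, _MYOTOME_H))
    return x, y, ("dorsal" if y >= _MYOTOME_H / 2 else "ventral")


def simulate_population(config: SimulationConfig
                        ) -> tuple[dict[float, pd.DataFrame], GroundTruth]:
    """Simulate the fiber population over ``config.t_grid``.

    Returns
    -------
    timeseries:
        time -> DataFrame of fibers alive at that time, columns
        ``fiber_id, myotome_id, compartment, medial_edge, x, y, volume,
        nucleus_count, c1, c2, c3, tagged, deformed, puncta, time``.
    ground_truth:
        Full per-fiber birth/death/trajectory record plus event links.
    """
    seq = np.random.SeedSequence(config.seed)
    kids = seq.spawn(4)  # fixed stream order: population, colors, render, qpcr
    rng = np.random.default_rng(kids[0])
    color_rng = np.random.default_rng(kids[1])

    fibers: dict[int, FiberState] = {}
    events: list[dict] = []
    next_id = 0
    t0 = config.t_grid[0]

    def new_fiber(t: float, myotome: int, near: FiberState | None = None
                  ) -> FiberState:
        nonlocal next_id
        if near is None:
            x, y, comp = _place_fiber(rng)
            medial = bool(rng.random() < 0.5)
        else:
            # newborn inside the parent's footprint, sharing its geometry
            r = math.sqrt(max(near.volumes.get(max(near.volumes, default=t),
                                               800.0), 1.0) / math.pi) / 10.0
            x = near.x + float(rng.uniform(-r, r))
            y = near.y + float(rng.uniform(-r, r))
            comp = near.compartment
            medial = near.medial_edge
        # color tagging happens at induction (first observation) only;
        # fibers born later carry the default, unlabeled state
        tagged = t == t0 and bool(rng.random() < config.labeling_fraction)
        f = FiberState(fiber_id=next_id, myotome_id=myotome, compartment=comp,
                       medial_edge=medial, x=x, y=y, birth_time=t,
                       tagged=tagged)
        f.nucleus_counts[t] = int(rng.integers(2, 8))
        next_id += 1
        fibers[f.fiber_id] = f
        return f

    # initial population at the first observation time
    for m in range(config.n_myotomes):
        for _ in range(config.initial_fibers_per_myotome):
            new_fiber(t0, m)

    hazard = config.hazard
    alive: set[int] = set(fibers)

    # nucleus accretion per day, same for all surviving fibers
    nuc_rate = 0.6

    for ti, t in enumerate(config.t_grid):
        if ti > 0:
            t_prev = config.t_grid[ti - 1]
            dt = t - t_prev
            p_die = 1.0 - (1.0 - hazard) ** dt
            died_now: list[FiberState] = []
            for fid in sorted(alive):
                f = fibers[fid]
                # elimination favors the medial edge: scale the per-fiber
                # probability so that P(medial | death) matches the
                # compartment bias in a half-medial population
                bias = config.medial_edge_bias[f.compartment]
                factor = 2.0 * bias if f.medial_edge else 2.0 * (1.0 - bias)
                # linear scaling keeps P(medial | death) = bias exactly in a
                # half-medial population; p_die = 1 means certain death
                p_i = 1.0 if p_die >= 1.0 else min(p_die * factor, 1.0)
                if rng.random() < p_i:
                    f.death_time = t
                    died_now.append(f)
            for f in died_now:
                alive.discard(f.fiber_id)
                # deformation precedes death by deformation_lead_steps frames
                lead = min(config.deformation_lead_steps, ti)
                f.deformed_at.extend(config.t_grid[ti - lead:ti])
                k = int(rng.choice(len(config.replacement_dist),
                                   p=config.replacement_dist))
                n_children = k if k < 5 else 5 + int(rng.poisson(0.5))
                children = [new_fiber(t, f.myotome_id, near=f)
                            for _ in range(n_children)]
                for c in children:
                    alive.add(c.fiber_id)
                events.append({"parent": f.fiber_id, "time": t,
                               "children": [c.fiber_id for c in children],
                               "compartment": f.compartment,
                               "medial_edge": f.medial_edge})
            # growth-front hyperplasia
            for m in range(config.n_myotomes):
                n_new = int(rng.poisson(config.hyperplasia_rate * dt))
                for _ in range(n_new):
                    alive.add(new_fiber(t, m).fiber_id)
            # nucleus accretion for survivors
            if t_prev < config.hypertrophy_cap_day:
                grow_until = min(t, config.hypertrophy_cap_day)
                dn_days = max(grow_until - t_prev, 0.0)
                for fid in sorted(alive):
                    f = fibers[fid]
                    if f.birth_time >= t:
                        continue
                    n_prev = f.nucleus_counts[max(f.nucleus_counts)]
                    f.nucleus_counts[t] = n_prev + int(
                        rng.poisson(nuc_rate * dn_days))
            else:
                for fid in sorted(alive):
                    f = fibers[fid]
                    if f.birth_time < t:
                        f.nucleus_counts[t] = f.nucleus_counts[
                            max(f.nucleus_counts)]

        # volumes from the nuclear-domain law, frozen after the cap day
        s = config.slope_at(min(t, config.hypertrophy_cap_day))
        for fid in sorted(alive):
            f = fibers[fid]
            n = f.nucleus_counts[max(k for k in f.nucleus_counts if k <= t)]
            noise = (1.0 + config.volume_noise_cv * rng.standard_normal()
                     if config.volume_noise_cv > 0 else 1.0)
            if t > config.hypertrophy_cap_day and f.volumes:
                f.volumes[t] = f.volumes[max(f.volumes)]
            else:
                f.volumes[t] = max(s * n * noise, 1.0)

        # puncta in deformed fibers (about to die) vs normal neighbours
        for fid in sorted(alive):
            f = fibers[fid]
            deformed = t in f.deformed_at
            p = (config.deformed_puncta_prob if deformed
                 else config.normal_puncta_prob)
            f.puncta = bool(rng.random() < p)

    # one Brainbow color per fiber, fixed for its lifetime
    assign_brainbow_colors(list(fibers.values()), config, rng=color_rng)

    gt = GroundTruth(fibers=fibers, events=events, config=config)
    timeseries = {t: population_frame(gt, t) for t in config.t_grid}
    return timeseries, gt


def population_frame(gt: GroundTruth, t: float) -> pd.DataFrame:
    """Tabulate the fibers alive at time t as one analysis-ready frame."""
    rows = []
    for f in sorted(gt.alive_at(t), key=lambda f: f.fiber_id):
        c = f.color_fractions or (0.0, 0.0, 0.0)
        nk = max(k for k in f.nucleus_counts if k <= t)
        vk = max(k for k in f.volumes if k <= t)
        rows.append({
            "fiber_id": f.fiber_id, "myotome_id": f.myotome_id,
            "compartment": f.compartment, "medial_edge": f.medial_edge,
            "x": f.x, "y": f.y,
            "volume": f.volumes[vk], "nucleus_count": f.nucleus_counts[nk],
            "c1": c[0], "c2": c[1], "c3": c[2],
            "tagged": f.tagged, "deformed": t in f.deformed_at,
            "puncta": f.puncta, "time": t,
        })
    cols = ["fiber_id", "myotome_id", "compartment", "medial_edge", "x", "y",
            "volume", "nucleus_count", "c1", "c2", "c3", "tagged",
            "deformed", "puncta", "time"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Brainbow color assignment
# ---------------------------------------------------------------------------

def assign_brainbow_colors(fibers: Sequence[FiberState],
                           config: SimulationConfig,
                           rng: np.random.Generator | None = None) -> None:
    """Draw each tagged fiber's color barcode; fixed for its lifetime.

    Each of ``cassette_copies`` cassette copies independently recombines to
    one of three fluorophores with probabilities ``fluorophore_probs``; the
    fiber's color is the per-fluorophore copy fraction. Untagged fibers carry
    the default (no-color) state.
    """
    if config.cassette_copies < 1:
        raise ValueError("cassette_copies must be >= 1")
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed).spawn(4)[1])
    probs = np.asarray(config.fluorophore_probs, dtype=float)
    for f in sorted(fibers, key=lambda f: f.fiber_id):
        if not f.tagged:
            f.color_fractions = (0.0, 0.0, 0.0)
            continue
        counts = rng.multinomial(config.cassette_copies, probs)
        f.color_fractions = tuple(counts / config.cassette_copies)


# ---------------------------------------------------------------------------
# Image rendering
# ---------------------------------------------------------------------------

@dataclass
class SceneSpec:
    """Geometry and noise description of one rendered cross-section."""

    outline: tuple[float, float] = (_MYOTOME_W, _MYOTOME_H)  # µm (W, H)
    pixel_size: float = 1.0          # µm per pixel, isotropic in-plane
    membrane_thickness: float = 0.9  # µm
    nucleus_fwhm: float = 7.0        # µm
    channel_gain: float = 200.0
    shot_scale: float = 0.0          # Poisson gain; 0 disables shot noise
    read_sd: float = 0.0             # additive Gaussian sd; 0 disables
    lloyd_iterations: int = 100

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.nucleus_fwhm <= 0:
            raise ValueError("nucleus_fwhm must be > 0")


CHANNELS = ("membrane", "c1", "c2", "c3", "nuclei")


def render_myotome_image(fibers: pd.DataFrame, scene: SceneSpec,
                         seed: int = 0,
                         nuclei_per_fiber: Mapping[int, int] | None = None
                         ) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Render one myotome cross-section.

    Fibers tile the rectangular outline as an area-weighted, Lloyd-relaxed
    Voronoi partition whose target areas are proportional to each fiber's
    cross-sectional area (volume / constant fiber length). The membrane
    channel traces boundaries; three color channels are filled with the
    fiber's copy fractions; nuclei are isotropic Gaussian blobs of the stated
    FWHM placed inside their fiber. Poisson shot noise scaled by gain plus
    additive Gaussian read noise is applied when enabled.

    Parameters
    ----------
    fibers:
        Frame with columns fiber_id, x, y, volume, nucleus_count, c1..c3.
    nuclei_per_fiber:
        Optional override of the rendered nucleus count per fiber id.

    Returns
    -------
    image:
        float array, shape (5, H, W), channel order ``CHANNELS``.
    labels:
        uint16 label map identical to the noiseless tiling; background 0.
    nuclei:
        DataFrame of true nucleus centroids (columns fiber_id, x, y, µm).
    """
    if len(fibers) == 0:
        raise ValueError("at least one fiber is required")
    rng = np.random.default_rng(seed)
    w_um, h_um = scene.outline
    W = int(round(w_um / scene.pixel_size))
    H = int(round(h_um / scene.pixel_size))

    pts = fibers[["x", "y"]].to_numpy(dtype=float) / scene.pixel_size
    if (pts[:, 0] < 0).any() or (pts[:, 0] > W).any() \
            or (pts[:, 1] < 0).any() or (pts[:, 1] > H).any():
        raise ValueError("fiber seed points must lie inside the outline")
    pts = np.clip(pts, 0.5, [[W - 0.5, H - 0.5]])

    vol = fibers["volume"].to_numpy(dtype=float)
    target = vol / vol.sum()  # target area shares

    yy, xx = np.mgrid[0:H, 0:W]
    grid = np.stack([xx.ravel() + 0.5, yy.ravel() + 0.5], axis=1)
    n = len(pts)
    weights = np.zeros(n)

    # Lloyd relaxation on a power diagram: pixels go to
    # argmin(||p - s_i||^2 - w_i); weights adjusted toward target areas,
    # seeds moved to cell centroids.
    lab_flat = None
    for _ in range(max(scene.lloyd_iterations, 1)):
        d2 = ((grid[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2) - weights
        lab_flat = d2.argmin(axis=1)
        areas = np.bincount(lab_flat, minlength=n).astype(float)
        weights += 0.5 * (target - areas / (H * W)) * (H * W)
        weights -= weights.mean()
        for i in range(n):
            sel = lab_flat == i
            if sel.any():
                pts[i] = grid[sel].mean(axis=0)
    # no cell may be empty: give each starved seed its nearest pixel
    areas = np.bincount(lab_flat, minlength=n)
    for i in np.nonzero(areas == 0)[0]:
        j = ((grid - pts[i]) ** 2).sum(axis=1).argmin()
        lab_flat[j] = i
    labels = (lab_flat.reshape(H, W) + 1).astype(np.uint16)

    fiber_ids = fibers["fiber_id"].to_numpy()
    # membrane: boundaries between different labels
    membrane = np.zeros((H, W), dtype=bool)
    membrane[:, 1:] |= labels[:, 1:] != labels[:, :-1]
    membrane[1:, :] |= labels[1:, :] != labels[:-1, :]
    thick = max(int(round(scene.membrane_thickness / scene.pixel_size)), 1)
    if thick > 1:
        from scipy import ndimage as ndi
        membrane = ndi.binary_dilation(membrane, iterations=thick - 1)

    img = np.zeros((len(CHANNELS), H, W), dtype=float)
    img[0] = membrane * scene.channel_gain
    colors = fibers[["c1", "c2", "c3"]].to_numpy(dtype=float)
    for i in range(n):
        mask = labels == i + 1
        for c in range(3):
            img[1 + c][mask] = colors[i, c] * scene.channel_gain
    # keep interiors color-only: membrane pixels stay membrane
    for c in range(1, 4):
        img[c][membrane] = 0.0

    # nuclei as Gaussian blobs inside their fiber
    sigma_px = scene.nucleus_fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0))) \
        / scene.pixel_size
    nuc_rows = []
    counts = fibers["nucleus_count"].to_numpy(dtype=int)
    for i in range(n):
        k = int(nuclei_per_fiber.get(int(fiber_ids[i]), counts[i])) \
            if nuclei_per_fiber is not None else int(counts[i])
        mask = labels == i + 1
        ys, xs = np.nonzero(mask & ~membrane)
        if len(ys) == 0 or k <= 0:
            continue
        idx = rng.choice(len(ys), size=min(k, len(ys)), replace=False)
        for j in idx:
            cy, cx = float(ys[j]), float(xs[j])
            nuc_rows.append({"fiber_id": int(fiber_ids[i]),
                             "x": cx * scene.pixel_size,
                             "y": cy * scene.pixel_size})
            y0, y1 = max(int(cy - 4 * sigma_px), 0), \
                min(int(cy + 4 * sigma_px) + 1, H)
            x0, x1 = max(int(cx - 4 * sigma_px), 0), \
                min(int(cx + 4 * sigma_px) + 1, W)
            gy, gx = np.mgrid[y0:y1, x0:x1]
            blob = np.exp(-(((gx - cx) ** 2 + (gy - cy) ** 2)
                            / (2 * sigma_px ** 2)))
            img[4, y0:y1, x0:x1] += blob * scene.channel_gain

    if scene.shot_scale > 0:
        img = rng.poisson(np.maximum(img, 0) * scene.shot_scale) \
            / scene.shot_scale
    if scene.read_sd > 0:
        img = img + rng.normal(0.0, scene.read_sd, size=img.shape)

    nuclei = pd.DataFrame(nuc_rows, columns=["fiber_id", "x", "y"])
    return img.astype(float), labels, nuclei


# ---------------------------------------------------------------------------
# qPCR simulation
# ---------------------------------------------------------------------------

def simulate_qpcr(tagged_share: Mapping[float, float],
                  seed: int = 0,
                  base_ct: float = 20.0,
                  ref_ct: float = 16.0,
                  noise_sd: float = 0.0,
                  n_biological: int = 4,
                  n_technical: int = 3,
                  ct_max: float = 40.0) -> pd.DataFrame:
    """Simulate a recombined-cassette qPCR Ct table.

    ``tagged_share`` maps each sampled time to the tagged-fiber transcript
    share of the whole-animal transcript pool (elimination shrinks the
    numerator; animal growth inflates the denominator). Target Ct follows
    ``base_ct - log2(share)`` plus Gaussian noise; the reference gene has
    constant per-cell abundance, so its Ct is flat. Samples follow the
    biological-quadruplicate / technical-triplicate replicate structure.

    Zero shares are capped at ``ct_max`` and flagged in the ``censored``
    column.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for t in sorted(tagged_share):
        share = float(tagged_share[t])
        if share < 0:
            raise ValueError("tagged share must be >= 0")
        for b in range(1, n_biological + 1):
            bio_eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            for r in range(1, n_technical + 1):
                tech_eps = rng.normal(0.0, noise_sd / 2) if noise_sd > 0 else 0.0
                if share == 0.0:
                    ct_t, censored = ct_max, True
                else:
                    ct_t = base_ct - math.log2(share) + bio_eps + tech_eps
                    censored = ct_t >= ct_max
                    ct_t = min(ct_t, ct_max)
                rows.append({"time": t, "bio_rep": b, "tech_rep": r,
                             "gene": "target", "ct": ct_t,
                             "censored": censored})
                rows.append({"time": t, "bio_rep": b, "tech_rep": r,
                             "gene": "reference",
                             "ct": ref_ct + (rng.normal(0.0, noise_sd / 2)
                                             if noise_sd > 0 else 0.0),
                             "censored": False})
    return pd.DataFrame(rows, columns=["time", "bio_rep", "tech_rep",
                                       "gene", "ct", "censored"])


def tagged_share_trajectory(gt: GroundTruth) -> dict[float, float]:
    """Tagged transcript share over time from a simulated ground truth.

    Transcript abundance per fiber is taken proportional to its volume, so
    the share is (tagged volume at birth cohort still alive) / (total volume).
    """
    out = {}
    for t in gt.config.t_grid:
        alive = gt.alive_at(t)
        tot = sum(f.volumes[max(k for k in f.volumes if k <= t)]
                  for f in alive) or 1.0
        # tagged signal comes from the induction cohort only
        t0 = gt.config.t_grid[0]
        tag = sum(f.volumes[max(k for k in f.volumes if k <= t)]
                  for f in alive if f.tagged and f.birth_time <= t0)
        out[t] = tag / tot
    return out
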