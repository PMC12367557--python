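"""Synthetic test inputs with known ground truth.

The pipeline's geometric operations are exercised on banded ellipsoids: a
UV tessellation of an ellipsoid (poles on the X body axis, so bands mimic
abdominal tergite stripes) coloured two-tone by an analytic stripe
function of normalised X position.  The stripe function is returned with
the mesh, so segmentation, distance maps and pattern interpolation can be
checked against an exact oracle.  Two ellipsoids built with the same
tessellation but different band phases share topology and therefore form a
valid corresponded pair without any projection step.

Behavioural data are simulated with known parameters.  Feeding-station
sessions draw an attack order from a Plackett-Luce scheme: each dish's
aversion follows its stimulus type's true learning curve at session t
(plus Gaussian noise on the logit-protection scale), and dishes are chosen
sequentially with probability proportional to exp(-beta * aversion); a
stopping rule leaves a fraction of dishes unopened.  The latent per-dish
aversions are returned alongside the attack orders so curve-recovery tests
can fit directly on the scale the curves are defined on.  Chick trials add
per-trait latency effects to a baseline with Gaussian noise, truncated at
0.05 s.

Everything here is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .behaviour_stats import LearningCurveFit
from .experiment_design import ALL_PERFECT, ALL_POOR, chick_trial_sequence
from .mesh_io import ColouredMesh, quantize_colour
from .shape_morph import CorrespondedPair


class FixtureError(ValueError):
    """Raised for invalid fixture parameters."""


# -- banded ellipsoid meshes -------------------------------------------------

@dataclass
class BandedEllipsoidParams:
    n_lat: int = 16
    n_lon: int = 32
    semi_axes: tuple[float, float, float] = (7.0, 3.0, 3.0)
    n_bands: int = 3
    band_phase: float = 0.0
    colour_1: tuple[int, int, int] = (255, 220, 0)
    colour_2: tuple[int, int, int] = (30, 30, 30)
    colour_noise_sd: float = 0.0
    seed: int = 0

    def check(self) -> None:
        if self.n_lat < 4 or self.n_lon < 8:
            raise FixtureError("tessellation too coarse (need n_lat >= 4, n_lon >= 8)")
        if min(self.semi_axes) <= 0:
            raise FixtureError("semi-axes must be positive")
        if self.n_bands < 1:
            raise FixtureError("need at least one band")
        if not 0.0 <= self.band_phase < 1.0:
            raise FixtureError("band_phase must lie in [0, 1)")


@dataclass
class BandedEllipsoid:
    mesh: ColouredMesh
    true_labels: np.ndarray
    stripe: Callable[[np.ndarray], np.ndarray]
    params: BandedEllipsoidParams


def stripe_function(params: BandedEllipsoidParams) -> Callable[[np.ndarray], np.ndarray]:
    """Analytic band labels from X coordinates (1 = colour_1, 2 = colour_2).

    ``band_phase`` is expressed in stripe widths (half of a full two-tone
    period), so a phase of 1 would shift the pattern by one whole stripe;
    phases in [0, 1) therefore never produce the complementary pattern,
    and the phase-to-shift map is linear (the analytic pattern midway
    between two phases is the pattern at the mean phase).
    """
    a = params.semi_axes[0]

    def stripe(x: np.ndarray) -> np.ndarray:
        xn = (np.asarray(x, dtype=float) + a) / (2.0 * a)
        u = params.n_bands * xn + 0.5 * params.band_phase
        return np.where((u - np.floor(u)) < 0.5, 1, 2).astype(np.int64)

    return stripe


def make_banded_ellipsoid(params: BandedEllipsoidParams) -> BandedEllipsoid:
    """Banded two-tone ellipsoid with an analytic stripe oracle.

    Vertex count is n_lat * n_lon + 2 (rings plus two poles) and face
    count 2 * n_lat * n_lon.  Two calls differing only in band phase,
    colours or noise share topology exactly.
    """
    params.check()
    a, b, c = params.semi_axes
    n_lat, n_lon = params.n_lat, params.n_lon

    theta = np.pi * np.arange(1, n_lat + 1) / (n_lat + 1)
    phi = 2.0 * np.pi * np.arange(n_lon) / n_lon
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    ring = np.column_stack(
        [
            (a * np.cos(tt)).ravel(),
            (b * np.sin(tt) * np.cos(pp)).ravel(),
            (c * np.sin(tt) * np.sin(pp)).ravel(),
        ]
    )
    vertices = np.vstack([[a, 0.0, 0.0], ring, [-a, 0.0, 0.0]])

    faces = []
    south = n_lat * n_lon + 1

    def rv(i, j):  # ring vertex index (ring i, longitude j)
        return 1 + i * n_lon + (j % n_lon)

    for j in range(n_lon):  # pole fans
        faces.append([0, rv(0, j), rv(0, j + 1)])
        faces.append([south, rv(n_lat - 1, j + 1), rv(n_lat - 1, j)])
    for i in range(n_lat - 1):  # quad strips between rings
        for j in range(n_lon):
            faces.append([rv(i, j), rv(i + 1, j), rv(i + 1, j + 1)])
            faces.append([rv(i, j), rv(i + 1, j + 1), rv(i, j + 1)])

    stripe = stripe_function(params)
    labels = stripe(vertices[:, 0])
    palette = np.array([params.colour_1, params.colour_2], dtype=float)
    colours = palette[labels - 1]
    if params.colour_noise_sd > 0.0:
        rng = np.random.default_rng(params.seed)
        colours = colours + rng.normal(0.0, params.colour_noise_sd, size=colours.shape)
    mesh = ColouredMesh(
        vertices,
        np.array(faces, dtype=np.int64),
        quantize_colour(colours),
        name=f"banded_phase{params.band_phase:g}",
    )
    return BandedEllipsoid(mesh, labels, stripe, params)


def make_banded_pair(
    phase_a: float = 0.0,
    phase_b: float = 0.5,
    **kwargs,
) -> tuple[BandedEllipsoid, BandedEllipsoid, CorrespondedPair]:
    """Two phase-shifted banded ellipsoids sharing topology."""
    pa = BandedEllipsoidParams(band_phase=phase_a, **kwargs)
    pb = BandedEllipsoidParams(band_phase=phase_b, **kwargs)
    ea = make_banded_ellipsoid(pa)
    eb = make_banded_ellipsoid(pb)
    pair = CorrespondedPair(ea.mesh, eb.mesh, ea.mesh.faces.copy())
    return ea, eb, pair


# -- simulated feeding-station sessions --------------------------------------

@dataclass
class SessionSimParams:
    n_sessions: int = 30
    composition: dict = field(
        default_factory=lambda: {"V100": 17, "M100": 10, "mimic": 22}
    )
    curves: dict = field(
        default_factory=lambda: {
            "V100": ("asymptotic", (3.0, 0.2, -1.0)),
            "M100": ("asymptotic", (-2.0, 0.0, -1.0)),
            "mimic": ("asymptotic", (0.5, 0.1, -1.0)),
        }
    )
    beta: float = 1.0
    noise_sd: float = 0.3
    stop_fraction: float = 0.9
    seed: int = 0

    def check(self) -> None:
        if self.n_sessions < 1 or not self.composition:
            raise FixtureError("need at least one session and one dish type")
        if any(v < 1 for v in self.composition.values()):
            raise FixtureError("dish counts must be positive")
        if not 0.0 < self.stop_fraction <= 1.0:
            raise FixtureError("stop_fraction must lie in (0, 1]")
        for stim in self.composition:
            if stim not in self.curves:
                raise FixtureError(f"no learning curve given for {stim!r}")


def _curve_value(family: str, abc: tuple[float, float, float], t: float) -> float:
    a, b, c = abc
    fit = LearningCurveFit(family=family, a=a, b=b, c=c, rss=0.0, converged=True)
    return float(fit.predict(t))


@dataclass
class SimulatedSessions:
    sequences: list  # of behaviour_stats.AttackSequence
    latent: pd.DataFrame  # per session/dish: type, aversion (logit scale)


def simulate_sessions(params: SessionSimParams) -> SimulatedSessions:
    """Seeded attack orders from type-specific learning curves.

    Per session t, every dish's latent aversion is its type's curve value
    at t plus Gaussian noise (sd ``noise_sd``) on the logit-protection
    scale.  The attack order is a Plackett-Luce draw with scores
    -beta * aversion, realised through the Gumbel trick; ``beta = 0``
    gives a uniformly random order, ``beta = inf`` sorts by aversion.
    The first ``round(stop_fraction * n)`` dishes are opened and the rest
    left unopened.
    """
    from .behaviour_stats import AttackSequence

    params.check()
    rng = np.random.default_rng(params.seed)
    types = [s for s, cnt in params.composition.items() for _ in range(cnt)]
    n = len(types)
    n_open = int(round(params.stop_fraction * n))
    dish_ids = [f"{s}#{k}" for k, s in enumerate(types)]

    sequences = []
    rows = []
    for t in range(1, params.n_sessions + 1):
        aversion = np.array(
            [_curve_value(*params.curves[s], t) for s in types]
        ) + rng.normal(0.0, params.noise_sd, size=n)
        if np.isinf(params.beta):
            order = np.argsort(aversion, kind="stable")
        else:
            gumbel = rng.gumbel(size=n)
            # Plackett-Luce with scores -beta*aversion == ascending sort of
            # beta*aversion - Gumbel
            order = np.argsort(params.beta * aversion - gumbel, kind="stable")
        attacked = [dish_ids[k] for k in order[:n_open]]
        unopened = {dish_ids[k] for k in order[n_open:]}
        sequences.append(
            AttackSequence(
                session_id=f"s{t}", feeder_id="sim", attacked=attacked,
                unopened=unopened, n=n,
            )
        )
        for k in range(n):
            rows.append(
                {"session": t, "dish": dish_ids[k], "type": types[k],
                 "aversion": aversion[k]}
            )
    return SimulatedSessions(sequences=sequences, latent=pd.DataFrame(rows))


def session_mean_aversion(sim: SimulatedSessions, stimulus_type: str) -> pd.DataFrame:
    """Per-session mean latent aversion of one stimulus type (fit input)."""
    sub = sim.latent[sim.latent["type"] == stimulus_type]
    out = sub.groupby("session", as_index=False)["aversion"].mean()
    return out.rename(columns={"aversion": "mean_aversion"})


# -- simulated chick trials --------------------------------------------------

LEVEL_FRACTION = {"poor": 0.0, "good": 0.5, "perfect": 1.0}


def simulate_chick_trials(
    trait_effects: dict[str, float],
    baseline: float = 0.8,
    noise_sd: float = 0.1,
    n_trials: int = 10,
    seed: int = 0,
    trial_offset_sd: float = 0.0,
) -> pd.DataFrame:
    """Latency tables for chick testing trials with known trait effects.

    Latency = baseline + sum over traits of effect * level fraction
    (poor 0, good 0.5, perfect 1) + trial offset + Gaussian noise,
    truncated at 0.05 s.  Roles (fly / wasp / probe) follow the chick
    trial sequence for seed + trial index.
    """
    if baseline <= 0:
        raise FixtureError("baseline latency must be positive")
    if not all(np.isfinite(list(trait_effects.values()))):
        raise FixtureError("trait effects must be finite")
    rng = np.random.default_rng(seed)
    level_of = {"0": "poor", "50": "good", "100": "perfect"}
    rows = []
    for trial in range(n_trials):
        sequence = chick_trial_sequence("testing", seed=seed + 1000 + trial)
        offset = rng.normal(0.0, trial_offset_sd) if trial_offset_sd > 0 else 0.0
        for k, pres in enumerate(sequence.presentations):
            # decode trait levels from the stimulus label, e.g. S0/P50/C100/Z100
            letters = {"S": "shape", "P": "pattern", "C": "colour", "Z": "size"}
            levels = {}
            for token in pres.stimulus.split("/"):
                levels[letters[token[0]]] = level_of[token[1:]]
            effect = sum(
                trait_effects.get(trait, 0.0) * LEVEL_FRACTION[levels[trait]]
                for trait in levels
            )
            latency = baseline + effect + offset + (
                rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            )
            if levels == ALL_POOR and not pres.probe:
                role = "fly"
            elif levels == ALL_PERFECT and not pres.probe:
                role = "wasp"
            else:
                role = "probe"
            rows.append(
                {"trial": trial, "presentation": k, "stimulus": pres.stimulus,
                 "role": role, "rewarded": pres.rewarded, "probe": pres.probe,
                 "latency": max(latency, 0.05)}
            )
    return pd.DataFrame(rows)
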