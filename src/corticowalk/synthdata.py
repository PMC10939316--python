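"""Deterministic synthetic fixtures for every analysis in the package.

Everything here is parameterized, seeded and desk-scale: laminar mark sets
with known zone-occupancy targets, biased-random-walk track tables with
known speed/directionality/occupancy targets, and textured drift movies
with ground-truth cumulative flow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .laminar import BoundaryPolyline, NeuronMark
from .trackstats import Track
from .undrift import FlowField, Movie

__all__ = [
    "GenotypeProfile",
    "PROFILE_PRESETS",
    "make_marks",
    "make_boundaries",
    "make_tracks",
    "make_movie",
]


@dataclass(frozen=True)
class GenotypeProfile:
    """Qualitative stand-in for a genotype's laminar/motility phenotype."""

    name: str
    zone_fractions: tuple[float, ...]  # ventricular-first, sums to 1
    speed_um_min: float = 0.5
    directionality: float = 0.9

    def __post_init__(self) -> None:
        fr = np.asarray(self.zone_fractions, dtype=float)
        if np.any(fr < 0) or not np.isclose(fr.sum(), 1.0, atol=1e-9):
            raise ValueError("zone fractions must be non-negative and sum to 1")
        if not 0.0 <= self.directionality <= 1.0:
            raise ValueError("directionality must be in [0, 1]")


PROFILE_PRESETS = {
    # qualitative shapes only; never digitized from any figure
    "control-like": GenotypeProfile(
        name="control-like",
        zone_fractions=(0.02, 0.03, 0.05, 0.07, 0.08, 0.10, 0.13, 0.16, 0.19, 0.17),
        speed_um_min=0.6,
        directionality=0.9,
    ),
    "ko-like": GenotypeProfile(
        name="ko-like",
        zone_fractions=(0.1,) * 10,
        speed_um_min=0.25,
        directionality=0.6,
    ),
    "mosaic-mutant-like": GenotypeProfile(
        name="mosaic-mutant-like",
        zone_fractions=(0.18, 0.2, 0.2, 0.16, 0.1, 0.06, 0.04, 0.03, 0.02, 0.01),
        speed_um_min=0.35,
        directionality=0.8,
    ),
}


def make_boundaries(
    width: float = 500.0,
    height: float = 200.0,
    curved: bool = False,
    amplitude: float = 5.0,
    n_vertices: int = 30,
) -> tuple[BoundaryPolyline, BoundaryPolyline]:
    """A ventricular/pial boundary pair, optionally gently curved."""
    x = np.linspace(-0.2 * width, 1.2 * width, n_vertices)
    wav = amplitude * np.sin(2 * np.pi * x / width) if curved else np.zeros_like(x)
    vent = BoundaryPolyline(np.column_stack([x, wav]), role="ventricular")
    pial = BoundaryPolyline(np.column_stack([x, height + wav]), role="pial")
    return vent, pial


def make_marks(
    profile: GenotypeProfile,
    n: int,
    seed: int,
    boundaries: tuple[BoundaryPolyline, BoundaryPolyline] | None = None,
    width: float = 500.0,
    height: float = 200.0,
    marker: str = "green",
    genotype: str | None = None,
    animal_id: str = "a0",
    hemisphere_id: str = "h0",
) -> tuple[list[NeuronMark], tuple[BoundaryPolyline, BoundaryPolyline]]:
    """Sample neuron marks whose relative-distance binning recovers the profile.

    Zone membership is multinomial in the target fractions; within a zone the
    relative depth is uniform with a small margin so gentle boundary curvature
    cannot push a mark across a zone edge.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if boundaries is None:
        boundaries = make_boundaries(width=width, height=height)
    vent, pial = boundaries
    n_zones = len(profile.zone_fractions)
    zones = rng.choice(n_zones, size=n, p=np.asarray(profile.zone_fractions))
    margin = 0.04  # fraction of one zone width kept clear of the edges
    r = (zones + rng.uniform(margin, 1.0 - margin, size=n)) / n_zones

    x = rng.uniform(0.1 * width, 0.9 * width, size=n)
    y_v = np.interp(x, vent.vertices[:, 0], vent.vertices[:, 1])
    y_p = np.interp(x, pial.vertices[:, 0], pial.vertices[:, 1])
    y = y_v + r * (y_p - y_v)
    marks = [
        NeuronMark(
            x=float(xi),
            y=float(yi),
            marker=marker,
            genotype=genotype if genotype is not None else profile.name,
            animal_id=animal_id,
            hemisphere_id=hemisphere_id,
        )
        for xi, yi in zip(x, y)
    ]
    return marks, boundaries


def make_tracks(
    n: int,
    seed: int,
    lower_fraction: float = 0.5,
    y_mid: float = 100.0,
    speed_um_min: float = 0.5,
    directionality: float = 0.9,
    duration_min: float = 725.0,
    frame_interval_min: float = 15.0,
    heading_noise: float = 0.0,
    yellow_fraction: float = 0.0,
    channel: str = "green",
) -> list[Track]:
    """Biased-walk tracks hitting speed/directionality/occupancy targets.

    Each track is a zig-zag around a straight pial-ward course: with zero
    ``heading_noise`` the realized mean straight-line speed equals
    ``speed_um_min`` and the realized meandering index equals
    ``directionality`` exactly.  Start positions are below ``y_mid`` with
    probability ``lower_fraction``.  A ``yellow_fraction`` of tracks is
    labelled yellow to exercise the exclusion rule.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 < directionality <= 1.0:
        raise ValueError("directionality target must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n_steps = max(2, int(round(duration_min / frame_interval_min)))
    times = np.arange(n_steps + 1) * frame_interval_min
    t_net = times[-1] - times[0]
    d_net = speed_um_min * t_net
    step_len = (d_net / directionality) / n_steps
    phi = np.arccos(np.clip(directionality, 0.0, 1.0))

    tracks = []
    for i in range(n):
        start_lower = rng.random() < lower_fraction
        y0 = rng.uniform(0.05 * y_mid, 0.9 * y_mid) if start_lower else rng.uniform(
            1.1 * y_mid, 1.9 * y_mid
        )
        x0 = rng.uniform(0.0, 200.0)
        signs = np.where(np.arange(n_steps) % 2 == 0, 1.0, -1.0)
        angles = signs * phi
        if heading_noise > 0:
            angles = angles + rng.normal(0.0, heading_noise, size=n_steps)
        dx = step_len * np.sin(angles)
        dy = step_len * np.cos(angles)
        if n_steps % 2 == 1:
            # an unpaired zig would shift the endpoint laterally; cancel it
            dx[-1] = 0.0
            dy[-1] = step_len * directionality if heading_noise == 0 else dy[-1]
        x = x0 + np.concatenate([[0.0], np.cumsum(dx)])
        y = y0 + np.concatenate([[0.0], np.cumsum(dy)])
        chan = "yellow" if rng.random() < yellow_fraction else channel
        tracks.append(
            Track(
                track_id=f"t{i:04d}",
                samples=np.column_stack([times, x, y]),
                channel=chan,
            )
        )
    return tracks


def _constant_drift(shape, n_frames, d_row, d_col):
    cum = []
    for k in range(n_frames):
        cum.append(
            FlowField(
                d_row=np.full(shape, k * d_row, dtype=float),
                d_col=np.full(shape, k * d_col, dtype=float),
            )
        )
    return cum


def _sinusoidal_drift(shape, n_frames, amplitude, period):
    cum = []
    for k in range(n_frames):
        val = amplitude * np.sin(2 * np.pi * k / period)
        cum.append(
            FlowField(
                d_row=np.full(shape, val, dtype=float),
                d_col=np.full(shape, 0.5 * val, dtype=float),
            )
        )
    return cum


def make_movie(
    seed: int,
    shape: tuple[int, int] = (256, 256),
    n_frames: int = 20,
    n_cells: int = 8,
    drift: str = "constant",
    drift_params: dict | None = None,
    cell_speed_px: float = 1.0,
    cell_sigma_px: float = 2.0,
    noise_sigma: float = 0.0,
    poisson: bool = False,
) -> tuple[Movie, list[FlowField]]:
    """Textured movie with moving spot cells under known smooth drift.

    Returns the movie and the ground-truth cumulative drift field per frame
    (frame 0 is zero).  Drift presets: ``none``, ``constant`` (params
    ``d_row``, ``d_col`` px/frame) and ``sinusoidal`` (params ``amplitude``,
    ``period``).
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    params = drift_params or {}
    if drift == "none":
        truth = [
            FlowField(d_row=np.zeros(shape), d_col=np.zeros(shape))
            for _ in range(n_frames)
        ]
    elif drift == "constant":
        truth = _constant_drift(
            shape, n_frames, params.get("d_row", 1.0), params.get("d_col", 0.5)
        )
    elif drift == "sinusoidal":
        truth = _sinusoidal_drift(
            shape, n_frames, params.get("amplitude", 5.0), params.get("period", 20.0)
        )
    else:
        raise ValueError(f"unknown drift preset {drift!r}")

    background = gaussian_filter(rng.uniform(0.0, 1.0, size=shape), sigma=4.0)
    background = (background - background.min()) / np.ptp(background)

    cell_pos0 = np.column_stack(
        [rng.uniform(0.2 * h, 0.8 * h, n_cells), rng.uniform(0.2 * w, 0.8 * w, n_cells)]
    )
    ang = rng.uniform(0.0, 2 * np.pi, n_cells)
    cell_vel = cell_speed_px * np.column_stack([np.cos(ang), np.sin(ang)])

    rows, cols = np.meshgrid(
        np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij"
    )
    frames = np.empty((n_frames, h, w), dtype=float)
    for k in range(n_frames):
        scene = background.copy()
        centers = cell_pos0 + k * cell_vel
        for cr, cc in centers:
            scene += 1.5 * np.exp(
                -((rows - cr) ** 2 + (cols - cc) ** 2) / (2 * cell_sigma_px**2)
            )
        # forward-warp approximation: sample the scene at x - C_k(x)
        from scipy.ndimage import map_coordinates

        frames[k] = map_coordinates(
            scene,
            [rows - truth[k].d_row, cols - truth[k].d_col],
            order=3,
            mode="nearest",
        )
    if poisson:
        frames = rng.poisson(np.maximum(frames, 0.0) * 50.0).astype(float) / 50.0
    if noise_sigma > 0:
        frames = frames + rng.normal(0.0, noise_sigma, size=frames.shape)
    movie = Movie(data=frames, pixel_size_um=1.0, frame_interval_min=15.0)
    return movie, truth
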