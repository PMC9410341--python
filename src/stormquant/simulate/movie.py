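"""Synthetic ECG-gated two-channel movies of a paced heart surface.

A rectangular grid of myocytes is paced at a fixed rate (default 8 Hz).
Every cell emits one Ca²⁺ transient per cycle — instantaneous rise at its
peak phase followed by exponential decay — and the camera records a fixed
number of frames per cycle, each tagged with its trigger phase (fraction
of the cardiac cycle).  Synchronous cells peak at exactly the same phase
every cycle, so a frame gated at a fixed phase sees a constant value;
dyssynchronous cells jitter their peak phase per cycle (Gaussian SD as a
fraction of the cycle), producing cycle-to-cycle intensity variation at
the gate — the signature the dyssynchrony map detects.

The neutrophil channel holds static Gaussian blobs, placed either
uniformly over the field of view or clustered within a given radius of a
randomly chosen dyssynchronous cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from stormquant.imaging import CalciumMovie

__all__ = ["MovieSimSpec", "MovieGroundTruth", "simulate_calcium_movie"]


@dataclass
class MovieSimSpec:
    """Parameters of one synthetic gated movie (one field of view)."""

    grid: tuple[int, int] = (6, 6)        # myocyte grid (rows, cols)
    cell_px: int = 8                      # square cell edge, pixels
    pixel_size_um: float = 2.0
    pacing_rate_hz: float = 8.0
    n_cycles: int = 30
    frames_per_cycle: int = 8
    dyssync_cells: dict[int, float] = field(default_factory=dict)  # index -> jitter SD (cycle fraction)
    neutrophil_mode: str = "uniform"      # "uniform" | "clustered"
    n_neutrophils: int = 0
    cluster_radius_um: float = 25.0
    noise_sd: float = 0.0                 # additive noise, units of transient amplitude
    baseline: float = 0.1
    amplitude: float = 1.0
    peak_phase: float = 0.125             # nominal transient peak (cycle fraction)
    decay_frac: float = 0.2               # exponential decay constant (cycle fraction)
    neutrophil_sigma_um: float = 4.0
    seed: int = 0

    @property
    def n_cells(self) -> int:
        return self.grid[0] * self.grid[1]

    @property
    def fov_px(self) -> tuple[int, int]:
        return (self.grid[0] * self.cell_px, self.grid[1] * self.cell_px)

    def validate(self) -> None:
        if min(self.grid) < 1 or self.cell_px < 1:
            raise ValueError("grid and cell_px must be positive")
        if self.pixel_size_um <= 0 or self.pacing_rate_hz <= 0:
            raise ValueError("pixel_size_um and pacing_rate_hz must be positive")
        if self.n_cycles < 1 or self.frames_per_cycle < 1:
            raise ValueError("n_cycles and frames_per_cycle must be positive")
        for idx, sd in self.dyssync_cells.items():
            if not 0 <= idx < self.n_cells:
                raise ValueError(f"dyssync cell index {idx} outside grid")
            if sd <= 0:
                raise ValueError("jitter SD must be positive for dyssynchronous cells")
        if self.neutrophil_mode not in ("uniform", "clustered"):
            raise ValueError(f"unknown neutrophil mode {self.neutrophil_mode!r}")
        if self.neutrophil_mode == "clustered" and self.n_neutrophils > 0 \
                and not self.dyssync_cells:
            raise ValueError("clustered placement requires >= 1 dyssynchronous cell")
        if self.cluster_radius_um <= 0 or self.noise_sd < 0:
            raise ValueError("cluster_radius_um must be positive; noise_sd >= 0")


@dataclass
class MovieGroundTruth:
    """Planted truth for one synthetic movie (JSON-serializable)."""

    dyssync_cell_indices: list[int]
    cell_map: np.ndarray                   # bool grid (rows, cols), True = dyssynchronous
    cell_bounds_px: list[tuple[int, int, int, int]]  # (r0, r1, c0, c1) per dyssync cell
    neutrophil_xy_um: np.ndarray           # (n, 2) columns (x, y)
    peak_phase_per_cycle: np.ndarray       # (n_cells, n_cycles)

    def to_dict(self) -> dict:
        return {
            "dyssync_cell_indices": list(self.dyssync_cell_indices),
            "cell_map": self.cell_map.astype(int).tolist(),
            "cell_bounds_px": [list(b) for b in self.cell_bounds_px],
            "neutrophil_xy_um": self.neutrophil_xy_um.tolist(),
            "peak_phase_per_cycle": self.peak_phase_per_cycle.tolist(),
        }


def simulate_calcium_movie(spec: MovieSimSpec) -> tuple[CalciumMovie, MovieGroundTruth]:
    """Generate a two-channel gated movie plus its ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.grid
    n_cells = spec.n_cells
    n_frames = spec.n_cycles * spec.frames_per_cycle

    # per-cell per-cycle transient peak phase
    peaks = np.full((n_cells, spec.n_cycles), spec.peak_phase)
    for idx, sd in spec.dyssync_cells.items():
        peaks[idx] += rng.normal(0.0, sd, spec.n_cycles)

    frame_phase = (np.arange(n_frames) % spec.frames_per_cycle) / spec.frames_per_cycle
    cycle_of_frame = np.arange(n_frames) // spec.frames_per_cycle

    # cell intensity per frame: baseline + A * exp(-((phase - peak) mod 1)/tau)
    phase = frame_phase[None, :]                        # (1, T)
    peak = peaks[:, cycle_of_frame]                     # (n_cells, T)
    lag = np.mod(phase - peak, 1.0)
    cell_val = spec.baseline + spec.amplitude * np.exp(-lag / spec.decay_frac)

    # expand cells to pixel blocks -> (T, Y, X)
    ca = cell_val.reshape(rows, cols, n_frames).transpose(2, 0, 1)
    ca = np.repeat(np.repeat(ca, spec.cell_px, axis=1), spec.cell_px, axis=2)

    h_px, w_px = spec.fov_px
    fov_um = (w_px * spec.pixel_size_um, h_px * spec.pixel_size_um)

    # neutrophil coordinates (x, y) in um
    neut_xy = np.empty((0, 2))
    if spec.n_neutrophils > 0:
        if spec.neutrophil_mode == "uniform":
            neut_xy = np.column_stack([
                rng.uniform(0, fov_um[0], spec.n_neutrophils),
                rng.uniform(0, fov_um[1], spec.n_neutrophils),
            ])
        else:
            centers = _cell_centers_um(spec, list(spec.dyssync_cells))
            pick = rng.integers(0, centers.shape[0], spec.n_neutrophils)
            theta = rng.uniform(0, 2 * np.pi, spec.n_neutrophils)
            r = spec.cluster_radius_um * np.sqrt(rng.uniform(0, 1, spec.n_neutrophils))
            neut_xy = centers[pick] + np.column_stack([r * np.cos(theta), r * np.sin(theta)])
            neut_xy[:, 0] = np.clip(neut_xy[:, 0], 0, fov_um[0] - 1e-6)
            neut_xy[:, 1] = np.clip(neut_xy[:, 1], 0, fov_um[1] - 1e-6)

    neut_frame = _render_blobs(neut_xy, (h_px, w_px), spec.pixel_size_um,
                               spec.neutrophil_sigma_um)
    neut = np.broadcast_to(neut_frame, (n_frames, h_px, w_px)).copy()

    if spec.noise_sd > 0:
        ca = ca + rng.normal(0.0, spec.noise_sd, ca.shape)
        neut = neut + rng.normal(0.0, spec.noise_sd, neut.shape)

    movie = CalciumMovie(
        ca=ca,
        neutrophil=neut,
        pixel_size_um=spec.pixel_size_um,
        trigger_phase=frame_phase,
        fov_id=f"sim-{spec.seed}",
    )

    cell_map = np.zeros((rows, cols), dtype=bool)
    bounds = []
    for idx in spec.dyssync_cells:
        r, c = divmod(idx, cols)
        cell_map[r, c] = True
        bounds.append((r * spec.cell_px, (r + 1) * spec.cell_px,
                       c * spec.cell_px, (c + 1) * spec.cell_px))
    truth = MovieGroundTruth(
        dyssync_cell_indices=sorted(spec.dyssync_cells),
        cell_map=cell_map,
        cell_bounds_px=bounds,
        neutrophil_xy_um=neut_xy,
        peak_phase_per_cycle=peaks,
    )
    return movie, truth


def sample_separated_cells(
    rng: np.random.Generator,
    grid: tuple[int, int] = (10, 10),
    n: int = 3,
) -> list[int]:
    """Draw ``n`` cell indices with no two cells 8-adjacent on the grid.

    Planted dyssynchronous myocytes are kept spatially separated so each
    one produces its own hotspot component rather than merging with a
    neighbor.
    """
    rows, cols = grid
    while True:
        idx = rng.choice(rows * cols, n, replace=False)
        rc = [(int(i) // cols, int(i) % cols) for i in idx]
        if all(
            max(abs(a[0] - b[0]), abs(a[1] - b[1])) > 1
            for i, a in enumerate(rc) for b in rc[i + 1:]
        ):
            return [int(i) for i in idx]


def _cell_centers_um(spec: MovieSimSpec, indices: list[int]) -> np.ndarray:
    """Centers of the given cells as (x, y) in um."""
    rows, cols = spec.grid
    out = np.empty((len(indices), 2))
    for k, idx in enumerate(indices):
        r, c = divmod(idx, cols)
        out[k, 0] = (c + 0.5) * spec.cell_px * spec.pixel_size_um
        out[k, 1] = (r + 0.5) * spec.cell_px * spec.pixel_size_um
    return out


def _render_blobs(
    xy_um: np.ndarray, shape_px: tuple[int, int], px_um: float, sigma_um: float
) -> np.ndarray:
    img = np.zeros(shape_px)
    if xy_um.size == 0:
        return img
    yy = (np.arange(shape_px[0]) + 0.5) * px_um
    xx = (np.arange(shape_px[1]) + 0.5) * px_um
    for x, y in xy_um:
        gy = np.exp(-0.5 * ((yy - y) / sigma_um) ** 2)
        gx = np.exp(-0.5 * ((xx - x) / sigma_um) ** 2)
        img += np.outer(gy, gx)
    return img
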