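"""Synthetic SMLM fields, FRAP traces and N:C images with known ground truth.

The field generator emulates STORM acquisitions of nucleoporin-labeled
nuclei: nuclear pore complexes (NPCs) are 8-fold rings of labeled corner
sites scattered over the projected nuclear surface; each labeled site blinks
several times; every blink is localized with isotropic Gaussian error and
assigned a uniform random acquisition frame; uniform background
localizations and optional frame-dependent stage drift complete the model.

Defaults follow the imaging regime the pipeline targets: 20,000 frames at
10 ms exposure, ~25 nm image resolution (FWHM), hence a localization noise
s.d. of 25/2.355 ~ 10.6 nm, and a 107 nm ring diameter (the canonical NPC
scaffold diameter). Dot-like labels (MAB414/NUP93-style) are obtained by
shrinking ``ring_diameter`` below ``sigma_loc`` rather than via a separate
emitter model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .errors import DensityError, GeometryError, ParameterError
from .io_formats import LocalizationTable, NucleusROI, disk_roi


@dataclass
class NPCFieldParams:
    """Parameters of one simulated nucleus-surface localization field.

    Rates are per µm² of ROI area; lengths in nm; ``drift`` is the total
    (dx, dy) displacement in nm accumulated over the movie.
    """

    roi: NucleusROI = field(default_factory=disk_roi)
    npc_density: float = 4.0           # pores / µm²
    ring_diameter: float = 107.0       # nm
    n_corners: int = 8
    label_prob: float = 0.6            # P(corner site carries >= 1 dye)
    mean_blinks: float = 4.0           # mean localizations per labeled site
    blink_law: Literal["poisson", "fixed"] = "poisson"
    sigma_loc: float = 10.6            # localization noise s.d., nm
    bg_rate: float = 40.0              # background localizations / µm²
    frame_count: int = 20_000
    drift: tuple[float, float] = (0.0, 0.0)
    drift_mode: Literal["linear", "sinusoidal"] = "linear"
    min_separation: float = 150.0      # nm between NPC centers
    sigma_range: tuple[float, float] = (100.0, 180.0)     # emitter PSF widths
    bg_sigma_range: tuple[float, float] = (100.0, 300.0)  # background PSF widths
    seed: int | None = None

    def validate(self) -> None:
        if not 0.0 <= self.label_prob <= 1.0:
            raise ParameterError("label_prob must lie in [0, 1]")
        if self.npc_density < 0 or self.bg_rate < 0:
            raise ParameterError("densities must be non-negative")
        if self.mean_blinks < 1:
            raise ParameterError("mean_blinks must be >= 1")
        if self.frame_count < 1:
            raise ParameterError("frame_count must be >= 1")
        if self.n_corners < 1 or self.ring_diameter < 0:
            raise ParameterError("invalid ring geometry")


@dataclass
class SimulationTruth:
    """Ground truth for one simulated field.

    ``emitter_positions[i]`` are the labeled corner coordinates of NPC *i*;
    ``blink_counts[i]`` the per-emitter blink counts, aligned. Positions are
    pre-drift. ``injected_drift`` is the per-frame (dx, dy) track in nm.
    """

    npc_centers: np.ndarray                 # (n_npc, 2) nm
    emitter_positions: list[np.ndarray]     # per NPC: (n_labeled, 2) nm
    blink_counts: list[np.ndarray]          # per NPC: (n_labeled,) int
    injected_drift: np.ndarray              # (frame_count, 2) nm
    background_count: int = 0

    @property
    def n_npc(self) -> int:
        return len(self.npc_centers)

    @property
    def total_blinks(self) -> int:
        return int(sum(b.sum() for b in self.blink_counts))


def drift_track(
    total: tuple[float, float], frame_count: int, mode: str = "linear"
) -> np.ndarray:
    """Per-frame (dx, dy) in nm. Linear ramps from 0 to ``total``; the
    sinusoidal stress-test option completes one period of amplitude
    ``total`` and returns to 0."""
    t = (
        np.zeros(frame_count)
        if frame_count == 1
        else np.arange(frame_count) / (frame_count - 1)
    )
    total_arr = np.asarray(total, float)
    if mode == "linear":
        return t[:, None] * total_arr[None, :]
    if mode == "sinusoidal":
        return np.sin(2 * np.pi * t)[:, None] * total_arr[None, :]
    raise ParameterError(f"unknown drift mode {mode!r}")


def _sample_in_roi(roi: NucleusROI, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform points inside the ROI polygon by bounding-box rejection."""
    lo = roi.polygon.min(axis=0)
    hi = roi.polygon.max(axis=0)
    out = np.empty((0, 2))
    while len(out) < n:
        cand = rng.uniform(lo, hi, size=(max(2 * (n - len(out)), 64), 2))
        out = np.vstack([out, cand[roi.contains(cand)]])
    return out[:n]


def _place_centers(
    roi: NucleusROI, n: int, min_sep: float, rng: np.random.Generator
) -> np.ndarray:
    """Dart-throwing with a hard-core min_sep constraint; capped retries."""
    centers: list[np.ndarray] = []
    attempts, cap = 0, max(200 * n, 1000)
    min_sep2 = min_sep**2
    while len(centers) < n:
        if attempts >= cap:
            raise DensityError(
                f"placed {len(centers)}/{n} NPC centers in {cap} attempts; "
                "lower npc_density or min_separation"
            )
        cand = _sample_in_roi(roi, 1, rng)[0]
        attempts += 1
        if centers:
            d2 = ((np.asarray(centers) - cand) ** 2).sum(axis=1)
            if (d2 < min_sep2).any():
                continue
        centers.append(cand)
    return np.asarray(centers).reshape(-1, 2)


def simulate_npc_field(params: NPCFieldParams) -> tuple[LocalizationTable, SimulationTruth]:
    """Simulate one nucleus: localization table plus ground truth.

    NPC count ~ Poisson(npc_density x area) thinned by the hard-core
    ``min_separation``; each NPC carries ``n_corners`` sites equally spaced
    on its ring at a random global rotation; sites are labeled independently
    with ``label_prob``; labeled sites blink B ~ 1 + Poisson(mean_blinks - 1)
    times (or exactly round(mean_blinks) under the zero-variance ``fixed``
    law); blinks get isotropic Gaussian position noise, a uniform random
    frame and a PSF sigma from ``sigma_range``. Background is CSR over the
    ROI at ``bg_rate`` with sigmas from the broader ``bg_sigma_range``.
    Per-frame drift is added to every localization according to its frame.
    Identical seed + params give bit-identical outputs.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    roi = params.roi
    area = roi.area  # µm²

    n_npc = int(rng.poisson(params.npc_density * area))
    centers = (
        _place_centers(roi, n_npc, params.min_separation, rng)
        if n_npc
        else np.empty((0, 2))
    )

    r = params.ring_diameter / 2.0
    emitter_positions: list[np.ndarray] = []
    blink_counts: list[np.ndarray] = []
    xs, ys = [], []
    for c in centers:
        phase = rng.uniform(0, 2 * np.pi)
        th = phase + 2 * np.pi * np.arange(params.n_corners) / params.n_corners
        sites = c + r * np.c_[np.cos(th), np.sin(th)]
        labeled = sites[rng.random(params.n_corners) < params.label_prob]
        if params.blink_law == "fixed":
            blinks = np.full(len(labeled), int(round(params.mean_blinks)))
        else:
            blinks = 1 + rng.poisson(params.mean_blinks - 1.0, size=len(labeled))
        emitter_positions.append(labeled)
        blink_counts.append(blinks.astype(np.int64))
        for site, b in zip(labeled, blinks):
            pos = site + rng.normal(0.0, params.sigma_loc, size=(b, 2))
            xs.append(pos[:, 0])
            ys.append(pos[:, 1])

    n_signal = int(sum(b.sum() for b in blink_counts))
    n_bg = int(rng.poisson(params.bg_rate * area))
    bg = _sample_in_roi(roi, n_bg, rng) if n_bg else np.empty((0, 2))

    x = np.concatenate(xs + [bg[:, 0]]) if (xs or n_bg) else np.empty(0)
    y = np.concatenate(ys + [bg[:, 1]]) if (ys or n_bg) else np.empty(0)
    n = len(x)
    sigma = np.empty(n)
    sigma[:n_signal] = rng.uniform(*params.sigma_range, size=n_signal)
    sigma[n_signal:] = rng.uniform(*params.bg_sigma_range, size=n_bg)
    frame = rng.integers(1, params.frame_count + 1, size=n)

    track = drift_track(params.drift, params.frame_count, params.drift_mode)
    if n:
        shift = track[frame - 1]
        x = x + shift[:, 0]
        y = y + shift[:, 1]

    df = pd.DataFrame(
        {
            "frame": frame.astype(np.int64),
            "x": x,
            "y": y,
            "sigma": sigma,
        }
    )
    table = LocalizationTable(df, source_id="simulated", frame_count=params.frame_count)
    truth = SimulationTruth(
        npc_centers=centers,
        emitter_positions=emitter_positions,
        blink_counts=blink_counts,
        injected_drift=track,
        background_count=n_bg,
    )
    assert len(table) == truth.total_blinks + truth.background_count
    return table, truth


# -- FRAP ---------------------------------------------------------------------


def default_frap_grid(t_max: float = 500.0, dt: float = 10.0) -> np.ndarray:
    """Post-bleach sampling grid: one frame every ``dt`` s out to ``t_max``."""
    return np.arange(0.0, t_max + 0.5 * dt, dt)


def simulate_frap_trace(
    f0: float,
    plateau: float,
    k: float,
    t_grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
):
    """Exponential-association recovery with additive Gaussian noise.

    intensity(t) = f0 + (plateau - f0)(1 - exp(-k t)) + N(0, noise_sd²).
    """
    from .frap import FRAPTrace, recovery_model

    if k <= 0:
        raise ParameterError("rate k must be positive")
    if plateau <= f0:
        raise ParameterError("plateau must exceed the post-bleach floor f0")
    t = default_frap_grid() if t_grid is None else np.asarray(t_grid, float)
    intensity = recovery_model(t, f0, plateau, k)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sd, size=t.shape)
    return FRAPTrace(t, intensity)


# -- N:C images ---------------------------------------------------------------


def concentric_masks(
    shape: tuple[int, int] = (64, 64), r_cell: float = 28.0, r_nuc: float = 14.0
) -> tuple[np.ndarray, np.ndarray]:
    """Disk-in-disk nucleus/cell masks centered in the image."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    d2 = (yy - (h - 1) / 2) ** 2 + (xx - (w - 1) / 2) ** 2
    return d2 <= r_nuc**2, d2 <= r_cell**2


def simulate_nc_image(
    nuc_mean: float,
    cyto_mean: float,
    nucleus_mask: np.ndarray,
    cell_mask: np.ndarray,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flat nucleus/cytoplasm intensities plus Gaussian pixel noise.

    The nucleus mask must be non-empty and contained in the cell mask.
    """
    nucleus_mask = np.asarray(nucleus_mask, bool)
    cell_mask = np.asarray(cell_mask, bool)
    if nucleus_mask.shape != cell_mask.shape:
        raise GeometryError("mask shapes differ")
    if not nucleus_mask.any():
        raise GeometryError("nucleus mask is empty")
    if (nucleus_mask & ~cell_mask).any():
        raise GeometryError("nucleus mask not contained in cell mask")
    image = np.zeros(cell_mask.shape, float)
    image[cell_mask] = cyto_mean
    image[nucleus_mask] = nuc_mean
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        image[cell_mask] += rng.normal(0.0, noise_sd, size=int(cell_mask.sum()))
    return image, nucleus_mask, cell_mask
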