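"""Ground-truthed synthetic 4D multiphoton scenes.

Emulates intravital calvarial bone imaging well enough to exercise every
downstream stage with a known answer: an undulating SHG⁺ bone surface,
TRAP-tdTomato⁺ mature osteoclasts in two functional states — static
bone-resorbing "R-type" cells that carry acidification (pHocas-3) foci and
motile non-resorbing "N-type" cells that deform and translate —
CX₃CR1-EGFP⁺ precursor monocytes with configurable speed distributions and
bone-contact propensity, plus spectral mixing, autofluorescence, Poisson
shot noise and lateral field drift on the rendered side.

The ground truth (trajectories, footprints, contact flags, acidification
events) is kept separate from the rendered stack, so recovery of known
quantities can be asserted at every stage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse

from .core import ImageStack
from .preprocess import SpectralLibrary, default_library

logger = logging.getLogger(__name__)

__all__ = [
    "SceneConfig",
    "CellTruth",
    "AcidificationEvent",
    "GroundTruthScene",
    "UnmixableSceneError",
    "osteoclast_movie_config",
    "precursor_movie_config",
    "GROUP_PRESETS",
    "simulate_trajectories",
    "render_stack",
    "write_ground_truth",
    "read_ground_truth",
]


class UnmixableSceneError(ValueError):
    """A fluorophore present in the scene is missing from the spectral
    library, so the rendered stack could never be unmixed."""


@dataclass(frozen=True)
class SceneConfig:
    """All knobs of one simulated acquisition.

    Defaults mirror the acquisition geometry of calvarial multiphoton
    imaging: 512 x 512 fields, 3 µm vertical steps, 30 s frames for
    precursor movies and 5 min frames for osteoclast movies.  The lateral
    pixel size is not published for this type of acquisition; 0.62 µm/px is
    a plausible value for a 20x objective at 1.5x zoom over 512 px and is a
    free simulation parameter.
    """

    field_size_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.62
    z_step_um: float = 3.0
    n_z: int = 6
    n_frames: int = 11
    frame_interval_s: float = 30.0
    group_label: str = "steady"
    n_osteoclasts: int = 0
    r_type_fraction: float = 0.5
    n_precursors: int = 0
    precursor_speed_um_min: tuple[float, float] = (3.0, 1.0)
    adhesion_probability: float = 0.3
    drift_um_per_frame: tuple[float, float] = (0.0, 0.0)
    autofluorescence_level: float = 0.1
    photon_scale: float | None = 200.0
    seed: int = 0
    # scene morphology (free parameters, physically plausible scales)
    osteoclast_radius_um: float = 6.0
    precursor_radius_um: float = 3.0
    n_type_step_um: float = 2.5
    r_type_step_um: float = 0.05
    acidification_intensity: float = 3.0
    acidification_radius_um: float = 3.0
    psf_sigma_um: float = 0.4
    bone_height_um: float = 4.5
    bone_relief_um: float = 0.8
    contact_dwell_fraction: float = 1.0

    def __post_init__(self) -> None:
        for name in ("pixel_size_um", "z_step_um", "frame_interval_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("r_type_fraction", "adhesion_probability", "contact_dwell_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_z < 1 or self.n_frames < 1:
            raise ValueError("n_z and n_frames must be >= 1")
        if min(self.field_size_px) < 8:
            raise ValueError("field_size_px too small")
        if self.photon_scale is not None and self.photon_scale <= 0:
            raise ValueError("photon_scale must be positive or None (noiseless)")

    @property
    def field_size_um(self) -> tuple[float, float]:
        return (
            self.field_size_px[0] * self.pixel_size_um,
            self.field_size_px[1] * self.pixel_size_um,
        )

    @property
    def frame_interval_min(self) -> float:
        return self.frame_interval_s / 60.0


def osteoclast_movie_config(**overrides) -> SceneConfig:
    """Acquisition preset for mature-osteoclast movies: 5-min frames with
    the tdTomato and pHocas-3 channels (resorption and deformation
    analyses)."""
    base = dict(
        frame_interval_s=300.0,
        n_frames=3,
        n_osteoclasts=8,
        n_precursors=0,
        photon_scale=200.0,
    )
    base.update(overrides)
    return SceneConfig(**base)


def precursor_movie_config(**overrides) -> SceneConfig:
    """Acquisition preset for precursor movies: 30-s frames with the EGFP
    channel (tracking and bone-adhesion analyses)."""
    base = dict(
        frame_interval_s=30.0,
        n_frames=11,
        n_osteoclasts=0,
        n_precursors=12,
        photon_scale=200.0,
    )
    base.update(overrides)
    return SceneConfig(**base)


#: Cohort presets encoding the qualitative effect directions of the LPS
#: inflammation model and JAK1 inhibition: versus steady state, LPS (the
#: vehicle group) raises resorption, lowers osteoclast motility, slows
#: precursors, increases bone adhesion and expands the TRAP⁺ area; JAK
#: inhibition reverses each of these relative to vehicle.
GROUP_PRESETS: dict[str, dict] = {
    "steady": dict(
        r_type_fraction=0.35,
        n_osteoclasts=4,
        precursor_speed_um_min=(3.0, 1.0),
        adhesion_probability=0.15,
    ),
    "vehicle": dict(
        r_type_fraction=0.85,
        n_osteoclasts=9,
        precursor_speed_um_min=(1.2, 0.5),
        adhesion_probability=0.85,
    ),
    "jaki": dict(
        r_type_fraction=0.45,
        n_osteoclasts=5,
        precursor_speed_um_min=(2.4, 0.8),
        adhesion_probability=0.25,
    ),
}


# ---------------------------------------------------------------------------
# Ground-truth containers
# ---------------------------------------------------------------------------


@dataclass
class CellTruth:
    """One simulated cell: identity, per-frame centroid (µm), per-frame
    footprint (stored as a patch + origin to stay compact), and bone-contact
    flags."""

    cell_id: int
    kind: str  # "osteoclast" | "precursor"
    state: str  # "R" | "N" | "n/a"
    reporter: str  # "tdTomato" | "EGFP"
    trajectory_um: np.ndarray  # (n_frames, 3): z, y, x in µm
    footprints: list[tuple[int, int, np.ndarray]]  # per frame (y0, x0, patch)
    bone_contact: np.ndarray  # (n_frames,) bool

    def footprint_mask(self, frame: int, field_shape: tuple[int, int]) -> np.ndarray:
        """Render the frame's footprint into a full-field boolean mask."""
        mask = np.zeros(field_shape, dtype=bool)
        y0, x0, patch = self.footprints[frame]
        ys = slice(max(y0, 0), min(y0 + patch.shape[0], field_shape[0]))
        xs = slice(max(x0, 0), min(x0 + patch.shape[1], field_shape[1]))
        py = slice(ys.start - y0, ys.stop - y0)
        px = slice(xs.start - x0, xs.stop - x0)
        mask[ys, xs] = patch[py, px]
        return mask

    def frame_speeds_um_min(self, frame_interval_s: float) -> np.ndarray:
        """Instantaneous speed at each frame (NaN at frame 0)."""
        d = np.diff(self.trajectory_um, axis=0)
        step = np.linalg.norm(d, axis=1)
        speeds = np.full(len(self.trajectory_um), np.nan)
        speeds[1:] = step / (frame_interval_s / 60.0)
        return speeds

    def mean_speed_um_min(self, frame_interval_s: float) -> float:
        d = np.diff(self.trajectory_um, axis=0)
        path = float(np.linalg.norm(d, axis=1).sum())
        elapsed_min = (len(self.trajectory_um) - 1) * frame_interval_s / 60.0
        return path / elapsed_min


@dataclass
class AcidificationEvent:
    """A pHocas-3 focus: localized acidification on the bone surface under
    one R-type osteoclast."""

    cell_id: int
    frame_start: int
    frame_stop: int  # exclusive
    center_um: tuple[float, float]  # y, x
    radius_um: float
    intensity: float


@dataclass
class GroundTruthScene:
    config: SceneConfig
    bone_height_map_um: np.ndarray  # (ny, nx)
    cells: list[CellTruth]
    acidification_events: list[AcidificationEvent]
    drift_track_um: np.ndarray  # (n_frames, 2): cumulative (dy, dx)

    def cells_of(self, kind: str, state: str | None = None) -> list[CellTruth]:
        return [
            c
            for c in self.cells
            if c.kind == kind and (state is None or c.state == state)
        ]


# ---------------------------------------------------------------------------
# Trajectory simulation
# ---------------------------------------------------------------------------


def _persistent_walk(
    rng: np.random.Generator,
    start_yx: np.ndarray,
    step_um: float,
    n_frames: int,
    bounds_um: tuple[float, float],
    turn_sd: float = 0.6,
) -> np.ndarray:
    """Biased (persistent) random walk with fixed step length, reflected at
    the field boundary."""
    pos = np.empty((n_frames, 2))
    pos[0] = start_yx
    angle = rng.uniform(0, 2 * math.pi)
    for t in range(1, n_frames):
        angle += rng.normal(0.0, turn_sd)
        step = step_um * np.array([math.sin(angle), math.cos(angle)])
        nxt = pos[t - 1] + step
        for i, limit in enumerate(bounds_um):
            if nxt[i] < 0:
                nxt[i] = -nxt[i]
                angle += math.pi / 2
            elif nxt[i] > limit:
                nxt[i] = 2 * limit - nxt[i]
                angle += math.pi / 2
        pos[t] = nxt
    return pos


def _ellipse_patch(
    center_px: tuple[float, float],
    r_major_px: float,
    r_minor_px: float,
    angle: float,
) -> tuple[int, int, np.ndarray]:
    """Rasterise an ellipse into a minimal patch; returns (y0, x0, patch)."""
    r = int(math.ceil(max(r_major_px, r_minor_px))) + 2
    cy, cx = center_px
    y0, x0 = int(round(cy)) - r, int(round(cx)) - r
    patch = np.zeros((2 * r + 1, 2 * r + 1), dtype=bool)
    rr, cc = draw_ellipse(
        cy - y0, cx - x0, r_major_px, r_minor_px, shape=patch.shape, rotation=angle
    )
    patch[rr, cc] = True
    return y0, x0, patch


def simulate_trajectories(config: SceneConfig) -> GroundTruthScene:
    """Simulate the ground-truth scene: bone geometry, osteoclasts (R/N),
    precursors, acidification events and the drift track.

    Deterministic for a fixed ``config.seed``.  R-type osteoclasts move
    with near-zero amplitude and each carries an acidification focus;
    N-type osteoclasts translate and deform with no acidification.
    Precursor per-track speeds are drawn from the configured normal
    distribution (floored at 0.05 µm/min), and a ``adhesion_probability``
    fraction is flagged as bone-contacting for the configured dwell.
    """
    rng = np.random.default_rng(config.seed)
    ny, nx = config.field_size_px
    px = config.pixel_size_um
    fy, fx = config.field_size_um

    yy, xx = np.meshgrid(
        np.arange(ny) * px, np.arange(nx) * px, indexing="ij"
    )
    bone = config.bone_height_um + config.bone_relief_um * (
        np.sin(2 * math.pi * yy / (0.7 * fy) + rng.uniform(0, 2 * math.pi))
        * np.cos(2 * math.pi * xx / (0.9 * fx) + rng.uniform(0, 2 * math.pi))
    )

    cells: list[CellTruth] = []
    events: list[AcidificationEvent] = []
    cell_id = 0

    # --- mature osteoclasts -------------------------------------------
    n_r = int(round(config.n_osteoclasts * config.r_type_fraction))
    states = ["R"] * n_r + ["N"] * (config.n_osteoclasts - n_r)
    placed: list[tuple[np.ndarray, float]] = []  # (yx, radius) at frame 0
    for state in states:
        radius = max(2.0, rng.normal(config.osteoclast_radius_um, 1.0))
        margin = radius + 5 * px  # rasterised patch padding + centre rounding
        # osteoclasts spread over the bone surface rather than stacking:
        # reject starts that overlap an already placed cell (best effort)
        for _ in range(200):
            start = rng.uniform([margin, margin], [fy - margin, fx - margin])
            if all(
                np.linalg.norm(start - yx0) >= radius + r0 + 2.0
                for yx0, r0 in placed
            ):
                break
        placed.append((start, radius))
        step = config.r_type_step_um if state == "R" else config.n_type_step_um
        yx = _persistent_walk(rng, start, step, config.n_frames, (fy, fx))
        z_surface = float(
            bone[int(min(start[0] / px, ny - 1)), int(min(start[1] / px, nx - 1))]
        )
        traj = np.column_stack([np.full(config.n_frames, z_surface + 0.5), yx])
        footprints = []
        aspect = 1.0
        angle = rng.uniform(0, math.pi)
        for t in range(config.n_frames):
            if state == "N":  # deformable: axis ratio wanders frame to frame
                aspect = float(np.clip(aspect + rng.normal(0, 0.18), 0.55, 1.8))
                angle += rng.normal(0, 0.4)
            r_px = radius / px
            footprints.append(
                _ellipse_patch(
                    (yx[t, 0] / px, yx[t, 1] / px),
                    r_px * aspect,
                    r_px / aspect,
                    angle,
                )
            )
        cells.append(
            CellTruth(
                cell_id=cell_id,
                kind="osteoclast",
                state=state,
                reporter="tdTomato",
                trajectory_um=traj,
                footprints=footprints,
                bone_contact=np.full(config.n_frames, state == "R"),
            )
        )
        if state == "R":
            events.append(
                AcidificationEvent(
                    cell_id=cell_id,
                    frame_start=0,
                    frame_stop=config.n_frames,
                    center_um=(float(yx[0, 0]), float(yx[0, 1])),
                    radius_um=config.acidification_radius_um,
                    intensity=config.acidification_intensity,
                )
            )
        cell_id += 1

    # --- precursors ----------------------------------------------------
    mean_v, sd_v = config.precursor_speed_um_min
    dwell = max(1, int(math.ceil(config.contact_dwell_fraction * config.n_frames)))
    for _ in range(config.n_precursors):
        radius = max(1.5, rng.normal(config.precursor_radius_um, 0.4))
        margin = radius + 5 * px
        start = rng.uniform([margin, margin], [fy - margin, fx - margin])
        speed = max(0.05, rng.normal(mean_v, sd_v))  # µm/min per-track speed
        step = speed * config.frame_interval_min
        yx = _persistent_walk(rng, start, step, config.n_frames, (fy, fx))
        contact = bool(rng.random() < config.adhesion_probability)
        contact_flags = np.zeros(config.n_frames, dtype=bool)
        if contact:
            contact_flags[:dwell] = True
        z_off = 1.0 if contact else 7.0  # µm above local bone surface
        z = np.array(
            [
                float(
                    bone[
                        int(min(yx[t, 0] / px, ny - 1)),
                        int(min(yx[t, 1] / px, nx - 1)),
                    ]
                )
                + z_off
                for t in range(config.n_frames)
            ]
        )
        traj = np.column_stack([z, yx])
        footprints = [
            _ellipse_patch((yx[t, 0] / px, yx[t, 1] / px), radius / px, radius / px, 0.0)
            for t in range(config.n_frames)
        ]
        cells.append(
            CellTruth(
                cell_id=cell_id,
                kind="precursor",
                state="n/a",
                reporter="EGFP",
                trajectory_um=traj,
                footprints=footprints,
                bone_contact=contact_flags,
            )
        )
        cell_id += 1

    drift = np.outer(
        np.arange(config.n_frames), np.asarray(config.drift_um_per_frame, dtype=float)
    )
    return GroundTruthScene(
        config=config,
        bone_height_map_um=bone,
        cells=cells,
        acidification_events=events,
        drift_track_um=drift,
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

_REPORTER_FLUOR = {"tdTomato": "tdTomato", "EGFP": "EGFP"}


def scene_fluorophores(scene: GroundTruthScene) -> list[str]:
    """Fluorophores with non-trivial abundance in this scene (SHG and
    autofluorescence are always present)."""
    present = {"SHG", "autofluorescence"}
    for cell in scene.cells:
        present.add(_REPORTER_FLUOR[cell.reporter])
    if scene.acidification_events:
        present.add("pHocas3")
    return sorted(present)


def abundance_volume(scene: GroundTruthScene, frame: int) -> tuple[np.ndarray, list[str]]:
    """Per-fluorophore abundance volume for one frame, shape
    (n_fluor, n_z, ny, nx), in specimen (drift-free) coordinates."""
    cfg = scene.config
    ny, nx = cfg.field_size_px
    fluors = scene_fluorophores(scene)
    vol = np.zeros((len(fluors), cfg.n_z, ny, nx))
    z_centers = (np.arange(cfg.n_z) + 0.5) * cfg.z_step_um

    shg = fluors.index("SHG")
    for iz, zc in enumerate(z_centers):
        vol[shg, iz] = (zc <= scene.bone_height_map_um).astype(float)

    af = fluors.index("autofluorescence")
    vol[af] = cfg.autofluorescence_level

    for cell in scene.cells:
        fl = fluors.index(_REPORTER_FLUOR[cell.reporter])
        mask = cell.footprint_mask(frame, (ny, nx))
        z_cell = cell.trajectory_um[frame, 0]
        height = 4.0 if cell.kind == "osteoclast" else 2.0  # cell thickness, µm
        in_z = np.abs(z_centers - z_cell) <= height / 2 + cfg.z_step_um / 2
        if not in_z.any():  # always occupy at least the nearest slice
            in_z[np.argmin(np.abs(z_centers - z_cell))] = True
        for iz in np.flatnonzero(in_z):
            vol[fl, iz][mask] = 1.0

    if scene.acidification_events:
        ph = fluors.index("pHocas3")
        yy, xx = np.meshgrid(
            np.arange(ny) * cfg.pixel_size_um,
            np.arange(nx) * cfg.pixel_size_um,
            indexing="ij",
        )
        for ev in scene.acidification_events:
            if not (ev.frame_start <= frame < ev.frame_stop):
                continue
            focus = (yy - ev.center_um[0]) ** 2 + (xx - ev.center_um[1]) ** 2 <= (
                ev.radius_um**2
            )
            # bone-anchored probe: the focus sits at the bone-surface slice
            iz = int(
                np.clip(
                    np.searchsorted(z_centers, scene.bone_height_map_um[
                        int(ev.center_um[0] / cfg.pixel_size_um),
                        int(ev.center_um[1] / cfg.pixel_size_um),
                    ]),
                    0,
                    cfg.n_z - 1,
                )
            )
            vol[ph, iz][focus] = ev.intensity
    return vol, fluors


def render_stack(
    scene: GroundTruthScene,
    config: SceneConfig | None = None,
    spectral_library: SpectralLibrary | None = None,
) -> ImageStack:
    """Render the scene into a detected multi-band stack.

    Per voxel: detected intensity = spectral mixing of fluorophore
    abundances (autofluorescence included), Gaussian-blurred laterally by
    the configured PSF width, shifted by the frame's drift, then
    Poisson-sampled at ``photon_scale`` detected photons per abundance unit
    (``photon_scale=None`` renders noiselessly).  The ground truth is left
    untouched.
    """
    cfg = config or scene.config
    library = spectral_library or default_library()
    present = scene_fluorophores(scene)
    missing = [f for f in present if f not in library.fluorophores]
    if missing:
        raise UnmixableSceneError(
            f"fluorophores {missing} present in the scene but absent from the "
            f"spectral library {library.fluorophores}"
        )
    sub = library.subset(present)
    rng = np.random.default_rng(cfg.seed + 1)  # independent of trajectory stream
    ny, nx = cfg.field_size_px
    sigma_px = cfg.psf_sigma_um / cfg.pixel_size_um
    out = np.empty((cfg.n_frames, cfg.n_z, ny, nx, sub.n_bands))
    for t in range(cfg.n_frames):
        vol, _ = abundance_volume(scene, t)  # (n_fluor, z, y, x)
        mixed = np.tensordot(sub.matrix, vol, axes=(1, 0))  # (bands, z, y, x)
        if sigma_px > 0:
            mixed = ndimage.gaussian_filter(
                mixed, sigma=(0.0, 0.0, sigma_px, sigma_px)
            )
        drift_px = scene.drift_track_um[t] / cfg.pixel_size_um
        if np.any(drift_px != 0):
            order = 0 if np.allclose(drift_px, np.round(drift_px)) else 1
            mixed = ndimage.shift(
                mixed,
                (0.0, 0.0, drift_px[0], drift_px[1]),
                order=order,
                mode="constant",
                cval=0.0,
            )
        if cfg.photon_scale is not None:
            mixed = rng.poisson(np.clip(mixed, 0, None) * cfg.photon_scale) / (
                cfg.photon_scale
            )
        out[t] = np.moveaxis(mixed, 0, -1)
    return ImageStack(
        data=out,
        channel_names=sub.band_names,
        pixel_size_um=cfg.pixel_size_um,
        z_step_um=cfg.z_step_um,
        frame_interval_s=cfg.frame_interval_s,
        axes="TZYXC",
    )


# ---------------------------------------------------------------------------
# Ground-truth I/O
# ---------------------------------------------------------------------------


def ground_truth_tables(scene: GroundTruthScene) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format per-cell-per-frame table and acidification-event table."""
    cfg = scene.config
    rows = []
    for cell in scene.cells:
        speeds = cell.frame_speeds_um_min(cfg.frame_interval_s)
        for t in range(cfg.n_frames):
            rows.append(
                dict(
                    cell_id=cell.cell_id,
                    frame=t,
                    kind=cell.kind,
                    state=cell.state,
                    reporter=cell.reporter,
                    z_um=cell.trajectory_um[t, 0],
                    y_um=cell.trajectory_um[t, 1],
                    x_um=cell.trajectory_um[t, 2],
                    speed_um_min=speeds[t],
                    bone_contact=bool(cell.bone_contact[t]),
                )
            )
    cell_cols = [
        "cell_id", "frame", "kind", "state", "reporter",
        "z_um", "y_um", "x_um", "speed_um_min", "bone_contact",
    ]
    cells_df = pd.DataFrame(rows, columns=cell_cols)
    events_df = pd.DataFrame(
        [
            dict(
                cell_id=ev.cell_id,
                frame_start=ev.frame_start,
                frame_stop=ev.frame_stop,
                y_um=ev.center_um[0],
                x_um=ev.center_um[1],
                radius_um=ev.radius_um,
                intensity=ev.intensity,
            )
            for ev in scene.acidification_events
        ],
        columns=[
            "cell_id", "frame_start", "frame_stop",
            "y_um", "x_um", "radius_um", "intensity",
        ],
    )
    return cells_df, events_df


def write_ground_truth(scene: GroundTruthScene, path: str | Path) -> None:
    """Write the ground truth as two delimited text files
    (``cells.csv``, ``events.csv``) under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cells_df, events_df = ground_truth_tables(scene)
    cells_df.to_csv(path / "cells.csv", index=False, float_format="%.12g")
    events_df.to_csv(path / "events.csv", index=False, float_format="%.12g")


def read_ground_truth(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    path = Path(path)
    # keep_default_na=False so the literal state token "n/a" survives;
    # empty fields (frame-0 speed) still parse as NaN
    return (
        pd.read_csv(path / "cells.csv", keep_default_na=False, na_values=[""]),
        pd.read_csv(path / "events.csv"),
    )
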