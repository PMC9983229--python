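"""Image conditioning applied before segmentation.

Mirrors the acquisition-side processing used in intravital multiphoton bone
imaging: linear spectral unmixing against a saved spectral library (so that
autofluorescence can be separated and discarded), per-channel gamma
correction, maximum-intensity projection over z, and correction of lateral
field drift by registration to the first frame.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .core import ImageStack

logger = logging.getLogger(__name__)

__all__ = [
    "SpectralLibrary",
    "IdentifiabilityError",
    "DriftEstimate",
    "default_library",
    "unmix",
    "gamma_correct",
    "max_intensity_projection",
    "correct_drift",
    "GAMMA_TDTOMATO",
    "GAMMA_PHOCAS",
]

#: Gamma exponents applied before resorption scoring (acquisition-software
#: convention: normalise to [0, 1], raise to gamma, rescale).
GAMMA_TDTOMATO = 0.9
GAMMA_PHOCAS = 2.5


class IdentifiabilityError(ValueError):
    """The spectral library cannot be inverted (rank-deficient or
    fewer detection bands than fluorophores)."""


@dataclass
class SpectralLibrary:
    """Emission fractions of each fluorophore across detection bands.

    ``matrix`` has shape (n_bands, n_fluorophores); each column is the
    unit-normalised emission spectrum of one fluorophore, so columns are
    non-negative and sum to 1.
    """

    band_names: tuple[str, ...]
    fluorophores: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.band_names = tuple(self.band_names)
        self.fluorophores = tuple(self.fluorophores)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.band_names), len(self.fluorophores)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.band_names)} bands x {len(self.fluorophores)} fluorophores"
            )
        if (self.matrix < 0).any():
            raise ValueError("emission fractions must be non-negative")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError(f"columns must sum to 1; got {sums}")

    @property
    def n_bands(self) -> int:
        return len(self.band_names)

    @property
    def n_fluorophores(self) -> int:
        return len(self.fluorophores)

    def subset(self, fluorophores: list[str]) -> "SpectralLibrary":
        idx = [self.fluorophores.index(f) for f in fluorophores]
        return SpectralLibrary(self.band_names, tuple(fluorophores), self.matrix[:, idx])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            self.matrix, index=list(self.band_names), columns=list(self.fluorophores)
        ).to_csv(Path(path), index_label="band")

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectralLibrary":
        df = pd.read_csv(Path(path), index_col="band")
        return cls(tuple(df.index), tuple(df.columns), df.to_numpy())


def default_library() -> SpectralLibrary:
    """Plausible emission fractions for the five signals seen in calvarial
    bone imaging: SHG (narrow, blue-shifted), EGFP and pHocas-3 (green),
    tdTomato (orange-red) and a broad autofluorescence background.

    The numbers are synthetic (no instrument calibration is published); what
    matters downstream is that the matrix is well-conditioned and that each
    column is a unit-normalised spectrum.
    """
    bands = ("SP492", "BP525/50", "BP560/20", "BP583/22", "BP620/40", "BP660/50")
    fluors = ("SHG", "tdTomato", "EGFP", "pHocas3", "autofluorescence")
    m = np.array(
        [
            # SHG   tdTom  EGFP   pHocas AF
            [0.960, 0.000, 0.080, 0.020, 0.150],
            [0.020, 0.050, 0.600, 0.350, 0.200],
            [0.010, 0.250, 0.200, 0.380, 0.200],
            [0.005, 0.400, 0.080, 0.150, 0.170],
            [0.005, 0.220, 0.030, 0.070, 0.150],
            [0.000, 0.080, 0.010, 0.030, 0.130],
        ]
    )
    return SpectralLibrary(bands, fluors, m)


# ---------------------------------------------------------------------------
# Spectral unmixing
# ---------------------------------------------------------------------------


def _collinear_columns(matrix: np.ndarray, names: tuple[str, ...]) -> list[str]:
    """Greedily build a maximal independent column set; return the rest."""
    kept: list[int] = []
    dependent: list[str] = []
    for j in range(matrix.shape[1]):
        trial = kept + [j]
        if np.linalg.matrix_rank(matrix[:, trial]) == len(trial):
            kept.append(j)
        else:
            dependent.append(names[j])
    return dependent


def nnls_voxels(matrix: np.ndarray, pixels: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Exact non-negative least squares for many right-hand sides at once.

    Solves ``min ||matrix @ x - b||  s.t. x >= 0`` for every row ``b`` of
    ``pixels`` by enumerating active sets: for each subset of columns the
    restricted least-squares solution is computed for all voxels in one
    matrix product, and for each voxel the feasible (non-negative) candidate
    with the smallest residual is kept.  The global NNLS optimum is feasible
    for its own active set, so it is always among the candidates.  Exact for
    any full-column-rank matrix; vectorised over millions of voxels where a
    per-voxel iterative solver would be prohibitive.
    """
    m, k = matrix.shape
    pixels = np.asarray(pixels, dtype=float)
    n = pixels.shape[0]
    best_res = np.einsum("ij,ij->i", pixels, pixels)  # empty active set: x = 0
    best_x = np.zeros((n, k))
    for size in range(1, k + 1):
        for subset in itertools.combinations(range(k), size):
            sub = matrix[:, subset]
            pinv = np.linalg.pinv(sub)
            xs = pixels @ pinv.T  # (n, size)
            feasible = (xs >= -tol).all(axis=1)
            if not feasible.any():
                continue
            resid = pixels - xs @ sub.T
            res = np.einsum("ij,ij->i", resid, resid)
            better = feasible & (res < best_res - 1e-15 * (best_res + 1.0))
            if better.any():
                best_res[better] = res[better]
                best_x[np.ix_(better, list(subset))] = xs[better]
                # zero out components not in this subset
                others = [j for j in range(k) if j not in subset]
                if others:
                    best_x[np.ix_(better, others)] = 0.0
    np.clip(best_x, 0.0, None, out=best_x)
    return best_x


def unmix(stack: ImageStack, library: SpectralLibrary) -> ImageStack:
    """Invert the spectral mixing model per voxel.

    Each voxel's band vector is decomposed into non-negative fluorophore
    abundances by least squares against the library.  Autofluorescence is
    returned as its own channel so callers can drop it explicitly.

    Raises
    ------
    IdentifiabilityError
        If the library has fewer bands than fluorophores or linearly
        dependent columns.
    """
    c_axis = stack.axis("C")
    if stack.data.shape[c_axis] != library.n_bands:
        raise ValueError(
            f"stack has {stack.data.shape[c_axis]} bands, library {library.n_bands}"
        )
    if library.n_bands < library.n_fluorophores:
        raise IdentifiabilityError(
            f"{library.n_fluorophores} fluorophores cannot be separated from "
            f"{library.n_bands} detection bands (underdetermined system)"
        )
    if np.linalg.matrix_rank(library.matrix) < library.n_fluorophores:
        bad = _collinear_columns(library.matrix, library.fluorophores)
        raise IdentifiabilityError(
            f"spectral library is rank-deficient; collinear columns: {bad}"
        )
    moved = np.moveaxis(stack.data, c_axis, -1)
    shape = moved.shape
    flat = moved.reshape(-1, library.n_bands)
    abundances = nnls_voxels(library.matrix, flat)
    out = abundances.reshape(shape[:-1] + (library.n_fluorophores,))
    out = np.moveaxis(out, -1, c_axis)
    return stack.with_data(out, channel_names=library.fluorophores)


# ---------------------------------------------------------------------------
# Gamma correction and projection
# ---------------------------------------------------------------------------


def gamma_correct(image: np.ndarray, gamma: float) -> np.ndarray:
    """Apply a gamma transfer curve: min-max normalise, raise to ``gamma``,
    rescale to the original range.  Order-preserving for any gamma > 0.

    A constant image has no range to normalise; it is returned unchanged
    (with a log message) rather than raising.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    image = np.asarray(image, dtype=float)
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        logger.warning("gamma_correct: constant image, returned unchanged")
        return image.copy()
    norm = (image - lo) / (hi - lo)
    return norm**gamma * (hi - lo) + lo


def max_intensity_projection(stack: ImageStack) -> ImageStack:
    """Project over z by taking the per-voxel maximum; the result has axes
    ``TYXC`` and no axial calibration."""
    z_axis = stack.axis("Z")
    projected = stack.data.max(axis=z_axis)
    return stack.with_data(
        projected, axes=stack.axes.replace("Z", ""), z_step_um=None
    )


# ---------------------------------------------------------------------------
# Drift correction
# ---------------------------------------------------------------------------


@dataclass
class DriftEstimate:
    """Per-frame lateral displacement of the field relative to frame 0.

    ``shifts_px[k]`` is the (dy, dx) drift of frame ``k``'s content in
    pixels; frame 0 is (0, 0) by definition.  ``scores`` are the
    registration confidence (1 - normalised cross-correlation error).
    """

    shifts_px: np.ndarray  # (n_frames, 2)
    scores: np.ndarray  # (n_frames,)

    def __post_init__(self) -> None:
        self.shifts_px = np.asarray(self.shifts_px, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if not np.allclose(self.shifts_px[0], 0.0):
            raise ValueError("shift of frame 0 must be (0, 0)")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "frame": np.arange(len(self.scores)),
                "dy_px": self.shifts_px[:, 0],
                "dx_px": self.shifts_px[:, 1],
                "score": self.scores,
            }
        ).to_csv(Path(path), index=False)


def correct_drift(
    stack: ImageStack,
    reference_channel: str,
    upsample_factor: int = 1,
) -> tuple[ImageStack, DriftEstimate]:
    """Estimate and remove lateral field drift.

    The drift of every frame relative to frame 0 is estimated on the
    reference channel (maximum-projected over z when present) by maximising
    the cross-correlation with frame 0; all channels of each frame are then
    shifted by the negated estimate.  ``upsample_factor > 1`` enables
    subpixel refinement; the default is integer-pixel registration.

    A frame with (near-)zero variance cannot be registered; its shift is
    carried over from the previous frame and a warning is logged.
    """
    if stack.n_frames < 2:
        raise ValueError("drift correction requires at least 2 frames")
    ref = stack.channel(reference_channel)  # (t, [z,] y, x)
    if stack.has_z:
        # mean (not max) over z: a thick structure saturates a maximum
        # projection into a flat field, while the mean keeps its relief
        ref = ref.mean(axis=1)
    n = stack.n_frames
    shifts = np.zeros((n, 2))
    scores = np.ones(n)
    frame0 = ref[0]
    for k in range(1, n):
        frame = ref[k]
        if float(frame.std()) < 1e-12 or float(frame0.std()) < 1e-12:
            logger.warning(
                "correct_drift: frame %d has no contrast; carrying previous shift", k
            )
            shifts[k] = shifts[k - 1]
            scores[k] = 0.0
            continue
        shift, error, _ = phase_cross_correlation(
            frame0, frame, upsample_factor=upsample_factor, normalization=None
        )
        # phase_cross_correlation returns the shift that maps `frame` onto
        # `frame0`; the drift of frame k's content is the negative of that.
        shifts[k] = -shift
        scores[k] = 1.0 - float(error)
    estimate = DriftEstimate(shifts_px=shifts, scores=scores)

    corrected = np.empty_like(stack.data, dtype=float)
    t_axis = stack.axis("T")
    y_axis = stack.axis("Y")
    x_axis = stack.axis("X")
    for k in range(n):
        frame = np.take(stack.data, k, axis=t_axis).astype(float)
        # after removing T, y/x axis indices shift down by one if T precedes
        ya = y_axis - (t_axis < y_axis)
        xa = x_axis - (t_axis < x_axis)
        shift_vec = np.zeros(frame.ndim)
        shift_vec[ya] = -shifts[k, 0]
        shift_vec[xa] = -shifts[k, 1]
        order = 0 if np.allclose(shifts[k], np.round(shifts[k])) else 1
        moved = ndimage.shift(frame, shift_vec, order=order, mode="constant", cval=0.0)
        sl = [slice(None)] * stack.data.ndim
        sl[t_axis] = k
        corrected[tuple(sl)] = moved
    return stack.with_data(corrected), estimate
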