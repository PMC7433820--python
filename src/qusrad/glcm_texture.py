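"""Gray-level co-occurrence texture on QUS parametric maps.

Each parametric map is min-max quantized to L gray levels inside the ROI mask,
and symmetric co-occurrence matrices are accumulated at the four standard
angles (0, 45, 90, 135 degrees) for a fixed displacement.  Four Haralick-type
features are derived per matrix and averaged over the angles:

* contrast   CON = sum P(i,j) (i-j)^2
* correlation COR = sum P(i,j) (i-mu)(j-mu) / sigma^2  (marginal mu, sigma)
* energy     ENE = sum P(i,j)^2
* homogeneity HOM = sum P(i,j) / (1 + |i-j|)

Only pixel pairs with both members inside the mask are counted, so ragged ROI
boundaries do not contaminate the statistics.  For a constant map (sigma = 0)
correlation is defined as 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .rf_core import ValidationError
from .spectral_qus import ParametricMap

logger = logging.getLogger("qusrad")

__all__ = [
    "QuantizedMap",
    "GLCMatrix",
    "TextureFeatures",
    "ANGLES_DEG",
    "quantize_map",
    "compute_glcm",
    "glcm_features",
    "texture_for_map",
]

ANGLES_DEG = (0, 45, 90, 135)

# (row offset, column offset) per angle, displacement 1; rows increase with
# depth, so 45 deg is up-and-right in image convention
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass
class QuantizedMap:
    levels: np.ndarray  # int matrix, 0..L-1
    L: int
    mask: np.ndarray

    def __post_init__(self) -> None:
        masked = self.levels[self.mask]
        if masked.size and (masked.min() < 0 or masked.max() > self.L - 1):
            raise ValidationError("quantized levels out of range")


@dataclass
class GLCMatrix:
    P: np.ndarray
    angle: int
    displacement: int

    def __post_init__(self) -> None:
        s = self.P.sum()
        if not np.isclose(s, 1.0, atol=1e-12):
            raise ValidationError("co-occurrence matrix must sum to 1")
        if np.any(self.P < 0):
            raise ValidationError("co-occurrence probabilities must be >= 0")


@dataclass
class TextureFeatures:
    CON: float
    COR: float
    ENE: float
    HOM: float


def quantize_map(pmap: ParametricMap, L: int = 16) -> QuantizedMap:
    """Linear min-max binning of the masked map values into L gray levels.

    The maximum maps to level L-1; a constant map quantizes to all zeros.
    """
    if L < 2:
        raise ValidationError("need at least 2 gray levels")
    vals = pmap.values
    mask = pmap.mask
    mv = vals[mask]
    if not np.all(np.isfinite(mv)):
        raise ValidationError("masked map values must be finite")
    vmin, vmax = mv.min(), mv.max()
    levels = np.zeros(vals.shape, dtype=np.int32)
    if vmax > vmin:
        scaled = (vals - vmin) / (vmax - vmin) * L
        levels = np.clip(np.floor(scaled), 0, L - 1).astype(np.int32)
        levels[~mask] = 0
    return QuantizedMap(levels=levels, L=L, mask=mask.copy())


def compute_glcm(qm: QuantizedMap, angle: int, displacement: int = 1) -> GLCMatrix:
    """Symmetric, normalized co-occurrence matrix for one angle/displacement.

    Pairs are counted in both directions (symmetrization) and only when both
    pixels lie inside the mask.
    """
    if angle not in _ANGLE_OFFSETS:
        raise ValidationError(f"angle must be one of {ANGLES_DEG}")
    dr, dc = (o * displacement for o in _ANGLE_OFFSETS[angle])
    rows, cols = np.nonzero(qm.mask)
    r2, c2 = rows + dr, cols + dc
    nr, nc = qm.mask.shape
    ok = (r2 >= 0) & (r2 < nr) & (c2 >= 0) & (c2 < nc)
    rows, cols, r2, c2 = rows[ok], cols[ok], r2[ok], c2[ok]
    ok = qm.mask[r2, c2]
    rows, cols, r2, c2 = rows[ok], cols[ok], r2[ok], c2[ok]
    if rows.size == 0:
        raise ValidationError("offset exceeds ROI: no valid pixel pairs")
    i = qm.levels[rows, cols]
    j = qm.levels[r2, c2]
    P = np.zeros((qm.L, qm.L), dtype=float)
    np.add.at(P, (i, j), 1.0)
    np.add.at(P, (j, i), 1.0)
    P /= P.sum()
    return GLCMatrix(P=P, angle=angle, displacement=displacement)


def glcm_features(g: GLCMatrix) -> TextureFeatures:
    """Contrast, correlation, energy, homogeneity of one co-occurrence matrix."""
    P = g.P
    L = P.shape[0]
    idx = np.arange(L)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    con = float(np.sum(P * (ii - jj) ** 2))
    ene = float(np.sum(P**2))
    hom = float(np.sum(P / (1.0 + np.abs(ii - jj))))
    marg = P.sum(axis=1)  # symmetric: row marginal == column marginal
    mu = float(np.sum(idx * marg))
    var = float(np.sum((idx - mu) ** 2 * marg))
    if var <= 0:
        cor = 1.0
    else:
        cor = float(np.sum(P * (ii - mu) * (jj - mu)) / var)
    return TextureFeatures(CON=con, COR=cor, ENE=ene, HOM=hom)


def texture_for_map(
    pmap: ParametricMap, L: int = 16, displacement: int = 1
) -> TextureFeatures:
    """Angle-averaged texture features of one parametric map.

    Features are computed at 0, 45, 90 and 135 degrees and arithmetic-mean
    averaged; an angle with no valid pixel pair is omitted from the mean
    (logged).  All four failing is an error.
    """
    qm = quantize_map(pmap, L)
    per_angle = []
    for ang in ANGLES_DEG:
        try:
            per_angle.append(glcm_features(compute_glcm(qm, ang, displacement)))
        except ValidationError as exc:
            logger.warning("GLCM angle %d omitted for %s: %s", ang, pmap.name, exc)
    if not per_angle:
        raise ValidationError("no angle produced a valid co-occurrence matrix")
    return TextureFeatures(
        CON=float(np.mean([t.CON for t in per_angle])),
        COR=float(np.mean([t.COR for t in per_angle])),
        ENE=float(np.mean([t.ENE for t in per_angle])),
        HOM=float(np.mean([t.HOM for t in per_angle])),
    )
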