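"""Quantitative evaluation of stain deconvolution results.

Three assessments, mirroring common practice in the stain-deconvolution
literature:

* a ground-truth stain matrix built from biologically annotated pixels
  (nuclei pixels for haematoxylin, cytoplasm pixels for eosin): per-channel
  medians of the annotated pixels' OD values, unit-normalised;
* the Euclidean distance between estimated and ground-truth stain vectors
  (both unit-norm, so the distance is the chord length of their angle);
* agreement of estimated vs ground-truth density maps, via Pearson
  correlation and Bland–Altman bias / limits of agreement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .estimation import DensityMaps, StainMatrix, _angle_deg, _canonical_column
from .od_io import OdImage

__all__ = [
    "AnnotatedPixelSet",
    "BlandAltman",
    "EvalReport",
    "ground_truth_stain_matrix",
    "stain_vector_distance",
    "stain_vector_angle",
    "density_correlation",
    "bland_altman",
]


@dataclass
class AnnotatedPixelSet:
    """Pixel coordinates annotated per stain, by biological structure.

    ``coords`` maps a stain label to a list of (row, col) positions. The
    convention that pixels are chosen by structure (nuclei vs cytoplasm)
    rather than by colour is a curation contract recorded here as metadata;
    it cannot be checked mechanically.
    """

    coords: dict[str, list[tuple[int, int]]]
    source: str = ""

    @classmethod
    def from_csv(cls, path: str | Path, tile: str | None = None) -> "AnnotatedPixelSet":
        """Load from a ``tile,stain,row,col`` CSV (0-based coordinates)."""
        df = pd.read_csv(path)
        required = {"tile", "stain", "row", "col"}
        if not required.issubset(df.columns):
            raise ValueError(f"annotation CSV must have columns {sorted(required)}")
        if tile is not None:
            df = df[df["tile"] == tile]
        coords: dict[str, list[tuple[int, int]]] = {}
        for stain, grp in df.groupby("stain"):
            coords[str(stain)] = list(zip(grp["row"].astype(int), grp["col"].astype(int)))
        return cls(coords=coords, source=tile or str(path))

    def to_csv(self, path: str | Path, tile: str = "") -> None:
        rows = [
            {"tile": tile or self.source, "stain": stain, "row": r, "col": c}
            for stain, pts in self.coords.items()
            for r, c in pts
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class BlandAltman:
    """Bias and 95% limits of agreement for paired differences."""

    bias: float
    loa_low: float
    loa_high: float
    differences: np.ndarray = field(repr=False)


@dataclass
class EvalReport:
    """Per-stain evaluation metrics for one tile."""

    distances: dict[str, float]
    correlations: dict[str, tuple[float, float]]
    bland_altman: dict[str, BlandAltman]

    def to_dict(self) -> dict:
        return {
            "distances": self.distances,
            "correlations": {k: {"r": r, "p": p} for k, (r, p) in self.correlations.items()},
            "bland_altman": {
                k: {"bias": ba.bias, "loa_low": ba.loa_low, "loa_high": ba.loa_high}
                for k, ba in self.bland_altman.items()
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def ground_truth_stain_matrix(
    od: OdImage,
    annots: AnnotatedPixelSet,
    stain_order: tuple[str, str] = ("haematoxylin", "eosin"),
) -> StainMatrix:
    """Build the reference stain matrix from annotated pixels.

    Each stain vector is the per-channel median of the annotated pixels' OD
    values, unit-normalised. The residual (third) column is completed as
    the normalised cross product of the two stain vectors, passed through
    the same canonicalisation as estimated columns (a repo convention — the
    annotations say nothing about the residual direction).
    """
    h, w = od.shape
    vectors = []
    for stain in stain_order:
        pts = annots.coords.get(stain, [])
        if not pts:
            raise ValueError(f"no annotated pixels for stain '{stain}'")
        idx = []
        for r, c in pts:
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError(f"annotation ({r}, {c}) out of bounds for {h}x{w} tile")
            idx.append(r * w + c)
        med = np.median(od.d[:, idx], axis=1)
        nrm = np.linalg.norm(med)
        if nrm == 0:
            raise ValueError(f"annotated pixels for '{stain}' have zero OD")
        vectors.append(med / nrm)
    residual = np.cross(vectors[0], vectors[1])
    residual = _canonical_column(residual)
    m = np.column_stack([vectors[0], vectors[1], residual])
    return StainMatrix(m=m, labels=(stain_order[0], stain_order[1], "residual"))


def stain_vector_distance(m_est: StainMatrix, m_gt: StainMatrix) -> dict[str, float]:
    """Euclidean distance between matching unit-norm stain vectors.

    For unit vectors this equals ``2 sin(theta / 2)`` and is bounded by 2.
    Computed for every label the two matrices share.
    """
    out = {}
    for label in m_est.labels:
        if label in m_gt.labels:
            out[label] = float(np.linalg.norm(m_est.vector(label) - m_gt.vector(label)))
    return out


def stain_vector_angle(m_est: StainMatrix, m_gt: StainMatrix) -> dict[str, float]:
    """Angle in degrees between matching stain vectors (recovery error)."""
    out = {}
    for label in m_est.labels:
        if label in m_gt.labels:
            out[label] = _angle_deg(m_est.vector(label), m_gt.vector(label))
    return out


def density_correlation(
    n_est: DensityMaps, n_gt: DensityMaps, clip: bool = False
) -> dict[str, tuple[float, float]]:
    """Pearson correlation (r, two-sided p) per stain over all pixels.

    By default computed on the raw, un-clipped densities; ``clip=True``
    clips both maps at zero first. A zero-variance map yields (nan, nan).
    """
    if n_est.shape != n_gt.shape:
        raise ValueError("density maps have different shapes")
    out = {}
    for i, label in enumerate(n_est.labels):
        a, b = n_est.n[i], n_gt.n[i]
        if clip:
            a, b = np.maximum(a, 0.0), np.maximum(b, 0.0)
        if a.std() == 0 or b.std() == 0:
            out[label] = (float("nan"), float("nan"))
            continue
        r, p = stats.pearsonr(a, b)
        out[label] = (float(r), float(p))
    return out


def bland_altman(
    n_est: DensityMaps | np.ndarray,
    n_gt: DensityMaps | np.ndarray,
    subsample: int | None = 5000,
    seed: int = 0,
    multiplier: float = 1.96,
) -> dict[str, BlandAltman] | BlandAltman:
    """Bland–Altman agreement: bias and bias ± 1.96 SD of paired differences.

    Accepts either two :class:`DensityMaps` (returns one result per stain)
    or two bare arrays (returns a single result). ``subsample`` draws a
    seeded random subset of pixels, mirroring plots made from randomly
    selected pixels; ``None`` uses every pixel.
    """
    if isinstance(n_est, DensityMaps):
        if n_est.shape != n_gt.shape:
            raise ValueError("density maps have different shapes")
        return {
            label: _bland_altman_1d(n_est.n[i], n_gt.n[i], subsample, seed, multiplier)
            for i, label in enumerate(n_est.labels)
        }
    return _bland_altman_1d(
        np.asarray(n_est).ravel(), np.asarray(n_gt).ravel(), subsample, seed, multiplier
    )


def _bland_altman_1d(
    a: np.ndarray, b: np.ndarray, subsample: int | None, seed: int, multiplier: float
) -> BlandAltman:
    if a.shape != b.shape:
        raise ValueError("paired arrays have different shapes")
    diff = a - b
    if subsample is not None and diff.size > subsample:
        rng = np.random.default_rng(seed)
        diff = diff[rng.choice(diff.size, size=subsample, replace=False)]
    bias = float(diff.mean())
    spread = multiplier * float(diff.std(ddof=1)) if diff.size > 1 else 0.0
    return BlandAltman(
        bias=bias, loa_low=bias - spread, loa_high=bias + spread, differences=diff
    )
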