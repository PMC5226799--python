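"""Stain mixing-matrix estimation by ICA and optical-density deconvolution.

The OD image obeys the linear mixing model ``D = M N`` with M the 3x3 stain
matrix (columns = unit-norm OD absorption directions of haematoxylin,
eosin and a residual component) and N the per-pixel stain densities. M is
estimated by fixed-point ICA — either on the kurtosis-selected wavelet
sub-bands (the sub-band method) or directly on the centred raw OD matrix
(the plain-ICA baseline used for comparison). Density maps are then
recovered as ``N = M^{-1} D`` on the *raw* OD image.

ICA leaves sign, scale and permutation of its components undetermined;
:func:`resolve_ambiguities` fixes a canonical form (non-negative unit-norm
columns, labelled by proximity to reference haematoxylin/eosin OD
directions). The reference directions are used only for labelling, never
for estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .od_io import OdImage, RgbImage
from .subband import FilteredObservations

__all__ = [
    "StainMatrix",
    "DensityMaps",
    "REFERENCE_HAEMATOXYLIN_OD",
    "REFERENCE_EOSIN_OD",
    "estimate_mixing_matrix",
    "plain_ica_baseline",
    "resolve_ambiguities",
    "deconvolve",
    "stain_channel_image",
]


def _unit(v: np.ndarray) -> np.ndarray:
    return np.asarray(v, dtype=np.float64) / np.linalg.norm(v)


#: widely used haematoxylin / eosin OD absorption directions; labelling
#: references only — estimation never sees them
REFERENCE_HAEMATOXYLIN_OD = _unit([0.650, 0.704, 0.286])
REFERENCE_EOSIN_OD = _unit([0.072, 0.990, 0.105])

DEFAULT_LABELS = ("haematoxylin", "eosin", "residual")

#: condition number above which a stain matrix is considered ill-conditioned
COND_WARN = 1e4


@dataclass
class StainMatrix:
    """3x3 stain mixing matrix; columns are unit-norm OD stain vectors."""

    m: np.ndarray
    labels: tuple[str, str, str] = DEFAULT_LABELS

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=np.float64)
        if self.m.shape != (3, 3):
            raise ValueError(f"stain matrix must be 3x3, got {self.m.shape}")
        cond = np.linalg.cond(self.m)
        if not np.isfinite(cond):
            raise ValueError("stain matrix is singular")
        if cond > COND_WARN:
            warnings.warn(
                f"stain matrix is ill-conditioned (cond={cond:.3g})", stacklevel=2
            )

    def vector(self, label_or_idx: int | str) -> np.ndarray:
        """Return one stain vector (a column) by index or label."""
        if isinstance(label_or_idx, str):
            label_or_idx = self.labels.index(label_or_idx)
        return self.m[:, label_or_idx]

    @property
    def cond(self) -> float:
        return float(np.linalg.cond(self.m))


@dataclass
class DensityMaps:
    """Per-pixel stain densities, 3 x P (rows follow the stain labels)."""

    n: np.ndarray
    shape: tuple[int, int]
    labels: tuple[str, str, str] = DEFAULT_LABELS

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=np.float64)
        if self.n.ndim != 2 or self.n.shape[0] != 3:
            raise ValueError(f"density matrix must be 3 x P, got {self.n.shape}")
        h, w = self.shape
        if self.n.shape[1] != h * w:
            raise ValueError("density matrix column count does not match shape")

    def plane(self, label_or_idx: int | str) -> np.ndarray:
        """One stain's density map reshaped to the (H, W) image plane."""
        if isinstance(label_or_idx, str):
            label_or_idx = self.labels.index(label_or_idx)
        return self.n[label_or_idx].reshape(self.shape)


def _run_fastica(
    x: np.ndarray,
    n_components: int,
    seed: int,
    max_iter: int,
    tol: float,
) -> np.ndarray:
    """Fixed-point ICA on a k x p observation matrix; returns the k x k mixing
    matrix. Retries with fresh deterministic seeds on non-convergence."""
    # guard against rank deficiency: a constant channel breaks whitening
    row_std = x.std(axis=1)
    if np.any(row_std == 0):
        dead = int(np.argmin(row_std))
        raise ValueError(
            f"observation matrix is rank-deficient: channel {dead} has zero variance"
        )
    if x.shape[1] < 10 * n_components:
        raise ValueError(
            f"need at least {10 * n_components} observation columns, got {x.shape[1]}"
        )
    last_err: Exception | None = None
    for attempt in range(3):
        rs = (seed + 7919 * attempt) % (2**31)
        ica = FastICA(
            n_components=n_components,
            algorithm="parallel",
            fun="logcosh",
            whiten="unit-variance",
            max_iter=max_iter,
            tol=tol,
            random_state=rs,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            try:
                ica.fit(x.T)
            except Exception as exc:  # pragma: no cover - numerical failure
                last_err = exc
                continue
        if not any(issubclass(c.category, ConvergenceWarning) for c in caught):
            return ica.mixing_
        last_err = RuntimeError("FastICA did not converge")
    raise RuntimeError(
        f"ICA failed to converge after 3 seeded restarts (seed={seed}): {last_err}"
    )


def estimate_mixing_matrix(
    obs: FilteredObservations,
    n_components: int = 3,
    seed: int = 0,
    max_iter: int = 400,
    tol: float = 1e-4,
) -> StainMatrix:
    """Estimate the stain matrix by ICA on the filtered sub-band observations.

    The ICA mixing matrix of D' is the stain matrix of the raw OD image
    (linear filtering leaves the mixing unchanged), up to ICA's intrinsic
    sign/scale/permutation ambiguities, which are resolved to the canonical
    labelled form. Deterministic for a fixed seed.
    """
    m_raw = _run_fastica(obs.dprime, n_components, seed, max_iter, tol)
    return resolve_ambiguities(m_raw)


def plain_ica_baseline(
    od: OdImage,
    n_components: int = 3,
    seed: int = 0,
    max_iter: int = 400,
    tol: float = 1e-4,
) -> StainMatrix:
    """ICA applied directly to the centred raw OD matrix (no sub-band
    filtering) — the comparison arm for the sub-band method."""
    x = od.d - od.d.mean(axis=1, keepdims=True)
    m_raw = _run_fastica(x, n_components, seed, max_iter, tol)
    return resolve_ambiguities(m_raw)


def _canonical_column(col: np.ndarray) -> np.ndarray:
    """Sign so the entry sum is >= 0, clip negative residues, unit-normalise."""
    if col.sum() < 0:
        col = -col
    col = np.maximum(col, 0.0)
    nrm = np.linalg.norm(col)
    if nrm == 0:
        raise ValueError("stain vector collapsed to zero during canonicalisation")
    return col / nrm


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def resolve_ambiguities(
    m_raw: np.ndarray, labels: tuple[str, str, str] = DEFAULT_LABELS
) -> StainMatrix:
    """Fix ICA's sign/scale/permutation indeterminacies to a canonical form.

    Each column is sign-flipped so its entry sum is non-negative (OD
    absorption cannot be negative), negative residues are clipped, and the
    column is scaled to unit norm. Columns are then permuted so column 1 is
    the candidate closest in angle to the reference haematoxylin direction
    and column 2 closest to the reference eosin direction; conflicts are
    settled by the assignment minimising the total angle over all ordered
    column pairs, with ties broken by blue-channel weight (haematoxylin
    absorbs more in blue).
    """
    m_raw = np.asarray(m_raw, dtype=np.float64)
    if m_raw.shape != (3, 3):
        raise ValueError(f"expected a 3x3 matrix, got {m_raw.shape}")
    if abs(np.linalg.det(m_raw)) < 1e-12:
        raise ValueError("raw mixing matrix is singular")
    cols = [_canonical_column(m_raw[:, j]) for j in range(3)]

    best: tuple[float, float, tuple[int, int]] | None = None
    for h_idx, e_idx in permutations(range(3), 2):
        total = _angle_deg(cols[h_idx], REFERENCE_HAEMATOXYLIN_OD) + _angle_deg(
            cols[e_idx], REFERENCE_EOSIN_OD
        )
        # tie-break: prefer the assignment whose H candidate has more blue
        key = (round(total, 9), -cols[h_idx][2], (h_idx, e_idx))
        if best is None or key < best:
            best = key
    h_idx, e_idx = best[2]
    r_idx = ({0, 1, 2} - {h_idx, e_idx}).pop()
    m = np.column_stack([cols[h_idx], cols[e_idx], cols[r_idx]])
    return StainMatrix(m=m, labels=labels)


def deconvolve(od: OdImage, m: StainMatrix) -> DensityMaps:
    """Recover density maps from the raw OD image: ``N = M^{-1} D``.

    The reconstruction ``M N`` reproduces D to machine precision (densities
    are kept unclipped; negative values are information-preserving and only
    clipped for rendering).
    """
    if m.cond > COND_WARN:
        warnings.warn(
            f"ill-conditioned stain matrix (cond={m.cond:.3g}); using pseudo-inverse",
            stacklevel=2,
        )
        n = np.linalg.pinv(m.m) @ od.d
    else:
        n = np.linalg.solve(m.m, od.d)
    return DensityMaps(n=n, shape=od.shape, labels=m.labels)


def stain_channel_image(
    nmaps: DensityMaps,
    m: StainMatrix,
    stain: int | str,
    i0: float = 255.0,
) -> RgbImage:
    """Render a single stain's contribution as an RGB tile.

    Applies the Beer–Lambert forward model to one stain only:
    ``I_k = I0 * exp(-m_k n_k)``, with the density clipped at 0 for
    rendering. Summing the per-stain OD contributions over all stains
    reproduces the full OD image (before clipping).
    """
    if isinstance(stain, str):
        stain = nmaps.labels.index(stain)
    if stain not in (0, 1, 2):
        raise ValueError(f"stain index must be 0, 1 or 2, got {stain}")
    density = np.maximum(nmaps.n[stain], 0.0)
    od_k = np.outer(m.m[:, stain], density)  # 3 x P
    h, w = nmaps.shape
    pixels = np.clip(i0 * np.exp(-od_k).T.reshape(h, w, 3), 0.0, i0)
    return RgbImage(pixels=pixels, i0=i0)
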