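"""Multi-resolution sub-band decomposition and non-Gaussianity selection.

The central trick of wavelet-domain blind source separation: because the
wavelet transform is linear, any sub-band of the mixed observations obeys
the same mixing model as the raw data (``F(M N) = M F(N)``). Sub-bands
whose coefficient distribution is far from Gaussian carry the most
source-specific structure, so ICA is run only on those.

Each OD colour channel is decomposed with a decimated 2-D wavelet cascade.
At every level the four orientation blocks — approximation (a), horizontal
(h), vertical (v) and diagonal (o) — are retained, including the running
approximation, giving ``4 * levels`` composed 3-channel bands (20 at the
default depth of 5). Non-Gaussianity of each composed band is scored by the
excess kurtosis of its pooled, standardised coefficients; the top-|K| bands
are concatenated horizontally into the filtered observation matrix D'.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import stats

from .od_io import OdImage

__all__ = [
    "ORIENTATIONS",
    "Band",
    "SubbandStack",
    "FilteredObservations",
    "decompose",
    "normalise_band",
    "excess_kurtosis",
    "select_subbands",
]

#: canonical orientation order: approximation, horizontal, vertical, diagonal
ORIENTATIONS = ("a", "h", "v", "o")

#: default boundary mode; periodization keeps the decimated transform exactly
#: orthonormal for orthogonal wavelets (energy conserved, p_{l+1} = p_l / 4)
DEFAULT_MODE = "periodization"


@dataclass
class Band:
    """One composed 3-channel sub-band.

    ``coeffs`` stacks the red, green, blue coefficient blocks of a given
    (level, orientation) as the rows of a 3 x p_l matrix, flattened in
    row-major order. ``kurtosis`` is the pooled excess kurtosis of the
    standardised coefficients; ``degenerate`` flags zero-variance bands,
    which are never selected.
    """

    level: int
    orientation: str
    coeffs: np.ndarray
    kurtosis: float = float("nan")
    degenerate: bool = False

    @property
    def band_id(self) -> tuple[int, str]:
        return (self.level, self.orientation)

    @property
    def p(self) -> int:
        return self.coeffs.shape[1]


@dataclass
class SubbandStack:
    """All composed sub-bands of one OD image, with kurtosis scores."""

    levels: int
    wavelet: str
    mode: str
    bands: list[Band]
    shape: tuple[int, int]

    def band(self, level: int, orientation: str) -> Band:
        for b in self.bands:
            if b.level == level and b.orientation == orientation:
                return b
        raise KeyError((level, orientation))

    def ranking(self) -> list[Band]:
        """Non-degenerate bands sorted by descending |K|.

        Ties are broken by (level ascending, orientation in a, h, v, o
        order) so the ranking — and everything downstream — is
        deterministic and invariant to the stored band order.
        """
        eligible = [b for b in self.bands if not b.degenerate]
        return sorted(
            eligible,
            key=lambda b: (-abs(b.kurtosis), b.level, ORIENTATIONS.index(b.orientation)),
        )


@dataclass
class FilteredObservations:
    """Concatenation D' of the selected, normalised sub-bands (3 x p)."""

    dprime: np.ndarray
    selected_ids: list[tuple[int, str]]

    @property
    def p(self) -> int:
        return self.dprime.shape[1]


def decompose(
    od: OdImage,
    wavelet: str = "db2",
    levels: int = 5,
    mode: str = DEFAULT_MODE,
) -> SubbandStack:
    """Decompose each OD channel into decimated wavelet sub-bands.

    A cascade of single-level 2-D transforms is applied to the running
    approximation of each channel; all four orientation blocks (including
    that level's approximation) are kept at every level. Kurtosis scores
    are computed on the pooled standardised coefficients of each composed
    band.

    If the tile is too small for the requested depth, the depth is reduced
    to the maximum feasible with a warning.
    """
    h, w = od.shape
    if levels < 1:
        raise ValueError("levels must be >= 1")
    feasible = int(math.floor(math.log2(max(2, min(h, w)))))
    if levels > feasible:
        warnings.warn(
            f"tile {h}x{w} too small for {levels} levels; using {feasible}",
            stacklevel=2,
        )
        levels = feasible

    approx = [od.channel_plane(c) for c in range(3)]
    bands: list[Band] = []
    for level in range(1, levels + 1):
        per_channel = {o: [] for o in ORIENTATIONS}
        next_approx = []
        for chan in approx:
            ca, (ch, cv, cd) = pywt.dwt2(chan, wavelet, mode=mode)
            per_channel["a"].append(ca)
            per_channel["h"].append(ch)
            per_channel["v"].append(cv)
            per_channel["o"].append(cd)
            next_approx.append(ca)
        approx = next_approx
        for orient in ORIENTATIONS:
            coeffs = np.stack([blk.ravel() for blk in per_channel[orient]])
            band = Band(level=level, orientation=orient, coeffs=coeffs)
            normed, degenerate = normalise_band(coeffs)
            band.degenerate = degenerate
            band.kurtosis = float("nan") if degenerate else excess_kurtosis(normed)
            bands.append(band)
    return SubbandStack(levels=levels, wavelet=wavelet, mode=mode, bands=bands, shape=(h, w))


def normalise_band(band: np.ndarray) -> tuple[np.ndarray, bool]:
    """Standardise a 3 x p_l band to zero mean and pooled unit variance.

    Each channel row is centred on its own mean — centring commutes with
    the mixing matrix (the row means of ``M S`` are ``M`` applied to the
    row means of ``S``), so this keeps the linear mixing model exact. In
    particular it removes the large level-dependent DC offsets of the
    approximation bands, which would otherwise enter the concatenated
    observations as a spurious band-indexed component along (1, 1, 1).

    Scaling, by contrast, must be a single pooled scalar: one standard
    deviation computed over all ``3 * p_l`` centred coefficients divides
    every entry, so the relative scaling *between* the three channel rows —
    which encodes the mixing matrix — is preserved. Per-row standard
    deviations would rescale the rows independently and destroy it.

    The result has pooled mean 0 and pooled variance 1. Returns the
    normalised band and a degeneracy flag; a zero-variance band comes back
    as all-zeros and flagged so it is never selected.
    """
    band = np.asarray(band, dtype=np.float64)
    if band.size < 2:
        raise ValueError("band must contain at least 2 coefficients")
    centred = band - band.mean(axis=1, keepdims=True)
    sigma = centred.std()
    # OD coefficients are O(1); anything below 1e-12 is numerical dust
    if sigma < 1e-12 or not np.isfinite(sigma):
        return np.zeros_like(band), True
    return centred / sigma, False


def excess_kurtosis(band: np.ndarray) -> float:
    """Excess kurtosis (fourth standardised moment minus 3) of the pooled
    coefficients.

    Zero for a Gaussian; large |K| marks the sub-bands where the source
    signals are most separable.
    """
    flat = np.asarray(band).ravel()
    if flat.size < 4:
        raise ValueError("kurtosis undefined for fewer than 4 coefficients")
    return float(stats.kurtosis(flat, fisher=True, bias=True))


def select_subbands(stack: SubbandStack, n: int | None = None) -> FilteredObservations:
    """Concatenate the ``n`` least-Gaussian bands into the filtered matrix D'.

    Bands are ranked by descending |K| (degenerate bands excluded), each
    selected band is pooled-standardised, and the 3-row blocks are
    concatenated horizontally. ``n`` defaults to all available bands, the
    setting that performed best in the sub-band-count experiments.
    """
    total = 4 * stack.levels
    if n is None:
        n = total
    if n < 1 or n > total:
        raise ValueError(f"n must be in [1, {total}], got {n}")
    ranked = stack.ranking()
    if not ranked:
        raise ValueError("no non-degenerate sub-bands available (constant image?)")
    if n > len(ranked):
        warnings.warn(
            f"only {len(ranked)} non-degenerate bands available; using all",
            stacklevel=2,
        )
        n = len(ranked)
    chosen = ranked[:n]
    blocks = [normalise_band(b.coeffs)[0] for b in chosen]
    return FilteredObservations(
        dprime=np.concatenate(blocks, axis=1),
        selected_ids=[b.band_id for b in chosen],
    )
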