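"""End-to-end convenience pipeline: tile in, stain matrix + density maps out."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimation import DensityMaps, StainMatrix, deconvolve, estimate_mixing_matrix
from .od_io import OdImage, RgbImage, rgb_to_od
from .subband import SubbandStack, decompose, select_subbands


@dataclass
class DeconvolutionResult:
    """Everything the full pipeline computed for one tile."""

    stain_matrix: StainMatrix
    density_maps: DensityMaps
    od: OdImage
    stack: SubbandStack
    selected_ids: list[tuple[int, str]]


def deconvolve_tile(
    img: RgbImage,
    wavelet: str = "db2",
    levels: int = 5,
    n_subbands: int | None = None,
    seed: int = 0,
    matrix: StainMatrix | None = None,
) -> DeconvolutionResult:
    """Run the full sub-band ICA deconvolution on one RGB tile.

    Converts to optical density, decomposes into wavelet sub-bands, selects
    the least-Gaussian ones by |kurtosis|, estimates the stain matrix by
    ICA on the selection (unless a precomputed ``matrix`` is supplied) and
    deconvolves the raw OD image. Deterministic for a fixed seed.
    """
    od = rgb_to_od(img)
    stack = decompose(od, wavelet=wavelet, levels=levels)
    obs = select_subbands(stack, n=n_subbands)
    if matrix is None:
        matrix = estimate_mixing_matrix(obs, seed=seed)
    nmaps = deconvolve(od, matrix)
    return DeconvolutionResult(
        stain_matrix=matrix,
        density_maps=nmaps,
        od=od,
        stack=stack,
        selected_ids=obs.selected_ids,
    )
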