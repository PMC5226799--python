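"""Beer–Lambert phantom tiles with known ground truth.

The phantoms emulate the structure the sub-band method exploits in real
H&E tissue: a nuclei-like stain-1 density built from sparse smooth blobs
(spatially compact, heavy-tailed coefficient statistics) and a
cytoplasm-like stain-2 density built from band-limited filtered noise
(spatially extended, fibrous). The two densities can be made correlated to
a target level — the regime where plain ICA on raw OD degrades — by mixing
a *smoothed* copy of the nuclei field into the fibrous field: the shared
component then lives in the low-frequency bands, while the high-frequency
detail bands stay close to independent, which is exactly the mechanism
sub-band selection is meant to exploit.

The forward model is ``I = I0 exp(-M N)`` plus optional additive Gaussian
sensor noise, quantised to 8 bits. Everything is deterministic per seed.
"""

from __future__ import annotations

import json
import shutil
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .estimation import (
    REFERENCE_EOSIN_OD,
    REFERENCE_HAEMATOXYLIN_OD,
    DensityMaps,
    StainMatrix,
    _canonical_column,
)
from .od_io import RgbImage, write_tile, write_float_tiff

__all__ = [
    "PhantomSpec",
    "Phantom",
    "default_stain_matrix",
    "make_density_maps",
    "render",
    "phantom_suite",
    "validate_suite",
]


def default_stain_matrix() -> StainMatrix:
    """Default ground-truth stain matrix for phantoms.

    Columns are the reference haematoxylin and eosin OD directions
    (~40 degrees apart — deliberately non-orthogonal, like real H&E) plus
    the canonicalised cross-product residual. Repo constants, configurable
    per spec.
    """
    h = REFERENCE_HAEMATOXYLIN_OD
    e = REFERENCE_EOSIN_OD
    r = _canonical_column(np.cross(h, e))
    return StainMatrix(m=np.column_stack([h, e, r]))


@dataclass
class PhantomSpec:
    """Parameters of one synthetic tile.

    Defaults describe a 256x256 tile with ~150 nuclei-like blobs of
    Gaussian radius 4 px over a fibrous background with 3 px correlation
    length, independent stains, no sensor noise — the baseline condition of
    the recovery experiments.
    """

    size: tuple[int, int] = (256, 256)
    m_true: StainMatrix | None = None
    blob_count: int = 150
    blob_radius: float = 4.0
    blob_amplitude: float = 1.0
    fiber_scale: float = 3.0
    fiber_mean_od: float = 0.35
    rho: float = 0.0
    noise_sigma: float = 0.0
    i0: float = 255.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.size
        if h < 32 or w < 32:
            raise ValueError("phantom tiles must be at least 32x32 (5-level transform)")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError(f"rho must lie in [0, 1), got {self.rho}")
        if self.m_true is None:
            self.m_true = default_stain_matrix()

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["m_true"] = np.asarray(self.m_true.m).tolist()
        return d


@dataclass
class Phantom:
    """A rendered tile together with its generating ground truth."""

    image: RgbImage
    n_true: DensityMaps
    m_true: StainMatrix
    spec: PhantomSpec


def _blob_field(rng: np.random.Generator, spec: PhantomSpec) -> np.ndarray:
    """Sparse sum of sharp-edged radial discs (nuclei-like texture).

    The radial profile ``exp(-(r / radius)^6)`` is near-flat inside the
    nucleus and falls off over ~1 px at the boundary, like the sharp
    chromatin/background edges real nuclei present; the sharp edges give
    the fine detail bands genuine signal energy.
    """
    h, w = spec.size
    out = np.zeros((h, w))
    if spec.blob_count == 0:
        return out
    half = int(np.ceil(2.0 * spec.blob_radius))
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    r = np.sqrt(yy**2 + xx**2) / spec.blob_radius
    kernel = np.exp(-(r**6))
    rows = rng.integers(0, h, size=spec.blob_count)
    cols = rng.integers(0, w, size=spec.blob_count)
    amps = spec.blob_amplitude * rng.uniform(0.7, 1.3, size=spec.blob_count)
    for rr, cc, a in zip(rows, cols, amps):
        r0, r1 = max(0, rr - half), min(h, rr + half + 1)
        c0, c1 = max(0, cc - half), min(w, cc + half + 1)
        kr0, kc0 = r0 - (rr - half), c0 - (cc - half)
        out[r0:r1, c0:c1] += a * kernel[kr0 : kr0 + (r1 - r0), kc0 : kc0 + (c1 - c0)]
    return out


def _fiber_field(rng: np.random.Generator, spec: PhantomSpec) -> np.ndarray:
    """Anisotropic band-limited fibrous texture (cytoplasm/stroma-like).

    White noise smoothed much more strongly along one axis than the other
    produces directional fibres; the absolute value adds ridge-like valleys
    along the zero crossings of the underlying field and keeps fine
    cross-fibre detail.
    """
    h, w = spec.size
    g = gaussian_filter(
        rng.standard_normal((h, w)), (0.8, 2.0 * spec.fiber_scale)
    )
    return np.abs(g)


def _standardise(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def make_density_maps(spec: PhantomSpec) -> DensityMaps:
    """Generate ground-truth density maps for one phantom.

    Stain 1 is the blob field, stain 2 the fibrous field; the residual row
    is zero. When ``rho > 0``, a gaussian-smoothed copy of the blob field
    is mixed into the fibrous field with a gain calibrated (from the
    realised fields) so that corr(n1, n2) hits the target; the shared
    component is low-frequency by construction. The fibrous field is then
    affinely rescaled to be non-negative with mean OD ``fiber_mean_od``
    (affine maps preserve the correlation).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    n1 = _blob_field(rng, spec)
    z2 = _standardise(_fiber_field(rng, spec))
    if spec.rho > 0.0:
        if n1.std() == 0:
            raise ValueError("cannot induce correlation: stain-1 field is constant")
        smooth = gaussian_filter(n1, spec.blob_radius)
        z1s = _standardise(smooth)
        c = float(np.corrcoef(z1s.ravel(), n1.ravel())[0, 1])
        alpha = spec.rho / max(c, 1e-6)
        if alpha > 0.999:
            warnings.warn(
                f"target correlation rho={spec.rho} exceeds the maximum reachable "
                f"({c:.2f}) for this texture; saturating",
                stacklevel=2,
            )
            alpha = 0.999
        z = alpha * z1s + np.sqrt(1.0 - alpha**2) * z2
    else:
        z = z2
    shifted = z - z.min()
    mean = shifted.mean()
    n2 = spec.fiber_mean_od * shifted / mean if mean > 0 else shifted
    n = np.stack([n1.ravel(), n2.ravel(), np.zeros(h * w)])
    return DensityMaps(n=n, shape=(h, w), labels=spec.m_true.labels)


def render(spec: PhantomSpec) -> Phantom:
    """Render a phantom tile through the Beer–Lambert forward model.

    ``I = I0 exp(-M N)``, plus optional additive Gaussian sensor noise in
    counts, rounded and clipped to 8-bit. Bit-identical for a fixed seed.
    """
    nmaps = make_density_maps(spec)
    od_lin = spec.m_true.m @ nmaps.n
    h, w = spec.size
    intensity = spec.i0 * np.exp(-od_lin).T.reshape(h, w, 3)
    if spec.noise_sigma > 0:
        noise_rng = np.random.default_rng([spec.seed, 0x5EED])
        intensity = intensity + noise_rng.normal(0.0, spec.noise_sigma, intensity.shape)
    pixels = np.clip(np.rint(intensity), 0, spec.i0).astype(np.uint8)
    return Phantom(
        image=RgbImage(pixels=pixels, i0=spec.i0),
        n_true=nmaps,
        m_true=spec.m_true,
        spec=spec,
    )


def phantom_suite(
    out_dir: str | Path,
    seeds: list[int],
    rhos: tuple[float, ...] = (0.0, 0.3, 0.6),
    noise_sigmas: tuple[float, ...] = (0.0, 2.0),
    size: tuple[int, int] = (256, 256),
    force: bool = False,
    **spec_kwargs,
) -> dict:
    """Write a grid of phantom tiles with ground truth to ``out_dir``.

    Layout: ``tiles/*.png``, ``truth/matrix_<tag>.csv``,
    ``truth/density_<tag>_{H,E}.tif`` and a ``manifest.json`` listing every
    tile with its generating spec. Refuses to write into a non-empty
    directory unless ``force``.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()):
        if not force:
            raise FileExistsError(f"{out_dir} is not empty (pass force=True to overwrite)")
        shutil.rmtree(out_dir)
    (out_dir / "tiles").mkdir(parents=True, exist_ok=True)
    (out_dir / "truth").mkdir(parents=True, exist_ok=True)

    entries = []
    for seed in seeds:
        for rho in rhos:
            for sigma in noise_sigmas:
                spec = PhantomSpec(
                    size=size, rho=rho, noise_sigma=sigma, seed=seed, **spec_kwargs
                )
                ph = render(spec)
                tag = f"s{seed}_rho{rho:g}_sig{sigma:g}"
                tile_rel = f"tiles/{tag}.png"
                write_tile(ph.image, out_dir / tile_rel)
                mat_rel = f"truth/matrix_{tag}.csv"
                pd.DataFrame(
                    ph.m_true.m, index=["r", "g", "b"], columns=ph.m_true.labels
                ).to_csv(out_dir / mat_rel)
                dens_rels = []
                for idx, short in ((0, "H"), (1, "E")):
                    rel = f"truth/density_{tag}_{short}.tif"
                    write_float_tiff(ph.n_true.plane(idx), out_dir / rel)
                    dens_rels.append(rel)
                entries.append(
                    {
                        "tile": tile_rel,
                        "matrix": mat_rel,
                        "densities": dens_rels,
                        "spec": spec.to_jsonable(),
                    }
                )
    manifest = {"n_tiles": len(entries), "entries": entries}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def validate_suite(out_dir: str | Path) -> dict:
    """Check that every file listed in a suite manifest exists; return it."""
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    missing = []
    for entry in manifest["entries"]:
        for rel in [entry["tile"], entry["matrix"], *entry["densities"]]:
            if not (out_dir / rel).exists():
                missing.append(rel)
    if missing:
        raise FileNotFoundError(f"suite at {out_dir} is missing files: {missing}")
    return manifest
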