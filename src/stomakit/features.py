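"""Rotation-invariant circular-FFT features from fixed-size image disks.

A stoma candidate is described by a circular disk (default 80 px
diameter) centered on a pixel.  Concentric rings are sampled at equally
spaced angles by bilinear interpolation and each ring is passed through
a 1-D DFT over angle.  The per-ring harmonic amplitudes are invariant to
in-plane rotation of the disk; phases are reported relative to the first
harmonic of the same ring (phase_k − k·phase_1), which removes the
rotation-dependent offset and leaves a shape descriptor.  The flattened
amplitude+phase vectors are compressed by PCA before classification.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from sklearn.decomposition import PCA

__all__ = [
    "DiskSpec",
    "RadialFFTFeatures",
    "PCABasis",
    "extract_disk",
    "circular_fft",
    "features_at_points",
    "fit_pca",
    "project",
]


@dataclass(frozen=True)
class DiskSpec:
    """Geometry of the sampling disk and its ring/harmonic discretization.

    ``n_rings`` concentric rings at radii k·r_max/n_rings for k=1..n_rings,
    with r_max = (diameter−1)/2 so the outermost ring stays interpolable
    inside the patch.  ``harmonics_kept`` angular harmonics (plus the DC
    term for amplitudes) are retained per ring.
    """

    diameter_px: int = 80
    n_rings: int = 40
    angles_per_ring: int = 64
    harmonics_kept: int = 8

    def __post_init__(self) -> None:
        if self.diameter_px < 4 or self.diameter_px % 2 != 0:
            raise ValueError("diameter_px must be even and >= 4")
        if not (1 <= self.n_rings <= self.diameter_px // 2):
            raise ValueError("n_rings must be in [1, diameter/2]")
        if self.angles_per_ring < 4:
            raise ValueError("angles_per_ring must be >= 4")
        if not (1 <= self.harmonics_kept <= self.angles_per_ring // 2):
            raise ValueError("harmonics_kept must be in [1, angles_per_ring/2]")

    @property
    def radius_px(self) -> int:
        return self.diameter_px // 2

    @property
    def ring_radii(self) -> np.ndarray:
        r_max = (self.diameter_px - 1) / 2.0
        return np.arange(1, self.n_rings + 1) * (r_max / self.n_rings)

    @property
    def n_features(self) -> int:
        """Length of the flattened "raw" feature vector (amplitudes then phases)."""
        return self.n_rings * (self.harmonics_kept + 1) + self.n_rings * self.harmonics_kept

    def feature_length(self, encoding: str = "raw") -> int:
        if encoding == "raw":
            return self.n_features
        if encoding == "weighted":
            return self.n_rings * (self.harmonics_kept + 1) + 2 * self.n_rings * self.harmonics_kept
        raise ValueError(f"unknown encoding {encoding!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RadialFFTFeatures:
    """Per-ring harmonic amplitudes and rotation-referenced phases.

    amplitudes: (n_rings, harmonics_kept+1), |DFT|/n_angles, harmonic 0 first.
    phases: (n_rings, harmonics_kept), phase_k − k·phase_1 wrapped to (−π, π].
    """

    amplitudes: np.ndarray
    phases: np.ndarray

    def flatten(self, encoding: str = "raw") -> np.ndarray:
        """Ring-major flattening.

        ``"raw"``: all amplitudes (ring-major) then all relative phases.
        ``"weighted"``: amplitudes, then amplitude-weighted phase
        components A_k·cos φ and A_k·sin φ — the harmonic-1-derotated
        complex coefficients.  Phases of near-zero harmonics are
        circular-uniform noise; weighting by amplitude keeps the phase
        information without letting that noise dominate downstream PCA.
        """
        if encoding == "raw":
            return np.concatenate([self.amplitudes.ravel(), self.phases.ravel()])
        if encoding == "weighted":
            a = self.amplitudes[:, 1:]
            return np.concatenate(
                [
                    self.amplitudes.ravel(),
                    (a * np.cos(self.phases)).ravel(),
                    (a * np.sin(self.phases)).ravel(),
                ]
            )
        raise ValueError(f"unknown encoding {encoding!r}")


def extract_disk(
    image: np.ndarray, center: tuple[float, float], spec: DiskSpec = DiskSpec()
) -> tuple[np.ndarray, np.ndarray]:
    """Cut the square patch around ``center`` with its inscribed-circle mask.

    ``center`` is (x, y) in pixel coordinates and must be at least
    diameter/2 from every edge; there is no padding.
    """
    x, y = center
    r = spec.radius_px
    h, w = image.shape
    ix, iy = int(round(x)), int(round(y))
    if ix < r or iy < r or ix > w - r or iy > h - r:
        raise ValueError(
            f"disk of diameter {spec.diameter_px} at ({x}, {y}) exceeds image bounds {w}x{h}"
        )
    patch = np.asarray(image[iy - r : iy + r, ix - r : ix + r], dtype=float)
    c = (spec.diameter_px - 1) / 2.0
    yy, xx = np.mgrid[0 : spec.diameter_px, 0 : spec.diameter_px]
    mask = (xx - c) ** 2 + (yy - c) ** 2 <= ((spec.diameter_px - 1) / 2.0) ** 2
    return patch, mask


def _bilinear(image: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Vectorized bilinear sampling with edge clamping."""
    h, w = image.shape
    xs = np.clip(xs, 0.0, w - 1.0)
    ys = np.clip(ys, 0.0, h - 1.0)
    x0 = np.floor(xs).astype(np.intp)
    y0 = np.floor(ys).astype(np.intp)
    x1 = np.minimum(x0 + 1, w - 1)
    y1 = np.minimum(y0 + 1, h - 1)
    fx = xs - x0
    fy = ys - y0
    v00 = image[y0, x0]
    v01 = image[y0, x1]
    v10 = image[y1, x0]
    v11 = image[y1, x1]
    return (
        v00 * (1 - fy) * (1 - fx)
        + v01 * (1 - fy) * fx
        + v10 * fy * (1 - fx)
        + v11 * fy * fx
    )


def _dft_basis(spec: DiskSpec, dtype=np.float64) -> tuple[np.ndarray, np.ndarray]:
    """Truncated DFT basis: cos/sin matrices (n_angles, harmonics_kept+1).

    Only harmonics 0..harmonics_kept are needed, so a dense matrix product
    replaces a full FFT.  X_k = samples @ cos − i·(samples @ sin).
    """
    n = spec.angles_per_ring
    k = np.arange(spec.harmonics_kept + 1)
    ang = 2 * np.pi * np.outer(np.arange(n), k) / n
    return np.cos(ang).astype(dtype), np.sin(ang).astype(dtype)


def _ring_samples_to_features(samples: np.ndarray, spec: DiskSpec) -> tuple[np.ndarray, np.ndarray]:
    """DFT over the angle axis; samples shape (..., n_rings, n_angles)."""
    n = spec.angles_per_ring
    cosM, sinM = _dft_basis(spec, dtype=samples.dtype if samples.dtype == np.float32 else np.float64)
    re = samples @ cosM
    im = -(samples @ sinM)
    k = spec.harmonics_kept
    amplitudes = np.hypot(re, im) / n
    raw_phase = np.arctan2(im[..., 1 : k + 1], re[..., 1 : k + 1])
    harmonic_idx = np.arange(1, k + 1)
    rel = raw_phase - harmonic_idx * raw_phase[..., :1]
    # wrap to (-pi, pi]
    phases = np.pi - np.mod(np.pi - rel, 2 * np.pi)
    return amplitudes, phases


def _encode(amplitudes: np.ndarray, phases: np.ndarray, encoding: str) -> np.ndarray:
    """Flatten per-ring features for a batch; shapes (n, R, H+1)/(n, R, H)."""
    n = amplitudes.shape[0]
    if encoding == "raw":
        return np.concatenate(
            [amplitudes.reshape(n, -1), phases.reshape(n, -1)], axis=1
        )
    if encoding == "weighted":
        a = amplitudes[..., 1:]
        return np.concatenate(
            [
                amplitudes.reshape(n, -1),
                (a * np.cos(phases)).reshape(n, -1),
                (a * np.sin(phases)).reshape(n, -1),
            ],
            axis=1,
        )
    raise ValueError(f"unknown encoding {encoding!r}")


def circular_fft(patch: np.ndarray, spec: DiskSpec = DiskSpec()) -> RadialFFTFeatures:
    """Ring-sample a disk patch and take the angular DFT of every ring."""
    patch = np.asarray(patch, dtype=float)
    side = spec.diameter_px
    if patch.shape != (side, side):
        raise ValueError(f"patch must be {side}x{side}, got {patch.shape}")
    r_max = (side - 1) / 2.0
    radii = spec.ring_radii
    if radii[-1] > r_max + 1e-9:
        raise ValueError("ring radius exceeds disk radius")
    c = (side - 1) / 2.0
    theta = 2 * np.pi * np.arange(spec.angles_per_ring) / spec.angles_per_ring
    xs = c + radii[:, None] * np.cos(theta)[None, :]
    ys = c + radii[:, None] * np.sin(theta)[None, :]
    samples = _bilinear(patch, xs, ys)
    amplitudes, phases = _ring_samples_to_features(samples, spec)
    return RadialFFTFeatures(amplitudes=amplitudes, phases=phases)


def features_at_points(
    image: np.ndarray,
    centers: np.ndarray,
    spec: DiskSpec = DiskSpec(),
    chunk: int = 4096,
    encoding: str = "raw",
) -> np.ndarray:
    """Flattened circular-FFT feature vectors at many centers at once.

    Equivalent to ``circular_fft(extract_disk(...)).flatten()`` per center
    but samples rings directly from the full image, chunked to bound
    memory.  ``centers`` is (n, 2) of integer-valued (x, y); every disk
    must fit inside the image.
    """
    centers = np.asarray(centers)
    if centers.ndim != 2 or centers.shape[1] != 2:
        raise ValueError("centers must be (n, 2)")
    h, w = image.shape
    r = spec.radius_px
    cx = np.round(centers[:, 0]).astype(np.intp)
    cy = np.round(centers[:, 1]).astype(np.intp)
    if ((cx < r) | (cy < r) | (cx > w - r) | (cy > h - r)).any():
        raise ValueError("some disks exceed image bounds")
    radii = spec.ring_radii
    theta = 2 * np.pi * np.arange(spec.angles_per_ring) / spec.angles_per_ring
    # Patch center (side-1)/2 maps to image coordinate (c - 0.5): keep the
    # per-patch and whole-image paths bit-comparable.
    dx = (radii[:, None] * np.cos(theta)[None, :]).ravel() - 0.5
    dy = (radii[:, None] * np.sin(theta)[None, :]).ravel() - 0.5
    # The ring offsets are shared by every center, so loop over the (ring,
    # angle) offsets and vectorize the 4-neighbor bilinear gather over
    # centers; center-chunking bounds the sample buffer.
    x0 = np.floor(dx).astype(np.intp)
    y0 = np.floor(dy).astype(np.intp)
    fx = (dx - x0).astype(np.float32)
    fy = (dy - y0).astype(np.float32)
    img = np.asarray(image, dtype=np.float32)
    n_off = len(dx)
    out = np.empty((len(centers), spec.feature_length(encoding)), dtype=np.float32)
    for start in range(0, len(centers), chunk):
        sl = slice(start, min(start + chunk, len(centers)))
        ccx, ccy = cx[sl], cy[sl]
        samples = np.empty((len(ccx), n_off), dtype=np.float32)
        for j in range(n_off):
            ax0 = ccx + x0[j]
            ay0 = ccy + y0[j]
            ax1 = np.minimum(ax0 + 1, w - 1)
            ay1 = np.minimum(ay0 + 1, h - 1)
            wx, wy = fx[j], fy[j]
            samples[:, j] = (
                img[ay0, ax0] * ((1 - wy) * (1 - wx))
                + img[ay0, ax1] * ((1 - wy) * wx)
                + img[ay1, ax0] * (wy * (1 - wx))
                + img[ay1, ax1] * (wy * wx)
            )
        samples = samples.reshape(-1, spec.n_rings, spec.angles_per_ring)
        amplitudes, phases = _ring_samples_to_features(samples, spec)
        out[sl] = _encode(amplitudes, phases, encoding)
    return out


def grid_features(
    image: np.ndarray,
    spec: DiskSpec = DiskSpec(),
    stride_px: int = 2,
    encoding: str = "raw",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Circular-FFT features at every stride-spaced valid disk center.

    Exploits the regular grid: for each fixed (ring, angle) offset the
    bilinear-interpolated values at all centers are weighted sums of four
    strided slices of the image, so no per-center gathering is needed.

    Returns (gx, gy, feats) with feats of shape (len(gy), len(gx),
    n_features), row-major in (y, x).
    """
    if stride_px < 1:
        raise ValueError("stride_px must be >= 1")
    h, w = image.shape
    r = spec.radius_px
    if h < spec.diameter_px or w < spec.diameter_px:
        raise ValueError("image smaller than the sampling disk")
    gx = np.arange(r, w - r + 1, stride_px)
    gy = np.arange(r, h - r + 1, stride_px)
    nx, ny = len(gx), len(gy)
    img = np.asarray(image, dtype=np.float32)
    radii = spec.ring_radii
    theta = 2 * np.pi * np.arange(spec.angles_per_ring) / spec.angles_per_ring
    dx = radii[:, None] * np.cos(theta)[None, :] - 0.5
    dy = radii[:, None] * np.sin(theta)[None, :] - 0.5
    x0 = np.floor(dx).astype(int)
    y0 = np.floor(dy).astype(int)
    fx = (dx - x0).astype(np.float32)
    fy = (dy - y0).astype(np.float32)
    cosM, sinM = _dft_basis(spec, dtype=np.float32)
    n_ang = spec.angles_per_ring
    k = spec.harmonics_kept
    n_amp = spec.n_rings * (k + 1)
    n_ph = spec.n_rings * k
    feats = np.empty((ny * nx, spec.feature_length(encoding)), dtype=np.float32)

    # Contiguous decimated copies, one per (row, col) parity, make the
    # per-offset slices unit-stride and markedly faster to combine.
    s = stride_px
    dec = {
        (py, px): np.ascontiguousarray(img[py::s, px::s])
        for py in range(s)
        for px in range(s)
    }

    def shifted(oy: int, ox: int) -> np.ndarray:
        Y, X = gy[0] + oy, gx[0] + ox
        d = dec[(Y % s, X % s)]
        return d[Y // s : Y // s + ny, X // s : X // s + nx]

    samples = np.empty((ny, nx, n_ang), dtype=np.float32)
    for ring in range(spec.n_rings):
        for a in range(n_ang):
            ox, oy = x0[ring, a], y0[ring, a]
            wx, wy = fx[ring, a], fy[ring, a]
            acc = shifted(oy, ox) * ((1 - wy) * (1 - wx))
            if wx > 0:
                acc += shifted(oy, ox + 1) * ((1 - wy) * wx)
            if wy > 0:
                acc += shifted(oy + 1, ox) * (wy * (1 - wx))
            if wx > 0 and wy > 0:
                acc += shifted(oy + 1, ox + 1) * (wy * wx)
            samples[:, :, a] = acc
        flat = samples.reshape(-1, n_ang)
        re = flat @ cosM
        im = -(flat @ sinM)
        amp = np.hypot(re, im) / n_ang
        raw_phase = np.arctan2(im[:, 1:], re[:, 1:])
        rel = raw_phase - np.arange(1, k + 1, dtype=np.float32) * raw_phase[:, :1]
        ph = np.pi - np.mod(np.pi - rel, 2 * np.pi)
        feats[:, ring * (k + 1) : (ring + 1) * (k + 1)] = amp
        if encoding == "raw":
            feats[:, n_amp + ring * k : n_amp + (ring + 1) * k] = ph
        elif encoding == "weighted":
            a = amp[:, 1:]
            feats[:, n_amp + ring * k : n_amp + (ring + 1) * k] = a * np.cos(ph)
            feats[:, n_amp + n_ph + ring * k : n_amp + n_ph + (ring + 1) * k] = a * np.sin(ph)
        else:
            raise ValueError(f"unknown encoding {encoding!r}")
    return gx, gy, feats.reshape(ny, nx, -1)


# ---------------------------------------------------------------------------
# PCA compression


@dataclass
class PCABasis:
    """Orthonormal PCA basis for the flattened circular-FFT features.

    components: (n_features, n_components), orthonormal columns ordered by
    decreasing explained variance with a deterministic sign convention
    (largest-magnitude loading positive).
    """

    mean: np.ndarray
    components: np.ndarray
    explained_variance_ratio: np.ndarray
    flattening: str = "amplitudes-ring-major,phases-ring-major"

    @property
    def n_components(self) -> int:
        return self.components.shape[1]


def fit_pca(
    X: np.ndarray,
    n_components: int | None = None,
    variance_target: float = 0.95,
) -> PCABasis:
    """Fit a PCA basis; keep ``n_components`` or enough for ``variance_target``."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains non-finite values")
    max_rank = min(X.shape[0] - 1, X.shape[1])
    if n_components is not None:
        if not (1 <= n_components <= max_rank):
            raise ValueError(f"n_components must be in [1, {max_rank}]")
        k = n_components
    else:
        k = variance_target  # sklearn: smallest k reaching the target
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(X)
    comps = pca.components_  # (k, n_features)
    signs = np.sign(comps[np.arange(comps.shape[0]), np.argmax(np.abs(comps), axis=1)])
    signs[signs == 0] = 1.0
    comps = comps * signs[:, None]
    return PCABasis(
        mean=pca.mean_.copy(),
        components=comps.T.copy(),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
    )


def save_basis(basis: PCABasis, path_prefix) -> None:
    """Serialize a basis as flat TSV (mean, components, variance fractions)
    plus a JSON sidecar with dimensions and the flattening order."""
    import json
    from pathlib import Path

    prefix = Path(path_prefix)
    mat = np.vstack([basis.mean[None, :], basis.components.T])
    np.savetxt(prefix.with_suffix(".tsv"), mat, delimiter="\t")
    sidecar = {
        "n_features": int(basis.mean.shape[0]),
        "n_components": int(basis.n_components),
        "flattening": basis.flattening,
        "explained_variance_ratio": [float(v) for v in basis.explained_variance_ratio],
        "layout": "row 0 = mean; rows 1.. = components (one per row)",
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_basis(path_prefix) -> PCABasis:
    import json
    from pathlib import Path

    prefix = Path(path_prefix)
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    mat = np.loadtxt(prefix.with_suffix(".tsv"), delimiter="\t", ndmin=2)
    return PCABasis(
        mean=mat[0],
        components=mat[1:].T,
        explained_variance_ratio=np.array(sidecar["explained_variance_ratio"]),
        flattening=sidecar["flattening"],
    )


def project(x: np.ndarray, basis: PCABasis) -> np.ndarray:
    """Score vector(s) componentsᵀ·(x − mean); accepts (d,) or (n, d)."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != basis.mean.shape[0]:
        raise ValueError(
            f"dimension mismatch: got {x.shape[-1]}, basis expects {basis.mean.shape[0]}"
        )
    return (x - basis.mean) @ basis.components
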