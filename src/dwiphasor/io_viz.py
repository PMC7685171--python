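"""Reading/writing diffusion volumes, phasor-space histograms and polygon
gating.

Diffusion data enter as a 4D NIfTI volume (x, y, z, b) with an FSL-style
`.bval` sidecar (one whitespace-separated line).  Acquisitions with repeated
b-values (e.g. three orthogonal diffusion directions) are geometrically
averaged per b-value on read, then sorted by ascending b.

Phasor maps are visualized as 2D histograms over (g, s) with square bins of
width 1/300 and a log(1 + count) color scale, with the ideal semicircle and
the scheme's sampled monoexponential curve overlaid.  Voxel populations with
a shared decay signature can be selected by a polygon gate drawn in phasor
space; gates are plain CSV vertex lists so a gate defined on one subject can
be reapplied to others.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely

from .phasor import ReferenceCurve, reference_curve, transform_many
from .signals import SamplingScheme

__all__ = [
    "PhasorHistogram",
    "PolygonGate",
    "read_dwi",
    "write_dwi",
    "phasor_histogram",
    "polygon_gate",
    "phasor_coordinates",
    "plot_phasor",
]

DEFAULT_BIN_WIDTH = 1.0 / 300.0


# ---------------------------------------------------------------------------
# NIfTI + bval I/O
# ---------------------------------------------------------------------------

def read_dwi(nifti_path, bval_path) -> tuple[np.ndarray, SamplingScheme, np.ndarray]:
    """Load a 4D diffusion volume and its b-values.

    Duplicate b-values are geometrically averaged voxel-wise (the k-th root
    of the product of the k volumes sharing one b) and volumes are sorted by
    ascending b.  Returns ``(volume4d, scheme, affine)``.
    """
    import nibabel as nib

    img = nib.load(str(nifti_path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 4:
        raise ValueError("expected a 4D diffusion volume")
    bvals = np.atleast_1d(np.loadtxt(str(bval_path), dtype=float))
    if bvals.size != data.shape[-1]:
        raise ValueError("b-value count does not match the 4th volume dimension")
    if np.any(bvals < 0):
        raise ValueError("negative b-values are not allowed")

    unique_b = np.unique(bvals)
    out = np.empty(data.shape[:3] + (unique_b.size,))
    for i, b in enumerate(unique_b):
        sel = data[..., bvals == b]
        k = sel.shape[-1]
        if k == 1:
            out[..., i] = sel[..., 0]
        else:
            sign = np.sign(sel).prod(axis=-1)
            out[..., i] = sign * np.abs(sel).prod(axis=-1) ** (1.0 / k)
    return out, SamplingScheme(tuple(float(b) for b in unique_b)), img.affine


def write_dwi(nifti_path, bval_path, volume4d: np.ndarray, scheme: SamplingScheme,
              affine: np.ndarray | None = None) -> None:
    """Write a 4D volume as NIfTI plus a `.bval` sidecar."""
    import nibabel as nib

    from .signals import write_bval

    volume4d = np.asarray(volume4d, dtype=float)
    if volume4d.ndim != 4 or volume4d.shape[-1] != scheme.n_b:
        raise ValueError("volume must be 4D with last axis matching the scheme")
    img = nib.Nifti1Image(volume4d, np.eye(4) if affine is None else affine)
    nib.save(img, str(nifti_path))
    write_bval(bval_path, scheme)


def phasor_coordinates(volume4d: np.ndarray, scheme: SamplingScheme,
                       mask: np.ndarray | None = None) -> np.ndarray:
    """Per-voxel phasor coordinates of a 4D volume as an (N, 2) array of
    finite (g, s) pairs (masked-out and zero-sum voxels are dropped)."""
    z = transform_many(np.asarray(volume4d, float), scheme)
    if mask is not None:
        z = z[np.asarray(mask, bool)]
    z = z.ravel()
    z = z[np.isfinite(z)]
    return np.column_stack([z.real, z.imag])


# ---------------------------------------------------------------------------
# Phasor histogram
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhasorHistogram:
    """2D count grid over phasor space with origin-anchored square bins.

    ``counts[i, j]`` covers the half-open cell
    [i0+i, i0+i+1) × [j0+j, j0+j+1) in units of ``bin_width``, where
    ``(i0, j0) = origin_index`` along (g, s).
    """

    counts: np.ndarray
    bin_width: float
    origin_index: tuple[int, int]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(g_min, g_max, s_min, s_max) of the covered area."""
        i0, j0 = self.origin_index
        ni, nj = self.counts.shape
        w = self.bin_width
        return (i0 * w, (i0 + ni) * w, j0 * w, (j0 + nj) * w)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def phasor_histogram(points: np.ndarray, bin_width: float = DEFAULT_BIN_WIDTH) -> PhasorHistogram:
    """Bin (g, s) points on a square grid anchored at the origin.

    Binning is half-open, [k·w, (k+1)·w) on both axes, so a point on a bin
    boundary deterministically lands in the higher bin.  The grid covers all
    finite points; the total count equals the number of such points.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    pts = pts[np.isfinite(pts).all(axis=1)]
    if pts.size == 0:
        return PhasorHistogram(np.zeros((1, 1), dtype=np.int64), bin_width, (0, 0))
    idx = np.floor(pts / bin_width).astype(np.int64)
    i0, j0 = idx.min(axis=0)
    shape = idx.max(axis=0) - (i0, j0) + 1
    counts = np.zeros(tuple(shape), dtype=np.int64)
    np.add.at(counts, (idx[:, 0] - i0, idx[:, 1] - j0), 1)
    return PhasorHistogram(counts, float(bin_width), (int(i0), int(j0)))


def plot_phasor(hist: PhasorHistogram, scheme: SamplingScheme | None = None,
                ax=None, ref: ReferenceCurve | None = None):
    """Render a phasor histogram on a log(1 + count) scale.

    Overlays the ideal continuous-sampling semicircle (radius 1/2 centred at
    (1/2, 0)) and, when a scheme is given, its sampled monoexponential curve.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    g_min, g_max, s_min, s_max = hist.extent
    ax.imshow(
        np.log1p(hist.counts).T,
        origin="lower",
        extent=(g_min, g_max, s_min, s_max),
        aspect="equal",
        cmap="viridis",
        interpolation="nearest",
    )
    theta = np.linspace(0, np.pi, 400)
    ax.plot(0.5 + 0.5 * np.cos(theta), 0.5 * np.sin(theta),
            color="tab:blue", lw=1, label="ideal semicircle")
    if scheme is not None or ref is not None:
        if ref is None:
            ref = reference_curve(scheme)
        ax.plot(ref.points.real, ref.points.imag, color="tab:orange", lw=1,
                label="sampled curve")
    ax.set_xlabel("g")
    ax.set_ylabel("s")
    return ax


# ---------------------------------------------------------------------------
# Polygon gating
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PolygonGate:
    """A simple polygon in (g, s) space used to select voxels."""

    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        verts = tuple((float(g), float(s)) for g, s in self.vertices)
        if len(verts) < 3:
            raise ValueError("a gate needs at least 3 vertices")
        if not shapely.LinearRing(verts).is_simple:
            raise ValueError("self-intersecting gate polygons are not allowed")
        object.__setattr__(self, "vertices", verts)

    @classmethod
    def from_csv(cls, path) -> "PolygonGate":
        verts = np.loadtxt(str(path), delimiter=",", ndmin=2)
        return cls(tuple(map(tuple, verts)))

    def to_csv(self, path) -> None:
        np.savetxt(str(path), np.asarray(self.vertices), delimiter=",")


def polygon_gate(points: np.ndarray, gate: PolygonGate) -> np.ndarray:
    """Boolean mask of the (…, 2) phasor points inside the gate.

    Points exactly on the polygon boundary count as inside.  NaN coordinates
    are outside.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[-1] != 2:
        raise ValueError("points must have a trailing (g, s) axis")
    poly = shapely.Polygon(gate.vertices)
    flat = pts.reshape(-1, 2)
    ok = np.isfinite(flat).all(axis=1)
    inside = np.zeros(flat.shape[0], dtype=bool)
    if ok.any():
        geoms = shapely.points(flat[ok])
        inside[ok] = shapely.covers(poly, geoms)
    return inside.reshape(pts.shape[:-1])
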