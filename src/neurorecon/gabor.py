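"""Self-inverting Gabor wavelet codec.

A natural image ``I`` (flattened to a ``p``-vector, ``p = side**2``) is
encoded into a feature vector ``F = G_fwd I`` by a bank of Gabor wavelets
and decoded back with the scaled transpose ``I' = G_rev F``,
``G_rev = alpha * G_fwd.T``.  The bank covers four spatial scales placed on
11x11 / 5x5 / 3x3 / 1x1 grids, four orientations and a quadrature phase
pair, 1248 filters in total on the 32x32 analysis raster (43 degrees of
visual field).  The transform is only approximately self-inverting; the
scalar ``alpha`` is fitted to minimize the round-trip squared error on a
reference image set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np

__all__ = [
    "GaborBankSpec",
    "GaborBank",
    "ImageStack",
    "FeatureMatrix",
    "build_gabor_bank",
    "encode_images",
    "decode_features",
    "fit_reverse_scale",
]


@dataclass(frozen=True)
class GaborBankSpec:
    """Geometry of the wavelet bank.

    ``scales`` are ordered from coarse to fine: each entry gives the nominal
    envelope size (pixels of the pre-downsampling stimulus raster, metadata
    only), the side of the square placement grid, and the carrier spatial
    frequency in cycles/degree.  Spatial frequency must increase as the
    envelope shrinks.
    """

    image_side: int = 32
    field_of_view: float = 43.0
    orientations: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    n_phases: int = 2
    # (envelope px, grid side, cycles/degree), coarse -> fine
    scales: tuple[tuple[int, int, float], ...] = (
        (64, 1, 0.02),
        (32, 3, 0.04),
        (16, 5, 0.09),
        (8, 11, 0.18),
    )
    sigma_factor: float = 0.4  # envelope sigma as a fraction of wavelength
    tight_frame: bool = True  # per-scale gain calibration toward a tight frame

    @property
    def degrees_per_pixel(self) -> float:
        return self.field_of_view / self.image_side

    @property
    def n_pixels(self) -> int:
        return self.image_side**2

    @property
    def n_filters(self) -> int:
        return sum(g * g for _, g, _ in self.scales) * len(self.orientations) * self.n_phases

    def validate(self) -> None:
        if self.image_side <= 0 or self.field_of_view <= 0:
            raise ValueError("image_side and field_of_view must be positive")
        if self.n_phases < 1:
            raise ValueError("need at least one phase")
        if not self.scales:
            raise ValueError("need at least one scale")
        last_cpd = 0.0
        for size, grid, cpd in self.scales:
            if size <= 0 or grid <= 0 or cpd <= 0:
                raise ValueError(f"non-positive scale entry {(size, grid, cpd)}")
            if cpd <= last_cpd:
                raise ValueError("spatial frequency must increase coarse -> fine")
            last_cpd = cpd


@dataclass
class GaborBank:
    """Built filter bank: ``forward`` is f x p, ``reverse = alpha * forward.T``."""

    spec: GaborBankSpec
    forward: np.ndarray
    alpha: float = 1.0
    # per-filter geometry (parallel arrays of length f)
    scale_index: np.ndarray = field(default=None, repr=False)
    center_y: np.ndarray = field(default=None, repr=False)
    center_x: np.ndarray = field(default=None, repr=False)
    orientation: np.ndarray = field(default=None, repr=False)
    phase: np.ndarray = field(default=None, repr=False)
    cpd: np.ndarray = field(default=None, repr=False)

    @property
    def f(self) -> int:
        return self.forward.shape[0]

    @property
    def p(self) -> int:
        return self.forward.shape[1]

    @property
    def reverse(self) -> np.ndarray:
        return self.alpha * self.forward.T

    def filter_image(self, j: int) -> np.ndarray:
        """The j-th filter reshaped to (side, side)."""
        side = self.spec.image_side
        return self.forward[j].reshape(side, side)

    def save(self, path) -> None:
        with h5py.File(path, "w") as h5:
            h5.attrs["schema"] = "neurorecon.gabor_bank/1"
            h5.create_dataset("forward", data=self.forward)
            h5.attrs["alpha"] = self.alpha
            h5.attrs["image_side"] = self.spec.image_side
            h5.attrs["field_of_view"] = self.spec.field_of_view
            h5.attrs["orientations"] = list(self.spec.orientations)
            h5.attrs["n_phases"] = self.spec.n_phases
            h5.attrs["scales"] = [list(s) for s in self.spec.scales]
            h5.attrs["sigma_factor"] = self.spec.sigma_factor
            h5.attrs["tight_frame"] = self.spec.tight_frame
            for name in ("scale_index", "center_y", "center_x", "orientation", "phase", "cpd"):
                h5.create_dataset(name, data=getattr(self, name))

    @classmethod
    def load(cls, path) -> "GaborBank":
        with h5py.File(path, "r") as h5:
            spec = GaborBankSpec(
                image_side=int(h5.attrs["image_side"]),
                field_of_view=float(h5.attrs["field_of_view"]),
                orientations=tuple(float(o) for o in h5.attrs["orientations"]),
                n_phases=int(h5.attrs["n_phases"]),
                scales=tuple(
                    (int(a), int(b), float(c)) for a, b, c in h5.attrs["scales"]
                ),
                sigma_factor=float(h5.attrs["sigma_factor"]),
                tight_frame=bool(h5.attrs["tight_frame"]),
            )
            bank = cls(spec=spec, forward=h5["forward"][()], alpha=float(h5.attrs["alpha"]))
            for name in ("scale_index", "center_y", "center_x", "orientation", "phase", "cpd"):
                setattr(bank, name, h5[name][()])
        return bank


@dataclass
class ImageStack:
    """Flattened grayscale images, ``pixels`` is p x s with gray = 0.

    Values nominally live in [-1, 1] (stimuli) but reconstructions may
    exceed that range; ``clipped()`` gives a render-safe view.  Flattening
    is row-major with the origin at the top-left corner.
    """

    pixels: np.ndarray
    side: int
    degrees_per_pixel: float = 43.0 / 32.0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim == 1:
            self.pixels = self.pixels[:, None]
        if self.pixels.shape[0] != self.side**2:
            raise ValueError(
                f"pixel rows {self.pixels.shape[0]} != side**2 = {self.side ** 2}"
            )

    @property
    def n_images(self) -> int:
        return self.pixels.shape[1]

    def image(self, k: int) -> np.ndarray:
        return self.pixels[:, k].reshape(self.side, self.side)

    def clipped(self) -> "ImageStack":
        return ImageStack(np.clip(self.pixels, -1.0, 1.0), self.side, self.degrees_per_pixel)

    @classmethod
    def from_arrays(cls, images, degrees_per_pixel=43.0 / 32.0) -> "ImageStack":
        """Stack of 2-D arrays (s, side, side) or a single (side, side) image."""
        arr = np.asarray(images, dtype=float)
        if arr.ndim == 2:
            arr = arr[None]
        s, side, side2 = arr.shape
        if side != side2:
            raise ValueError("images must be square")
        return cls(arr.reshape(s, side * side).T, side, degrees_per_pixel)

    @classmethod
    def from_files(cls, paths, side=32, degrees_per_pixel=43.0 / 32.0) -> "ImageStack":
        """Read 8/16-bit grayscale TIFF/PNG files, map linearly to [-1, 1].

        Images are center-cropped to square and block-downsampled to
        ``side`` pixels; mid-gray maps to 0.
        """
        from PIL import Image

        from skimage.transform import resize

        cols = []
        for path in paths:
            img = np.asarray(Image.open(path).convert("I")).astype(float)
            n = min(img.shape)
            y0 = (img.shape[0] - n) // 2
            x0 = (img.shape[1] - n) // 2
            img = img[y0 : y0 + n, x0 : x0 + n]
            img = resize(img, (side, side), anti_aliasing=True)
            vmax = img.max()
            if vmax <= 0:
                cols.append(np.full(side * side, -1.0))
                continue
            cols.append((2.0 * img / vmax - 1.0).ravel())
        return cls(np.array(cols).T, side, degrees_per_pixel)

    def to_tiff(self, path) -> None:
        import tifffile

        side = self.side
        stack = self.pixels.T.reshape(-1, side, side).astype(np.float32)
        tifffile.imwrite(path, stack)


@dataclass
class FeatureMatrix:
    """Gabor feature values, f x s, tied to the bank that produced them."""

    values: np.ndarray
    bank_id: int

    @property
    def f(self) -> int:
        return self.values.shape[0]

    @property
    def n_images(self) -> int:
        return self.values.shape[1]


def _filter_rows(spec: GaborBankSpec):
    """Raw (DC-free, unit-norm) filter rows plus per-filter geometry."""
    side = spec.image_side
    yy, xx = np.mgrid[0:side, 0:side].astype(float)
    rows, geom = [], {k: [] for k in ("scale", "cy", "cx", "orient", "phase", "cpd")}
    phases = [i * np.pi / 2 for i in range(spec.n_phases)]
    for s_idx, (_, grid, cpd) in enumerate(spec.scales):
        lam_px = (1.0 / cpd) / spec.degrees_per_pixel
        sigma = spec.sigma_factor * lam_px
        spacing = side / grid
        centers = (np.arange(grid) + 0.5) * spacing - 0.5
        for cy in centers:
            for cx in centers:
                for theta in spec.orientations:
                    t = np.deg2rad(theta)
                    xr = (xx - cx) * np.cos(t) + (yy - cy) * np.sin(t)
                    yr = -(xx - cx) * np.sin(t) + (yy - cy) * np.cos(t)
                    env = np.exp(-(xr**2 + yr**2) / (2.0 * sigma**2))
                    for ph in phases:
                        g = env * np.cos(2.0 * np.pi * xr / lam_px + ph)
                        g -= g.mean()
                        nrm = np.linalg.norm(g)
                        if nrm == 0:
                            raise ValueError("degenerate filter (zero after DC removal)")
                        rows.append((g / nrm).ravel())
                        geom["scale"].append(s_idx)
                        geom["cy"].append(cy)
                        geom["cx"].append(cx)
                        geom["orient"].append(theta)
                        geom["phase"].append(np.rad2deg(ph))
                        geom["cpd"].append(cpd)
    return np.array(rows), geom


def _tight_frame_gains(forward: np.ndarray, scale_index: np.ndarray) -> np.ndarray:
    """Least-squares per-scale gains making sum_c w_c * Gc^T Gc closest to I."""
    scales = np.unique(scale_index)
    grams = []
    for s in scales:
        G = forward[scale_index == s]
        grams.append(G.T @ G)
    A = np.array([[np.sum(Mi * Mj) for Mj in grams] for Mi in grams])
    b = np.array([np.trace(Mi) for Mi in grams])
    w = np.linalg.solve(A, b)
    if np.any(w <= 0):  # ill-posed geometry; fall back to plain unit-norm rows
        return np.ones(len(scales))
    return np.sqrt(w)


def build_gabor_bank(spec: GaborBankSpec | None = None) -> GaborBank:
    """Construct the bank; ``alpha`` starts at 1 until fitted.

    Filters at each scale sit on an evenly spaced grid with half-spacing
    margins; carrier wavelength realizes the scale's cycles/degree on the
    analysis raster; each filter is DC-removed and L2-normalized, then
    per-scale gains are calibrated toward a tight frame (so that
    ``G_fwd.T G_fwd`` is as close to a multiple of the identity as four
    scalars allow).
    """
    spec = spec or GaborBankSpec()
    spec.validate()
    forward, geom = _filter_rows(spec)
    scale_index = np.array(geom["scale"])
    if spec.tight_frame and len(spec.scales) > 1:
        gains = _tight_frame_gains(forward, scale_index)
        forward = forward * gains[scale_index][:, None]
    return GaborBank(
        spec=spec,
        forward=forward,
        alpha=1.0,
        scale_index=scale_index,
        center_y=np.array(geom["cy"]),
        center_x=np.array(geom["cx"]),
        orientation=np.array(geom["orient"]),
        phase=np.array(geom["phase"]),
        cpd=np.array(geom["cpd"]),
    )


def encode_images(bank: GaborBank, images: ImageStack) -> FeatureMatrix:
    """``F = G_fwd I`` — linear feature transform of an image stack."""
    if images.pixels.shape[0] != bank.p:
        raise ValueError(
            f"image has {images.pixels.shape[0]} pixels, bank expects {bank.p}"
        )
    return FeatureMatrix(bank.forward @ images.pixels, bank_id=id(bank))


def decode_features(bank: GaborBank, feats: FeatureMatrix | np.ndarray) -> ImageStack:
    """``I' = G_rev F = alpha * G_fwd.T F``.  Output is not clipped."""
    values = feats.values if isinstance(feats, FeatureMatrix) else np.asarray(feats, float)
    if values.ndim == 1:
        values = values[:, None]
    if values.shape[0] != bank.f:
        raise ValueError(f"feature rows {values.shape[0]} != bank filters {bank.f}")
    return ImageStack(
        bank.alpha * (bank.forward.T @ values),
        bank.spec.image_side,
        bank.spec.degrees_per_pixel,
    )


def fit_reverse_scale(bank: GaborBank, images: ImageStack) -> GaborBank:
    """Fit ``alpha`` minimizing the summed round-trip squared error.

    The objective ``sum_s || I_s - alpha * G^T G I_s ||^2`` has the closed
    form minimizer ``alpha = <M I, I> / ||M I||^2`` with ``M = G^T G``,
    accumulated over the stack.  Returns a new bank; the input is unchanged.
    """
    if images.n_images < 1:
        raise ValueError("need at least one image")
    M_I = bank.forward.T @ (bank.forward @ images.pixels)
    denom = float(np.sum(M_I * M_I))
    if denom == 0.0:
        raise ValueError("alpha undefined for all-zero images")
    alpha = float(np.sum(M_I * images.pixels)) / denom
    new = replace(bank, alpha=alpha)
    # dataclasses.replace keeps the geometry arrays by reference, which is fine
    return new
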