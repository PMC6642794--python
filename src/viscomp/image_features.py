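"""Image complexity features over HSV channels.

Perceived visual complexity correlates with how much non-redundant
structure an image contains.  The descriptors implemented here quantify
that structure channel by channel:

* **compression error** — the RMS loss incurred by lossy JPEG or fractal
  (quadtree PIFS) coding; complex images compress badly;
* **edge density** — the fraction of pixels marked by a Canny detector;
* **Zipf statistics** — slope and goodness of fit of a log-log line
  through the rank-frequency ("Rank") or value-frequency ("Size")
  distribution of quantized intensities;
* **basic moments** — mean and standard deviation of the plane.

Every descriptor can be evaluated on the raw Hue/Saturation/Value plane
or after an edge-filter preprocessing step (Canny or Sobel, full or
single-axis).  A :class:`FeatureKey` names one (family, filter, channel,
output) combination in the conventional dialect, e.g.
``JPEG(Canny(S),High)`` or ``Rank(NoFilter(S),R2)``.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, replace

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import feature as skfeature
from skimage import filters as skfilters
from skimage.color import rgb2hsv

logger = logging.getLogger(__name__)

# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

FILTER_KINDS = (
    "none",
    "canny_all",
    "canny_h",
    "canny_v",
    "sobel_all",
    "sobel_h",
    "sobel_v",
)

#: Table-style rendering of each filter kind.
_FILTER_TOKEN = {
    "none": "NoFilter",
    "canny_all": "Canny",
    "canny_h": "Canny_h",
    "canny_v": "Canny_v",
    "sobel_all": "Sobel",
    "sobel_h": "Sobel_h",
    "sobel_v": "Sobel_v",
}
_TOKEN_FILTER = {v: k for k, v in _FILTER_TOKEN.items()}

CHANNELS = ("H", "S", "V")
#: Composite channel: mean of Hue and contrast-stretched Saturation.
COMPOSITE_CHANNEL = "H+CS"

LEVELS = ("Low", "Medium", "High")
ZIPF_OUTPUTS = ("M", "R2")

#: JPEG codec quality used for each fidelity level.
JPEG_QUALITY = {"Low": 25, "Medium": 50, "High": 75}

#: Quadtree split tolerance (RMS, [0,1] intensity units) per fidelity level.
#: High fidelity = tight tolerance = deep quadtree = small residual error.
FRACTAL_TOLERANCE = {"Low": 0.15, "Medium": 0.08, "High": 0.02}

#: Number of intensity bins for the Zipf statistics (native 8-bit depth).
ZIPF_BINS = 256


class FormatError(ValueError):
    """Raised when an input image or plane violates the format contract."""


@dataclass(frozen=True)
class StimulusImage:
    """An 8-bit RGB stimulus.

    Parameters
    ----------
    pixels:
        ``H x W x 3`` array of integer intensities in ``[0, 255]``.
    id:
        Stable label used in feature tables.
    """

    pixels: np.ndarray
    id: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise FormatError(f"expected HxWx3 RGB pixels, got shape {px.shape}")
        if px.shape[0] < 8 or px.shape[1] < 8:
            raise FormatError(f"image too small: {px.shape[:2]} (minimum 8x8)")
        if px.min() < 0 or px.max() > 255:
            raise FormatError("intensities must lie in [0, 255]")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @classmethod
    def from_file(cls, path, id: str | None = None) -> "StimulusImage":
        """Load a PNG/JPEG/BMP file, converting to 8-bit RGB."""
        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGB"))
        return cls(pixels=arr, id=id if id is not None else str(path))


@dataclass(frozen=True)
class ChannelPlane:
    """A single real-valued channel of a stimulus, scaled to ``[0, 1]``."""

    values: np.ndarray
    channel: str = "composite"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise FormatError(f"plane must be 2-D, got shape {v.shape}")
        object.__setattr__(self, "values", np.clip(v, 0.0, 1.0))


@dataclass(frozen=True)
class EdgeFilterSpec:
    """Edge-filter preprocessing specification.

    ``canny_*`` kinds produce binary planes via Gaussian smoothing,
    non-maximum suppression and hysteresis; ``sobel_*`` kinds produce the
    gradient magnitude rescaled to ``[0, 1]``.  The ``_h``/``_v`` variants
    use only the corresponding gradient component, i.e. respond only to
    horizontal/vertical edges.  Hysteresis thresholds are quantiles of the
    gradient-magnitude distribution, which keeps the detector parameter-free
    across stimuli of very different contrast.
    """

    kind: str = "canny_all"
    canny_sigma: float = 1.0
    canny_low: float = 0.70
    canny_high: float = 0.90

    def __post_init__(self):
        if self.kind not in FILTER_KINDS:
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.canny_sigma <= 0:
            raise ValueError("canny_sigma must be positive")
        if not (0 <= self.canny_low < self.canny_high <= 1):
            raise ValueError("require 0 <= canny_low < canny_high <= 1")


@dataclass(frozen=True, order=True)
class FeatureKey:
    """Canonical name of one complexity feature.

    Rendered in the conventional ``Family(Filter(Channel),Output)`` dialect,
    e.g. ``JPEG(Canny(S),High)``; families without an output level render as
    ``Family(Filter(Channel))``.
    """

    family: str
    filter: str
    channel: str
    output: str | None = None

    def __post_init__(self):
        if self.family in ("JPEG", "Fractal"):
            if self.output not in LEVELS:
                raise ValueError(f"{self.family} needs output in {LEVELS}")
        elif self.family in ("Size", "Rank"):
            if self.output not in ZIPF_OUTPUTS:
                raise ValueError(f"{self.family} needs output in {ZIPF_OUTPUTS}")
        elif self.family in ("EdgeDensity", "Mean", "StdDev"):
            if self.output is not None:
                raise ValueError(f"{self.family} takes no output level")
        else:
            raise ValueError(f"unknown feature family {self.family!r}")
        if self.filter not in FILTER_KINDS:
            raise ValueError(f"unknown filter kind {self.filter!r}")
        if self.family == "EdgeDensity" and not self.filter.startswith("canny"):
            raise ValueError("EdgeDensity requires a (binary) Canny filter")

    @property
    def name(self) -> str:
        inner = f"{_FILTER_TOKEN[self.filter]}({self.channel})"
        if self.output is None:
            return f"{self.family}({inner})"
        return f"{self.family}({inner},{self.output})"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name

    @classmethod
    def parse(cls, name: str) -> "FeatureKey":
        """Inverse of :attr:`name`."""
        family, sep, rest = name.partition("(")
        if not sep or not rest.endswith(")"):
            raise ValueError(f"unparseable feature name {name!r}")
        inner = rest[:-1]                      # "Canny(S),High" or "Canny(H)"
        filt_tok, sep, chan_rest = inner.partition("(")
        channel, sep, tail = chan_rest.partition(")")
        if filt_tok not in _TOKEN_FILTER or not sep:
            raise ValueError(f"unparseable feature name {name!r}")
        output = tail[1:] if tail.startswith(",") else None
        return cls(family=family, filter=_TOKEN_FILTER[filt_tok],
                   channel=channel, output=output)


@dataclass(frozen=True)
class FeatureVector:
    """Ordered mapping of :class:`FeatureKey` to finite feature values."""

    keys: tuple
    values: np.ndarray
    registry_version: str = "default"

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if len(self.keys) != vals.size:
            raise ValueError("keys/values length mismatch")
        if not np.all(np.isfinite(vals)):
            raise ValueError("feature values must be finite")
        object.__setattr__(self, "values", vals)

    def as_dict(self) -> dict:
        return {k.name: v for k, v in zip(self.keys, self.values)}

    def __len__(self) -> int:
        return len(self.keys)


# --------------------------------------------------------------------------
# channel extraction
# --------------------------------------------------------------------------

def rgb_to_hsv_planes(img: StimulusImage):
    """Split a stimulus into Hue, Saturation and Value planes in [0, 1].

    Hue is treated as an ordinary linear channel (no circular statistics);
    this matches naive channel extraction and is a documented limitation.
    """
    hsv = rgb2hsv(img.pixels)
    return (
        ChannelPlane(hsv[:, :, 0], "H"),
        ChannelPlane(hsv[:, :, 1], "S"),
        ChannelPlane(hsv[:, :, 2], "V"),
    )


def composite_plane(h: ChannelPlane, s: ChannelPlane) -> ChannelPlane:
    """The ``H+CS`` composite: mean of Hue and contrast-stretched Saturation.

    The composite channel appearing in published feature tables is not
    defined in this codebase's sources; this implementation is an explicit,
    documented choice (see the methods note).
    """
    sv = s.values
    rng = sv.max() - sv.min()
    cs = (sv - sv.min()) / rng if rng > 0 else np.zeros_like(sv)
    return ChannelPlane((h.values + cs) / 2.0, COMPOSITE_CHANNEL)


# --------------------------------------------------------------------------
# edge filters
# --------------------------------------------------------------------------

def _directional_canny(values: np.ndarray, axis: int, spec: EdgeFilterSpec) -> np.ndarray:
    """Canny restricted to one gradient axis.

    axis 0 = vertical derivative = response to horizontal edges (``canny_h``);
    axis 1 = horizontal derivative = response to vertical edges (``canny_v``).
    Standard detectors do not expose a single-axis mode, so this implements
    the smoothing / non-maximum-suppression / hysteresis chain directly on
    the one gradient component.
    """
    smoothed = ndimage.gaussian_filter(values, sigma=spec.canny_sigma)
    grad = np.gradient(smoothed, axis=axis)
    mag = np.abs(grad)
    if mag.max() <= 1e-12:
        return np.zeros_like(values)
    # non-maximum suppression along the gradient axis
    before = np.roll(mag, 1, axis=axis)
    after = np.roll(mag, -1, axis=axis)
    if axis == 0:
        before[0, :] = 0.0
        after[-1, :] = 0.0
    else:
        before[:, 0] = 0.0
        after[:, -1] = 0.0
    ridge = (mag >= before) & (mag >= after)
    nms = np.where(ridge, mag, 0.0)
    nz = mag[mag > 0]
    low, high = np.quantile(nz, [spec.canny_low, spec.canny_high])
    if high <= 0:
        return np.zeros_like(values)
    edges = skfilters.apply_hysteresis_threshold(nms, low, high)
    return edges.astype(float)


def apply_edge_filter(plane: ChannelPlane, spec: EdgeFilterSpec) -> ChannelPlane:
    """Apply an edge filter, returning a binary (Canny) or [0,1] (Sobel) plane.

    Degenerate (constant) planes yield an all-zero plane rather than an error.
    """
    if spec.kind == "none":
        raise ValueError("apply_edge_filter requires spec.kind != 'none'")
    v = plane.values
    if np.ptp(v) <= 1e-12:
        return ChannelPlane(np.zeros_like(v), plane.channel)

    if spec.kind == "canny_all":
        edges = skfeature.canny(
            v,
            sigma=spec.canny_sigma,
            low_threshold=spec.canny_low,
            high_threshold=spec.canny_high,
            use_quantiles=True,
        )
        out = edges.astype(float)
    elif spec.kind == "canny_h":
        out = _directional_canny(v, axis=0, spec=spec)
    elif spec.kind == "canny_v":
        out = _directional_canny(v, axis=1, spec=spec)
    else:
        if spec.kind == "sobel_all":
            mag = skfilters.sobel(v)
        elif spec.kind == "sobel_h":
            mag = np.abs(skfilters.sobel_h(v))
        else:  # sobel_v
            mag = np.abs(skfilters.sobel_v(v))
        peak = mag.max()
        out = mag / peak if peak > 0 else np.zeros_like(mag)
    return ChannelPlane(out, plane.channel)


def edge_density(plane: ChannelPlane) -> float:
    """Fraction of pixels marked as edges in a binary plane."""
    v = plane.values
    if not np.all((v == 0.0) | (v == 1.0)):
        raise FormatError("edge_density requires a binary (Canny) plane")
    return float(np.count_nonzero(v) / v.size)


# --------------------------------------------------------------------------
# compression-error families
# --------------------------------------------------------------------------

def jpeg_error(plane: ChannelPlane, level: str = "Medium") -> float:
    """RMS reconstruction error after a JPEG round trip at the given fidelity.

    The plane is quantized to 8 bits, encoded as a grayscale JPEG at the
    codec quality mapped from `level` (Low/Medium/High -> 25/50/75), decoded,
    and compared pixelwise on the [0, 1] scale.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    v8 = np.round(plane.values * 255.0).astype(np.uint8)
    buf = io.BytesIO()
    try:
        Image.fromarray(v8, mode="L").save(buf, format="JPEG",
                                           quality=JPEG_QUALITY[level])
        buf.seek(0)
        decoded = np.asarray(Image.open(buf), dtype=float)
    except OSError as exc:  # pragma: no cover - codec failure
        raise IOError(f"JPEG codec round trip failed: {exc}") from exc
    diff = (v8.astype(float) - decoded) / 255.0
    return float(np.sqrt(np.mean(diff * diff)))


class _FractalCoder:
    """Quadtree PIFS coder used as a complexity probe.

    Range blocks from 16 down to 4 px; domain blocks twice the range size,
    sampled on a grid with step equal to the range size and contracted by
    2x2 averaging; per-block affine intensity map ``s*D + o`` with the
    contrast ``s`` clamped to [-0.9, 0.9] so the decoder is contractive by
    construction.  The reported error is the collage RMS, which is the
    standard deterministic proxy for the reconstruction error.  A block is
    split while its best-fit RMS exceeds the level tolerance; a split is kept
    only if it lowers the summed squared error, which makes the error
    monotone non-increasing as the tolerance tightens Low -> High.
    """

    MAX_RANGE = 16
    MIN_RANGE = 4
    S_CLAMP = 0.9

    def __init__(self, values: np.ndarray):
        h, w = values.shape
        ph = (-h) % self.MAX_RANGE
        pw = (-w) % self.MAX_RANGE
        if ph or pw:
            values = np.pad(values, ((0, ph), (0, pw)), mode="reflect")
        self.values = values
        self._domains: dict[int, tuple] = {}

    def _domain_pool(self, r: int):
        """Contracted domain blocks of size r (from 2r x 2r), flattened."""
        if r in self._domains:
            return self._domains[r]
        v = self.values
        h, w = v.shape
        blocks = []
        d = 2 * r
        for i in range(0, h - d + 1, r):
            for j in range(0, w - d + 1, r):
                sub = v[i:i + d, j:j + d]
                contracted = sub.reshape(r, 2, r, 2).mean(axis=(1, 3))
                blocks.append(contracted.ravel())
        if not blocks:  # plane smaller than one domain: use whole plane scaled
            contracted = _resize_mean(v, r)
            blocks = [contracted.ravel()]
        D = np.asarray(blocks)
        mu = D.mean(axis=1)
        var = D.var(axis=1)
        self._domains[r] = (D, mu, var)
        return self._domains[r]

    def _best_sse(self, block: np.ndarray) -> float:
        """Best collage SSE of one range block over the domain pool."""
        r = block.shape[0]
        D, mu_d, var_d = self._domain_pool(r)
        rb = block.ravel()
        n = rb.size
        mu_r = rb.mean()
        var_r = rb.var()
        cov = D @ rb / n - mu_d * mu_r
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.where(var_d > 0, cov / np.where(var_d > 0, var_d, 1.0), 0.0)
        s = np.clip(s, -self.S_CLAMP, self.S_CLAMP)
        # with optimal offset: SSE = n*(var_r - 2 s cov + s^2 var_d)
        sse = n * (var_r - 2 * s * cov + s * s * var_d)
        return float(max(sse.min(), 0.0))

    def _code_block(self, i: int, j: int, r: int, tol: float) -> float:
        block = self.values[i:i + r, j:j + r]
        sse = self._best_sse(block)
        if r > self.MIN_RANGE and np.sqrt(sse / block.size) > tol:
            half = r // 2
            child = sum(
                self._code_block(i + di, j + dj, half, tol)
                for di in (0, half) for dj in (0, half)
            )
            sse = min(sse, child)
        return sse

    def error(self, tol: float) -> float:
        v = self.values
        total = 0.0
        for i in range(0, v.shape[0], self.MAX_RANGE):
            for j in range(0, v.shape[1], self.MAX_RANGE):
                total += self._code_block(i, j, self.MAX_RANGE, tol)
        return float(np.sqrt(total / v.size))


def _resize_mean(v: np.ndarray, r: int) -> np.ndarray:
    """Block-average v down to an r x r array (pads by reflection if needed)."""
    h, w = v.shape
    ph, pw = (-h) % r, (-w) % r
    if ph or pw:
        v = np.pad(v, ((0, ph), (0, pw)), mode="reflect")
    fh, fw = v.shape[0] // r, v.shape[1] // r
    return v.reshape(r, fh, r, fw).mean(axis=(1, 3))


def fractal_error(plane: ChannelPlane, level: str = "Medium",
                  _coder_cache: dict | None = None) -> float:
    """RMS error of a quadtree PIFS fractal code at the given fidelity level.

    ``level`` selects the quadtree split tolerance (High = tight = deep
    quadtree = small error).  Deterministic for a fixed schedule.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    if _coder_cache is not None and id(plane) in _coder_cache:
        coder = _coder_cache[id(plane)]
    else:
        coder = _FractalCoder(plane.values)
        if _coder_cache is not None:
            _coder_cache[id(plane)] = coder
    return coder.error(FRACTAL_TOLERANCE[level])


# --------------------------------------------------------------------------
# Zipf statistics
# --------------------------------------------------------------------------

def loglog_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares line through (log x, log y); returns (slope, R^2).

    Natural logarithms; inputs must be strictly positive.
    """
    lx = np.log(np.asarray(x, dtype=float))
    ly = np.log(np.asarray(y, dtype=float))
    n = lx.size
    mx, my = lx.mean(), ly.mean()
    sxx = np.sum((lx - mx) ** 2)
    sxy = np.sum((lx - mx) * (ly - my))
    syy = np.sum((ly - my) ** 2)
    if sxx <= 0 or n < 3:
        return 0.0, 0.0
    slope = sxy / sxx
    r2 = (sxy * sxy) / (sxx * syy) if syy > 0 else 1.0
    return float(slope), float(r2)


def _bin_counts(plane: ChannelPlane, bins: int = ZIPF_BINS) -> np.ndarray:
    counts, _ = np.histogram(plane.values, bins=bins, range=(0.0, 1.0))
    return counts


def zipf_rank_metrics(plane: ChannelPlane, bins: int = ZIPF_BINS) -> tuple[float, float]:
    """Zipf rank-frequency statistics of the quantized intensity histogram.

    Bin occupancy counts are sorted in descending order and a line is fit to
    log(count) versus log(rank) over the nonzero bins.  Returns the slope M
    and the R^2 of the fit; fewer than 3 occupied bins yields the (0, 0)
    sentinel with a logged warning.
    """
    counts = np.sort(_bin_counts(plane, bins))[::-1]
    counts = counts[counts > 0]
    if counts.size < 3:
        logger.warning("zipf_rank_metrics: fewer than 3 occupied bins; "
                       "returning (0, 0)")
        return 0.0, 0.0
    ranks = np.arange(1, counts.size + 1)
    return loglog_fit(ranks, counts)


def zipf_size_metrics(plane: ChannelPlane, bins: int = ZIPF_BINS) -> tuple[float, float]:
    """Zipf size-frequency statistics: log(count) versus log(bin value).

    The abscissa for occupied bin i (0-based) is i + 1 so that the darkest
    bin has a finite logarithm.  Same degenerate contract as
    :func:`zipf_rank_metrics`.
    """
    counts = _bin_counts(plane, bins)
    nz = np.nonzero(counts)[0]
    if nz.size < 3:
        logger.warning("zipf_size_metrics: fewer than 3 occupied bins; "
                       "returning (0, 0)")
        return 0.0, 0.0
    return loglog_fit(nz + 1, counts[nz])


def basic_stats(plane: ChannelPlane) -> tuple[float, float]:
    """Arithmetic mean and population standard deviation of the plane."""
    v = plane.values
    return float(v.mean()), float(v.std())


# --------------------------------------------------------------------------
# registry and extraction
# --------------------------------------------------------------------------

def default_registry(edge_spec: EdgeFilterSpec | None = None) -> list[FeatureKey]:
    """The default feature grid.

    Families JPEG/Fractal (3 levels) and Size/Rank (M, R2) are crossed with
    all seven filters and the H/S/V channels; Size/Rank additionally cover
    the unfiltered ``H+CS`` composite channel; EdgeDensity covers the three
    (binary) Canny filters; Mean/StdDev cover all filters.  The exact
    composition of the historical 329-feature set is not recoverable, so the
    registry is configuration, not a constant — its length is whatever the
    grid implies (265 by default).
    """
    keys: list[FeatureKey] = []
    for fam in ("JPEG", "Fractal"):
        for filt in FILTER_KINDS:
            for chan in CHANNELS:
                for lvl in LEVELS:
                    keys.append(FeatureKey(fam, filt, chan, lvl))
    for fam in ("Size", "Rank"):
        for filt in FILTER_KINDS:
            for chan in CHANNELS:
                for out in ZIPF_OUTPUTS:
                    keys.append(FeatureKey(fam, filt, chan, out))
        for out in ZIPF_OUTPUTS:
            keys.append(FeatureKey(fam, "none", COMPOSITE_CHANNEL, out))
    for filt in ("canny_all", "canny_h", "canny_v"):
        for chan in CHANNELS:
            keys.append(FeatureKey("EdgeDensity", filt, chan))
    for fam in ("Mean", "StdDev"):
        for filt in FILTER_KINDS:
            for chan in CHANNELS:
                keys.append(FeatureKey(fam, filt, chan))
    return keys


def extract_features(img: StimulusImage,
                     registry: list[FeatureKey] | None = None,
                     edge_spec: EdgeFilterSpec | None = None) -> FeatureVector:
    """Evaluate every registry entry on one stimulus.

    A pure function of (pixels, registry, edge parameters): the same image
    always yields a bit-identical vector.  Degenerate sub-metrics (constant
    planes, near-empty histograms) produce their documented sentinel values;
    the vector never has holes.
    """
    if registry is None:
        registry = default_registry()
    if edge_spec is None:
        edge_spec = EdgeFilterSpec()

    h, s, v = rgb_to_hsv_planes(img)
    planes = {"H": h, "S": s, "V": v, COMPOSITE_CHANNEL: composite_plane(h, s)}

    filtered: dict[tuple, ChannelPlane] = {}

    def get_plane(filt: str, chan: str) -> ChannelPlane:
        key = (filt, chan)
        if key not in filtered:
            base = planes[chan]
            if filt == "none":
                filtered[key] = base
            else:
                filtered[key] = apply_edge_filter(base, replace(edge_spec, kind=filt))
        return filtered[key]

    coder_cache: dict = {}
    values = np.empty(len(registry))
    for idx, key in enumerate(registry):
        plane = get_plane(key.filter, key.channel)
        if key.family == "JPEG":
            val = jpeg_error(plane, key.output)
        elif key.family == "Fractal":
            val = fractal_error(plane, key.output, _coder_cache=coder_cache)
        elif key.family == "Rank":
            m, r2 = zipf_rank_metrics(plane)
            val = m if key.output == "M" else r2
        elif key.family == "Size":
            m, r2 = zipf_size_metrics(plane)
            val = m if key.output == "M" else r2
        elif key.family == "EdgeDensity":
            val = edge_density(plane)
        elif key.family == "Mean":
            val = basic_stats(plane)[0]
        else:  # StdDev
            val = basic_stats(plane)[1]
        values[idx] = val
    return FeatureVector(keys=tuple(registry), values=values)
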