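"""Parametric visual stimulus synthesis with analytic ground truth.

Three families of grayscale movies (relative luminance in [0, 1], 100 Hz
refresh) drive the model:

* random-dot figure/ground movies at 0.33°/pixel — a textured square, bar,
  edge or theta-motion figure moving over a similarly textured background;
* uniform/grating movies imitating calcium-imaging stimuli (dark bar, small
  object, wide-field square grating, dark bar over a low-contrast grating);
* a synthetic 360° panorama with a superimposed gray bar, a stand-in for
  high-dynamic-range natural scenes, passed through the Naka–Rushton
  light-adaptation transform before compositing.

Every movie carries per-frame boolean ground-truth masks of the foreground
figure, generated analytically from the same displacement bookkeeping that
renders the frames.  Azimuth wraps periodically in all movies so that long
presentations keep the figure in view.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "StimulusSpec",
    "StimulusMovie",
    "michelson_contrast",
    "rms_contrast",
    "naka_rushton",
    "make_dot_texture",
    "make_panorama",
    "make_movie",
    "save_movie",
    "load_movie",
]

KINDS = (
    "square",
    "edge",
    "bar_on_ground",
    "theta",
    "theta_moving_bg",
    "small_obj",
    "bar",
    "wide_field_grating",
    "bar_plus_grating",
    "synthetic_scene_bar",
)

#: kinds whose figure/background are random-dot textures
_TEXTURED = {"square", "edge", "bar_on_ground", "theta", "theta_moving_bg"}


# ---------------------------------------------------------------------------
# contrast and adaptation primitives
# ---------------------------------------------------------------------------

def michelson_contrast(i_max: float, i_min: float) -> float:
    """Michelson contrast (Imax − Imin)/(Imax + Imin) of a two-level pattern.

    Returns 0 for a pair of zero luminances.  Raises for negative luminance
    or an inverted pair.
    """
    if i_min < 0 or i_max < 0:
        raise ValueError("luminance must be nonnegative")
    if i_min > i_max:
        raise ValueError("i_min must not exceed i_max")
    if i_max == 0:
        return 0.0
    return (i_max - i_min) / (i_max + i_min)


def rms_contrast(image: np.ndarray) -> float:
    """RMS contrast C_RMS = I_SD / I_mean (population SD over all pixels)."""
    image = np.asarray(image, dtype=float)
    mean = image.mean()
    if mean <= 0:
        raise ValueError("rms_contrast requires an image with positive mean")
    return float(image.std() / mean)


def naka_rushton(intensity: np.ndarray, i_mean: float, mu: float = 0.7) -> np.ndarray:
    """Naka–Rushton light-adaptation transform I^μ / (I^μ + I_mean^μ).

    Compresses arbitrarily bright inputs into [0, 1), with the half-saturation
    point pinned at the image mean.  ``mu`` is the adaptation exponent.
    """
    if i_mean <= 0:
        raise ValueError("i_mean must be positive")
    if mu <= 0:
        raise ValueError("mu must be positive")
    intensity = np.asarray(intensity, dtype=float)
    if np.any(intensity < 0):
        raise ValueError("luminance must be nonnegative")
    p = np.power(intensity, mu)
    return p / (p + i_mean**mu)


# ---------------------------------------------------------------------------
# textures
# ---------------------------------------------------------------------------

def _delta_i(contrast: float, i0: float) -> float:
    """Luminance half-difference ΔI giving the requested Michelson contrast.

    With two-level dots at I0 ± ΔI the Michelson contrast is ΔI/I0, so
    ΔI = contrast·I0.  Rejects combinations leaving [0, 1].
    """
    if not 0.0 <= contrast <= 1.0:
        raise ValueError("contrast must lie in [0, 1]")
    di = contrast * i0
    if i0 + di > 1.0 + 1e-12 or i0 - di < -1e-12:
        raise ValueError(
            f"contrast {contrast} at mean luminance {i0} leaves the [0, 1] range"
        )
    return di


def make_dot_texture(
    shape: tuple[int, int],
    dot_size_px: int,
    contrast: float,
    i0: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Random black/white dot texture on a fixed block grid.

    Each ``dot_size_px`` × ``dot_size_px`` block is independently I0 + ΔI or
    I0 − ΔI with equal probability, ΔI chosen so the texture's Michelson
    contrast equals ``contrast`` exactly.  Deterministic for a given seed.
    """
    if dot_size_px < 1:
        raise ValueError("dot_size_px must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    di = _delta_i(contrast, i0)
    rows, cols = shape
    brows = -(-rows // dot_size_px)
    bcols = -(-cols // dot_size_px)
    bits = rng.integers(0, 2, size=(brows, bcols))
    blocks = np.where(bits == 1, i0 + di, i0 - di)
    tex = np.kron(blocks, np.ones((dot_size_px, dot_size_px)))
    return tex[:rows, :cols]


def make_panorama(
    shape: tuple[int, int],
    c_rms: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Synthetic natural-scene stand-in: log-normal 1/f-amplitude panorama.

    A Gaussian random field with a 1/f amplitude spectrum (the canonical
    second-order statistic of natural images) is exponentiated into a
    positive, high-dynamic-range luminance map whose RMS contrast is set by
    the log-normal spread: C_RMS = sqrt(exp(s²) − 1) → s = sqrt(ln(1 + C²)).
    Columns wrap periodically (360° azimuth).  This is a synthetic surrogate,
    not a photograph; see docs/methods.md.
    """
    if c_rms <= 0:
        raise ValueError("c_rms must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows, cols = shape
    noise = rng.standard_normal((rows, cols))
    fy = np.fft.fftfreq(rows)[:, None]
    fx = np.fft.fftfreq(cols)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = 1.0
    spec = np.fft.fft2(noise) / f
    spec[0, 0] = 0.0
    z = np.fft.ifft2(spec).real
    z /= z.std()
    s = np.sqrt(np.log1p(c_rms**2))
    scene = np.exp(s * z - s**2 / 2)  # unit mean
    return scene


# ---------------------------------------------------------------------------
# specs and movies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusSpec:
    """Full parametric description of one stimulus movie.

    Speeds are in degrees/second, signed (+ = rightward).
    ``internal_texture_speed`` is the *on-screen* speed of a theta figure's
    internal texture; the slip relative to the envelope is
    internal − figure.  ``figure_start_deg`` is the azimuth of the figure's
    left edge in frame 0.
    """

    kind: str = "bar_on_ground"
    azimuth_extent: float = 180.0
    elevation_extent: float = 90.0
    deg_per_pixel: float = 0.33
    refresh_hz: float = 100.0
    duration_frames: int = 300
    figure_width: float = 25.0
    figure_height: float = 90.0
    figure_speed: float = 66.0
    background_speed: float = 0.0
    internal_texture_speed: float = 0.0
    dot_size: float = 2.6
    michelson_contrast: float = 0.8
    mean_luminance: float = 0.5
    grating_wavelength: float = 17.8
    figure_luminance: float | None = None
    background_luminances: tuple[float, float] = (0.25, 0.75)
    c_rms: float = 1.0
    naka_rushton_mu: float = 0.7
    figure_start_deg: float = 20.0
    rng_seed: int = 0
    mirror: bool = False

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.deg_per_pixel <= 0 or self.refresh_hz <= 0:
            raise ValueError("deg_per_pixel and refresh_hz must be positive")
        if self.duration_frames < 1:
            raise ValueError("duration_frames must be >= 1")

    # -- pixel bookkeeping -------------------------------------------------
    @property
    def frame_shape(self) -> tuple[int, int]:
        return (
            round(self.elevation_extent / self.deg_per_pixel),
            round(self.azimuth_extent / self.deg_per_pixel),
        )

    def px(self, degrees: float) -> int:
        return round(degrees / self.deg_per_pixel)

    def displacement_px(self, speed: float, frame: int) -> int:
        """Accumulated displacement after ``frame`` frames, in whole pixels."""
        return round(speed * frame / (self.refresh_hz * self.deg_per_pixel))

    def mirrored(self) -> "StimulusSpec":
        """Left-right mirrored stimulus: all speeds negated, figure start
        reflected, frames flipped.  Same seed → exactly mirrored movie."""
        return replace(
            self,
            figure_speed=-self.figure_speed,
            background_speed=-self.background_speed,
            internal_texture_speed=-self.internal_texture_speed,
            figure_start_deg=self.azimuth_extent
            - self.figure_start_deg
            - self.figure_width,
            mirror=not self.mirror,
        )


@dataclass
class StimulusMovie:
    """Time-ordered luminance frames with aligned ground-truth masks."""

    frames: np.ndarray  # (T, H, W) float in [0, 1]
    gt_masks: np.ndarray  # (T, H, W) bool, True = foreground
    spec: StimulusSpec

    def __post_init__(self):
        if self.frames.shape != self.gt_masks.shape:
            raise ValueError("frames and gt_masks must share shape")

    def __len__(self) -> int:
        return self.frames.shape[0]


def _warn_if_subpixel(spec: StimulusSpec, *speeds: float) -> None:
    px_per_frame = [s / (spec.refresh_hz * spec.deg_per_pixel) for s in speeds if s]
    bad = [p for p in px_per_frame if abs(p - round(p)) > 1e-9]
    if bad:
        warnings.warn(
            "speed is not a whole number of pixels per frame; displacements "
            "are accumulated and rendered at the nearest pixel",
            stacklevel=3,
        )


def _grating(shape: tuple[int, int], wavelength_px: int, lums: tuple[float, float]) -> np.ndarray:
    """Vertical square-wave grating; columns wrap with period ``wavelength_px``."""
    lo, hi = lums
    cols = np.arange(shape[1])
    phase = (cols % wavelength_px) < (wavelength_px / 2)
    row = np.where(phase, hi, lo)
    return np.broadcast_to(row, shape).copy()


def make_movie(spec: StimulusSpec) -> StimulusMovie:
    """Render a stimulus movie and its analytic ground truth.

    Figure and background displace by whole pixels per frame (accumulated in
    degrees, rounded per frame).  Azimuth is treated as periodic.

    A spec with ``mirror=True`` describes the left-right mirrored movie: the
    canonical (unmirrored) spec is recovered by the same involution that
    :meth:`StimulusSpec.mirrored` applies, rendered, and flipped, so
    ``make_movie(spec.mirrored())`` is exactly the frame-flipped
    ``make_movie(spec)``.
    """
    if spec.mirror:
        canonical = spec.mirrored()  # involution: recovers the unmirrored spec
        movie = make_movie(canonical)
        return StimulusMovie(
            frames=movie.frames[:, :, ::-1].copy(),
            gt_masks=movie.gt_masks[:, :, ::-1].copy(),
            spec=spec,
        )
    H, W = spec.frame_shape
    T = spec.duration_frames
    rng = np.random.default_rng(spec.rng_seed)
    _warn_if_subpixel(
        spec, spec.figure_speed, spec.background_speed, spec.internal_texture_speed
    )

    kind = spec.kind
    frames = np.empty((T, H, W))
    masks = np.zeros((T, H, W), dtype=bool)

    dot_px = max(1, spec.px(spec.dot_size))
    fig_w = spec.px(spec.figure_width)
    fig_h = min(H, spec.px(spec.figure_height))
    r0 = (H - fig_h) // 2
    x0 = spec.px(spec.figure_start_deg)
    wl_px = max(2, spec.px(spec.grating_wavelength))

    # background canvas ------------------------------------------------------
    if kind in _TEXTURED:
        background = make_dot_texture(
            (H, W), dot_px, spec.michelson_contrast, spec.mean_luminance, rng
        )
    elif kind in ("small_obj", "bar"):
        background = np.full((H, W), spec.background_luminances[1])
    elif kind in ("wide_field_grating", "bar_plus_grating"):
        background = _grating((H, W), wl_px, spec.background_luminances)
    elif kind == "synthetic_scene_bar":
        scene = make_panorama((H, W), spec.c_rms, rng)
        background = naka_rushton(scene, float(scene.mean()), spec.naka_rushton_mu)
    else:  # pragma: no cover
        raise AssertionError(kind)

    # figure texture canvas --------------------------------------------------
    # Wide enough for the worst-case texture slip relative to the envelope;
    # indexed modulo its width, which is a whole number of dot blocks so the
    # periodic continuation keeps the block statistics intact.
    has_figure = kind != "wide_field_grating"
    figure_tex = None
    if kind in _TEXTURED:
        slip_total = abs(
            spec.displacement_px(spec.internal_texture_speed, T)
            - spec.displacement_px(spec.figure_speed, T)
        )
        tex_w = -(-(fig_w + slip_total + dot_px) // dot_px) * dot_px
        figure_tex = make_dot_texture(
            (fig_h, tex_w), dot_px, spec.michelson_contrast, spec.mean_luminance, rng
        )
    elif kind in ("small_obj", "bar"):
        figure_tex = np.full((fig_h, fig_w), spec.background_luminances[0])
    elif kind == "bar_plus_grating":
        lum = 0.0 if spec.figure_luminance is None else spec.figure_luminance
        figure_tex = np.full((fig_h, fig_w), lum)
    elif kind == "synthetic_scene_bar":
        lum = 0.5 if spec.figure_luminance is None else spec.figure_luminance
        figure_tex = np.full((fig_h, fig_w), lum)

    for t in range(T):
        bg_off = spec.displacement_px(spec.background_speed, t)
        frame = np.roll(background, bg_off, axis=1)

        if has_figure:
            fig_off = spec.displacement_px(spec.figure_speed, t)
            x = x0 + fig_off
            if kind == "edge":
                # advancing edge: everything left of the edge is figure
                # texture translating rigidly with the edge (no wrap).
                edge_x = int(np.clip(x + fig_w, 0, W))
                cols = np.arange(edge_x)
                tex_cols = (cols - fig_off) % figure_tex.shape[1]
                frame[r0 : r0 + fig_h, :edge_x] = figure_tex[:, tex_cols]
                masks[t, r0 : r0 + fig_h, :edge_x] = True
            else:
                cols = (x + np.arange(fig_w)) % W
                if kind in ("theta", "theta_moving_bg"):
                    tex_off = spec.displacement_px(
                        spec.internal_texture_speed, t
                    ) - fig_off
                    tex_cols = (np.arange(fig_w) - tex_off) % figure_tex.shape[1]
                elif kind in _TEXTURED:
                    tex_cols = np.arange(fig_w) % figure_tex.shape[1]
                else:
                    tex_cols = np.arange(fig_w)
                frame[r0 : r0 + fig_h, cols] = figure_tex[:, tex_cols]
                masks[t, r0 : r0 + fig_h, cols] = True

        frames[t] = frame

    if frames.min() < 0 or frames.max() > 1:  # invariant guard
        raise AssertionError("rendered luminance left [0, 1]")
    return StimulusMovie(frames=frames, gt_masks=masks, spec=spec)


# ---------------------------------------------------------------------------
# disk round trip (numbered PNG frames + YAML sidecar)
# ---------------------------------------------------------------------------

def save_movie(movie: StimulusMovie, directory: str | Path) -> Path:
    """Write frames/masks as 16-bit / 8-bit PNGs with a YAML spec sidecar."""
    import imageio.v3 as iio
    import yaml

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for t, (frame, mask) in enumerate(zip(movie.frames, movie.gt_masks)):
        iio.imwrite(
            directory / f"frame_{t:05d}.png",
            np.round(frame * 65535).astype(np.uint16),
        )
        iio.imwrite(
            directory / f"mask_{t:05d}.png", (mask * 255).astype(np.uint8)
        )
    spec_dict = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in vars(movie.spec).items()
    }
    (directory / "spec.yaml").write_text(yaml.safe_dump(spec_dict))
    return directory


def load_movie(directory: str | Path) -> StimulusMovie:
    """Inverse of :func:`save_movie` (luminance quantized to 16 bits)."""
    import imageio.v3 as iio
    import yaml

    directory = Path(directory)
    spec_dict = yaml.safe_load((directory / "spec.yaml").read_text())
    for k, v in spec_dict.items():
        if isinstance(v, list):
            spec_dict[k] = tuple(v)
    spec = StimulusSpec(**spec_dict)
    frame_files = sorted(directory.glob("frame_*.png"))
    frames = np.stack([iio.imread(f) / 65535.0 for f in frame_files])
    masks = np.stack(
        [iio.imread(f) > 127 for f in sorted(directory.glob("mask_*.png"))]
    )
    return StimulusMovie(frames=frames, gt_masks=masks, spec=spec)
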