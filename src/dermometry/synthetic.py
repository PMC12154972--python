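"""Seeded synthetic microscopy images with exact ground truth.

Two generators emulate the two imaging scales of the dermal-collagen
morphometry study:

* :func:`generate_he_section` — an H&E-like light-microscopy field with a
  dark eosin-stained fibrillar phase and a bright unstained amorphous
  phase at a controlled area fraction. The amorphous phase is a
  thresholded Gaussian random field, so the ground-truth mask is exact.
* :func:`generate_tem_bundle` — a TEM-like field of parallel, wavy
  collagen fibrils (dark) separated by bright interfibrillar gaps, with
  axial D-band intensity modulation, rendered from a sinusoidal bundle
  centerline whose arc length (hence linearity index) is known
  analytically.

:func:`generate_cohort` assembles a full experiment: 2 conditions (CT,
HA) x 2 timepoints (24, 48 h) x 2 dermis layers (papillary, reticular)
x 2 replicates, with per-image parameter jitter standing in for
biological variability and every seed recorded for replay.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.ndimage import gaussian_filter

from .images import CalibratedImage, Polyline

__all__ = [
    "SynthHistologyParams",
    "SynthTemParams",
    "SynthGroundTruth",
    "generate_he_section",
    "generate_tem_bundle",
    "sinusoid_linearity",
    "amplitude_for_linearity",
    "GroupSpec",
    "CohortDesign",
    "CohortItem",
    "control_design",
    "paper_effect_design",
    "generate_cohort",
    "group_label",
]

_QUANT = 65535.0  # images are quantized to 16-bit so disk round trips are exact


def _finish(img: np.ndarray) -> np.ndarray:
    return np.round(np.clip(img, 0.0, 1.0) * _QUANT) / _QUANT


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class SynthHistologyParams:
    """Controls for one synthetic H&E-like dermis field.

    The amorphous (unstained) phase is brighter than the stained fibrillar
    phase; `blob_length_scale_um` sets the correlation length of the
    random field that shapes the amorphous blobs.
    """

    image_size: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.5
    target_amorphous_fraction: float = 0.25
    blob_length_scale_um: float = 6.0
    stained_intensity_mean: float = 0.35
    unstained_intensity_mean: float = 0.85
    noise_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        r, c = self.image_size
        if r < 8 or c < 8:
            raise ValueError("image_size too small")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if not 0.0 <= self.target_amorphous_fraction <= 1.0:
            raise ValueError("target_amorphous_fraction must lie in [0, 1]")
        if self.blob_length_scale_um <= 0:
            raise ValueError("blob_length_scale_um must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        gap = self.unstained_intensity_mean - self.stained_intensity_mean
        if gap < 4.0 * self.noise_sd:
            raise ValueError(
                "phases not separable: unstained - stained mean "
                f"({gap:.3f}) must be >= 4*noise_sd ({4 * self.noise_sd:.3f})"
            )


@dataclass
class SynthTemParams:
    """Controls for one synthetic TEM collagen-bundle field.

    The bundle is `n_fibrils` parallel dark bands of width
    `fibril_diameter_nm` separated by bright gaps of width
    `interfibrillar_gap_nm`, following a sinusoidal centerline
    ``y(x) = A sin(2 pi x / lambda + phase)``; each fibril's intensity is
    modulated along its axis with period `d_period_nm`.
    """

    image_size: tuple[int, int] = (176, 384)
    pixel_size_nm: float = 8.0
    fibril_diameter_nm: float = 80.0
    interfibrillar_gap_nm: float = 20.0
    n_fibrils: int = 5
    d_period_nm: float = 62.0
    d_band_contrast: float = 0.35
    centerline_amplitude_nm: float = 120.0
    centerline_wavelength_nm: float = 1800.0
    centerline_phase: float = 0.0
    fibril_intensity: float = 0.40
    background_intensity: float = 0.85
    noise_sd: float = 0.04
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "pixel_size_nm",
            "fibril_diameter_nm",
            "d_period_nm",
            "centerline_wavelength_nm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.interfibrillar_gap_nm < 0 or self.centerline_amplitude_nm < 0:
            raise ValueError("gap and amplitude must be >= 0")
        if self.n_fibrils < 1:
            raise ValueError("n_fibrils must be >= 1")
        if not 0.0 <= self.d_band_contrast <= 1.0:
            raise ValueError("d_band_contrast must lie in [0, 1]")
        if self.fibril_diameter_nm < 3.0 * self.pixel_size_nm:
            raise ValueError("fibril_diameter_nm must be >= 3 pixels")
        if self.d_period_nm < 4.0 * self.pixel_size_nm:
            raise ValueError("d_period_nm must be >= 4 pixels (Nyquist margin)")
        if self.centerline_wavelength_nm <= 2.0 * self.centerline_amplitude_nm:
            raise ValueError("centerline_wavelength_nm must exceed 2*amplitude")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def bundle_thickness_nm(self) -> float:
        n = self.n_fibrils
        return n * self.fibril_diameter_nm + (n - 1) * self.interfibrillar_gap_nm


@dataclass
class SynthGroundTruth:
    """Generator-side truth paired with each synthetic image.

    Stands in for the expert's manual measurements: the amorphous mask for
    LM fields; centerline geometry, fibril diameters, gaps and D period
    for TEM fields.
    """

    amorphous_mask: np.ndarray | None = None
    centerline: Polyline | None = None
    true_linearity_index: float | None = None
    true_bundle_thickness_nm: float | None = None
    true_fibril_diameters_nm: list[float] = field(default_factory=list)
    true_gaps_nm: list[float] = field(default_factory=list)
    true_d_period_nm: float | None = None

    @property
    def amorphous_fraction(self) -> float:
        if self.amorphous_mask is None:
            raise ValueError("no amorphous mask in this ground truth")
        return float(self.amorphous_mask.mean())


# ---------------------------------------------------------------------------
# light-microscopy generator
# ---------------------------------------------------------------------------

def generate_he_section(
    params: SynthHistologyParams,
) -> tuple[CalibratedImage, SynthGroundTruth]:
    """Render one H&E-like dermis field plus its exact amorphous mask.

    The amorphous phase is obtained by thresholding a smoothed Gaussian
    random field at the quantile matching the target fraction, which
    pins the realized area fraction to the target within one pixel's
    worth of probability mass.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    shape = tuple(params.image_size)

    t = params.target_amorphous_fraction
    if t == 0.0:
        mask = np.zeros(shape, dtype=bool)
    elif t == 1.0:
        mask = np.ones(shape, dtype=bool)
    else:
        sigma_px = params.blob_length_scale_um / params.pixel_size_um
        fld = gaussian_filter(rng.standard_normal(shape), sigma=sigma_px)
        thr = np.quantile(fld, 1.0 - t)
        mask = fld > thr
        realized = mask.mean()
        if abs(realized - t) > 0.01:
            lo = 1.0 / mask.size
            hi = 1.0 - lo
            raise ValueError(
                f"target fraction {t} unreachable at blob scale "
                f"{params.blob_length_scale_um} um (realized {realized:.4f}; "
                f"achievable range about [{lo:.4f}, {hi:.4f}])"
            )

    img = np.where(
        mask, params.unstained_intensity_mean, params.stained_intensity_mean
    ).astype(float)
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, shape)
    image = CalibratedImage(_finish(img), params.pixel_size_um, "LM")
    return image, SynthGroundTruth(amorphous_mask=mask)


# ---------------------------------------------------------------------------
# TEM bundle generator
# ---------------------------------------------------------------------------

def sinusoid_linearity(
    amplitude: float, wavelength: float, span: float, phase: float = 0.0
) -> float:
    """Linearity (tortuosity) index of ``y = A sin(2 pi x/lambda + phase)``
    over ``x in [0, span]``: arc length / chord length, by dense quadrature."""
    if span <= 0:
        raise ValueError("span must be > 0")
    k = 2.0 * math.pi / wavelength
    x = np.linspace(0.0, span, 4096)
    yp = amplitude * k * np.cos(k * x + phase)
    arc = float(np.trapezoid(np.sqrt(1.0 + yp * yp), x))
    dy = amplitude * (math.sin(k * span + phase) - math.sin(phase))
    chord = math.hypot(span, dy)
    return arc / chord


def amplitude_for_linearity(
    target: float, wavelength: float, span: float, phase: float = 0.0
) -> float:
    """Invert :func:`sinusoid_linearity` for the amplitude giving a target
    linearity index (target >= 1)."""
    from scipy.optimize import brentq

    if target < 1.0:
        raise ValueError("linearity index must be >= 1")
    if target == 1.0:
        return 0.0
    hi = wavelength / 2.01  # validity bound: wavelength > 2*amplitude
    f = lambda a: sinusoid_linearity(a, wavelength, span, phase) - target
    if f(hi) < 0:
        raise ValueError("target linearity unreachable at this wavelength")
    return float(brentq(f, 0.0, hi, xtol=1e-6))


def _axial_arclength_nm(params: SynthTemParams, x_nm: np.ndarray) -> np.ndarray:
    """Cumulative arc length of the centerline at each column position."""
    k = 2.0 * math.pi / params.centerline_wavelength_nm
    yp = (
        params.centerline_amplitude_nm
        * k
        * np.cos(k * x_nm + params.centerline_phase)
    )
    ds = np.sqrt(1.0 + yp * yp)
    s = np.concatenate(([0.0], np.cumsum(0.5 * (ds[1:] + ds[:-1]) * np.diff(x_nm))))
    return s


def generate_tem_bundle(
    params: SynthTemParams,
) -> tuple[CalibratedImage, SynthGroundTruth]:
    """Render one TEM-like collagen bundle plus full geometric truth.

    Fibrils are drawn as bands of constant width measured perpendicular
    to the centerline (vertical offsets are corrected by the local slope
    factor), with a one-pixel linear edge ramp for sub-pixel fidelity.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    rows, cols = params.image_size
    px = params.pixel_size_nm
    A = params.centerline_amplitude_nm
    lam = params.centerline_wavelength_nm
    k = 2.0 * math.pi / lam
    ph = params.centerline_phase

    half_extent = params.bundle_thickness_nm / 2.0 + A
    if half_extent + 2 * px > rows * px / 2.0:
        raise ValueError(
            f"bundle (half-extent {half_extent:.0f} nm) exceeds canvas "
            f"({rows * px:.0f} nm tall)"
        )

    x_nm = np.arange(cols) * px
    row_c_nm = (rows - 1) / 2.0 * px
    y0_nm = row_c_nm + A * np.sin(k * x_nm + ph)
    yp = A * k * np.cos(k * x_nm + ph)
    cos_t = 1.0 / np.sqrt(1.0 + yp * yp)

    r_nm = (np.arange(rows) * px)[:, None]
    d_nm = (r_nm - y0_nm[None, :]) * cos_t[None, :]  # approx. normal distance

    D = params.fibril_diameter_nm
    g = params.interfibrillar_gap_nm
    pitch = D + g
    offsets = (np.arange(params.n_fibrils) - (params.n_fibrils - 1) / 2.0) * pitch

    edge = px  # one-pixel ramp
    w = np.zeros((rows, cols))
    for o in offsets:
        w += np.clip((D / 2.0 - np.abs(d_nm - o)) / edge + 0.5, 0.0, 1.0)
    w = np.clip(w, 0.0, 1.0)

    s_nm = _axial_arclength_nm(params, x_nm)
    band = 1.0 + params.d_band_contrast * np.cos(
        2.0 * math.pi * s_nm / params.d_period_nm
    )
    fib = params.fibril_intensity * band  # axial D-band modulation
    img = params.background_intensity + w * (fib[None, :] - params.background_intensity)
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, img.shape)

    centerline = Polyline(np.column_stack((y0_nm / px, np.arange(cols, dtype=float))))
    truth = SynthGroundTruth(
        centerline=centerline,
        true_linearity_index=sinusoid_linearity(A, lam, x_nm[-1], ph),
        true_bundle_thickness_nm=params.bundle_thickness_nm,
        true_fibril_diameters_nm=[D] * params.n_fibrils,
        true_gaps_nm=[g] * (params.n_fibrils - 1),
        true_d_period_nm=params.d_period_nm,
    )
    image = CalibratedImage(_finish(img), px, "TEM")
    return image, truth


# ---------------------------------------------------------------------------
# cohort design
# ---------------------------------------------------------------------------

CONDITIONS = ("CT", "HA")
TIMEPOINTS = (24, 48)
LAYERS = ("papillary", "reticular")
REPLICATES = (1, 2)

IMAGE_KINDS = ("lm", "bundle", "fibril", "dband")


def group_label(condition: str, timepoint: int, layer: str) -> str:
    return f"{condition}-{timepoint}h-{layer}"


@dataclass
class GroupSpec:
    """Generator settings for one condition x timepoint x layer group.

    Scalar fields are group means; the ``*_jitter`` entries are per-image
    spreads standing in for biological variability (SDs for additive
    jitter, CVs for multiplicative jitter).
    """

    amorphous_target: float = 0.25
    amorphous_jitter_sd: float = 0.012
    # bundle-scale regime (8900x analogue)
    bundle_fibril_diameter_nm: float = 90.0
    bundle_gap_nm: float = 18.0
    bundle_n_fibrils: int = 5
    linearity_index: float = 1.05
    # fibril-scale regime (36000x analogue)
    fibril_diameter_nm: float = 85.0
    interfibrillar_gap_nm: float = 18.0
    d_period_nm: float = 62.0
    d_period_jitter_sd_nm: float = 1.2
    size_jitter_cv: float = 0.10
    linearity_jitter_cv: float = 0.25  # applies to (LI - 1)


@dataclass
class CohortDesign:
    """Full experiment design: per-group generator settings plus per-image
    counts and raster/calibration choices shared by all groups."""

    groups: dict[tuple[str, int, str], GroupSpec]
    n_lm: int = 40  # images per group (half per replicate)
    n_bundle: int = 40
    n_fibril: int = 40
    n_dband: int = 100
    lm_image_size: tuple[int, int] = (256, 256)
    lm_pixel_size_um: float = 0.5
    lm_blob_scale_um: float = 6.0
    lm_noise_sd: float = 0.05
    bundle_image_size: tuple[int, int] = (176, 384)
    bundle_pixel_size_nm: float = 8.0
    bundle_wavelength_nm: float = 1800.0
    fibril_image_size: tuple[int, int] = (320, 256)
    fibril_pixel_size_nm: float = 2.0
    fibril_n_fibrils: int = 3
    dband_image_size: tuple[int, int] = (96, 320)
    dband_pixel_size_nm: float = 2.0
    tem_noise_sd: float = 0.04

    def scaled(self, factor: float = 0.5) -> "CohortDesign":
        """A raster-scaled copy for fast simulation studies (group
        parameters and counts untouched)."""
        d = copy.deepcopy(self)
        r, c = d.lm_image_size
        d.lm_image_size = (max(48, int(r * factor)), max(48, int(c * factor)))
        # bundle rows must still hold the bundle; shorten along the axis only
        r, c = d.bundle_image_size
        d.bundle_image_size = (r, max(96, int(c * factor)))
        return d


def _layer_baseline(layer: str) -> GroupSpec:
    # papillary dermis: compact matrix, thin fibrils/bundles, more tortuous;
    # reticular: looser matrix, thick parallel bundles
    if layer == "papillary":
        return GroupSpec(
            amorphous_target=0.135,
            bundle_fibril_diameter_nm=70.0,
            bundle_gap_nm=15.0,
            bundle_n_fibrils=4,
            linearity_index=1.055,
            fibril_diameter_nm=70.0,
            interfibrillar_gap_nm=16.0,
        )
    return GroupSpec(
        amorphous_target=0.23,
        bundle_fibril_diameter_nm=100.0,
        bundle_gap_nm=20.0,
        bundle_n_fibrils=5,
        linearity_index=1.04,
        fibril_diameter_nm=95.0,
        interfibrillar_gap_nm=18.0,
    )


def control_design(**overrides) -> CohortDesign:
    """Null design: HA groups identical to CT at every timepoint/layer."""
    groups = {
        (cond, tp, layer): _layer_baseline(layer)
        for cond in CONDITIONS
        for tp in TIMEPOINTS
        for layer in LAYERS
    }
    return CohortDesign(groups=groups, **overrides)


def paper_effect_design(**overrides) -> CohortDesign:
    """Design encoding the reported HA effects in the reticular dermis at
    24 h: amorphous fraction 0.23 -> 0.28, bundle thickness -10%,
    linearity +5%, fibril diameter +10%, interfibrillar gap -20%, D-band
    period unchanged."""
    design = control_design(**overrides)
    g = design.groups[("HA", 24, "reticular")] = copy.deepcopy(
        design.groups[("HA", 24, "reticular")]
    )
    g.amorphous_target = 0.28
    g.bundle_fibril_diameter_nm *= 0.90  # thickness scales with its parts
    g.bundle_gap_nm *= 0.90
    g.linearity_index = 1.05 * g.linearity_index  # +5% on the index itself
    g.fibril_diameter_nm *= 1.10
    g.interfibrillar_gap_nm *= 0.80
    return design


@dataclass
class CohortItem:
    """One synthetic image with its tags, seed and ground truth."""

    kind: str  # lm | bundle | fibril | dband
    condition: str
    timepoint: int
    layer: str
    replicate: int
    index: int
    seed: int
    image: CalibratedImage
    truth: SynthGroundTruth

    @property
    def group(self) -> str:
        return group_label(self.condition, self.timepoint, self.layer)

    @property
    def name(self) -> str:
        return (
            f"{self.kind}_{self.condition}_{self.timepoint}h_{self.layer}"
            f"_r{self.replicate}_{self.index:03d}"
        )


def _tem_params_for(
    design: CohortDesign, spec: GroupSpec, kind: str, rng: np.random.Generator, seed: int
) -> SynthTemParams:
    jit = lambda mean, cv: float(mean * rng.lognormal(0.0, cv)) if cv > 0 else mean
    if kind == "bundle":
        size, px = design.bundle_image_size, design.bundle_pixel_size_nm
        D = jit(spec.bundle_fibril_diameter_nm, spec.size_jitter_cv)
        g = jit(spec.bundle_gap_nm, spec.size_jitter_cv)
        n = spec.bundle_n_fibrils
        P = spec.d_period_nm  # unresolved at bundle scale; irrelevant
        lam = design.bundle_wavelength_nm
        span = (size[1] - 1) * px
        li = 1.0 + min(jit(spec.linearity_index - 1.0, spec.linearity_jitter_cv), 0.22)
        phase = float(rng.uniform(0.0, 2.0 * math.pi))
        amp = amplitude_for_linearity(li, lam, span, phase)
        contrast = 0.0
    elif kind == "fibril":
        size, px = design.fibril_image_size, design.fibril_pixel_size_nm
        D = jit(spec.fibril_diameter_nm, spec.size_jitter_cv)
        g = max(4 * px, jit(spec.interfibrillar_gap_nm, spec.size_jitter_cv))
        n = design.fibril_n_fibrils
        P = float(rng.normal(spec.d_period_nm, spec.d_period_jitter_sd_nm))
        lam, amp, phase, contrast = 1500.0, 20.0, float(rng.uniform(0, 2 * math.pi)), 0.3
    elif kind == "dband":
        size, px = design.dband_image_size, design.dband_pixel_size_nm
        D = jit(spec.fibril_diameter_nm, spec.size_jitter_cv)
        g, n = 20.0, 1
        P = float(rng.normal(spec.d_period_nm, spec.d_period_jitter_sd_nm))
        lam, amp, phase, contrast = 1500.0, 10.0, float(rng.uniform(0, 2 * math.pi)), 0.4
    else:  # pragma: no cover
        raise ValueError(kind)
    # keep jittered geometry inside the canvas: cap the amplitude, then
    # shrink the cross-section if an extreme draw would still overflow
    max_half = size[0] * px / 2.0 - 3.0 * px
    amp = min(amp, 0.45 * max_half)
    half_bundle = (n * D + (n - 1) * g) / 2.0
    if half_bundle > max_half - amp:
        scale = (max_half - amp) / half_bundle
        D = max(3.0 * px, D * scale)
        g = g * scale
    return SynthTemParams(
        image_size=size,
        pixel_size_nm=px,
        fibril_diameter_nm=D,
        interfibrillar_gap_nm=g,
        n_fibrils=n,
        d_period_nm=P,
        d_band_contrast=contrast,
        centerline_amplitude_nm=amp,
        centerline_wavelength_nm=lam,
        centerline_phase=phase,
        noise_sd=design.tem_noise_sd,
        seed=seed,
    )


def generate_cohort(
    design: CohortDesign,
    master_seed: int,
    kinds: Iterable[str] = IMAGE_KINDS,
    groups: Iterable[tuple[str, int, str]] | None = None,
) -> list[CohortItem]:
    """Generate the full synthetic cohort for a design.

    Every image receives a child seed derived deterministically from
    `master_seed`; per-image parameter jitter is drawn from the same
    child stream, so identical (design, master_seed) pairs reproduce the
    cohort exactly. `kinds`/`groups` restrict generation for targeted
    simulation studies.
    """
    kinds = tuple(kinds)
    wanted = set(groups) if groups is not None else None
    counts = {
        "lm": design.n_lm,
        "bundle": design.n_bundle,
        "fibril": design.n_fibril,
        "dband": design.n_dband,
    }
    items: list[CohortItem] = []
    root = np.random.SeedSequence(master_seed)
    # stable enumeration order -> stable seed assignment
    for gi, (cond, tp, layer) in enumerate(
        (c, t, l) for c in CONDITIONS for t in TIMEPOINTS for l in LAYERS
    ):
        if wanted is not None and (cond, tp, layer) not in wanted:
            continue
        spec = design.groups[(cond, tp, layer)]
        for ki, kind in enumerate(IMAGE_KINDS):
            if kind not in kinds:
                continue
            n = counts[kind]
            for i in range(n):
                child = np.random.SeedSequence(
                    entropy=root.entropy, spawn_key=(gi, ki, i)
                )
                seed = int(child.generate_state(1, np.uint32)[0])
                rng = np.random.default_rng(child)
                replicate = 1 if i < (n + 1) // 2 else 2
                if kind == "lm":
                    tgt = float(
                        np.clip(
                            rng.normal(spec.amorphous_target, spec.amorphous_jitter_sd),
                            0.02,
                            0.6,
                        )
                    )
                    params = SynthHistologyParams(
                        image_size=design.lm_image_size,
                        pixel_size_um=design.lm_pixel_size_um,
                        target_amorphous_fraction=tgt,
                        blob_length_scale_um=design.lm_blob_scale_um,
                        noise_sd=design.lm_noise_sd,
                        seed=seed,
                    )
                    image, truth = generate_he_section(params)
                else:
                    tem = _tem_params_for(design, spec, kind, rng, seed)
                    image, truth = generate_tem_bundle(tem)
                items.append(
                    CohortItem(
                        kind=kind,
                        condition=cond,
                        timepoint=tp,
                        layer=layer,
                        replicate=replicate,
                        index=i,
                        seed=seed,
                        image=image,
                        truth=truth,
                    )
                )
    return items
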