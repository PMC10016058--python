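"""Synthetic intrinsic-signal imaging sessions with known ground truth.

This module generates populations of synthetic mice: for each animal a
ground-truth layout of the four tonotopic auditory areas (A1, VAF, AAF, A2),
each with frequency domains at 3, 10 and 30 kHz; rendered widefield trial
stacks with hemodynamic blur and acquisition noise; and skull reference
marks with a configurable human placement error. Every downstream stage of
the analysis (imaging, segmentation, registration, population statistics)
can therefore be exercised and scored against known truth.

The emulated variability follows the structure of real transcranial
mapping data:

* whole-cortex translation relative to bregma (hundreds of micrometres,
  the dominant inter-animal effect),
* a strain-specific AP shift (CBA cortices sit posterior of B6),
* rotation of the AP/DV axes in the image around 0.370 rad,
* per-animal bregma-lambda distance around 4.2 mm,
* a variable A1-AAF gap that makes the tone low-responsive centre region
  (CTR) present in some animals and absent in others,
* optional dropout of A2/VAF domains (some animals lack clear responses
  to 1-2 of the 3 tones).

Human error in mark placement is modelled as a common translation of the
whole mark triplet (stereotaxic alignment error; the manipulator places
the marks with machine-precise relative spacing) plus an optional small
independent per-mark jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .coords import STANDARD_BLDIST_MM, StereotaxicTransform
from .registration import NOMINAL_MARKS_MM, scaled_reference_coordinates

FREQUENCIES_KHZ = (3.0, 10.0, 30.0)
AREAS = ("A1", "VAF", "AAF", "A2")

#: Canonical domain centres, (AP, DV) mm from bregma, before per-animal
#: variation. Gradient directions encode the field's identification rules:
#: A1 low->high rostrodorsal, VAF rostroventral, AAF caudoventral, A2 a
#: weak ventral gradient between VAF and AAF.
CANONICAL_CENTERS_MM: dict[tuple[str, float], tuple[float, float]] = {
    ("A1", 3.0): (-3.35, 2.55),
    ("A1", 10.0): (-3.10, 2.30),
    ("A1", 30.0): (-2.85, 2.05),
    ("VAF", 3.0): (-3.10, 2.86),
    ("VAF", 10.0): (-2.95, 3.10),
    ("VAF", 30.0): (-2.80, 3.35),
    ("AAF", 3.0): (-2.30, 2.05),
    ("AAF", 10.0): (-2.45, 2.30),
    ("AAF", 30.0): (-2.60, 2.55),
    ("A2", 3.0): (-2.42, 2.85),
    ("A2", 10.0): (-2.40, 2.98),
    ("A2", 30.0): (-2.38, 3.11),
}

#: Relative response amplitude per area (A1 strongest, A2 weakest).
AREA_AMPLITUDE = {"A1": 1.0, "AAF": 0.9, "VAF": 0.75, "A2": 0.65}

#: Canonical border gap between A1 and AAF implied by the canonical centres
#: (mm); the sampled per-animal gap shifts AAF along AP relative to this.
CANONICAL_GAP_MM = 0.25


@dataclass(frozen=True)
class AcquisitionConfig:
    """Widefield acquisition parameters for one synthetic session.

    The defaults are a scaled-down version of a transcranial setup imaging
    a 3.3 x 3.3 mm field of view: one trial is a 1 s baseline, a 1 s tone,
    and a post-stimulus tail, sampled at 16 Hz; responses are quantified
    0.5-2 s from sound onset. ``response_amplitude`` is the peak fractional
    reflectance *decrease* of the strongest domain; ``noise_sd`` is the
    i.i.d. per-pixel per-frame fractional noise.
    """

    frame_rate_hz: float = 16.0
    baseline_s: float = 1.0
    stimulus_s: float = 1.0
    trial_s: float = 3.0
    response_window_s: tuple[float, float] = (0.5, 2.0)
    image_size_px: int = 256
    fov_mm: float = 3.3
    n_trials: int = 16
    response_amplitude: float = 3e-3
    noise_sd: float = 5e-3
    blur_sigma_um: float = 200.0
    baseline_level: float = 1.0

    def validate(self) -> None:
        if self.frame_rate_hz <= 0 or self.image_size_px <= 0 or self.fov_mm <= 0:
            raise ValueError("frame rate, image size and FOV must be positive")
        if self.baseline_s + self.stimulus_s > self.trial_s:
            raise ValueError("trial too short for baseline + stimulus")
        lo, hi = self.response_window_s
        if not (0 <= lo < hi <= self.trial_s - self.baseline_s):
            raise ValueError("response window must lie within the post-onset trial")
        if self.n_trials < 1:
            raise ValueError("need at least one trial")
        if self.noise_sd < 0 or self.blur_sigma_um < 0:
            raise ValueError("noise SD and blur sigma must be >= 0")

    @property
    def pixel_scale_um(self) -> float:
        return self.fov_mm * 1000.0 / self.image_size_px

    @property
    def n_frames(self) -> int:
        return int(round(self.trial_s * self.frame_rate_hz))

    def trials_in_recommended_range(self) -> bool:
        return 6 <= self.n_trials <= 20


@dataclass
class PopulationParams:
    """Distributions from which per-animal ground-truth layouts are drawn.

    All SDs may be set to zero to switch a source of variability off.
    Translation is the whole-cortex offset relative to bregma (per-axis SD
    in micrometres); the rotation prior is N(0.370, 0.011) rad with the
    posterior side down; BLdist is N(4.2, 0.15) mm; the A1-AAF border gap
    is N(250, 150) um clipped at 0 (a zero gap means A1 and AAF abut and
    CTR is absent).
    """

    translation_sd_um: tuple[float, float] = (300.0, 150.0)
    rotation_mean_rad: float = 0.370
    rotation_sd_rad: float = 0.011
    bldist_mean_mm: float = STANDARD_BLDIST_MM
    bldist_sd_mm: float = 0.15
    gap_mean_um: float = 250.0
    gap_sd_um: float = 150.0
    gap_max_um: float = 700.0
    amplitude_jitter: tuple[float, float] = (0.8, 1.2)
    scale_jitter_frac: float = 0.01
    domain_sigma_um: float = 110.0
    convergence_distance_um: float = 400.0
    dropout_p: float = 0.0
    strain_probs: dict = field(
        default_factory=lambda: {
            "B6": 14 / 41,
            "CBA": 13 / 41,
            "PV-Cre x Ai9": 8 / 41,
            "VGAT-Cre x Ai9": 6 / 41,
        }
    )
    strain_ap_shift_mm: dict = field(default_factory=lambda: {"CBA": -0.285})
    sex_probs: dict = field(default_factory=lambda: {"M": 25 / 41, "F": 16 / 41})
    age_range_wk: tuple[float, float] = (6.0, 12.0)

    def validate(self) -> None:
        sds = (*self.translation_sd_um, self.rotation_sd_rad, self.bldist_sd_mm,
               self.gap_sd_um, self.scale_jitter_frac)
        if any(s < 0 for s in sds):
            raise ValueError("distribution SDs must be >= 0")
        if self.bldist_mean_mm <= 0:
            raise ValueError("BLdist mean must be positive")
        if not 0 <= self.dropout_p <= 1:
            raise ValueError("dropout probability must be in [0, 1]")
        for probs, name in ((self.strain_probs, "strain"), (self.sex_probs, "sex")):
            if not probs or abs(sum(probs.values()) - 1.0) > 1e-6:
                raise ValueError(f"{name} probabilities must sum to 1")


@dataclass
class GroundTruthLayout:
    """Ground truth for one synthetic animal.

    ``centers_mm`` holds the bregma-absolute (AP, DV) position of every
    rendered frequency domain; missing (dropped-out) domains are simply
    absent from the dict. The transform fields define how the stereotaxic
    plane is rendered into image pixels; bregma usually lies outside the
    imaged field, as in the real preparation.
    """

    centers_mm: dict[tuple[str, float], np.ndarray]
    amplitudes: dict[tuple[str, float], float]
    rotation_rad: float
    scale_ap_um: float
    scale_dv_um: float
    bldist_mm: float
    bregma_px: np.ndarray
    translation_mm: np.ndarray
    gap_mm: float
    domain_sigma_um: float
    strain: str = "B6"
    sex: str = "M"
    age_wk: float = 9.0
    image_size_px: int = 256

    @property
    def transform(self) -> StereotaxicTransform:
        return StereotaxicTransform(
            theta_rad=self.rotation_rad,
            scale_ap_um=self.scale_ap_um,
            scale_dv_um=self.scale_dv_um,
            bregma_px=self.bregma_px,
            bldist_mm=self.bldist_mm,
        )

    def gradient_direction(self, area: str) -> np.ndarray:
        """Unit low->high tonotopic gradient of ``area`` in (AP, DV) mm."""
        freqs = sorted(f for (a, f) in self.centers_mm if a == area)
        if len(freqs) < 2:
            raise ValueError(f"{area} has fewer than 2 domains")
        lo = self.centers_mm[(area, freqs[0])]
        hi = self.centers_mm[(area, freqs[-1])]
        v = hi - lo
        return v / np.linalg.norm(v)

    def domain_center_px(self, area: str, freq: float) -> np.ndarray:
        return self.transform.mm_to_px(self.centers_mm[(area, freq)])


# ----------------------------------------------------------------------
# population sampling
# ----------------------------------------------------------------------

def _categorical(rng: np.random.Generator, probs: dict) -> str:
    keys = list(probs)
    return keys[rng.choice(len(keys), p=np.array([probs[k] for k in keys]))]


def sample_population_layouts(
    params: PopulationParams | None = None,
    n_mice: int = 1,
    seed: int | np.random.Generator = 0,
    config: AcquisitionConfig | None = None,
) -> list[GroundTruthLayout]:
    """Draw ``n_mice`` ground-truth layouts from the population model.

    Deterministic given the seed. Each layout satisfies the gradient-sign
    conventions of the four areas and keeps the A1 and VAF low-frequency
    poles within the configured convergence distance.
    """
    if n_mice < 1:
        raise ValueError("n_mice must be >= 1")
    params = params or PopulationParams()
    params.validate()
    config = config or AcquisitionConfig()
    config.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    layouts = []
    for _ in range(n_mice):
        strain = _categorical(rng, params.strain_probs)
        sex = _categorical(rng, params.sex_probs)
        age = float(rng.uniform(*params.age_range_wk))
        translation = rng.normal(0.0, 1.0, size=2) * (
            np.asarray(params.translation_sd_um) / 1000.0
        )
        ap_shift = params.strain_ap_shift_mm.get(strain, 0.0)
        rotation = float(rng.normal(params.rotation_mean_rad, params.rotation_sd_rad))
        bldist = float(rng.normal(params.bldist_mean_mm, params.bldist_sd_mm))
        bldist = max(bldist, 0.5)
        gap = float(
            np.clip(rng.normal(params.gap_mean_um, params.gap_sd_um),
                    0.0, params.gap_max_um) / 1000.0
        )
        base_scale = config.pixel_scale_um
        scale_ap = base_scale * float(1.0 + params.scale_jitter_frac * rng.normal())
        scale_dv = base_scale * float(1.0 + params.scale_jitter_frac * rng.normal())

        centers: dict[tuple[str, float], np.ndarray] = {}
        amps: dict[tuple[str, float], float] = {}
        offset = np.array([translation[0] + ap_shift, translation[1]])
        gap_shift = np.array([gap - CANONICAL_GAP_MM, 0.0])
        for (area, freq), base in CANONICAL_CENTERS_MM.items():
            c = np.asarray(base, dtype=float) + offset
            if area == "AAF":
                c = c + gap_shift
            dropped = (
                params.dropout_p > 0
                and area in ("A2", "VAF")
                and freq != 3.0
                and rng.uniform() < params.dropout_p
            )
            amp = AREA_AMPLITUDE[area] * float(rng.uniform(*params.amplitude_jitter))
            if not dropped:
                centers[(area, freq)] = c
                amps[(area, freq)] = amp

        # enforce A1/VAF low-frequency convergence
        d = centers[("VAF", 3.0)] - centers[("A1", 3.0)]
        dist_um = np.linalg.norm(d) * 1000.0
        if dist_um > params.convergence_distance_um:
            centers[("VAF", 3.0)] = (
                centers[("A1", 3.0)]
                + d / np.linalg.norm(d) * params.convergence_distance_um / 1000.0
            )

        layout = GroundTruthLayout(
            centers_mm=centers,
            amplitudes=amps,
            rotation_rad=rotation,
            scale_ap_um=scale_ap,
            scale_dv_um=scale_dv,
            bldist_mm=bldist,
            bregma_px=np.zeros(2),
            translation_mm=offset.copy(),
            gap_mm=gap,
            domain_sigma_um=params.domain_sigma_um,
            strain=strain,
            sex=sex,
            age_wk=age,
            image_size_px=config.image_size_px,
        )
        layout.bregma_px = _frame_bregma(layout, config)
        layouts.append(layout)
    return layouts


def _frame_bregma(layout: GroundTruthLayout, config: AcquisitionConfig) -> np.ndarray:
    """Bregma pixel position that centres the session content in the image.

    Emulates the experimenter framing the field of view on the auditory
    cortex and the nearby skull marks; bregma itself ends up off-image.
    """
    pts = list(layout.centers_mm.values())
    pts.extend(scaled_reference_coordinates(layout.bldist_mm))
    pts = np.asarray(pts)
    target_mm = (pts.min(axis=0) + pts.max(axis=0)) / 2.0
    center_px = np.array([(config.image_size_px - 1) / 2.0] * 2)
    probe = StereotaxicTransform(
        theta_rad=layout.rotation_rad,
        scale_ap_um=layout.scale_ap_um,
        scale_dv_um=layout.scale_dv_um,
        bregma_px=np.zeros(2),
        bldist_mm=layout.bldist_mm,
    )
    return center_px - probe.mm_to_px(target_mm)


# ----------------------------------------------------------------------
# rendering
# ----------------------------------------------------------------------

def render_response_field(
    layout: GroundTruthLayout,
    frequency_khz: float,
    config: AcquisitionConfig | None = None,
) -> np.ndarray:
    """Noiseless fractional-change image for one tone frequency.

    Each present domain contributes an isotropic Gaussian bump of peak
    magnitude ``amplitude * config.response_amplitude``; intrinsic signals
    darken, so values are negative. The field is then convolved with the
    hemodynamic blur kernel.
    """
    config = config or AcquisitionConfig()
    config.validate()
    if frequency_khz not in FREQUENCIES_KHZ:
        raise ValueError(f"unknown stimulus frequency {frequency_khz} kHz")
    n = config.image_size_px
    field_img = np.zeros((n, n), dtype=float)
    scale = np.sqrt(layout.scale_ap_um * layout.scale_dv_um)
    sigma_px = layout.domain_sigma_um / scale
    for (area, freq), center in layout.centers_mm.items():
        if freq != frequency_khz:
            continue
        amp = layout.amplitudes[(area, freq)] * config.response_amplitude
        cx, cy = layout.transform.mm_to_px(center)
        r = int(np.ceil(5 * sigma_px))
        x0, x1 = max(0, int(cx) - r), min(n, int(cx) + r + 1)
        y0, y1 = max(0, int(cy) - r), min(n, int(cy) + r + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        xs = np.arange(x0, x1) - cx
        ys = np.arange(y0, y1) - cy
        g = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2 * sigma_px**2))
        field_img[y0:y1, x0:x1] -= amp * g
    if config.blur_sigma_um > 0:
        field_img = gaussian_filter(
            field_img, config.blur_sigma_um / scale, mode="reflect"
        )
    return field_img


def response_time_course(t_s, peak_s: float = 1.5, shape: float = 2.0):
    """Unit-peak hemodynamic time course, ``t_s`` seconds after tone onset.

    A gamma-shaped kernel peaking ``peak_s`` (default 1.5 s) after onset;
    tone-evoked intrinsic responses peak around 1-2 s after sound onset.
    """
    t = np.asarray(t_s, dtype=float)
    w = np.zeros_like(t)
    pos = t > 0
    tp = t[pos] / peak_s
    w[pos] = tp**shape * np.exp(shape * (1.0 - tp))
    return w


def render_trial_stack(
    field: np.ndarray,
    config: AcquisitionConfig,
    seed: int | np.random.Generator = 0,
    frequency_khz: float | None = None,
):
    """Render repeated trials of one tone into a raw frame stack.

    Frames are ``baseline * (1 + w(t) * field + noise)`` with ``w`` the
    hemodynamic time course (zero during the 1 s baseline) and i.i.d.
    Gaussian pixel noise. Returns a :class:`tonomap.imaging.TrialStack`.
    """
    from .imaging import TrialStack

    config.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_frames = config.n_frames
    t = np.arange(n_frames) / config.frame_rate_hz - config.baseline_s
    w = response_time_course(t).astype(np.float32)
    field32 = np.asarray(field, dtype=np.float32)
    frames = np.empty(
        (config.n_trials, n_frames, *field32.shape), dtype=np.float32
    )
    for trial in range(config.n_trials):
        signal = 1.0 + w[:, None, None] * field32[None, :, :]
        if config.noise_sd > 0:
            signal = signal + rng.standard_normal(
                signal.shape, dtype=np.float32
            ) * np.float32(config.noise_sd)
        frames[trial] = np.float32(config.baseline_level) * signal
    return TrialStack(
        frames=frames,
        frame_rate_hz=config.frame_rate_hz,
        stim_onset_s=config.baseline_s,
        frequency_khz=frequency_khz,
    )


# ----------------------------------------------------------------------
# skull reference marks
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class MarkPlacement:
    """One experimenter's placement of the three skull marks."""

    pixels: np.ndarray  # (3, 2)
    nominal_mm: np.ndarray  # (3, 2) unscaled nominal coordinates
    bldist_mm: float
    in_image: np.ndarray  # (3,) bool

    @property
    def any_outside(self) -> bool:
        return bool(~self.in_image.all())


def place_reference_marks(
    layout: GroundTruthLayout,
    human_error_sd_um: float = 0.0,
    seed: int | np.random.Generator = 0,
    per_mark_jitter_um: float = 0.0,
) -> MarkPlacement:
    """Simulate ink marking of the three stereotaxic reference points.

    The nominal coordinates are scaled by BLdist/4.2 and mapped through the
    layout's true transform into pixels. ``human_error_sd_um`` is applied
    as a common isotropic offset of the whole triplet (alignment error);
    ``per_mark_jitter_um`` adds independent noise per mark (needle touch).
    """
    if human_error_sd_um < 0 or per_mark_jitter_um < 0:
        raise ValueError("error SDs must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scaled = scaled_reference_coordinates(layout.bldist_mm)
    common = rng.normal(0.0, human_error_sd_um / 1000.0, size=2)
    px = layout.transform.mm_to_px(scaled + common)
    if per_mark_jitter_um > 0:
        scale = np.array([layout.scale_ap_um, layout.scale_dv_um]).mean()
        px = px + rng.normal(0.0, per_mark_jitter_um / scale, size=px.shape)
    n = layout.image_size_px
    in_image = ((px >= 0) & (px <= n - 1)).all(axis=1)
    return MarkPlacement(
        pixels=px,
        nominal_mm=NOMINAL_MARKS_MM.copy(),
        bldist_mm=layout.bldist_mm,
        in_image=in_image,
    )


# ----------------------------------------------------------------------
# whole sessions
# ----------------------------------------------------------------------

@dataclass
class SyntheticSession:
    """One synthetic animal: ground truth, trial stacks, and skull marks."""

    layout: GroundTruthLayout
    config: AcquisitionConfig
    stacks: dict  # freq_khz -> TrialStack
    marks: MarkPlacement
    mouse_id: str = "mouse"


def simulate_session(
    layout: GroundTruthLayout,
    config: AcquisitionConfig | None = None,
    seed: int | np.random.Generator = 0,
    human_error_sd_um: float = 100.0,
    mouse_id: str = "mouse",
) -> SyntheticSession:
    """Render the full session (all three tone frequencies) for one layout."""
    config = config or AcquisitionConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    stacks = {
        f: render_trial_stack(
            render_response_field(layout, f, config), config, rng, frequency_khz=f
        )
        for f in FREQUENCIES_KHZ
    }
    marks = place_reference_marks(layout, human_error_sd_um, rng)
    return SyntheticSession(layout, config, stacks, marks, mouse_id)
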