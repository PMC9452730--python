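"""Synthetic two-class block-design BOLD generation.

The generator emulates what a desk-scale stand-in for the acquisition needs:
a "tutor" (healthy reference) whose happy-imagery and motor-imagery
activation patterns define the template, and "patient" subjects whose
patterns resemble the tutor's only up to a controllable spatial fidelity.
Each run is

    baseline * (1 + sum_c pattern_c * (boxcar_c (*) HRF)) + drift + AR(1) noise

on a 3-mm grid (default 20 x 24 x 20 voxels, an ellipsoidal brain support),
with the canonical SPM double-gamma HRF (peak ~6 s, undershoot ~16 s) and a
linear low-frequency drift. Session-to-session learning is modelled as a
per-session increment of the pattern fidelity, capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from nilearn.glm.first_level import compute_regressor
from scipy import ndimage, signal

from .images import BoldRun
from .paradigm import Condition, Paradigm

DEFAULT_SHAPE = (20, 24, 20)
DEFAULT_VOXEL_MM = 3.0
DEFAULT_BASELINE = 100.0
DEFAULT_AMPLITUDE = 0.01  # task signal change, fraction of baseline


def default_affine(
    shape: tuple[int, int, int] = DEFAULT_SHAPE, voxel_mm: float = DEFAULT_VOXEL_MM
) -> np.ndarray:
    """Voxel-to-world affine: isotropic voxels, world origin at grid centre."""
    affine = np.eye(4)
    affine[:3, :3] *= voxel_mm
    affine[:3, 3] = -voxel_mm * (np.asarray(shape) - 1) / 2.0
    return affine


def brain_support(shape: tuple[int, int, int] = DEFAULT_SHAPE) -> np.ndarray:
    """Boolean ellipsoid inscribed in the grid, the simulated brain."""
    coords = np.indices(shape).astype(float)
    centre = (np.asarray(shape, float) - 1) / 2.0
    semi = np.asarray(shape, float) / 2.0 - 0.5
    r2 = sum(((coords[i] - centre[i]) / semi[i]) ** 2 for i in range(3))
    return r2 <= 1.0


def _gaussian_blob(
    shape: tuple[int, int, int], centre_frac: tuple[float, float, float], sigma_vox: float
) -> np.ndarray:
    coords = np.indices(shape).astype(float)
    centre = np.asarray(centre_frac) * (np.asarray(shape) - 1)
    r2 = sum((coords[i] - centre[i]) ** 2 for i in range(3))
    return np.exp(-r2 / (2 * sigma_vox**2))


def tutor_patterns(
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    amplitude: float = DEFAULT_AMPLITUDE,
) -> tuple[np.ndarray, np.ndarray]:
    """Template activation maps (happy, motor), fraction-of-baseline units.

    Two smooth multi-focal patterns in disjoint locations: the happy pattern
    sits anterior-ventral (a stand-in for an emotion network), the motor
    pattern dorsal-posterior (a stand-in for sensorimotor cortex). Both are
    zero outside the brain support.
    """
    support = brain_support(shape)
    happy = (
        _gaussian_blob(shape, (0.35, 0.75, 0.35), 2.0)
        + _gaussian_blob(shape, (0.65, 0.75, 0.35), 2.0)
        + 0.6 * _gaussian_blob(shape, (0.50, 0.60, 0.30), 2.5)
    )
    motor = (
        _gaussian_blob(shape, (0.30, 0.40, 0.75), 2.0)
        + _gaussian_blob(shape, (0.70, 0.40, 0.75), 2.0)
        + 0.6 * _gaussian_blob(shape, (0.50, 0.30, 0.80), 2.5)
    )
    happy = amplitude * happy / happy.max() * support
    motor = amplitude * motor / motor.max() * support
    return happy, motor


def _orthogonalize(field: np.ndarray, templates: list[np.ndarray],
                   support: np.ndarray) -> np.ndarray:
    """Remove from `field` (within support) its projection onto each
    template, after mean-centring, so the Pearson correlations over the
    support are 0. Degenerate (all-zero) templates are skipped."""
    out = np.zeros_like(field)
    f = field[support] - field[support].mean()
    for template in templates:
        t = template[support] - template[support].mean()
        norm = t @ t
        if norm > 0:
            f = f - (f @ t) / norm * t
    out[support] = f
    return out


@dataclass
class SubjectProfile:
    """Generative parameters of one simulated subject.

    ``pattern_fidelity`` is the spatial correlation of the subject's
    activation patterns with the tutor template: 1 reproduces the template
    exactly, 0 gives patterns orthogonal to it. ``learning_rate`` increments
    the fidelity by that amount per training session (capped at 1).
    """

    template_happy: np.ndarray
    template_motor: np.ndarray
    idio_happy: np.ndarray      # orthogonal idiosyncratic component, unit template norm
    idio_motor: np.ndarray
    pattern_fidelity: float
    baseline: np.ndarray        # positive inside support, 0 outside
    noise_sigma: float = 0.5    # stationary SD of the AR(1) noise, intensity units
    ar1_coefficient: float = 0.3
    drift_amplitude: float = 0.5  # peak-to-centre linear drift, intensity units
    learning_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pattern_fidelity <= 1.0:
            raise ValueError("pattern_fidelity must be in [0, 1]")
        if not 0.0 <= self.ar1_coefficient < 1.0:
            raise ValueError("ar1_coefficient must be in [0, 1)")
        for name in ("noise_sigma", "drift_amplitude", "learning_rate"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        for name in ("template_happy", "template_motor", "idio_happy",
                     "idio_motor", "baseline"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.template_happy.shape

    @property
    def support(self) -> np.ndarray:
        return self.baseline > 0

    def fidelity_at_session(self, session: int) -> float:
        if session < 1:
            raise ValueError("session is 1-based")
        return min(1.0, self.pattern_fidelity + (session - 1) * self.learning_rate)

    def patterns_at_session(self, session: int) -> tuple[np.ndarray, np.ndarray]:
        """Fidelity-blended activation maps used at a given session.

        pattern = f * template + sqrt(1 - f^2) * idiosyncratic keeps the
        pattern norm equal to the template norm while its correlation with
        the template equals f.
        """
        f = self.fidelity_at_session(session)
        g = np.sqrt(max(0.0, 1.0 - f * f))
        return (
            f * self.template_happy + g * self.idio_happy,
            f * self.template_motor + g * self.idio_motor,
        )

    @property
    def pattern_happy(self) -> np.ndarray:
        return self.patterns_at_session(1)[0]

    @property
    def pattern_motor(self) -> np.ndarray:
        return self.patterns_at_session(1)[1]


def make_subject_profile(
    pattern_fidelity: float = 1.0,
    seed: int = 0,
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    amplitude: float = DEFAULT_AMPLITUDE,
    baseline_value: float = DEFAULT_BASELINE,
    noise_sigma: float = 0.5,
    ar1_coefficient: float = 0.3,
    drift_amplitude: float = 0.5,
    learning_rate: float = 0.0,
) -> SubjectProfile:
    """Create a subject whose patterns correlate `pattern_fidelity` with the tutor.

    The idiosyncratic component is a seeded smooth random field on the brain
    support, orthogonalized against the template and rescaled to the template
    norm, so blending by fidelity gives exactly the requested correlation.
    """
    support = brain_support(shape)
    t_happy, t_motor = tutor_patterns(shape, amplitude)
    rng = np.random.default_rng(seed)
    idio = []
    for template in (t_happy, t_motor):
        raw = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=1.5)
        # orthogonal to BOTH templates so the subject's happy-minus-motor
        # difference map is also uncorrelated with the tutor's at fidelity 0
        orth = _orthogonalize(raw * support, [t_happy, t_motor], support)
        tc = template[support] - template[support].mean()
        tnorm = np.linalg.norm(tc)
        if tnorm > 0:
            orth *= tnorm / np.linalg.norm(orth[support])
        else:
            orth = np.zeros(shape)
        idio.append(orth * support)
    baseline = np.where(support, baseline_value, 0.0)
    return SubjectProfile(
        template_happy=t_happy,
        template_motor=t_motor,
        idio_happy=idio[0],
        idio_motor=idio[1],
        pattern_fidelity=pattern_fidelity,
        baseline=baseline,
        noise_sigma=noise_sigma,
        ar1_coefficient=ar1_coefficient,
        drift_amplitude=drift_amplitude,
        learning_rate=learning_rate,
    )


def _hrf_steady_state(tr: float) -> float:
    """Sustained response of the SPM HRF to a unit boxcar (the plateau a
    long block settles to), used to scale regressors so that the pattern
    amplitude means percent signal change at plateau."""
    frame_times = np.arange(0, 200.0, tr)
    reg, _ = compute_regressor(np.array([[0.0], [180.0], [1.0]]), "spm", frame_times)
    return float(reg[int(150.0 / tr), 0])


def task_regressors(paradigm: Paradigm) -> dict[Condition, np.ndarray]:
    """Boxcar-convolved-with-SPM-HRF regressor per task condition, sampled
    at volume acquisition times (length n_volumes, plateau ~ 1)."""
    frame_times = np.arange(paradigm.n_volumes) * paradigm.tr_seconds
    scale = _hrf_steady_state(paradigm.tr_seconds)
    out: dict[Condition, np.ndarray] = {}
    for cond in (Condition.HAPPY, Condition.MOTOR):
        onsets = [b.onset_seconds for b in paradigm.blocks if b.condition == cond]
        durations = [b.duration_seconds for b in paradigm.blocks if b.condition == cond]
        if not onsets:
            out[cond] = np.zeros(paradigm.n_volumes)
            continue
        exp_condition = np.array([onsets, durations, [1.0] * len(onsets)])
        reg, _ = compute_regressor(exp_condition, "spm", frame_times)
        out[cond] = reg[:, 0] / scale
    return out


def simulate_run(
    paradigm: Paradigm,
    profile: SubjectProfile,
    session: int = 1,
    seed: int = 0,
) -> BoldRun:
    """Simulate one BOLD run for one subject at one training session.

    Deterministic: identical arguments (including seed) give bit-identical
    data. Noise and drift are confined to the brain support so the outside
    stays exactly zero.
    """
    n = paradigm.n_volumes
    shape = profile.shape
    support = profile.support
    regs = task_regressors(paradigm)
    p_happy, p_motor = profile.patterns_at_session(session)

    task = (
        p_happy[..., None] * regs[Condition.HAPPY][None, None, None, :]
        + p_motor[..., None] * regs[Condition.MOTOR][None, None, None, :]
    )
    data = profile.baseline[..., None] * (1.0 + task)

    if profile.drift_amplitude > 0:
        ramp = np.linspace(-1.0, 1.0, n)
        data[support] += profile.drift_amplitude * ramp[None, :]

    if profile.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        rho = profile.ar1_coefficient
        burn = 50
        innov_sd = profile.noise_sigma * np.sqrt(1.0 - rho * rho)
        eps = rng.standard_normal((int(support.sum()), n + burn)) * innov_sd
        noise = signal.lfilter([1.0], [1.0, -rho], eps, axis=1)[:, burn:]
        data[support] += noise

    return BoldRun(
        data=data,
        affine=default_affine(shape),
        tr_seconds=paradigm.tr_seconds,
        labels=paradigm.volume_labels(),
    )
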