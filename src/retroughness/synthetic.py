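"""Synthetic retinal cohorts with known ground-truth roughness.

Layered macular anatomy is emulated as smooth radial thickness profiles
with a foveal pit on the inner layers, perturbed by fractional Brownian
(fBm) roughness fields with controllable Hurst exponent H (spectral
synthesis; power spectral density proportional to f^-(2H+2), theoretical
surface fractal dimension 3 - H).  Boundary surfaces are built by
cumulative summation of non-negative layer thicknesses from the inner
limiting membrane, which enforces the non-crossing invariant structurally.

Cohorts carry a latent two-factor structure: each subject draws factor
scores (F1, F2) that load onto per-layer roughness amplitudes in two
disjoint layer blocks (inner/neural block vs the photoreceptor-related
outer-segment block), an additive group effect raises amplitudes in the
simulated-disease arm, and covariates (MMSE, visual acuity, age) are
linked to subject roughness with fixed signs: cognition and acuity fall,
age rises, as roughness grows.

Identical seeds produce bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .surfaces_io import LAYER_NAMES, N_LAYERS, ScanGeometry, SurfaceStack

#: layer blocks carrying the two latent factors (1-based layer indices)
FACTOR1_BLOCK = (1, 2, 3, 4, 5, 6, 7, 10)   # inner/neural layers + RPE
FACTOR2_BLOCK = (8, 9)                      # OSL + OPR (photoreceptor-related)


def generate_fbm_field(
    hurst: float,
    rows: int,
    cols: int,
    pixel_pitch_xy: tuple[float, float] = (11.7, 46.9),
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Fractional Brownian surface by Fourier spectral synthesis.

    White Gaussian noise is filtered in the frequency domain with amplitude
    f^-(H+1) (PSD proportional to f^-(2H+2)); the result is normalised to
    zero mean and unit RMS.  Deterministic given ``seed``.
    """
    if not (0.0 < hurst < 1.0):
        raise ValueError(f"hurst must be in (0, 1), got {hurst}")
    if min(rows, cols) < 8:
        raise ValueError("rows and cols must be >= 8")
    if rng is None:
        rng = np.random.default_rng(seed)
    px, py = pixel_pitch_xy
    fy = np.fft.fftfreq(rows, d=py)[:, None]
    fx = np.fft.fftfreq(cols, d=px)[None, :]
    f = np.hypot(fx, fy)
    amp = np.zeros_like(f)
    nonzero = f > 0
    amp[nonzero] = f[nonzero] ** (-(hurst + 1.0))
    noise = rng.standard_normal((rows, cols))
    field_ = np.fft.ifft2(np.fft.fft2(noise) * amp).real
    field_ -= field_.mean()
    rms = np.sqrt(np.mean(field_**2))
    return field_ / rms


@dataclass(frozen=True)
class RadialProfile:
    """Smooth radial layer-thickness profile (um) with an optional foveal pit.

    thickness(r) = base * (1 - pit_depth * exp(-r^2 / (2 sigma^2))), r in um.
    """

    base_um: float
    pit_depth: float = 0.0
    pit_sigma_um: float = 500.0

    def __call__(self, r_um: np.ndarray) -> np.ndarray:
        r = np.asarray(r_um, dtype=float)
        return self.base_um * (
            1.0 - self.pit_depth * np.exp(-(r**2) / (2.0 * self.pit_sigma_um**2))
        )


@dataclass(frozen=True)
class SyntheticLayerSpec:
    """Ground-truth description of one layer's smooth anatomy and roughness."""

    layer_index: int
    base_profile: RadialProfile
    hurst: float = 0.5
    amplitude_um: float = 24.0
    loading_f1: float = 0.0
    loading_f2: float = 0.0

    def __post_init__(self):
        if not (1 <= self.layer_index <= N_LAYERS):
            raise ValueError("layer_index must be in 1..10")
        if not (0.0 < self.hurst < 1.0):
            raise ValueError("hurst must be in (0, 1)")
        if self.amplitude_um < 0:
            raise ValueError("amplitude must be >= 0")


# periphery thickness (um) and foveal-pit depth fraction per layer; the pit
# is applied to the inner layers (1..6) only
_LAYER_ANATOMY = (
    (22.0, 0.85), (36.0, 0.90), (33.0, 0.85), (31.0, 0.70), (26.0, 0.50),
    (68.0, 0.25), (26.0, 0.0), (21.0, 0.0), (18.0, 0.0), (25.0, 0.0),
)

#: roughness-amplitude loadings (um per unit factor score) and residual noise
DEFAULT_LOADING_UM = 3.0
DEFAULT_AMPLITUDE_NOISE_UM = 0.5


def default_layer_specs(
    hurst: float = 0.5,
    amplitude_um: float = 24.0,
    loading_um: float = DEFAULT_LOADING_UM,
) -> list[SyntheticLayerSpec]:
    """The default 10-layer anatomy with two-block factor loadings."""
    specs = []
    for i, (base, pit) in enumerate(_LAYER_ANATOMY, start=1):
        specs.append(
            SyntheticLayerSpec(
                layer_index=i,
                base_profile=RadialProfile(base_um=base, pit_depth=pit),
                hurst=hurst,
                amplitude_um=amplitude_um,
                loading_f1=loading_um if i in FACTOR1_BLOCK else 0.0,
                loading_f2=loading_um if i in FACTOR2_BLOCK else 0.0,
            )
        )
    return specs


@dataclass(frozen=True)
class CovariateModel:
    """Linear Gaussian link of subject roughness to the clinical covariates.

    Slopes are per um of subject roughness-amplitude deviation; signs are
    fixed (cognition and visual acuity fall with roughness, age rises).
    Group means/SDs emulate a mild-disease cohort: MMSE 23.4 +/- 3.1
    (range clipped to [17, 29]) vs 28.4 +/- 2.0 ([25, 31]); age about
    79 vs 76 years; visual acuity on a decimal scale.
    """

    mmse_slope: float = -1.0
    va_slope: float = -0.10
    age_slope: float = 1.5
    mmse_sd: float = 2.0
    va_sd: float = 0.10
    age_sd: float = 3.0
    mmse_mean_ad: float = 23.4
    mmse_mean_ctl: float = 28.4
    mmse_range_ad: tuple[float, float] = (17.0, 29.0)
    mmse_range_ctl: tuple[float, float] = (25.0, 31.0)
    va_mean: float = 0.9
    age_mean_ad: float = 79.2
    age_mean_ctl: float = 75.7


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters of a synthetic cohort."""

    n_ad: int = 19
    n_ctl: int = 24
    group_roughness_effect_um: float = 1.8
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    layer_specs: tuple[SyntheticLayerSpec, ...] | None = None
    amplitude_noise_um: float = DEFAULT_AMPLITUDE_NOISE_UM
    seed: int = 0

    def __post_init__(self):
        if min(self.n_ad, self.n_ctl) < 2:
            raise ValueError("need at least 2 subjects per group")

    def specs(self) -> list[SyntheticLayerSpec]:
        return list(self.layer_specs) if self.layer_specs else default_layer_specs()


@dataclass
class CohortData:
    """A sampled cohort: ground-truth amplitudes, covariates, optional stacks."""

    spec: CohortSpec
    covariates: pd.DataFrame
    amplitudes: pd.DataFrame           # subjects x 10, roughness amplitude (um)
    factor_scores: pd.DataFrame        # subjects x (F1, F2)
    stacks: list[SurfaceStack] | None = None

    @property
    def subject_ids(self) -> list[str]:
        return list(self.covariates.index)


def sample_cohort_params(spec: CohortSpec) -> CohortData:
    """Draw latent factors, roughness amplitudes and covariates (no imaging).

    Per-layer roughness amplitude of subject i is

        amp = base + loading_f1 * F1_i + loading_f2 * F2_i
                   + group_effect * [i in disease arm] + noise,   floored at 0,

    with F1, F2 independent standard normals.  Covariates follow the linear
    Gaussian model of :class:`CovariateModel`, driven by the subject's mean
    amplitude deviation from the smooth baseline.
    """
    specs = spec.specs()
    if len(specs) != N_LAYERS:
        raise ValueError(f"need exactly {N_LAYERS} layer specs")
    n = spec.n_ad + spec.n_ctl
    root = np.random.SeedSequence(spec.seed)
    cov_ss, *_ = root.spawn(1)
    rng = np.random.default_rng(cov_ss)

    groups = ["AD"] * spec.n_ad + ["CTL"] * spec.n_ctl
    ids = [f"S{i + 1:03d}" for i in range(n)]
    f_scores = rng.standard_normal((n, 2))
    noise = rng.standard_normal((n, N_LAYERS)) * spec.amplitude_noise_um
    base = np.array([s.amplitude_um for s in specs])
    l1 = np.array([s.loading_f1 for s in specs])
    l2 = np.array([s.loading_f2 for s in specs])
    is_ad = np.array([g == "AD" for g in groups], dtype=float)
    amp = (
        base[None, :]
        + f_scores[:, [0]] * l1[None, :]
        + f_scores[:, [1]] * l2[None, :]
        + is_ad[:, None] * spec.group_roughness_effect_um
        + noise
    )
    amp = np.clip(amp, 0.0, None)

    cm = spec.covariate_model
    dev = amp.mean(axis=1) - base.mean()
    mmse = np.where(is_ad > 0, cm.mmse_mean_ad, cm.mmse_mean_ctl)
    mmse = mmse + cm.mmse_slope * dev + rng.standard_normal(n) * cm.mmse_sd
    mmse = np.where(
        is_ad > 0,
        np.clip(mmse, *cm.mmse_range_ad),
        np.clip(mmse, *cm.mmse_range_ctl),
    )
    va = cm.va_mean + cm.va_slope * dev + rng.standard_normal(n) * cm.va_sd
    va = np.clip(va, 0.1, 1.5)
    age = np.where(is_ad > 0, cm.age_mean_ad, cm.age_mean_ctl)
    age = age + cm.age_slope * dev + rng.standard_normal(n) * cm.age_sd
    age = np.clip(age, 60.0, 95.0)

    covariates = pd.DataFrame(
        {
            "group": groups,
            "mmse": np.round(mmse, 1),
            "visual_acuity": np.round(va, 2),
            "age": np.round(age, 1),
        },
        index=pd.Index(ids, name="subject_id"),
    )
    amplitudes = pd.DataFrame(
        amp, index=covariates.index,
        columns=[f"amp_layer_{k}" for k in range(1, N_LAYERS + 1)],
    )
    factor_scores = pd.DataFrame(
        f_scores, index=covariates.index, columns=["F1", "F2"]
    )
    return CohortData(
        spec=spec, covariates=covariates, amplitudes=amplitudes,
        factor_scores=factor_scores, stacks=None,
    )


def generate_surface_stack(
    specs: list[SyntheticLayerSpec],
    subject_amplitudes: np.ndarray,
    geometry: ScanGeometry = ScanGeometry(),
    seed: int | np.random.SeedSequence = 0,
    subject_id: str = "",
    landmark_jitter_px: float = 1.5,
    axis_length_um: float | None = None,
    axis_tilt_deg: float | None = None,
    return_fields: bool = False,
):
    """Render one subject's 11 boundary surfaces.

    Layer thickness = radial base profile + amplitude-scaled fBm roughness,
    clipped at 0; surfaces are the cumulative sums of the thicknesses below
    the inner limiting membrane, so surface k+1 is never above surface k.
    The fovea sits at the grid center (with a small jitter) and the papilla
    landmark at the subject's maculopapillary axis end (it may fall outside
    the scanned grid).  When ``return_fields`` is True the pre-clip
    thickness fields are also returned for generator bookkeeping.
    """
    if len(specs) != N_LAYERS:
        raise ValueError(f"need exactly {N_LAYERS} layer specs")
    amps = np.asarray(subject_amplitudes, dtype=float)
    if amps.shape != (N_LAYERS,):
        raise ValueError("subject_amplitudes must have one entry per layer")
    if (amps < 0).any():
        raise ValueError("amplitudes must be >= 0")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    rows, cols = geometry.shape
    px, py = geometry.pixel_pitch_x, geometry.pixel_pitch_y

    fovea_r = (rows - 1) / 2.0 + rng.uniform(-landmark_jitter_px, landmark_jitter_px)
    fovea_c = (cols - 1) / 2.0 + rng.uniform(-landmark_jitter_px, landmark_jitter_px)
    length = axis_length_um if axis_length_um is not None else rng.normal(4377.0, 120.0)
    tilt = np.radians(
        axis_tilt_deg if axis_tilt_deg is not None else rng.normal(6.766, 1.0)
    )
    papilla_r = fovea_r + length * np.sin(tilt) / py
    papilla_c = fovea_c + length * np.cos(tilt) / px

    yy = (np.arange(rows)[:, None] - fovea_r) * py
    xx = (np.arange(cols)[None, :] - fovea_c) * px
    r_um = np.hypot(xx, yy)

    # mild posterior-pole curvature of the inner limiting membrane
    ilm = 40.0 * (r_um / 3000.0) ** 2
    surfaces = np.empty((11, rows, cols))
    surfaces[0] = ilm
    fields = {}
    z = ilm.copy()
    for k, spec_k in enumerate(specs):
        base = spec_k.base_profile(r_um)
        rough = generate_fbm_field(
            spec_k.hurst, rows, cols, (px, py), rng=rng
        )
        t_pre = base + amps[k] * rough
        if return_fields:
            fields[spec_k.layer_index] = t_pre
        z = z + np.clip(t_pre, 0.0, None)
        surfaces[k + 1] = z

    stack = SurfaceStack(
        geometry=geometry,
        surfaces=surfaces,
        valid_mask=np.ones((rows, cols), dtype=bool),
        fovea_rc=(float(fovea_r), float(fovea_c)),
        papilla_rc=(float(papilla_r), float(papilla_c)),
        subject_id=subject_id,
    )
    stack.validate()
    return (stack, fields) if return_fields else stack


def generate_cohort(
    spec: CohortSpec, geometry: ScanGeometry = ScanGeometry()
) -> CohortData:
    """Sample a cohort and render each subject's surface stack."""
    data = sample_cohort_params(spec)
    root = np.random.SeedSequence(spec.seed)
    subject_ss = root.spawn(1 + len(data.subject_ids))[1:]
    stacks = []
    for i, subj in enumerate(data.subject_ids):
        stacks.append(
            generate_surface_stack(
                spec.specs(),
                data.amplitudes.iloc[i].to_numpy(),
                geometry=geometry,
                seed=subject_ss[i],
                subject_id=subj,
            )
        )
    data.stacks = stacks
    return data


def generate_layer_maps(
    spec: CohortSpec, side_px: int = 64, pitch_um: float = 40.0
) -> tuple[dict[tuple[str, int], np.ndarray], CohortData]:
    """Reduced-scale cohort: fovea-centred isotropic layer maps, no imaging.

    Renders each subject's 10 layer thickness maps directly on a small
    ``side_px`` x ``side_px`` grid (skipping surface stacking, tilt
    correction and resampling, which are identities for these maps), for
    replicate-heavy calibration studies.  Returns the map dictionary keyed
    by (subject_id, layer_index) together with the sampled cohort.
    """
    data = sample_cohort_params(spec)
    specs = spec.specs()
    root = np.random.SeedSequence(spec.seed)
    subject_ss = root.spawn(1 + len(data.subject_ids))[1:]
    half = (side_px - 1) / 2.0
    ax = (np.arange(side_px) - half) * pitch_um
    r_um = np.hypot(ax[:, None], ax[None, :])
    maps: dict[tuple[str, int], np.ndarray] = {}
    for i, subj in enumerate(data.subject_ids):
        rng = np.random.default_rng(subject_ss[i])
        amps = data.amplitudes.iloc[i].to_numpy()
        for k, spec_k in enumerate(specs):
            base = spec_k.base_profile(r_um)
            rough = generate_fbm_field(
                spec_k.hurst, side_px, side_px, (pitch_um, pitch_um), rng=rng
            )
            maps[(subj, spec_k.layer_index)] = np.clip(
                base + amps[k] * rough, 0.0, None
            )
    return maps, data


def write_cohort(data: CohortData, out_dir) -> None:
    """Write stacks (HDF5) and the covariate CSV of a rendered cohort."""
    from pathlib import Path

    from .surfaces_io import write_stack

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if data.stacks is None:
        raise ValueError("cohort has no rendered stacks")
    for stack in data.stacks:
        write_stack(stack, out / f"{stack.subject_id}.h5")
    cov = data.covariates.reset_index()
    cov.to_csv(out / "covariates.csv", index=False)
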