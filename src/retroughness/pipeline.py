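"""End-to-end orchestration: stacks -> thickness -> normalization -> FD -> statistics.

``run_pipeline`` executes the full post-segmentation analysis for a cohort
(synthetic or read from a stack directory): left-eye flip, per-layer
cosine-corrected thickness, spatial normalization to the canonical macular
frame, central-ROI extraction, grayscale box-counting fractal dimension,
group comparisons, the roughness correlation matrix and the two-factor
model.  Per-stage failures are attributed to (subject, layer, stage) and
the run continues; results, exclusion accounting and timings are written
to a manifest so a run is reproducible from its config and seed alone.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import factors as fct
from . import stats as st
from .fd import BoxCountingConfig, fractal_dimension, robustness_configs
from .normalize import NormalizationParams, central_roi, resample, similarity_transform
from .surfaces_io import N_LAYERS, SurfaceStack, flip_left_eye, read_stack
from .synthetic import CohortSpec, generate_cohort, generate_layer_maps, sample_cohort_params
from .thickness import orthogonal_thickness, raw_thickness, total_retina_thickness


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    cohort: CohortSpec | None = None          # synthetic source ...
    stack_dir: str | None = None              # ... or a directory of stack files
    covariates_csv: str | None = None
    normalization: NormalizationParams = field(default_factory=NormalizationParams)
    box_counting: BoxCountingConfig = field(default_factory=BoxCountingConfig)
    robustness: bool = False
    out_dir: str | None = None
    seed: int = 0

    def cache_key(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    fd_table: pd.DataFrame
    group_stats: dict
    correlations: dict
    factor_model: fct.FactorModel | None
    manifest: dict
    robustness_report: dict | None = None


def process_stack(
    stack: SurfaceStack,
    normalization: NormalizationParams,
    box_counting: BoxCountingConfig,
) -> tuple[dict[int, float], float]:
    """FD of every layer of one stack (plus total retina FD).

    Raises with a stage-labelled message on the first failing layer.
    """
    if stack.geometry.eye == "left":
        stack = flip_left_eye(stack)
    transform = similarity_transform(
        stack.fovea_rc, stack.papilla_rc, stack.geometry, normalization
    )
    fds: dict[int, float] = {}
    for layer in range(1, N_LAYERS + 1):
        tmap = orthogonal_thickness(raw_thickness(stack, layer), stack)
        norm = resample(tmap, transform, normalization)
        roi = central_roi(norm, normalization)
        if not roi.valid_mask.all():
            raise ValueError(
                f"stage=roi layer={layer}: ROI contains "
                f"{int((~roi.valid_mask).sum())} invalid pixels"
            )
        fds[layer] = fractal_dimension(roi, box_counting).fd
    total = total_retina_thickness(stack)
    roi_total = central_roi(resample(total, transform, normalization), normalization)
    fd_total = fractal_dimension(roi_total, box_counting).fd
    return fds, fd_total


def _fd_table_for_stacks(
    stacks: list[SurfaceStack],
    normalization: NormalizationParams,
    box_counting: BoxCountingConfig,
    exclusions: list[dict],
    timings: dict,
) -> pd.DataFrame:
    rows = {}
    for stack in stacks:
        t0 = time.perf_counter()
        try:
            fds, fd_total = process_stack(stack, normalization, box_counting)
        except Exception as exc:  # noqa: BLE001 - per-subject isolation
            exclusions.append(
                {"subject_id": stack.subject_id, "reason": str(exc)}
            )
            continue
        row = {f"fd_layer_{k}": fds[k] for k in fds}
        vals = np.array([fds[k] for k in range(1, N_LAYERS + 1)])
        row["mean_fd_10"] = vals.mean()
        row["mean_fd_9"] = vals[:-1].mean()
        row["fd_total_retina"] = fd_total
        rows[stack.subject_id] = row
        timings[stack.subject_id] = time.perf_counter() - t0
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "subject_id"
    return df


def cohort_statistics(table: pd.DataFrame) -> tuple[dict, dict, fct.FactorModel | None]:
    """Group comparisons, correlation matrices and the two-factor model."""
    stats_out: dict = {}
    for col in ("mean_fd_10", "mean_fd_9"):
        res = st.group_comparison(table, col, alternative="greater")
        stats_out[col] = {
            "W": res.extra["W"], "U": res.extra["U"], "p_one_sided": res.p_value,
            "mean_ad": float(table.loc[table.group == "AD", col].mean()),
            "mean_ctl": float(table.loc[table.group == "CTL", col].mean()),
        }
    layer_cols = [f"fd_layer_{k}" for k in range(1, N_LAYERS + 1)]
    ad_means = table.loc[table.group == "AD", layer_cols].mean().to_numpy()
    ctl_means = table.loc[table.group == "CTL", layer_cols].mean().to_numpy()
    paired = st.paired_t(ad_means, ctl_means, alternative="greater")
    paired9 = st.paired_t(ad_means[:-1], ctl_means[:-1], alternative="greater")
    stats_out["paired_layers"] = {
        "t_10": paired.statistic, "df_10": paired.df, "p_10": paired.p_value,
        "t_9": paired9.statistic, "df_9": paired9.df, "p_9": paired9.p_value,
        "shapiro_W_ad": st.shapiro_wilk(ad_means).statistic,
        "shapiro_W_ctl": st.shapiro_wilk(ctl_means).statistic,
        "fisher_F_10": st.fisher_variance_ratio(ad_means, ctl_means).statistic,
        "fisher_F_9": st.fisher_variance_ratio(ad_means[:-1], ctl_means[:-1]).statistic,
    }
    per_layer = {}
    for k, col in enumerate(layer_cols, start=1):
        res = st.group_comparison(table, col, alternative="greater")
        per_layer[col] = {
            "W": res.extra["W"], "p_one_sided": res.p_value,
            "diff_x1000": 1000.0 * (ad_means[k - 1] - ctl_means[k - 1]),
        }
    stats_out["per_layer"] = per_layer

    correlations = {}
    for subset in ("all", "AD"):
        try:
            cm = st.correlation_matrix(table, subset=subset)
            correlations[subset] = {
                "r": cm.r, "p": cm.p, "significant": cm.significant, "n": cm.n
            }
        except ValueError as exc:
            correlations[subset] = {"error": str(exc)}

    model = None
    if len(table.dropna(subset=layer_cols)) >= 15:
        model = fct.fit_two_factor(table)
    return stats_out, correlations, model


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis described by ``config``.

    Deterministic given the config (the synthetic cohort seed covers all
    randomness).  Fails only if fewer than 2 subjects per group survive.
    """
    t_start = time.perf_counter()
    exclusions: list[dict] = []
    timings: dict = {}

    if config.cohort is not None:
        spec = replace(config.cohort, seed=config.seed if config.seed else config.cohort.seed)
        data = generate_cohort(spec)
        stacks = data.stacks
        covariates = data.covariates
    elif config.stack_dir is not None:
        paths = sorted(Path(config.stack_dir).glob("*.h5"))
        stacks = [read_stack(p) for p in paths]
        covariates = None
        if config.covariates_csv:
            covariates = pd.read_csv(config.covariates_csv).set_index("subject_id")
        elif (Path(config.stack_dir) / "covariates.csv").exists():
            covariates = pd.read_csv(
                Path(config.stack_dir) / "covariates.csv"
            ).set_index("subject_id")
    else:
        raise ValueError("config needs either a synthetic cohort or a stack directory")

    cache_dir = Path(config.out_dir) / "cache" if config.out_dir else None
    cache_file = cache_dir / f"fd_{config.cache_key()}.csv" if cache_dir else None
    if cache_file is not None and cache_file.exists():
        fd_table = pd.read_csv(cache_file).set_index("subject_id")
        excl_file = cache_file.with_suffix(".exclusions.json")
        if excl_file.exists():
            exclusions.extend(json.loads(excl_file.read_text()))
    else:
        fd_table = _fd_table_for_stacks(
            stacks, config.normalization, config.box_counting, exclusions, timings
        )
        if cache_file is not None:
            cache_dir.mkdir(parents=True, exist_ok=True)
            fd_table.to_csv(cache_file)
            cache_file.with_suffix(".exclusions.json").write_text(
                json.dumps(exclusions)
            )

    if covariates is not None:
        table = fd_table.join(covariates, how="inner")
    else:
        table = fd_table.copy()
        table["group"] = "CTL"
    for grp in ("AD", "CTL"):
        if (table.group == grp).sum() < 2 and covariates is not None:
            raise RuntimeError(f"fewer than 2 surviving subjects in group {grp}")

    group_stats, correlations, model = cohort_statistics(table) if covariates is not None else ({}, {}, None)

    robustness_report = None
    if config.robustness:
        robustness_report = {"variants": [], "sign_agreement": True}
        base_sign = None
        for cfg in robustness_configs(config.box_counting):
            excl: list[dict] = []
            tbl = _fd_table_for_stacks(stacks, config.normalization, cfg, excl, {})
            tbl = tbl.join(covariates, how="inner")
            diff = (
                tbl.loc[tbl.group == "AD", "mean_fd_10"].mean()
                - tbl.loc[tbl.group == "CTL", "mean_fd_10"].mean()
            )
            res = st.group_comparison(tbl, "mean_fd_10", alternative="greater")
            sign = int(np.sign(diff))
            if base_sign is None:
                base_sign = sign
            elif sign != base_sign:
                robustness_report["sign_agreement"] = False
            robustness_report["variants"].append(
                {
                    "algorithm": cfg.algorithm, "coding": cfg.coding,
                    "mean_fd_diff": float(diff), "W": res.extra["W"],
                    "p_one_sided": res.p_value,
                }
            )

    manifest = {
        "config": json.loads(json.dumps(asdict(config), default=str)),
        "seed": config.seed,
        "n_subjects_in": len(stacks),
        "n_subjects_analyzed": len(fd_table),
        "exclusions": exclusions,
        "per_subject_fd_seconds": timings,
        "total_seconds": time.perf_counter() - t_start,
    }
    assert manifest["n_subjects_analyzed"] + len(exclusions) == manifest["n_subjects_in"]

    result = PipelineResult(
        fd_table=table,
        group_stats=group_stats,
        correlations=correlations,
        factor_model=model,
        manifest=manifest,
        robustness_report=robustness_report,
    )
    if config.out_dir:
        write_result_bundle(result, config.out_dir)
    return result


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict())
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_result_bundle(result: PipelineResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.fd_table.to_csv(out / "fd_table.csv")
    (out / "group_stats.json").write_text(
        json.dumps(_jsonable(result.group_stats), indent=2)
    )
    (out / "correlations.json").write_text(
        json.dumps(_jsonable(result.correlations), indent=2)
    )
    if result.factor_model is not None:
        m = result.factor_model
        payload = {
            "loadings": m.loadings.to_dict(),
            "uniquenesses": m.uniquenesses.tolist(),
            "variance_explained": m.variance_explained.tolist(),
            "chi2_sufficiency": {
                "chi2": m.chi2_sufficiency.statistic,
                "df": m.chi2_sufficiency.df,
                "p": m.chi2_sufficiency.p_value,
            },
            "kmo": m.kmo,
            "bartlett": {
                "chi2": m.bartlett.statistic, "df": m.bartlett.df,
                "p": m.bartlett.p_value,
            },
            "corr_det": m.corr_det,
            "heywood": m.heywood,
        }
        (out / "factor_model.json").write_text(json.dumps(_jsonable(payload), indent=2))
    if result.robustness_report is not None:
        (out / "robustness.json").write_text(
            json.dumps(_jsonable(result.robustness_report), indent=2)
        )
    (out / "manifest.json").write_text(json.dumps(_jsonable(result.manifest), indent=2))


def quick_cohort_fd(
    spec: CohortSpec,
    side_px: int = 64,
    pitch_um: float = 40.0,
    box_counting: BoxCountingConfig = BoxCountingConfig(),
) -> pd.DataFrame:
    """Reduced-scale cohort FD table for replicate-heavy simulation studies.

    Uses :func:`~retroughness.synthetic.generate_layer_maps` (fovea-centred
    isotropic maps, no surface stacking or resampling) and returns the
    joined cohort table of per-layer FDs, means and covariates.
    """
    maps, data = generate_layer_maps(spec, side_px=side_px, pitch_um=pitch_um)
    rows = {}
    for subj in data.subject_ids:
        fds = np.array(
            [
                fractal_dimension(maps[(subj, k)], box_counting).fd
                for k in range(1, N_LAYERS + 1)
            ]
        )
        row = {f"fd_layer_{k}": fds[k - 1] for k in range(1, N_LAYERS + 1)}
        row["mean_fd_10"] = fds.mean()
        row["mean_fd_9"] = fds[:-1].mean()
        rows[subj] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "subject_id"
    return df.join(data.covariates)
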