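"""Single-subject and cohort orchestration.

A subject run processes each echo independently: spatial smoothing, then
either the absolute-CVR path (EtCO2 synchronization by residual-minimizing
delay search, GLM in %ΔBOLD/mmHg) when a capnograph trace is available, or
the gas-free path (filtered global-signal regressor, whole-brain-normalized
relative map). A cohort run stacks per-subject maps, performs the voxel-wise
one-sample t and age-regression analyses with cluster-extent thresholding,
defines the ROI from the surviving negative clusters, and fits the ROI-level
group/age regressions with a sex covariate.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import contrast as contrast_mod
from . import cvr as cvr_mod
from . import group as group_mod
from . import physio
from .errors import ConfigurationError, InvalidArgumentError

logger = logging.getLogger("chp_elastic")


@dataclass
class PipelineConfig:
    """All tunable analysis settings with their protocol defaults."""

    paradigm: str = "hypercapnia"
    fwhm_mm: float = 4.0
    delay_search_s: tuple[float, float] = (-5.0, 30.0)
    delay_step_s: float = 0.5
    min_breath_interval_s: float = 2.0
    lowpass_cutoff_hz: float = 0.1164
    filter_order: int = 2
    p_threshold: float = 0.005
    cluster_min: int = 50
    connectivity: int = 26
    shell_thickness: int = 2
    use_motion: bool = False
    seed: int = 0

    def __post_init__(self):
        self.delay_search_s = tuple(self.delay_search_s)
        if self.fwhm_mm < 0:
            raise ConfigurationError("fwhm_mm must be >= 0")
        if self.delay_search_s[1] <= self.delay_search_s[0] or self.delay_step_s <= 0:
            raise ConfigurationError("invalid delay search settings")
        if not 0 < self.p_threshold < 1:
            raise ConfigurationError("p_threshold must be in (0, 1)")
        if self.cluster_min < 0 or self.connectivity not in (6, 26):
            raise ConfigurationError("invalid cluster settings")
        if self.lowpass_cutoff_hz <= 0 or self.filter_order < 1:
            raise ConfigurationError("invalid filter settings")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["delay_search_s"] = list(self.delay_search_s)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(self.as_dict(), sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class SubjectResult:
    """Per-echo CVR maps and contrast ratios for one subject."""

    maps: list[cvr_mod.CVRMap]
    contrasts: list[contrast_mod.ContrastResult]
    delay_fits: list[physio.DelayFit | None]
    provenance: dict = field(default_factory=dict)


def run_subject(
    bold_list: list[cvr_mod.BoldSeries],
    trace=None,
    config: PipelineConfig | None = None,
    csf_mask: np.ndarray | None = None,
    tissue_mask: np.ndarray | None = None,
    motion: np.ndarray | None = None,
) -> SubjectResult:
    """Process one subject: per echo, smoothing then CVR estimation.

    With ``trace`` (capnograph recording): end-tidal extraction, delay search
    against that echo's global BOLD course, absolute CVR GLM. Without:
    filtered global-signal regressor and relative CVR. If ``csf_mask`` is
    given a CSF/tissue contrast ratio is computed per echo (tissue defaults to
    a periventricular dilation shell).
    """
    config = config or PipelineConfig()
    if len(bold_list) < 1:
        raise ConfigurationError("need at least one echo")
    n_volumes = {b.acq.n_volumes for b in bold_list}
    if len(n_volumes) != 1:
        raise ConfigurationError(f"echoes disagree on volume count: {sorted(n_volumes)}")
    if trace is not None and trace.times[-1] < bold_list[0].volume_times[-1]:
        raise ConfigurationError("physio trace is shorter than the BOLD scan")
    maps, contrasts, fits = [], [], []
    for i, bold in enumerate(bold_list):
        t0 = time.perf_counter()
        te = bold.acq.te_list[i] if len(bold.acq.te_list) == len(bold_list) else bold.acq.te_list[0]
        smoothed = cvr_mod.smooth_gaussian(bold, config.fwhm_mm)
        if trace is not None:
            etco2, fit = physio.synchronize(
                trace,
                smoothed.global_mean(),
                smoothed.volume_times,
                search_range=config.delay_search_s,
                step=config.delay_step_s,
                min_breath_interval=config.min_breath_interval_s,
            )
            cmap = cvr_mod.fit_cvr_glm(smoothed, etco2)
            fits.append(fit)
        else:
            reg = cvr_mod.global_regressor(smoothed, config.lowpass_cutoff_hz, config.filter_order)
            cmap = cvr_mod.fit_relative_cvr(
                smoothed, reg, motion=motion if config.use_motion else None
            )
            fits.append(None)
        cmap.metadata["te_ms"] = te
        maps.append(cmap)
        if csf_mask is not None:
            shell = (
                tissue_mask
                if tissue_mask is not None
                else contrast_mod.periventricular_shell(
                    csf_mask, config.shell_thickness, brain_mask=bold.brain_mask
                )
            )
            contrasts.append(
                contrast_mod.compute_contrast_ratio(
                    bold.data.mean(axis=-1), csf_mask, shell, te=te
                )
            )
        logger.info(
            "echo %d (TE %.0f ms) done in %.2fs [config %s]",
            i + 1, te, time.perf_counter() - t0, config.digest(),
        )
    provenance = {"config": config.as_dict(), "config_digest": config.digest()}
    return SubjectResult(maps, contrasts, fits, provenance)


@dataclass
class CohortResult:
    """Cohort analysis output: voxel-wise tests, ROI table and regressions."""

    subject_table: pd.DataFrame
    negative_clusters: group_mod.ClusterResult
    age_clusters: group_mod.ClusterResult | None
    roi_mask: np.ndarray | None
    group_test: group_mod.RoiRegressionResult | None
    age_test: group_mod.RoiRegressionResult | None
    maps: list[cvr_mod.CVRMap]
    failures: list[tuple[str, str]]


def run_cohort(
    subjects,
    config: PipelineConfig | None = None,
    echo_index: int = 0,
    use_physio: bool | None = None,
) -> CohortResult:
    """Analyze a cohort of subjects on a common grid.

    ``subjects`` is an iterable of :class:`~chp_elastic.phantom.SimulatedSubject`
    (or objects with ``bold``, ``trace``, ``covariates``). Per subject the
    single-subject pipeline runs on echo ``echo_index``; a failed subject is
    logged and excluded. Group steps: one-sample t in the negative direction
    with cluster-extent thresholding; ROI = surviving negative clusters;
    ROI-mean per subject; group and age regressions with sex covariate; an
    age-regression map in the positive direction.
    """
    config = config or PipelineConfig()
    maps, rows, failures = [], [], []
    for subj in subjects:
        sid = getattr(subj, "subject_id", subj.covariates.get("subject", "?"))
        try:
            trace = subj.trace if (use_physio if use_physio is not None else subj.trace is not None) else None
            res = run_subject(subj.bold, trace=trace, config=config)
            maps.append(res.maps[echo_index])
            rows.append(dict(subj.covariates))
        except Exception as exc:  # noqa: BLE001 - continue, report, exclude
            logger.warning("subject %s failed and was excluded: %s", sid, exc)
            failures.append((sid, str(exc)))
    if len(maps) < 3:
        raise InvalidArgumentError(
            f"cohort analysis needs >= 3 successful subjects, got {len(maps)}"
        )
    neg = group_mod.one_sample_t_map(
        maps,
        direction="negative",
        p_threshold=config.p_threshold,
        cluster_min=config.cluster_min,
        connectivity=config.connectivity,
    )
    table = pd.DataFrame(rows)
    ages = table["age"].to_numpy(float) if "age" in table else None
    age_clusters = None
    if ages is not None and np.std(ages) > 0:
        age_clusters = group_mod.regression_map(
            maps,
            ages,
            direction="positive",
            p_threshold=config.p_threshold,
            cluster_min=config.cluster_min,
            connectivity=config.connectivity,
        )
    roi_mask = neg.surviving_mask if neg.surviving_mask.any() else None
    group_test = age_test = None
    if roi_mask is not None:
        table["roi_value"] = [m.mean_in(roi_mask) for m in maps]
        if "group" in table and table["group"].nunique() >= 2:
            group_test = group_mod.roi_regression(table, predictor="group")
        if ages is not None and np.std(ages) > 0:
            age_test = group_mod.roi_regression(table, predictor="age")
    return CohortResult(
        subject_table=table,
        negative_clusters=neg,
        age_clusters=age_clusters,
        roi_mask=roi_mask,
        group_test=group_test,
        age_test=age_test,
        maps=maps,
        failures=failures,
    )
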