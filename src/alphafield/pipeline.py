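"""End-to-end analysis pipeline: signals to feature table to model report.

For each subject the pipeline (i) detects the analysis IAF from the four
pre/post video runs, (ii) reads the Hilbert-envelope alpha amplitude per
run and forms ΔΔ ALPHA_AMP, (iii) builds the alpha regressor, fits the
voxelwise GLM per run, averages the four t-maps and derives the
MASK_alphaBOLD / MASK_strong dose values, (iv) computes mPFC-PCC
connectivity per run and forms ΔΔ CONNECTIVITY, (v) forms MISMATCH from
the tACS-session mean IAF, and (vi) assembles the feature table on which
the ANOVA/ANCOVA and the regression model variants run.

Subjects without an identifiable alpha peak are excluded with a recorded
reason (strict and lenient mode agree on this); other per-subject failures
abort in strict mode and exclude in lenient mode.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectivity as conn
from . import fusion, spectral, stats
from .errors import AlphaFieldError, InputError, SubjectExclusion
from .io import CohortLayout
from .synthetic import ANALYSIS_RUNS, SESSIONS, SubjectRecord

log = logging.getLogger("alphafield")

#: unit-suffixed column names used in on-disk feature tables
FEATURE_UNITS = {
    "dd_alpha_amp": "dd_alpha_amp_uV",
    "dd_connectivity": "dd_connectivity_z",
    "dd_sleepiness": "dd_sleepiness",
    "mismatch": "mismatch_Hz",
    "efield_alphabold": "efield_alphabold_V_per_m",
    "efield_strong": "efield_strong_V_per_m",
}


@dataclass
class PipelineConfig:
    """Analysis parameters with the published defaults.

    ``k_voxels`` is the dose-mask size (1000 gray-matter voxels);
    ``band`` the IAF search band (8-12 Hz); ``filter_halfwidth`` the
    band-pass half width around the IAF (2 Hz).
    """

    k_voxels: int = 1000
    band: tuple[float, float] = spectral.ALPHA_BAND
    filter_halfwidth: float = 2.0
    channels: tuple[str, ...] = spectral.DEFAULT_CHANNELS
    epoch_length: float = 10.0
    resolution: float = 0.1
    smoothing: float = 0.5
    prominence_fraction: float = 0.2
    edge_trim: float = 1.0
    drift_order: int = 1
    roi_specs: tuple[conn.RoiSpec, ...] | None = None
    rmse_ddof: int = 0
    strict: bool = True

    def validate(self):
        if self.k_voxels <= 0:
            raise InputError("k_voxels must be positive")
        if not 0 < self.band[0] < self.band[1]:
            raise InputError("band must be an increasing positive interval")


@dataclass
class PipelineResult:
    features: pd.DataFrame
    exclusions: pd.DataFrame
    models: dict[str, stats.ModelFit]
    anova: dict[str, stats.AnovaResult] = field(default_factory=dict)
    ancova: dict[str, tuple] = field(default_factory=dict)

    def report(self) -> dict:
        sig, threshold = stats.bonferroni(
            [self.models[k].f_pvalue for k in
             ("alpha_alphabold", "alpha_strong", "conn_alphabold", "conn_strong")]
        ) if len(self.models) >= 4 else (np.array([]), 0.0125)
        return {
            "n_included": int(len(self.features)),
            "exclusions": self.exclusions.to_dict(orient="records"),
            "models": {k: m.to_dict() for k, m in self.models.items()},
            "bonferroni": {"threshold": threshold,
                           "significant": [bool(s) for s in sig]},
            "anova": {
                k: {"F": a.f, "p": a.p, "dof": list(a.dof)} for k, a in self.anova.items()
            },
            "ancova": {
                k: {"F": v[0], "p": v[1], "dof": list(v[2])} for k, v in self.ancova.items()
            },
        }


def _analysis_iafs(record: SubjectRecord, pcfg: PipelineConfig):
    """Per-run IAF detection over the four usable pre/post runs."""
    iafs = {}
    for session in SESSIONS:
        for run in ANALYSIS_RUNS:
            rr = record.runs.get((session, run))
            if rr is None or not rr.usable:
                raise InputError(f"{record.subject_id}: missing usable {session}/{run} run")
            spec = spectral.power_spectrum(
                rr.eeg, channels=pcfg.channels, epoch_length=pcfg.epoch_length,
                resolution=pcfg.resolution, smoothing=pcfg.smoothing,
            )
            res = spectral.detect_iaf(spec, band=pcfg.band,
                                      prominence_fraction=pcfg.prominence_fraction)
            iafs[(session, run)] = res.iaf  # None when not identifiable
    return iafs


def subject_features(
    record: SubjectRecord,
    pcfg: PipelineConfig,
    roi_specs: tuple[conn.RoiSpec, ...],
) -> stats.SubjectFeatures:
    """Run the full per-subject chain and return one feature-table row."""
    t0 = time.perf_counter()
    iafs = _analysis_iafs(record, pcfg)
    identified = [v for v in iafs.values() if v is not None]
    if not identified:
        raise SubjectExclusion("non-identifiable alpha peak in all pre/post runs")
    analysis_iaf = float(np.mean(identified))
    tacs_iafs = [iafs[("tacs", r)] for r in ANALYSIS_RUNS if iafs[("tacs", r)] is not None]
    if not tacs_iafs:
        raise SubjectExclusion("non-identifiable alpha peak in the tACS session")
    mismatch = spectral.mismatch(record.tacs_frequency, float(np.mean(tacs_iafs)))
    log.info("%s spectral: IAF %.2f Hz, mismatch %.2f Hz (%.1f s)",
             record.subject_id, analysis_iaf, mismatch, time.perf_counter() - t0)

    # alpha amplitudes and ΔΔ ALPHA_AMP
    amp = {
        key: spectral.alpha_amplitude(
            record.runs[key].eeg, analysis_iaf, channels=pcfg.channels,
            halfwidth=pcfg.filter_halfwidth, edge_trim=pcfg.edge_trim,
        )
        for key in ((s, r) for s in SESSIONS for r in ANALYSIS_RUNS)
    }
    dd_alpha = spectral.double_delta(
        spectral.delta(amp[("tacs", "post")], amp[("tacs", "pre")]),
        spectral.delta(amp[("sham", "post")], amp[("sham", "pre")]),
    )

    # EEG-informed GLM, pooled t-map, dose masks
    t0 = time.perf_counter()
    tmaps = []
    for session in SESSIONS:
        for run in ANALYSIS_RUNS:
            rr = record.runs[(session, run)]
            reg = fusion.build_alpha_regressor(
                rr.eeg, analysis_iaf, rr.bold.tr, rr.bold.n_volumes,
                channels=pcfg.channels, halfwidth=pcfg.filter_halfwidth,
            )
            tmaps.append(fusion.voxelwise_glm(rr.bold, reg, drift_order=pcfg.drift_order))
    pooled = fusion.average_tmaps(tmaps)
    occ_gray = record.occipital_mask.intersect(record.gray_mask)
    mask_alphabold = fusion.select_topk_mask(pooled, occ_gray, pcfg.k_voxels,
                                            direction="most-negative")
    mask_strong = fusion.select_topk_mask(record.field_map, record.gray_mask,
                                          pcfg.k_voxels, direction="largest")
    efield_alphabold = fusion.mean_field(record.field_map, mask_alphabold)
    efield_strong = fusion.mean_field(record.field_map, mask_strong)
    log.info("%s fusion: EFIELD_alphaBOLD %.3f, EFIELD_strong %.3f V/m (%.1f s)",
             record.subject_id, efield_alphabold, efield_strong,
             time.perf_counter() - t0)

    # DMN connectivity and ΔΔ CONNECTIVITY
    roi_a, roi_b = roi_specs[:2]
    some_bold = record.runs[("tacs", "pre")].bold
    mask_a = conn.sphere_mask(some_bold.values.shape[:3], some_bold.affine, roi_a)
    mask_b = conn.sphere_mask(some_bold.values.shape[:3], some_bold.affine, roi_b)
    z = {}
    for key in ((s, r) for s in SESSIONS for r in ANALYSIS_RUNS):
        bold = record.runs[key].bold
        z[key] = conn.fisherz_spearman(
            conn.roi_series(bold, mask_a), conn.roi_series(bold, mask_b)
        ).z
    dd_conn = conn.connectivity_contrast(
        z[("tacs", "post")], z[("tacs", "pre")], z[("sham", "post")], z[("sham", "pre")]
    )

    sl = record.sleepiness
    dd_sleep = spectral.double_delta(
        spectral.delta(sl[("tacs", "post")], sl[("tacs", "pre")]),
        spectral.delta(sl[("sham", "post")], sl[("sham", "pre")]),
    )

    feats = stats.SubjectFeatures(
        subject_id=record.subject_id,
        dd_alpha_amp=dd_alpha,
        dd_connectivity=dd_conn,
        dd_sleepiness=dd_sleep,
        mismatch=mismatch,
        efield_alphabold=efield_alphabold,
        efield_strong=efield_strong,
    )
    # stash per-run readouts for the group ANOVA/ANCOVA
    feats.run_amplitudes = amp  # type: ignore[attr-defined]
    feats.run_z = z  # type: ignore[attr-defined]
    feats.run_sleepiness = {k: sl[k] for k in amp}  # type: ignore[attr-defined]
    return feats


def _as_2x2(per_subject: list[dict]) -> np.ndarray:
    """Stack per-run dicts into (n, run[pre,post], session[tacs,sham])."""
    return np.array(
        [
            [[d[(s, r)] for s in SESSIONS] for r in ANALYSIS_RUNS]
            for d in per_subject
        ]
    )


def run_pipeline(
    cohort,
    pcfg: PipelineConfig | None = None,
    out_dir=None,
) -> PipelineResult:
    """Run the pipeline over a cohort and fit the model variants.

    ``cohort`` is a :class:`~alphafield.io.CohortLayout` (on-disk tree) or a
    list of in-memory :class:`SubjectRecord`; in the latter case ROI specs
    must be supplied through ``pcfg.roi_specs``. Writes ``features.csv`` and
    ``report.json`` into ``out_dir`` when given.
    """
    pcfg = pcfg or PipelineConfig()
    pcfg.validate()
    if isinstance(cohort, CohortLayout):
        roi_specs = pcfg.roi_specs or cohort.roi_specs
        subjects = [(sid, lambda sid=sid: cohort.load_subject(sid)) for sid in cohort.subject_ids]
    else:
        roi_specs = pcfg.roi_specs
        subjects = [(rec.subject_id, lambda rec=rec: rec) for rec in cohort]
    if not roi_specs:
        raise InputError("no ROI specs: provide PipelineConfig.roi_specs or a cohort roi_specs.tsv")

    rows, excluded = [], {}
    amps, zs, sleeps = [], [], []
    for sid, load in subjects:
        t0 = time.perf_counter()
        try:
            feats = subject_features(load(), pcfg, roi_specs)
        except SubjectExclusion as exc:
            log.info("%s excluded: %s", sid, exc.reason)
            excluded[sid] = exc.reason
            continue
        except AlphaFieldError as exc:
            if pcfg.strict:
                raise
            log.warning("%s failed (%s); excluded in lenient mode", sid, exc)
            excluded[sid] = f"stage failure: {exc}"
            continue
        rows.append(feats)
        amps.append(feats.run_amplitudes)
        zs.append(feats.run_z)
        sleeps.append(feats.run_sleepiness)
        log.info("%s done in %.1f s", sid, time.perf_counter() - t0)

    table, exclusions = stats.assemble_features(rows, excluded)
    result = PipelineResult(features=table, exclusions=exclusions, models={})
    if len(table) >= 5:
        result.models = stats.fit_model_variants(table, rmse_ddof=pcfg.rmse_ddof)
    if len(table) >= 2:
        for name, data in (("alpha_amplitude", amps), ("connectivity_z", zs),
                           ("sleepiness", sleeps)):
            result.anova[name] = stats.rm_anova_2x2(_as_2x2(data))
        d_amp = _as_2x2(amps)[:, 1, :] - _as_2x2(amps)[:, 0, :]  # (n, session)
        d_z = _as_2x2(zs)[:, 1, :] - _as_2x2(zs)[:, 0, :]
        d_sleep = _as_2x2(sleeps)[:, 1, :] - _as_2x2(sleeps)[:, 0, :]
        result.ancova["alpha_amplitude"] = stats.ancova_group(d_amp, d_sleep)
        result.ancova["connectivity_z"] = stats.ancova_group(d_z, d_sleep)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_features_csv(table, out / "features.csv")
        (out / "report.json").write_text(json.dumps(result.report(), indent=2))
        exclusions.to_csv(out / "exclusions.csv", index=False)
    return result


def write_features_csv(table: pd.DataFrame, path) -> None:
    """Write the feature table with unit-suffixed column headers."""
    table.rename(columns=FEATURE_UNITS).to_csv(path)


def read_features_csv(path) -> pd.DataFrame:
    """Read a feature table, accepting unit-suffixed or plain headers."""
    frame = pd.read_csv(path, index_col=0)
    inverse = {v: k for k, v in FEATURE_UNITS.items()}
    return frame.rename(columns=inverse)
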