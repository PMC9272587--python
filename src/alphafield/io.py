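"""Readers and writers for the on-disk cohort formats.

Volumes are NIfTI-1 (``.nii.gz``). EEG runs are EDF (read-only, via MNE) or
the documented TSV format: first column ``time_s``, remaining columns one
channel each in uV (header suffix ``_uV``); artifact segments live in an
optional sidecar TSV with ``onset_s``/``offset_s`` columns. A cohort is a
directory tree::

    root/
      config.yaml          # generating configuration, structured text
      participants.tsv     # tACS frequency + per-run sleepiness
      roi_specs.tsv        # label, x_mm, y_mm, z_mm, radius_mm
      ground_truth.json    # planted values (synthetic cohorts only)
      sub-01/
        field_map.nii.gz  gray_mask.nii.gz  occipital_mask.nii.gz
        ses-tacs/ run-pre_eeg.tsv  run-pre_bold.nii.gz  ...
        ses-sham/ ...
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .connectivity import RoiSpec
from .errors import InputError
from .fusion import BOLDRun, FieldMap, VoxelMask
from .spectral import EEGRun
from .synthetic import (
    RUNS,
    SESSIONS,
    GroundTruth,
    RunRecord,
    SimConfig,
    SubjectRecord,
    grid_affine,
    synthetic_roi_specs,
)


# ---------------------------------------------------------------------------
# volumes


def write_volume(data: np.ndarray, affine: np.ndarray, path) -> None:
    data = np.asarray(data)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, np.asarray(affine, dtype=float)), str(path))


def read_volume(path, expect_ndim: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume; returns ``(values, affine)``.

    ``expect_ndim`` of 3 or 4 rejects the wrong dimensionality with a typed
    error instead of failing downstream.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise InputError(f"cannot read {path} as NIfTI: {exc}") from exc
    data = np.asarray(img.get_fdata())
    if expect_ndim is not None and data.ndim != expect_ndim:
        raise InputError(f"{path}: expected a {expect_ndim}-D volume, got {data.ndim}-D")
    return data, img.affine


# ---------------------------------------------------------------------------
# EEG


def write_eeg_tsv(run: EEGRun, path, artifacts_path=None) -> None:
    """Write the documented TSV format (time in s, channels in uV)."""
    t = np.arange(run.n_samples) / run.sampling_rate
    header = "time_s\t" + "\t".join(f"{c}_uV" for c in run.channel_labels)
    np.savetxt(
        str(path),
        np.column_stack([t, run.samples.T]),
        delimiter="\t",
        header=header,
        comments="",
        fmt="%.10g",
    )
    if artifacts_path is not None and run.artifact_segments:
        segs = np.asarray(run.artifact_segments, dtype=float) / run.sampling_rate
        np.savetxt(
            str(artifacts_path), segs, delimiter="\t",
            header="onset_s\toffset_s", comments="", fmt="%.10g",
        )


def _read_eeg_tsv(path: Path) -> tuple[float, tuple[str, ...], np.ndarray]:
    try:
        frame = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise InputError(f"cannot parse {path} as EEG TSV: {exc}") from exc
    if frame.empty or frame.shape[1] < 2:
        raise InputError(f"{path}: EEG TSV needs a time column and >= 1 channel")
    t = frame.iloc[:, 0].to_numpy(dtype=float)
    dt = np.diff(t)
    if t.size < 2 or np.any(dt <= 0):
        raise InputError(f"{path}: time column must be strictly increasing")
    step = np.median(dt)
    if np.any(np.abs(dt - step) > 1e-6 * max(step, 1.0)):
        raise InputError(f"{path}: non-uniform sampling in time column")
    labels = tuple(c[:-3] if c.endswith("_uV") else c for c in frame.columns[1:])
    return 1.0 / step, labels, frame.iloc[:, 1:].to_numpy(dtype=float).T


def _read_edf(path: Path) -> tuple[float, tuple[str, ...], np.ndarray]:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return float(raw.info["sfreq"]), tuple(raw.ch_names), raw.get_data() * 1e6


def read_eeg(path, artifacts_path=None, required_channels=()) -> EEGRun:
    """Read an EEG run from EDF or the documented TSV.

    Artifact onsets/offsets (seconds, half-open) come from the optional
    sidecar TSV and are converted to sample intervals; overlap or
    out-of-range segments are rejected by :class:`EEGRun` validation.
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise InputError(f"{path}: missing or empty EEG file")
    if path.suffix.lower() == ".edf":
        fs, labels, samples = _read_edf(path)
    else:
        fs, labels, samples = _read_eeg_tsv(path)
    missing = [c for c in required_channels if c not in labels]
    if missing:
        raise InputError(f"{path}: channels {missing} not found; available: {list(labels)}")
    segments = ()
    if artifacts_path is not None and Path(artifacts_path).exists():
        art = pd.read_csv(artifacts_path, sep="\t")
        segments = tuple(
            (round(row.iloc[0] * fs), round(row.iloc[1] * fs)) for _, row in art.iterrows()
        )
    return EEGRun(fs, labels, samples, artifact_segments=segments)


# ---------------------------------------------------------------------------
# cohort trees


def _subject_dir(root: Path, subject_id: str) -> Path:
    return root / subject_id


def write_cohort(
    records,
    config: SimConfig,
    root,
    ground_truth: GroundTruth | None = None,
    roi_specs: tuple[RoiSpec, ...] | None = None,
) -> None:
    """Write a cohort directory tree; ``records`` may be any iterable."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    (root / "config.yaml").write_text(yaml.safe_dump(dataclasses.asdict(config)))

    if roi_specs is None:
        roi_specs = synthetic_roi_specs(config)
    pd.DataFrame(
        [
            {"label": r.label, "x_mm": r.center[0], "y_mm": r.center[1],
             "z_mm": r.center[2], "radius_mm": r.radius}
            for r in roi_specs
        ]
    ).to_csv(root / "roi_specs.tsv", sep="\t", index=False)

    part_rows = []
    for rec in records:
        sub = _subject_dir(root, rec.subject_id)
        sub.mkdir(exist_ok=True)
        write_volume(rec.field_map.magnitude, rec.field_map.affine, sub / "field_map.nii.gz")
        write_volume(rec.gray_mask.selected, rec.gray_mask.affine, sub / "gray_mask.nii.gz")
        write_volume(rec.occipital_mask.selected, rec.occipital_mask.affine,
                     sub / "occipital_mask.nii.gz")
        for (session, run), rr in rec.runs.items():
            ses = sub / f"ses-{session}"
            ses.mkdir(exist_ok=True)
            write_eeg_tsv(rr.eeg, ses / f"run-{run}_eeg.tsv",
                          ses / f"run-{run}_eeg_artifacts.tsv")
            write_volume(rr.bold.values, rr.bold.affine, ses / f"run-{run}_bold.nii.gz")
        row = {"subject_id": rec.subject_id, "tacs_frequency_hz": rec.tacs_frequency,
               "first_session": rec.session_order[0]}
        for s in SESSIONS:
            for r in RUNS:
                row[f"sleepiness_{s}_{r}"] = rec.sleepiness.get((s, r), np.nan)
        part_rows.append(row)
    pd.DataFrame(part_rows).to_csv(root / "participants.tsv", sep="\t", index=False)

    if ground_truth is not None:
        payload = {
            "features": ground_truth.features.reset_index().to_dict(orient="records"),
            "run_iaf": ground_truth.run_iaf.to_dict(orient="records"),
            "coupled_voxels": ground_truth.coupled_voxels.tolist(),
            "planted_rho": ground_truth.planted_rho.to_dict(orient="records"),
        }
        (root / "ground_truth.json").write_text(json.dumps(payload))


class CohortLayout:
    """Lazy view of an on-disk cohort: paths + participant metadata.

    Subject volumes and EEG are loaded per subject through
    :meth:`load_subject`, keeping peak memory at one subject.
    """

    def __init__(self, root):
        self.root = Path(root)
        ptsv = self.root / "participants.tsv"
        if not ptsv.exists():
            raise InputError(f"{self.root} is not a cohort (no participants.tsv)")
        self.participants = pd.read_csv(ptsv, sep="\t")
        self.subject_ids = list(self.participants["subject_id"])
        cfg_path = self.root / "config.yaml"
        self.config = (
            SimConfig(**_tuplify(yaml.safe_load(cfg_path.read_text())))
            if cfg_path.exists() else None
        )
        roi_path = self.root / "roi_specs.tsv"
        self.roi_specs = None
        if roi_path.exists():
            rois = pd.read_csv(roi_path, sep="\t")
            self.roi_specs = tuple(
                RoiSpec(r["label"], (r["x_mm"], r["y_mm"], r["z_mm"]), r["radius_mm"])
                for _, r in rois.iterrows()
            )
        for sid in self.subject_ids:
            if not _subject_dir(self.root, sid).is_dir():
                raise InputError(f"participants.tsv lists {sid} but {sid}/ is missing")

    def sleepiness(self, subject_id: str) -> dict[tuple[str, str], float]:
        row = self.participants.set_index("subject_id").loc[subject_id]
        return {
            (s, r): float(row[f"sleepiness_{s}_{r}"])
            for s in SESSIONS for r in RUNS if f"sleepiness_{s}_{r}" in row
        }

    def tacs_frequency(self, subject_id: str) -> float:
        row = self.participants.set_index("subject_id").loc[subject_id]
        return float(row["tacs_frequency_hz"])

    def load_subject(self, subject_id: str) -> SubjectRecord:
        sub = _subject_dir(self.root, subject_id)
        fmag, faff = read_volume(sub / "field_map.nii.gz", expect_ndim=3)
        gmask, gaff = read_volume(sub / "gray_mask.nii.gz", expect_ndim=3)
        omask, oaff = read_volume(sub / "occipital_mask.nii.gz", expect_ndim=3)
        runs = {}
        for session in SESSIONS:
            for run in RUNS:
                ses = sub / f"ses-{session}"
                eeg_path = ses / f"run-{run}_eeg.tsv"
                if not eeg_path.exists():
                    continue
                eeg = read_eeg(eeg_path, ses / f"run-{run}_eeg_artifacts.tsv")
                bvals, baff = read_volume(ses / f"run-{run}_bold.nii.gz", expect_ndim=4)
                if not np.allclose(baff, faff):
                    raise InputError(
                        f"{subject_id} {session}/{run}: BOLD affine\n{baff}\n"
                        f"does not match field-map affine\n{faff}"
                    )
                tr = self.config.tr if self.config else 2.0
                usable = not (
                    len(eeg.artifact_segments) == 1
                    and eeg.artifact_segments[0] == (0, eeg.n_samples)
                )
                runs[(session, run)] = RunRecord(
                    eeg=eeg,
                    bold=BOLDRun(bvals.astype(np.float32), tr, baff),
                    usable=usable,
                )
        return SubjectRecord(
            subject_id=subject_id,
            tacs_frequency=self.tacs_frequency(subject_id),
            sleepiness=self.sleepiness(subject_id),
            runs=runs,
            field_map=FieldMap(fmag, faff),
            gray_mask=VoxelMask(gmask > 0.5, gaff),
            occipital_mask=VoxelMask(omask > 0.5, oaff),
        )


def _tuplify(d: dict) -> dict:
    """YAML round-trips tuples as lists; restore tuple-typed config fields."""
    out = dict(d)
    for key in ("grid_shape", "iaf_range", "channel_labels"):
        if key in out and isinstance(out[key], list):
            out[key] = tuple(out[key])
    return out


def read_cohort(root) -> CohortLayout:
    return CohortLayout(root)
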