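"""Directory-level session model: manifest, TIFF stacks, ground truth.

A session directory holds one multi-frame TIFF per trial movie, a
``manifest.json`` listing per-trial metadata and acquisition defaults, and
(for synthetic sessions) a ``ground_truth.json`` plus 0/255 mask TIFFs.
All coordinates are 0-based row-major with the time axis first; times are
seconds from trial start.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile

from .core import Channel, Genotype, RoiMask, Subject, TrialMovie
from .synth import SessionGroundTruth

MANIFEST_NAME = "manifest.json"
TRUTH_NAME = "ground_truth.json"


@dataclass
class TrialRecord:
    file: str
    trial_id: str
    channel: str
    odorant: str
    concentration_pct_svp: float
    odor_onset_s: float
    odor_duration_s: float
    frame_rate_hz: float
    n_frames: int
    subject_id: str
    age_months: float
    genotype: str


@dataclass
class SessionManifest:
    trials: list[TrialRecord]
    height: int
    width: int
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"trials": [asdict(t) for t in self.trials],
                "height": self.height, "width": self.width,
                "provenance": self.provenance}

    @classmethod
    def from_dict(cls, d: dict) -> "SessionManifest":
        return cls(trials=[TrialRecord(**t) for t in d["trials"]],
                   height=d["height"], width=d["width"],
                   provenance=d.get("provenance", {}))


def write_session(
    movies: list[TrialMovie],
    out_dir: str | Path,
    truth: SessionGroundTruth | None = None,
    provenance: dict | None = None,
) -> SessionManifest:
    """Write trial TIFFs + manifest (and ground truth when given)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    h, w = movies[0].shape_hw
    for m in movies:
        fname = f"{m.trial_id}_{m.channel.value}.tif"
        tifffile.imwrite(out / fname, m.frames.astype(np.float32))
        records.append(TrialRecord(
            file=fname, trial_id=m.trial_id, channel=m.channel.value,
            odorant=m.odorant, concentration_pct_svp=m.concentration_pct_svp,
            odor_onset_s=m.odor_onset_s, odor_duration_s=m.odor_duration_s,
            frame_rate_hz=m.frame_rate_hz, n_frames=m.n_frames,
            subject_id=m.subject.subject_id,
            age_months=m.subject.age_months,
            genotype=Genotype(m.subject.genotype).value,
        ))
    prov = dict(provenance or {})
    if truth is not None:
        prov.setdefault("generator", "obnvc.synth")
        prov.setdefault("seed", truth.seed)
        write_ground_truth(truth, out)
    else:
        prov.setdefault("generator", "real")
    manifest = SessionManifest(trials=records, height=h, width=w, provenance=prov)
    (out / MANIFEST_NAME).write_text(json.dumps(manifest.to_dict(), indent=1))
    return manifest


def write_ground_truth(truth: SessionGroundTruth, out_dir: str | Path) -> None:
    out = Path(out_dir)
    mask_files = {}
    for hemi, m in truth.vessel_masks.items():
        fname = f"vessel_mask_{hemi}.tif"
        tifffile.imwrite(out / fname, (m.astype(np.uint8) * 255))
        mask_files[hemi] = fname
    d = {
        "true_hrf": {"y_m": truth.true_hrf.y_m, "t_m": truth.true_hrf.t_m,
                     "alpha": truth.true_hrf.alpha, "y_0": truth.true_hrf.y_0},
        "ca_tau_s": truth.ca_tau_s,
        "bleach_tau_s": truth.bleach_tau_s,
        "bleach_amp_frac": truth.bleach_amp_frac,
        "noise_sd_frac": truth.noise_sd_frac,
        "conc_gain": {str(k): v for k, v in truth.conc_gain.items()},
        "age_gain_per_month": truth.age_gain_per_month,
        "genotype_gain": truth.genotype_gain,
        "seed": truth.seed,
        "vessel_mask_files": mask_files,
        "ca_scale": truth.ca_scale,
        "bv_scale": truth.bv_scale,
    }
    (out / TRUTH_NAME).write_text(json.dumps(d, indent=1))


def read_session(session_dir: str | Path) -> tuple[list[TrialMovie], SessionManifest]:
    """Load and validate a session directory atomically.

    Collects every validation problem (missing files, geometry or
    frame-count mismatches, duplicate ids) and raises one error listing
    them all; on success returns the typed movies and the manifest.
    """
    d = Path(session_dir)
    mpath = d / MANIFEST_NAME
    if not mpath.exists():
        raise FileNotFoundError(f"no {MANIFEST_NAME} in {d}")
    manifest = SessionManifest.from_dict(json.loads(mpath.read_text()))
    errors: list[str] = []
    seen_keys: set[tuple[str, str]] = set()
    movies: list[TrialMovie] = []
    for rec in manifest.trials:
        key = (rec.trial_id, rec.channel)
        if key in seen_keys:
            errors.append(f"duplicate trial id {rec.trial_id} ({rec.channel})")
        seen_keys.add(key)
        fpath = d / rec.file
        if not fpath.exists():
            errors.append(f"missing file: {rec.file}")
            continue
        try:
            frames = tifffile.imread(fpath)
        except Exception as exc:  # corrupt stack
            errors.append(f"unreadable TIFF {rec.file}: {exc}")
            continue
        if frames.ndim != 3 or frames.shape[1:] != (manifest.height, manifest.width):
            errors.append(
                f"{rec.file}: geometry {frames.shape} != declared "
                f"(*, {manifest.height}, {manifest.width})")
            continue
        if frames.shape[0] != rec.n_frames:
            errors.append(
                f"{rec.file}: {frames.shape[0]} frames, manifest says {rec.n_frames}")
            continue
        movies.append(TrialMovie(
            frames=np.asarray(frames, dtype=np.float64),
            frame_rate_hz=rec.frame_rate_hz,
            channel=Channel(rec.channel),
            odorant=rec.odorant,
            concentration_pct_svp=rec.concentration_pct_svp,
            odor_onset_s=rec.odor_onset_s,
            odor_duration_s=rec.odor_duration_s,
            subject=Subject(rec.subject_id, rec.age_months, Genotype(rec.genotype)),
            trial_id=rec.trial_id,
        ))
    if errors:
        raise ValueError("session validation failed:\n  " + "\n  ".join(errors))
    return movies, manifest


def write_mask(mask: RoiMask, path: str | Path) -> None:
    """Serialize a mask as 0/255 TIFF plus a JSON descriptor sidecar."""
    path = Path(path)
    tifffile.imwrite(path, mask.mask.astype(np.uint8) * 255)
    desc = {
        "roi_kind": mask.roi_kind.value,
        "hemisphere": mask.hemisphere.value,
        "k_sd": mask.k_sd,
        "min_trials": mask.min_trials,
        "n_trials": mask.n_trials,
        "n_pixels": mask.n_pixels,
        "warning": mask.warning,
    }
    path.with_suffix(".json").write_text(json.dumps(desc, indent=1))
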