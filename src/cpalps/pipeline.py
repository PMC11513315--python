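"""End-to-end pipeline: cohort simulation -> phantom realization ->
segmentation & ALPS measurement -> study statistics.

Every random draw descends from one master seed.  Per-subject phantom seeds
use the documented splitting rule ``SeedSequence((master_seed, group_code,
subject_index))`` (group codes: ESRD=1, control=2), so a single subject can
be re-realized identically regardless of cohort size.  Reports record the
full configuration, its hash, and the seed, and reruns with the same
manifest reproduce all numbers bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .calibration import (
    default_alps_roi,
    phantom_spec_for_cp_pct,
    study_cohort_spec,
    tensor_spec_for_alps,
)
from .alps import compute_alps
from .segmentation import SegmentationOptions, segment_cp
from .stats import format_study_report, run_study
from .synthetic import (
    CohortSpec,
    PhantomSpec,
    TensorPhantomSpec,
    generate_cohort,
    generate_phantom,
    generate_tensor_phantom,
)

GROUP_CODE = {"ESRD": 1, "control": 2}


class PipelineError(RuntimeError):
    """Stage failure, tagged with stage name and subject id."""


@dataclass
class PipelineConfig:
    """Configuration of a full simulated-study run."""

    preset: str = "section3"
    seed: int = 0
    out_dir: str = "pipeline_out"
    n_esrd: int | None = None  # None -> the preset's published group sizes
    n_control: int | None = None
    run_segmentation: bool = True  # realize CP% via phantom + GMM segmentation
    run_alps: bool = True  # realize ALPS via tensor phantom + index computation
    save_volumes: bool = False  # write per-subject NIfTI phantoms (large)
    log_level: str = "info"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def subject_seed(master_seed: int, group: str, index: int) -> int:
    """Deterministic per-subject seed, independent of cohort size (< 2^31)."""
    ss = np.random.SeedSequence((int(master_seed), GROUP_CODE[group], int(index)))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_all(
    config: PipelineConfig,
    cohort_spec: CohortSpec | None = None,
    phantom_base: PhantomSpec | None = None,
    tensor_base: TensorPhantomSpec | None = None,
) -> dict:
    """Run the full simulated study and write all artifacts to ``out_dir``.

    Returns the study report.  Measured quantities replace the drawn targets
    in the analyzed cohort table (the targets are kept in ``*_target``
    columns), so the statistics exercise the whole measurement pipeline.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    spec = cohort_spec or study_cohort_spec(config.preset)
    if config.n_esrd is not None:
        spec = replace(spec, esrd=replace(spec.esrd, n=config.n_esrd))
    if config.n_control is not None:
        spec = replace(spec, control=replace(spec.control, n=config.n_control))

    try:
        cohort = generate_cohort(spec, seed=config.seed)
    except Exception as exc:
        raise PipelineError(f"stage simulate failed: {exc}") from exc

    phantom_base = phantom_base or PhantomSpec()
    tensor_base = tensor_base or TensorPhantomSpec()
    roi = default_alps_roi(tensor_base)

    if config.run_segmentation:
        cohort["cp_pct_target"] = cohort["cp_pct"]
    if config.run_alps:
        cohort["alps_target"] = cohort["alps"]

    counters: dict[str, int] = {"ESRD": 0, "control": 0}
    for i, row in cohort.iterrows():
        group = row["group"]
        idx = counters[group]
        counters[group] += 1
        sid = row["subject_id"]
        seed_i = subject_seed(config.seed, group, idx)
        if config.run_segmentation:
            try:
                pspec = phantom_spec_for_cp_pct(float(row["cp_pct"]), seed=seed_i, base=phantom_base)
                t1, vent, cp_true, _ = generate_phantom(pspec)
                res = segment_cp(t1, vent, pspec.tiv_mm3, SegmentationOptions())
                cohort.loc[i, "cp_pct"] = res.cp_volume_pct
                if config.save_volumes:
                    from .volume import write_volume

                    sdir = out / "volumes" / sid
                    sdir.mkdir(parents=True, exist_ok=True)
                    write_volume(t1, sdir / "t1.nii.gz")
                    write_volume(vent, sdir / "ventricles.nii.gz")
                    write_volume(res.cp_mask, sdir / "cp_mask.nii.gz")
            except Exception as exc:
                raise PipelineError(f"stage segment-cp failed for subject {sid}: {exc}") from exc
        if config.run_alps:
            try:
                tspec = tensor_spec_for_alps(float(row["alps"]), seed=seed_i, base=tensor_base)
                tensors, _, _ = generate_tensor_phantom(tspec)
                cohort.loc[i, "alps"] = compute_alps(tensors, roi).index
            except Exception as exc:
                raise PipelineError(f"stage alps failed for subject {sid}: {exc}") from exc

    try:
        report = run_study(cohort)
    except Exception as exc:
        raise PipelineError(f"stage stats failed: {exc}") from exc

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "cohort_columns": list(cohort.columns),
    }
    cohort.to_csv(out / "cohort.tsv", sep="\t", index=False)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (out / "report.txt").write_text(format_study_report(report) + "\n")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return report
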