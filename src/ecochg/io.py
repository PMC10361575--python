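"""Delimited-text and manifest I/O for recordings and simulated cohorts.

Recordings travel as plain TSV (time or sample index, potential) with a
YAML/JSON manifest carrying the stimulus metadata; units must be declared in
the manifest — an undeclared unit is an error, never a guess.  Simulated
cohorts are written one TSV per record plus a cohort manifest listing the
generating parameters, labels, seed, and a dataset digest.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ManifestError
from .forward_model import CohortDataset, CohortSpec
from .signal_core import AverageCycle, StimulusSpec, SweepRecording

__all__ = [
    "read_recording",
    "write_cohort",
    "read_cohort",
    "write_run_log",
]

_POTENTIAL_UNITS = {"uV": 1.0, "mV": 1e3, "V": 1e6}
_TIME_UNITS = {"s": 1.0, "ms": 1e-3, "sample": None}


def read_recording(data_path: str | Path, manifest_path: str | Path) -> SweepRecording:
    """Load one sweep waveform from TSV plus its metadata manifest."""
    manifest_path = Path(manifest_path)
    manifest = yaml.safe_load(manifest_path.read_text())
    if not isinstance(manifest, dict):
        raise ManifestError(f"manifest {manifest_path} is not a mapping")
    units = manifest.get("units")
    if not units or "potential" not in units or "time" not in units:
        raise ManifestError(
            f"manifest {manifest_path} must declare units for time and potential"
        )
    if units["potential"] not in _POTENTIAL_UNITS:
        raise ManifestError(f"unknown potential unit {units['potential']!r}")
    if units["time"] not in _TIME_UNITS:
        raise ManifestError(f"unknown time unit {units['time']!r}")
    table = pd.read_csv(data_path, sep="\t")
    if table.shape[1] < 2:
        raise ManifestError(f"{data_path} must have time and potential columns")
    waveform = table.iloc[:, 1].to_numpy(dtype=float) * _POTENTIAL_UNITS[
        units["potential"]
    ]
    try:
        stimulus = StimulusSpec(**manifest["stimulus"])
    except (KeyError, TypeError) as exc:
        raise ManifestError(f"bad stimulus block in {manifest_path}: {exc}") from exc
    return SweepRecording(
        waveform=waveform,
        stimulus=stimulus,
        subject_id=str(manifest.get("subject_id", "")),
        cohort_tag=str(manifest.get("cohort_tag", "")),
        species=manifest.get("species", "gerbil"),
        pre_ms=float(manifest.get("pre_ms", 0.0)),
        post_ms=float(manifest.get("post_ms", 0.0)),
    )


def _stimulus_dict(stimulus: StimulusSpec) -> dict:
    return {
        "frequency": stimulus.frequency,
        "level": stimulus.level,
        "phase": stimulus.phase,
        "repetitions": stimulus.repetitions,
        "burst_duration_ms": stimulus.burst_duration_ms,
        "sampling_rate": stimulus.sampling_rate,
        "level_scale": stimulus.level_scale,
    }


def write_cohort(dataset: CohortDataset, out_dir: str | Path) -> Path:
    """Write a cohort as per-record TSVs plus a YAML manifest; returns the
    manifest path."""
    out_dir = Path(out_dir)
    records_dir = out_dir / "records"
    records_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, rec in enumerate(dataset.records):
        name = f"record_{i:05d}.tsv"
        pd.DataFrame(
            {
                "sample": np.arange(rec.n_points),
                "condensation_uv": rec.condensation,
                "rarefaction_uv": rec.rarefaction,
            }
        ).to_csv(records_dir / name, sep="\t", index=False, float_format="%.9g")
        entries.append(
            {
                "file": f"records/{name}",
                "subject_id": rec.subject_id,
                "cohort_tag": rec.cohort_tag,
                "species": rec.species,
                "n_points": rec.n_points,
                "stimulus": _stimulus_dict(rec.stimulus),
                "truth": {k: _plain(v) for k, v in rec.truth.items()},
            }
        )
    manifest = {
        "units": {"potential": "uV", "time": "sample"},
        "spec": {
            "preset": dataset.spec.preset,
            "n_subjects": dataset.spec.n_subjects,
            "frequencies": list(dataset.spec.frequencies),
            "levels": list(dataset.spec.levels),
            "snr_db": dataset.spec.snr_db,
            "seed": dataset.spec.seed,
            "n_points": dataset.spec.n_points,
        },
        "digest": dataset.digest(),
        "records": entries,
    }
    manifest_path = out_dir / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest_path


def _plain(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, np.bool_):
        return bool(v)
    return v


def read_cohort(cohort_dir: str | Path) -> CohortDataset:
    """Reconstruct a cohort dataset written by :func:`write_cohort`."""
    cohort_dir = Path(cohort_dir)
    manifest_path = cohort_dir / "manifest.yaml"
    if not manifest_path.exists():
        raise ManifestError(f"no manifest.yaml under {cohort_dir}")
    manifest = yaml.safe_load(manifest_path.read_text())
    units = manifest.get("units", {})
    if units.get("potential") != "uV":
        raise ManifestError("cohort manifest must declare potential unit uV")
    spec_d = manifest["spec"]
    spec = CohortSpec(
        preset=spec_d["preset"],
        n_subjects=spec_d["n_subjects"],
        frequencies=tuple(spec_d["frequencies"]),
        levels=tuple(spec_d["levels"]),
        snr_db=spec_d["snr_db"],
        seed=spec_d["seed"],
        n_points=spec_d["n_points"],
    )
    records = []
    for entry in manifest["records"]:
        table = pd.read_csv(cohort_dir / entry["file"], sep="\t")
        rec = AverageCycle.from_phase_pair(
            table["condensation_uv"].to_numpy(),
            table["rarefaction_uv"].to_numpy(),
            stimulus=StimulusSpec(**entry["stimulus"]),
            n_points=entry["n_points"],
            subject_id=entry["subject_id"],
            cohort_tag=entry["cohort_tag"],
            species=entry["species"],
        ).with_truth(**entry.get("truth", {}))
        records.append(rec)
    return CohortDataset(records=records, spec=spec)


def write_run_log(out_dir: str | Path, command: str, config: dict) -> Path:
    """Record the exact configuration of a command for reproducibility."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = {"command": command, "version": __version__, "config": config}
    path = out_dir / f"run_{command}.json"
    path.write_text(json.dumps(log, indent=2, default=_plain))
    return path
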