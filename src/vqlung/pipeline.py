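"""End-to-end composition: volumes in, tables and a manifest out.

``process_patient`` runs one patient's volumes through segmentation and
dosimetry. ``run_pipeline`` does that for a set of patients, appends the
per-patient metric rows to ``metrics.csv``, runs the cohort analysis
(``table1.csv`` with baseline-characteristic comparisons, ``table2.csv`` with
stratified correlations and dominance labels) and writes a ``manifest.json``
with input hashes, the effective configuration, the software version and the
seed. Outputs contain no timestamps, so a rerun from the same manifest is
byte-identical. A stage failure aborts with the patient and stage named, and
whatever was written is moved to a ``quarantine`` subdirectory.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    PatientRecord,
    compare_characteristics,
    read_cohort_csv,
    records_to_dataframe,
    subgroup_correlations,
)
from .config import RunConfig
from .dosimetry import (
    activity_weighted_metrics,
    compute_metrics,
    cumulative_dvh,
    dvh_to_dataframe,
)
from .grid import resample_mask_to, resample_to, validate_alignment
from .io import write_json, write_mask
from .segmentation import segment_functional
from .synthetic import PhantomBundle


class PipelineError(RuntimeError):
    """A stage failed; message names the patient and the stage."""


def _array_sha256(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


def bundle_hashes(bundle: PhantomBundle) -> dict:
    return {
        "dose": _array_sha256(bundle.dose.values),
        "q_activity": _array_sha256(bundle.q_activity.values),
        "v_activity": _array_sha256(bundle.v_activity.values),
        "lung": _array_sha256(bundle.lung.values.astype(np.uint8)),
    }


def align_bundle(bundle: PhantomBundle, config: RunConfig) -> PhantomBundle:
    """Resample activities (linear) and lung (nearest) onto the dose grid."""
    dose = bundle.dose
    kw = dict(spacing_atol_mm=config.spacing_atol_mm, origin_atol_mm=config.origin_atol_mm)
    q = bundle.q_activity
    v = bundle.v_activity
    lung = bundle.lung
    if not validate_alignment(q, dose, **kw):
        q = resample_to(q, dose, mode="linear")
    if not validate_alignment(v, dose, **kw):
        v = resample_to(v, dose, mode="linear")
    if not validate_alignment(lung, dose, **kw):
        lung = resample_mask_to(lung, dose)
    return PhantomBundle(dose=dose, q_activity=q, v_activity=v, lung=lung)


@dataclass(frozen=True)
class PatientResult:
    patient_id: str
    q_func: object
    v_func: object
    metrics: object
    dvhs: dict


def process_patient(patient_id: str, bundle: PhantomBundle, config: RunConfig) -> PatientResult:
    """Segment functional lung and compute DVHs and the six metrics."""

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise PipelineError(f"patient {patient_id}, stage {name}: {exc}") from exc

    aligned = stage("alignment", lambda: align_bundle(bundle, config))
    q_func = stage(
        "segmentation (perfusion)",
        lambda: segment_functional(
            aligned.q_activity, aligned.lung, config.threshold_fraction, "perfusion"
        ),
    )
    v_func = stage(
        "segmentation (ventilation)",
        lambda: segment_functional(
            aligned.v_activity, aligned.lung, config.threshold_fraction, "ventilation"
        ),
    )
    dvhs = {
        label: stage(
            f"dvh ({label})",
            lambda m=mask, lb=label: cumulative_dvh(
                aligned.dose, m, config.dvh_bin_width_gy, mask_label=lb
            ),
        )
        for label, mask in (
            ("lung", aligned.lung),
            ("Q-functional", q_func.mask),
            ("V-functional", v_func.mask),
        )
    }
    if config.functional_mode == "binary_mask":
        metrics = stage(
            "metrics",
            lambda: compute_metrics(
                aligned.dose, aligned.lung, q_func, v_func,
                x=config.vx_dose_gy, inclusive=config.vx_inclusive,
                provenance={"patient_id": patient_id,
                            "threshold_fraction": config.threshold_fraction},
            ),
        )
    else:
        raise PipelineError(
            f"patient {patient_id}, stage metrics: activity_weighted mode has no "
            "six-metric record; call activity_weighted_metrics directly"
        )
    return PatientResult(patient_id, q_func, v_func, metrics, dvhs)


def _write_patient_outputs(result: PatientResult, out_dir: Path) -> list[str]:
    # manifest paths are relative to out_dir so a rerun elsewhere is byte-identical
    pdir = out_dir / "patients" / result.patient_id
    pdir.mkdir(parents=True, exist_ok=True)
    written = []
    for tag, func in (("q_functional", result.q_func), ("v_functional", result.v_func)):
        nii = pdir / f"{tag}.nii.gz"
        write_mask(func.mask, nii)
        sidecar = pdir / f"{tag}.json"
        write_json(
            {
                "modality": func.modality,
                "threshold_fraction": func.threshold_fraction,
                "reference_max": func.reference_max,
                "voxel_count": func.mask.voxel_count,
            },
            sidecar,
        )
        written += [str(nii.relative_to(out_dir)), str(sidecar.relative_to(out_dir))]
    for label, curve in result.dvhs.items():
        path = pdir / f"dvh_{label.replace('-', '_').lower()}.csv"
        dvh_to_dataframe(curve).to_csv(path, index=False)
        written.append(str(path.relative_to(out_dir)))
    return written


def run_pipeline(
    config: RunConfig,
    patients: dict[str, PhantomBundle] | None = None,
    cohort: list[PatientRecord] | str | Path | None = None,
    out_dir: str | Path = "vqlung_out",
    strata=("copd", "pft", "location", "stage"),
) -> dict:
    """Run the full analysis and write all artifacts under ``out_dir``.

    ``patients`` maps patient id -> aligned volume bundle (per-patient
    segmentation sidecars, DVH CSVs and a metrics.csv row are written).
    ``cohort`` is a list of PatientRecord or a cohort CSV path (table1.csv,
    table2.csv and summary.txt are written). Returns the manifest dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "software": {"name": "vqlung", "version": __version__},
        "config": config.to_dict(),
        "seed": config.seed,
        "inputs": {},
        "outputs": [],
    }
    try:
        if patients:
            rows = []
            for pid in sorted(patients):
                result = process_patient(pid, patients[pid], config)
                manifest["inputs"][pid] = bundle_hashes(patients[pid])
                manifest["outputs"] += _write_patient_outputs(result, out_dir)
                row = {"patient_id": pid}
                row.update(result.metrics.as_dict())
                rows.append(row)
            metrics_csv = out_dir / "metrics.csv"
            pd.DataFrame(rows).to_csv(metrics_csv, index=False)
            manifest["outputs"].append(metrics_csv.name)

        if cohort is not None:
            if isinstance(cohort, (str, Path)):
                manifest["inputs"]["cohort_csv"] = str(cohort)
                cohort = read_cohort_csv(cohort)
            table1 = compare_characteristics(cohort)
            table2 = subgroup_correlations(
                cohort,
                strata=strata,
                epsilon=config.dominance_epsilon,
                p_method=config.p_method,
                n_perm=config.n_perm,
                seed=config.seed,
            ).to_dataframe()
            t1 = out_dir / "table1.csv"
            t2 = out_dir / "table2.csv"
            table1.to_csv(t1, index=False)
            table2.to_csv(t2, index=False)
            events = sum(rec.rilt_event for rec in cohort)
            n = len(cohort)
            summary = out_dir / "summary.txt"
            summary.write_text(
                f"patients: {n}\n"
                f"RILT (grade >= 2): {events} ({100.0 * events / n:.1f}%)\n"
                f"non-RILT (grade <= 1): {n - events} ({100.0 * (n - events) / n:.1f}%)\n"
                f"all-patients comparison: "
                f"{table2[table2.subgroup == 'all'].comparison.iloc[0]}\n"
            )
            manifest["outputs"] += [t1.name, t2.name, summary.name]
    except Exception:
        quarantine = out_dir / "quarantine"
        quarantine.mkdir(exist_ok=True)
        for name in ("metrics.csv", "table1.csv", "table2.csv", "summary.txt"):
            p = out_dir / name
            if p.exists():
                p.rename(quarantine / name)
        raise
    write_json(manifest, out_dir / "manifest.json")
    return manifest
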