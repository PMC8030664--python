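"""File I/O glue: result bundles, cohort directories, text reports."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .lesions import write_mask

__all__ = ["save_results", "write_report", "write_cohort", "load_grid_search"]


def _save_nifti(volume, affine, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), str(path))


def save_results(res, output_dir, atlas_volume=None, region_names=None, prefix="lsm"):
    """Write a fitted :class:`~svrlsm.model.SvrLsmResults` bundle.

    NIfTI beta/p/significance maps, the grid-search trace as JSON, the
    region table as TSV (when an atlas is given) and a text report.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    lm = res.model.lesion_matrix
    if lm is not None:
        _save_nifti(res.beta_volume(), lm.affine, out / f"{prefix}_beta.nii.gz")
        _save_nifti(res.p_volume(), lm.affine, out / f"{prefix}_p.nii.gz")
        _save_nifti(
            res.significance_volume(), lm.affine, out / f"{prefix}_sig.nii.gz"
        )
    if res.search is not None:
        (out / f"{prefix}_grid_search.json").write_text(
            json.dumps(grid_search_to_dict(res.search), indent=2)
        )
    region_table = None
    if atlas_volume is not None and lm is not None:
        region_table = res.region_table(atlas_volume, region_names=region_names)
        region_table.to_csv(out / f"{prefix}_regions.tsv", sep="\t", index=False)
    (out / f"{prefix}_report.txt").write_text(write_report(res, region_table))
    return out


def grid_search_to_dict(search) -> dict:
    return {
        "chosen": vars(search.chosen) | {},
        "model_p": search.model_p,
        "n_permutations": search.n_permutations,
        "seed": search.seed,
        "grid": [
            {"cost": hp.cost, "gamma": hp.gamma, "epsilon": hp.epsilon,
             "cv_mse": mse, "perm_p": p}
            for hp, mse, p in search.grid
        ],
    }


def load_grid_search(path) -> dict:
    return json.loads(Path(path).read_text())


def write_report(res, region_table: pd.DataFrame | None = None) -> str:
    """Deterministic human-readable run report."""
    parts = [res.summary(), ""]
    if region_table is not None:
        parts.append("Significant regions (volume mm3, descending)")
        parts.append("-" * 44)
        if len(region_table):
            parts.append(region_table.to_string(index=False))
        else:
            parts.append("(none)")
        parts.append("")
    return "\n".join(parts)


def write_cohort(cohort, output_dir) -> Path:
    """Write a synthetic cohort as a ready-to-run directory.

    NIfTI masks under ``masks/``, truth-region maps, long-format span and
    detection TSVs, and a JSON snapshot of the generating configuration.
    """
    from dataclasses import asdict

    out = Path(output_dir)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    for m in cohort.masks:
        write_mask(m, out / "masks" / f"{m.subject_id}.nii.gz")
    affine = cohort.masks[0].affine
    _save_nifti(cohort.truth_phon.astype(np.float32), affine, out / "truth_phon.nii.gz")
    _save_nifti(cohort.truth_sem.astype(np.float32), affine, out / "truth_sem.nii.gz")

    span_rows = []
    for sid, tasks in cohort.span_curves.items():
        for task, curve in tasks.items():
            for length, n_trials, n_correct in curve.entries:
                span_rows.append((sid, task.value, length, n_trials, n_correct))
    pd.DataFrame(
        span_rows, columns=["subject_id", "task", "list_length", "n_trials", "n_correct"]
    ).to_csv(out / "spans.tsv", sep="\t", index=False)

    det_rows = []
    for sid, conds in cohort.detections.items():
        c = conds["phonological"]
        det_rows.append((sid, "match", c.n_match, c.n_hits))
        for name, cc in conds.items():
            det_rows.append(
                (sid, f"{name}_foil", cc.n_foil, cc.n_foil - cc.n_false_alarms)
            )
    pd.DataFrame(
        det_rows, columns=["subject_id", "condition", "n_trials", "n_correct"]
    ).to_csv(out / "detections.tsv", sep="\t", index=False)

    cohort.latents.to_csv(out / "latents.tsv", sep="\t", index=False)
    cfg = asdict(cohort.config)
    (out / "sim_config.json").write_text(json.dumps(cfg, indent=2, default=list))
    return out
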