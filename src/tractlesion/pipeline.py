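"""End-to-end orchestration: overlap scoring and cohort regression.

`run_overlap_pipeline` processes a cohort subject by subject: it loads
each subject's native tract and the three template sub-bundles (applying
a supplied affine when the templates still live in template space),
scores transection overlap against the ablation mask, and overlap volumes
against the nuclei segmentation. A subject with a missing or broken asset
is recorded as failed and the run continues; the report lists failures.

`run_cohort_analysis` assembles the per-subject outcome table (percent
score changes at the latest follow-up, treatment summaries, overlaps) and
runs the two-stage forward selection for each response, writing one JSON
model report per response.

All outputs are plain CSV/JSON and deterministic given config + seed.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import clinical as clin
from .errors import TractLesionError, ValidationError
from .overlap import label_overlap_volumes, streamline_mask_overlap
from .regression import two_stage_select
from .spatial import (SpatialTransform, read_affine_text, read_label_volume,
                      read_tractogram, transform_tractogram)

log = logging.getLogger("tractlesion")

RESPONSES = ("crst_a_change", "crst_b_change", "crst_c_change",
             "crst_t_change", "hts_d_change", "hts_nd_change")

DEFAULT_PATIENT_POOL = [
    "age", "sex", "brain_volume", "sdr_mean", "sdr_sd",
    "skull_thickness_mean", "skull_thickness_sd",
    "inner_angle_mean", "inner_angle_sd",
    "outer_angle_mean", "outer_angle_sd",
]
DEFAULT_TREATMENT_POOL = [
    "ablation_volume", "native_overlap", "adrtt_overlap", "mdrtt_overlap",
    "pdrtt_overlap", "max_temperature", "active_elements",
    "total_sonications", "summed_temperature",
]


@dataclass
class RunConfig:
    """Validated run configuration (parsed from YAML)."""

    raw: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(raw=yaml.safe_load(fh) or {})

    def get(self, key, default=None):
        return self.raw.get(key, default)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _write_json(obj, path):
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# overlap pipeline
# ---------------------------------------------------------------------------

def _subject_overlaps(sub: dict, overlap_step, space_id: str):
    """Score one subject; returns (streamline rows, label rows)."""
    mask = read_label_volume(sub["ablation_mask"], space_id=space_id)
    transform = None
    if sub.get("transform_affine"):
        transform = SpatialTransform(affine=read_affine_text(
            sub["transform_affine"]))

    bundles = {"native": read_tractogram(sub["native_tck"], space_id=space_id)}
    for name, path in (sub.get("bundles") or {}).items():
        t = read_tractogram(path, space_id=space_id)
        if transform is not None:
            t = transform_tractogram(t, transform, space_id=space_id)
        bundles[name] = t

    stream_rows = []
    for name, t in bundles.items():
        res = streamline_mask_overlap(t, mask, step=overlap_step,
                                      bundle_name=name)
        log.info("subject %s bundle %s: %d/%d streamlines transected "
                 "(%.2f%%)", sub["id"], name, res.n_transected,
                 res.n_streamlines, res.percent)
        stream_rows.append({"subject_id": sub["id"], "bundle": name,
                            "n_streamlines": res.n_streamlines,
                            "n_transected": res.n_transected,
                            "percent": res.percent})

    label_rows = []
    if sub.get("nuclei_seg"):
        seg = read_label_volume(sub["nuclei_seg"], space_id=space_id)
        lres = label_overlap_volumes(seg, mask)
        for lab, vol in sorted(lres.volumes_mm3.items()):
            label_rows.append({
                "subject_id": sub["id"], "label": lab,
                "name": lres.label_names.get(lab, f"label_{lab}"),
                "overlap_mm3": vol,
            })
    return stream_rows, label_rows


def run_overlap_pipeline(config: RunConfig) -> dict:
    """Run the overlap stage for every subject listed in the config.

    Writes ``overlap_streamlines.csv``, ``overlap_labels.csv`` and
    ``overlap_summary.json`` under ``output_dir``. Per-subject failures
    are isolated: they are logged, recorded in the summary, and the run
    continues; the summary's ``n_failed`` is nonzero in that case.
    """
    out_dir = config.get("output_dir", ".")
    os.makedirs(out_dir, exist_ok=True)
    subjects = config.get("subjects", [])
    if not subjects:
        raise ValidationError("config lists no subjects")
    overlap_step = (config.get("overlap") or {}).get("step")
    space_id = config.get("space_id", "unknown")

    stream_rows, label_rows, failures = [], [], []
    for sub in subjects:
        try:
            srows, lrows = _subject_overlaps(sub, overlap_step, space_id)
            stream_rows.extend(srows)
            label_rows.extend(lrows)
        except (TractLesionError, OSError) as exc:
            log.error("subject %s failed: %s", sub.get("id", "?"), exc)
            failures.append({"subject_id": sub.get("id", "?"),
                             "error": str(exc)})

    sdf = pd.DataFrame(stream_rows,
                       columns=["subject_id", "bundle", "n_streamlines",
                                "n_transected", "percent"])
    sdf.to_csv(os.path.join(out_dir, "overlap_streamlines.csv"), index=False)
    ldf = pd.DataFrame(label_rows,
                       columns=["subject_id", "label", "name", "overlap_mm3"])
    ldf.to_csv(os.path.join(out_dir, "overlap_labels.csv"), index=False)

    report = {
        "n_subjects": len(subjects),
        "n_failed": len(failures),
        "failures": failures,
        "parameters": {"overlap_step": overlap_step, "space_id": space_id},
    }
    _write_json(report, os.path.join(out_dir, "overlap_summary.json"))
    return report


# ---------------------------------------------------------------------------
# cohort table assembly
# ---------------------------------------------------------------------------

def load_clinical_csv(path) -> list:
    """Read the clinical CSV into `ClinicalRecord` objects.

    Expected columns: subject_id, date, timepoint, crst_a, crst_b, crst_c,
    ``hts_d_<item>`` for the eight dominant-hand items and
    ``hts_nd_<item>`` for the seven non-dominant-hand items.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "date": str})
    records = []
    for _, row in df.iterrows():
        records.append(clin.ClinicalRecord(
            subject_id=row["subject_id"],
            timepoint=row["timepoint"],
            date=row.get("date"),
            crst_a=float(row["crst_a"]), crst_b=float(row["crst_b"]),
            crst_c=float(row["crst_c"]),
            hts_items_dominant={i: float(row[f"hts_d_{i}"])
                                for i in clin.HTS_ITEMS_DOMINANT},
            hts_items_nondominant={i: float(row[f"hts_nd_{i}"])
                                   for i in clin.HTS_ITEMS_NONDOMINANT},
        ))
    return records


def score_changes(records: list) -> pd.DataFrame:
    """Percent score changes per subject (pre vs latest follow-up).

    Undefined changes (pre-treatment score of zero) are reported as NaN so
    the affected subject drops out of the regression for that response.
    """
    by_subject = {}
    for r in records:
        by_subject.setdefault(r.subject_id, []).append(r)
    rows = []
    for sid, recs in by_subject.items():
        pre = [r for r in recs if r.timepoint == "pre"]
        if not pre:
            raise ValidationError(f"subject {sid} has no pre-treatment record")
        pre = pre[0]
        post = clin.latest_followup(recs)
        row = {"subject_id": sid}
        pairs = {
            "crst_a_change": (pre.crst_a, post.crst_a),
            "crst_b_change": (pre.crst_b, post.crst_b),
            "crst_c_change": (pre.crst_c, post.crst_c),
            "crst_t_change": (clin.crst_total(pre), clin.crst_total(post)),
            "hts_d_change": (clin.hts_score(pre, "dominant"),
                             clin.hts_score(post, "dominant")),
            "hts_nd_change": (clin.hts_score(pre, "non-dominant"),
                              clin.hts_score(post, "non-dominant")),
        }
        for name, (a, b) in pairs.items():
            try:
                row[name] = clin.percent_change(a, b)
            except TractLesionError:
                row[name] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def load_treatment_csv(arrays_path, scalars_path=None) -> dict:
    """Read per-element arrays (long CSV: subject_id, parameter,
    element_index, value) plus optional per-treatment scalars into
    `TreatmentParams` per subject."""
    df = pd.read_csv(arrays_path, dtype={"subject_id": str})
    scal = (pd.read_csv(scalars_path, dtype={"subject_id": str})
            .set_index("subject_id")
            if scalars_path else None)
    out = {}
    for sid, g in df.groupby("subject_id"):
        arrays = {}
        for param, gp in g.groupby("parameter"):
            gp = gp.sort_values("element_index")
            arrays[param] = gp["value"].to_numpy(dtype=np.float64)
        kw = {}
        if scal is not None and sid in scal.index:
            s = scal.loc[sid]
            kw = {"max_temperature": float(s["max_temperature"]),
                  "active_elements": int(s["active_elements"]),
                  "total_sonications": int(s["total_sonications"]),
                  "summed_temperature": float(s["summed_temperature"])}
        out[sid] = clin.TreatmentParams(subject_id=sid, arrays=arrays, **kw)
    return out


def build_cohort_table(changes: pd.DataFrame, subjects: pd.DataFrame,
                       treatment: dict,
                       overlap_streamlines: pd.DataFrame | None = None,
                       overlap_labels: pd.DataFrame | None = None) -> pd.DataFrame:
    """Merge score changes, subject metadata, treatment summaries and
    overlap measurements into the per-subject regression table."""
    table = changes.merge(subjects, on="subject_id", how="inner")
    trows = []
    for sid, tp in treatment.items():
        summ = clin.treatment_summary(tp)
        row = {"subject_id": sid}
        for param in summ.index:
            row[f"{param}_mean"] = summ.loc[param, "mean"]
            row[f"{param}_sd"] = summ.loc[param, "sd"]
        for scalar in ("max_temperature", "active_elements",
                       "total_sonications", "summed_temperature"):
            v = getattr(tp, scalar)
            if v is not None:
                row[scalar] = v
        trows.append(row)
    if trows:
        table = table.merge(pd.DataFrame(trows), on="subject_id", how="left")
    if overlap_streamlines is not None and len(overlap_streamlines):
        wide = overlap_streamlines.pivot_table(
            index="subject_id", columns="bundle", values="percent")
        wide.columns = [f"{b}_overlap" for b in wide.columns]
        table = table.merge(wide.reset_index(), on="subject_id", how="left")
    if overlap_labels is not None and len(overlap_labels):
        wide = overlap_labels.pivot_table(
            index="subject_id", columns="name", values="overlap_mm3")
        wide.columns = [f"{n}_overlap_mm3" for n in wide.columns]
        table = table.merge(wide.reset_index(), on="subject_id", how="left")
    return table


# ---------------------------------------------------------------------------
# cohort regression
# ---------------------------------------------------------------------------

def model_report(baseline, extended, comparison) -> dict:
    """Serializable report of one two-stage selection run."""
    def _model(m):
        return {"predictors": m.predictors,
                "beta_std": m.beta_std, "beta_raw": m.beta_raw,
                "intercept": m.intercept, "pvalues": m.pvalues,
                "r2": m.r2, "rss": m.rss, "n": m.n}
    return {
        "baseline": _model(baseline),
        "extended": _model(extended),
        "anova": {"f": comparison.f, "p": comparison.p,
                  "df": list(comparison.df), "identical": comparison.identical},
    }


def run_cohort_analysis(config: RunConfig) -> dict:
    """Run the two-stage selection for every response in the config.

    The cohort table either comes ready-made (``cohort_csv``) or is built
    from ``clinical_csv`` + ``subjects_csv`` + ``treatment_csv`` (+
    optional ``scalars_csv`` and the overlap CSVs of a previous overlap
    run). One JSON report per response lands in ``output_dir``; subjects
    flagged ``secondary_lesion`` are dropped when ``exclude_secondary``.
    """
    out_dir = config.get("output_dir", ".")
    os.makedirs(out_dir, exist_ok=True)

    if config.get("cohort_csv"):
        table = pd.read_csv(config.get("cohort_csv"))
    else:
        records = load_clinical_csv(config.get("clinical_csv"))
        changes = score_changes(records)
        subjects = pd.read_csv(config.get("subjects_csv"),
                               dtype={"subject_id": str})
        treatment = load_treatment_csv(config.get("treatment_csv"),
                                       config.get("scalars_csv"))
        ost = (pd.read_csv(config.get("overlap_streamlines_csv"),
                           dtype={"subject_id": str})
               if config.get("overlap_streamlines_csv") else None)
        ola = (pd.read_csv(config.get("overlap_labels_csv"),
                           dtype={"subject_id": str})
               if config.get("overlap_labels_csv") else None)
        table = build_cohort_table(changes, subjects, treatment, ost, ola)

    if config.get("exclude_secondary") and "secondary_lesion" in table:
        table = table[~table["secondary_lesion"].astype(bool)].reset_index(
            drop=True)

    responses = config.get("responses", list(RESPONSES))
    patient_pool = config.get("patient_pool", DEFAULT_PATIENT_POOL)
    treatment_pool = config.get("treatment_pool", DEFAULT_TREATMENT_POOL)
    alpha = float(config.get("alpha", 0.05))

    reports = {}
    for response in responses:
        cols = [response, *patient_pool, *treatment_pool]
        avail = [c for c in cols if c in table.columns]
        sub = table.dropna(subset=avail)
        ppool = [c for c in patient_pool if c in sub.columns]
        tpool = [c for c in treatment_pool if c in sub.columns]
        if len(sub) < len(ppool) // 2 + 4:
            log.warning("response %s: only %d complete rows; skipping",
                        response, len(sub))
            continue
        baseline, extended, comparison = two_stage_select(
            sub, response, ppool, tpool, alpha=alpha)
        rep = model_report(baseline, extended, comparison)
        rep["n_rows"] = int(len(sub))
        reports[response] = rep
        _write_json(rep, os.path.join(out_dir, f"model_{response}.json"))
        log.info("response %s: baseline %s, extended %s (R2=%.3f)",
                 response, baseline.predictors, extended.predictors,
                 extended.r2)
    _write_json({"responses": sorted(reports)},
                os.path.join(out_dir, "analysis_summary.json"))
    return reports
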