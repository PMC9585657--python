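"""Dataset assembly: slice-level instances, patient-level aggregation, splits.

Two analysis modes mirror the study design:

* **single-slice multiple sampling** — every tumor-bearing slice is one
  sample (an augmentation that multiplies the instance count roughly
  eightfold for a typical cohort);
* **multislice** — one sample per patient, the unweighted mean of that
  patient's per-slice feature vectors (area-weighted mean available).

All splits are stratified by label. Slice-level splits are additionally
grouped by patient, so no patient contributes slices to both sides of any
split — a deliberate strengthening against within-patient leakage.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold, train_test_split

from .io import feature_columns

VALID_SCHEMES = ("cv10", "holdout:90:10", "holdout:80:20", "holdout:70:30")


def enumerate_slice_instances(per_patient_tables: dict[str, pd.DataFrame],
                              labels: dict[str, str]) -> pd.DataFrame:
    """Stack per-patient slice feature tables into one slice-level table.

    Parameters
    ----------
    per_patient_tables : dict
        ``patient_id -> DataFrame`` with ``slice_index`` + feature columns
        (one row per eligible tumor-bearing slice).
    labels : dict
        ``patient_id -> label``.

    Patients with zero eligible slices are excluded with a warning.
    """
    frames = []
    for pid, table in per_patient_tables.items():
        if len(table) == 0:
            warnings.warn(f"patient {pid}: no eligible slices; excluded", stacklevel=2)
            continue
        t = table.copy()
        t.insert(0, "patient_id", pid)
        t["label"] = labels[pid]
        frames.append(t)
    if not frames:
        raise ValueError("no patients with eligible slices")
    return pd.concat(frames, ignore_index=True)


def aggregate_multislice(slice_table: pd.DataFrame,
                         weight_by: str | None = None) -> pd.DataFrame:
    """Collapse a slice-level table to one row per patient.

    Features are averaged across a patient's slices — unweighted by default,
    or weighted by a feature column (e.g. ``SHAPE_area_T1C``) when
    ``weight_by`` is given. Records ``n_slices``.
    """
    feats = feature_columns(slice_table)
    rows = []
    for pid, grp in slice_table.groupby("patient_id", sort=True):
        if weight_by is not None:
            w = grp[weight_by].to_numpy(dtype=float)
            if w.sum() <= 0:
                raise ValueError(f"non-positive weights for patient {pid}")
            agg = {f: float(np.average(grp[f], weights=w)) for f in feats}
        else:
            agg = {f: float(grp[f].mean()) for f in feats}
        rows.append(
            {"patient_id": pid, "label": grp["label"].iloc[0], "n_slices": len(grp), **agg}
        )
    return pd.DataFrame(rows, columns=["patient_id", "label", "n_slices"] + feats)


def _binary_y(labels: pd.Series, positive_label: str) -> np.ndarray:
    return (labels.to_numpy() == positive_label).astype(int)


def group_aware_split(
    table: pd.DataFrame,
    scheme: str,
    seed: int = 0,
    positive_label: str = "mutant",
    grouped: bool = True,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Train/test index partitions for a feature table.

    ``scheme`` is ``"cv10"`` (10-fold stratified CV, grouped by patient for
    slice-level tables) or ``"holdout:<train>:<test>"``; row indices refer to
    positions in ``table``. For holdout schemes the patient list itself is
    split with stratification, then slices follow their patient.

    Raises when the minority class cannot cover every CV fold.
    """
    y = _binary_y(table["label"], positive_label)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes required for splitting")
    groups = table["patient_id"].to_numpy()

    if scheme == "cv10" or scheme.startswith("cv"):
        n_folds = int(scheme[2:]) if len(scheme) > 2 else 10
        # per-patient stratification check: pigeonhole on minority patients
        pat = table.drop_duplicates("patient_id")
        n_pos_patients = int((pat["label"] == positive_label).sum())
        n_neg_patients = len(pat) - n_pos_patients
        if min(n_pos_patients, n_neg_patients) < n_folds:
            raise ValueError(
                f"{n_folds}-fold stratification impossible with "
                f"{min(n_pos_patients, n_neg_patients)} minority-class patients; "
                "use fewer folds"
            )
        if grouped:
            splitter = StratifiedGroupKFold(n_splits=n_folds, shuffle=True, random_state=seed)
            return [(tr, te) for tr, te in splitter.split(np.zeros(len(y)), y, groups)]
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        return [(tr, te) for tr, te in splitter.split(np.zeros(len(y)), y)]

    if scheme.startswith("holdout:"):
        parts = scheme.split(":")
        if len(parts) != 3:
            raise ValueError(f"bad holdout scheme {scheme!r}; expected holdout:<train>:<test>")
        train_frac = float(parts[1]) / (float(parts[1]) + float(parts[2]))
        pat = table.drop_duplicates("patient_id")[["patient_id", "label"]]
        train_ids, test_ids = train_test_split(
            pat["patient_id"].to_numpy(),
            train_size=train_frac,
            stratify=pat["label"].to_numpy(),
            random_state=seed,
        )
        tr = np.flatnonzero(np.isin(groups, train_ids))
        te = np.flatnonzero(np.isin(groups, test_ids))
        return [(tr, te)]

    raise ValueError(f"unknown split scheme {scheme!r}; expected one of {VALID_SCHEMES}")
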