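"""Feature separability (one-way ANOVA) and the false-positive workflow.

Per-feature malignant-vs-benign separability is scored with the ANOVA
F-statistic (between-class over within-class variance) and its upper-tail
p-value. Unspecified findings (ROIs not attributable to lesions, scars or
recognized artifacts) are benchmarked against each patient's dominant lesion
intensity, mapped into a standardized top-feature subspace, and counted as
false positives when they fall nearer the malignant centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .radiomics import FEATURE_ORDER

#: Feature subspace of the false-positive mapping: the three top-separability
#: texture/intensity features.
FP_FEATURES = ("First-order Entropy", "GLCM Joint Entropy", "NGTDM Strength")

BENCHMARK_KAPPA = 0.9


class StatsInputError(ValueError):
    pass


def anova_f(values: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """One-way ANOVA F-statistic and p-value for grouped observations.

    F = [sum_k n_k (xbar_k - xbar)^2 / (K-1)] / [sum_ki (x_ki - xbar_k)^2 / (N-K)],
    p the upper tail of F_(K-1, N-K). Zero within-group variance with unequal
    means yields F = inf, p = 0.
    """
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    if not np.all(np.isfinite(values)):
        raise StatsInputError("non-finite feature values")
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise StatsInputError("need at least two classes")
    if any(len(g) < 2 for g in groups):
        raise StatsInputError("each class needs at least 2 observations")
    n = len(values)
    k = len(groups)
    grand = values.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(np.sum((g - g.mean()) ** 2) for g in groups)
    df1, df2 = k - 1, n - k
    if ss_within <= 1e-300 * max(ss_between, 1.0):
        if ss_between <= 0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = (ss_between / df1) / (ss_within / df2)
    p = float(sps.f.sf(f, df1, df2))
    return float(f), p


def separability_table(features: pd.DataFrame, label_col: str = "label",
                       classes: tuple[str, str] = ("malignant", "benign"),
                       n_bins: int = 64) -> pd.DataFrame:
    """Per-feature ANOVA separability report in the canonical feature order.

    ``features`` holds one row per ROI with the 25 feature columns and a
    class label column. Rows with missing values for a feature are flagged in
    the output rather than silently dropped.
    """
    sub = features[features[label_col].isin(classes)]
    if sub.empty:
        raise StatsInputError("no rows for the requested classes")
    rows = []
    for cat, name in FEATURE_ORDER:
        col = f"{cat} {name}"
        vals = sub[col].to_numpy(float)
        labs = sub[label_col].to_numpy()
        ok = np.isfinite(vals)
        flagged = bool((~ok).any())
        try:
            f, p = anova_f(vals[ok], labs[ok])
        except StatsInputError:
            f, p = np.nan, np.nan
            flagged = True
        rows.append({"Feature Category": cat, "Feature Name": name,
                     "Separability Score": f, "p-value": p,
                     "flagged": flagged})
    out = pd.DataFrame(rows)
    out.attrs["metadata"] = {"Metric": "ANOVA", "Fixed Bin Number": n_bins,
                             "Label Category 1": classes[0].capitalize(),
                             "Label Category 2": classes[1].capitalize()}
    return out


def format_separability(table: pd.DataFrame) -> pd.DataFrame:
    """Display form: scores to 2 decimals, p-values to 3, floored at 0."""
    disp = table.copy()
    disp["Separability Score"] = disp["Separability Score"].round(2)
    disp["p-value"] = disp["p-value"].round(3)
    return disp.drop(columns=["flagged"])


# ---------------------------------------------------------------------------
# False-positive workflow
# ---------------------------------------------------------------------------

@dataclass
class FPReport:
    n_healthy_breasts: int
    n_unspecified: int
    n_confused: int
    findings: list[dict] = field(default_factory=list)

    @property
    def fp_rate(self) -> float:
        """Percentage: 100 * confused findings / healthy breasts analyzed."""
        if self.n_healthy_breasts <= 0:
            raise StatsInputError("no healthy breasts in the analysis")
        return 100.0 * self.n_confused / self.n_healthy_breasts


def benchmark_intensity(unspecified: pd.DataFrame, index_lesion_mean: float,
                        kappa: float = BENCHMARK_KAPPA) -> pd.DataFrame:
    """Retain unspecified ROIs of intensity comparable to the index lesion.

    An unspecified finding is retained when its mean intensity is at least
    ``kappa`` times the patient's dominant detected lesion ROI mean
    (kappa = 0 disables the filter).
    """
    if index_lesion_mean <= 0:
        raise StatsInputError("index lesion must have positive mean intensity")
    keep = unspecified["mean_intensity"].to_numpy(float) >= kappa * index_lesion_mean
    return unspecified[keep]


def fp_workflow(features: pd.DataFrame, n_healthy_breasts: int,
                label_col: str = "label",
                patient_col: str = "patient",
                feature_subspace: tuple[str, ...] = FP_FEATURES,
                kappa: float = BENCHMARK_KAPPA) -> FPReport:
    """Count unspecified findings confused with malignant lesions.

    Labeled malignant/benign rows place the class centroids in the
    standardized feature subspace (standardization fit on lesion rows only);
    each retained unspecified finding is assigned to the nearer centroid and
    counted as confused when that is the malignant one. Patients without a
    detected index lesion are excluded before calling this (their findings
    carry no intensity benchmark).
    """
    if n_healthy_breasts <= 0:
        raise StatsInputError("no healthy breasts in the analysis")
    lesions = features[features[label_col].isin(["malignant", "benign"])]
    unspec = features[features[label_col] == "unspecified"]
    if lesions.empty:
        raise StatsInputError("no labeled lesions to place centroids")

    # per-patient intensity benchmark against the dominant malignant/benign ROI
    retained_rows = []
    for pat, grp in unspec.groupby(patient_col):
        idx_rows = lesions[lesions[patient_col] == pat]
        if "index_mean_intensity" in grp.columns and grp["index_mean_intensity"].notna().any():
            bench = float(grp["index_mean_intensity"].iloc[0])
        elif not idx_rows.empty:
            bench = float(idx_rows["mean_intensity"].max())
        else:
            continue  # patient without detected index lesion: excluded
        retained_rows.append(benchmark_intensity(grp, bench, kappa))
    retained = (pd.concat(retained_rows) if retained_rows
                else unspec.iloc[0:0])

    cols = list(feature_subspace)
    X_les = lesions[cols].to_numpy(float)
    mu = X_les.mean(axis=0)
    sd = X_les.std(axis=0)
    sd[sd <= 0] = 1.0
    Z = (X_les - mu) / sd
    lab = lesions[label_col].to_numpy()
    c_mal = Z[lab == "malignant"].mean(axis=0)
    c_ben = Z[lab == "benign"].mean(axis=0)

    findings = []
    n_conf = 0
    if not retained.empty:
        Zu = (retained[cols].to_numpy(float) - mu) / sd
        d_mal = np.linalg.norm(Zu - c_mal, axis=1)
        d_ben = np.linalg.norm(Zu - c_ben, axis=1)
        for r, (row_idx, row) in enumerate(retained.iterrows()):
            confused = bool(d_mal[r] < d_ben[r])
            n_conf += confused
            findings.append({"patient": row[patient_col],
                             "coords": Zu[r].tolist(),
                             "d_malignant": float(d_mal[r]),
                             "d_benign": float(d_ben[r]),
                             "confused": confused})
    return FPReport(n_healthy_breasts=n_healthy_breasts,
                    n_unspecified=int(len(retained)),
                    n_confused=int(n_conf), findings=findings)
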