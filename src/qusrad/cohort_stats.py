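"""Patient-level feature assembly and per-feature two-group statistics.

The radiomic feature vector has 31 entries per patient: the seven spectral
parameters (window means over the ROI, averaged over 3-5 tumor slices) plus
24 texture features (four GLCM statistics on each of the six parametric maps;
no texture is computed for the per-ROI attenuation scalar).

Group comparison (responders vs nonresponders) mirrors common clinical
reporting: Shapiro-Wilk normality per group, then a two-sided Welch t-test
when both groups look normal at alpha = .05, otherwise a two-sided
Mann-Whitney U test; means +/- SEM per group; significance flagged at .05
with no multiplicity correction (a Benjamini-Hochberg column is emitted for
transparency but does not drive the flag).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats
from statsmodels.stats.multitest import multipletests

from .rf_core import ValidationError

logger = logging.getLogger("qusrad")

__all__ = [
    "SPECTRAL_FEATURES",
    "TEXTURE_FEATURES",
    "ALL_FEATURES",
    "PatientFeatureVector",
    "GroupComparisonResult",
    "aggregate_patient",
    "compare_groups",
    "comparison_table",
]

SPECTRAL_FEATURES = ("MBF", "SS", "SI", "ASD", "AAC", "ACE", "SAS")
_TEXTURE_STATS = ("CON", "COR", "ENE", "HOM")
_TEXTURE_MAPS = ("MBF", "SS", "SI", "ASD", "AAC", "SAS")
TEXTURE_FEATURES = tuple(
    f"{m}-{s}" for m in _TEXTURE_MAPS for s in _TEXTURE_STATS
)
ALL_FEATURES = SPECTRAL_FEATURES + TEXTURE_FEATURES  # 7 + 24 = 31


@dataclass
class PatientFeatureVector:
    """The 31 named radiomic features plus response label for one patient."""

    patient_id: str
    response: str
    features: dict
    slice_count: int

    def __post_init__(self) -> None:
        if self.response not in ("R", "NR"):
            raise ValidationError("response must be 'R' or 'NR'")
        missing = set(ALL_FEATURES) - set(self.features)
        extra = set(self.features) - set(ALL_FEATURES)
        if missing or extra:
            raise ValidationError(
                f"feature vector must have exactly the 31 named features; "
                f"missing={sorted(missing)}, extra={sorted(extra)}"
            )
        bad = [k for k, v in self.features.items() if not np.isfinite(v)]
        if bad:
            raise ValidationError(f"non-finite feature values: {bad}")

    def as_series(self) -> pd.Series:
        s = pd.Series({f: self.features[f] for f in ALL_FEATURES})
        s["patient_id"] = self.patient_id
        s["response"] = self.response
        return s


def aggregate_patient(slices, label: str, patient_id: str) -> PatientFeatureVector:
    """Average per-slice features into one patient vector.

    ``slices`` is a sequence of dicts, one per tumor slice, each holding all
    31 features (spectral values already window-averaged within the slice's
    ROI).  3-5 slices is the expected acquisition; other counts produce the
    vector with a warning.
    """
    slices = list(slices)
    if not slices:
        raise ValidationError("at least one slice is required")
    for si, sl in enumerate(slices):
        for f in ALL_FEATURES:
            if f not in sl:
                raise ValidationError(f"slice {si} is missing feature {f!r}")
    if not (3 <= len(slices) <= 5):
        warnings.warn(
            f"patient {patient_id}: {len(slices)} slices outside the expected "
            "3-5 range",
            stacklevel=2,
        )
    feats = {f: float(np.mean([sl[f] for sl in slices])) for f in ALL_FEATURES}
    return PatientFeatureVector(
        patient_id=patient_id, response=label, features=feats,
        slice_count=len(slices),
    )


@dataclass
class GroupComparisonResult:
    feature: str
    mean_r: float
    sem_r: float
    mean_nr: float
    sem_nr: float
    shapiro_p_r: float
    shapiro_p_nr: float
    test_used: str  # "t" or "Mann-Whitney"
    p_value: float
    significant: bool
    p_bh: float = np.nan


def _shapiro_p(x: np.ndarray, feature: str, group: str) -> float:
    if np.ptp(x) == 0:
        logger.warning(
            "feature %s group %s has zero variance; Shapiro-Wilk undefined, "
            "falling back to Mann-Whitney", feature, group,
        )
        return 0.0  # force the nonparametric path
    return float(_stats.shapiro(x).pvalue)


def compare_groups(cohort: pd.DataFrame, alpha: float = 0.05):
    """Per-feature responder/nonresponder comparison.

    Expects a cohort table with a ``response`` column ('R'/'NR') and the 31
    feature columns.  Returns a list of :class:`GroupComparisonResult`.
    """
    for col in ("response", *ALL_FEATURES):
        if col not in cohort.columns:
            raise ValidationError(f"cohort table missing column {col!r}")
    r = cohort[cohort["response"] == "R"]
    nr = cohort[cohort["response"] == "NR"]
    if len(r) < 3 or len(nr) < 3:
        raise ValidationError("both groups need at least 3 members")
    results = []
    for f in ALL_FEATURES:
        xr = r[f].to_numpy(dtype=float)
        xnr = nr[f].to_numpy(dtype=float)
        p_sw_r = _shapiro_p(xr, f, "R")
        p_sw_nr = _shapiro_p(xnr, f, "NR")
        if p_sw_r > alpha and p_sw_nr > alpha:
            test = "t"
            p = float(_stats.ttest_ind(xr, xnr, equal_var=False).pvalue)
        else:
            test = "Mann-Whitney"
            p = float(_stats.mannwhitneyu(xr, xnr, alternative="two-sided").pvalue)
        results.append(
            GroupComparisonResult(
                feature=f,
                mean_r=float(xr.mean()),
                sem_r=float(_stats.sem(xr)),
                mean_nr=float(xnr.mean()),
                sem_nr=float(_stats.sem(xnr)),
                shapiro_p_r=p_sw_r,
                shapiro_p_nr=p_sw_nr,
                test_used=test,
                p_value=p,
                significant=p < alpha,
            )
        )
    _, p_bh, *_ = multipletests([res.p_value for res in results], method="fdr_bh")
    for res, pb in zip(results, p_bh):
        res.p_bh = float(pb)
    return results


def comparison_table(results) -> pd.DataFrame:
    """Group-comparison report as a DataFrame (one row per feature)."""
    return pd.DataFrame(
        [
            {
                "feature": r.feature,
                "mean_R": r.mean_r,
                "SEM_R": r.sem_r,
                "mean_NR": r.mean_nr,
                "SEM_NR": r.sem_nr,
                "test": r.test_used,
                "p": r.p_value,
                "p_BH": r.p_bh,
                "significant": r.significant,
            }
            for r in results
        ]
    )
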