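"""Two-group comparisons, clinical correlations and cohort summaries.

Per band, each of the 66 unordered ROI pairs (and each of the 12 nodes)
gets a pooled-variance two-sided independent-samples t-test at alpha=.05.
Uncorrected p-values are the primary criterion; a Benjamini-Hochberg
column is always reported alongside, never silently replacing them.
Direction labels record whether patients are higher or lower.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDataError, InputError, SchemaError

DEFAULT_ALPHA = 0.05


def two_sample_ttest(x, y, equal_var: bool = True):
    """Independent-samples t-test (pooled variance, two-sided).

    Returns ``(t, p)``.  Zero pooled variance with equal means gives
    t = 0, p = 1; with unequal means it is a degenerate-data error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InputError("each group needs >= 2 values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InputError("non-finite values in input")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if np.isclose(x.mean(), y.mean()):
            return 0.0, 1.0
        raise DegenerateDataError(
            "zero pooled variance with unequal means: t undefined"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(t), float(p)


@dataclass
class GroupStatsResult:
    """Per-test table plus per-band significant counts by direction."""

    table: pd.DataFrame            # one row per band x pair (or band x node)
    alpha_level: float
    kind: str                      # "fc" or "degree"

    def counts(self, direction: str = "patient_higher", corrected: bool = False) -> dict:
        col = "significant_bh" if corrected else "significant"
        t = self.table
        return {
            b: int(((t["band"] == b) & t[col] & (t["direction"] == direction)).sum())
            for b in t["band"].unique()
        }

    def band_table(self, band: str) -> pd.DataFrame:
        return self.table[self.table["band"] == band].reset_index(drop=True)


def _stack_fc(fcs, band):
    mats = [f.R for f in fcs if f.band.name == band]
    if not mats:
        raise InputError(f"no FC matrices for band {band!r}")
    return np.stack(mats)


def compare_fc_groups(
    fc_patients, fc_controls, alpha_level: float = DEFAULT_ALPHA,
    roi_names=None, equal_var: bool = True,
) -> GroupStatsResult:
    """t-test every ROI pair per band between two cohorts of FCMatrix.

    ``fc_patients`` / ``fc_controls`` are flat lists of
    :class:`megfc.connectivity.FCMatrix` covering the bands to compare.
    """
    bands = []
    for f in fc_patients:
        if f.band.name not in bands:
            bands.append(f.band.name)
    for b in bands:
        if not any(f.band.name == b for f in fc_controls):
            raise InputError(f"control group is missing band {b!r}")
    if roi_names is None:
        roi_names = next(iter(fc_patients)).roi_names
    rows = []
    for band in bands:
        P = _stack_fc(fc_patients, band)        # (n_p, R, R)
        C = _stack_fc(fc_controls, band)
        if P.shape[0] < 2 or C.shape[0] < 2:
            raise InputError(f"need >= 2 subjects per group in band {band}")
        n_roi = P.shape[1]
        iu = np.triu_indices(n_roi, k=1)
        with warnings.catch_warnings():
            # near-identical values across subjects (e.g. saturated pairs)
            # trigger scipy's precision-loss warning; t=0/p=1 is the right
            # answer there and needs no escalation
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = stats.ttest_ind(P[:, iu[0], iu[1]], C[:, iu[0], iu[1]],
                                   axis=0, equal_var=equal_var)
        mp = P[:, iu[0], iu[1]].mean(axis=0)
        mc = C[:, iu[0], iu[1]].mean(axis=0)
        for k in range(iu[0].size):
            a, b = iu[0][k], iu[1][k]
            rows.append({
                "band": band,
                "roi_a": roi_names[a] if roi_names else str(a),
                "roi_b": roi_names[b] if roi_names else str(b),
                "mean_patient": mp[k], "mean_control": mc[k],
                "t": float(t[k]), "p": float(p[k]),
                "direction": "patient_higher" if mp[k] > mc[k] else "patient_lower",
            })
    return _finalize(rows, alpha_level, kind="fc")


def compare_degree_groups(
    deg_patients, deg_controls, alpha_level: float = DEFAULT_ALPHA,
    roi_names=None, equal_var: bool = True,
) -> GroupStatsResult:
    """t-test every node's degree per band between two cohorts."""
    bands = []
    for d in deg_patients:
        if d.band.name not in bands:
            bands.append(d.band.name)
    for b in bands:
        if not any(d.band.name == b for d in deg_controls):
            raise InputError(f"control group is missing band {b!r}")
    if roi_names is None:
        roi_names = next(iter(deg_patients)).roi_names
    rows = []
    for band in bands:
        P = np.stack([d.degrees for d in deg_patients if d.band.name == band])
        C = np.stack([d.degrees for d in deg_controls if d.band.name == band])
        if P.shape[0] < 2 or C.shape[0] < 2:
            raise InputError(f"need >= 2 subjects per group in band {band}")
        for i in range(P.shape[1]):
            try:
                t, p = two_sample_ttest(P[:, i], C[:, i], equal_var=equal_var)
            except DegenerateDataError:
                t, p = np.inf * np.sign(P[:, i].mean() - C[:, i].mean()), 0.0
            rows.append({
                "band": band,
                "roi": roi_names[i] if roi_names else str(i),
                "mean_patient": P[:, i].mean(), "mean_control": C[:, i].mean(),
                "t": float(t), "p": float(p),
                "direction": ("patient_higher" if P[:, i].mean() > C[:, i].mean()
                              else "patient_lower"),
            })
    return _finalize(rows, alpha_level, kind="degree")


def _finalize(rows, alpha_level, kind) -> GroupStatsResult:
    df = pd.DataFrame(rows)
    df["significant"] = df["p"] < alpha_level
    df["p_bh"] = np.nan
    for band in df["band"].unique():
        m = df["band"] == band
        _, p_bh, _, _ = multipletests(df.loc[m, "p"], alpha=alpha_level,
                                      method="fdr_bh")
        df.loc[m, "p_bh"] = p_bh
    df["significant_bh"] = df["p_bh"] < alpha_level
    return GroupStatsResult(table=df, alpha_level=alpha_level, kind=kind)


def spearman_clinical(fc_values, covariate):
    """Spearman rank correlation (average ranks) with t-approximation p."""
    x = np.asarray(fc_values, dtype=float)
    y = np.asarray(covariate, dtype=float)
    if x.size != y.size:
        raise InputError("paired observations required")
    if x.size < 4:
        raise InputError(f"need >= 4 paired observations, got {x.size}")
    if np.ptp(y) == 0.0 or np.ptp(x) == 0.0:
        raise DegenerateDataError("constant covariate or FC values")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def report_text(clinical_summary=None, fc_stats: GroupStatsResult | None = None,
                degree_stats: GroupStatsResult | None = None) -> str:
    """Plain-text run report: cohort summary plus per-band findings."""
    lines = []
    if clinical_summary:
        s = clinical_summary
        lines += [
            "Clinical cohort",
            "---------------",
            f"n = {s['n']}  (male/female {s['n_male']}/{s['n_female']})",
            f"age {s['age_mean']} +/- {s['age_sd_sample']} y (sample SD; "
            f"population SD {s['age_sd_population']})",
            f"epilepsy duration {s['duration_mean']} +/- {s['duration_sd_sample']} y",
            f"seizure-free {s['n_seizure_free']}/{s['n']} ({s['seizure_free_pct']}%)",
            f"FCD histopathology {s['n_fcd']}/{s['n']} ({s['fcd_pct']}%)",
            "",
        ]
    for label, res in (("FC pairs", fc_stats), ("node degree", degree_stats)):
        if res is None:
            continue
        lines += [f"Significant group differences: {label}",
                  "-" * (31 + len(label))]
        higher = res.counts("patient_higher")
        lower = res.counts("patient_lower")
        for band in higher:
            lines.append(
                f"{band:>6}: {higher[band]} patient-higher, "
                f"{lower[band]} patient-lower (p < {res.alpha_level}, uncorrected)"
            )
        lines.append("")
    return "\n".join(lines)


_CLINICAL_REQUIRED = (
    "subject_id", "sex", "age_years", "duration_years",
    "histopathology_label", "outcome_label",
)


def load_clinical_table(source=None) -> pd.DataFrame:
    """Load a clinical covariate table (TSV); default is the packaged cohort."""
    if source is None:
        from importlib import resources
        with resources.files("megfc.data").joinpath("clinical_patients.tsv").open() as fh:
            return pd.read_csv(fh, sep="\t")
    if isinstance(source, pd.DataFrame):
        return source.copy()
    return pd.read_csv(source, sep="\t")


def summarize_clinical(table: pd.DataFrame) -> dict:
    """Cohort summary: means +/- SD, sex counts, outcome and pathology rates.

    Both population (ddof=0) and sample (ddof=1) SDs are reported, since
    printed tables are reproducible only under a specific convention.
    Report-style values are rounded to one decimal.
    """
    if table is None or len(table) == 0:
        raise SchemaError("empty clinical table")
    missing = [c for c in _CLINICAL_REQUIRED if c not in table.columns]
    if missing:
        raise SchemaError(f"clinical table missing column(s): {missing}")
    age = table["age_years"].astype(float)
    dur = table["duration_years"].astype(float)
    n = len(table)
    fcd = table["histopathology_label"].str.startswith("FCD")
    seizure_free = table["outcome_label"] == "seizure_free"
    summary = {
        "n": n,
        "age_mean": round(float(age.mean()), 1),
        "age_sd_sample": round(float(age.std(ddof=1)), 1),
        "age_sd_population": round(float(age.std(ddof=0)), 1),
        "duration_mean": round(float(dur.mean()), 1),
        "duration_sd_sample": round(float(dur.std(ddof=1)), 1),
        "duration_sd_population": round(float(dur.std(ddof=0)), 1),
        "n_male": int((table["sex"] == "M").sum()),
        "n_female": int((table["sex"] == "F").sum()),
        "n_seizure_free": int(seizure_free.sum()),
        "seizure_free_pct": round(100.0 * seizure_free.mean()),
        "n_fcd": int(fcd.sum()),
        "fcd_pct": round(100.0 * fcd.mean()),
        "histopathology_counts": table["histopathology_label"].value_counts().to_dict(),
    }
    return summary
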