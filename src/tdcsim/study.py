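"""Within-subject montage comparison over a phantom population.

`run_study` produces a long-format table (one row per subject x montage) of
the three outcome measures plus the peak-midpoint offset; the statistics
layer mirrors the original analysis: one-way repeated-measures ANOVA with
Greenhouse-Geisser (or Huynh-Feldt) sphericity correction, Tukey-HSD
post-hoc tests on the within-subject error term, and two-way mixed-effects
single-measure intraclass correlation between the on-target (ROI) and
whole-brain (99th-percentile) dose measures.

All statistics are computed from explicit sums of squares (numpy/pandas);
scipy supplies the F and studentized-range distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, DesignError, TdcsimError
from .metrics import compute_metrics, locate_roi
from .montage import MONTAGE_NAMES, build_study_montage
from .phantom import ConductivityMap, build_phantom
from .solver import solve_montage
from .tenten import locate_1010

log = logging.getLogger("tdcsim.study")

METRIC_COLUMNS = ("roi_mean", "p99_mean", "focality_mm3", "peak_offset")


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df1: float
    df2: float
    epsilon: float
    p: float
    ms_error: float
    n_subjects: int
    k_conditions: int


@dataclass(frozen=True)
class PairwiseResult:
    condition_a: str
    condition_b: str
    mean_diff: float
    p_adj: float


@dataclass(frozen=True)
class ICCResult:
    montage_name: str
    icc: float
    model: str


# ---------------------------------------------------------------------------
# simulation pipeline
# ---------------------------------------------------------------------------

def run_study(
    population,
    montages=MONTAGE_NAMES,
    sigma: ConductivityMap | None = None,
    current_mA: float = 2.0,
    roi_label: str = "C3",
    roi_radius_mm: float = 10.0,
    solver_tol: float = 1e-8,
    max_abort_fraction: float = 0.05,
) -> pd.DataFrame:
    """Solve every montage on every phantom of the population.

    The ROI is located once per subject (under `roi_label`) and held fixed
    across that subject's montages, so montage contrasts are purely
    electrode effects.  Subjects on which any montage fails geometrically
    are dropped with a logged reason; the study errors out if more than
    `max_abort_fraction` of subjects abort.
    """
    sigma = sigma or ConductivityMap()
    rows = []
    aborted = []
    for subj_id, spec in enumerate(population):
        try:
            phantom = build_phantom(spec)
            eeg = locate_1010(phantom)
            roi = locate_roi(phantom, eeg, label=roi_label, radius_mm=roi_radius_mm)
            subj_rows = []
            for name in montages:
                m = build_study_montage(name, phantom, eeg, total_current_mA=current_mA)
                sol = solve_montage(phantom, m, sigma=sigma, tol=solver_tol)
                ms = compute_metrics(sol, roi)
                if len(m.electrodes) == 2:
                    dist = float(
                        phantom.shape_model.geodesic_distance(
                            m.electrodes[0].center, m.electrodes[1].center
                        )[0]
                    )
                else:
                    dist = float("nan")
                subj_rows.append(
                    {
                        "subject_id": subj_id,
                        "montage_name": name,
                        "round_tag": m.round_tag,
                        "roi_mean": ms.roi_mean_Vpm,
                        "p99_mean": ms.p99_mean_Vpm,
                        "focality_mm3": ms.focality_mm3,
                        "peak_offset": ms.peak_midpoint_offset_mm,
                        "electrode_distance_mm": dist,
                    }
                )
        except TdcsimError as err:
            log.warning("subject %d aborted: %s", subj_id, err)
            aborted.append((subj_id, str(err)))
            continue
        rows.extend(subj_rows)
    n = len(population)
    if n and len(aborted) > max_abort_fraction * n:
        raise TdcsimError(
            f"{len(aborted)}/{n} subjects aborted "
            f"(> {max_abort_fraction:.0%}): {aborted[:3]}..."
        )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id", "montage_name", "round_tag",
            *METRIC_COLUMNS, "electrode_distance_mm",
        ],
    )


def _pivot(table: pd.DataFrame, metric: str, montages=None) -> pd.DataFrame:
    if metric not in table.columns:
        raise DesignError(f"unknown metric {metric!r}")
    sub = table if montages is None else table[table.montage_name.isin(montages)]
    wide = sub.pivot(index="subject_id", columns="montage_name", values=metric)
    if montages is not None:
        missing = [m for m in montages if m not in wide.columns]
        if missing:
            raise DesignError(f"montages absent from table: {missing}")
        wide = wide[list(montages)]
    if wide.isna().any().any():
        raise DesignError("incomplete paired design (missing subject x montage cells)")
    return wide


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------

def gg_epsilon(wide: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the doubly-centred covariance."""
    S = np.cov(wide, rowvar=False, ddof=1)
    k = S.shape[0]
    Sc = (
        S
        - S.mean(axis=0, keepdims=True)
        - S.mean(axis=1, keepdims=True)
        + S.mean()
    )
    num = np.trace(Sc) ** 2
    den = (k - 1) * np.sum(Sc**2)
    if den == 0:
        raise DegenerateDataError("zero covariance structure")
    return float(num / den)


def rm_anova(
    table: pd.DataFrame,
    metric: str,
    montages=None,
    correction: str = "gg",
) -> AnovaResult:
    """One-way repeated-measures ANOVA with sphericity-corrected dfs.

    `correction`: "gg" (Greenhouse-Geisser, default), "hf" (Huynh-Feldt) or
    "none".
    """
    wide = _pivot(table, metric, montages).to_numpy(dtype=float)
    n, k = wide.shape
    if k < 2:
        raise DesignError("need at least 2 conditions")
    if n < 3:
        raise DesignError("need at least 3 subjects")
    grand = wide.mean()
    cond_means = wide.mean(axis=0)
    subj_means = wide.mean(axis=1)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    resid = wide - cond_means[None, :] - subj_means[:, None] + grand
    ss_err = np.sum(resid**2)
    df1 = k - 1.0
    df2 = (k - 1.0) * (n - 1.0)
    if ss_err == 0:
        raise DegenerateDataError("zero within-cell variance everywhere")
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    F = ms_cond / ms_err
    eps = 1.0
    if correction in ("gg", "hf"):
        eps = gg_epsilon(wide)
        if correction == "hf":
            num = n * (k - 1) * eps - 2.0
            den = (k - 1) * (n - 1 - (k - 1) * eps)
            eps = min(num / den, 1.0) if den > 0 else 1.0
    elif correction != "none":
        raise DesignError(f"unknown correction {correction!r}")
    p = float(stats.f.sf(F, df1 * eps, df2 * eps))
    return AnovaResult(
        F=float(F),
        df1=float(df1 * eps),
        df2=float(df2 * eps),
        epsilon=float(eps),
        p=p,
        ms_error=float(ms_err),
        n_subjects=n,
        k_conditions=k,
    )


def tukey_pairs(table: pd.DataFrame, metric: str, montages=None) -> list:
    """All pairwise condition contrasts, Tukey-HSD adjusted.

    The studentized-range statistic uses the within-subject error mean
    square of the repeated-measures ANOVA with its (k-1)(n-1) dfs.
    """
    wide = _pivot(table, metric, montages)
    res = rm_anova(table, metric, montages, correction="none")
    names = list(wide.columns)
    n, k = res.n_subjects, res.k_conditions
    se = np.sqrt(res.ms_error / n)
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(wide.iloc[:, i].mean() - wide.iloc[:, j].mean())
            q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, (k - 1) * (n - 1)))
            out.append(
                PairwiseResult(
                    condition_a=names[i],
                    condition_b=names[j],
                    mean_diff=diff,
                    p_adj=min(max(p, 0.0), 1.0),
                )
            )
    return out


# ---------------------------------------------------------------------------
# ICC between ROI and 99th-percentile dose
# ---------------------------------------------------------------------------

def _icc_mean_squares(data: np.ndarray):
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    return ms_rows, ms_cols, ms_err


def icc_consistency(data: np.ndarray) -> float:
    """ICC(3,1): two-way mixed effects, single measure, consistency."""
    n, k = data.shape
    ms_rows, _, ms_err = _icc_mean_squares(data)
    denom = ms_rows + (k - 1) * ms_err
    if denom == 0:
        raise DegenerateDataError("no variance for ICC")
    return float((ms_rows - ms_err) / denom)


def icc_agreement(data: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, single measure, absolute agreement."""
    n, k = data.shape
    ms_rows, ms_cols, ms_err = _icc_mean_squares(data)
    denom = ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
    if denom == 0:
        raise DegenerateDataError("no variance for ICC")
    return float((ms_rows - ms_err) / denom)


def icc_roi_vs_p99(
    table: pd.DataFrame, montage: str, form: str = "consistency"
) -> ICCResult:
    """Agreement between on-target and whole-brain dose for one montage.

    High ICC means the montage's maximal field lands on the target: subjects
    with strong ROI fields are the same subjects with strong whole-brain
    peaks.  `form` selects consistency (default; a fixed offset between the
    two dose scales is ignored) or absolute agreement.
    """
    sub = table[table.montage_name == montage]
    if len(sub) < 3:
        raise DesignError("need >= 3 subjects for ICC")
    data = sub[["roi_mean", "p99_mean"]].to_numpy(dtype=float)
    if np.allclose(data[:, 0].var(), 0) or np.allclose(data[:, 1].var(), 0):
        raise DegenerateDataError("zero variance in a metric")
    if form == "consistency":
        return ICCResult(montage, icc_consistency(data), "ICC(3,1) consistency")
    if form == "agreement":
        return ICCResult(montage, icc_agreement(data), "ICC(2,1) agreement")
    raise DesignError(f"unknown ICC form {form!r}")


# ---------------------------------------------------------------------------
# ordinal summary of the four modelling rounds
# ---------------------------------------------------------------------------

def _paired_contrast(wide: pd.DataFrame, a: str, b: str) -> dict:
    d = wide[a] - wide[b]
    n = len(d)
    mean = float(d.mean())
    if n > 1 and d.std(ddof=1) > 0:
        half = float(stats.t.ppf(0.975, n - 1) * d.std(ddof=1) / np.sqrt(n))
    else:
        half = 0.0
    return {
        "pair": (a, b),
        "mean_diff": mean,
        "ci95": (mean - half, mean + half),
        "sign_consistency": float((np.sign(d) == np.sign(mean)).mean()) if mean != 0 else 0.0,
    }


def ordinal_report(table: pd.DataFrame) -> dict:
    """Per-round rankings and key paired contrasts; pure function of the table."""
    report: dict = {}
    for tag in sorted(table.round_tag.unique()):
        sub = table[table.round_tag == tag]
        names = list(sub.montage_name.unique())
        block: dict = {}
        for metric in ("roi_mean", "p99_mean", "focality_mm3"):
            wide = _pivot(sub, metric, names)
            means = wide.mean(axis=0)
            ascending = metric == "focality_mm3"
            ranking = list(means.sort_values(ascending=ascending).index)
            block[metric] = {"means": means.to_dict(), "ranking": ranking}
        report[tag] = block
    # headline contrasts of the electrode-position round
    r1 = table[table.round_tag == "round1"]
    if set(("APPS", "M1_SO", "BILAT_M1")) <= set(r1.montage_name.unique()):
        wide = _pivot(r1, "roi_mean", ["APPS", "M1_SO", "BILAT_M1"])
        report["contrasts"] = {
            "roi_mean": [
                _paired_contrast(wide, "APPS", "M1_SO"),
                _paired_contrast(wide, "APPS", "BILAT_M1"),
            ]
        }
    return report
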