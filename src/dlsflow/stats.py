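"""Nonparametric statistical battery for cohort comparisons.

Per-subject summary values (medians over the 15 minutes preceding each
timepoint) are compared with the study's battery: Kruskal-Wallis across the
three groups at each timepoint, followed — only when the omnibus test is
significant — by pairwise Wilcoxon rank-sum tests with Bonferroni
correction; the Friedman test within each group over the four timepoints,
followed by pairwise Wilcoxon signed-rank tests with Bonferroni correction;
a paired signed-rank comparison of central versus peripheral sites; and a
Youden-index cutoff analysis discriminating the control and LPS groups.

All tests are two-sided.  Wilcoxon tests use the exact null distribution
for n <= 25 without ties and the tie/continuity-corrected normal
approximation otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sst

ALPHA = 0.05
TIMEPOINT_WINDOW_S = 900.0      # 15-min summary window before each timepoint
EXACT_N_MAX = 25


@dataclass
class ComparisonResult:
    """One hypothesis test: statistic, raw and Bonferroni-adjusted p."""

    test: str
    statistic: float
    p_raw: float
    contrast: str = ""
    n_per_group: tuple = ()
    p_adjusted: float | None = None

    def adjust(self, n_contrasts: int) -> "ComparisonResult":
        self.p_adjusted = min(1.0, self.p_raw * n_contrasts)
        return self


@dataclass
class CutoffResult:
    """Mean-of-maximal-Youden cutoff with its sensitivity and specificity.

    ``direction`` is "below" when the positive (diseased) class lies below
    the cutoff, "above" otherwise.  Sensitivity and specificity are in
    percent; the Youden index is ``sens/100 + spec/100 - 1``.
    """

    cutoff: float
    sensitivity: float
    specificity: float
    youden: float
    direction: str


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def timepoint_median(series, timepoint_s: float,
                     window_s: float = TIMEPOINT_WINDOW_S) -> float:
    """Median of a series over the half-open window ``[t - w, t)``.

    ``series`` is a :class:`~dlsflow.signals.BloodFlowSeries`-like object
    with ``samples``, ``fs`` and ``start_time``; missing samples (NaN) are
    ignored.  Returns NaN with a warning when no samples fall in the window.
    """
    t = series.times()
    sel = (t >= timepoint_s - window_s) & (t < timepoint_s)
    vals = series.samples[sel]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        warnings.warn(f"no samples in [{timepoint_s - window_s}, {timepoint_s})",
                      stacklevel=2)
        return float("nan")
    return float(np.median(vals))


def kruskal_wallis(groups) -> ComparisonResult:
    """Kruskal-Wallis H test (tie-corrected, chi-square reference).

    ``groups`` is a sequence of >= 3 samples, each with n >= 2.  Identical
    values across all groups yield H = 0 and p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("Kruskal-Wallis needs at least three groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return ComparisonResult("kruskal-wallis", 0.0, 1.0,
                                n_per_group=tuple(g.size for g in groups))
    h, p = sst.kruskal(*groups)
    return ComparisonResult("kruskal-wallis", float(h), float(p),
                            n_per_group=tuple(g.size for g in groups))


def _rank_sum(x, y) -> ComparisonResult:
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("rank-sum test needs n >= 2 per group")
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (max(x.size, y.size) <= EXACT_N_MAX and not ties) else "asymptotic"
    stat, p = sst.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return ComparisonResult("wilcoxon-rank-sum", float(stat), float(p),
                            n_per_group=(x.size, y.size))


def _signed_rank(x, y) -> ComparisonResult:
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("paired test needs equal-length samples")
    d = x - y
    if np.all(d == 0):
        return ComparisonResult("wilcoxon-signed-rank", 0.0, 1.0,
                                n_per_group=(x.size, y.size))
    nz = d[d != 0]
    ties = np.unique(np.abs(nz)).size < nz.size
    method = "exact" if (nz.size <= EXACT_N_MAX and not ties) else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")     # scipy warns on zeros/ties
        stat, p = sst.wilcoxon(x, y, alternative="two-sided", method=method,
                               zero_method="wilcox", correction=(method == "approx"))
    return ComparisonResult("wilcoxon-signed-rank", float(stat), float(p),
                            n_per_group=(x.size, y.size))


def pairwise_wilcoxon(groups, paired: bool = False,
                      labels=None) -> list[ComparisonResult]:
    """All pairwise Wilcoxon tests with Bonferroni over the emitted contrasts.

    Rank-sum (unpaired) or signed-rank (paired) tests for every pair of the
    given samples; each raw p is multiplied by the number of contrasts
    actually performed (capped at 1).
    """
    groups = [np.asarray(g, float) for g in groups]
    labels = labels if labels is not None else [str(i) for i in range(len(groups))]
    pairs = list(combinations(range(len(groups)), 2))
    results = []
    for i, j in pairs:
        res = (_signed_rank if paired else _rank_sum)(groups[i], groups[j])
        res.contrast = f"{labels[i]} vs {labels[j]}"
        results.append(res)
    for res in results:
        res.adjust(len(pairs))
    return results


def friedman(matrix) -> ComparisonResult:
    """Friedman test on a complete subjects x conditions matrix.

    Within-subject rank statistic with chi-square reference; missing cells
    raise (no imputation).  Identical columns yield statistic 0, p = 1.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 3:
        raise ValueError("need a 2-D matrix with >= 2 subjects and >= 3 conditions")
    if not np.all(np.isfinite(m)):
        raise ValueError("Friedman test requires a complete matrix")
    if np.all(m == m[:, :1]):
        return ComparisonResult("friedman", 0.0, 1.0, n_per_group=(m.shape[0],))
    stat, p = sst.friedmanchisquare(*m.T)
    return ComparisonResult("friedman", float(stat), float(p),
                            n_per_group=(m.shape[0],))


def youden_cutoff(values, labels) -> CutoffResult:
    """Mean-of-maximal-Youden-index cutoff with sensitivity/specificity.

    Candidate cutoffs are the midpoints between adjacent sorted unique
    values; sensitivity and specificity are evaluated at each, the final
    cutoff is the mean of all candidates attaining the maximal Youden index,
    and the reported sensitivity/specificity are computed at that final
    cutoff.  The positive (diseased) class is called below the cutoff when
    its median is lower than the reference class's, above otherwise.

    Parameters
    ----------
    values
        Scalar diagnostic values.
    labels
        Boolean array, True for the positive (diseased) class; both classes
        must be present.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if values.shape != labels.shape:
        raise ValueError("values and labels must align")
    pos, neg = values[labels], values[~labels]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    direction = "below" if np.median(pos) < np.median(neg) else "above"

    uniq = np.unique(values)
    if uniq.size == 1:
        candidates = uniq
    else:
        candidates = (uniq[:-1] + uniq[1:]) / 2.0

    def sens_spec(cut):
        if direction == "below":
            sens = np.mean(pos < cut)
            spec = np.mean(neg >= cut)
        else:
            sens = np.mean(pos > cut)
            spec = np.mean(neg <= cut)
        return sens, spec

    youdens = np.array([sum(sens_spec(c)) - 1.0 for c in candidates])
    best = np.max(youdens)
    cutoff = float(np.mean(candidates[youdens == best]))
    sens, spec = sens_spec(cutoff)
    return CutoffResult(cutoff=cutoff, sensitivity=100.0 * sens,
                        specificity=100.0 * spec,
                        youden=float(sens + spec - 1.0), direction=direction)


# ---------------------------------------------------------------------------
# cohort-level battery
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = ("subject_id", "group", "site", "timepoint", "parameter", "value")


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table lacks columns {missing}")
    dup = table.duplicated(subset=["subject_id", "site", "timepoint", "parameter"])
    if dup.any():
        raise ValueError("cohort table has duplicate subject/site/timepoint/parameter rows")
    return table


def run_comparisons(table: pd.DataFrame, alpha: float = ALPHA,
                    positive_group: str = "LPS",
                    reference_group: str = "control") -> dict[str, pd.DataFrame]:
    """Run the full statistical battery on a tidy cohort table.

    ``table`` holds one row per subject x site x timepoint x parameter with
    columns ``subject_id, group, site, timepoint, parameter, value``.

    Returns a dict of tidy result tables:

    ``between_groups``
        Kruskal-Wallis per parameter/site/timepoint, plus pairwise
        Bonferroni-corrected rank-sum rows whenever the omnibus p < alpha.
    ``within_groups``
        Friedman per parameter/site/group over timepoints, plus pairwise
        Bonferroni-corrected signed-rank rows whenever significant.
    ``site_contrast``
        Paired central-vs-peripheral signed-rank per parameter/timepoint.
    ``youden``
        Mean-of-maximal-Youden cutoff discriminating ``positive_group``
        from ``reference_group`` per parameter/site/timepoint.
    """
    table = _check_table(table)
    groups = list(dict.fromkeys(table["group"]))
    tps = list(dict.fromkeys(table["timepoint"]))
    between, within, site_rows, youden_rows = [], [], [], []

    for (param, site, tp), sub in table.groupby(["parameter", "site", "timepoint"],
                                                sort=False):
        samples = [sub.loc[sub["group"] == g, "value"].to_numpy() for g in groups]
        if any(s.size < 2 for s in samples):
            raise ValueError(
                f"omnibus test needs n >= 2 per group for {param}/{site}/{tp}"
            )
        kw = kruskal_wallis(samples)
        between.append(dict(parameter=param, site=site, timepoint=tp,
                            test=kw.test, contrast="omnibus",
                            statistic=kw.statistic, p_raw=kw.p_raw,
                            p_adjusted=np.nan))
        if kw.p_raw < alpha:
            for res in pairwise_wilcoxon(samples, paired=False, labels=groups):
                between.append(dict(parameter=param, site=site, timepoint=tp,
                                    test=res.test, contrast=res.contrast,
                                    statistic=res.statistic, p_raw=res.p_raw,
                                    p_adjusted=res.p_adjusted))
        # Youden discrimination between the positive and reference groups
        if positive_group in groups and reference_group in groups:
            mask = sub["group"].isin([positive_group, reference_group])
            cut = youden_cutoff(sub.loc[mask, "value"].to_numpy(),
                                (sub.loc[mask, "group"] == positive_group).to_numpy())
            youden_rows.append(dict(parameter=param, site=site, timepoint=tp,
                                    cutoff=cut.cutoff, sensitivity=cut.sensitivity,
                                    specificity=cut.specificity, youden=cut.youden,
                                    direction=cut.direction))

    for (param, site, group), sub in table.groupby(["parameter", "site", "group"],
                                                   sort=False):
        if len(tps) < 3:        # within-subject trend needs >= 3 timepoints
            break
        wide = sub.pivot(index="subject_id", columns="timepoint", values="value")
        wide = wide.reindex(columns=tps)
        if wide.isna().any().any():
            raise ValueError(f"incomplete timepoint matrix for {param}/{site}/{group}")
        fr = friedman(wide.to_numpy())
        within.append(dict(parameter=param, site=site, group=group,
                           test=fr.test, contrast="omnibus",
                           statistic=fr.statistic, p_raw=fr.p_raw,
                           p_adjusted=np.nan))
        if fr.p_raw < alpha:
            cols = [wide[tp].to_numpy() for tp in tps]
            for res in pairwise_wilcoxon(cols, paired=True, labels=tps):
                within.append(dict(parameter=param, site=site, group=group,
                                   test=res.test, contrast=res.contrast,
                                   statistic=res.statistic, p_raw=res.p_raw,
                                   p_adjusted=res.p_adjusted))

    for (param, tp), sub in table.groupby(["parameter", "timepoint"], sort=False):
        wide = sub.pivot(index="subject_id", columns="site", values="value")
        if {"central", "peripheral"} <= set(wide.columns) and not wide.isna().any().any():
            res = _signed_rank(wide["central"].to_numpy(),
                               wide["peripheral"].to_numpy())
            site_rows.append(dict(parameter=param, timepoint=tp, test=res.test,
                                  contrast="central vs peripheral",
                                  statistic=res.statistic, p_raw=res.p_raw))

    return {
        "between_groups": pd.DataFrame(between),
        "within_groups": pd.DataFrame(within),
        "site_contrast": pd.DataFrame(site_rows),
        "youden": pd.DataFrame(youden_rows),
    }
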