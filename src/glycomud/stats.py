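"""Grouped glycosite biomarker statistics.

The discovery procedure on an assembled abundance matrix:

1. frequency filter — keep glycoforms detected in at least 70% of all
   samples (both cohorts pooled);
2. per-glycoform two-tailed two-sample t-test (Welch by default) on raw
   abundances, with selection at p < 1e-5 AND detection frequency >= 90%;
3. per-glycoform ROC AUC with the cancer cohort as the positive class;
4. a logistic-regression combined panel per GP group, scored in-sample;
5. glycan-class roll-ups: log2 fold change of class abundance and
   within-(sample, GP group) relative abundances.

No multiple-testing correction enters selection (the stringent 1e-5
cutoff stands on its own); a Benjamini–Hochberg column is available for
reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as scistats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

from .glycans import GlycanClass, classify_glycan
from .matching import AbundanceMatrix

DEFAULT_P_THRESHOLD = 1e-5
DEFAULT_FREQ_THRESHOLD = 0.90
DEFAULT_PREFILTER_FREQ = 0.70


def frequency_filter(matrix: AbundanceMatrix, threshold: float) -> AbundanceMatrix:
    """Retain entries detected in >= threshold of ALL samples (pooled).

    The boundary is inclusive: 63 detections out of 90 samples passes a
    0.70 threshold exactly.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("frequency threshold must lie in [0, 1]")
    if matrix.values.empty:
        raise ValueError("empty abundance matrix")
    freq = matrix.detected.mean(axis=0)
    return matrix.subset_entries(list(freq.index[freq >= threshold]))


def two_sample_test(x: np.ndarray, y: np.ndarray, equal_var: bool = False) -> float:
    """Two-tailed two-sample t-test p-value (Welch unless ``equal_var``).

    Degenerate inputs follow the conventions: zero variance in both
    groups gives p = 1 for equal means and p = 0 for different means;
    fewer than two observations per group is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least two observations")
    if np.var(x) == 0 and np.var(y) == 0:
        return 1.0 if np.mean(x) == np.mean(y) else 0.0
    return float(scistats.ttest_ind(x, y, equal_var=equal_var).pvalue)


def _vectorized_ttest(
    a: np.ndarray, b: np.ndarray, equal_var: bool = False
) -> np.ndarray:
    """Column-wise Welch/pooled t-test p-values with degenerate handling."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = scistats.ttest_ind(a, b, axis=0, equal_var=equal_var).pvalue
    p = np.asarray(p, dtype=float)
    degenerate = (a.var(axis=0) == 0) & (b.var(axis=0) == 0)
    if degenerate.any():
        equal = np.isclose(a.mean(axis=0), b.mean(axis=0))
        p[degenerate & equal] = 1.0
        p[degenerate & ~equal] = 0.0
    return p


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """AUC = P(score_pos > score_neg) + 0.5 P(tie); positive class = True.

    Equivalent to the normalised Mann–Whitney U statistic.
    """
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present to compute an AUC")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def _split_groups(
    matrix: AbundanceMatrix, positive_group: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    labels = matrix.groups.loc[matrix.values.index].to_numpy()
    pos = labels == positive_group
    if not pos.any() or pos.all():
        raise ValueError(
            f"positive group {positive_group!r} must be present along with "
            "at least one other group"
        )
    v = matrix.values.to_numpy(dtype=float)
    return v[pos], v[~pos], pos


def compute_marker_stats(
    matrix: AbundanceMatrix,
    positive_group: str = "cancer",
    p_threshold: float = DEFAULT_P_THRESHOLD,
    freq_threshold: float = DEFAULT_FREQ_THRESHOLD,
    equal_var: bool = False,
    frequency_scope: str = "pooled",
) -> pd.DataFrame:
    """Per-glycoform marker statistics and the two-criterion selection.

    Returns one row per entry with detection frequency, two-tailed
    t-test p-value, ROC AUC (positive = ``positive_group``), group
    means, log2 fold change (positive/negative; NaN when the negative
    mean is zero) and the ``selected`` flag (p < p_threshold strictly
    AND frequency >= freq_threshold inclusively).  ``frequency_scope``
    is ``"pooled"`` (fraction of all samples, the default reading) or
    ``"per_group"`` (both cohorts must individually reach the
    threshold).
    """
    if frequency_scope not in ("pooled", "per_group"):
        raise ValueError("frequency_scope must be 'pooled' or 'per_group'")
    pos_v, neg_v, pos_mask = _split_groups(matrix, positive_group)
    keys = matrix.entry_keys
    det = matrix.detected.to_numpy()
    freq_pooled = det.mean(axis=0)
    freq_pos = det[pos_mask].mean(axis=0)
    freq_neg = det[~pos_mask].mean(axis=0)

    pvals = _vectorized_ttest(pos_v, neg_v, equal_var=equal_var)
    labels = pos_mask
    aucs = np.array(
        [
            roc_auc(matrix.values.iloc[:, j].to_numpy(), labels)
            for j in range(len(keys))
        ]
    )
    mean_pos = pos_v.mean(axis=0)
    mean_neg = neg_v.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.where(
            (mean_neg > 0) & (mean_pos > 0), np.log2(mean_pos / mean_neg), np.nan
        )
    freq_crit = (
        freq_pooled >= freq_threshold
        if frequency_scope == "pooled"
        else (freq_pos >= freq_threshold) & (freq_neg >= freq_threshold)
    )
    selected = (pvals < p_threshold) & freq_crit

    rows = []
    for j, k in enumerate(keys):
        e = matrix.entries.get(k)
        comp = e.total_composition if e is not None else None
        rows.append(
            {
                "entry_key": k,
                "group": matrix.entry_group(k),
                "theoretical_mass": e.theoretical_mass if e else np.nan,
                "hex": comp.hex if comp else pd.NA,
                "hexnac": comp.hexnac if comp else pd.NA,
                "fuc": comp.fuc if comp else pd.NA,
                "neuac": comp.neuac if comp else pd.NA,
                "frequency": freq_pooled[j],
                "frequency_control": freq_neg[j],
                "frequency_cancer": freq_pos[j],
                "p_value": pvals[j],
                "auc": aucs[j],
                "mean_control": mean_neg[j],
                "mean_cancer": mean_pos[j],
                "log2fc": log2fc[j],
                "selected": bool(selected[j]),
            }
        )
    df = pd.DataFrame(rows)
    finite = df["p_value"].notna() & (df["p_value"] > 0)
    df["p_bh"] = np.nan
    if finite.any():
        df.loc[finite, "p_bh"] = multipletests(
            df.loc[finite, "p_value"], method="fdr_bh"
        )[1]
    return df


def select_markers(
    stats_df: pd.DataFrame,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    freq_threshold: float = DEFAULT_FREQ_THRESHOLD,
) -> list[str]:
    """Entry keys with p < p_threshold (strict) and frequency >= freq_threshold."""
    sel = (stats_df["p_value"] < p_threshold) & (stats_df["frequency"] >= freq_threshold)
    return list(stats_df.loc[sel, "entry_key"])


@dataclass
class PanelModel:
    """A logistic-regression combined biomarker panel for one GP group.

    Coefficients are on the standardised-abundance scale (the stored
    means/sds map back to raw abundances); the combined score is the
    linear predictor, and the AUC is computed in-sample on those scores.
    """

    group_label: str
    member_keys: list[str]
    intercept: float
    coefficients: list[float]
    feature_means: list[float]
    feature_sds: list[float]
    combined_scores: pd.Series
    combined_auc: float
    separation_fallback: bool = False

    def to_dict(self) -> dict:
        return {
            "group": self.group_label,
            "members": self.member_keys,
            "intercept": self.intercept,
            "coefficients": dict(zip(self.member_keys, self.coefficients)),
            "feature_means": dict(zip(self.member_keys, self.feature_means)),
            "feature_sds": dict(zip(self.member_keys, self.feature_sds)),
            "combined_auc": self.combined_auc,
            "separation_fallback": self.separation_fallback,
        }


def fit_combined_panel(
    matrix: AbundanceMatrix,
    marker_keys: Sequence[str],
    positive_group: str = "cancer",
    group_label: Optional[str] = None,
) -> PanelModel:
    """Fit the combined logistic panel over the given markers.

    Abundances are standardised, a maximum-likelihood logistic
    regression (intercept + one coefficient per marker) is fitted, and
    the in-sample linear predictor is scored by ROC AUC.  When the fit
    is degenerate (perfect separation, non-convergence), a bounded
    ridge-penalised logistic fit is used instead and flagged.
    """
    marker_keys = list(marker_keys)
    if not marker_keys:
        raise ValueError("panel needs at least one marker")
    missing = [k for k in marker_keys if k not in matrix.values.columns]
    if missing:
        raise ValueError(f"markers absent from matrix: {missing}")
    if group_label is None:
        gl = {matrix.entry_group(k) for k in marker_keys}
        group_label = gl.pop() if len(gl) == 1 else "+".join(sorted(gl | set()))

    X = matrix.values[marker_keys].to_numpy(dtype=float)
    y = (matrix.groups.loc[matrix.values.index] == positive_group).to_numpy()
    if y.all() or not y.any():
        raise ValueError("both classes must be present to fit a panel")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd

    intercept, coefs, fallback = _fit_logistic(Z, y)
    scores = intercept + Z @ coefs
    return PanelModel(
        group_label=group_label,
        member_keys=marker_keys,
        intercept=float(intercept),
        coefficients=[float(c) for c in coefs],
        feature_means=[float(m) for m in mu],
        feature_sds=[float(s) for s in sd],
        combined_scores=pd.Series(scores, index=matrix.values.index, name="score"),
        combined_auc=roc_auc(scores, y),
        separation_fallback=fallback,
    )


def _fit_logistic(Z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, bool]:
    """ML logistic fit; ridge-penalised fallback on separation/divergence."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y.astype(float), sm.add_constant(Z, has_constant="add")).fit(
                disp=0, maxiter=200
            )
        params = np.asarray(res.params, dtype=float)
        converged = bool(res.mle_retvals.get("converged", False))
        if converged and np.all(np.isfinite(params)) and np.abs(params).max() < 1e3:
            return float(params[0]), params[1:], False
    except Exception:
        pass
    clf = LogisticRegression(C=1.0, max_iter=1000)
    clf.fit(Z, y)
    return float(clf.intercept_[0]), clf.coef_[0].astype(float), True


def class_summaries(
    matrix: AbundanceMatrix,
    positive_group: str = "cancer",
    classifier: Callable[[object], GlycanClass] = classify_glycan,
    equal_var: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Glycan-class roll-up per GP group.

    Each entry's *total* composition is classified (two-site totals are
    classified as a whole).  Per (GP group, class): per-sample class
    abundance is the sum of member glycoform abundances; the log2 fold
    change is log2(mean_cancer / mean_control) of class abundance (NaN
    and flagged when the control mean is zero); relative abundances are
    normalised within (sample, GP group) and compared by t-test.

    Returns ``(summary, relative)``: the summary table and the
    per-sample relative abundances (columns MultiIndexed by
    (group, class); relative abundances sum to 1 over the five classes
    within each sample × group with any nonzero signal).
    """
    keys = matrix.entry_keys
    gp_of = {k: matrix.entry_group(k) for k in keys}
    cls_of = {}
    for k in keys:
        e = matrix.entries.get(k)
        if e is None:
            raise ValueError(f"no library entry available to classify {k}")
        cls_of[k] = classifier(e.total_composition)

    gps = sorted(set(gp_of.values()))
    classes = list(GlycanClass)
    abs_frames = {}
    for gp in gps:
        for cl in classes:
            members = [k for k in keys if gp_of[k] == gp and cls_of[k] is cl]
            abs_frames[(gp, cl.value)] = (
                matrix.values[members].sum(axis=1)
                if members
                else pd.Series(0.0, index=matrix.values.index)
            )
    class_abund = pd.DataFrame(abs_frames)
    class_abund.columns = pd.MultiIndex.from_tuples(
        class_abund.columns, names=["group", "glycan_class"]
    )

    rel = class_abund.copy()
    for gp in gps:
        totals = class_abund[gp].sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            block = class_abund[gp].div(totals.replace(0, np.nan), axis=0)
        rel.loc[:, pd.IndexSlice[gp, :]] = block.fillna(0.0).to_numpy()

    y = matrix.groups.loc[matrix.values.index] == positive_group
    rows = []
    for gp in gps:
        for cl in classes:
            a = class_abund[(gp, cl.value)]
            r = rel[(gp, cl.value)]
            m_pos, m_neg = a[y].mean(), a[~y].mean()
            defined = m_neg > 0 and m_pos > 0
            rows.append(
                {
                    "group": gp,
                    "glycan_class": cl.value,
                    "mean_control": m_neg,
                    "mean_cancer": m_pos,
                    "log2fc": np.log2(m_pos / m_neg) if defined else np.nan,
                    "fold_defined": defined,
                    "rel_mean_control": r[~y].mean(),
                    "rel_mean_cancer": r[y].mean(),
                    "p_value_relative": (
                        two_sample_test(r[y], r[~y], equal_var=equal_var)
                        if len(r[y]) >= 2 and len(r[~y]) >= 2
                        else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows), rel


def site_map_report(
    profile: AbundanceMatrix | pd.Series,
    top_n: int = 10,
    group_of: Optional[Callable[[str], str]] = None,
) -> pd.DataFrame:
    """Top glycoforms per GP group with relative-abundance tiers.

    ``profile`` is either an abundance matrix (averaged over samples)
    or a single-sample Series indexed by entry key.  Within each group,
    glycoforms are ranked by their share of the group's total
    abundance; the top ``top_n`` are annotated with a tier: ``>10%``
    (strictly more than 10%), ``1-10%`` (at least 1%), ``<1%``.
    """
    if isinstance(profile, AbundanceMatrix):
        series = profile.values.mean(axis=0)
        group_of = group_of or profile.entry_group
    else:
        series = profile
        group_of = group_of or (lambda k: str(k).split(":", 1)[0])
    if series.empty:
        raise ValueError("empty profile")
    rows = []
    by_group: dict[str, list[str]] = {}
    for k in series.index:
        by_group.setdefault(group_of(k), []).append(k)
    for gp in sorted(by_group):
        sub = series.loc[by_group[gp]].sort_values(ascending=False)
        total = sub.sum()
        for rank, (k, v) in enumerate(sub.head(top_n).items(), start=1):
            share = v / total if total > 0 else 0.0
            tier = ">10%" if share > 0.10 else ("1-10%" if share >= 0.01 else "<1%")
            rows.append(
                {
                    "group": gp,
                    "rank": rank,
                    "entry_key": k,
                    "relative_abundance": share,
                    "tier": tier,
                }
            )
    return pd.DataFrame(rows, columns=["group", "rank", "entry_key", "relative_abundance", "tier"])
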