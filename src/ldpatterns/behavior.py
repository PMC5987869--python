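"""Behavioral analysis of the in-scanner arithmetic task.

Trials without a response inside the item time limit are excluded from
accuracy and reaction-time aggregation and tallied as per-cell non-response
percentages.  Each measure (accuracy, RT, non-response) is then analysed with
a mixed 2 (dyslexia) x 2 (dyscalculia) x 3 (format, within-subject) ANOVA:
between-subject effects are tested against the subject-within-group stratum
and within-subject effects against the format-by-subject stratum, with Type
III sums of squares to accommodate the unbalanced groups.  Pairwise follow-up
comparisons are Bonferroni-corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

EFFECT_ORDER = ("Format", "DL", "DC", "Format x DL", "Format x DC", "DL x DC", "Format x DL x DC")


def filter_trials(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop non-response trials; summarize per subject x format.

    Returns ``(scored, summary)`` where ``summary`` has one row per subject x
    format with trial counts, non-response percentage, accuracy over scored
    trials and mean RT over correct trials.  Cells with no scored trials keep
    NaN accuracy/RT and are flagged.
    """
    t = table.copy()
    missing = t["correct"].isna() | t["rt_s"].isna()
    scored = t[~missing]
    grp = t.groupby(["subject_id", "format"], sort=False, observed=True)
    summary = grp.agg(
        dyslexia=("dyslexia", "first"),
        dyscalculia=("dyscalculia", "first"),
        n_trials=("trial_index", "size"),
        n_nonresponse=("correct", lambda c: int(c.isna().sum())),
    ).reset_index()
    summary["pct_nonresponse"] = 100.0 * summary["n_nonresponse"] / summary["n_trials"]
    acc = scored.groupby(["subject_id", "format"], sort=False, observed=True)["correct"].mean()
    rt = (
        scored[scored["correct"] == 1]
        .groupby(["subject_id", "format"], sort=False, observed=True)["rt_s"]
        .mean()
    )
    key = pd.MultiIndex.from_frame(summary[["subject_id", "format"]])
    summary["accuracy"] = acc.reindex(key).to_numpy()
    summary["mean_rt_s"] = rt.reindex(key).to_numpy()
    summary["no_scored_trials"] = summary["n_nonresponse"] == summary["n_trials"]
    return scored.reset_index(drop=True), summary


def aggregate_cells(table: pd.DataFrame, measure: str, rt_trials: str = "correct") -> pd.DataFrame:
    """Subject x format cell means in wide form for one measure.

    ``measure`` is 'accuracy', 'rt' or 'nonresponse'.  RT cells average
    correct trials by default (``rt_trials='all'`` uses every scored trial).
    Subjects missing any format cell are dropped (listwise deletion).
    """
    _, summary = filter_trials(table)
    if measure == "accuracy":
        summary["value"] = 100.0 * summary["accuracy"]
    elif measure == "rt":
        if rt_trials == "all":
            scored, _ = filter_trials(table)
            rt = scored.groupby(["subject_id", "format"], sort=False, observed=True)["rt_s"].mean()
            key = pd.MultiIndex.from_frame(summary[["subject_id", "format"]])
            summary["value"] = rt.reindex(key).to_numpy()
        else:
            summary["value"] = summary["mean_rt_s"]
    elif measure == "nonresponse":
        summary["value"] = summary["pct_nonresponse"]
    else:
        raise ValueError(f"measure must be 'accuracy', 'rt' or 'nonresponse', got {measure!r}")
    wide = summary.pivot_table(index=["subject_id", "dyslexia", "dyscalculia"], columns="format", values="value")
    wide = wide.dropna(axis=0, how="any").reset_index()
    wide.columns.name = None
    return wide


@dataclass
class AnovaTable:
    """The seven mixed-ANOVA effects for one behavioral measure."""

    table: pd.DataFrame  # effect, df_num, df_den, F, p

    def effect(self, name: str) -> pd.Series:
        return self.table.set_index("effect").loc[name]


def _type3_stratum(Y: np.ndarray, blocks: dict[str, np.ndarray], dof_err: int) -> list[tuple[str, int, float]]:
    """Type III F numerators by model comparison over effect-coded blocks.

    ``Y`` is the long response vector, ``blocks`` maps effect name to its
    design columns (the full model is their concatenation).  Returns
    (effect, df_num, SS_effect) with the full-model RSS appended last under
    the key '__error__'.
    """
    names = list(blocks)
    X_full = np.hstack([blocks[k] for k in names])
    rss_full = float(np.sum((Y - X_full @ np.linalg.lstsq(X_full, Y, rcond=None)[0]) ** 2))
    out = []
    for k in names:
        X_red = np.hstack([blocks[j] for j in names if j != k])
        if X_red.size == 0:
            beta = np.zeros(0)
            rss_red = float(np.sum(Y**2))
        else:
            rss_red = float(np.sum((Y - X_red @ np.linalg.lstsq(X_red, Y, rcond=None)[0]) ** 2))
        out.append((k, blocks[k].shape[1], rss_red - rss_full))
    out.append(("__error__", dof_err, rss_full))
    return out


def mixed_anova(wide: pd.DataFrame, formats: tuple = ("dots", "digits", "words")) -> AnovaTable:
    """Mixed 2 x 2 x (len(formats)) ANOVA on subject x format cell means.

    ``wide`` must carry ``subject_id``, ``dyslexia``, ``dyscalculia`` and one
    column per format.  Between-subject effects (DL, DC, DL x DC) are tested
    against subjects-within-groups; within-subject effects (Format and its
    interactions) against the format x subject residual.  No sphericity
    correction is applied (degrees of freedom are reported uncorrected).
    """
    missing = [f for f in formats if f not in wide.columns]
    if missing:
        raise ValueError(f"missing format columns: {missing}")
    dl = wide["dyslexia"].to_numpy(bool)
    dc = wide["dyscalculia"].to_numpy(bool)
    Y = wide.loc[:, list(formats)].to_numpy(float)
    N, p = Y.shape
    cells = [(~dl & ~dc), (dl & ~dc), (~dl & dc), (dl & dc)]
    if any(c.sum() < 2 for c in cells):
        raise ValueError(f"every dyslexia x dyscalculia cell needs >= 2 subjects; sizes {[int(c.sum()) for c in cells]}")
    a = np.where(dl, 1.0, -1.0)[:, None]
    b = np.where(dc, 1.0, -1.0)[:, None]

    # between-subject stratum: subject means, error = subjects within groups
    m = Y.mean(axis=1)
    blocks_b = {
        "intercept": np.ones((N, 1)),
        "DL": a,
        "DC": b,
        "DL x DC": a * b,
    }
    between = _type3_stratum(m, blocks_b, N - 4)
    rss_b = dict((k, ss) for k, _, ss in between)["__error__"]
    mse_b = rss_b / (N - 4)

    # within-subject stratum: row-centered data in long form
    W = (Y - m[:, None]).ravel()  # subject-major, format-minor
    F_codes = np.zeros((p, p - 1))
    F_codes[: p - 1, :] = np.eye(p - 1)
    F_codes[p - 1, :] = -1.0
    fmt_block = np.tile(F_codes, (N, 1))
    a_long = np.repeat(a, p, axis=0)
    b_long = np.repeat(b, p, axis=0)
    blocks_w = {
        "Format": fmt_block,
        "Format x DL": fmt_block * a_long,
        "Format x DC": fmt_block * b_long,
        "Format x DL x DC": fmt_block * a_long * b_long,
    }
    dof_w = (N - 4) * (p - 1)
    within = _type3_stratum(W, blocks_w, dof_w)
    rss_w = dict((k, ss) for k, _, ss in within)["__error__"]
    mse_w = rss_w / dof_w

    # relative scale to recognise exactly-degenerate strata (all cells equal)
    tiny = 1e-12 * max(float(np.mean(Y**2)), 1e-300)

    def _f(ss, dfn, mse):
        if mse < tiny:
            return np.inf if ss > tiny else 0.0
        return max(ss / dfn / mse, 0.0)

    rows = []
    for name, dfn, ss in within[:-1]:
        F = _f(ss, dfn, mse_w)
        rows.append((name, dfn, dof_w, F, float(stats.f.sf(F, dfn, dof_w))))
    for name, dfn, ss in between[:-1]:
        if name == "intercept":
            continue
        F = _f(ss, dfn, mse_b)
        rows.append((name, dfn, N - 4, F, float(stats.f.sf(F, dfn, N - 4))))
    table = pd.DataFrame(rows, columns=["effect", "df_num", "df_den", "F", "p"])
    table["effect"] = pd.Categorical(table["effect"], categories=EFFECT_ORDER, ordered=True)
    table = table.sort_values("effect").reset_index(drop=True)
    return AnovaTable(table=table)


def bonferroni_pairwise(comparisons: pd.DataFrame, p_col: str = "p_raw") -> pd.DataFrame:
    """Bonferroni adjustment over a family: p_adj = min(1, m * p_raw)."""
    out = comparisons.copy()
    m = len(out)
    if m < 1:
        raise ValueError("comparison family must contain at least one comparison")
    out["p_adj"] = np.minimum(1.0, m * out[p_col].to_numpy(float))
    return out


def pairwise_format_comparisons(wide: pd.DataFrame, formats: tuple = ("dots", "digits", "words")) -> pd.DataFrame:
    """Paired t-tests between formats on marginal means, Bonferroni-corrected."""
    rows = []
    for i in range(len(formats)):
        for j in range(i + 1, len(formats)):
            x, y = wide[formats[i]].to_numpy(float), wide[formats[j]].to_numpy(float)
            t, pval = stats.ttest_rel(x, y)
            rows.append((f"{formats[i]} vs {formats[j]}", float(np.mean(x - y)), float(t), float(pval)))
    return bonferroni_pairwise(pd.DataFrame(rows, columns=["comparison", "mean_diff", "t", "p_raw"]))
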