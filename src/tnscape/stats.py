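"""Window- and gene-level summaries of the insertion landscape.

100-nt tiling windows carry insertion density, mean decoded state, mean
conservation/diversity and a mutually exclusive annotation class; on top of
those sit the annotation-class comparisons, the model-free functional
threshold (95th percentile of insertion density in essential coding
windows), and gene-level fitness correlations.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, pearsonr, spearmanr

from .genome import ANNOTATION_CLASSES, AnnotationSet, Genome

#: Window size (nt) and the minimum mappable fraction for a mean state.
WINDOW = 100
MIN_MAPPABLE_FRACTION = 0.95


def _window_sums(values: np.ndarray, window: int, n_win: int) -> np.ndarray:
    return values[: n_win * window].reshape(n_win, window).sum(axis=1)


def window_metrics(
    genome: Genome,
    site_table: pd.DataFrame,
    states_full: dict[str, np.ndarray] | None,
    mask: dict[str, np.ndarray] | None = None,
    conservation: dict[str, np.ndarray] | None = None,
    diversity: dict[str, np.ndarray] | None = None,
    class_codes: dict[str, np.ndarray] | None = None,
    window: int = WINDOW,
    min_mappable: float = MIN_MAPPABLE_FRACTION,
) -> pd.DataFrame:
    """Non-overlapping tiling windows with per-window metrics.

    ``unique`` counts strand-resolved insertion sites, ``mean_count`` is the
    total deduplicated count divided by window length (zero-count bases
    included). The mean decoded state is reported only for windows with at
    least ``min_mappable`` of positions mappable. Windows entirely covered
    by one annotation class get that class; others are unassigned. Trailing
    partial windows are dropped.
    """
    sites_by_chrom = dict(tuple(site_table.groupby("chrom")))
    rows = []
    for chrom, length in genome.chrom_lengths.items():
        n_win = length // window
        if n_win == 0:
            continue
        unique = np.zeros(n_win * window)
        counts = np.zeros(n_win * window)
        if chrom in sites_by_chrom:
            grp = sites_by_chrom[chrom]
            pos = grp["pos"].to_numpy()
            keep = pos < n_win * window
            np.add.at(unique, pos[keep], 1.0)
            np.add.at(counts, pos[keep], grp["count"].to_numpy()[keep].astype(float))
        uniq_w = _window_sums(unique, window, n_win)
        count_w = _window_sums(counts, window, n_win) / window
        if mask is not None:
            map_frac = _window_sums(np.asarray(mask[chrom], float), window, n_win) / window
        else:
            map_frac = np.ones(n_win)
        if states_full is not None:
            st = np.asarray(states_full[chrom], float)[: n_win * window]
            st = np.where(st > 0, st, np.nan)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                mean_state = np.nanmean(st.reshape(n_win, window), axis=1)
            mean_state = np.where(map_frac >= min_mappable, mean_state, np.nan)
        else:
            mean_state = np.full(n_win, np.nan)
        mean_cons = _window_nanmean(conservation, chrom, window, n_win)
        mean_div = _window_nanmean(diversity, chrom, window, n_win)
        if class_codes is not None:
            codes = np.asarray(class_codes[chrom][: n_win * window]).reshape(n_win, window)
            uniform = (codes == codes[:, :1]).all(axis=1)
            dominant = np.where(
                uniform, codes[:, 0], -1
            )
        else:
            dominant = np.full(n_win, -1)
        for w in range(n_win):
            rows.append(
                (
                    chrom, w * window, uniq_w[w], count_w[w], mean_state[w],
                    mean_cons[w], mean_div[w], map_frac[w],
                    ANNOTATION_CLASSES[dominant[w]] if dominant[w] >= 0 else None,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "unique", "mean_count", "mean_state",
            "mean_conservation", "mean_diversity", "mappable_fraction", "class",
        ],
    )


def _window_nanmean(track, chrom, window, n_win):
    if track is None:
        return np.full(n_win, np.nan)
    vals = np.asarray(track[chrom], float)[: n_win * window].reshape(n_win, window)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(vals, axis=1)


def state_category(mean_state: float | np.ndarray) -> np.ndarray | int:
    """Window state category: 1 or 2 only for exact means, 3-5 within 0.5.

    Category 1 (or 2) requires the window mean to be exactly 1 (or 2) —
    which is frequent, because decoded states come in long constant runs;
    categories 3-5 take any mean within 0.5 of the state. Everything else
    (including NaN) is 0, "none".
    """
    m = np.asarray(mean_state, dtype=float)
    out = np.zeros(m.shape, dtype=np.int64)
    eps = 1e-9
    out[np.abs(m - 1.0) <= eps] = 1
    out[np.abs(m - 2.0) <= eps] = 2
    for k in (3, 4, 5):
        sel = (np.abs(m - k) < 0.5) & (out == 0) & (np.abs(m - 1.0) > eps) & (
            np.abs(m - 2.0) > eps
        )
        out[sel] = k
    if np.isscalar(mean_state):
        return int(out)
    return out


def rank_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p (normal approximation with continuity
    correction; exact when both samples are small and tie-free)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    method = "auto" if (len(x) < 50 and len(y) < 50) else "asymptotic"
    return float(mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def annotation_class_summary(
    windows: pd.DataFrame,
    metric: str,
    group_col: str = "class",
    order: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class distribution summaries plus adjacent-pair rank tests.

    Windows without a group assignment are ignored. Classes with fewer than
    two windows are skipped in testing, with a note. P-values are computed
    on untrimmed data (outlier trimming is a display concern only).
    """
    data = windows[windows[group_col].notna()]
    if order is None:
        order = [c for c in ANNOTATION_CLASSES if c in set(data[group_col])]
    summaries = []
    for cls in order:
        vals = data.loc[data[group_col] == cls, metric].dropna()
        summaries.append(
            (cls, len(vals), vals.median() if len(vals) else np.nan,
             vals.mean() if len(vals) else np.nan)
        )
    summary = pd.DataFrame(summaries, columns=[group_col, "n", "median", "mean"])
    tests = []
    for a, b in zip(order, order[1:]):
        xa = data.loc[data[group_col] == a, metric].dropna().to_numpy()
        xb = data.loc[data[group_col] == b, metric].dropna().to_numpy()
        if len(xa) < 2 or len(xb) < 2:
            tests.append((a, b, np.nan, "skipped: <2 windows"))
            continue
        tests.append((a, b, rank_test(xa, xb), ""))
    test_df = pd.DataFrame(tests, columns=["group_a", "group_b", "p", "note"])
    return summary, test_df


def percentile_linear(values: np.ndarray, pct: float) -> float:
    """Linear-interpolation percentile (the 'type 7' definition)."""
    return float(np.percentile(np.asarray(values, float), pct, method="linear"))


def model_free_threshold(
    windows: pd.DataFrame,
    pct: float = 95.0,
    metric: str = "unique",
    essential_class: str = "eCDS",
    constraint_col: str = "mean_conservation",
    threshold: float | None = None,
) -> dict:
    """Model-free functional threshold from essential-coding insertion density.

    The threshold is the ``pct``-th percentile of ``metric`` over windows
    fully inside essential CDS; windows strictly below it count as
    insertion-depleted ("functional"). Reports the genome-wide fraction
    below, per-class fractions, and a rank-sum comparison of conservation
    between below- and above-threshold noncoding windows. An explicit
    ``threshold`` skips the percentile computation (useful for degenerate
    inputs such as an empty site table, where any positive threshold puts
    every window below).
    """
    import logging

    ess = windows[windows["class"] == essential_class]
    if threshold is None:
        if len(ess) == 0:
            raise ValueError("no windows fully inside essential CDS")
        if len(ess) < 20:
            logging.getLogger("tnscape").warning(
                "only %d essential-CDS windows; the percentile threshold is unstable",
                len(ess),
            )
        threshold = percentile_linear(ess[metric].to_numpy(), pct)
    below = windows[metric] < threshold
    per_class = {}
    for cls in ANNOTATION_CLASSES:
        sel = windows["class"] == cls
        per_class[cls] = float(below[sel].mean()) if sel.any() else float("nan")
    noncoding = windows["class"].isin(["UTR_intron", "ncRNA", "unannotated"])
    low = windows.loc[noncoding & below, constraint_col].dropna()
    high = windows.loc[noncoding & ~below, constraint_col].dropna()
    comparison = {
        "low_mean_constraint": float(low.mean()) if len(low) else float("nan"),
        "high_mean_constraint": float(high.mean()) if len(high) else float("nan"),
        "p": rank_test(low.to_numpy(), high.to_numpy())
        if len(low) >= 2 and len(high) >= 2
        else float("nan"),
    }
    return {
        "threshold": threshold,
        "fraction_below": float(below.mean()),
        "per_class_fraction_below": per_class,
        "constraint_comparison": comparison,
        "n_essential_windows": int(len(ess)),
    }


def gene_metrics(
    annotations: AnnotationSet,
    site_table: pd.DataFrame,
    states_full: dict[str, np.ndarray],
    mask: dict[str, np.ndarray] | None = None,
    cds_only: bool = False,
) -> pd.DataFrame:
    """Per-gene unique insertion sites/nt and mean decoded state.

    The gene span is the full transcript extent by default (CDS-only behind
    a flag); insertions/nt uses the mappable span length. Genes with zero
    mappable length are excluded (reported via the ``excluded`` column count
    upstream)."""
    feats = annotations.of_type("CDS") if cds_only else annotations.features
    feats = feats[feats["gene_id"] != ""]
    spans = feats.groupby("gene_id").agg(
        chrom=("chrom", "first"), start=("start", "min"), end=("end", "max")
    )
    sites_by_chrom = dict(tuple(site_table.groupby("chrom")))
    rows = []
    for gid, row in spans.iterrows():
        chrom, start, end = row["chrom"], int(row["start"]), int(row["end"])
        if chrom not in states_full:
            continue
        m = (
            np.asarray(mask[chrom][start:end], bool)
            if mask is not None
            else np.ones(end - start, bool)
        )
        mappable_len = int(m.sum())
        if mappable_len == 0:
            rows.append((gid, chrom, start, end, 0, np.nan, np.nan, True))
            continue
        n_sites = 0
        if chrom in sites_by_chrom:
            pos = sites_by_chrom[chrom]["pos"].to_numpy()
            inside = (pos >= start) & (pos < end)
            n_sites = int(m[pos[inside] - start].sum())
        st = np.asarray(states_full[chrom][start:end], float)[m]
        st = st[st > 0]
        mean_state = float(st.mean()) if len(st) else np.nan
        rows.append(
            (gid, chrom, start, end, mappable_len, n_sites / mappable_len,
             mean_state, False)
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "chrom", "start", "end", "mappable_length",
            "inserts_per_nt", "mean_state", "excluded",
        ],
    )
    out["essentiality"] = out["gene_id"].map(annotations.gene_status)
    return out


def gene_metrics_and_correlation(
    annotations: AnnotationSet,
    site_table: pd.DataFrame,
    states_full: dict[str, np.ndarray],
    fitness_table: pd.DataFrame,
    mask: dict[str, np.ndarray] | None = None,
    cds_only: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Gene metrics joined to a fitness table, with correlation report.

    ``fitness_table`` needs gene_id and fitness columns (e.g. knockout
    colony size); genes without fitness are skipped. Pearson and Spearman
    correlations are reported for each metric with the shared-gene count.
    """
    metrics = gene_metrics(annotations, site_table, states_full, mask, cds_only)
    merged = metrics[~metrics["excluded"]].merge(
        fitness_table[["gene_id", "fitness"]], on="gene_id", how="inner"
    )
    merged = merged.dropna(subset=["fitness"])
    if len(merged) < 3:
        raise ValueError(f"only {len(merged)} genes shared with the fitness table")
    report: dict = {"n": int(len(merged)), "excluded": int(metrics["excluded"].sum())}
    for metric in ("inserts_per_nt", "mean_state"):
        sub = merged.dropna(subset=[metric])
        report[metric] = {
            "pearson_r": float(pearsonr(sub[metric], sub["fitness"])[0]),
            "spearman_r": float(spearmanr(sub[metric], sub["fitness"])[0]),
            "n": int(len(sub)),
        }
    return merged, report
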