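"""HMM-defined elements (HDEs): maximal runs of one decoded state.

Unmappable gaps break runs, so the retained elements exactly tile the
mappable genome. HDE boundaries are compared to annotation edges against a
random-placement null.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .genome import ANNOTATION_CLASSES, AnnotationSet
from .io import _constant_runs

HDE_COLUMNS = ["chrom", "start", "end", "state", "length"]

#: Edge-type priority for breaking exact ties (highest first).
EDGE_PRIORITY = ["five_prime_UTR", "three_prime_UTR", "transcript", "CDS", "ncRNA"]


def path_to_full(length: int, positions: np.ndarray, path: np.ndarray) -> np.ndarray:
    """Expand a mappable-positions state path to a full-length array
    (0 marks unmappable/undecoded bases)."""
    full = np.zeros(length, dtype=np.int64)
    full[np.asarray(positions)] = np.asarray(path)
    return full


def decode_to_hdes(states_full: dict[str, np.ndarray]) -> pd.DataFrame:
    """Run-length encode decoded states into HDEs.

    ``states_full`` maps chromosome to a per-base state array with 0 at
    unmappable positions; zero runs are dropped, so a state run interrupted
    by an unmappable gap yields two elements.
    """
    rows = []
    for chrom, states in states_full.items():
        for start, end, value in _constant_runs(np.asarray(states, dtype=float)):
            if value > 0:
                rows.append((chrom, start, end, int(value), end - start))
    return pd.DataFrame(rows, columns=HDE_COLUMNS)


def filter_hdes(
    hdes: pd.DataFrame, drop_states: set[int] = frozenset({4, 5})
) -> tuple[pd.DataFrame, dict]:
    """Drop S4/S5 elements; summarise what remains.

    The retained fraction is retained length over total mappable length
    (the HDEs tile the mappable genome, so their total length is its size).
    """
    mappable_length = int(hdes["length"].sum())
    kept = hdes[~hdes["state"].isin(drop_states)].reset_index(drop=True)
    summary = {
        "n_hdes": int(len(kept)),
        "median_length": float(kept["length"].median()) if len(kept) else float("nan"),
        "retained_fraction": (
            float(kept["length"].sum() / mappable_length) if mappable_length else 0.0
        ),
    }
    return kept, summary


def annotation_edges(annotations: AnnotationSet) -> pd.DataFrame:
    """All annotation boundary coordinates with their edge type.

    Both endpoints of every feature of an edge-bearing type contribute; at a
    shared coordinate only the highest-priority type is kept (UTR >
    transcript > CDS > ncRNA), which makes nearest-edge typing deterministic.
    """
    rows = []
    for row in annotations.of_type(*EDGE_PRIORITY).itertuples():
        rows.append((row.chrom, row.start, row.type))
        rows.append((row.chrom, row.end, row.type))
    edges = pd.DataFrame(rows, columns=["chrom", "coord", "type"])
    if len(edges) == 0:
        raise ValueError("annotation edge set is empty")
    edges["priority"] = edges["type"].map(EDGE_PRIORITY.index)
    edges = (
        edges.sort_values(["chrom", "coord", "priority"], kind="stable")
        .drop_duplicates(subset=["chrom", "coord"], keep="first")
        .reset_index(drop=True)
    )
    return edges


def _nearest_edges(query: np.ndarray, coords: np.ndarray, priority: np.ndarray):
    """Distance and index of the nearest coordinate for each query.

    Exact distance ties between the left and right neighbour go to the
    higher-priority type, then to the left edge.
    """
    idx_right = np.searchsorted(coords, query)
    idx_left = np.clip(idx_right - 1, 0, len(coords) - 1)
    idx_right = np.clip(idx_right, 0, len(coords) - 1)
    d_left = np.abs(query - coords[idx_left])
    d_right = np.abs(coords[idx_right] - query)
    take_left = (d_left < d_right) | (
        (d_left == d_right) & (priority[idx_left] <= priority[idx_right])
    )
    chosen = np.where(take_left, idx_left, idx_right)
    return np.minimum(d_left, d_right), chosen


def edge_distance_analysis(
    hdes: pd.DataFrame,
    annotations: AnnotationSet,
    chrom_lengths: dict[str, int],
    n_null: int = 100,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, np.ndarray, float]:
    """Distances from HDE edges to the nearest annotation edge, versus a
    random-placement null.

    The null keeps the number and lengths of elements per chromosome but
    places them uniformly at random (overlaps allowed), ``n_null`` times;
    distances are pooled. Returns (per-edge table, null distances, two-sided
    rank-sum p-value).
    """
    rng = np.random.default_rng(seed)
    edges = annotation_edges(annotations)
    by_chrom = {
        chrom: (grp["coord"].to_numpy(), grp["priority"].to_numpy(), grp["type"].to_numpy())
        for chrom, grp in edges.groupby("chrom")
    }
    obs_rows = []
    for chrom, grp in hdes.groupby("chrom"):
        if chrom not in by_chrom:
            continue
        coords, priority, types = by_chrom[chrom]
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        states = grp["state"].to_numpy()
        for which, q in (("start", starts), ("end", ends)):
            dist, chosen = _nearest_edges(q, coords, priority)
            for j in range(len(q)):
                obs_rows.append(
                    (chrom, int(q[j]), which, int(states[j]), int(dist[j]),
                     types[chosen[j]])
                )
    obs = pd.DataFrame(
        obs_rows, columns=["chrom", "coord", "edge", "state", "distance", "nearest_type"]
    )
    null_dists = []
    for _ in range(n_null):
        for chrom, grp in hdes.groupby("chrom"):
            if chrom not in by_chrom:
                continue
            coords, priority, _types = by_chrom[chrom]
            lengths = grp["length"].to_numpy()
            max_start = np.maximum(chrom_lengths[chrom] - lengths, 1)
            starts = (rng.random(len(lengths)) * max_start).astype(np.int64)
            q = np.concatenate([starts, starts + lengths])
            dist, _ = _nearest_edges(q, coords, priority)
            null_dists.append(dist)
    null = np.concatenate(null_dists) if null_dists else np.array([])
    if len(obs) and len(null):
        p = float(
            mannwhitneyu(obs["distance"], null, alternative="two-sided").pvalue
        )
    else:
        p = float("nan")
    return obs, null, p


def hde_summaries(
    hdes: pd.DataFrame,
    class_codes: dict[str, np.ndarray],
    conservation: dict[str, np.ndarray] | None = None,
    expression: dict[str, np.ndarray] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-HDE metrics and per-state aggregates.

    Per HDE: length, mean conservation, mean expression and the fraction of
    bases in each annotation class. Per state: element count, mean length
    and mean class composition.
    """
    per_rows = []
    n_classes = len(ANNOTATION_CLASSES)
    for row in hdes.itertuples():
        codes = class_codes[row.chrom][row.start : row.end]
        comp = np.bincount(codes, minlength=n_classes) / len(codes)
        cons = (
            float(np.nanmean(conservation[row.chrom][row.start : row.end]))
            if conservation is not None
            else float("nan")
        )
        expr = (
            float(np.nanmean(expression[row.chrom][row.start : row.end]))
            if expression is not None
            else float("nan")
        )
        per_rows.append(
            (row.chrom, row.start, row.end, row.state, row.length, cons, expr, *comp)
        )
    per_hde = pd.DataFrame(
        per_rows,
        columns=[
            "chrom", "start", "end", "state", "length",
            "mean_conservation", "mean_expression",
            *[f"frac_{c}" for c in ANNOTATION_CLASSES],
        ],
    )
    aggs = {"length": "mean", "mean_conservation": "mean", "mean_expression": "mean"}
    aggs.update({f"frac_{c}": "mean" for c in ANNOTATION_CLASSES})
    per_state = per_hde.groupby("state").agg(
        n=("length", "size"), total_length=("length", "sum"), **{
            k: (k, v) for k, v in aggs.items()
        }
    ).reset_index()
    return per_hde, per_state
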