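"""Insertion-site calling from aligned read records.

Deduplicates PCR copies by UMI, applies the mapping-quality filter, groups
surviving reads into a strand-resolved site table, and derives the mappability
mask from read retention in 500-nt windows.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import Genome, Track

UMI_RE = re.compile(r"^[ACGT]{10}$")

#: Mapping-quality cutoff used throughout (reads below are discarded).
MIN_MAPQ = 30
#: Window size and minimum read-retention fraction for the mappability mask.
MAPPABILITY_WINDOW = 500
MIN_RETAINED = 0.9


@dataclass
class DedupReport:
    """Bookkeeping from UMI deduplication."""

    n_input: int = 0
    n_malformed: int = 0
    n_duplicates: int = 0
    n_output: int = 0
    malformed_examples: list[str] = field(default_factory=list)


def deduplicate_umis(
    records: pd.DataFrame, umi_only: bool = False
) -> tuple[pd.DataFrame, DedupReport]:
    """Collapse PCR duplicates: one record per (chrom, pos, strand, umi).

    The first record in input order survives. Records with a malformed UMI
    (not 10 nt over ACGT) are rejected and counted in the report. With
    ``umi_only=True`` the key is the UMI alone — the literal reading of
    "exactly matching 10mers" — which additionally collapses genuinely
    independent insertions whose UMIs collide.
    """
    report = DedupReport(n_input=len(records))
    if len(records) == 0:
        return records.copy(), report
    ok = records["umi"].str.fullmatch(UMI_RE)
    report.n_malformed = int((~ok).sum())
    report.malformed_examples = records.loc[~ok, "umi"].head(5).tolist()
    valid = records[ok]
    key = ["umi"] if umi_only else ["chrom", "pos", "strand", "umi"]
    deduped = valid.drop_duplicates(subset=key, keep="first")
    report.n_duplicates = len(valid) - len(deduped)
    report.n_output = len(deduped)
    return deduped.reset_index(drop=True), report


def call_insertion_sites(records: pd.DataFrame, min_mapq: int = MIN_MAPQ) -> pd.DataFrame:
    """Group deduplicated records into per-(chrom,pos,strand) counts.

    Records with mapq < ``min_mapq`` are dropped; insertions at the same
    position but on opposite strands are distinct sites.
    """
    kept = records[records["mapq"] >= min_mapq]
    if len(kept) == 0:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "count"]).astype(
            {"pos": np.int64, "count": np.int64}
        )
    sites = (
        kept.groupby(["chrom", "pos", "strand"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    return sites


def per_base_counts(sites: pd.DataFrame, genome: Genome) -> Track:
    """Total deduplicated insertion count per base (strands summed)."""
    track = Track.zeros(genome, "insertion_count")
    for chrom, grp in sites.groupby("chrom"):
        if chrom in track.data:
            np.add.at(track.data[chrom], grp["pos"].to_numpy(), grp["count"].to_numpy())
    return track


def unique_site_counts(sites: pd.DataFrame, genome: Genome) -> Track:
    """Number of unique strand-resolved insertion sites per base (0, 1 or 2)."""
    track = Track.zeros(genome, "unique_sites")
    for chrom, grp in sites.groupby("chrom"):
        if chrom in track.data:
            np.add.at(track.data[chrom], grp["pos"].to_numpy(), 1.0)
    return track


def mappability_mask(
    records_prefilter: pd.DataFrame,
    records_postfilter: pd.DataFrame,
    genome: Genome,
    window: int = MAPPABILITY_WINDOW,
    min_retained: float = MIN_RETAINED,
) -> tuple[Track, float]:
    """Per-base mappability from read retention in tiling windows.

    A base is mappable iff its window retained at least ``min_retained`` of
    the prefilter reads after quality filtering. Windows with zero prefilter
    reads are mappable by convention (0/0 counts as full retention); the last
    partial window is evaluated on its actual span. Returns the boolean mask
    (as a 0/1 track) and the mappable fraction of the genome.
    """
    mask = Track.full(genome, 1.0, "mappable")
    pre_by_chrom = dict(tuple(records_prefilter.groupby("chrom")))
    post_by_chrom = dict(tuple(records_postfilter.groupby("chrom")))
    total = mappable = 0
    for chrom, length in genome.chrom_lengths.items():
        n_win = (length + window - 1) // window
        pre = np.zeros(n_win)
        post = np.zeros(n_win)
        if chrom in pre_by_chrom:
            np.add.at(pre, pre_by_chrom[chrom]["pos"].to_numpy() // window, 1.0)
        if chrom in post_by_chrom:
            np.add.at(post, post_by_chrom[chrom]["pos"].to_numpy() // window, 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            retained = np.where(pre > 0, post / np.maximum(pre, 1), 1.0)
        win_ok = retained >= min_retained
        mask.data[chrom] = np.repeat(win_ok.astype(float), window)[:length]
        total += length
        mappable += int(mask.data[chrom].sum())
    return mask, mappable / total if total else 0.0


def mask_to_bed(mask: Track) -> pd.DataFrame:
    """Mappable intervals as a BED-style table."""
    from .io import _constant_runs

    rows = [
        (chrom, s, e)
        for chrom, values in mask.data.items()
        for s, e, v in _constant_runs(np.asarray(values, dtype=float))
        if v > 0
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])
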