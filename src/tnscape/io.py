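"""Readers and writers for the flat formats the pipeline touches.

FASTA via Biopython; GFF3, bedGraph and the TSV dialects via pandas. GFF3 is
1-based inclusive on disk and converted to 0-based half-open on load (and back
on write); bedGraph is already 0-based half-open.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import (
    FEATURE_COLUMNS,
    KNOWN_FEATURE_TYPES,
    AnnotationSet,
    Genome,
    Track,
)

log = logging.getLogger("tnscape")

RECORD_COLUMNS = ["chrom", "pos", "strand", "umi", "mapq"]
SITE_COLUMNS = ["chrom", "pos", "strand", "count"]


class FormatError(ValueError):
    """A malformed line in an input file; the message names file and line."""


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> Genome:
    names, seqs = [], {}
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        seqs[rec.id] = str(rec.seq).upper()
    if not names:
        raise FormatError(f"{path}: no FASTA records found")
    return Genome(names, seqs)


def write_fasta(path: str | Path, genome: Genome, width: int = 80) -> None:
    recs = [
        SeqRecord(Seq(genome.sequence[c]), id=c, description="")
        for c in genome.chrom_names
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


# ---------------------------------------------------------------- GFF3

def read_gff3(path: str | Path, genome: Genome | None = None) -> pd.DataFrame:
    """Parse GFF3 into the internal feature table (0-based half-open).

    Unknown feature types are skipped with a logged warning; malformed lines
    raise :class:`FormatError` naming the file and line number.
    """
    rows = []
    unknown: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(parts)}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype not in KNOWN_FEATURE_TYPES:
                unknown.add(ftype)
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start_i < 1 or end_i < start_i:
                raise FormatError(f"{path}:{lineno}: bad interval {start}-{end}")
            gene_id = _parse_gene_id(attrs)
            rows.append((chrom, start_i - 1, end_i, strand, ftype, gene_id))
    if unknown:
        log.warning("ignored unknown GFF3 feature types: %s", sorted(unknown))
    feats = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    if genome is not None:
        lengths = genome.chrom_lengths
        bad = feats[
            ~feats["chrom"].isin(lengths)
            | (feats["end"] > feats["chrom"].map(lengths).fillna(-1))
        ]
        if len(bad):
            raise FormatError(
                f"{path}: features outside the genome:\n{bad.head(10)}"
            )
    return feats


def _parse_gene_id(attrs: str) -> str:
    fields = dict(
        kv.split("=", 1) for kv in attrs.split(";") if kv and "=" in kv
    )
    for key in ("gene_id", "Parent", "ID"):
        if key in fields:
            return fields[key]
    return ""


def write_gff3(path: str | Path, features: pd.DataFrame, source: str = "tnscape") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in features.itertuples():
            attrs = f"ID={row.gene_id}" if row.gene_id else "."
            fh.write(
                f"{row.chrom}\t{source}\t{row.type}\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\t{attrs}\n"
            )


def read_essentiality(path: str | Path) -> dict[str, str]:
    """Two-column TSV gene_id -> {essential, nonessential, unknown}."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "status"], comment="#")
    allowed = {"essential", "nonessential", "unknown"}
    bad = df[~df["status"].isin(allowed)]
    if len(bad):
        raise FormatError(f"{path}: bad essentiality values:\n{bad.head(10)}")
    return dict(zip(df["gene_id"], df["status"]))


def write_essentiality(path: str | Path, essentiality: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for gid, status in essentiality.items():
            fh.write(f"{gid}\t{status}\n")


# ---------------------------------------------------------------- bedGraph

def read_bedgraph(
    path: str | Path, genome: Genome, semantic: str = "", missing: float = np.nan
) -> Track:
    """Load a bedGraph into a per-base track; uncovered bases get ``missing``."""
    track = Track.full(genome, missing, semantic or Path(path).stem)
    lengths = genome.chrom_lengths
    offenders = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            chrom, start, end, value = parts
            if chrom not in lengths:
                offenders.append(chrom)
                continue
            try:
                s, e, v = int(start), int(end), float(value)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad numeric field") from exc
            if not (0 <= s < e <= lengths[chrom]):
                raise FormatError(f"{path}:{lineno}: interval outside chromosome")
            track.data[chrom][s:e] = v
    if offenders:
        raise FormatError(
            f"{path}: chromosomes absent from genome: {sorted(set(offenders))}"
        )
    return track


def write_bedgraph(path: str | Path, track: Track, skip_missing: bool = True) -> None:
    """Write a track as bedGraph, merging runs of constant value."""
    with open(path, "w") as fh:
        for chrom, values in track.data.items():
            for start, end, value in _constant_runs(values):
                if skip_missing and np.isnan(value):
                    continue
                fh.write(f"{chrom}\t{start}\t{end}\t{_fmt(value)}\n")


def _fmt(value: float) -> str:
    return str(int(value)) if float(value).is_integer() else repr(float(value))


def _constant_runs(values: np.ndarray):
    """Yield (start, end, value) runs; NaN runs are grouped together."""
    n = len(values)
    if n == 0:
        return
    vals = np.asarray(values, dtype=float)
    same = (vals[1:] == vals[:-1]) | (np.isnan(vals[1:]) & np.isnan(vals[:-1]))
    breaks = np.flatnonzero(~same) + 1
    starts = np.concatenate([[0], breaks])
    ends = np.concatenate([breaks, [n]])
    for s, e in zip(starts, ends):
        yield int(s), int(e), vals[s]


def write_state_track(path: str | Path, states: Track | dict[str, np.ndarray]) -> None:
    """Decoded Viterbi states as bedGraph (state 0 = unmappable, skipped)."""
    if isinstance(states, dict):
        states = Track(states, "hmm_state")
    masked = Track(
        {c: np.where(v > 0, v, np.nan) for c, v in states.data.items()},
        states.semantic or "hmm_state",
    )
    write_bedgraph(path, masked, skip_missing=True)


def read_state_track(path: str | Path, genome: Genome) -> dict[str, np.ndarray]:
    track = read_bedgraph(path, genome, "hmm_state")
    return {
        c: np.nan_to_num(v, nan=0.0).astype(np.int64) for c, v in track.data.items()
    }


# ---------------------------------------------------------------- TSV tables

def read_records(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "umi": str})
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: record table missing columns {missing}")
    return df[RECORD_COLUMNS]


def write_records(path: str | Path, records: pd.DataFrame) -> None:
    records[RECORD_COLUMNS].to_csv(path, sep="\t", index=False)


def read_site_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: site table missing columns {missing}")
    return df[SITE_COLUMNS]


def write_site_table(path: str | Path, sites: pd.DataFrame) -> None:
    sites[SITE_COLUMNS].to_csv(path, sep="\t", index=False)


def write_bed(path: str | Path, intervals: pd.DataFrame, score_col: str | None = None) -> None:
    """BED6 writer (name '.', strand '+' unless provided)."""
    with open(path, "w") as fh:
        for row in intervals.itertuples():
            score = getattr(row, score_col) if score_col else 0
            strand = getattr(row, "strand", "+")
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t.\t{score}\t{strand}\n")


# ---------------------------------------------------------------- bundle

def load_inputs(
    genome_path: str | Path,
    gff_path: str | Path,
    track_paths: dict[str, str | Path],
    records_path: str | Path,
    essentiality_path: str | Path | None = None,
) -> tuple[Genome, AnnotationSet, dict[str, Track], pd.DataFrame]:
    """Load the full input bundle, converting all coordinates to internal form."""
    genome = read_fasta(genome_path)
    features = read_gff3(gff_path, genome)
    essentiality = read_essentiality(essentiality_path) if essentiality_path else {}
    annotations = AnnotationSet(features, essentiality)
    tracks = {
        name: read_bedgraph(path, genome, semantic=name)
        for name, path in track_paths.items()
    }
    records = read_records(records_path)
    return genome, annotations, tracks, records
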