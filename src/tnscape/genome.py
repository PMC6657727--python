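"""Core in-memory containers: genome sequences, annotations, per-base tracks.

All coordinates are 0-based half-open internally. Conversion to the 1-based
inclusive GFF3 convention happens only inside the readers/writers in
:mod:`tnscape.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Feature types the pipeline understands; anything else is ignored on load.
KNOWN_FEATURE_TYPES = (
    "CDS",
    "five_prime_UTR",
    "three_prime_UTR",
    "intron",
    "ncRNA",
    "transcript",
)

#: Mutually exclusive annotation classes for per-base labelling, in priority
#: order (a base in both an essential CDS and a UTR is counted as eCDS).
ANNOTATION_CLASSES = ("eCDS", "nCDS", "UTR_intron", "ncRNA", "unannotated")

FEATURE_COLUMNS = ["chrom", "start", "end", "strand", "type", "gene_id"]


@dataclass
class Genome:
    """Nucleotide sequences keyed by chromosome, in a fixed order."""

    chrom_names: list[str]
    sequence: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        missing = [c for c in self.chrom_names if c not in self.sequence]
        if missing:
            raise ValueError(f"no sequence for chromosomes: {missing}")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(self.sequence[c]) for c in self.chrom_names}

    def __len__(self) -> int:
        return sum(self.chrom_lengths.values())


@dataclass
class AnnotationSet:
    """Genomic features plus a gene-level essentiality call.

    ``features`` has columns chrom/start/end/strand/type/gene_id with 0-based
    half-open coordinates; ``essentiality`` maps gene_id to one of
    ``essential`` / ``nonessential`` / ``unknown``.
    """

    features: pd.DataFrame
    essentiality: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in FEATURE_COLUMNS if c not in self.features.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing}")
        feats = self.features
        if len(feats) and not (feats["start"] < feats["end"]).all():
            bad = feats[~(feats["start"] < feats["end"])]
            raise ValueError(f"empty/inverted intervals:\n{bad}")
        cds = feats[feats["type"] == "CDS"]
        if len(cds) and (cds["gene_id"].isna() | (cds["gene_id"] == "")).any():
            raise ValueError("every CDS feature needs a gene_id")

    def of_type(self, *types: str) -> pd.DataFrame:
        return self.features[self.features["type"].isin(types)]

    def gene_status(self, gene_id: str) -> str:
        return self.essentiality.get(gene_id, "unknown")

    def gene_ids(self) -> list[str]:
        ids = self.features["gene_id"].dropna()
        return sorted(set(ids[ids != ""]))


@dataclass
class Track:
    """One float value per genomic base; NaN marks missing data."""

    data: dict[str, np.ndarray]
    semantic: str = ""

    def __post_init__(self) -> None:
        self.data = {c: np.asarray(v, dtype=float) for c, v in self.data.items()}

    def validate_against(self, genome: Genome) -> None:
        for chrom, length in genome.chrom_lengths.items():
            if chrom not in self.data:
                raise ValueError(f"track {self.semantic!r} missing chromosome {chrom}")
            if len(self.data[chrom]) != length:
                raise ValueError(
                    f"track {self.semantic!r} length {len(self.data[chrom])} != "
                    f"chromosome {chrom} length {length}"
                )

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.data[chrom]

    @classmethod
    def zeros(cls, genome: Genome, semantic: str = "") -> "Track":
        return cls(
            {c: np.zeros(n) for c, n in genome.chrom_lengths.items()}, semantic
        )

    @classmethod
    def full(cls, genome: Genome, value: float, semantic: str = "") -> "Track":
        return cls(
            {c: np.full(n, value, dtype=float) for c, n in genome.chrom_lengths.items()},
            semantic,
        )


def annotation_class_track(genome: Genome, annotations: AnnotationSet) -> dict[str, np.ndarray]:
    """Label every base with one mutually exclusive annotation class.

    Classes and precedence: eCDS > nCDS > UTR/intron > ncRNA > unannotated.
    Returns int8 arrays indexing into :data:`ANNOTATION_CLASSES`.
    """
    unann = ANNOTATION_CLASSES.index("unannotated")
    labels = {
        c: np.full(n, unann, dtype=np.int8) for c, n in genome.chrom_lengths.items()
    }
    # paint lowest priority first so higher classes overwrite
    order = [
        ("ncRNA", ("ncRNA",)),
        ("UTR_intron", ("five_prime_UTR", "three_prime_UTR", "intron")),
        ("nCDS", ("CDS",)),
        ("eCDS", ("CDS",)),
    ]
    for cls_name, types in order:
        code = ANNOTATION_CLASSES.index(cls_name)
        feats = annotations.of_type(*types)
        if cls_name in ("eCDS", "nCDS"):
            want = "essential" if cls_name == "eCDS" else "nonessential"
            keep = feats["gene_id"].map(lambda g: annotations.gene_status(g) == want)
            feats = feats[keep.fillna(False)]
        for row in feats.itertuples():
            if row.chrom in labels:
                labels[row.chrom][row.start : row.end] = code
    return labels
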