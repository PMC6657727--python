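"""Insertion sequence preference: motif learning and the genome-wide
insertion motif similarity score (IMSS).

The transposase prefers a degenerate sequence at the integration site. From
in-vitro insertion positions we tabulate per-position nucleotide frequencies
in a 41-nt window centred on each insertion, pick the 20-position window that
deviates most from the genome-wide base composition, and score every genomic
position with the log-likelihood ratio

    IMSS(a_1..a_20) = sum_i [ ln p_i(a_i) - ln p_gw(a_i) ]

(natural log). Positive scores mean "looks like an insertion site".
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import Genome, Track

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}

#: Width of the learning window (insertion point at index FLANK).
FLANK = 20
LEARN_WIDTH = 2 * FLANK + 1
#: Width of the scored motif window.
MOTIF_WIDTH = 20
#: Probability floor applied before taking logs.
PROB_FLOOR = 1e-4


@dataclass
class PositionMotif:
    """20x4 positional nucleotide probabilities plus genome background.

    ``offset`` is where the 20-position window starts within the 41-nt
    learning window (the insertion point itself sits at learning index 20).
    """

    p: np.ndarray
    p_gw: np.ndarray
    offset: int

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.p_gw = np.asarray(self.p_gw, dtype=float)
        if self.p.shape != (MOTIF_WIDTH, 4):
            raise ValueError(f"motif matrix must be {MOTIF_WIDTH}x4, got {self.p.shape}")
        if not np.allclose(self.p.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("motif rows must sum to 1")
        if not np.isclose(self.p_gw.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")
        if (self.p <= 0).any() or (self.p_gw <= 0).any():
            raise ValueError("probabilities must be positive (apply the floor)")

    @property
    def log_ratio(self) -> np.ndarray:
        return np.log(self.p) - np.log(self.p_gw)[None, :]

    @classmethod
    def flat(cls, p_gw: np.ndarray, offset: int = 10) -> "PositionMotif":
        """Motif equal to the background: IMSS identically zero."""
        return cls(np.tile(p_gw, (MOTIF_WIDTH, 1)), p_gw, offset)


def encode_sequence(seq: str) -> np.ndarray:
    """ACGT -> 0..3, anything else (N) -> -1, as int8."""
    table = np.full(256, -1, dtype=np.int8)
    for b, i in _CODE.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def genome_background(genome: Genome) -> np.ndarray:
    """Genome-wide nucleotide probabilities over A,C,G,T (N ignored)."""
    counts = np.zeros(4)
    for chrom in genome.chrom_names:
        codes = encode_sequence(genome.sequence[chrom])
        counts += np.bincount(codes[codes >= 0], minlength=4)[:4]
    if counts.sum() == 0:
        raise ValueError("genome contains no ACGT bases")
    return counts / counts.sum()


def learn_position_frequencies(
    genome: Genome, invitro_sites: pd.DataFrame, flank: int = FLANK
) -> np.ndarray:
    """Per-position nucleotide frequencies in (2*flank+1)-nt windows.

    ``invitro_sites`` needs chrom/pos columns. Sites whose window would leave
    the chromosome or contains N are skipped; the returned matrix is
    column-stochastic over the contributing sites.
    """
    width = 2 * flank + 1
    counts = np.zeros((width, 4))
    n_used = n_skipped = 0
    coded = {c: encode_sequence(genome.sequence[c]) for c in genome.chrom_names}
    for row in invitro_sites.itertuples():
        codes = coded.get(row.chrom)
        if codes is None:
            n_skipped += 1
            continue
        start = row.pos - flank
        if start < 0 or start + width > len(codes):
            n_skipped += 1
            continue
        window = codes[start : start + width]
        if (window < 0).any():
            n_skipped += 1
            continue
        counts[np.arange(width), window] += 1
        n_used += 1
    if n_used == 0:
        raise ValueError(
            f"no in-vitro site had a full {width}-nt context ({n_skipped} skipped)"
        )
    return counts / n_used


def select_motif_window(
    freqs41: np.ndarray,
    p_gw: np.ndarray,
    width: int = MOTIF_WIDTH,
    delta: float = 0.01,
) -> PositionMotif:
    """Pick the contiguous window most distinct from the background.

    The window maximising the number of positions whose composition deviates
    from the background by at least ``delta`` for some nucleotide wins; ties
    go to the window whose centre is nearest the insertion point, then
    leftmost. Probabilities are floored at ``PROB_FLOOR`` and renormalised.
    """
    freqs41 = np.asarray(freqs41, dtype=float)
    n_pos = freqs41.shape[0]
    deviates = (np.abs(freqs41 - p_gw[None, :]) >= delta).any(axis=1)
    if not deviates.any():
        raise ValueError(
            "no position differs from the background by the required margin; "
            "the motif is indistinguishable from background (use a flat motif)"
        )
    insertion_point = (n_pos - 1) / 2
    best = None
    for offset in range(n_pos - width + 1):
        score = int(deviates[offset : offset + width].sum())
        centre_dist = abs(offset + (width - 1) / 2 - insertion_point)
        key = (-score, centre_dist, offset)
        if best is None or key < best[0]:
            best = (key, offset)
    offset = best[1]
    p = np.maximum(freqs41[offset : offset + width], PROB_FLOOR)
    p = p / p.sum(axis=1, keepdims=True)
    bg = np.maximum(p_gw, PROB_FLOOR)
    bg = bg / bg.sum()
    return PositionMotif(p, bg, offset)


def imss_score(string20: str, motif: PositionMotif) -> float:
    """Score one 20-mer; returns NaN if the string contains N."""
    if len(string20) != MOTIF_WIDTH:
        raise ValueError(f"expected a {MOTIF_WIDTH}-mer, got length {len(string20)}")
    codes = encode_sequence(string20)
    if (codes < 0).any():
        return float("nan")
    return float(motif.log_ratio[np.arange(MOTIF_WIDTH), codes].sum())


def _scan_codes(codes: np.ndarray, motif: PositionMotif) -> np.ndarray:
    """Plus-strand scan of an encoded chromosome.

    The score at position t uses the 20-mer occupying the motif's offsets
    relative to a notional insertion at t, i.e. genomic coordinates
    [t - FLANK + offset, t - FLANK + offset + 20) — the same geometry the
    motif was learned in.
    """
    length = len(codes)
    out = np.full(length, np.nan)
    shift = motif.offset - FLANK
    t0 = max(0, -shift)
    t1 = min(length, length - MOTIF_WIDTH - shift + 1)
    if t1 <= t0:
        return out
    lr = motif.log_ratio
    acc = np.zeros(t1 - t0)
    bad = np.zeros(t1 - t0, dtype=bool)
    for i in range(MOTIF_WIDTH):
        seg = codes[t0 + shift + i : t1 + shift + i]
        bad |= seg < 0
        acc += lr[i, np.clip(seg, 0, 3)]
    acc[bad] = np.nan
    out[t0:t1] = acc
    return out


_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.int8)


def imss_scan(genome: Genome, motif: PositionMotif, stranded: str = "both") -> Track:
    """IMSS track over the genome.

    ``stranded="both"`` (default) scores both strands at each position and
    keeps the maximum; ``"plus"`` reproduces a single-strand scan. Positions
    whose window leaves the chromosome or contains N are missing.
    """
    if stranded not in ("both", "plus"):
        raise ValueError("stranded must be 'both' or 'plus'")
    data = {}
    for chrom in genome.chrom_names:
        codes = encode_sequence(genome.sequence[chrom])
        plus = _scan_codes(codes, motif)
        if stranded == "plus":
            data[chrom] = plus
            continue
        rc = _COMPLEMENT[np.clip(codes[::-1], 0, 3)].astype(np.int8)
        rc[codes[::-1] < 0] = -1
        minus = _scan_codes(rc, motif)[::-1]
        data[chrom] = np.where(
            np.isnan(plus), minus, np.where(np.isnan(minus), plus, np.maximum(plus, minus))
        )
    return Track(data, "imss")


# ---------------------------------------------------------------- serialization

def write_motif(path: str | Path, motif: PositionMotif) -> None:
    """TSV: 20 motif rows + one background row, columns A,C,G,T."""
    frame = pd.DataFrame(motif.p, columns=list(BASES))
    frame.insert(0, "position", np.arange(MOTIF_WIDTH) + motif.offset)
    bg = pd.DataFrame([[-1, *motif.p_gw]], columns=["position", *BASES])
    pd.concat([frame, bg]).to_csv(path, sep="\t", index=False)


def read_motif(path: str | Path) -> PositionMotif:
    df = pd.read_csv(path, sep="\t")
    bg = df[df["position"] < 0]
    body = df[df["position"] >= 0]
    return PositionMotif(
        body[list(BASES)].to_numpy(),
        bg[list(BASES)].to_numpy()[0],
        int(body["position"].iloc[0]),
    )
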