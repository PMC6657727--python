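"""Synthetic genomes, annotations, covariate tracks and insertion data.

The generator is the statistical twin of the analysis: a gene-dense yeast-like
genome whose annotation classes define the true hidden states (essential CDS
-> 1, nonessential CDS -> 2, UTR/intron/ncRNA -> 3, unannotated -> 4, plus
short planted state-5 segments), smooth autocorrelated nucleosome density
elevated in coding sequence, an insertion motif, and insertion observations
drawn from the state-wise zero-inflated Poisson regression. Read-level
records add random 10-nt UMIs, PCR duplicates and a mapping-quality flag so
the deduplication, site-calling and mappability filters are all exercised.

True state paths are piecewise-constant by annotation, not sampled from a
transition matrix: states are conceived as functional units, and this lets
tests ask directly whether segmentation recovers annotation boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import FEATURE_COLUMNS, AnnotationSet, Genome, Track, annotation_class_track
from .hmm import ObservedSeries
from .motif import BASES, MOTIF_WIDTH, PositionMotif, imss_scan

_STATE_OF_CLASS = {"eCDS": 1, "nCDS": 2, "UTR_intron": 3, "ncRNA": 3, "unannotated": 4}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic twin.

    Emission parameters are on the scale of the HMM's observed variable:
    per-state intercepts spaced 1.5 on the log scale, a negative nucleosome
    slope (insertions favour nucleosome-free DNA) and a positive motif
    slope. Layout fractions approximate a gene-dense yeast genome.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chrI": 120_000, "chrII": 80_000}
    )
    # annotation layout
    essential_cds_fraction: float = 0.22
    nonessential_cds_fraction: float = 0.33
    utr_intron_fraction: float = 0.15
    mean_cds_length: int = 1400
    mean_utr5_length: int = 150
    mean_utr3_length: int = 250
    mean_intron_length: int = 60
    intron_prob: float = 0.5
    ncrna_per_100kb: float = 3.0
    mean_ncrna_length: int = 400
    state5_per_100kb: float = 4.0
    state5_length_range: tuple[int, int] = (40, 90)
    # emissions (per state 1..5)
    beta0: tuple[float, ...] = (-3.0, -1.5, 0.0, 1.5, 3.0)
    beta1: float = -0.4  # nucleosome slope
    beta2: float = 0.3   # IMSS slope
    omega: tuple[float, ...] = (0.8, 0.6, 0.4, 0.25, 0.1)
    self_prob: float = 0.95  # reference value for estimated transitions
    # covariate tracks
    nucleosome_rho: float = 0.99
    nucleosome_coding_shift: float = 1.0
    nucleosome_missing_fraction: float = 0.05
    # read-level layer
    duplication_rate: float = 0.25
    base_low_mapq_rate: float = 0.0
    low_map_mapq_rate: float = 0.5
    low_mapq: int = 10
    good_mapq: int = 60
    n_states: int = 5

    def __post_init__(self) -> None:
        if self.n_states < 2:
            raise ValueError("need at least 2 states")
        if len(self.beta0) != self.n_states or len(self.omega) != self.n_states:
            raise ValueError("per-state parameter lengths must equal n_states")
        for w in self.omega:
            if not 0.0 <= w <= 1.0:
                raise ValueError("omega must lie in [0, 1]")
        if any(v <= 0 for v in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        if self.duplication_rate < 0:
            raise ValueError("duplication rate must be >= 0")
        genic = (
            self.essential_cds_fraction
            + self.nonessential_cds_fraction
            + self.utr_intron_fraction
        )
        if genic >= 0.9:
            raise ValueError("genic fractions leave no intergenic space")


def recovery_config(length: int = 200_000) -> SimulationConfig:
    """Study conditions for the parameter-recovery experiment.

    Intercepts are spaced 1.5 on the log scale and zero-fractions lie in
    [0.1, 0.8], like the pipeline defaults, but the smallest state rate is
    exp(-1) rather than exp(-3): a zero-inflated Poisson with rate near zero
    degenerates into a ridge where (lambda, omega) trade off against each
    other and the intercept is not estimable, so recovery is only a
    well-posed question when every state's rate is bounded away from zero.
    """
    return SimulationConfig(
        chrom_lengths={"chrI": length},
        beta0=(-1.0, 0.5, 2.0, 3.5, 5.0),
        omega=(0.6, 0.45, 0.3, 0.2, 0.1),
    )


@dataclass
class GroundTruth:
    """Per-position truth used as the oracle in recovery tests."""

    states: dict[str, np.ndarray]
    rates: dict[str, np.ndarray] | None = None
    motif: PositionMotif | None = None

    def validate_against(self, genome: Genome) -> None:
        for chrom, length in genome.chrom_lengths.items():
            if len(self.states[chrom]) != length:
                raise ValueError(f"truth states wrong length on {chrom}")


# ---------------------------------------------------------------- genome/annotation

def _sample_lengths(rng, mean: int, n: int, minimum: int = 20) -> np.ndarray:
    """Right-skewed positive lengths with the requested mean."""
    draws = rng.gamma(shape=4.0, scale=mean / 4.0, size=n)
    return np.maximum(draws.round().astype(int), minimum)


def generate_genome_and_annotations(
    config: SimulationConfig, seed: int | np.random.Generator
) -> tuple[Genome, AnnotationSet, GroundTruth]:
    """Random genome with non-overlapping gene models and true states."""
    rng = np.random.default_rng(seed)
    names = list(config.chrom_lengths)
    sequences, all_feats, ess = {}, [], {}
    states: dict[str, np.ndarray] = {}
    gene_counter = 0
    for chrom in names:
        length = config.chrom_lengths[chrom]
        sequences[chrom] = "".join(
            np.array(list(BASES))[rng.integers(0, 4, size=length)]
        )
        st = np.full(length, _STATE_OF_CLASS["unannotated"], dtype=np.int8)
        target_cds = (
            config.essential_cds_fraction + config.nonessential_cds_fraction
        ) * length
        n_genes = 0 if target_cds < 60 else max(1, round(target_cds / config.mean_cds_length))
        cds_lens = _sample_lengths(rng, config.mean_cds_length, n_genes, 60)
        if n_genes:
            cds_lens = _rescale(cds_lens, target_cds, 60)
        utr5 = _sample_lengths(rng, config.mean_utr5_length, n_genes)
        utr3 = _sample_lengths(rng, config.mean_utr3_length, n_genes)
        has_intron = rng.random(n_genes) < config.intron_prob
        intron_lens = _sample_lengths(rng, config.mean_intron_length, n_genes, 25)
        intron_lens[~has_intron] = 0
        target_utr = config.utr_intron_fraction * length
        accessory = utr5 + utr3 + intron_lens
        scale = target_utr / accessory.sum() if n_genes else 0.0
        utr5 = np.maximum((utr5 * scale).round().astype(int), 20)
        utr3 = np.maximum((utr3 * scale).round().astype(int), 20)
        intron_lens = np.where(
            has_intron, np.maximum((intron_lens * scale).round().astype(int), 25), 0
        )
        footprints = cds_lens + utr5 + utr3 + intron_lens
        genic_total = int(footprints.sum())
        if genic_total > 0.95 * length:
            raise ValueError(
                f"layout infeasible on {chrom}: genic {genic_total} of {length} nt"
            )
        # essential genes: greedily mark until the essential CDS target is met
        essential = np.zeros(n_genes, dtype=bool)
        target_ecds = config.essential_cds_fraction * length
        order = rng.permutation(n_genes)
        acc = 0
        for g in order:
            if acc >= target_ecds:
                break
            essential[g] = True
            acc += cds_lens[g]
        gap = (length - genic_total) / (n_genes + 1)
        if n_genes and gap < 1:
            raise ValueError(f"layout infeasible on {chrom}: no intergenic space")
        cursor = 0.0
        gaps: list[tuple[int, int]] = []
        for g in range(n_genes):
            cursor += gap
            start = int(round(cursor))
            gaps.append((int(round(cursor - gap)), start))
            gene_counter += 1
            gid = f"SYNG{gene_counter:05d}"
            strand = "+" if rng.random() < 0.5 else "-"
            feats, end = _gene_features(
                chrom, start, strand, gid,
                int(utr5[g]), int(cds_lens[g]), int(intron_lens[g]), int(utr3[g]),
                rng,
            )
            all_feats.extend(feats)
            ess[gid] = "essential" if essential[g] else "nonessential"
            state_code = 1 if essential[g] else 2
            for (_, fs, fe, _, ftype, _) in feats:
                if ftype == "CDS":
                    st[fs:fe] = state_code
                elif ftype in ("five_prime_UTR", "three_prime_UTR", "intron"):
                    st[fs:fe] = 3
            cursor = end
        gaps.append((int(round(cursor)), length))
        # ncRNAs inside a subset of gaps
        n_ncrna = rng.poisson(config.ncrna_per_100kb * length / 1e5)
        free_gaps = [g for g in gaps if g[1] - g[0] > config.mean_ncrna_length + 40]
        rng.shuffle(free_gaps)
        for gs, ge in free_gaps[:n_ncrna]:
            nc_len = min(
                max(int(rng.gamma(4.0, config.mean_ncrna_length / 4.0)), 60),
                ge - gs - 20,
            )
            nc_start = gs + 10
            gene_counter += 1
            all_feats.append(
                (chrom, nc_start, nc_start + nc_len, "+", "ncRNA",
                 f"SYNC{gene_counter:05d}")
            )
            st[nc_start : nc_start + nc_len] = 3
        # short planted state-5 segments in remaining unannotated space
        n_s5 = rng.poisson(config.state5_per_100kb * length / 1e5)
        unannotated = np.flatnonzero(st == 4)
        lo, hi = config.state5_length_range
        for _ in range(n_s5):
            if len(unannotated) == 0:
                break
            seg_len = int(rng.integers(lo, hi + 1))
            anchor = int(rng.choice(unannotated))
            seg = slice(anchor, min(anchor + seg_len, length))
            if (st[seg] == 4).all():
                st[seg] = 5
        states[chrom] = st
    genome = Genome(names, sequences)
    features = pd.DataFrame(all_feats, columns=FEATURE_COLUMNS).sort_values(
        ["chrom", "start"], kind="stable", ignore_index=True
    )
    annotations = AnnotationSet(features, ess)
    truth = GroundTruth(states)
    truth.validate_against(genome)
    return genome, annotations, truth


def _rescale(lengths: np.ndarray, target: float, minimum: int) -> np.ndarray:
    scale = target / lengths.sum()
    return np.maximum((lengths * scale).round().astype(int), minimum)


def _gene_features(chrom, start, strand, gid, utr5, cds, intron, utr3, rng):
    """Lay out 5'UTR / CDS(+intron) / 3'UTR left to right, respecting strand."""
    left_utr, right_utr = (utr5, utr3) if strand == "+" else (utr3, utr5)
    left_type = "five_prime_UTR" if strand == "+" else "three_prime_UTR"
    right_type = "three_prime_UTR" if strand == "+" else "five_prime_UTR"
    feats = []
    pos = start
    feats.append((chrom, pos, pos + left_utr, strand, left_type, gid))
    pos += left_utr
    if intron > 0:
        split = int(rng.integers(max(cds // 4, 1), max(3 * cds // 4, 2)))
        feats.append((chrom, pos, pos + split, strand, "CDS", gid))
        pos += split
        feats.append((chrom, pos, pos + intron, strand, "intron", gid))
        pos += intron
        feats.append((chrom, pos, pos + cds - split, strand, "CDS", gid))
        pos += cds - split
    else:
        feats.append((chrom, pos, pos + cds, strand, "CDS", gid))
        pos += cds
    feats.append((chrom, pos, pos + right_utr, strand, right_type, gid))
    pos += right_utr
    feats.append((chrom, start, pos, strand, "transcript", gid))
    return feats, pos


# ---------------------------------------------------------------- covariates

def generate_covariate_tracks(
    genome: Genome,
    annotations: AnnotationSet,
    config: SimulationConfig,
    seed: int | np.random.Generator,
    truth: GroundTruth | None = None,
) -> tuple[Track, Track, Track]:
    """(nucleosome, conservation, expression) tracks.

    Nucleosome density: stationary AR(1) noise passed through softplus after
    a positive shift in coding bases, with a configurable missing fraction.
    Conservation is elevated where the true state is low; expression is
    elevated over transcripts.
    """
    rng = np.random.default_rng(seed)
    classes = annotation_class_track(genome, annotations)
    nuc, cons, expr = {}, {}, {}
    rho = config.nucleosome_rho
    innov_sd = math.sqrt(1.0 - rho * rho)
    cons_level = {1: 0.8, 2: 0.5, 3: 0.25, 4: 0.02, 5: 0.02}
    for chrom, length in genome.chrom_lengths.items():
        ar = np.empty(length)
        ar[0] = rng.normal()
        eps = rng.normal(scale=innov_sd, size=length)
        for t in range(1, length):
            ar[t] = rho * ar[t - 1] + eps[t]
        coding = np.isin(classes[chrom], [0, 1])  # eCDS or nCDS codes
        shifted = ar + config.nucleosome_coding_shift * coding
        density = np.log1p(np.exp(shifted))  # softplus keeps it positive
        miss = rng.random(length) < config.nucleosome_missing_fraction
        density[miss] = np.nan
        nuc[chrom] = density
        if truth is not None:
            level = np.vectorize(cons_level.get)(truth.states[chrom])
        else:
            level = np.where(coding, 0.6, 0.1)
        cons[chrom] = level + rng.normal(scale=0.15, size=length)
        on_transcript = np.zeros(length, dtype=bool)
        for row in annotations.of_type("transcript", "ncRNA").itertuples():
            if row.chrom == chrom:
                on_transcript[row.start : row.end] = True
        expr[chrom] = np.exp(rng.normal(loc=2.0 * on_transcript, scale=0.3))
    return (
        Track(nuc, "nucleosome"),
        Track(cons, "conservation"),
        Track(expr, "expression"),
    )


# ---------------------------------------------------------------- insertions

def _per_position_rates(
    truth: GroundTruth, nuc_norm: Track, imss: Track, config: SimulationConfig, chrom: str
) -> tuple[np.ndarray, np.ndarray]:
    """(state index per position, Poisson rate per position)."""
    st = truth.states[chrom]
    nuc = np.asarray(nuc_norm[chrom], float)
    nuc = np.where(np.isfinite(nuc), nuc, np.nanmedian(nuc))
    im = np.nan_to_num(np.asarray(imss[chrom], float), nan=0.0)
    b0 = np.asarray(config.beta0)[st - 1]
    lam = np.exp(np.clip(b0 + config.beta1 * nuc + config.beta2 * im, -30, 30))
    return st, lam


def simulate_observed_series(
    genome: Genome,
    truth: GroundTruth,
    nuc_norm: Track,
    imss: Track,
    config: SimulationConfig,
    seed: int | np.random.Generator,
    mask: Track | None = None,
    class_codes: dict[str, np.ndarray] | None = None,
) -> dict[str, ObservedSeries]:
    """Draw the HMM's observed variable directly from the state-wise ZIP
    regression — the exact generative twin of the fitted model, used for
    parameter-recovery experiments."""
    rng = np.random.default_rng(seed)
    out = {}
    omegas = np.asarray(config.omega)
    for chrom in genome.chrom_names:
        st, lam = _per_position_rates(truth, nuc_norm, imss, config, chrom)
        om = omegas[st - 1]
        zero = rng.random(len(st)) < om
        y = np.where(zero, 0, rng.poisson(lam))
        if truth.rates is None:
            truth.rates = {}
        truth.rates[chrom] = lam
        keep = (
            np.ones(len(st), bool) if mask is None else mask[chrom].astype(bool)
        )
        idx = np.flatnonzero(keep)
        nuc = np.asarray(nuc_norm[chrom], float)
        nuc = np.where(np.isfinite(nuc), nuc, np.nanmedian(nuc))
        im = np.nan_to_num(np.asarray(imss[chrom], float), nan=0.0)
        out[chrom] = ObservedSeries(
            chrom, idx, y[idx], nuc[idx], im[idx],
            unique=(y[idx] > 0).astype(float),
            classes=None if class_codes is None else class_codes[chrom][idx],
        )
    return out


def simulate_insertion_counts(
    genome: Genome,
    truth: GroundTruth,
    nuc_norm: Track,
    imss: Track,
    config: SimulationConfig,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Strand-resolved site table of raw insertion counts.

    Per position the total count is zero with probability omega_s, else
    Poisson with the state's covariate-dependent rate; each insertion unit
    is then assigned a strand at random.
    """
    rng = np.random.default_rng(seed)
    rows = []
    omegas = np.asarray(config.omega)
    for chrom in genome.chrom_names:
        st, lam = _per_position_rates(truth, nuc_norm, imss, config, chrom)
        om = omegas[st - 1]
        zero = rng.random(len(st)) < om
        counts = np.where(zero, 0, rng.poisson(lam))
        if truth.rates is None:
            truth.rates = {}
        truth.rates[chrom] = lam
        pos = np.flatnonzero(counts > 0)
        plus = rng.binomial(counts[pos], 0.5)
        minus = counts[pos] - plus
        for p, c in zip(pos[plus > 0], plus[plus > 0]):
            rows.append((chrom, int(p), "+", int(c)))
        for p, c in zip(pos[minus > 0], minus[minus > 0]):
            rows.append((chrom, int(p), "-", int(c)))
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "count"])
    return sites.sort_values(["chrom", "pos", "strand"], ignore_index=True)


_UMI_BASES = np.array(list(BASES))


def _random_umis(rng: np.random.Generator, n: int) -> np.ndarray:
    codes = rng.integers(0, 4, size=(n, 10))
    return np.array(["".join(row) for row in _UMI_BASES[codes]])


def simulate_read_records(
    site_table: pd.DataFrame,
    config: SimulationConfig,
    seed: int | np.random.Generator,
    low_map_regions: list[tuple[str, int, int]] | None = None,
) -> pd.DataFrame:
    """Expand a site table into shuffled read-level records.

    Each insertion unit becomes one record with a uniform-random 10-nt UMI
    (collisions allowed); PCR duplicates add Poisson(duplication_rate) extra
    copies sharing the (chrom, pos, strand, UMI) key. Records falling in
    ``low_map_regions`` get mapq below the filter cutoff with probability
    ``low_map_mapq_rate``; elsewhere with ``base_low_mapq_rate``.
    """
    rng = np.random.default_rng(seed)
    n_units = int(site_table["count"].sum())
    chrom = np.repeat(site_table["chrom"].to_numpy(), site_table["count"].to_numpy())
    pos = np.repeat(site_table["pos"].to_numpy(), site_table["count"].to_numpy())
    strand = np.repeat(site_table["strand"].to_numpy(), site_table["count"].to_numpy())
    umi = _random_umis(rng, n_units)
    copies = 1 + rng.poisson(config.duplication_rate, size=n_units)
    records = pd.DataFrame(
        {
            "chrom": np.repeat(chrom, copies),
            "pos": np.repeat(pos, copies),
            "strand": np.repeat(strand, copies),
            "umi": np.repeat(umi, copies),
        }
    )
    low_rate = np.full(len(records), config.base_low_mapq_rate)
    if low_map_regions:
        for reg_chrom, start, end in low_map_regions:
            inside = (
                (records["chrom"] == reg_chrom)
                & (records["pos"] >= start)
                & (records["pos"] < end)
            )
            low_rate[inside.to_numpy()] = config.low_map_mapq_rate
    is_low = rng.random(len(records)) < low_rate
    records["mapq"] = np.where(is_low, config.low_mapq, config.good_mapq)
    return records.sample(frac=1.0, random_state=rng.integers(0, 2**31)).reset_index(
        drop=True
    )


def choose_low_map_regions(
    genome: Genome,
    fraction: float,
    seed: int | np.random.Generator,
    window: int = 500,
) -> list[tuple[str, int, int]]:
    """Pick random window-aligned regions covering about ``fraction`` of the
    genome, to play the role of repeat-rich low-mappability sequence."""
    rng = np.random.default_rng(seed)
    regions = []
    for chrom, length in genome.chrom_lengths.items():
        n_win = length // window
        n_pick = int(round(fraction * n_win))
        if n_pick == 0:
            continue
        for w in rng.choice(n_win, size=n_pick, replace=False):
            regions.append((chrom, int(w) * window, (int(w) + 1) * window))
    return regions


# ---------------------------------------------------------------- motif layer

def planted_motif(
    p_gw: np.ndarray | None = None, offset: int = 10, strength: float = 0.45
) -> PositionMotif:
    """A degenerate T....A-style insertion motif for simulations.

    T is enriched two positions before the insertion point and A three after
    (motif indices 8 and 13 with the default offset), echoing the palindromic
    TNNNNA preference of the transposase.
    """
    if p_gw is None:
        p_gw = np.full(4, 0.25)
    p = np.tile(p_gw, (MOTIF_WIDTH, 1)).astype(float)
    for index, base in ((8, "T"), (13, "A")):
        row = np.full(4, (1.0 - strength) / 3.0)
        row[BASES.index(base)] = strength
        p[index] = row
    return PositionMotif(p, p_gw, offset)


def simulate_invitro_sites(
    genome: Genome,
    motif: PositionMotif,
    n: int,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Sample in-vitro insertion positions with probability proportional to
    exp(IMSS) under the planted motif (plus strand, matching how the learned
    motif consumes strand-resolved in-vitro data)."""
    rng = np.random.default_rng(seed)
    if n > len(genome):
        raise ValueError(f"cannot sample {n} sites from a {len(genome)}-nt genome")
    track = imss_scan(genome, motif, stranded="plus")
    chroms, positions, weights = [], [], []
    for chrom in genome.chrom_names:
        vals = track[chrom]
        ok = np.isfinite(vals)
        idx = np.flatnonzero(ok)
        chroms.extend([chrom] * len(idx))
        positions.append(idx)
        weights.append(np.exp(vals[idx]))
    pos_all = np.concatenate(positions)
    w = np.concatenate(weights)
    w = w / w.sum()
    pick = rng.choice(len(pos_all), size=n, replace=True, p=w)
    chrom_arr = np.array(chroms)
    return pd.DataFrame({"chrom": chrom_arr[pick], "pos": pos_all[pick]})
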