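"""Stage orchestration: run the pipeline end to end from a declarative config.

Each stage reads its inputs from the output directory, writes TSV/bedGraph
artifacts plus a JSON manifest recording its parameters and seed, and can be
run on its own provided its upstream artifacts exist. Outputs are
deterministic given (inputs, config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import calling, hmm, io, motif, segmentation, simulate, stats
from .genome import annotation_class_track

log = logging.getLogger("tnscape")

STAGE_ORDER = [
    "simulate",
    "call-sites",
    "imss",
    "select-model",
    "fit-hmm",
    "segment",
    "windows",
    "threshold",
    "gene-metrics",
]

#: Upstream artifacts each stage requires, and the stage that makes them.
_REQUIRES = {
    "call-sites": [("records.tsv", "simulate")],
    "imss": [("genome.fa", "simulate"), ("invitro_sites.tsv", "simulate")],
    "select-model": [("sites.tsv", "call-sites"), ("imss.bedGraph", "imss")],
    "fit-hmm": [("sites.tsv", "call-sites"), ("imss.bedGraph", "imss")],
    "segment": [("states.bedGraph", "fit-hmm")],
    "windows": [("states.bedGraph", "fit-hmm"), ("sites.tsv", "call-sites")],
    "threshold": [("windows.tsv", "windows")],
    "gene-metrics": [("states.bedGraph", "fit-hmm"), ("fitness.tsv", "simulate")],
}


class MissingArtifact(RuntimeError):
    pass


def _check_requirements(stage: str, outdir: Path) -> None:
    for artifact, producer in _REQUIRES.get(stage, []):
        if not (outdir / artifact).exists():
            raise MissingArtifact(
                f"stage {stage!r} needs {artifact}; run stage {producer!r} first"
            )


def _manifest(outdir: Path, stage: str, seed: int, params: dict) -> None:
    path = outdir / f"manifest_{stage.replace('-', '_')}.json"
    with open(path, "w") as fh:
        json.dump({"stage": stage, "seed": seed, "params": params}, fh, indent=1,
                  sort_keys=True, default=str)


def run_pipeline(config: dict) -> Path:
    """Run the configured stages in dependency order.

    ``config`` keys: outdir (required), seed (default 0), stages (default:
    all), plus optional per-stage parameter mappings keyed by stage name.
    """
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    wanted = config.get("stages") or STAGE_ORDER
    unknown = [s for s in wanted if s not in STAGE_ORDER]
    if unknown:
        raise ValueError(f"unknown stages {unknown}; choose from {STAGE_ORDER}")
    n_states = int(config.get("fit-hmm", {}).get("states", 5))
    if n_states < 2:
        raise ValueError("state count must be at least 2")
    for stage in STAGE_ORDER:
        if stage not in wanted:
            continue
        _check_requirements(stage, outdir)
        log.info("running stage %s", stage)
        _STAGES[stage](outdir, seed, config.get(stage, {}))
    return outdir


# ---------------------------------------------------------------- stages

def _stage_simulate(outdir: Path, seed: int, params: dict) -> None:
    cfg = simulate.SimulationConfig(**params.get("config", {}))
    rng = np.random.default_rng(seed)
    genome, annotations, truth = simulate.generate_genome_and_annotations(cfg, rng)
    nuc, cons, expr = simulate.generate_covariate_tracks(
        genome, annotations, cfg, rng, truth
    )
    planted = simulate.planted_motif(motif.genome_background(genome))
    truth.motif = planted
    nuc_norm = hmm.normalize_nucleosome(nuc)
    imss_track = motif.imss_scan(genome, planted, stranded="plus")
    sites = simulate.simulate_insertion_counts(genome, truth, nuc_norm, imss_track, cfg, rng)
    low_map = simulate.choose_low_map_regions(genome, params.get("low_map_fraction", 0.02), rng)
    records = simulate.simulate_read_records(sites, cfg, rng, low_map)
    invitro = simulate.simulate_invitro_sites(
        genome, planted, int(params.get("n_invitro", 10000)), rng
    )
    # gene fitness: noisy monotone function of tolerated insertion rate
    fitness_rows = []
    class_codes = annotation_class_track(genome, annotations)
    for gid in annotations.gene_ids():
        status = annotations.gene_status(gid)
        if status == "unknown":
            continue
        base = 0.3 if status == "essential" else 1.0
        fitness_rows.append((gid, base + rng.normal(scale=0.15)))
    io.write_fasta(outdir / "genome.fa", genome)
    io.write_gff3(outdir / "annotations.gff3", annotations.features)
    io.write_essentiality(outdir / "essentiality.tsv", annotations.essentiality)
    io.write_bedgraph(outdir / "nucleosome.bedGraph", nuc)
    io.write_bedgraph(outdir / "conservation.bedGraph", cons)
    io.write_bedgraph(outdir / "expression.bedGraph", expr)
    io.write_state_track(outdir / "truth_states.bedGraph", truth.states)
    io.write_site_table(outdir / "sites_true.tsv", sites)
    io.write_records(outdir / "records.tsv", records)
    invitro.to_csv(outdir / "invitro_sites.tsv", sep="\t", index=False)
    pd.DataFrame(fitness_rows, columns=["gene_id", "fitness"]).to_csv(
        outdir / "fitness.tsv", sep="\t", index=False
    )
    pd.DataFrame(low_map, columns=["chrom", "start", "end"]).to_csv(
        outdir / "low_map_regions.tsv", sep="\t", index=False
    )
    _manifest(outdir, "simulate", seed, {**asdict(cfg), **params})


def _load_world(outdir: Path):
    genome = io.read_fasta(outdir / "genome.fa")
    features = io.read_gff3(outdir / "annotations.gff3", genome)
    essentiality = io.read_essentiality(outdir / "essentiality.tsv")
    from .genome import AnnotationSet

    return genome, AnnotationSet(features, essentiality)


def _stage_call_sites(outdir: Path, seed: int, params: dict) -> None:
    genome, _ = _load_world(outdir)
    records = io.read_records(outdir / "records.tsv")
    deduped, report = calling.deduplicate_umis(
        records, umi_only=bool(params.get("umi_only", False))
    )
    min_mapq = int(params.get("min_mapq", calling.MIN_MAPQ))
    sites = calling.call_insertion_sites(deduped, min_mapq)
    post = deduped[deduped["mapq"] >= min_mapq]
    mask, mappable_fraction = calling.mappability_mask(deduped, post, genome)
    io.write_site_table(outdir / "sites.tsv", sites)
    bed = calling.mask_to_bed(mask)
    bed.to_csv(outdir / "mappable.bed", sep="\t", index=False, header=False)
    _manifest(outdir, "call-sites", seed, {
        **params, "dedup": vars(report), "mappable_fraction": mappable_fraction,
    })


def _stage_imss(outdir: Path, seed: int, params: dict) -> None:
    genome, _ = _load_world(outdir)
    invitro = pd.read_csv(outdir / "invitro_sites.tsv", sep="\t")
    freqs = motif.learn_position_frequencies(genome, invitro)
    p_gw = motif.genome_background(genome)
    learned = motif.select_motif_window(freqs, p_gw)
    track = motif.imss_scan(genome, learned, stranded=params.get("stranded", "both"))
    motif.write_motif(outdir / "motif.tsv", learned)
    io.write_bedgraph(outdir / "imss.bedGraph", track)
    _manifest(outdir, "imss", seed, params)


def _read_mask(outdir: Path, genome) -> dict[str, np.ndarray]:
    mask = {c: np.zeros(n, bool) for c, n in genome.chrom_lengths.items()}
    bed = pd.read_csv(
        outdir / "mappable.bed", sep="\t", header=None,
        names=["chrom", "start", "end"],
    )
    for row in bed.itertuples():
        mask[row.chrom][row.start : row.end] = True
    return mask


def _build_series(outdir: Path, genome, annotations):
    sites = io.read_site_table(outdir / "sites.tsv")
    nuc = io.read_bedgraph(outdir / "nucleosome.bedGraph", genome, "nucleosome")
    nuc_norm = hmm.normalize_nucleosome(nuc)
    imss_track = io.read_bedgraph(outdir / "imss.bedGraph", genome, "imss")
    mask = _read_mask(outdir, genome)
    counts = calling.per_base_counts(sites, genome)
    unique = calling.unique_site_counts(sites, genome)
    classes = annotation_class_track(genome, annotations)
    series = {
        chrom: hmm.make_series(
            chrom, counts[chrom], nuc_norm[chrom], imss_track[chrom],
            mask[chrom], unique[chrom], classes[chrom],
        )
        for chrom in genome.chrom_names
    }
    return series, sites, mask, classes


def _stage_select_model(outdir: Path, seed: int, params: dict) -> None:
    genome, annotations = _load_world(outdir)
    series, *_ = _build_series(outdir, genome, annotations)
    chrom = params.get("chrom", genome.chrom_names[0])
    ser = series[chrom]
    subset_length = int(params.get("subset_length", 20000))
    n_subsets = int(params.get("n_subsets", 4))
    length = genome.chrom_lengths[chrom]
    starts = np.linspace(0, length - subset_length, n_subsets).astype(int)
    subsets = [(int(s), int(s) + subset_length) for s in starts]
    candidates = params.get("candidates") or [("annotation", 2), ("annotation", 5)]
    candidates = [tuple(c) for c in candidates]
    table = hmm.select_model(ser, subsets, candidates,
                             max_iter=int(params.get("max_iter", hmm.EM_MAX_ITER)))
    table.to_csv(outdir / "model_selection.tsv", sep="\t", index=False)
    _manifest(outdir, "select-model", seed, {**params, "subsets": subsets})


def _stage_fit_hmm(outdir: Path, seed: int, params: dict) -> None:
    genome, annotations = _load_world(outdir)
    series, _, mask, _ = _build_series(outdir, genome, annotations)
    n = int(params.get("states", 5))
    scheme = params.get("scheme", "annotation")
    states_full = {}
    models = {}
    for chrom, ser in series.items():
        model = hmm.fit_hmm(ser, scheme=scheme, n=n,
                            max_iter=int(params.get("max_iter", hmm.EM_MAX_ITER)))
        path = hmm.viterbi_decode(model, ser)
        states_full[chrom] = segmentation.path_to_full(
            genome.chrom_lengths[chrom], ser.positions, path
        )
        models[chrom] = model.to_dict()
    io.write_state_track(outdir / "states.bedGraph", states_full)
    with open(outdir / "model.json", "w") as fh:
        json.dump(models, fh, indent=1)
    _manifest(outdir, "fit-hmm", seed, params)


def _stage_segment(outdir: Path, seed: int, params: dict) -> None:
    genome, annotations = _load_world(outdir)
    states_full = io.read_state_track(outdir / "states.bedGraph", genome)
    hdes = segmentation.decode_to_hdes(states_full)
    kept, summary = segmentation.filter_hdes(hdes)
    obs, null, p = segmentation.edge_distance_analysis(
        kept, annotations, genome.chrom_lengths,
        n_null=int(params.get("n_null", 100)), seed=seed,
    )
    classes = annotation_class_track(genome, annotations)
    cons = io.read_bedgraph(outdir / "conservation.bedGraph", genome, "conservation")
    expr = io.read_bedgraph(outdir / "expression.bedGraph", genome, "expression")
    per_hde, per_state = segmentation.hde_summaries(kept, classes, cons.data, expr.data)
    io.write_bed(outdir / "hdes.bed", kept, score_col="state")
    per_hde.to_csv(outdir / "hde_table.tsv", sep="\t", index=False)
    per_state.to_csv(outdir / "hde_state_summary.tsv", sep="\t", index=False)
    obs.to_csv(outdir / "hde_edges.tsv", sep="\t", index=False)
    _manifest(outdir, "segment", seed, {**params, **summary, "edge_rank_p": p})


def _stage_windows(outdir: Path, seed: int, params: dict) -> None:
    genome, annotations = _load_world(outdir)
    sites = io.read_site_table(outdir / "sites.tsv")
    states_full = io.read_state_track(outdir / "states.bedGraph", genome)
    mask = _read_mask(outdir, genome)
    classes = annotation_class_track(genome, annotations)
    cons = io.read_bedgraph(outdir / "conservation.bedGraph", genome, "conservation")
    windows = stats.window_metrics(
        genome, sites, states_full, mask, cons.data, None, classes,
    )
    windows.to_csv(outdir / "windows.tsv", sep="\t", index=False)
    _manifest(outdir, "windows", seed, params)


def _stage_threshold(outdir: Path, seed: int, params: dict) -> None:
    windows = pd.read_csv(outdir / "windows.tsv", sep="\t")
    result = stats.model_free_threshold(windows, pct=float(params.get("pct", 95.0)))
    with open(outdir / "threshold.json", "w") as fh:
        json.dump(result, fh, indent=1)
    _manifest(outdir, "threshold", seed, params)


def _stage_gene_metrics(outdir: Path, seed: int, params: dict) -> None:
    genome, annotations = _load_world(outdir)
    sites = io.read_site_table(outdir / "sites.tsv")
    states_full = io.read_state_track(outdir / "states.bedGraph", genome)
    mask = _read_mask(outdir, genome)
    fitness = pd.read_csv(outdir / "fitness.tsv", sep="\t")
    merged, report = stats.gene_metrics_and_correlation(
        annotations, sites, states_full, fitness, mask,
        cds_only=bool(params.get("cds_only", False)),
    )
    merged.to_csv(outdir / "gene_metrics.tsv", sep="\t", index=False)
    with open(outdir / "gene_correlations.json", "w") as fh:
        json.dump(report, fh, indent=1)
    _manifest(outdir, "gene-metrics", seed, params)


_STAGES = {
    "simulate": _stage_simulate,
    "call-sites": _stage_call_sites,
    "imss": _stage_imss,
    "select-model": _stage_select_model,
    "fit-hmm": _stage_fit_hmm,
    "segment": _stage_segment,
    "windows": _stage_windows,
    "threshold": _stage_threshold,
    "gene-metrics": _stage_gene_metrics,
}
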