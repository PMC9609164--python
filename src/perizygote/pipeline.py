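"""End-to-end orchestration of the peri-zygotic analysis stages.

``run_pipeline`` drives simulate -> dnm -> phase -> cluster ->
signatures -> cnv -> junctions (and, when ontology inputs are supplied,
hpo) behind one configuration, and emits a JSON report carrying every
statistic together with the exact constants used, so a run is fully
reproducible from its seed. Stage toggles allow partial runs; a stage
failure aborts with the stage name and flags the partial report.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import (
    breakpoint_clustering,
    depth_cnv,
    dnm_discovery,
    fixtures,
    haplotype_phasing,
    junction_analysis,
    mutational_signatures,
    phenotype_similarity,
    synthetic_trio,
)
from .records import POST_ZYGOTIC, UNPHASED

ALL_STAGES = ("simulate", "dnm", "phase", "cluster", "signatures", "cnv", "junctions", "hpo")


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: Optional[str] = None
    stages: tuple[str, ...] = ALL_STAGES[:-1]  # hpo needs external inputs
    sim: dict = field(default_factory=dict)
    flank: int = 1_000_000
    refit_max_delta: float = mutational_signatures.DEFAULT_MAX_DELTA
    cbs_alpha: float = depth_cnv.CBS_ALPHA
    cbs_permutations: int = depth_cnv.CBS_PERMUTATIONS
    k_max: int = phenotype_similarity.DEFAULT_K_MAX
    obo: Optional[str] = None
    annotations: Optional[str] = None
    proband_terms: Optional[str] = None

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for path in (self.obo, self.annotations, self.proband_terms):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(path)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the toggled stages and return (and optionally write) the
    consolidated report."""
    report: dict = {
        "constants": {
            "seed": config.seed,
            "flank": config.flank,
            "min_gq": dnm_discovery.MIN_GQ,
            "min_alt_reads": dnm_discovery.MIN_ALT_READS,
            "cluster_distance": dnm_discovery.CLUSTER_DISTANCE,
            "vaf_bounds": [dnm_discovery.VAF_LOWER, dnm_discovery.VAF_UPPER],
            "min_informative_sites": haplotype_phasing.MIN_INFORMATIVE_SITES,
            "min_consistency": haplotype_phasing.MIN_CONSISTENCY,
            "gain_threshold": depth_cnv.GAIN_THRESHOLD,
            "loss_threshold": depth_cnv.LOSS_THRESHOLD,
            "refit_max_delta": config.refit_max_delta,
            "cbs_alpha": config.cbs_alpha,
            "mpv_improvement": phenotype_similarity.MPV_IMPROVEMENT,
        },
        "stages": {},
        "partial": False,
    }
    state: dict = {}
    try:
        for stage in ALL_STAGES:
            if stage not in config.stages:
                continue
            runner = _RUNNERS[stage]
            report["stages"][stage] = runner(config, state)
    except Exception as exc:  # noqa: BLE001 - stage name must surface
        report["partial"] = True
        report["failed_stage"] = stage
        _write_report(report, config)
        raise StageError(stage, exc) from exc
    _write_report(report, config)
    return report


def _write_report(report: dict, config: PipelineConfig) -> None:
    if config.out_dir is None:
        return
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.ndarray,)):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def _stage_simulate(config: PipelineConfig, state: dict) -> dict:
    sim_cfg = synthetic_trio.SimConfig(**{**config.sim, "seed": config.seed})
    sim = synthetic_trio.simulate_trio(sim_cfg)
    state["sim"] = sim
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sim.write_vcf(out / "trio.vcf")
        sim.write_cnv_bed(out / "cnv_truth.bed")
        sim.write_dnm_truth(out / "dnm_truth.tsv")
    return {
        "n_sites": int(len(sim.variants)),
        "n_cnv": len(sim.truth.cnvs),
        "n_dnm_planted": int(len(sim.truth.dnms)),
    }


def _stage_dnm(config: PipelineConfig, state: dict) -> dict:
    sim = state["sim"]
    candidates = dnm_discovery.extract_candidates(sim.variants)
    kept, log = dnm_discovery.apply_filters(candidates)
    kept = kept.copy()
    kept["zygosity"] = dnm_discovery.classify_zygosity_table(kept)
    state["calls"] = kept
    truth_keys = set(zip(sim.truth.dnms["chrom"], sim.truth.dnms["pos"]))
    call_keys = set(zip(kept["chrom"], kept["pos"]))
    snvs = [
        (r, a) for r, a in zip(kept["ref"], kept["alt"]) if len(r) == 1 == len(a)
    ]
    categories = dnm_discovery.mutation_categories(kept, sim.reference)
    return {
        "n_candidates": int(len(candidates)),
        "n_calls": int(len(kept)),
        "n_filtered": int(len(log)),
        "recall": len(truth_keys & call_keys) / len(truth_keys),
        "false_calls": len(call_keys - truth_keys),
        "n_post_zygotic": int((kept["zygosity"] == POST_ZYGOTIC).sum()),
        "titv": dnm_discovery.titv_ratio(snvs),
        "categories": {k: int(v) for k, v in categories.items()},
    }


def _stage_phase(config: PipelineConfig, state: dict) -> dict:
    sim = state["sim"]
    informative = haplotype_phasing.informative_sites(sim.variants)
    block_sites = sim.truth.block_sites.rename(columns={"pos0": "pos"}).copy()
    block_sites["pos"] = block_sites["pos"] + 1
    assignments = haplotype_phasing.assign_all_blocks(block_sites, informative)
    truth = sim.truth.dnms
    phased = haplotype_phasing.phase_dnm_table(truth, assignments)
    ok = (phased == truth["parent"]) & (phased != UNPHASED)
    n_phased = int((phased != UNPHASED).sum())
    # CNV parent-of-origin through intra-duplication allele ratios
    child_het = sim.variants[sim.variants["child_gt"] == "0/1"]
    het_for_cnv = child_het.merge(informative, on=["chrom", "pos"])
    het_for_cnv = het_for_cnv.rename(
        columns={"child_ref": "ref_depth", "child_alt": "alt_depth"}
    )
    cnv_origins = []
    for cnv in sim.truth.cnvs:
        sites = het_for_cnv[het_for_cnv["chrom"] == cnv.chrom]
        origin = haplotype_phasing.phase_dncnv(cnv, sites)
        cnv_origins.append(origin == cnv.parent_of_origin)
    state["assignments"] = assignments
    return {
        "n_informative_sites": int(len(informative)),
        "n_blocks_assigned": sum(
            a.hap_a_origin != "unassigned" for a in assignments.values()
        ),
        "n_blocks": len(assignments),
        "dnm_phased": n_phased,
        "dnm_phase_accuracy": float(ok.sum() / n_phased) if n_phased else float("nan"),
        "cnv_origin_correct": int(sum(cnv_origins)),
        "cnv_total": len(cnv_origins),
    }


def _stage_cluster(config: PipelineConfig, state: dict) -> dict:
    sim = state["sim"]
    calls = state["calls"]
    haploid = breakpoint_clustering.mappable_size(sim.reference)
    windows = breakpoint_clustering.build_windows(
        sim.truth.cnvs, config.flank, sim.config.chrom_lengths
    )
    result = breakpoint_clustering.poisson_cluster_test(
        calls[["chrom", "pos"]], windows, len(calls), 2 * haploid, "diploid"
    )
    return {
        "observed": result.observed,
        "expected": result.expected,
        "p_value": result.p_value,
        "window_length": windows.total_length,
        "mappable_haploid": haploid,
    }


def _stage_signatures(config: PipelineConfig, state: dict) -> dict:
    sim = state["sim"]
    calls = state["calls"]
    spectrum = mutational_signatures.build_spectrum(calls, sim.reference)
    catalog = mutational_signatures.synthetic_catalog(5, seed=config.seed)
    refit = mutational_signatures.strict_refit_best_subset(
        spectrum, catalog, config.refit_max_delta
    )
    outside = mutational_signatures.exclude_near_cnv(calls, sim.truth.cnvs, config.flank)
    return {
        "spectrum_total": int(spectrum.sum()),
        "selected": refit.signatures,
        "cosine": refit.cosine,
        "n_calls_outside_cnv_flank": int(len(outside)),
    }


def _stage_cnv(config: PipelineConfig, state: dict) -> dict:
    sim = state["sim"]
    rng = np.random.default_rng(np.random.SeedSequence(sim.config.seed).spawn(7)[-1])
    bins = synthetic_trio.simulate_depth_bins(
        sim.config.chrom_lengths, sim.truth.cnvs, sim.config.mean_depth, rng=rng
    )
    profiles = depth_cnv.normalize_log2(bins)
    events = []
    for profile in profiles:
        segs = depth_cnv.segment_profile(
            profile,
            alpha=config.cbs_alpha,
            n_permutations=config.cbs_permutations,
            seed=sim.config.seed,
        )
        events.append(depth_cnv.call_cnv(depth_cnv.recenter_segments(segs)))
    called = pd.concat(events, ignore_index=True)
    gains = called[called["call"] == "gain"]
    recovered = 0
    for cnv in sim.truth.cnvs:
        for g in gains.itertuples(index=False):
            if g.chrom != cnv.chrom:
                continue
            overlap = min(g.end, cnv.end) - max(g.start, cnv.start)
            if (
                overlap > 0
                and overlap >= 0.95 * cnv.size
                and overlap >= 0.95 * (g.end - g.start)
            ):
                recovered += 1
                break
    return {
        "n_gain_events": int(len(gains)),
        "recovered_duplications": recovered,
        "n_true_duplications": len(sim.truth.cnvs),
    }


def _stage_junctions(config: PipelineConfig, state: dict) -> dict:
    sim = state["sim"]
    rows = []
    for cnv in sim.truth.cnvs:
        junction = junction_analysis.JunctionCall.from_cnv(cnv)
        mh = junction_analysis.microhomology(sim.reference, junction)
        motifs = junction_analysis.scan_non_b_motifs(sim.reference, junction)
        rows.append(
            {
                "chrom": cnv.chrom,
                "planted_mh": cnv.mh_len,
                "observed_mh": mh.length,
                "n_motif_hits": len(motifs),
            }
        )
    exact = sum(r["planted_mh"] == r["observed_mh"] for r in rows)
    return {"junctions": rows, "mh_exact_recovery": exact, "n_junctions": len(rows)}


def _stage_hpo(config: PipelineConfig, state: dict) -> dict:
    if not (config.obo and config.annotations and config.proband_terms):
        return {"skipped": "no ontology inputs supplied"}
    ontology = phenotype_similarity.parse_obo(config.obo)
    gene_terms = phenotype_similarity.load_gene_annotations(config.annotations)
    corpus = phenotype_similarity.AnnotationCorpus(ontology, gene_terms)
    proband = [
        line.strip()
        for line in Path(config.proband_terms).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    result = phenotype_similarity.mpv_search(proband, gene_terms, corpus, config.k_max)
    return {
        "per_k": result.per_k.to_dict(orient="records"),
        "best_k": result.best_k,
        "mpv": result.mpv,
    }


_RUNNERS = {
    "simulate": _stage_simulate,
    "dnm": _stage_dnm,
    "phase": _stage_phase,
    "cluster": _stage_cluster,
    "signatures": _stage_signatures,
    "cnv": _stage_cnv,
    "junctions": _stage_junctions,
    "hpo": _stage_hpo,
}


def cohort_report() -> dict:
    """Statistics over the bundled cohort tables: totals, post-zygotic
    enrichment z-test, paternal-age regression, duplication geometry and
    the breakpoint-clustering expectation for the eight ~1 Mb tandem
    duplications."""
    cohort = fixtures.load_cohort_counts()
    mdn = cohort[cohort["group"] == "MdnCNV"]
    ctrl = cohort[cohort["group"] == "control"]
    mdn_summary = dnm_discovery.cohort_summary(mdn)
    ctrl_summary = dnm_discovery.cohort_summary(ctrl)
    z, p = dnm_discovery.postzygotic_proportion_test(
        mdn_summary["post_zygotic_total"],
        mdn_summary["total"],
        ctrl_summary["post_zygotic_total"],
        ctrl_summary["total"],
    )
    reg = dnm_discovery.germline_age_regression(
        cohort["father_age"], cohort["germline"]
    )
    dups = fixtures.bab9637_duplications()
    windows = breakpoint_clustering.build_windows(
        dups, breakpoint_clustering.DEFAULT_FLANK, fixtures.GRCH38_CHROM_LENGTHS
    )
    diploid = 2 * breakpoint_clustering.MAPPABLE_HAPLOID_GRCH38
    cluster = breakpoint_clustering.poisson_cluster_test(
        pd.DataFrame(columns=["chrom", "pos"]),
        windows,
        fixtures.BAB9637_TOTAL_DNM,
        diploid,
        "diploid",
        observed=7,
    )
    rates = dnm_discovery.dnm_rate(
        fixtures.BAB9637_TOTAL_DNM,
        breakpoint_clustering.MAPPABLE_HAPLOID_GRCH38,
        phased_paternal=round(
            fixtures.BAB9637_PHASED * fixtures.BAB9637_PHASED_PATERNAL_FRACTION
        ),
        phased_maternal=fixtures.BAB9637_PHASED
        - round(fixtures.BAB9637_PHASED * fixtures.BAB9637_PHASED_PATERNAL_FRACTION),
    )
    sizes = [d.size for d in dups]
    return {
        "mdncnv": mdn_summary,
        "control": ctrl_summary,
        "postzygotic_z": z,
        "postzygotic_p": p,
        "paternal_age_slope": reg.slope,
        "paternal_age_slope_ci": list(reg.slope_ci),
        "dup_size_min_kb": min(sizes) / 1000,
        "dup_size_max_kb": max(sizes) / 1000,
        "cluster_lambda": cluster.expected,
        "cluster_p": cluster.p_value,
        "cluster_window_length": windows.total_length,
        "rates": rates,
    }
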