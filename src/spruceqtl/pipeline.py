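"""End-to-end pipeline: simulate -> design -> arrays -> preprocess -> map
-> hotspots -> candidates, with one summary bundle written to disk."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import colloc, hotspots, io, pairdesign, preprocess, qtlmap, synth

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds, seeds and paths for a full pipeline run."""

    outdir: str = "spruceqtl_run"
    seed: int = 0
    lod_threshold: float = 3.84
    bin_cm: float = 10.0
    hotspot_factor: float = 1.5
    min_pqtl: int = 3
    min_frac: float = 0.4
    alpha: float = 0.05
    alpha_composite: float = 0.1
    replicates: int = 1000
    n_perm: int = 10000
    n_random_pairings: int = 200
    sim: synth.SimConfig = field(default_factory=synth.SimConfig)

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1 or not 0 < self.alpha_composite <= 1:
            raise ValueError("alphas must be in (0, 1]")
        if not 0 <= self.min_frac <= 1:
            raise ValueError("min_frac must be in [0, 1]")
        if self.lod_threshold < 0 or self.bin_cm <= 0 or self.hotspot_factor <= 0:
            raise ValueError("thresholds out of range")
        if min(self.replicates, self.n_perm, self.n_random_pairings) < 1:
            raise ValueError("replicate counts must be >= 1")
        if isinstance(self.sim, dict):
            sim = dict(self.sim)
            if "crosses" in sim:
                sim["crosses"] = [synth.Cross(*c) if not isinstance(c, synth.Cross) else c
                                  for c in sim["crosses"]]
            self.sim = synth.SimConfig(**sim)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)


def _stage_rngs(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on freshly simulated data and write the bundle.

    Returns the summary dict (also written to ``summary.json``).  A fixed
    seed reproduces every output file byte for byte.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    rngs = _stage_rngs(
        config.seed,
        ["pedigree", "architecture", "traits", "design", "arrays",
         "randomization", "collocation", "improvement"],
    )

    logger.info("stage: simulate pedigree")
    cfg = config.sim
    map_df, transmissions, cross_df = synth.simulate_pedigree(cfg, rngs["pedigree"])
    truth = cfg.architecture or synth.default_architecture(map_df, cfg, rngs["architecture"])
    expr_true, pheno, truth = synth.simulate_traits(
        map_df, transmissions, truth, cfg, rngs["traits"]
    )
    io.write_map(map_df, out / "map.tsv")
    io.write_transmissions(transmissions, out)
    io.write_crosses(cross_df, out / "crosses.tsv")
    io.write_matrix(pheno, out / "phenotypes.tsv")
    io.write_matrix(expr_true, out / "expression_true.tsv")
    truth.to_json(out / "truth.json")

    logger.info("stage: distant-pair design")
    dist = pairdesign.genetic_distance_matrix(transmissions)
    pairs = pairdesign.optimal_pairing(dist, cross_df["cross"])
    pairs = pairdesign.assign_strata(pairs, seed=rngs["design"])
    plan = pairdesign.assign_dyes(pairs, seed=rngs["design"])
    improvement = pairdesign.improvement_over_random(
        plan, dist, cross_df["cross"], n_random=config.n_random_pairings,
        seed=rngs["improvement"],
    )
    plan.to_csv(out / "plan.tsv", sep="\t", index=False, na_rep="NA")

    logger.info("stage: arrays + preprocessing")
    intensities, sheet, _tech = synth.simulate_arrays(expr_true, plan, cfg, rngs["arrays"])
    io.write_matrix(intensities, out / "intensities.tsv")
    io.write_samplesheet(sheet.reset_index(), out / "samplesheet.tsv")
    normalized = preprocess.glog_normalize(intensities, sheet)
    model = preprocess.remove_technical_effects(normalized, sheet)
    residuals = model.residuals
    io.write_matrix(residuals, out / "residuals.tsv")

    logger.info("stage: QTL mapping")
    pqtl = qtlmap.map_phenotypes(
        pheno, transmissions, map_df, config.lod_threshold, config.bin_cm,
        cross_of=cross_df["cross"],
    )
    eqtl = qtlmap.map_all_expression(
        residuals, transmissions, map_df, config.lod_threshold, config.bin_cm,
        cross_of=cross_df["cross"],
    )
    eqtl = qtlmap.classify_cis_trans(eqtl, truth.transcript_locations, config.bin_cm)
    io.write_qtl_table(pqtl, out / "qtl_pheno.tsv")
    io.write_qtl_table(eqtl, out / "qtl_expression.tsv")

    logger.info("stage: hotspots")
    counts = hotspots.count_per_marker(eqtl, map_df)
    n_eqtl = int(counts.sum())
    summary: dict = {
        "seed": config.seed,
        "n_markers": len(map_df),
        "n_progeny": len(cross_df),
        "n_arrays": len(plan),
        "pairing_improvement_pct": improvement,
        "n_eqtl": n_eqtl,
        "n_pqtl": int(len(pqtl)),
    }
    if n_eqtl > 0:
        chi2, dof, p = hotspots.uniform_gof(counts)
        rand = hotspots.randomization_max(
            n_eqtl, len(map_df), config.replicates, rngs["randomization"]
        )
        cutoff, flags = hotspots.declare_hotspots(counts, config.hotspot_factor)
        hubs = hotspots.find_hubs(
            flags, pqtl, map_df, counts=counts, bin_cm=config.bin_cm,
            min_pqtl=config.min_pqtl, trait_groups=synth.TRAIT_GROUPS,
        )
        hot = pd.DataFrame({"n_eqtl": counts, "hotspot": flags})
        hot.to_csv(out / "hotspots.tsv", sep="\t", na_rep="NA")
        hubs.to_csv(out / "hubs.tsv", sep="\t", index=False, na_rep="NA")
        hotspots.plot_density(counts, map_df, pqtl, cutoff, out / "eqtl_density.svg")
        summary.update(
            gof_chi2=chi2, gof_df=dof, gof_p=p,
            randomization_overall_max=rand.overall_max, randomization_q95=rand.q95,
            hotspot_cutoff=cutoff, n_hotspots=int(flags.sum()), n_hubs=int(len(hubs)),
        )
    else:
        summary.update(n_hotspots=0, n_hubs=0)

    logger.info("stage: collocation candidates")
    bins = colloc.build_bins(map_df, config.bin_cm)
    cands = colloc.candidate_table(
        eqtl, pqtl, bins, config.min_frac, config.alpha, config.n_perm,
        rngs["collocation"],
    )
    cands.to_csv(out / "candidates.tsv", sep="\t", index=False, na_rep="NA")
    summary["candidates_per_trait"] = {
        t: int(sub["candidate"].sum()) for t, sub in cands.groupby("trait")
    }
    if not cands.empty:
        comp = colloc.composite_candidates(cands, synth.TRAIT_GROUPS, config.alpha_composite)
        summary["composite_candidates"] = {k: len(v) for k, v in comp.group_candidates.items()}
        try:
            corr, agg = colloc.qtl_correlation_matrix(cands, synth.TRAIT_GROUPS)
            corr.to_csv(out / "qtl_correlations.tsv", sep="\t", na_rep="NA")
            summary["qtl_correlation_aggregates"] = agg
        except ValueError:
            logger.info("too few transcripts with eQTLs for QTL correlations")
    pheno_corr = colloc.phenotypic_correlation_matrix(pheno)
    pheno_corr.to_csv(out / "phenotypic_correlations.tsv", sep="\t", na_rep="NA")

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    logger.info("pipeline complete: %s", out / "summary.json")
    return summary
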