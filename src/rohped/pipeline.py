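"""End-to-end orchestration: QC → ROH → inbreeding → Ne → islands.

``run`` drives every stage from one :class:`RunConfig` (YAML-loadable), writes
each stage's tables under an output directory and records a JSON provenance
block (parameters, seeds, package version). Stage failures halt the run with
the stage name; tables written before the failure are preserved.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import genomic_inbreeding as gi
from . import islands as isl
from . import pedigree as pedmod
from . import popsize
from . import roh as rohmod
from .io_qc import GenotypeMatrix, apply_qc, read_pedigree, read_plink, summarize
from .synthetic import SimConfig, simulate

log = logging.getLogger("rohped")


@dataclass
class RunConfig:
    # inputs; leave plink_prefix unset to simulate instead
    plink_prefix: str | None = None
    pedigree_path: str | None = None
    annotation_path: str | None = None
    simulate: dict = field(default_factory=dict)  # SimConfig overrides
    # QC
    min_call_rate_snp: float = 0.90
    min_call_rate_sample: float = 0.90
    max_autosome: int = 31
    # ROH calibration
    alpha: float = 0.05
    roh_overrides: dict = field(default_factory=dict)  # RohParams overrides
    l_auto_bp: float | None = None  # default: covered length of the data
    # gene drop
    gene_drop_rounds: int = 100_000
    seed: int = 0
    # LD / Ne
    ld_min_bp: float = 1_000
    ld_max_bp: float = 50_000_000
    # islands
    consensus_thresholds: tuple = isl.DEFAULT_CONSENSUS_THRESHOLDS
    island_percentile: float = 99.0
    out_dir: str = "results/run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def run(cfg: RunConfig) -> dict:
    """Execute all stages; returns a dict of the in-memory result tables."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage = "input"
    try:
        if cfg.plink_prefix:
            gm = read_plink(Path(cfg.plink_prefix).with_suffix(".bed"))
        else:
            sim_cfg = SimConfig(**{"seed": cfg.seed, **cfg.simulate})
            gm, sim_ped, truth = simulate(sim_cfg)
            results["truth"] = truth
        ped = None
        if cfg.pedigree_path:
            ped = read_pedigree(cfg.pedigree_path)
        elif not cfg.plink_prefix:
            ped = sim_ped

        stage = "qc"
        gm, report = apply_qc(gm, cfg.min_call_rate_snp, cfg.min_call_rate_sample,
                              autosomes_only=True, max_autosome=cfg.max_autosome)
        report.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
        summ = summarize(gm)
        results["summary"] = summ

        stage = "roh"
        params = rohmod.params_from_data(
            cfg.alpha, summ.mean_heterozygosity, gm.n_snps, gm.n_samples,
            summ.mean_spacing_bp / 1000.0, **cfg.roh_overrides,
        )
        segments = rohmod.detect_roh(gm, params)
        rohmod.write_segments_tsv(segments, out / "roh_segments.tsv", params)
        length_table = rohmod.classify_lengths(segments)
        length_table.to_csv(out / "roh_length_classes.tsv", sep="\t", index=False)
        indiv_stats = rohmod.per_individual_stats(segments, gm.samples)
        indiv_stats.to_csv(out / "roh_per_individual.tsv", sep="\t")
        results.update(roh_params=params, segments=segments,
                       length_table=length_table, indiv_stats=indiv_stats)

        stage = "genomic_inbreeding"
        l_auto = cfg.l_auto_bp or summ.total_covered_bp
        coeffs = gi.f_roh_table(segments, gm.samples, l_auto)
        coeffs["f_hom"] = gi.f_hom(gm)
        coeffs["f_is"] = gi.f_is(gm)
        coeffs = coeffs.join(gi.f_hat(gm))
        results["genomic_coeffs"] = coeffs

        stage = "pedigree"
        if ped is not None:
            ped_table = pedmod.pedigree_inbreeding_table(
                ped, pedmod.GeneDropConfig(rounds=cfg.gene_drop_rounds, seed=cfg.seed)
            )
            ped_table.to_csv(out / "pedigree_coefficients.tsv", sep="\t")
            results["pedigree_coeffs"] = ped_table
            coeffs = coeffs.join(ped_table, how="left")
        else:
            log.info("no pedigree supplied; pedigree stage skipped")
        coeffs.to_csv(out / "inbreeding_coefficients.tsv", sep="\t")
        gi.summary_table(coeffs).to_csv(out / "inbreeding_summary.tsv", sep="\t")
        results["coeffs"] = coeffs

        stage = "popsize"
        traj = popsize.ld_ne_trajectory(gm, min_bp=cfg.ld_min_bp, max_bp=cfg.ld_max_bp)
        traj.to_csv(out / "ne_trajectory.tsv", sep="\t", index=False)
        f_means = {
            "all": coeffs["f_roh"].mean(),
            ">4": coeffs["f_roh_gt4"].mean(),
            ">8": coeffs["f_roh_gt8"].mean(),
            ">16": coeffs["f_roh_gt16"].mean(),
            ">32": coeffs["f_roh_gt32"].mean(),
        }
        ne_roh = popsize.ne_from_roh_means(f_means)
        ne_roh.to_csv(out / "ne_from_roh.tsv", sep="\t", index=False)
        results.update(ne_trajectory=traj, ne_roh=ne_roh)

        stage = "islands"
        track = isl.incidence(segments, gm.markers, gm.n_samples)
        track.df.to_csv(out / "roh_incidence.tsv", sep="\t", index=False)
        regions = isl.percentile_islands(track, cfg.island_percentile)
        for t in cfg.consensus_thresholds:
            regions += isl.consensus_roh(track, t)
        if cfg.annotation_path:
            regions = isl.annotate(regions, cfg.annotation_path)
        isl.regions_to_frame(regions).to_csv(out / "roh_islands.tsv", sep="\t", index=False)
        results.update(incidence=track, regions=regions)

        stage = "provenance"
        prov = {
            "package": "rohped",
            "version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "seed": cfg.seed,
            "config": _jsonable(dataclasses.asdict(cfg)),
            "roh_params": _jsonable(dataclasses.asdict(params)),
            "n_samples": gm.n_samples,
            "n_snps": gm.n_snps,
        }
        (out / "provenance.json").write_text(json.dumps(prov, indent=2))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return results


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
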