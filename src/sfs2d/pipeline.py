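"""End-to-end pipeline: filter -> build SFS -> fit -> compare -> report.

Every run is fully determined by a :class:`RunConfig` plus its input files:
intermediates (filter summary, SFS file, fit JSON, comparison TSV, residual
grid) are written under ``outdir`` and a rerun with the same config and seed
reproduces them.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as io_formats
from .containers import JointSFS
from .fit import DEFAULT_ROUNDS, compare_models, residuals
from .coalescent import expected_jsfs
from .models import get_model, model_registry
from .sfs import build_jsfs, choose_projection, diversity_stats, filter_genotypes

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Settings for one pipeline run (YAML-serialisable)."""

    vcf: str
    popmap: str
    pops: tuple = ("pop1", "pop2")
    projection: object = "auto"           # (n1, n2) or "auto"
    fold: bool = True
    max_missing_frac: float = 0.40
    min_depth: int = 10
    max_obs_het: float = 0.65
    one_snp_per_locus: bool = True
    registry: str = "full"
    nreps: int = 50_000
    rounds: tuple = DEFAULT_ROUNDS
    seed: int = 1
    outdir: str = "sfs2d_run"

    def __post_init__(self):
        if not (0 <= self.max_missing_frac <= 1 and 0 <= self.max_obs_het <= 1):
            raise ValueError("filter fractions must be in [0, 1]")
        if self.seed is None:
            raise ValueError("a seed is mandatory")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "rounds" in data:
            data["rounds"] = tuple(tuple(r) for r in data["rounds"])
        if isinstance(data.get("pops"), list):
            data["pops"] = tuple(data["pops"])
        if isinstance(data.get("projection"), list):
            data["projection"] = tuple(data["projection"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["pops"] = list(self.pops)
        d["rounds"] = [list(r) for r in self.rounds]
        if isinstance(d["projection"], tuple):
            d["projection"] = list(d["projection"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns ``{"comparison": ..., "paths": {...}}``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    stage = "read-input"
    try:
        gm = io_formats.read_vcf(config.vcf)
        popmap = io_formats.read_popmap(config.popmap)

        stage = "filter"
        n_before = gm.n_sites
        gm = filter_genotypes(gm, config.max_missing_frac, config.min_depth,
                              config.max_obs_het, config.one_snp_per_locus)
        paths["filtered_vcf"] = out / "filtered.vcf"
        io_formats.write_vcf(gm, paths["filtered_vcf"])

        stage = "diversity"
        stats = diversity_stats(gm, popmap)
        paths["diversity"] = out / "diversity.tsv"
        with open(paths["diversity"], "w") as fh:
            fh.write("population\tpi\texp_het\tpct_polymorphic"
                     "\tprivate_alleles\tn_sites_called\n")
            for s in stats.values():
                fh.write(f"{s.population}\t{s.pi:.6g}\t{s.exp_het:.6g}\t"
                         f"{s.pct_polymorphic:.6g}\t{s.private_alleles}\t"
                         f"{s.n_sites_called}\n")

        stage = "build-sfs"
        pop1, pop2 = config.pops
        if config.projection == "auto":
            n1, n2 = choose_projection(gm, popmap, (pop1, pop2))
        else:
            n1, n2 = config.projection
        obs = build_jsfs(gm, popmap, pop1, pop2, n1, n2,
                         fold_spectrum=config.fold)
        paths["sfs"] = out / "observed.sfs"
        io_formats.write_sfs_file(obs, paths["sfs"])

        stage = "fit"
        registry = model_registry(config.registry)
        cmp = compare_models(obs, registry, nreps=config.nreps,
                             seed=config.seed, rounds=config.rounds)

        stage = "report"
        paths["comparison"] = out / "comparison.tsv"
        io_formats.write_fit_table(cmp, paths["comparison"])
        paths["fits_json"] = out / "fits.json"
        with open(paths["fits_json"], "w") as fh:
            json.dump([{"model": f.model, "loglik": f.loglik, "k": f.k,
                        "AIC": f.aic, "theta": f.theta_hat,
                        "params": f.params.as_dict(), "seed": f.seed,
                        "trajectory": f.trajectory}
                       for f in cmp.results], fh, indent=1)
        best = cmp.best
        best_sfs = expected_jsfs(get_model(best.model), best.params, obs.n1,
                                 obs.n2, nreps=config.nreps,
                                 seed=config.seed).fold()
        grid = residuals(obs, best_sfs, best.theta_hat)
        paths["residuals"] = out / "residuals.tsv"
        np.savetxt(paths["residuals"], grid, fmt="%.4f", delimiter="\t")

        paths["log"] = out / "run.json"
        with open(paths["log"], "w") as fh:
            json.dump({"seed": config.seed, "sites_input": n_before,
                       "sites_after_filter": gm.n_sites,
                       "projection": [n1, n2],
                       "best_model": best.model}, fh, indent=1)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    logger.info("pipeline complete; best model %s", cmp.best.model)
    return {"comparison": cmp, "paths": paths}
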