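"""Self-contained synthetic RADseq-style fixtures: VCF + popmap + truth JSON.

A fixture emulates the statistical shape of a filtered two-population RADseq
SNP table: hundreds to thousands of independent RAD loci, each an
unrecombined fragment carrying few SNPs, diploid individuals from two
populations whose genealogies follow a chosen demographic model, plus
independent per-genotype missingness and Poisson-distributed read depth so
the standard depth/missingness/heterozygosity filters have something real to
do.  The generating parameters are written verbatim to ``truth.json`` so
recovery benchmarks and the command-line ``simulate`` entry share one
source of truth.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .coalescent import simulate_dataset
from .containers import DEPTH_UNKNOWN, MISSING, GenotypeMatrix, PopMap
from .io import write_popmap, write_vcf
from .models import ParamSet, get_model, validate_params

logger = logging.getLogger(__name__)

__all__ = ["FixtureSpec", "make_fixture", "preset_fixtures", "apply_noise"]


@dataclass
class FixtureSpec:
    """Everything needed to regenerate one synthetic dataset."""

    name: str
    model_name: str
    params: ParamSet
    n_loci: int = 2645
    individuals_per_pop: tuple = (12, 8)
    theta_per_locus: float = 0.2
    missing_rate: float = 0.10
    mean_depth: float = 25.0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["params"] = self.params.as_dict()
        d["individuals_per_pop"] = list(self.individuals_per_pop)
        return d


def apply_noise(gm: GenotypeMatrix, missing_rate: float, mean_depth: float,
                seed: int) -> GenotypeMatrix:
    """Inject independent missingness and Poisson read depth into a matrix.

    Each genotype goes missing independently with probability
    ``missing_rate`` (depth 0); called genotypes draw depth from
    Poisson(``mean_depth``).
    """
    gm = gm.copy()
    rng = np.random.default_rng(seed)
    shape = gm.genotypes.shape
    drop = rng.random(shape) < missing_rate
    gm.genotypes[drop] = MISSING
    gm.depths = rng.poisson(mean_depth, size=shape).astype(np.int32)
    gm.depths[gm.genotypes == MISSING] = 0
    return gm


def make_fixture(spec: FixtureSpec, outdir, overwrite: bool = False) -> dict:
    """Simulate a fixture and write ``<name>.vcf``, ``<name>.popmap.tsv`` and
    ``<name>.truth.json`` under ``outdir``; returns the three paths."""
    outdir = Path(outdir)
    paths = {
        "vcf": outdir / f"{spec.name}.vcf",
        "popmap": outdir / f"{spec.name}.popmap.tsv",
        "truth": outdir / f"{spec.name}.truth.json",
    }
    existing = [p for p in paths.values() if p.exists()]
    if existing and not overwrite:
        raise FileExistsError(
            f"refusing to overwrite {existing[0]} (pass overwrite=True)")
    outdir.mkdir(parents=True, exist_ok=True)

    model = get_model(spec.model_name)
    violations = validate_params(model, spec.params)
    if violations:
        raise ValueError(f"invalid fixture parameters: {violations}")

    rng = np.random.default_rng(spec.seed)
    sim_seed, noise_seed = (int(s) for s in rng.integers(2 ** 31, size=2))
    gm = simulate_dataset(model, spec.params, spec.n_loci,
                          spec.individuals_per_pop, spec.theta_per_locus,
                          seed=sim_seed)
    gm = apply_noise(gm, spec.missing_rate, spec.mean_depth, noise_seed)

    ind1, ind2 = spec.individuals_per_pop
    popmap = PopMap({ind: ("pop1" if i < ind1 else "pop2")
                     for i, ind in enumerate(gm.individuals)})
    write_vcf(gm, paths["vcf"])
    write_popmap(popmap, paths["popmap"])
    with open(paths["truth"], "w") as fh:
        json.dump(spec.as_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("fixture %s: %d SNPs across %d individuals", spec.name,
                gm.n_sites, gm.n_individuals)
    return paths


def preset_fixtures() -> list:
    """Presets seeded from the published best-fit values of the four named
    models, with 12 + 8 diploids so 24/16-allele down-projection is exact
    when nothing is missing."""
    return [
        FixtureSpec("vic_no_mig_table2", "vic_no_mig",
                    ParamSet(nuA=1.54, nu1=1.64, nu2=14.9, T=0.4, s=0.3)),
        FixtureSpec("vic_sec_contact_table2", "vic_sec_contact_asym_mig",
                    ParamSet(nuA=1.4, nu1=0.03, nu2=1.05, T1=0.43, T2=0.68,
                             s=0.4, m12=0.09, m21=0.05)),
        FixtureSpec("founder_sec_contact_table2",
                    "founder_sec_contact_asym_two_epoch",
                    ParamSet(nuA=0.43, nu1=10.01, nu2=0.36, T1=0.19, T2=0.5,
                             s=0.1, m12=0.23, m21=0.06)),
        FixtureSpec("founder_anc_table2", "founder_anc_asym_two_epoch",
                    ParamSet(nuA=0.2, nu1=7.24, nu2=0.12, T1=0.17, T2=0.02,
                             s=0.01, m12=1.77, m21=6.12)),
    ]


def get_preset(name: str) -> FixtureSpec:
    for spec in preset_fixtures():
        if spec.name == name:
            return spec
    raise KeyError(f"no preset named {name!r}")
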