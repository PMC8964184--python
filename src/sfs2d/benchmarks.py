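"""Desk-scale benchmark routines: bound enforcement, recovery, discrimination.

These are the package's standing simulation experiments, sized to run in
minutes on one core.  Each is deterministic given its seed.  They are used
by the test suite and the reproduction script; the module doubles as worked
examples of driving the library programmatically.
"""

from __future__ import annotations

import logging
import zlib

import numpy as np

from .containers import JointSFS, PopMap
from .coalescent import expected_jsfs, simulate_dataset
from .fit import optimize_model
from .models import ParamSet, get_model
from .sfs import build_jsfs
from .synthetic import get_preset

logger = logging.getLogger(__name__)

__all__ = ["s_bound_batch", "recovery_benchmark", "discrimination_benchmark",
           "poisson_observation"]

#: reduced optimizer schemas for desk-scale batches
SMALL_ROUNDS = ((2, 2.0, 20), (1, 1.5, 25))
MEDIUM_ROUNDS = ((5, 2.0, 40), (3, 1.5, 60), (2, 1.2, 80))
RECOVERY_ROUNDS = ((2, 1.5, 40), (1, 1.2, 50))

#: archetypal vicariance for the discrimination experiment: comparably
#: sized daughter populations, moderate split time
VIC_ARCHETYPE = ParamSet(nuA=1.0, nu1=1.0, nu2=1.5, T=0.5, s=0.4)


def poisson_observation(model_name: str, truth: ParamSet, n1: int, n2: int,
                        theta: float, seed: int,
                        nreps: int = 100_000) -> JointSFS:
    """Folded observed spectrum: Poisson counts around theta * expectation."""
    model = get_model(model_name)
    exp = expected_jsfs(model, truth, n1, n2, nreps=nreps,
                        seed=(seed * 7919 + 13) % (2 ** 31)).fold()
    rng = np.random.default_rng(seed)
    return JointSFS(rng.poisson(theta * exp.counts).astype(float),
                    folded=True, mask=exp.mask.copy())


def s_bound_batch(seed: int = 1, n_runs: int = 20, n_loci: int = 800,
                  nreps: int = 2_000):
    """Fit founder/vicariance models ``n_runs`` times to one synthetic
    preset dataset and collect every fitted founding fraction ``s``.

    The observed spectrum comes from the published-values vicariance preset,
    simulated as genotypes and projected to 12 x 8 alleles.  Returns
    ``(configured_bound, fitted_s_values)``.
    """
    spec = get_preset("vic_no_mig_table2")
    model = get_model(spec.model_name)
    gm = simulate_dataset(model, spec.params, n_loci,
                          spec.individuals_per_pop, spec.theta_per_locus,
                          seed=seed)
    popmap = PopMap({ind: ("pop1" if i < spec.individuals_per_pop[0] else "pop2")
                     for i, ind in enumerate(gm.individuals)})
    obs = build_jsfs(gm, popmap, "pop1", "pop2", 12, 8)

    candidates = ["vic_no_mig", "vic_sec_contact_asym_mig",
                  "founder_sec_contact_asym_two_epoch", "founder_no_mig"]
    bound = None
    fitted_s = []
    for run in range(n_runs):
        m = get_model(candidates[run % len(candidates)])
        bounds = {n: (lo, hi) for n, lo, hi in m.free_params}
        bound = bounds["s"][1] if bound is None else max(bound, bounds["s"][1])
        fit = optimize_model(m, obs, nreps=nreps,
                             seed=(seed * 1009 + run) % (2 ** 31),
                             rounds=SMALL_ROUNDS, n_scan=60)
        fitted_s.append(float(fit.params["s"]))
        logger.info("s-bound batch run %d (%s): s = %.4f", run, m.name,
                    fitted_s[-1])
    return bound, fitted_s


def recovery_benchmark(preset_names=None, seeds=(1, 2, 3), theta: float = 500.0,
                       n1: int = 24, n2: int = 16, nreps: int = 50_000):
    """Parameter recovery on spectra simulated at the published best-fit
    values: for each preset, fit the generating model to ``len(seeds)``
    Poisson spectra starting near the truth (local identifiability) and
    report per-parameter relative errors.

    Returns ``{preset: {param: [rel_err per seed]}}``.
    """
    if preset_names is None:
        preset_names = ["vic_no_mig_table2", "vic_sec_contact_table2",
                        "founder_sec_contact_table2", "founder_anc_table2"]
    out = {}
    for name in preset_names:
        spec = get_preset(name)
        model = get_model(spec.model_name)
        truth = spec.params
        errs = {p: [] for p in truth.as_dict()}
        for seed in seeds:
            obs_seed = zlib.crc32(f"{name}:{seed}".encode()) % (2 ** 31)
            obs = poisson_observation(spec.model_name, truth, n1, n2, theta,
                                      seed=obs_seed)
            fit = optimize_model(model, obs, nreps=nreps, seed=seed,
                                 rounds=RECOVERY_ROUNDS, start=truth)
            for p, v in truth.as_dict().items():
                errs[p].append(abs(fit.params[p] - v) / abs(v))
            logger.info("recovery %s seed %d: loglik %.2f", name, seed,
                        fit.loglik)
        out[name] = errs
    return out


def discrimination_benchmark(n_seeds: int = 10, theta: float = 500.0,
                             n1: int = 12, n2: int = 8, nreps: int = 3_000,
                             base_seed: int = 1000):
    """Model discrimination: simulate archetypal-vicariance spectra and ask
    whether the vicariance model outranks (by AIC) the founder model with
    secondary contact.  Returns the number of vicariance wins."""
    vic = get_model("vic_no_mig")
    fsc = get_model("founder_sec_contact_asym_two_epoch")
    exp = expected_jsfs(vic, VIC_ARCHETYPE, n1, n2, nreps=100_000,
                        seed=99).fold()
    wins = 0
    for s in range(n_seeds):
        rng = np.random.default_rng(base_seed + s)
        obs = JointSFS(rng.poisson(theta * exp.counts).astype(float),
                       folded=True, mask=exp.mask.copy())
        fv = optimize_model(vic, obs, nreps=nreps, seed=2 * s + 1,
                            rounds=MEDIUM_ROUNDS, n_scan=300)
        ff = optimize_model(fsc, obs, nreps=nreps, seed=2 * s + 2,
                            rounds=MEDIUM_ROUNDS, n_scan=300)
        win = fv.aic < ff.aic
        wins += int(win)
        logger.info("discrimination seed %d: vic AIC %.1f vs founder %.1f "
                    "-> %s", s, fv.aic, ff.aic, "vic" if win else "founder")
    return wins
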