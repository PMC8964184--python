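"""Genotype filtering, joint-SFS construction and per-population diversity.

The pipeline here mirrors standard RADseq practice for demographic inference:
genotypes failing a depth floor are set missing, sites with too much
missingness or excess observed heterozygosity (putative merged paralogs) are
dropped, one SNP per RAD locus is kept, and the surviving allele counts are
down-projected hypergeometrically onto a smaller, even allele sample size so
sites with missing genotypes still contribute to the spectrum.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .containers import MISSING, DEPTH_UNKNOWN, GenotypeMatrix, JointSFS, PopMap

logger = logging.getLogger(__name__)

__all__ = [
    "filter_genotypes", "allele_counts", "project_counts", "build_jsfs",
    "fold", "choose_projection", "diversity_stats", "DiversityStats",
]


def filter_genotypes(gm: GenotypeMatrix, max_missing_frac: float = 0.40,
                     min_depth: int = 10, max_obs_het: float = 0.65,
                     one_snp_per_locus: bool = True) -> GenotypeMatrix:
    """Apply the SNP-level filters feeding the spectrum, in a fixed order.

    1. genotypes with depth below ``min_depth`` (or unknown depth, which can
       never demonstrate sufficient coverage) are set missing;
    2. sites whose missing-genotype fraction exceeds ``max_missing_frac``
       are removed;
    3. sites whose observed heterozygosity among called genotypes exceeds
       ``max_obs_het`` are removed (paralog guard);
    4. optionally only the first (lowest-position) surviving SNP per locus
       is retained.

    Removal counts per step are logged.  An empty result is legal.
    """
    if not (0 <= max_missing_frac <= 1):
        raise ValueError("max_missing_frac must be in [0, 1]")
    if not (0 <= max_obs_het <= 1):
        raise ValueError("max_obs_het must be in [0, 1]")
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")

    gm = gm.copy()
    # (a) depth: unknown depth fails a positive depth floor
    if min_depth > 0:
        low = (gm.depths < min_depth)  # DEPTH_UNKNOWN == -1 < any positive floor
        n_masked = int((low & (gm.genotypes != MISSING)).sum())
        gm.genotypes[low] = MISSING
        logger.info("depth filter: %d genotypes set missing (depth < %d or unknown)",
                    n_masked, min_depth)

    n0 = gm.n_sites
    # (b) missingness per site
    miss_frac = (gm.genotypes == MISSING).mean(axis=1)
    keep = miss_frac <= max_missing_frac
    logger.info("missingness filter: %d of %d sites removed (> %.0f%% missing)",
                int((~keep).sum()), n0, 100 * max_missing_frac)
    gm = gm.take_sites(np.flatnonzero(keep))

    # (c) observed heterozygosity among called genotypes
    called = gm.genotypes != MISSING
    n_called = called.sum(axis=1)
    n_het = (gm.genotypes == 1).sum(axis=1)
    with np.errstate(invalid="ignore"):
        obs_het = np.where(n_called > 0, n_het / np.maximum(n_called, 1), 0.0)
    keep = obs_het <= max_obs_het
    logger.info("heterozygosity filter: %d sites removed (obs het > %.2f)",
                int((~keep).sum()), max_obs_het)
    gm = gm.take_sites(np.flatnonzero(keep))

    # (d) one SNP per locus: first = lowest position
    if one_snp_per_locus:
        best = {}
        for idx in range(gm.n_sites):
            loc = gm.locus[idx]
            if loc not in best or gm.pos[idx] < gm.pos[best[loc]]:
                best[loc] = idx
        keep_idx = sorted(best.values())
        logger.info("one-SNP-per-locus: %d of %d sites kept",
                    len(keep_idx), gm.n_sites)
        gm = gm.take_sites(np.asarray(keep_idx, dtype=np.intp))

    if gm.n_sites == 0:
        logger.warning("all sites removed by filtering")
    return gm


def allele_counts(gm: GenotypeMatrix, popmap: PopMap, pop: str):
    """Per-site (alt-allele count, called-allele count) within ``pop``."""
    cols = gm.columns_for(popmap, pop)
    sub = gm.genotypes[:, cols]
    called = sub != MISSING
    alt = np.where(called, sub, 0).sum(axis=1).astype(np.int64)
    n_alleles = 2 * called.sum(axis=1).astype(np.int64)
    return alt, n_alleles


def project_counts(i: int, n: int, n_proj: int) -> np.ndarray:
    """Hypergeometric down-projection of an allele count.

    Entry ``j`` is the probability that a subsample of ``n_proj`` of the
    ``n`` observed alleles contains ``j`` copies of the allele observed
    ``i`` times: ``C(i,j) C(n-i, n_proj-j) / C(n, n_proj)``.
    """
    if not (0 <= i <= n):
        raise ValueError(f"need 0 <= i <= n, got i={i}, n={n}")
    if not (1 <= n_proj <= n):
        raise ValueError(f"need 1 <= n_proj <= n, got n_proj={n_proj}, n={n}")
    j = np.arange(n_proj + 1)
    return hypergeom.pmf(j, n, i, n_proj)


def build_jsfs(gm: GenotypeMatrix, popmap: PopMap, pop1: str, pop2: str,
               n1: int, n2: int, fold_spectrum: bool = True) -> JointSFS:
    """Build the (down-projected) joint SFS for a pair of populations.

    Each site with at least ``n1`` called alleles in ``pop1`` and ``n2`` in
    ``pop2`` contributes the outer product of its two hypergeometric
    projection vectors (total mass exactly 1); other sites contribute
    nothing.  The alternate allele plays "derived"; with ``fold_spectrum``
    (the default) polarization is irrelevant.
    """
    if pop1 == pop2:
        raise ValueError("pop1 and pop2 must differ")
    for n, name in ((n1, "n1"), (n2, "n2")):
        if n <= 0 or n % 2:
            raise ValueError(f"{name} must be a positive even allele count")

    a1, c1 = allele_counts(gm, popmap, pop1)
    a2, c2 = allele_counts(gm, popmap, pop2)
    counts = np.zeros((n1 + 1, n2 + 1))
    usable = (c1 >= n1) & (c2 >= n2)
    # projection vectors depend only on (i, n); memoise across sites
    cache = {}

    def proj(i, n, n_proj):
        key = (i, n, n_proj)
        if key not in cache:
            cache[key] = project_counts(i, n, n_proj)
        return cache[key]

    for idx in np.flatnonzero(usable):
        v1 = proj(int(a1[idx]), int(c1[idx]), n1)
        v2 = proj(int(a2[idx]), int(c2[idx]), n2)
        counts += np.outer(v1, v2)

    sfs = JointSFS(counts, folded=False, pop_ids=(pop1, pop2))
    logger.info("built %dx%d JSFS from %d of %d sites (mass %.2f)",
                n1 + 1, n2 + 1, int(usable.sum()), gm.n_sites, sfs.sum())
    return sfs.fold() if fold_spectrum else sfs


def fold(sfs: JointSFS) -> JointSFS:
    """Fold a spectrum onto minor-allele frequency classes.

    Cell ``(i, j)`` is paired with its complement ``(n1-i, n2-j)``.  The
    member with the smaller total count ``i+j`` keeps the summed mass; the
    other half of the grid is masked and zeroed.  On the hinge
    ``i+j == (n1+n2)/2`` the lexicographically smaller member of each pair
    keeps the sum, and self-complementary cells keep their own value.
    Total unmasked mass is conserved; folding is idempotent.
    """
    if sfs.folded:
        logger.warning("fold() called on an already-folded spectrum; no-op")
        return sfs.copy()
    n1, n2 = sfs.n1, sfs.n2
    half = (n1 + n2) / 2.0
    counts = np.zeros_like(sfs.counts)
    mask = np.zeros_like(sfs.mask)
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            ci, cj = n1 - i, n2 - j
            tot = i + j
            if tot < half:
                counts[i, j] = sfs.counts[i, j] + sfs.counts[ci, cj]
            elif tot > half:
                mask[i, j] = True
            else:  # hinge
                if (i, j) == (ci, cj):
                    counts[i, j] = sfs.counts[i, j]
                elif (i, j) < (ci, cj):
                    counts[i, j] = sfs.counts[i, j] + sfs.counts[ci, cj]
                else:
                    mask[i, j] = True
    # input masks propagate: a masked cell or its complement stays masked
    mask |= sfs.mask | sfs.mask[::-1, ::-1]
    counts[mask] = 0.0
    return JointSFS(counts, folded=True, mask=mask, pop_ids=sfs.pop_ids)


def choose_projection(gm: GenotypeMatrix, popmap: PopMap, pops) -> tuple:
    """Pick projection sizes maximising expected segregating sites.

    Scans the grid of even candidate sizes per population; the objective is
    the expected number of sites still polymorphic after projection,
    ``sum_sites (1 - P[projected pair sample is monomorphic])``, where a site
    enters only if both populations have enough called alleles.  Ties break
    toward the larger total sample.
    """
    pop1, pop2 = pops
    a1, c1 = allele_counts(gm, popmap, pop1)
    a2, c2 = allele_counts(gm, popmap, pop2)
    max1 = 2 * len(popmap.members(pop1))
    max2 = 2 * len(popmap.members(pop2))
    cand1 = range(2, max1 + 1, 2)
    cand2 = range(2, max2 + 1, 2)

    def p_mono(a, c, n):
        # all-ref or all-alt in the hypergeometric subsample
        return (hypergeom.pmf(0, c, a, n) + hypergeom.pmf(n, c, a, n))

    best, best_score = None, -1.0
    for n1 in cand1:
        for n2 in cand2:
            ok = (c1 >= n1) & (c2 >= n2)
            if not ok.any():
                score = 0.0
            else:
                pm = p_mono(a1[ok], c1[ok], n1) * p_mono(a2[ok], c2[ok], n2)
                score = float((1.0 - pm).sum())
            if (score > best_score + 1e-12
                    or (abs(score - best_score) <= 1e-12
                        and best is not None and n1 + n2 > sum(best))):
                best, best_score = (n1, n2), score
    logger.info("projection chosen: %s (expected segregating sites %.1f)",
                best, best_score)
    return best


@dataclass
class DiversityStats:
    """Per-population summary: nucleotide diversity, heterozygosity, etc.

    ``pi`` uses the unbiased per-site estimator ``2 p (1-p) c/(c-1)``
    averaged over variant sites by default; pass ``n_total_sites`` to
    :func:`diversity_stats` to average over all recovered sites instead
    (the convention behind the very small genome-wide values RAD pipelines
    report).  ``NaN`` marks statistics undefined for a population with no
    called data.
    """

    population: str
    pi: float
    exp_het: float
    pct_polymorphic: float
    private_alleles: int
    n_sites_called: int


def diversity_stats(gm: GenotypeMatrix, popmap: PopMap,
                    n_total_sites: int = None) -> dict:
    """Table of per-population diversity statistics.

    Returns ``{population: DiversityStats}``.  A private allele is an allele
    (ref or alt) observed in exactly one population; each such observation
    adds one to that population's count.
    """
    pops = popmap.populations()
    per_pop = {}
    presence_ref = {}
    presence_alt = {}
    for pop in pops:
        alt, called = allele_counts(gm, popmap, pop)
        per_pop[pop] = (alt, called)
        presence_ref[pop] = (called - alt) > 0
        presence_alt[pop] = alt > 0

    results = {}
    for pop in pops:
        alt, called = per_pop[pop]
        use = called >= 2
        n_called_sites = int((called >= 1).sum())
        if n_called_sites == 0:
            results[pop] = DiversityStats(pop, float("nan"), float("nan"),
                                          float("nan"), 0, 0)
            continue
        p = np.zeros(len(alt))
        p[use] = alt[use] / called[use]
        het = 2 * p * (1 - p)
        pi_site = np.zeros(len(alt))
        pi_site[use] = het[use] * called[use] / (called[use] - 1)
        poly = use & (alt > 0) & (alt < called)
        n_variant = int(poly.sum())
        if n_total_sites is not None:
            denom = n_total_sites
        else:
            denom = max(n_variant, 1)
        pi = float(pi_site[poly].sum()) / denom if n_variant else 0.0
        exp_het = float(het[poly].sum()) / denom if n_variant else 0.0
        pct_poly = n_variant / max(int(use.sum()), 1)

        private = 0
        for pres in (presence_ref, presence_alt):
            here = pres[pop]
            elsewhere = np.zeros(len(alt), dtype=bool)
            for other in pops:
                if other != pop:
                    elsewhere |= pres[other]
            private += int((here & ~elsewhere).sum())
        results[pop] = DiversityStats(pop, pi, exp_het, pct_poly, private,
                                      n_called_sites)
    return results
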