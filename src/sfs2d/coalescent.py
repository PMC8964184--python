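"""Structured-coalescent Monte Carlo: expected spectra and simulated data.

Two engines share one event model (described in :mod:`sfs2d._kernel`):

* a compiled kernel that accumulates only branch *class* lengths — the fast
  path behind :func:`expected_jsfs`, evaluated thousands of times inside
  optimization;
* a plain-Python genealogy simulator that additionally tracks the leaf set
  under every branch, used to drop infinite-sites mutations and emit whole
  genotype datasets (:func:`simulate_dataset`) and as a readable reference
  implementation cross-checked against the kernel in the test suite.

Conventions: time in units of ``2*N_ref`` generations; a lineage pair in a
deme of relative size ``nu`` coalesces at rate ``1/nu``; a lineage currently
in population 1 jumps (backward) to population 2 at rate ``m12`` — the
scaled rate, ``2*N_ref*m``, at which population 1 receives migrants from
population 2 forward in time — and vice versa for ``m21``.
"""

from __future__ import annotations

import math

import numpy as np

from ._kernel import sim_branch_classes
from .containers import DEPTH_UNKNOWN, GenotypeMatrix, JointSFS
from .models import DemographicModel, EpochSchedule, ParamSet, to_epochs

__all__ = [
    "schedule_arrays", "simulate_genealogy", "expected_jsfs",
    "expected_jsfs_from_schedule", "simulate_locus_segments",
    "simulate_dataset",
]

_BIG = 1e30


def schedule_arrays(schedule: EpochSchedule):
    """Encode an EpochSchedule as the flat arrays the kernel consumes."""
    schedule.validate()
    ne = len(schedule.epochs) + 1
    dur = np.empty(ne)
    g0 = np.empty((ne, 2))
    beta = np.zeros((ne, 2))
    mig = np.zeros((ne, 2))
    for e, ep in enumerate(schedule.epochs):
        dur[e] = ep.duration
        g0[e] = ep.size_start
        for d in range(2):
            if ep.duration > 0 and ep.size_end[d] != ep.size_start[d]:
                beta[e, d] = math.log(ep.size_end[d] / ep.size_start[d]) / ep.duration
        mig[e] = ep.mig
    dur[-1] = _BIG
    g0[-1] = (schedule.nuA, 1.0)
    return dur, g0, beta, mig


def _class_lengths_python(n1, n2, dur, g0, beta, mig, rng,
                          track_leaves=False):
    """One genealogy; returns closed branch segments.

    Each segment is ``(leafset, i, j, length)``; ``leafset`` is a Python int
    bitmask over the ``n1 + n2`` sampled haplotypes (pop-1 leaves first) when
    ``track_leaves``, else 0.  The root branch is excluded.
    """
    ne = len(dur)
    # lineage records: [deme, i, j, birth, leafset]
    demes = [[], []]
    lineages = {}
    nxt = 0
    for d, nd in ((0, n1), (1, n2)):
        for _ in range(nd):
            leafset = (1 << nxt) if track_leaves else 0
            lineages[nxt] = [d, 1 - d, d, 0.0, leafset]
            demes[d].append(nxt)
            nxt += 1
    segments = []
    t, u, e = 0.0, 0.0, 0
    if ne == 1:
        demes[0].extend(demes[1])
        for s in demes[1]:
            lineages[s][0] = 0
        demes[1] = []

    while len(demes[0]) + len(demes[1]) > 1:
        k0, k1 = len(demes[0]), len(demes[1])
        mig_rate = k0 * mig[e, 0] + k1 * mig[e, 1]
        w_mig = rng.exponential() / mig_rate if mig_rate > 0 else _BIG
        waits = [w_mig]
        for d, k in ((0, k0), (1, k1)):
            if k < 2:
                waits.append(_BIG)
                continue
            g_cur = g0[e, d] * math.exp(beta[e, d] * u)
            rate0 = 0.5 * k * (k - 1) / g_cur
            ex = rng.exponential()
            b = beta[e, d]
            if abs(b) > 1e-12:
                arg = 1.0 - ex * b / rate0
                waits.append(-math.log(arg) / b if arg > 0 else _BIG)
            else:
                waits.append(ex / rate0)
        ev = int(np.argmin(waits))
        w = waits[ev]
        remaining = dur[e] - u
        if w >= remaining:
            t += remaining
            u = 0.0
            e += 1
            if e == ne - 1:
                demes[0].extend(demes[1])
                for s in demes[1]:
                    lineages[s][0] = 0
                demes[1] = []
            continue
        t += w
        u += w
        if ev == 0:
            d = 0 if rng.random() * mig_rate < k0 * mig[e, 0] else 1
            o = 1 - d
            idx = rng.integers(len(demes[d]))
            s = demes[d].pop(idx)
            lineages[s][0] = o
            demes[o].append(s)
        else:
            d = ev - 1
            ia, ib = rng.choice(len(demes[d]), size=2, replace=False)
            sa, sb = demes[d][ia], demes[d][ib]
            for s in (sa, sb):
                rec = lineages[s]
                # (leafset, class-i, class-j, length, birth time)
                segments.append((rec[4], rec[1], rec[2], t - rec[3], rec[3]))
            parent = [d, lineages[sa][1] + lineages[sb][1],
                      lineages[sa][2] + lineages[sb][2], t,
                      lineages[sa][4] | lineages[sb][4]]
            lineages[nxt] = parent
            demes[d] = [s for s in demes[d] if s not in (sa, sb)]
            demes[d].append(nxt)
            del lineages[sa], lineages[sb]
            nxt += 1
    return segments


def simulate_locus_segments(schedule: EpochSchedule, n1: int, n2: int, rng):
    """Closed branch segments ``(leafset, i, j, length, birth)`` for one
    genealogy (birth = backward time at which the lineage arose)."""
    dur, g0, beta, mig = schedule_arrays(schedule)
    return _class_lengths_python(n1, n2, dur, g0, beta, mig, rng,
                                 track_leaves=True)


def simulate_genealogy(schedule: EpochSchedule, n1: int, n2: int,
                       nreps: int, seed: int) -> np.ndarray:
    """Per-replicate branch-class length tables, shape (nreps, n1+1, n2+1)."""
    if n1 + n2 < 1:
        raise ValueError("need at least one sampled lineage")
    dur, g0, beta, mig = schedule_arrays(schedule)
    rng = np.random.default_rng(seed)
    out = np.zeros((nreps, n1 + 1, n2 + 1))
    for r in range(nreps):
        for _, i, j, length, _birth in _class_lengths_python(
                n1, n2, dur, g0, beta, mig, rng):
            out[r, i, j] += length
        out[r, n1, n2] = 0.0
    return out


def expected_jsfs_from_schedule(schedule: EpochSchedule, n1: int, n2: int,
                                nreps: int = 50_000, seed: int = 0,
                                pop_ids=("pop1", "pop2"),
                                return_se: bool = False):
    """Monte Carlo expected joint SFS at theta = 1 for an epoch schedule.

    Entry ``(i, j)`` is half the mean branch length in leaf class
    ``(i, j)``, so a history with mutation parameter theta predicts
    ``theta * counts`` sites per cell.  Deterministic given ``seed``: the
    same seed and replicate count reuse the same underlying random stream
    for every parameter value (common random numbers), which keeps
    likelihood surfaces smooth for the optimizer.
    """
    if nreps < 1:
        raise ValueError("nreps must be >= 1")
    dur, g0, beta, mig = schedule_arrays(schedule)
    lsum, lsq = sim_branch_classes(n1, n2, dur, g0, beta, mig, nreps,
                                   int(seed) % (2 ** 31))
    mean = lsum / nreps
    counts = mean / 2.0
    sfs = JointSFS(counts, folded=False, pop_ids=tuple(pop_ids))
    if not return_se:
        return sfs
    var = np.maximum(lsq / nreps - mean ** 2, 0.0)
    se = np.sqrt(var / nreps) / 2.0
    se[sfs.mask] = 0.0
    return sfs, se


def expected_jsfs(model: DemographicModel, p: ParamSet, n1: int, n2: int,
                  nreps: int = 50_000, seed: int = 0,
                  return_se: bool = False):
    """Expected joint SFS (theta = 1 scale) for a model and parameter set."""
    schedule = to_epochs(model, p)
    return expected_jsfs_from_schedule(schedule, n1, n2, nreps=nreps,
                                       seed=seed, return_se=return_se)


def simulate_dataset(model: DemographicModel, p: ParamSet, n_loci: int,
                     individuals_per_pop, theta_per_locus: float,
                     seed: int = 0, locus_length: int = 150) -> GenotypeMatrix:
    """Simulate a multi-locus biallelic SNP dataset under a demography.

    One independent genealogy per RAD locus; mutations fall on branches as a
    Poisson process with mean ``theta_per_locus * L_total / 2`` under
    infinite sites, each creating one biallelic SNP whose carriers are the
    leaves under the mutated branch.  Haplotypes are paired sequentially into
    diploid individuals (pop-1 individuals first).  Loci with no mutation
    emit nothing; loci with several SNPs emit all of them, so a downstream
    one-SNP-per-locus filter sees realistic input.  Depths are left unknown.
    """
    ind1, ind2 = individuals_per_pop
    n1, n2 = 2 * ind1, 2 * ind2
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if n1 + n2 > 64:
        raise ValueError("at most 64 haplotypes supported")
    if theta_per_locus < 0:
        raise ValueError("theta_per_locus must be >= 0")

    schedule = to_epochs(model, p)
    dur, g0, beta, mig = schedule_arrays(schedule)
    rng = np.random.default_rng(seed)
    individuals = ([f"p1_{i:03d}" for i in range(ind1)]
                   + [f"p2_{i:03d}" for i in range(ind2)])

    loci, positions, refs, alts, rows = [], [], [], [], []
    width = max(4, len(str(n_loci)))
    bases = ("A", "C", "G", "T")
    for li in range(n_loci):
        segs = _class_lengths_python(n1, n2, dur, g0, beta, mig, rng,
                                     track_leaves=True)
        lengths = np.array([s[3] for s in segs])
        l_total = lengths.sum()
        n_mut = rng.poisson(theta_per_locus * l_total / 2.0) if l_total > 0 else 0
        if n_mut == 0:
            continue
        chosen = rng.choice(len(segs), size=n_mut, p=lengths / l_total)
        pos = rng.choice(np.arange(1, locus_length + 1),
                         size=min(n_mut, locus_length), replace=False)
        pos.sort()
        name = f"locus_{li:0{width}d}"
        for snp, seg_idx in enumerate(chosen[: len(pos)]):
            leafset = segs[int(seg_idx)][0]
            hap = np.array([(leafset >> h) & 1 for h in range(n1 + n2)],
                           dtype=np.int8)
            dosage = hap[0::2] + hap[1::2]
            loci.append(name)
            positions.append(int(pos[snp]))
            ref, alt = rng.choice(4, size=2, replace=False)
            refs.append(bases[ref])
            alts.append(bases[alt])
            rows.append(dosage)

    if rows:
        genotypes = np.vstack(rows).astype(np.int8)
    else:
        genotypes = np.zeros((0, ind1 + ind2), dtype=np.int8)
    depths = np.full_like(genotypes, DEPTH_UNKNOWN, dtype=np.int32)
    return GenotypeMatrix(np.array(loci, dtype=object),
                          np.array(positions, dtype=np.int64),
                          np.array(refs, dtype=object),
                          np.array(alts, dtype=object),
                          genotypes, depths, individuals)
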