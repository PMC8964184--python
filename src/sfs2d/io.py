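"""File formats: VCF, population maps, flat SFS text, result tables.

The flat SFS dialect is the three-line text format used by diffusion-based
SFS software: a header line ``"(n1+1) (n2+1) [folded|unfolded] "pop1"
"pop2""``, a line of row-major entries, and a line of row-major mask flags
(1 = masked).
"""

from __future__ import annotations

import logging
import sys

import numpy as np
from cyvcf2 import VCF

from .containers import DEPTH_UNKNOWN, MISSING, GenotypeMatrix, JointSFS, PopMap

logger = logging.getLogger(__name__)

__all__ = [
    "read_popmap", "write_popmap", "read_vcf", "write_vcf",
    "read_sfs_file", "write_sfs_file", "write_fit_table", "setup_logging",
]

_BASES = {"A", "C", "G", "T"}


def setup_logging(level="INFO"):
    """Route package logging to stderr at the given level."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("sfs2d")
    root.handlers[:] = [handler]
    root.setLevel(level)


def read_popmap(path) -> PopMap:
    """Two-column TSV (individual, population), no header."""
    entries = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            ind, pop = parts
            if ind in entries:
                raise ValueError(f"{path}:{lineno}: duplicate individual {ind!r}")
            entries[ind] = pop
    return PopMap(entries)


def write_popmap(popmap: PopMap, path) -> None:
    with open(path, "w") as fh:
        for ind, pop in popmap.entries.items():
            fh.write(f"{ind}\t{pop}\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic SNP records from a VCF into a genotype matrix.

    Non-biallelic or non-SNP records are skipped.  Genotypes become
    alternate-allele dosage {0, 1, 2} (missing = no call); per-genotype
    depth comes from the DP FORMAT field when present, else is marked
    unknown.  The CHROM string is the RAD-locus identifier; POS stays
    1-based.
    """
    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    loci, pos, ref, alt, geno, depth = [], [], [], [], [], []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or v.REF not in _BASES or v.ALT[0] not in _BASES:
            n_skipped += 1
            continue
        gt = v.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        dosage = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2],
                           default=MISSING).astype(np.int8)
        dp = v.format("DP")
        if dp is None:
            d = np.full(len(individuals), DEPTH_UNKNOWN, dtype=np.int32)
        else:
            d = dp.reshape(-1).astype(np.int64)
            d = np.where(d < 0, DEPTH_UNKNOWN, d).astype(np.int32)
        loci.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        geno.append(dosage)
        depth.append(d)
    vcf.close()
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)
    if geno:
        genotypes = np.vstack(geno)
        depths = np.vstack(depth)
    else:
        genotypes = np.zeros((0, len(individuals)), dtype=np.int8)
        depths = np.zeros((0, len(individuals)), dtype=np.int32)
    return GenotypeMatrix(np.array(loci, dtype=object),
                          np.array(pos, dtype=np.int64),
                          np.array(ref, dtype=object),
                          np.array(alt, dtype=object),
                          genotypes, depths, individuals)


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a genotype matrix as an uncompressed VCF v4.2 text file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sfs2d\n")
        for contig in dict.fromkeys(gm.locus):
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.individuals) + "\n")
        for i in range(gm.n_sites):
            cells = []
            for g, d in zip(gm.genotypes[i], gm.depths[i]):
                dp = "." if d == DEPTH_UNKNOWN else str(int(d))
                cells.append(f"{_GT_STR[int(g)]}:{dp}")
            fh.write(f"{gm.locus[i]}\t{gm.pos[i]}\t.\t{gm.ref[i]}\t{gm.alt[i]}"
                     f"\t.\t.\t.\tGT:DP\t" + "\t".join(cells) + "\n")


def write_sfs_file(sfs: JointSFS, path) -> None:
    """Write a spectrum in the flat three-line SFS text dialect."""
    with open(path, "w") as fh:
        fold = "folded" if sfs.folded else "unfolded"
        fh.write(f'{sfs.n1 + 1} {sfs.n2 + 1} {fold} '
                 f'"{sfs.pop_ids[0]}" "{sfs.pop_ids[1]}"\n')
        fh.write(" ".join(repr(float(x)) for x in sfs.counts.ravel()) + "\n")
        fh.write(" ".join("1" if m else "0" for m in sfs.mask.ravel()) + "\n")


def read_sfs_file(path) -> JointSFS:
    """Inverse of :func:`write_sfs_file` (exact round-trip)."""
    with open(path) as fh:
        lines = [ln for ln in (l.strip() for l in fh) if ln]
    if len(lines) < 3:
        raise ValueError(f"{path}: expected 3 lines, got {len(lines)}")
    head = lines[0].split()
    if len(head) < 3:
        raise ValueError(f"{path}: malformed header line")
    d1, d2 = int(head[0]), int(head[1])
    fold_tag = head[2]
    if fold_tag not in ("folded", "unfolded"):
        raise ValueError(f"{path}: fold state must be folded|unfolded")
    pops = [p.strip('"') for p in head[3:5]] or ["pop1", "pop2"]
    while len(pops) < 2:
        pops.append(f"pop{len(pops) + 1}")
    vals = np.array([float(x) for x in lines[1].split()])
    mask = np.array([bool(int(x)) for x in lines[2].split()])
    if vals.size != d1 * d2 or mask.size != d1 * d2:
        raise ValueError(
            f"{path}: expected {d1 * d2} entries, got {vals.size} values "
            f"and {mask.size} mask flags")
    return JointSFS(vals.reshape(d1, d2), folded=(fold_tag == "folded"),
                    mask=mask.reshape(d1, d2), pop_ids=tuple(pops))


_PARAM_COLS = ("nuA", "nu1", "nu2", "T", "T1", "T2", "s", "m12", "m21")


def write_fit_table(cmp, path) -> None:
    """Tab-separated model-comparison table, best model (lowest AIC) first.

    Columns: model, log-likelihood, k, AIC, delta_AIC, akaike_weight, theta,
    then one column per free parameter; parameters absent from a model are
    left blank.
    """
    if not cmp.results:
        raise ValueError("empty model comparison")
    with open(path, "w") as fh:
        fh.write("model\tlog_likelihood\tk\tAIC\tdelta_AIC\takaike_weight"
                 "\ttheta\t" + "\t".join(_PARAM_COLS) + "\n")
        for fit, d, w in zip(cmp.results, cmp.delta_aic, cmp.weights):
            row = [fit.model, f"{fit.loglik:.4f}", str(fit.k),
                   f"{fit.aic:.4f}", f"{d:.4f}", f"{w:.4f}",
                   f"{fit.theta_hat:.4f}"]
            pd = fit.params.as_dict()
            for col in _PARAM_COLS:
                row.append(f"{pd[col]:.6g}" if col in pd else "")
            fh.write("\t".join(row) + "\n")
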