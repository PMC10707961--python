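"""Genotype containers and I/O for nuclear and plastome SNP data.

The central container is :class:`GenotypeMatrix`, a samples x sites
allele-dosage matrix (0/1/2 for diploids, 0/1 for haploids, -1 = missing)
with per-site chromosome/position metadata and a sample -> population map.
Haploid plastome data, once filtered and concatenated, live in
:class:`HaplotypeAlignment`.

VCF parsing is delegated to :mod:`pysam`; writing uses a minimal VCF 4.2
text emitter so that synthetic data round-trip through standard tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pysam

logger = logging.getLogger(__name__)

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Samples x sites allele-dosage matrix.

    Attributes
    ----------
    sample_ids : list of str
    pop_labels : dict mapping each sample id to a population/taxon label
    chrom : (n_sites,) array of chromosome labels
    pos : (n_sites,) int array of 1-based coordinates, strictly increasing
        within each chromosome
    dosage : (n_samples, n_sites) int8 array of alternate-allele dosages;
        ``-1`` marks a missing genotype
    ploidy : 1 or 2
    depth : optional (n_sites,) array of mean read depth per site
    """

    sample_ids: list[str]
    pop_labels: dict[str, str]
    chrom: np.ndarray
    pos: np.ndarray
    dosage: np.ndarray
    ploidy: int = 2
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.sample_ids), len(self.pos)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.pos)} sites"
            )
        valid = self.dosage[self.dosage != MISSING]
        if valid.size and (valid.min() < 0 or valid.max() > self.ploidy):
            raise ValueError("dosage outside [0, ploidy] at a non-missing entry")
        missing_pop = [s for s in self.sample_ids if s not in self.pop_labels]
        if missing_pop:
            raise ValueError(f"samples without population label: {missing_pop}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset sites (order-preserving); samples unchanged."""
        index = np.asarray(index)
        return replace(
            self,
            chrom=self.chrom[index],
            pos=self.pos[index],
            dosage=self.dosage[:, index],
            depth=None if self.depth is None else self.depth[index],
        )

    def samples_in(self, label: str) -> list[int]:
        """Row indices of samples carrying a population label."""
        return [i for i, s in enumerate(self.sample_ids) if self.pop_labels[s] == label]

    def check_sorted(self) -> None:
        """Raise if positions are not strictly increasing within chromosomes."""
        for c in dict.fromkeys(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")


@dataclass
class HaplotypeAlignment:
    """Equal-length haploid sequences (0/1 SNP states or nucleotides).

    ``total_locus_length`` (m_T) is the number of base pairs represented by
    the concatenated loci the columns were drawn from; it is always at least
    the number of variable columns and enters the mutational-time conversion
    of the mismatch analysis.
    """

    sample_ids: list[str]
    sequences: list[str]
    total_locus_length: int

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("sequences differ in length")
        if self.sequences and self.total_locus_length < len(self.sequences[0]):
            raise ValueError("total_locus_length smaller than alignment width")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def to_array(self) -> np.ndarray:
        """(n_samples, n_columns) array of single-character states."""
        return np.array([list(s) for s in self.sequences])

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, seq in zip(self.sample_ids, self.sequences):
                fh.write(f">{sid}\n{seq}\n")


def read_pop_map(path) -> dict[str, str]:
    """Read a 2-column TSV (sample, population/taxon)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed pop-map line: {line!r}")
            out[parts[0]] = parts[1]
    return out


def read_bed(path) -> dict[str, list[tuple[int, int]]]:
    """Read BED intervals as half-open [start, end) with 0-based starts.

    Intervals are validated (start < end) and returned per chromosome,
    sorted; overlapping intervals are merged.
    """
    raw: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            c, s, e = line.split("\t")[:3]
            s, e = int(s), int(e)
            if s >= e:
                raise ValueError(f"malformed BED interval {c}:{s}-{e}")
            raw.setdefault(c, []).append((s, e))
    merged: dict[str, list[tuple[int, int]]] = {}
    for c, ivals in raw.items():
        ivals.sort()
        acc = [list(ivals[0])]
        for s, e in ivals[1:]:
            if s <= acc[-1][1]:
                acc[-1][1] = max(acc[-1][1], e)
            else:
                acc.append([s, e])
        merged[c] = [tuple(x) for x in acc]
    return merged


def read_genotypes(vcf_path, pop_map: dict[str, str], ploidy: int = 2) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Multiallelic records are dropped (count logged).  Missing GT calls map
    to missing dosage.  Every VCF sample must appear in ``pop_map``; in
    diploid mode a non-diploid GT is an error.
    """
    vf = pysam.VariantFile(str(vcf_path))
    samples = list(vf.header.samples)
    for s in samples:
        if s not in pop_map:
            raise ValueError(f"sample {s!r} in VCF but absent from population map")

    chroms, poss, depths, cols = [], [], [], []
    n_multi = 0
    has_depth = False
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            n_multi += 1
            continue
        col = np.empty(len(samples), dtype=np.int8)
        for i, s in enumerate(samples):
            gt = rec.samples[s].get("GT")
            if gt is None or all(a is None for a in gt):
                col[i] = MISSING
                continue
            if ploidy == 2 and len(gt) != 2:
                raise ValueError(
                    f"non-diploid GT for sample {s} at {rec.chrom}:{rec.pos}"
                )
            alleles = [a for a in gt if a is not None]
            if len(alleles) < len(gt):
                col[i] = MISSING
            else:
                col[i] = sum(1 for a in alleles if a > 0)
        chroms.append(rec.chrom)
        poss.append(rec.pos)
        try:
            dp = rec.info.get("DP")
        except (KeyError, ValueError):  # DP absent from the header
            dp = None
        if dp is not None:
            has_depth = True
        depths.append(np.nan if dp is None else float(dp))
        cols.append(col)
    vf.close()
    if n_multi:
        logger.info("dropped %d multiallelic record(s)", n_multi)

    dosage = (
        np.column_stack(cols) if cols else np.empty((len(samples), 0), dtype=np.int8)
    )
    gm = GenotypeMatrix(
        sample_ids=samples,
        pop_labels={s: pop_map[s] for s in samples},
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        dosage=dosage,
        ploidy=ploidy,
        depth=np.array(depths) if has_depth else None,
    )
    gm.n_multiallelic_dropped = n_multi  # type: ignore[attr-defined]
    return gm


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF 4.2 text file.

    REF/ALT are written as A/T placeholders; dosage is the only payload
    the pipeline round-trips.
    """
    sep = "/" if gm.ploidy == 2 else ""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Float,Description="Mean depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in dict.fromkeys(gm.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for j in range(gm.n_sites):
            info = "." if gm.depth is None else f"DP={gm.depth[j]:g}"
            gts = []
            for i in range(gm.n_samples):
                d = int(gm.dosage[i, j])
                if d == MISSING:
                    gts.append(sep.join(["."] * gm.ploidy))
                elif gm.ploidy == 1:
                    gts.append(str(d))
                else:
                    gts.append(["0/0", "0/1", "1/1"][d])
            fh.write(
                f"{gm.chrom[j]}\t{gm.pos[j]}\t.\tA\tT\t.\tPASS\t{info}\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def write_pop_map(pop_labels: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for s, p in pop_labels.items():
            fh.write(f"{s}\t{p}\n")
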