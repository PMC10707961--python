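"""Synthetic dataset generators mirroring the study's three data shapes.

The real genotype data are not redistributable, so every analysis here
runs against coalescent-simulated stand-ins with the same shapes and the
statistical structure of the fitted demographic models:

* ``ficifolia-2524`` — 28 diploid crop accessions x 2,524 unlinked
  nuclear SNPs, simulated under the best-fit two-change history
  (expansion then recent bottleneck: N_anc2 = 215,232 -> N_anc1 =
  359,555 at 123,660 generations, -> N_curr = 43,229 at 2,409
  generations) with a genotype-level inbreeding coefficient f = 0.23
  matching the observed heterozygote deficit.
* ``five-taxa-6292`` — 142 diploids of the crop and four wild relatives
  plus 11 outgroup individuals x 6,292 SNPs, on the topology
  (((foetidissima, scabridifolia, pedatifolia), radicans), ficifolia)
  with split times scaled to desk scale (1/100 of the published
  divergence dates) and low recent crop-wild migration
  (1.1e-4 with radicans, 6.1e-6 with pedatifolia).
* ``plastome-440`` — 36 haploid plastome sequences, 440 SNP columns over
  a 44,143 bp concatenated-locus coordinate space, simulated under a
  sudden maternal-lineage expansion whose age is chosen so the locus
  clock expects ~440 segregating sites (see
  :func:`plastome_expansion_model`), with a BED file marking coding
  regions (about 240 of the 440 sites) so that the non-coding subset
  matches the mismatch analysis input.

All outputs are plain text (VCF, FASTA, TSV, BED) and bit-identical for
a given seed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .coalescent import (
    DemographicModel,
    Migration,
    SizeChange,
    Split,
    simulate_sequences,
    simulate_snp_matrix,
)
from .genotypes import GenotypeMatrix, write_pop_map, write_vcf

FIXTURE_NAMES = ("ficifolia-2524", "five-taxa-6292", "plastome-440")

# best-fit crop history (generations / diploid sizes)
FICIFOLIA_TWO_CHANGE = dict(
    n_curr=43_229.0, n_anc1=359_555.0, n_anc2=215_232.0, t1=2_409.0, t2=123_660.0
)
FICIFOLIA_INBREEDING_F = 0.23

MEXICAN_STATES = (
    "Michoacan", "Jalisco", "Puebla", "Chiapas", "EdoMex", "Oaxaca", "Tlaxcala",
)

PLASTOME_M_T = 44_143
PLASTOME_MU_PER_SITE_PER_YEAR = 0.0061e-6  # non-coding plastome, lower bound


def ficifolia_model(scale: float = 1.0) -> DemographicModel:
    """The fitted two-change crop history; ``scale`` shrinks sizes and
    times jointly (scale-invariant SFS shape) for desk-scale runs."""
    p = FICIFOLIA_TWO_CHANGE
    return DemographicModel(
        {"ficifolia": p["n_curr"] * scale},
        size_changes=[
            SizeChange(p["t1"] * scale, "ficifolia", p["n_anc1"] * scale),
            SizeChange(p["t2"] * scale, "ficifolia", p["n_anc2"] * scale),
        ],
    )


def five_taxa_model(
    m_radicans: float = 1.1e-4,
    m_pedatifolia: float = 6.1e-6,
    migration_window: float = 2_409.0,
) -> DemographicModel:
    """Desk-scale five-taxon model: published divergence dates scaled
    1/100 (wild-group trichotomy 8,000; radicans 13,400; crop 84,400;
    outgroup 120,000 generations), N = 20,000 everywhere, and
    bidirectional crop-wild migration restricted to the recent
    ``migration_window`` generations (the era of crop cultivation)."""
    n = 20_000.0
    sizes = {
        d: n
        for d in (
            "ficifolia", "radicans", "pedatifolia", "foetidissima",
            "scabridifolia", "cordata", "anc_fsp", "anc_wild", "anc_all", "root",
        )
    }
    migrations = []
    for partner, rate in (("radicans", m_radicans), ("pedatifolia", m_pedatifolia)):
        if rate > 0:
            migrations += [
                Migration("ficifolia", partner, rate, end_time=migration_window),
                Migration(partner, "ficifolia", rate, end_time=migration_window),
            ]
    return DemographicModel(
        sizes,
        splits=[
            Split(8_000.0, ["foetidissima", "scabridifolia", "pedatifolia"], "anc_fsp"),
            Split(13_400.0, ["anc_fsp", "radicans"], "anc_wild"),
            Split(84_400.0, ["anc_wild", "ficifolia"], "anc_all"),
            Split(120_000.0, ["anc_all", "cordata"], "root"),
        ],
        migrations=migrations,
    )


FIVE_TAXA_SAMPLES = {  # haploid counts (diploids x 2)
    "ficifolia": 56,
    "radicans": 88,
    "pedatifolia": 68,
    "foetidissima": 34,
    "scabridifolia": 38,
    "cordata": 22,
}


def plastome_expansion_model() -> DemographicModel:
    """Sudden maternal-lineage expansion: haploid size 200 -> 5,000,000
    at 45,000 generations ago.

    The expansion age is set so that the locus clock is self-consistent
    with the fixture's 440 segregating columns: with u = m_T * mu =
    44,143 bp * 6.1e-9 /site/generation, a 36-tip star-like genealogy of
    this depth carries ~440 expected mutations, and the fixture's own
    tau (= 2 u t ~ 24) converts back to ~45,000 years.  A shallower
    expansion cannot produce 440 segregating sites among 36 crop
    haplotypes: 440 polymorphic columns force a mean pairwise difference
    of at least ~2 S / n ~ 24."""
    return DemographicModel(
        {"ficifolia": 5_000_000.0},
        size_changes=[SizeChange(45_000.0, "ficifolia", 200.0)],
        ploidy=1,
    )


def make_ficifolia_fixture(out_dir, seed: int) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gm = simulate_snp_matrix(
        ficifolia_model(),
        {"ficifolia": 56},
        n_snps=2_524,
        seed=seed,
        inbreeding_f=FICIFOLIA_INBREEDING_F,
        n_chroms=20,
        spacing_bp=1_000,
        sample_prefix="fic",
    )
    # assign accessions to states round-robin for among-state statistics
    rng = np.random.default_rng(seed)
    states = {
        s: MEXICAN_STATES[i % len(MEXICAN_STATES)]
        for i, s in enumerate(gm.sample_ids)
    }
    gm.pop_labels = states
    vcf = out_dir / "ficifolia_2524.vcf"
    popmap = out_dir / "ficifolia_popmap.tsv"
    write_vcf(gm, vcf)
    write_pop_map(states, popmap)
    return {"vcf": vcf, "pop_map": popmap}


def make_five_taxa_fixture(out_dir, seed: int, n_snps: int = 6_292) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gm = simulate_snp_matrix(
        five_taxa_model(),
        FIVE_TAXA_SAMPLES,
        n_snps=n_snps,
        seed=seed,
        n_chroms=20,
        spacing_bp=1_000,
        sample_prefix="cuc",
    )
    vcf = out_dir / "five_taxa_6292.vcf"
    popmap = out_dir / "five_taxa_popmap.tsv"
    write_vcf(gm, vcf)
    write_pop_map(gm.pop_labels, popmap)
    return {"vcf": vcf, "pop_map": popmap}


def make_plastome_fixture(out_dir, seed: int) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_sites = 440
    aln = simulate_sequences(
        plastome_expansion_model(),
        {"ficifolia": 36},
        seq_len=PLASTOME_M_T,
        mu=0.0,  # conditioned on the observed number of segregating sites
        seed=seed,
        fixed_s=n_sites,
        sample_prefix="fic_hap",
    )
    rng = np.random.default_rng(seed + 1)
    positions = np.sort(rng.choice(PLASTOME_M_T, size=n_sites, replace=False)) + 1
    # order alignment columns by position
    order = rng.permutation(n_sites)
    arr = aln.to_array()[:, order]
    seqs = ["".join(row) for row in arr]
    aln.sequences = seqs
    aln.total_locus_length = PLASTOME_M_T

    dosage = np.array([[int(c) for c in s] for s in seqs], dtype=np.int8)
    depth = np.round(rng.gamma(3.0, 78.0 / 3.0, size=n_sites), 1)
    gm = GenotypeMatrix(
        sample_ids=list(aln.sample_ids),
        pop_labels={s: "ficifolia" for s in aln.sample_ids},
        chrom=np.array(["plastome"] * n_sites, dtype=object),
        pos=positions,
        dosage=dosage,
        ploidy=1,
        depth=depth,
    )
    # coding BED: one interval holding ~240 of the 440 sites
    cutoff = int(positions[239]) if n_sites >= 240 else int(positions[-1])
    fasta = out_dir / "plastome_440.fasta"
    vcf = out_dir / "plastome_440.vcf"
    bed = out_dir / "plastome_coding.bed"
    popmap = out_dir / "plastome_popmap.tsv"
    aln.write_fasta(fasta)
    write_vcf(gm, vcf)
    with open(bed, "w") as fh:
        fh.write(f"plastome\t0\t{cutoff}\n")
    write_pop_map(gm.pop_labels, popmap)
    return {"fasta": fasta, "vcf": vcf, "bed": bed, "pop_map": popmap}


def make_fixtures(name: str, out_dir, seed: int) -> dict[str, Path]:
    """Write the named fixture file set; deterministic given the seed."""
    if name == "ficifolia-2524":
        return make_ficifolia_fixture(out_dir, seed)
    if name == "five-taxa-6292":
        return make_five_taxa_fixture(out_dir, seed)
    if name == "plastome-440":
        return make_plastome_fixture(out_dir, seed)
    raise ValueError(f"unknown fixture {name!r}; options: {', '.join(FIXTURE_NAMES)}")
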