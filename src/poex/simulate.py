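"""Synthetic hybrid-seed transcriptome generator.

Emulates the data-generating process the analysis assumes, so every stage of
the pipeline can be exercised against a known truth table:

* two parental transcriptomes with configurable fixed divergence (~0.5%
  between accessions of the selfing species, ~5% between species) and
  heterozygosity in the outcrossing parent;
* whole-seed RNA mixtures: maternal sporophyte (all-maternal), endosperm
  (2 maternal : 1 paternal genome dose), embryo (1:1);
* per-gene imprinting classes — MEG (fully maternal in endosperm), PEG
  (mostly paternal), biparental (the 2:1 genomic dose), and PEGs that revert
  to maternal expression in the interspecific hybrid;
* reference-mapping bias, calibrated so a true 50:50 allele mix shows a
  configurable observed reference fraction (~60% in the allopolyploid
  control);
* read-depth sampling (negative binomial across genes) and per-base
  sequencing error.

Coverage model: each simulated read is assigned a parent (and, for the
heterozygous parent, a haplotype) once and observes every position of its
transcript.  Per-position counts within a gene therefore describe the *same*
set of reads, which is what makes the downstream per-gene statistic — mean
percent SNP with mean coverage as the effective count — correctly calibrated.
Haplotypes of a heterozygous parent split a gene's reads as evenly as integer
counts allow (floor/ceil), an idealised 50:50 allelic balance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UsageError

BASES = np.array(list("ACGT"))
IMPRINT_CLASSES = ("MEG", "PEG", "biparental", "reverted_PEG")


def _negative_binomial(rng: np.random.Generator, mean: float, sd: float, size) -> np.ndarray:
    """Depth sampler: negative binomial when overdispersed, Poisson otherwise."""
    if mean <= 0:
        raise UsageError("depth mean must be positive")
    var = sd * sd
    if var <= mean:
        return rng.poisson(mean, size)
    r = mean * mean / (var - mean)
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size)


# ---------------------------------------------------------------------------
# models


@dataclass(frozen=True)
class GenomeModel:
    """Parameters of a parental genome pair relative to one cDNA reference.

    ``divergence_rate`` is the per-site probability of a fixed difference
    between the two parents; ``heterozygosity_rate`` the per-site probability
    that the outcrossing (non-reference) parent is heterozygous;
    ``reference_parent_snp_rate`` plants sites where the reference-matched
    parent itself deviates from the reference (the self-SNP class that must be
    removed from the diagnostic set).  ``reference_seed`` lets several
    genotypes share one reference sequence; it defaults to ``seed``.
    """

    n_genes: int = 200
    gene_length: int = 1000
    divergence_rate: float = 0.05
    heterozygosity_rate: float = 0.0
    reference_parent_snp_rate: float = 0.0
    reference_parent: str = "maternal"
    seed: int = 0
    reference_seed: int | None = None

    def __post_init__(self):
        if self.n_genes < 1 or self.gene_length < 1:
            raise UsageError("GenomeModel requires n_genes >= 1 and gene_length >= 1")
        for rate in (self.divergence_rate, self.heterozygosity_rate, self.reference_parent_snp_rate):
            if not 0.0 <= rate <= 1.0:
                raise UsageError("rates must lie in [0, 1]")
        if self.reference_parent not in ("maternal", "paternal"):
            raise UsageError("reference_parent must be 'maternal' or 'paternal'")


class SyntheticGenome:
    """Realised reference + divergent-genotype sequences for a :class:`GenomeModel`.

    Bit-reproducible: identical seeds give identical genomes.
    """

    def __init__(self, model: GenomeModel):
        self.model = model
        n, L = model.n_genes, model.gene_length
        ref_seed = model.seed if model.reference_seed is None else model.reference_seed
        ref_rng = np.random.default_rng([int(ref_seed), 101])
        self.ref = ref_rng.integers(0, 4, size=(n, L), dtype=np.int8)
        rng = np.random.default_rng([int(model.seed), 102])
        self.div_mask = rng.random((n, L)) < model.divergence_rate
        offsets = rng.integers(1, 4, size=(n, L), dtype=np.int8)
        self.alt = ((self.ref + offsets) % 4).astype(np.int8)
        self.het_mask = (~self.div_mask) & (rng.random((n, L)) < model.heterozygosity_rate)
        het_offsets = rng.integers(1, 4, size=(n, L), dtype=np.int8)
        self.het_alt = ((self.ref + het_offsets) % 4).astype(np.int8)
        self.refparent_mask = (
            (~self.div_mask)
            & (~self.het_mask)
            & (rng.random((n, L)) < model.reference_parent_snp_rate)
        )
        refp_offsets = rng.integers(1, 4, size=(n, L), dtype=np.int8)
        self.refparent_alt = ((self.ref + refp_offsets) % 4).astype(np.int8)
        self.gene_ids = [f"g{i + 1:05d}" for i in range(n)]

    # -- base arrays -------------------------------------------------------
    def reference_parent_bases(self) -> np.ndarray:
        """Bases carried by the reference-matched parent (incl. its self-SNPs)."""
        return np.where(self.refparent_mask, self.refparent_alt, self.ref).astype(np.int8)

    def divergent_parent_haplotypes(self) -> tuple[np.ndarray, np.ndarray]:
        """The outcrossing parent's two haplotypes (differ at het sites only)."""
        hap1 = np.where(self.div_mask, self.alt, self.ref).astype(np.int8)
        hap2 = np.where(self.het_mask, self.het_alt, hap1).astype(np.int8)
        return hap1, hap2

    # -- truth frames ------------------------------------------------------
    def _sites_frame(self, mask: np.ndarray, base: np.ndarray, parent: str) -> pd.DataFrame:
        gi, pi = np.nonzero(mask)
        return pd.DataFrame(
            {
                "gene_id": np.asarray(self.gene_ids, dtype=object)[gi],
                "pos": pi + 1,
                "parent": parent,
                "snp_base": BASES[base[gi, pi]],
            }
        )

    def truth_snps(self) -> pd.DataFrame:
        """Every planted fixed difference carried by the non-reference parent."""
        parent = "paternal" if self.model.reference_parent == "maternal" else "maternal"
        return self._sites_frame(self.div_mask, self.alt, parent)

    def truth_reference_parent_snps(self) -> pd.DataFrame:
        return self._sites_frame(self.refparent_mask, self.refparent_alt, self.model.reference_parent)

    def truth_het_sites(self) -> pd.DataFrame:
        parent = "paternal" if self.model.reference_parent == "maternal" else "maternal"
        return self._sites_frame(self.het_mask, self.het_alt, parent)

    def reference_bases(self) -> pd.DataFrame:
        """Long-format (gene_id, pos, ref_base) map for every position."""
        n, L = self.ref.shape
        return pd.DataFrame(
            {
                "gene_id": np.repeat(np.asarray(self.gene_ids, dtype=object), L),
                "pos": np.tile(np.arange(1, L + 1), n),
                "ref_base": BASES[self.ref.ravel()],
            }
        )


@dataclass(frozen=True)
class SeedMixtureModel:
    """RNA composition of a whole-seed sample.

    Fractions are of total mRNA; doses are the maternal share of transcripts
    within the compartment for a biparentally expressed gene (endosperm 2/3
    from the 2m:1p genome ratio, embryo 1/2).  The whole-seed default
    (0.5 / 0.4 / 0.1) is a stated, configurable assumption — the maternal
    sporophyte fraction at 3 days after pollination is not measured.
    """

    f_maternal_tissue: float = 0.5
    f_endosperm: float = 0.4
    f_embryo: float = 0.1
    endosperm_maternal_dose: float = 2.0 / 3.0
    embryo_maternal_dose: float = 0.5

    def __post_init__(self):
        total = self.f_maternal_tissue + self.f_endosperm + self.f_embryo
        if abs(total - 1.0) > 1e-9:
            raise UsageError("mixture fractions must sum to 1")
        for v in (
            self.f_maternal_tissue,
            self.f_endosperm,
            self.f_embryo,
            self.endosperm_maternal_dose,
            self.embryo_maternal_dose,
        ):
            if not 0.0 <= v <= 1.0:
                raise UsageError("mixture fractions and doses must lie in [0, 1]")


ENDOSPERM_ONLY = SeedMixtureModel(f_maternal_tissue=0.0, f_endosperm=1.0, f_embryo=0.0)
#: A 1:1 allele mix with no maternal-tissue or endosperm dosage (leaf/genomic-DNA-like
#: control used to calibrate mapping bias).
EVEN_MIX = SeedMixtureModel(f_maternal_tissue=0.0, f_endosperm=0.0, f_embryo=1.0)


@dataclass
class ImprintingSpec:
    """Per-gene imprinting class and expression level.

    Maternal dose within the endosperm by class: MEG -> 1.0, biparental ->
    2/3, PEG -> ``peg_maternal_dose`` (default 0.1, i.e. 90% paternal), and
    reverted_PEG -> PEG-like in the intraspecific ``control`` design but fully
    maternal (1.0) in the interspecific ``hybrid`` design.
    """

    classes: pd.Series  # index gene_id -> class
    peg_maternal_dose: float = 0.1
    expression: pd.Series | None = None  # positive multiplier of depth_mean

    def __post_init__(self):
        bad = set(self.classes.unique()) - set(IMPRINT_CLASSES)
        if bad:
            raise UsageError(f"unknown imprinting classes: {sorted(bad)}")
        if not 0.0 <= self.peg_maternal_dose <= 1.0:
            raise UsageError("peg_maternal_dose must lie in [0, 1]")
        if self.expression is None:
            self.expression = pd.Series(1.0, index=self.classes.index)
        if (self.expression <= 0).any():
            raise UsageError("expression levels must be positive")

    @classmethod
    def random(
        cls,
        gene_ids: list[str],
        meg_fraction: float = 0.10,
        peg_fraction: float = 0.05,
        reverted_fraction: float = 0.0,
        peg_maternal_dose: float = 0.1,
        seed: int = 0,
    ) -> "ImprintingSpec":
        rng = np.random.default_rng([int(seed), 103])
        n = len(gene_ids)
        n_meg = int(round(meg_fraction * n))
        n_peg = int(round(peg_fraction * n))
        n_rev = int(round(reverted_fraction * n))
        if n_meg + n_peg + n_rev > n:
            raise UsageError("class fractions exceed 1")
        order = rng.permutation(n)
        classes = np.array(["biparental"] * n, dtype=object)
        classes[order[:n_meg]] = "MEG"
        classes[order[n_meg : n_meg + n_peg]] = "PEG"
        classes[order[n_meg + n_peg : n_meg + n_peg + n_rev]] = "reverted_PEG"
        return cls(
            classes=pd.Series(classes, index=pd.Index(gene_ids, name="gene_id")),
            peg_maternal_dose=peg_maternal_dose,
        )

    def endosperm_dose(self, design: str = "hybrid") -> pd.Series:
        """Maternal transcript dose within endosperm per gene for a cross design."""
        if design not in ("control", "hybrid"):
            raise UsageError("design must be 'control' or 'hybrid'")
        dose_map = {
            "MEG": 1.0,
            "biparental": 2.0 / 3.0,
            "PEG": self.peg_maternal_dose,
            "reverted_PEG": self.peg_maternal_dose if design == "control" else 1.0,
        }
        return self.classes.map(dose_map).astype(float)


@dataclass(frozen=True)
class BiasModel:
    """Reference-mapping bias as per-read loss of non-reference-parent reads.

    Parameterised by the observed reference-parent fraction at a true 50:50
    mix; 0.5 means no distortion.  The per-read loss probability q solves
    0.5 / (0.5 + 0.5 (1 - q)) = target, i.e. q = 2 - 1/target.
    """

    reference_fraction_at_even_mix: float = 0.5

    def __post_init__(self):
        if not 0.0 < self.reference_fraction_at_even_mix < 1.0:
            raise UsageError("reference_fraction_at_even_mix must lie in (0, 1)")

    @property
    def loss_probability(self) -> float:
        """Probability that a non-reference-parent read is lost (negative if the
        bias favours the non-reference parent)."""
        t = self.reference_fraction_at_even_mix
        if t >= 0.5:
            return 2.0 - 1.0 / t
        return -(2.0 - 1.0 / (1.0 - t))

    def distort(self, f_ref):
        """Expected observed reference-parent fraction given the true one."""
        f_ref = np.asarray(f_ref, dtype=float)
        q = self.loss_probability
        if q >= 0:
            out = f_ref / (f_ref + (1.0 - f_ref) * (1.0 - q))
        else:
            out = f_ref * (1.0 + q) / (f_ref * (1.0 + q) + (1.0 - f_ref))
        return out if out.ndim else float(out)


NO_BIAS = BiasModel(0.5)


# ---------------------------------------------------------------------------
# emission machinery


def _emit_counts(rng: np.random.Generator, components, error_rate: float) -> np.ndarray:
    """Sum multinomial base draws for (n_reads, base_idx array) components.

    Each read reports the true base with probability 1 - e and a uniformly
    random other base otherwise.
    """
    L = len(components[0][1])
    counts = np.zeros((L, 4), dtype=np.int64)
    e = error_rate
    for n_reads, base_idx in components:
        if n_reads <= 0:
            continue
        pvals = np.full((L, 4), e / 3.0)
        pvals[np.arange(L), base_idx] = 1.0 - e
        counts += rng.multinomial(int(n_reads), pvals)
    return counts


def _assemble_pileup(gene_ids, counts_per_gene, library_id: str):
    from .pileup import PileupTable

    frames = []
    for gid, counts in zip(gene_ids, counts_per_gene):
        depth = counts.sum(axis=1)
        keep = depth > 0
        if not keep.any():
            continue
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": gid,
                    "pos": np.flatnonzero(keep) + 1,
                    "A": counts[keep, 0],
                    "C": counts[keep, 1],
                    "G": counts[keep, 2],
                    "T": counts[keep, 3],
                }
            )
        )
    if frames:
        data = pd.concat(frames, ignore_index=True)
    else:
        data = pd.DataFrame(columns=["gene_id", "pos", "A", "C", "G", "T"])
        data = data.astype({"pos": np.int64, "A": np.int64, "C": np.int64, "G": np.int64, "T": np.int64})
    return PileupTable(library_id=library_id, data=data)


def _split_even(n: int) -> tuple[int, int]:
    """Balanced haplotype split: (ceil(n/2), floor(n/2))."""
    return (n + 1) // 2, n // 2


@dataclass
class ParentSimResult:
    maternal: "object"  # PileupTable
    paternal: "object"
    truth_snps: pd.DataFrame
    truth_reference_parent_snps: pd.DataFrame
    truth_het_sites: pd.DataFrame
    genome: SyntheticGenome


def simulate_parents(
    model_or_genome,
    depth_mean: float = 27.0,
    depth_sd: float = 23.0,
    error_rate: float = 0.005,
    seed: int | None = None,
) -> ParentSimResult:
    """Sequence both parents of a cross against the shared cDNA reference.

    Per-gene read depth is negative binomial (defaults match an empirical
    mean 27 / SD 23 per diagnostic position); the outcrossing parent's reads
    split evenly between its two haplotypes, so heterozygous sites emit ~50:50
    base mixes that the 95% SNP-purity filter must reject.  The returned truth
    tables list every planted fixed difference, reference-parent self-SNP and
    heterozygous site.
    """
    genome = model_or_genome if isinstance(model_or_genome, SyntheticGenome) else SyntheticGenome(model_or_genome)
    model = genome.model
    rng = np.random.default_rng([int(model.seed if seed is None else seed), 104])
    n = model.n_genes
    depths_ref = _negative_binomial(rng, depth_mean, depth_sd, n)
    depths_div = _negative_binomial(rng, depth_mean, depth_sd, n)

    ref_parent_bases = genome.reference_parent_bases()
    hap1, hap2 = genome.divergent_parent_haplotypes()

    ref_counts, div_counts = [], []
    for g in range(n):
        ref_counts.append(_emit_counts(rng, [(depths_ref[g], ref_parent_bases[g])], error_rate))
        n1, n2 = _split_even(int(depths_div[g]))
        div_counts.append(_emit_counts(rng, [(n1, hap1[g]), (n2, hap2[g])], error_rate))

    if model.reference_parent == "maternal":
        maternal = _assemble_pileup(genome.gene_ids, ref_counts, "maternal_parent")
        paternal = _assemble_pileup(genome.gene_ids, div_counts, "paternal_parent")
    else:
        maternal = _assemble_pileup(genome.gene_ids, div_counts, "maternal_parent")
        paternal = _assemble_pileup(genome.gene_ids, ref_counts, "paternal_parent")
    return ParentSimResult(
        maternal=maternal,
        paternal=paternal,
        truth_snps=genome.truth_snps(),
        truth_reference_parent_snps=genome.truth_reference_parent_snps(),
        truth_het_sites=genome.truth_het_sites(),
        genome=genome,
    )


@dataclass
class CrossSimResult:
    pileup: "object"  # PileupTable
    truth: pd.DataFrame  # gene_id, imprint_class, true/expected maternal fraction, n_reads


def simulate_cross(
    genome_or_model,
    imprinting: ImprintingSpec,
    mix: SeedMixtureModel = SeedMixtureModel(),
    bias: BiasModel = NO_BIAS,
    depth_mean: float = 50.0,
    depth_sd: float = 23.0,
    error_rate: float = 0.005,
    design: str = "hybrid",
    seed: int | None = None,
    cross_id: str = "cross",
    other_parent_genome: SyntheticGenome | None = None,
) -> CrossSimResult:
    """Sequence a hybrid seed transcriptome.

    The per-gene expected maternal fraction is the tissue mixture
    ``f_mat * 1 + f_endo * dose_endo(gene) + f_emb * dose_emb`` distorted by
    the mapping-bias model; reads are then assigned a parent binomially at
    that fraction.  The truth table records both the pre-bias mixture
    fraction and the post-bias pre-sampling expectation.

    By default one parent is the reference genotype (which one is set by
    ``genome.model.reference_parent``).  Passing ``other_parent_genome``
    replaces the reference-side parent by a second divergent genotype sharing
    the same reference (e.g. an intraspecific accession mother crossed to the
    outcrossing species); mapping bias then still applies to ``genome``'s
    side, the more divergent one.
    """
    genome = genome_or_model if isinstance(genome_or_model, SyntheticGenome) else SyntheticGenome(genome_or_model)
    model = genome.model
    if design not in ("control", "hybrid"):
        raise UsageError("design must be 'control' or 'hybrid'")
    if list(imprinting.classes.index) != list(genome.gene_ids):
        raise UsageError("imprinting spec gene ids do not match the genome")
    if other_parent_genome is not None and other_parent_genome.ref.shape != genome.ref.shape:
        raise UsageError("other_parent_genome must share the genome's reference layout")
    rng = np.random.default_rng([int(model.seed if seed is None else seed), 105])

    dose = imprinting.endosperm_dose(design).to_numpy()
    f_maternal = (
        mix.f_maternal_tissue * 1.0
        + mix.f_endosperm * dose
        + mix.f_embryo * mix.embryo_maternal_dose
    )
    if model.reference_parent == "maternal":
        f_obs = bias.distort(f_maternal)
    else:
        f_obs = 1.0 - bias.distort(1.0 - f_maternal)

    n = model.n_genes
    expr = imprinting.expression.to_numpy()
    if np.all(expr == expr[0]):
        depths = _negative_binomial(rng, depth_mean * expr[0], depth_sd, n).astype(np.int64)
    else:
        depths = np.array(
            [int(_negative_binomial(rng, depth_mean * expr[g], depth_sd, None)) for g in range(n)],
            dtype=np.int64,
        )
    n_maternal = rng.binomial(depths, f_obs)

    # haplotype sets each parent's reads emit from (one array for an inbred
    # reference parent, two for a divergent genotype with possible het sites)
    genome_haps = genome.divergent_parent_haplotypes()
    if other_parent_genome is not None:
        other_haps = other_parent_genome.divergent_parent_haplotypes()
    else:
        other_haps = (genome.reference_parent_bases(),)
    if model.reference_parent == "maternal":
        mat_haps, pat_haps = other_haps, genome_haps
    else:
        mat_haps, pat_haps = genome_haps, other_haps

    def _components(n_reads: int, haps, g: int):
        if len(haps) == 1:
            return [(n_reads, haps[0][g])]
        n1, n2 = _split_even(n_reads)
        return [(n1, haps[0][g]), (n2, haps[1][g])]

    counts_per_gene = []
    for g in range(n):
        n_m = int(n_maternal[g])
        n_p = int(depths[g]) - n_m
        components = _components(n_m, mat_haps, g) + _components(n_p, pat_haps, g)
        counts_per_gene.append(_emit_counts(rng, components, error_rate))

    pileup = _assemble_pileup(genome.gene_ids, counts_per_gene, cross_id)
    truth = pd.DataFrame(
        {
            "gene_id": genome.gene_ids,
            "imprint_class": imprinting.classes.to_numpy(),
            "endosperm_maternal_dose": dose,
            "true_maternal_fraction": f_maternal,
            "expected_maternal_fraction": f_obs,
            "n_reads": depths,
        }
    )
    return CrossSimResult(pileup=pileup, truth=truth)


# ---------------------------------------------------------------------------
# tissue-compartment expression matrix (LCM-style)

ENDOSPERM_COMPARTMENTS = ("micropylar_endosperm", "peripheral_endosperm", "chalazal_endosperm")
NON_ENDOSPERM_COMPARTMENTS = ("seed_coat", "embryo_proper", "suspensor")
STAGES = ("preglobular", "globular")


def default_compartment_map() -> dict[str, str]:
    cmap = {}
    for stage in STAGES:
        for comp in ENDOSPERM_COMPARTMENTS:
            cmap[f"{comp}_{stage}"] = "endosperm"
        for comp in NON_ENDOSPERM_COMPARTMENTS:
            cmap[f"{comp}_{stage}"] = "non_endosperm"
    return cmap


def simulate_lcm_matrix(
    n_genes: int = 2000,
    n_specific: int = 50,
    fold: float = 20.0,
    noise_sd: float = 0.2,
    floor: float = 2.3,
    amplitude_log10_mean: float = 1.6,
    amplitude_log10_sd: float = 0.45,
    seed: int = 0,
):
    """Seed-compartment expression matrix with planted endosperm-specific genes.

    Background genes have comparable endosperm and non-endosperm maxima;
    planted genes have their endosperm compartments elevated ``fold``-fold.
    All values sit above the background floor (default 2.3, the scale's zero).
    Returns ``(TissueExpressionMatrix, truth list of planted gene ids)``.
    """
    from .endosperm import TissueExpressionMatrix

    if n_specific > n_genes:
        raise UsageError("n_specific must not exceed n_genes")
    rng = np.random.default_rng([int(seed), 106])
    cmap = default_compartment_map()
    columns = list(cmap)
    gene_ids = [f"g{i + 1:05d}" for i in range(n_genes)]

    amplitude = 10.0 ** rng.normal(amplitude_log10_mean, amplitude_log10_sd, n_genes)
    specific = np.zeros(n_genes, dtype=bool)
    specific[rng.choice(n_genes, size=n_specific, replace=False)] = True

    values = np.empty((n_genes, len(columns)))
    for j, col in enumerate(columns):
        comp_fold = np.where(specific & (cmap[col] == "endosperm"), fold, 1.0)
        noise = 10.0 ** rng.normal(0.0, noise_sd, n_genes)
        values[:, j] = floor + amplitude * comp_fold * noise

    matrix = TissueExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=columns),
        compartment_map=cmap,
        floor=floor,
    )
    truth = [g for g, s in zip(gene_ids, specific) if s]
    return matrix, truth
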