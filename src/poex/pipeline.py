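"""End-to-end orchestration: parents -> diagnostic SNPs -> hybrid profiles ->
parental calls -> cross comparisons -> reports, from a single config.

The config (YAML mapping or dict) either points at real pileup files plus a
reference-base map, or carries a ``simulation`` block describing genotypes
and crosses for the synthetic generator.  Every stage writes TSVs under the
output directory and a ``manifest.json`` records the versions, seeds and
thresholds needed to reproduce any output byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    bh_adjust,
    chisq_between_crosses,
    classify_genes,
    common_gene_filter,
    compare_bias_distributions,
    compare_call_sets,
    summarize_cross,
    write_calls,
    annotate_with_literature,
    bias_correlation,
)
from .endosperm import endosperm_specific_set, write_tissue_matrix
from .errors import UsageError
from .overlap import hypergeometric_overlap
from .pileup import PileupTable, pool_replicates, read_pileup, write_pileup
from .quantify import apply_pseudocounts, genotype_positions, profile_genes, write_profiles
from .simulate import (
    BiasModel,
    GenomeModel,
    ImprintingSpec,
    SeedMixtureModel,
    SyntheticGenome,
    simulate_cross,
    simulate_lcm_matrix,
    simulate_parents,
)
from .snps import call_parental_snps, remove_reference_parent_snps, subtract_shared, write_snp_table

DEFAULT_THRESHOLDS = {
    "min_coverage": 5,
    "min_fraction": 0.95,
    "meg_threshold": 66.0,
    "peg_threshold": 50.0,
    "alpha": 0.05,
    "pseudocount_mode": "per-allele",
    "min_mean_reads": 5.0,
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    raw: dict
    seed: int = 0
    output_dir: Path = Path("out")
    thresholds: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        if ("simulation" in raw) == ("inputs" in raw):
            raise UsageError("config needs exactly one of a 'simulation' block or an 'inputs' block")
        thresholds = {**DEFAULT_THRESHOLDS, **raw.get("thresholds", {})}
        cfg = cls(
            raw=raw,
            seed=int(raw.get("seed", 0)),
            output_dir=Path(raw.get("output_dir", "out")),
            thresholds=thresholds,
        )
        cfg._validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def _validate(self) -> None:
        crosses = self._crosses()
        if not crosses:
            raise UsageError("config defines no crosses")
        genotype_ids = {g["id"] for g in self._genotypes()} | {"reference"}
        for cross in crosses:
            sides = {cross.get("maternal", "reference"), cross.get("paternal", "reference")}
            unknown = sides - genotype_ids
            if unknown:
                raise UsageError(f"cross {cross['id']}: undefined parents {sorted(unknown)}")
            if sides == {"reference"}:
                raise UsageError(f"cross {cross['id']}: both parents are the reference genotype")
        for pair in self.raw.get("comparisons", []):
            ids = {c["id"] for c in crosses}
            if len(pair) != 2 or set(pair) - ids:
                raise UsageError(f"comparison {pair} references unknown crosses")

    def _block(self) -> dict:
        return self.raw.get("simulation") or self.raw.get("inputs")

    def _genotypes(self) -> list[dict]:
        return self._block().get("genotypes", [])

    def _crosses(self) -> list[dict]:
        return self._block().get("crosses", [])

    @property
    def simulated(self) -> bool:
        return "simulation" in self.raw


def default_synthetic_config(seed: int = 0, output_dir: str = "out", n_genes: int = 300) -> dict:
    """The bundled study design: reciprocal intraspecific controls plus two
    interspecific hybrids sharing the outcrossing pollen parent."""
    return {
        "seed": seed,
        "output_dir": output_dir,
        "simulation": {
            "n_genes": n_genes,
            "gene_length": 400,
            "reference_parent_snp_rate": 0.002,
            "error_rate": 0.005,
            "parent_depth_mean": 27.0,
            "parent_depth_sd": 23.0,
            "depth_mean": 50.0,
            "depth_sd": 23.0,
            "imprinting": {
                "meg_fraction": 0.10,
                "peg_fraction": 0.05,
                "reverted_fraction": 0.03,
                "peg_maternal_dose": 0.1,
            },
            "mixture": {"f_maternal_tissue": 0.0, "f_endosperm": 1.0, "f_embryo": 0.0},
            "bias": {"reference_fraction_at_even_mix": 0.5},
            "genotypes": [
                {"id": "accession_b", "divergence_rate": 0.005, "heterozygosity_rate": 0.0},
                {"id": "outcrosser", "divergence_rate": 0.05, "heterozygosity_rate": 0.005},
            ],
            "crosses": [
                {"id": "ref_x_b", "maternal": "reference", "paternal": "accession_b", "design": "control"},
                {"id": "b_x_ref", "maternal": "accession_b", "paternal": "reference", "design": "control"},
                {"id": "ref_x_out", "maternal": "reference", "paternal": "outcrosser", "design": "hybrid"},
                {"id": "b_x_out", "maternal": "accession_b", "paternal": "outcrosser", "design": "hybrid"},
            ],
        },
        "comparisons": [
            ["ref_x_out", "b_x_out"],
            ["ref_x_out", "ref_x_b"],
            ["ref_x_b", "b_x_ref"],
            ["b_x_out", "ref_x_b"],
        ],
        "annotation": {"hybrid": "ref_x_out", "control": "ref_x_b"},
    }


def _derived_seed(master: int, offset: int) -> int:
    return (int(master) * 100003 + offset) % (2**31)


def run_pipeline(config: PipelineConfig | dict) -> dict:
    """Execute the full analysis; returns a report bundle of DataFrames.

    Outputs land under ``output_dir/{snps,profiles,calls,reports}`` plus a
    ``manifest.json``.  Reruns with an identical config and seed produce
    byte-identical files.
    """
    if isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    out = config.output_dir
    for sub in ("snps", "profiles", "calls", "reports"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    thresholds = config.thresholds
    manifest: dict = {
        "poex_version": __version__,
        "seed": config.seed,
        "thresholds": thresholds,
        "stages": {},
    }
    bundle: dict = {}

    if config.simulated:
        sim_inputs = _simulate_inputs(config, manifest)
    else:
        sim_inputs = _load_inputs(config)
    diagnostics, reference_bases, cross_pileups, truths, literature = sim_inputs

    # --- diagnostic SNP tables -------------------------------------------
    for geno_id, table in diagnostics.items():
        write_snp_table(table, out / "snps" / f"{geno_id}.diagnostic_snps.tsv")
        manifest["stages"][f"snps:{geno_id}"] = int(len(table))

    # --- per-cross quantification and classification ----------------------
    profiles_by_cross: dict[str, pd.DataFrame] = {}
    calls_by_cross: dict[str, pd.DataFrame] = {}
    for cross in config._crosses():
        cid = cross["id"]
        geno_id = cross.get("paternal") if cross.get("paternal", "reference") != "reference" else cross["maternal"]
        diag_parent = "paternal" if cross.get("paternal", "reference") != "reference" else "maternal"
        positions = genotype_positions(
            cross_pileups[cid],
            diagnostics[geno_id],
            reference_bases,
            min_coverage=thresholds["min_coverage"],
            diagnostic_parent=diag_parent,
        )
        profiles = profile_genes(positions, cross_id=cid)
        calls = classify_genes(
            profiles,
            meg_threshold=thresholds["meg_threshold"],
            peg_threshold=thresholds["peg_threshold"],
            alpha=thresholds["alpha"],
            pseudocount_mode=thresholds["pseudocount_mode"],
        )
        profiles_by_cross[cid] = profiles
        calls_by_cross[cid] = calls
        write_profiles(profiles, out / "profiles" / f"{cid}.profiles.tsv")
        write_calls(calls, out / "calls" / f"{cid}.calls.tsv")
        manifest["stages"][f"profiles:{cid}"] = int(len(profiles))

    summary = summarize_cross(pd.concat(calls_by_cross.values(), ignore_index=True))
    summary.to_csv(out / "reports" / "class_summary.tsv", sep="\t", index=False, float_format="%.6g")
    bundle["summary"] = summary
    bundle["profiles"] = profiles_by_cross
    bundle["calls"] = calls_by_cross

    # --- cross-vs-cross comparisons ---------------------------------------
    comparison_frames = []
    venn_rows = []
    stats_rows = []
    if len(profiles_by_cross) >= 2:
        common = common_gene_filter(profiles_by_cross, min_mean_reads=thresholds["min_mean_reads"])
        manifest["stages"]["common_genes"] = len(common)
    else:
        common = set()
    for cross_a, cross_b in config.raw.get("comparisons", []):
        pa = profiles_by_cross[cross_a].set_index("gene_id")
        pb = profiles_by_cross[cross_b].set_index("gene_id")
        genes = sorted(common & set(pa.index) & set(pb.index))
        if genes:
            nm_a, np_a = apply_pseudocounts(pa.loc[genes, "N_m"].to_numpy(), pa.loc[genes, "N_p"].to_numpy())
            nm_b, np_b = apply_pseudocounts(pb.loc[genes, "N_m"].to_numpy(), pb.loc[genes, "N_p"].to_numpy())
            chi2, p = chisq_between_crosses(nm_a, np_a, nm_b, np_b)
            comp = pd.DataFrame(
                {
                    "comparison_id": f"{cross_a}_vs_{cross_b}",
                    "gene_id": genes,
                    "chi2": chi2,
                    "p": p,
                    "padj": bh_adjust(p),
                }
            )
            comparison_frames.append(comp)
            if len(genes) >= 10:
                stat, wp, mean_a, mean_b = compare_bias_distributions(
                    pa.loc[genes, "P_p"].to_numpy(), pb.loc[genes, "P_p"].to_numpy()
                )
                r2, slope, rp = bias_correlation(
                    pa.loc[genes, "P_p"].to_numpy(), pb.loc[genes, "P_p"].to_numpy()
                )
                stats_rows.append(
                    {
                        "comparison_id": f"{cross_a}_vs_{cross_b}",
                        "n_genes": len(genes),
                        "wilcoxon_stat": stat,
                        "wilcoxon_p": wp,
                        "mean_Pp_a": mean_a,
                        "mean_Pp_b": mean_b,
                        "r_squared": r2,
                        "slope": slope,
                        "slope_p": rp,
                    }
                )
        venn = compare_call_sets(calls_by_cross[cross_a], calls_by_cross[cross_b])
        vc = venn.counts()
        vc.insert(0, "comparison_id", f"{cross_a}_vs_{cross_b}")
        venn_rows.append(vc)
    if comparison_frames:
        comparisons = pd.concat(comparison_frames, ignore_index=True)
        comparisons.to_csv(out / "reports" / "between_cross_tests.tsv", sep="\t", index=False, float_format="%.6g")
        bundle["between_cross_tests"] = comparisons
    if venn_rows:
        venn_table = pd.concat(venn_rows, ignore_index=True)
        venn_table.to_csv(out / "reports" / "call_set_overlaps.tsv", sep="\t", index=False)
        bundle["call_set_overlaps"] = venn_table
    if stats_rows:
        stats_table = pd.DataFrame(stats_rows)
        stats_table.to_csv(out / "reports" / "bias_statistics.tsv", sep="\t", index=False, float_format="%.6g")
        bundle["bias_statistics"] = stats_table

    # --- literature annotation --------------------------------------------
    annotation_cfg = config.raw.get("annotation")
    if literature is not None and annotation_cfg:
        annotation = annotate_with_literature(
            calls_by_cross[annotation_cfg["hybrid"]],
            calls_by_cross[annotation_cfg["control"]],
            literature,
        )
        annotation.to_csv(out / "reports" / "literature_annotation.tsv", sep="\t", index=False)
        bundle["literature_annotation"] = annotation

    # --- endosperm specificity and set overlap ----------------------------
    lcm_cfg = config.raw.get("lcm")
    if lcm_cfg is not None and config.simulated:
        matrix, planted = simulate_lcm_matrix(
            n_genes=lcm_cfg.get("n_genes", 2000),
            n_specific=lcm_cfg.get("n_specific", 50),
            fold=lcm_cfg.get("fold", 20.0),
            seed=_derived_seed(config.seed, 61),
        )
        write_tissue_matrix(matrix, out / "reports" / "lcm_matrix.tsv")
        specific, scores = endosperm_specific_set(matrix)
        scores.to_csv(out / "reports" / "endosperm_scores.tsv", sep="\t", index=False, float_format="%.6g")
        bundle["endosperm_specific"] = specific
        hybrid_id = (config.raw.get("annotation") or {}).get("hybrid")
        if hybrid_id:
            universe = set(scores.loc[scores["passed_expression_filter"], "gene_id"])
            pegs = set(
                calls_by_cross[hybrid_id].loc[calls_by_cross[hybrid_id]["class"] == "paternal", "gene_id"]
            )
            query = pegs & universe
            k = len(query & specific)
            if universe and query:
                test = hypergeometric_overlap(k, len(query), len(specific & universe), len(universe))
                bundle["peg_endosperm_overlap"] = test
                with open(out / "reports" / "peg_endosperm_overlap.json", "w") as fh:
                    json.dump(test.__dict__, fh, indent=2)

    if truths:
        for cid, truth in truths.items():
            truth.to_csv(out / "reports" / f"{cid}.truth.tsv", sep="\t", index=False, float_format="%.6g")
        bundle["truth"] = truths

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    bundle["manifest"] = manifest
    return bundle


# ---------------------------------------------------------------------------
# input preparation


def _simulate_inputs(config: PipelineConfig, manifest: dict):
    sim = config.raw["simulation"]
    seed = config.seed
    n_genes = sim.get("n_genes", 300)
    gene_length = sim.get("gene_length", 400)
    error_rate = sim.get("error_rate", 0.005)
    imprinting_cfg = sim.get("imprinting", {})
    mixture = SeedMixtureModel(**sim.get("mixture", {}))
    bias = BiasModel(**sim.get("bias", {}))

    genomes: dict[str, SyntheticGenome] = {}
    diagnostics: dict[str, pd.DataFrame] = {}
    reference_bases = None
    ref_parent_snps_by_geno = {}
    for idx, geno in enumerate(sim.get("genotypes", [])):
        model = GenomeModel(
            n_genes=n_genes,
            gene_length=gene_length,
            divergence_rate=geno.get("divergence_rate", 0.05),
            heterozygosity_rate=geno.get("heterozygosity_rate", 0.0),
            reference_parent_snp_rate=sim.get("reference_parent_snp_rate", 0.0),
            reference_parent="maternal",
            seed=_derived_seed(seed, 11 + idx),
            reference_seed=_derived_seed(seed, 7),
        )
        genome = SyntheticGenome(model)
        genomes[geno["id"]] = genome
        if reference_bases is None:
            reference_bases = genome.reference_bases()
        parents = simulate_parents(
            genome,
            depth_mean=sim.get("parent_depth_mean", 27.0),
            depth_sd=sim.get("parent_depth_sd", 23.0),
            error_rate=error_rate,
            seed=_derived_seed(seed, 31 + idx),
        )
        raw_snps = call_parental_snps(
            parents.paternal,
            reference_bases,
            parent=geno["id"],
            min_coverage=config.thresholds["min_coverage"],
            min_fraction=config.thresholds["min_fraction"],
        )
        self_snps = call_parental_snps(
            parents.maternal,
            reference_bases,
            parent="reference",
            min_coverage=config.thresholds["min_coverage"],
            min_fraction=config.thresholds["min_fraction"],
        )
        ref_parent_snps_by_geno[geno["id"]] = self_snps
        diagnostics[geno["id"]] = remove_reference_parent_snps(raw_snps, self_snps)
        manifest["stages"][f"raw_snps:{geno['id']}"] = int(len(raw_snps))

    geno_ids = list(diagnostics)
    for i in range(len(geno_ids)):
        for j in range(i + 1, len(geno_ids)):
            diagnostics[geno_ids[i]], diagnostics[geno_ids[j]] = subtract_shared(
                diagnostics[geno_ids[i]], diagnostics[geno_ids[j]]
            )

    first_genome = next(iter(genomes.values()))
    imprinting = ImprintingSpec.random(
        first_genome.gene_ids,
        meg_fraction=imprinting_cfg.get("meg_fraction", 0.10),
        peg_fraction=imprinting_cfg.get("peg_fraction", 0.05),
        reverted_fraction=imprinting_cfg.get("reverted_fraction", 0.0),
        peg_maternal_dose=imprinting_cfg.get("peg_maternal_dose", 0.1),
        seed=_derived_seed(seed, 41),
    )

    cross_pileups: dict[str, PileupTable] = {}
    truths: dict[str, pd.DataFrame] = {}
    for idx, cross in enumerate(config._crosses()):
        cid = cross["id"]
        maternal_geno = cross.get("maternal", "reference")
        paternal_geno = cross.get("paternal", "reference")
        # the primary genotype is the one whose diagnostic SNPs score the cross
        # (the paternal side when it is divergent, otherwise the maternal side)
        nonref = paternal_geno if paternal_geno != "reference" else maternal_geno
        orientation = "maternal" if paternal_geno != "reference" else "paternal"
        other = None
        if maternal_geno != "reference" and paternal_geno != "reference":
            other = genomes[maternal_geno]
        base_genome = genomes[nonref]
        oriented = SyntheticGenome(
            GenomeModel(**{**base_genome.model.__dict__, "reference_parent": orientation})
        )
        result = simulate_cross(
            oriented,
            imprinting,
            mix=mixture,
            bias=bias,
            depth_mean=cross.get("depth_mean", sim.get("depth_mean", 50.0)),
            depth_sd=cross.get("depth_sd", sim.get("depth_sd", 23.0)),
            error_rate=error_rate,
            design=cross.get("design", "hybrid"),
            seed=_derived_seed(seed, 51 + idx),
            cross_id=cid,
            other_parent_genome=other,
        )
        cross_pileups[cid] = result.pileup
        truths[cid] = result.truth

    literature_path = config.raw.get("literature")
    if literature_path:
        literature = pd.read_csv(literature_path, sep="\t", dtype=str)
    else:
        status = imprinting.classes.map(
            {"PEG": "known_PEG", "reverted_PEG": "known_PEG", "MEG": "known_MEG", "biparental": "none"}
        )
        literature = pd.DataFrame({"gene_id": imprinting.classes.index, "status": status.to_numpy()})
        literature = literature[literature["status"] != "none"].reset_index(drop=True)
    return diagnostics, reference_bases, cross_pileups, truths, literature


def _load_inputs(config: PipelineConfig):
    inputs = config.raw["inputs"]
    reference_bases = pd.read_csv(inputs["reference_bases"], sep="\t", dtype={"gene_id": str, "ref_base": str})
    diagnostics: dict[str, pd.DataFrame] = {}
    ref_self_snps = None
    if inputs.get("reference_parent_pileups"):
        pooled = pool_replicates([read_pileup(p) for p in inputs["reference_parent_pileups"]])
        ref_self_snps = call_parental_snps(
            pooled,
            reference_bases,
            parent="reference",
            min_coverage=config.thresholds["min_coverage"],
            min_fraction=config.thresholds["min_fraction"],
        )
    for geno in inputs.get("genotypes", []):
        pooled = pool_replicates([read_pileup(p) for p in geno["pileups"]])
        snps = call_parental_snps(
            pooled,
            reference_bases,
            parent=geno["id"],
            min_coverage=config.thresholds["min_coverage"],
            min_fraction=config.thresholds["min_fraction"],
        )
        if ref_self_snps is not None:
            snps = remove_reference_parent_snps(snps, ref_self_snps)
        diagnostics[geno["id"]] = snps
    geno_ids = list(diagnostics)
    for i in range(len(geno_ids)):
        for j in range(i + 1, len(geno_ids)):
            diagnostics[geno_ids[i]], diagnostics[geno_ids[j]] = subtract_shared(
                diagnostics[geno_ids[i]], diagnostics[geno_ids[j]]
            )
    cross_pileups = {}
    for cross in config._crosses():
        cross_pileups[cross["id"]] = pool_replicates([read_pileup(p) for p in cross["pileups"]])
    literature = None
    if config.raw.get("literature"):
        literature = pd.read_csv(config.raw["literature"], sep="\t", dtype=str)
    return diagnostics, reference_bases, cross_pileups, {}, literature
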