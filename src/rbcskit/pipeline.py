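"""End-to-end orchestration of the analysis stages on synthetic or user data.

``run_pipeline`` executes the enabled stages in dependency order
(simulate → curate → arrays → promoters → expression → contacts/screen →
selection), writes one TSV per stage plus a consolidated ``summary.json``,
and logs parameters and the seed so identical configs reproduce
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import packaged_branch_models_path
from .errors import InputError, RbcskitError
from .expression_analysis import compare_growth_habits, relative_abundance
from .family_curation import default_domain_models, filter_by_homology, screen_domains
from .io_core import (
    read_fasta,
    read_gff3,
    read_newick,
    read_pdb_atoms,
    write_fasta,
    write_gff3,
    write_pdb,
)
from .locus_analysis import detect_tandem_arrays
from .promoter_cre import (
    cre_composition,
    default_motif_library,
    extract_upstream,
    find_paired_ibox,
    load_motif_library,
    scan_motifs,
)
from .selection_analysis import (
    group_omega_summary,
    likelihood_ratio_test,
    read_branch_models,
)
from .structure_screen import interface_contacts, screen_alignment
from .synthetic_data import (
    SimulationConfig,
    make_expression_matrix,
    make_genome_with_arrays,
    make_promoters,
    make_toy_complex,
    simulate_codon_evolution,
)

logger = logging.getLogger("rbcskit.pipeline")

ALL_STAGES = ("simulate", "curate", "arrays", "promoters", "expression",
              "contacts", "selection")


@dataclass
class PipelineConfig:
    """Flat pipeline configuration (CLI flags override file values)."""

    output_dir: str = "rbcskit_out"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    # stage inputs (None → use the synthetic fixtures written by `simulate`)
    genome_fasta: str | None = None
    genes_gff3: str | None = None
    proteins_fasta: str | None = None
    tpm_tsv: str | None = None
    samples_tsv: str | None = None
    structure_pdb: str | None = None
    alignment_fasta: str | None = None
    tree_newick: str | None = None
    branch_models_tsv: str | None = None
    motif_library_tsv: str | None = None
    # stage parameters
    max_gap_bp: int = 300_000
    promoter_length: int = 2_000
    spacer_min: int = 20
    spacer_max: int = 30
    max_tss_distance: int = 168
    contact_cutoff: float = 4.0
    min_identity: float = 90.0
    min_coverage: float = 80.0
    small_chains: list[str] = field(default_factory=lambda: ["S"])
    large_chains: list[str] = field(default_factory=lambda: ["L"])
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        bad = [s for s in self.stages if s not in ALL_STAGES]
        if bad:
            raise InputError(f"unknown stages: {bad}")
        if "simulate" not in self.stages:
            for name in ("genome_fasta", "genes_gff3", "tpm_tsv",
                         "structure_pdb", "alignment_fasta", "tree_newick"):
                path = getattr(self, name)
                if path is not None and not Path(path).exists():
                    raise InputError(f"input path does not exist: {path}")


def _write_fixtures(cfg: PipelineConfig, outdir: Path) -> dict[str, Path]:
    """Generate the full synthetic fixture set for a demo run."""
    sim = SimulationConfig(seed=cfg.seed, spacer=25,
                           promoter_length=cfg.promoter_length)
    fx = outdir / "fixtures"
    fx.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    chrom, genes = make_genome_with_arrays(sim)
    paths["genome_fasta"] = fx / "genome.fasta"
    paths["genes_gff3"] = fx / "genes.gff3"
    write_fasta([chrom], paths["genome_fasta"])
    write_gff3(genes, paths["genes_gff3"])

    promoters = make_promoters(sim)
    paths["promoters_fasta"] = fx / "promoters.fasta"
    write_fasta(promoters, paths["promoters_fasta"])

    tpm, groups = make_expression_matrix(sim)
    paths["tpm_tsv"] = fx / "tpm.tsv"
    tpm.to_csv(paths["tpm_tsv"], sep="\t")
    paths["samples_tsv"] = fx / "samples.tsv"
    pd.DataFrame(
        sorted(groups.items()), columns=["sample", "growth_habit"]
    ).to_csv(paths["samples_tsv"], sep="\t", index=False)

    atoms = make_toy_complex({59: 3.5, 83: 3.9, 120: 4.0})
    paths["structure_pdb"] = fx / "complex.pdb"
    write_pdb(atoms, paths["structure_pdb"])

    newick = ("((fg1#fg:0.2,fg2#fg:0.2)anc1#fg:0.1,"
              "(bg1#bg:0.2,bg2#bg:0.2)anc2#bg:0.1);")
    tree = read_newick(newick)
    sim_codons = SimulationConfig(
        seed=cfg.seed, n_codons=300,
        omega_map={"fg": 0.2, "bg": 0.05, "default": 0.05},
    )
    alignment = simulate_codon_evolution(tree, sim_codons)
    paths["alignment_fasta"] = fx / "cds_alignment.fasta"
    write_fasta(alignment, paths["alignment_fasta"])
    paths["tree_newick"] = fx / "tree.nwk"
    paths["tree_newick"].write_text(newick + "\n")
    return paths


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages; returns the JSON-ready summary dict."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    log_lines = [f"seed={config.seed}", f"stages={config.stages}"]
    summary: dict = {"seed": config.seed, "stages_run": []}

    paths: dict[str, Path] = {}
    if "simulate" in config.stages:
        paths = _write_fixtures(config, outdir)
        summary["stages_run"].append("simulate")

    def resolve(name: str) -> Path | None:
        explicit = getattr(config, name, None)
        if explicit:
            return Path(explicit)
        return paths.get(name)

    library = (
        load_motif_library(config.motif_library_tsv)
        if config.motif_library_tsv
        else default_motif_library()
    )

    if "arrays" in config.stages:
        gff = resolve("genes_gff3")
        if gff is None:
            raise InputError("arrays stage needs genes_gff3")
        genes = read_gff3(gff, species="synthetic", sort=True)
        arrays, dispersed = detect_tandem_arrays(genes, config.max_gap_bp)
        pd.DataFrame(
            [
                (a.chromosome, ",".join(a.member_gene_ids),
                 len(a.member_gene_ids), a.span_bp, a.span_bp_inclusive)
                for a in arrays
            ],
            columns=["chromosome", "members", "n_members", "span_bp",
                     "span_bp_inclusive"],
        ).to_csv(outdir / "arrays.tsv", sep="\t", index=False)
        summary["tandem_arrays"] = [
            {"n_members": len(a.member_gene_ids), "span_bp": a.span_bp}
            for a in arrays
        ]
        summary["n_dispersed_copies"] = len(dispersed)
        summary["stages_run"].append("arrays")

    if "curate" in config.stages:
        prot = resolve("proteins_fasta")
        if prot is not None:
            candidates = read_fasta(prot, alphabet="protein")
            reference = candidates[0]
            retained, report = filter_by_homology(
                candidates, reference,
                config.min_identity, config.min_coverage,
            )
            report.to_csv(outdir / "curation.tsv", sep="\t", index=False)
            summary["n_curated"] = len(retained)
        else:
            summary["n_curated"] = None  # no protein input supplied
        summary["stages_run"].append("curate")

    if "promoters" in config.stages:
        pfa = resolve("promoters_fasta")
        if pfa is None:
            genome_path, gff = resolve("genome_fasta"), resolve("genes_gff3")
            if genome_path is None or gff is None:
                raise InputError("promoters stage needs promoters or genome+gff3")
            genome = read_fasta(genome_path)[0]
            genes = read_gff3(gff, sort=True)
            proms = [
                extract_upstream(genome, g, config.promoter_length)
                for g in genes
            ]
        else:
            proms = read_fasta(pfa)
        hit_rows, pair_rows = [], []
        hits_by_gene = {}
        for prom in proms:
            hits = scan_motifs(prom, library)
            hits_by_gene[prom.id] = hits
            hit_rows += [
                (h.gene_id, h.motif_name, h.tss_offset_start,
                 h.tss_offset_end, h.strand_of_hit)
                for h in hits
            ]
            for p in find_paired_ibox(
                hits, config.spacer_min, config.spacer_max,
                config.max_tss_distance,
            ):
                pair_rows.append(
                    (p.gene_id, p.hit_a.tss_offset_start,
                     p.hit_b.tss_offset_start, p.spacer_bp, p.tss_distance_bp)
                )
        pd.DataFrame(
            hit_rows,
            columns=["gene", "motif", "tss_offset_start", "tss_offset_end",
                     "strand"],
        ).to_csv(outdir / "motif_hits.tsv", sep="\t", index=False)
        pd.DataFrame(
            pair_rows,
            columns=["gene", "a_start", "b_start", "spacer_bp",
                     "tss_distance_bp"],
        ).to_csv(outdir / "ibox_pairs.tsv", sep="\t", index=False)
        presence, comp = cre_composition(hits_by_gene, library)
        presence.to_csv(outdir / "cre_presence.tsv", sep="\t")
        comp.to_csv(outdir / "cre_composition.tsv", sep="\t")
        summary["n_motif_hits"] = len(hit_rows)
        summary["ibox_pairs"] = [
            {"gene": r[0], "spacer_bp": r[3], "tss_distance_bp": r[4]}
            for r in pair_rows
        ]
        summary["stages_run"].append("promoters")

    if "expression" in config.stages:
        tpm_path = resolve("tpm_tsv")
        samples_path = resolve("samples_tsv")
        if tpm_path is None or samples_path is None:
            raise InputError("expression stage needs tpm_tsv and samples_tsv")
        tpm = pd.read_csv(tpm_path, sep="\t", index_col=0)
        meta = pd.read_csv(samples_path, sep="\t")
        groups = dict(zip(meta["sample"], meta["growth_habit"]))
        comparison = compare_growth_habits(tpm, groups)
        shares = relative_abundance(tpm, list(tpm.index), tpm.columns[0])
        shares.rename("share_percent").to_csv(
            outdir / "expression_shares.tsv", sep="\t"
        )
        summary["growth_habit_comparison"] = {
            "mean_winter": comparison.mean_winter,
            "mean_spring": comparison.mean_spring,
            "percent_difference": comparison.percent_difference,
            "t": comparison.t_statistic,
            "p": comparison.p_two_sided,
        }
        summary["stages_run"].append("expression")

    if "contacts" in config.stages:
        pdb = resolve("structure_pdb")
        if pdb is None:
            raise InputError("contacts stage needs structure_pdb")
        atoms = read_pdb_atoms(pdb)
        contacts = interface_contacts(
            atoms, config.small_chains, config.large_chains,
            config.contact_cutoff,
        )
        pd.DataFrame(
            [
                (c.chain_id, c.residue_index, c.residue_name,
                 c.min_interchain_distance)
                for c in contacts
            ],
            columns=["chain", "residue", "residue_name", "min_distance"],
        ).to_csv(outdir / "contacts.tsv", sep="\t", index=False)
        summary["contact_residues"] = [c.residue_index for c in contacts]
        summary["stages_run"].append("contacts")

    if "selection" in config.stages:
        models_path = resolve("branch_models_tsv")
        if models_path is None:
            models_path = packaged_branch_models_path()
        models = read_branch_models(models_path)
        lrt_rows = []
        for alt, null in (("two_branch_C4", "one_ratio"),
                          ("modelA_C4", "modelA_null_C4"),
                          ("modelA_Chr5", "modelA_null_Chr5")):
            if alt in models and null in models:
                res = likelihood_ratio_test(models[alt], models[null])
                lrt_rows.append(
                    (alt, null, res.two_delta_L, res.df, res.p_value)
                )
        pd.DataFrame(
            lrt_rows,
            columns=["alternative", "null", "two_delta_L", "df", "p_value"],
        ).to_csv(outdir / "lrt.tsv", sep="\t", index=False)
        summary["lrt"] = [
            {"alternative": r[0], "null": r[1], "two_delta_L": r[2],
             "df": r[3], "p": r[4]}
            for r in lrt_rows
        ]
        aln_path, tree_path = resolve("alignment_fasta"), resolve("tree_newick")
        if aln_path is not None and tree_path is not None:
            alignment = read_fasta(aln_path, alphabet="nucleotide")
            tree = read_newick(Path(tree_path).read_text())
            groups = tree.branch_groups
            if all(
                sum(1 for g in groups.values() if g == grp) >= 2
                for grp in set(groups.values())
            ):
                omega_summary, contrasts = group_omega_summary(
                    alignment, tree
                )
                omega_summary.to_csv(
                    outdir / "group_omega.tsv", sep="\t", index=False
                )
                summary["group_omega"] = dict(
                    zip(omega_summary["group"], omega_summary["mean_omega"])
                )
        summary["stages_run"].append("selection")

    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=float) + "\n"
    )
    log_lines.append("status=success")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary
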