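"""rbcskit: comparative analysis of the RuBisCO small-subunit gene family.

Modules
-------
io_core
    FASTA / GFF3 / PDB / Newick readers and writers; coordinate conventions.
synthetic_data
    Seeded generators for every input the pipeline consumes.
family_curation
    Identity/coverage homology filter and domain-presence screen.
locus_analysis
    Tandem-array detection, copy-number summaries, genome-size correlation.
promoter_cre
    Upstream-region extraction, IUPAC motif scanning, paired-I-box detection.
expression_analysis
    Family expression shares and winter/spring growth-habit comparison.
structure_screen
    Interface contacts, C3/C4 divergence classification, Kabsch RMSD.
selection_analysis
    Likelihood-ratio tests over nested codon models; NG86 dN/dS.
pipeline
    End-to-end orchestration; `rbcskit` console script in :mod:`rbcskit.cli`.
"""

from importlib.resources import files

__version__ = "0.1.0"


def packaged_branch_models_path():
    """Path to the bundled branch-model (np, lnL) table."""
    return files("rbcskit").joinpath("data/branch_models.tsv")
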