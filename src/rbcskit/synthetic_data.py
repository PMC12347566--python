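"""Seeded generators for synthetic inputs with the structure each stage assumes.

Every generator is a pure function of its :class:`SimulationConfig`: the same
seed yields byte-identical output.  Each generator draws from its own RNG
stream, derived from the master seed by a stable label, so adding draws to
one generator never perturbs another.

What is emulated (and what is not): chromosomes carry one clustered tandem
array plus dispersed singleton copies (no transposons, no synteny);
promoters are i.i.d. background with motifs written at exact offsets (no
chromatin grammar); codon alignments evolve by an acceptance-sampling
approximation of branch-specific dN/dS (nonsynonymous events fix with
probability ω, synonymous always — not a full GY94 rate matrix, and no
indels); expression matrices are i.i.d. lognormal TPM draws with a
winter-group multiplier; toy complexes are two chains with contacts planted
at exact distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .codons import (
    CODON_TO_AA,
    SENSE_CODONS,
    TRANSITIONS,
    is_stop,
)
from .errors import InputError, LayoutError, PlanError
from .io_core import AtomRecord, GeneModel, SequenceRecord, Tree
from .promoter_cre import IUPAC_TABLE, Motif, default_motif_library

# Stable per-generator stream labels (never reorder: seeds depend on them).
_STREAM_IDS = {
    "genome": 1,
    "promoters": 2,
    "codons": 3,
    "expression": 4,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAM_IDS[stream]])


@dataclass
class SimulationConfig:
    """All knobs for the synthetic generators (defaults = study-like conditions)."""

    seed: int = 0
    # genome / tandem array
    chromosome_length: int = 2_000_000
    array_size: int = 5
    array_gap: int = 50_000
    dispersed_copies: int = 2
    gene_length: int = 1_000
    # promoters
    promoter_length: int = 2_000
    n_promoters: int = 1
    motif_plan: list[tuple[str, int, str]] = field(default_factory=list)
    spacer: int | None = None
    ibox_tss_distance: int = 59
    background_gc: float = 0.5
    # codon evolution
    omega_map: dict[str, float] = field(
        default_factory=lambda: {"default": 0.05}
    )
    kappa: float = 2.0
    mu_t: float = 0.1
    n_codons: int = 500
    # expression
    n_family_genes: int = 6
    tpm_log_mean: float = 7.0
    tpm_log_sd: float = 0.5
    group_multiplier: float = 1.0
    n_winter: int = 5
    n_spring: int = 14

    def __post_init__(self) -> None:
        counts = (self.array_size, self.dispersed_copies, self.n_codons,
                  self.n_winter, self.n_spring, self.n_family_genes)
        if any(c < 0 for c in counts):
            raise InputError("all counts must be >= 0")
        if any(w < 0 for w in self.omega_map.values()):
            raise InputError("omega values must be >= 0")
        if self.kappa < 0:
            raise InputError("kappa must be >= 0")
        if self.group_multiplier <= 0:
            raise InputError("group_multiplier must be > 0")


def make_genome_with_arrays(
    config: SimulationConfig,
) -> tuple[SequenceRecord, list[GeneModel]]:
    """One chromosome with a tandem cluster plus dispersed singleton copies.

    The cluster holds ``array_size`` family genes separated by ``array_gap``
    bp gaps; ``dispersed_copies`` singletons are placed at least
    2 × ``array_gap`` away from the cluster and from one another — and never
    closer than twice the default tandem-clustering gap (600 kb), so that
    planted singletons are dispersed under default detector parameters.
    """
    rng = _rng(config.seed, "genome")
    L, g, gap = config.chromosome_length, config.gene_length, config.array_gap
    dispersed_sep = max(2 * gap, 2 * 300_000)
    models: list[GeneModel] = []
    cursor = max(1, L // 20)  # leave headroom for promoter extraction
    for i in range(config.array_size):
        start = cursor + i * (g + gap)
        models.append(
            GeneModel(
                gene_id=f"RBCS_arr{i + 1}",
                chromosome="chr_sim1",
                start=start,
                end=start + g - 1,
                strand="+",
                species="synthetic",
            )
        )
    cursor = (models[-1].end if models else cursor) + dispersed_sep
    for j in range(config.dispersed_copies):
        start = cursor + j * (g + dispersed_sep)
        models.append(
            GeneModel(
                gene_id=f"RBCS_disp{j + 1}",
                chromosome="chr_sim1",
                start=start,
                end=start + g - 1,
                strand="+" if j % 2 == 0 else "-",
                species="synthetic",
            )
        )
    if models and models[-1].end > L:
        raise LayoutError(
            f"gene layout runs to {models[-1].end} bp, beyond the "
            f"{L} bp chromosome"
        )
    for a, b in zip(models, models[1:]):
        if b.start <= a.end:
            raise LayoutError(f"genes {a.gene_id} and {b.gene_id} overlap")
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    chrom = SequenceRecord(
        id="chr_sim1",
        sequence=bytes(rng.choice(alphabet, size=L)).decode("ascii"),
        description="synthetic chromosome with planted tandem array",
    )
    return chrom, models


def _realize_consensus(consensus: str, rng: np.random.Generator) -> str:
    """One concrete sequence matching an IUPAC consensus (uniform per position)."""
    return "".join(rng.choice(list(IUPAC_TABLE[c])) for c in consensus.upper())


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def make_promoters(
    config: SimulationConfig, library: list[Motif] | None = None
) -> list[SequenceRecord]:
    """Background promoters with motifs planted at exact TSS-relative offsets.

    ``motif_plan`` entries are ``(motif_name, offset, strand)`` where the
    offset is the TSS-relative position of the motif's 5'-most base
    (offset −1 = base immediately upstream of the TSS).  When
    ``config.spacer`` is set, an I-box pair is additionally planted: the
    downstream copy ends ``ibox_tss_distance`` bp from the TSS and the
    upstream copy is separated from it by exactly ``spacer`` bp.
    """
    rng = _rng(config.seed, "promoters")
    library = library if library is not None else default_motif_library()
    by_name = {m.name: m for m in library}
    L = config.promoter_length
    gc = config.background_gc
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T

    plan = list(config.motif_plan)
    if config.spacer is not None:
        w = len(by_name["I-box"].consensus)
        b_end = -(config.ibox_tss_distance + 1)
        b_start = b_end - w + 1
        a_end = b_start - config.spacer - 1
        a_start = a_end - w + 1
        plan = plan + [("I-box", a_start, "+"), ("I-box", b_start, "+")]

    promoters: list[SequenceRecord] = []
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    for p in range(config.n_promoters):
        seq = list(bytes(rng.choice(alphabet, size=L, p=probs)).decode("ascii"))
        occupied: list[tuple[int, int]] = []
        for name, offset, strand in plan:
            motif = by_name[name]
            w = len(motif.consensus)
            start = L + offset  # offset is the 5'-most base, negative
            end = start + w
            if start < 0 or end > L:
                raise PlanError(
                    f"motif {name} at offset {offset} does not fit in a "
                    f"{L} bp promoter"
                )
            for s, e in occupied:
                if start < e and s < end:
                    raise PlanError(
                        f"planted motif {name} at offset {offset} overlaps "
                        f"a previous motif"
                    )
            occupied.append((start, end))
            instance = _realize_consensus(motif.consensus, rng)
            if strand == "-":
                instance = _revcomp(instance)
            seq[start:end] = list(instance)
        promoters.append(
            SequenceRecord(
                id=f"promoter_{p + 1}",
                sequence="".join(seq),
                description="synthetic promoter",
            )
        )
    return promoters


def simulate_codon_evolution(
    tree: Tree,
    config: SimulationConfig,
    branch_groups: dict[str, str] | None = None,
    root_sequence: str | None = None,
) -> list[SequenceRecord]:
    """Evolve a stop-free codon alignment along a tree with branch-specific ω.

    Along each edge the number of mutation events is Poisson with mean
    ``mu_t × 3 × n_codons × branch_length``; each event picks a uniform
    site and an alternative nucleotide (transitions weighted ``kappa``);
    events creating stop codons are redrawn; nonsynonymous events fix with
    probability ω of the edge's branch group, synonymous always.  Tips are
    returned gap-free and aligned.

    Branch groups are looked up per node label, falling back to the tree's
    own ``#group`` annotations and then to ``"default"``.
    """
    rng = _rng(config.seed, "codons")
    groups = dict(tree.branch_groups)
    groups.update(branch_groups or {})

    if root_sequence is None:
        root = "".join(rng.choice(SENSE_CODONS, size=config.n_codons))
    else:
        root = root_sequence.upper()
        if len(root) % 3:
            raise InputError("root sequence length must be divisible by 3")
        for i in range(0, len(root), 3):
            if is_stop(root[i:i + 3]):
                raise InputError("root sequence contains a stop codon")
    n_nt = len(root)

    def omega_for(label: str | None) -> float:
        if label is not None and label in groups:
            return config.omega_map.get(
                groups[label], config.omega_map.get("default", 1.0)
            )
        return config.omega_map.get("default", 1.0)

    def evolve(seq: str, branch_length: float, omega: float) -> str:
        n_events = rng.poisson(config.mu_t * n_nt * branch_length)
        s = list(seq)
        nts = "ACGT"
        for _ in range(n_events):
            for _attempt in range(100):  # redraw events that create stops
                pos = int(rng.integers(n_nt))
                current = s[pos]
                alts = [n for n in nts if n != current]
                weights = np.array(
                    [config.kappa if TRANSITIONS[current] == a else 1.0
                     for a in alts]
                )
                alt = rng.choice(alts, p=weights / weights.sum())
                c0 = pos - pos % 3
                old_codon = "".join(s[c0:c0 + 3])
                new_codon = (old_codon[:pos - c0] + alt
                             + old_codon[pos - c0 + 1:])
                if is_stop(new_codon):
                    continue
                if CODON_TO_AA[new_codon] != CODON_TO_AA[old_codon]:
                    if rng.random() >= omega:
                        break  # event rejected (purifying selection)
                s[pos] = alt
                break
        return "".join(s)

    tips: list[SequenceRecord] = []

    def walk(node, seq: str) -> None:
        for child in node.child_nodes():
            label = child.taxon.label if child.taxon else child.label
            bl = child.edge.length or 0.0
            child_seq = evolve(seq, bl, omega_for(label))
            if child.is_leaf():
                tips.append(
                    SequenceRecord(
                        id=label, sequence=child_seq,
                        description="simulated CDS",
                    )
                )
            else:
                walk(child, child_seq)

    root_node = tree.dendropy_tree.seed_node
    if root_node.is_leaf():
        raise InputError("tree must have at least two leaves")
    walk(root_node, root)
    order = {lbl: i for i, lbl in enumerate(tree.leaf_labels())}
    tips.sort(key=lambda r: order[r.id])
    return tips


def make_expression_matrix(config: SimulationConfig):
    """Lognormal TPM matrix (genes × samples) plus winter/spring labels.

    Values are i.i.d. lognormal(``tpm_log_mean``, ``tpm_log_sd``) per gene ×
    sample; winter columns are multiplied by ``group_multiplier``.
    Returns ``(DataFrame, dict sample_id → 'winter'|'spring')``.
    """
    import pandas as pd

    rng = _rng(config.seed, "expression")
    genes = [f"RBCS{i + 1}" for i in range(config.n_family_genes)]
    winter = [f"winter_{i + 1}" for i in range(config.n_winter)]
    spring = [f"spring_{i + 1}" for i in range(config.n_spring)]
    samples = winter + spring
    values = rng.lognormal(
        mean=config.tpm_log_mean,
        sigma=config.tpm_log_sd,
        size=(len(genes), len(samples)),
    )
    values[:, : len(winter)] *= config.group_multiplier
    df = pd.DataFrame(values, index=genes, columns=samples)
    groups = {s: "winter" for s in winter} | {s: "spring" for s in spring}
    return df, groups


def make_toy_complex(
    pair_distances: dict[int, float], n_far_residues: int = 2
) -> list[AtomRecord]:
    """Two-chain toy structure with planted small/large-subunit contacts.

    Chain "L" (large subunit) is a row of CA atoms 5 Å apart.  For each
    ``residue_index → distance`` entry, one chain-"S" atom is placed exactly
    that distance from its nearest L atom.  ``n_far_residues`` additional S
    residues sit ≥ 10 Å from every L atom.
    """
    for res, d in pair_distances.items():
        if d <= 0:
            raise InputError(f"residue {res}: distance must be > 0 (got {d})")
    atoms: list[AtomRecord] = []
    n_large = max(4, len(pair_distances))
    for i in range(n_large):
        atoms.append(
            AtomRecord(chain_id="L", residue_index=i + 1, residue_name="GLY",
                       atom_name="CA", element="C",
                       x=5.0 * i, y=0.0, z=0.0)
        )
    for k, (res, d) in enumerate(sorted(pair_distances.items())):
        # directly above L atom k: nearest L atom is (5k, 0, 0) at distance d
        atoms.append(
            AtomRecord(chain_id="S", residue_index=res, residue_name="ALA",
                       atom_name="CA", element="C",
                       x=5.0 * k, y=0.0, z=float(d))
        )
    used = set(pair_distances)
    far_index = 900
    for j in range(n_far_residues):
        while far_index in used:
            far_index += 1
        atoms.append(
            AtomRecord(chain_id="S", residue_index=far_index,
                       residue_name="SER", atom_name="CA", element="C",
                       x=0.0, y=50.0 + 10.0 * j, z=0.0)
        )
        far_index += 1
    return atoms
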