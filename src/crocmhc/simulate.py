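"""Synthetic clone-amplicon datasets with known truth.

The generator emulates the statistical structure the analyses assume:
codon sequences evolved along a two-family species tree under an
NY98-style model with a per-site omega profile (elevated at configured
PBR columns), trans-species retention of identical ancestral alleles,
diploid individuals over one alpha locus and two (or more) beta loci,
pseudogenising stop codons or single-base deletions, PCR point errors,
and single-crossover chimeric clones.  Every planted feature is recorded
in TruthTables, and ground-truth TSP clusters are recomputed from the
final allele set so truth and emitted data can never disagree.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

from .codons import (SENSE_CODONS, codon_indices, indices_to_seq,
                     ny98_rate_matrix, transition_probabilities, translate_codon)
from .phylo import TreeNode, parse_newick
from .seq_model import CloneRead, SpeciesMeta

_FAMILY_GENERA = {
    "A": ("Crocodylus", "Crocodilidae"),
    "B": ("Caiman", "Alligatoridae"),
}


@dataclass
class SimConfig:
    n_species: int = 20
    species_tree: str | None = None          # newick; generated when None
    n_beta_loci: int = 2
    alpha_codons: int = 57                   # 171 nt
    beta_codons: int = 86                    # 258 nt
    pbr_columns: tuple[int, ...] = (9, 11, 13, 26, 28, 30, 32, 37, 38, 47, 56)
    omega_background: float = 0.2
    omega_pbr: float = 5.0
    kappa: float = 2.0
    allele_divergence: float = 0.02          # expected subs/codon within species
    #: redraw within-species alleles until they sit at least this many nt
    #: apart, so distinct true alleles are not confusable with PCR-error
    #: copies under the <3 bp redundancy rule
    min_allele_spacing_nt: int = 4
    retention_rate: float = 0.3              # trans-species allele copying
    pseudogenization_rate: float = 0.0
    clones_min: int = 4
    clones_max: int = 6
    pcr_error_rate: float = 0.0              # per nt per clone
    chimera_rate: float = 0.0                # per clone
    #: heterozygous genotypes + round-robin template sampling, so every
    #: pool allele is observable in every individual (exactness tests)
    balanced_clones: bool = False
    seed: int = 0

    def __post_init__(self):
        for rate in (self.retention_rate, self.pseudogenization_rate,
                     self.pcr_error_rate, self.chimera_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.clones_min < 1 or self.clones_max < self.clones_min:
            raise ValueError("bad clone count range")
        if self.n_species < 2:
            raise ValueError("need >= 2 species")


@dataclass
class TruthTables:
    #: (species_prefix, individual_id, exon_target) -> set of template seqs
    true_variants: dict = field(default_factory=dict)
    #: clone_id -> (parent_seq_1, parent_seq_2, breakpoint_nt)
    true_chimeras: dict = field(default_factory=dict)
    #: (species_prefix, exon_target, locus, allele) -> (lesion, codon_site)
    true_pseudogenes: dict = field(default_factory=dict)
    #: dataset -> list of (aa_seq, frozenset of species prefixes)
    true_tsps: dict = field(default_factory=dict)
    #: dataset -> per-codon omega array
    omega_profile: dict = field(default_factory=dict)
    #: (species_prefix, exon_target, locus, allele) -> sequence
    alleles: dict = field(default_factory=dict)
    taxonomy: dict = field(default_factory=dict)


def make_species_tree(n_species: int, rng: np.random.Generator,
                      depth: float = 0.3) -> tuple[TreeNode, list[str]]:
    """Balanced two-clade species tree with exponential branch lengths.

    Leaves are labelled sp01..spNN; the first half forms family A, the
    second family B.  Branch lengths are expected substitutions/codon.
    """
    names = [f"sp{i + 1:02d}" for i in range(n_species)]

    def grow(members: list[str], scale: float) -> TreeNode:
        if len(members) == 1:
            return TreeNode(name=members[0])
        split = max(1, len(members) // 2)
        left = grow(members[:split], scale / 1.5)
        right = grow(members[split:], scale / 1.5)
        bl = float(rng.exponential(scale))
        br = float(rng.exponential(scale))
        return TreeNode(children=[(left, bl), (right, br)])

    half = n_species // 2
    fam_a = grow(names[:half], depth / 2)
    fam_b = grow(names[half:], depth / 2)
    root = TreeNode(children=[(fam_a, depth), (fam_b, depth)])
    return root, names


def _prefix_for(index: int) -> str:
    letters = string.ascii_lowercase
    a, b, c = index // 676, (index // 26) % 26, index % 26
    return ("S" + letters[a] + letters[b] + letters[c]).capitalize()


def default_taxonomy(names: list[str]) -> dict[str, SpeciesMeta]:
    """SpeciesMeta per simulated species; first half family A."""
    half = len(names) // 2
    out = {}
    for i, nm in enumerate(names):
        genus, _ = _FAMILY_GENERA["A" if i < half else "B"]
        prefix = _prefix_for(i)
        out[nm] = SpeciesMeta(common_name=nm, scientific_name=f"Simulus {nm}",
                              genus=genus, gene_prefix=prefix)
    return out


def omega_profile(n_codons: int, pbr_columns, background: float,
                  elevated: float) -> np.ndarray:
    prof = np.full(n_codons, background)
    for c in pbr_columns:
        if 1 <= c <= n_codons:
            prof[c - 1] = elevated
    return prof


def evolve_codon_sequences(tree: TreeNode, omega: np.ndarray, kappa: float,
                           rng: np.random.Generator,
                           root_seq: np.ndarray | None = None
                           ) -> dict[str, np.ndarray]:
    """Simulate codon sequences (index arrays) down a tree.

    Per-site rate matrices are normalised so branch lengths are expected
    substitutions per codon at that site's omega.
    """
    n_codons = len(omega)
    if root_seq is None:
        root_seq = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    groups: dict[float, np.ndarray] = {}
    for w in np.unique(omega):
        groups[float(w)] = np.flatnonzero(omega == w)
    q_by_omega = {w: ny98_rate_matrix(kappa, w, normalise=True) for w in groups}
    leaves: dict[str, np.ndarray] = {}

    def descend(node: TreeNode, seq: np.ndarray) -> None:
        if node.is_leaf:
            leaves[node.name] = seq
            return
        for child, bl in node.children:
            child_seq = seq.copy()
            if bl > 0:
                for w, sites in groups.items():
                    p = transition_probabilities(q_by_omega[w], bl)
                    cum = np.cumsum(p, axis=1)
                    u = rng.random(len(sites))
                    rows = cum[child_seq[sites]]
                    child_seq[sites] = (rows < u[:, None]).sum(axis=1)
            descend(child, child_seq)

    descend(tree, root_seq.copy())
    return leaves


def _nt_distance(a: np.ndarray, b: np.ndarray) -> int:
    return sum(
        x != y
        for i, j in zip(a, b)
        for x, y in zip(SENSE_CODONS[i], SENSE_CODONS[j])
    )


def _mutate_codons(seq: np.ndarray, q_norm_by_omega: dict, groups: dict,
                   t: float, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    for w, sites in groups.items():
        p = transition_probabilities(q_norm_by_omega[w], t)
        cum = np.cumsum(p, axis=1)
        u = rng.random(len(sites))
        rows = cum[out[sites]]
        out[sites] = (rows < u[:, None]).sum(axis=1)
    return out


def _apply_pcr_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for pos in hits:
        current = chars[pos]
        options = [b for b in "ACGT" if b != current]
        chars[pos] = options[rng.integers(0, 3)]
    return "".join(chars)


def simulate_dataset(config: SimConfig):
    """Generate (clone reads, truth) for one alpha and n beta loci.

    Returns (list[CloneRead], TruthTables, taxonomy dict keyed by prefix).
    """
    from .clone_validation import reverse_complement

    rng = np.random.default_rng(config.seed)
    if config.species_tree is not None:
        tree = parse_newick(config.species_tree)
        names = sorted(tree.leaves())
    else:
        tree, names = make_species_tree(config.n_species, rng)
    taxonomy_by_name = default_taxonomy(names)
    taxonomy = {m.gene_prefix: m for m in taxonomy_by_name.values()}
    truth = TruthTables(taxonomy=taxonomy)

    targets = [("IIa_ex2", 1, config.alpha_codons)]
    targets += [("IIb_ex3", config.n_beta_loci, config.beta_codons)]

    half = len(names) // 2
    families = {nm: ("A" if i < half else "B") for i, nm in enumerate(names)}

    reads: list[CloneRead] = []
    for exon_target, n_loci, n_codons in targets:
        prof = omega_profile(n_codons, config.pbr_columns,
                             config.omega_background, config.omega_pbr)
        truth.omega_profile[exon_target] = prof
        groups = {float(w): np.flatnonzero(prof == w) for w in np.unique(prof)}
        q_norm = {w: ny98_rate_matrix(config.kappa, w, normalise=True)
                  for w in groups}
        # per-locus allele pools (2 alleles per species per locus)
        pools: dict[tuple[str, int], dict[str, list[np.ndarray]]] = {}
        ancestral: dict[int, np.ndarray] = {}
        for locus in range(n_loci):
            root = rng.integers(0, len(SENSE_CODONS), size=n_codons)
            ancestral[locus] = root
            leaves = evolve_codon_sequences(tree, prof, config.kappa, rng,
                                            root_seq=root)
            per_species = {}
            for nm in names:
                # trans-species retention: allele 0 is the exact ancestral
                # allele in retained species, the species' own otherwise
                if rng.random() < config.retention_rate:
                    base = ancestral[locus].copy()
                else:
                    base = leaves[nm]
                for _ in range(50):
                    allele2 = _mutate_codons(leaves[nm], q_norm, groups,
                                             config.allele_divergence, rng)
                    if _nt_distance(allele2, base) >= config.min_allele_spacing_nt:
                        break
                per_species[nm] = [base, allele2]
            pools[(exon_target, locus)] = per_species
        # pseudogenisation on allele 1 (never the retained allele 0)
        allele_seqs: dict[tuple[str, int, int], str] = {}
        for locus in range(n_loci):
            per_species = pools[(exon_target, locus)]
            for nm in names:
                prefix = taxonomy_by_name[nm].gene_prefix
                for a, allele in enumerate(per_species[nm]):
                    seq = indices_to_seq(allele)
                    if a == 1 and rng.random() < config.pseudogenization_rate:
                        site = int(rng.integers(2, n_codons))  # 1-based codon
                        if rng.random() < 0.5:
                            seq = seq[: 3 * (site - 1)] + "TAA" + seq[3 * site:]
                            lesion = ("stop_codon", site)
                        else:
                            cut = 3 * (site - 1) + int(rng.integers(0, 3))
                            seq = seq[:cut] + seq[cut + 1:]
                            lesion = ("deletion", site)
                        truth.true_pseudogenes[(prefix, exon_target, locus, a)] = lesion
                    allele_seqs[(nm, locus, a)] = seq
                    truth.alleles[(prefix, exon_target, locus, a)] = seq

        # ground-truth TSPs from the final allele set
        by_aa: dict[str, set[str]] = {}
        for (nm, locus, a), seq in allele_seqs.items():
            aa = _translate(seq)
            by_aa.setdefault(aa, set()).add(taxonomy_by_name[nm].gene_prefix)
        truth.true_tsps[exon_target] = sorted(
            (aa, frozenset(sps)) for aa, sps in by_aa.items() if len(sps) >= 2
        )

        # clone sampling: two individuals per species, one PCR per target
        for nm in names:
            prefix = taxonomy_by_name[nm].gene_prefix
            for indiv_no in (1, 2):
                indiv = f"i{indiv_no}"
                templates = []
                for locus in range(n_loci):
                    pool = [allele_seqs[(nm, locus, a)] for a in range(2)]
                    if config.balanced_clones:
                        g = np.array([0, 1])   # heterozygous for the pool
                    else:
                        g = rng.integers(0, 2, size=2)  # two draws w/ replacement
                    templates.extend(pool[k] for k in g)
                truth.true_variants[(prefix, indiv, exon_target)] = sorted(
                    set(templates))
                pcr_id = f"{prefix}-{indiv}-{exon_target}"
                n_clones = int(rng.integers(config.clones_min,
                                            config.clones_max + 1))
                for c in range(1, n_clones + 1):
                    clone_id = f"{prefix}_{indiv}_{exon_target}_c{c}"
                    distinct = sorted(set(templates))
                    if (len(distinct) >= 2 and len(distinct[0]) == len(distinct[-1])
                            and rng.random() < config.chimera_rate):
                        pa, pb = rng.choice(len(distinct), size=2, replace=False)
                        s1, s2 = distinct[pa], distinct[pb]
                        L = len(s1)
                        k = int(rng.integers(10, L - 10))
                        seq = s1[:k] + s2[k:]
                        if seq in (s1, s2):    # breakpoint outside the
                            seq = s1           # divergent region: no chimera
                        else:
                            truth.true_chimeras[clone_id] = (s1, s2, k)
                    elif config.balanced_clones:
                        seq = distinct[(c - 1) % len(distinct)]
                    else:
                        seq = templates[int(rng.integers(0, len(templates)))]
                    seq = _apply_pcr_errors(seq, config.pcr_error_rate, rng)
                    meta = taxonomy_by_name[nm]
                    reads.append(CloneRead(
                        read_id=clone_id + "/F", species=meta,
                        individual_id=indiv, pcr_id=pcr_id,
                        direction="forward", seq=seq, exon_target=exon_target))
                    reads.append(CloneRead(
                        read_id=clone_id + "/R", species=meta,
                        individual_id=indiv, pcr_id=pcr_id,
                        direction="reverse", seq=reverse_complement(seq),
                        exon_target=exon_target))
    return reads, truth, taxonomy


def _translate(seq: str) -> str:
    aa = []
    for k in range(0, len(seq) - 2, 3):
        aa.append(translate_codon(seq[k : k + 3]))
    return "".join(aa)


def write_dataset(reads, truth: TruthTables, taxonomy, out_dir) -> dict:
    """Write clone FASTA + metadata TSV + taxonomy + truth JSON."""
    import json
    from pathlib import Path

    from .seq_model import write_clone_reads, write_taxonomy

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_clone_reads(reads, out / "reads.fasta", out / "meta.tsv")
    write_taxonomy(taxonomy, out / "taxonomy.tsv")
    truth_json = {
        "true_variants": {"|".join(k): v for k, v in truth.true_variants.items()},
        "true_chimeras": truth.true_chimeras,
        "true_pseudogenes": {"|".join(map(str, k)): v
                             for k, v in truth.true_pseudogenes.items()},
        "true_tsps": {ds: [[aa, sorted(sps)] for aa, sps in clusters]
                      for ds, clusters in truth.true_tsps.items()},
        "omega_profile": {ds: list(map(float, prof))
                          for ds, prof in truth.omega_profile.items()},
    }
    (out / "truth.json").write_text(json.dumps(truth_json, indent=1, sort_keys=True))
    return {"reads": str(out / "reads.fasta"), "meta": str(out / "meta.tsv"),
            "taxonomy": str(out / "taxonomy.tsv"), "truth": str(out / "truth.json")}
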