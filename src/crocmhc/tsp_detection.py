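"""Trans-species polymorphism detection and genus tallies.

A TSP cluster is one distinct translated sequence observed in two or
more species of a dataset.  Identity is exact string equality over the
full translated amplicon, including 'X' and '*' characters, so
pseudogenes participate.  Labels are global across datasets: datasets
are processed in a fixed order and clusters within a dataset are
numbered by descending species count, then lexicographic sequence.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

from .seq_model import EXON_TARGETS, SpeciesMeta

GENUS_ABBREV = {
    "Crocodylus": "Cro", "Mecistops": "Mec", "Osteolaemus": "Ost",
    "Alligator": "All", "Caiman": "Cai", "Paleosuchus": "Pal",
    "Melanosuchus": "Mel",
}


@dataclass(frozen=True)
class TspCluster:
    label: str
    aa_seq: str
    members: tuple[str, ...]       # variant names
    species_set: frozenset
    dataset: str

    def __post_init__(self):
        if len(self.species_set) < 2:
            raise ValueError("a TSP cluster needs >= 2 species")


def detect_tsps(translated: dict[str, dict[str, dict[str, str]]]
                ) -> list[TspCluster]:
    """Cluster identical translations shared by >=2 species.

    ``translated`` maps dataset -> species prefix -> variant name -> aa
    sequence.  Returns clusters labelled TSP1.. in dataset order
    (IIa_ex2, IIa_ex3, IIb_ex3), then by descending species count, then
    lexicographic aa sequence; invariant to input ordering.
    """
    unknown = set(translated) - set(EXON_TARGETS)
    if unknown:
        raise ValueError(f"unknown datasets: {sorted(unknown)}")
    clusters: list[TspCluster] = []
    counter = 1
    for dataset in EXON_TARGETS:
        per_aa: dict[str, list[tuple[str, str]]] = defaultdict(list)
        for prefix, variants in translated.get(dataset, {}).items():
            for name, aa in variants.items():
                per_aa[aa].append((prefix, name))
        shared = []
        for aa, members in per_aa.items():
            species = frozenset(p for p, _ in members)
            if len(species) >= 2:
                shared.append((aa, members, species))
        shared.sort(key=lambda item: (-len(item[2]), item[0]))
        for aa, members, species in shared:
            clusters.append(TspCluster(
                label=f"TSP{counter}", aa_seq=aa,
                members=tuple(sorted(n for _, n in members)),
                species_set=species, dataset=dataset,
            ))
            counter += 1
    return clusters


def tally_tsps(clusters: list[TspCluster],
               taxonomy: dict[str, SpeciesMeta]) -> pd.DataFrame:
    """Genus-count matrix, one row per TSP cluster.

    Columns: dataset, TSP, N, one column per genus abbreviation, members.
    Genus counts sum to N per row.
    """
    genera = list(GENUS_ABBREV.values())
    rows = []
    for cluster in clusters:
        counts = dict.fromkeys(genera, 0)
        for prefix in cluster.species_set:
            if prefix not in taxonomy:
                raise KeyError(f"species prefix {prefix!r} missing from taxonomy")
            genus = taxonomy[prefix].genus
            abbrev = GENUS_ABBREV.get(genus)
            if abbrev is None:
                raise KeyError(f"genus {genus!r} has no tally column")
            counts[abbrev] += 1
        row = {"dataset": cluster.dataset, "TSP": cluster.label,
               "N": len(cluster.species_set)}
        row.update(counts)
        row["members"] = ",".join(cluster.members)
        rows.append(row)
    df = pd.DataFrame(rows, columns=["dataset", "TSP", "N", *genera, "members"])
    if len(df) and not (df[genera].sum(axis=1) == df["N"]).all():
        raise AssertionError("genus counts do not sum to N")
    return df


def translations_from_variants(variants_by_dataset: dict[str, list],
                               phase: int = 0) -> dict:
    """Convenience: build the detect_tsps input from ValidatedVariant lists."""
    from .orf_annotation import translate_exon

    out: dict[str, dict[str, dict[str, str]]] = {}
    for dataset, variants in variants_by_dataset.items():
        per_species: dict[str, dict[str, str]] = defaultdict(dict)
        for v in variants:
            prefix = v.name.split("-")[0]
            per_species[prefix][v.name] = translate_exon(v.seq, phase)
        out[dataset] = dict(per_species)
    return out
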