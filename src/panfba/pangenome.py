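"""Pan-genome construction by iterative augmented-genome merging.

The pan-genome of a clade is built by repeatedly merging a subject genome
into an augmented reference: subject genes that share an ortholog cluster
with a gene already present are dropped, the rest are added.  Because the
resulting gene count depends on the merge order, the pan-genome is built
for several (by default all) genome orderings and the one with the most
genes is kept.

Gene families are the connected components of the ortholog-cluster graph
(transitive linkage).  A family is **core** when present in every genome,
**unique** when present in exactly one, and **dispensable** otherwise;
the three categories partition the families by definition, and the core
set is independent of the merge order.

Ortholog clusters are an input (e.g. OrthoMCL output re-shaped as a TSV);
a reciprocal-best-hit + single-linkage fallback clusterer over an
all-vs-all similarity table is provided as plumbing.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

CATEGORIES = ("core", "dispensable", "unique")
FUNCTION_CLASSES = ("metabolic", "non-metabolic", "hypothetical")

GenePair = tuple[str, str]  # (genome_id, gene_id)


class PangenomeInputError(ValueError):
    """Raised for inconsistent gene/cluster inputs."""


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    locus_tag: str = ""
    annotation: str = ""
    function_class: str | None = None


@dataclass
class GenomeGeneSet:
    """A (possibly augmented) set of genes.

    ``members`` maps ``(source_genome_id, gene_id)`` to the gene record, so
    provenance survives augmentation; ``constituents`` lists the genomes
    merged in, in order.
    """

    genome_id: str
    constituents: tuple[str, ...]
    members: dict[GenePair, GeneRecord]

    @classmethod
    def from_records(
        cls, genome_id: str, records: Iterable[GeneRecord]
    ) -> "GenomeGeneSet":
        if not genome_id:
            raise PangenomeInputError("genome_id must be non-empty")
        members: dict[GenePair, GeneRecord] = {}
        for rec in records:
            key = (genome_id, rec.gene_id)
            if key in members:
                raise PangenomeInputError(
                    f"duplicate gene id {rec.gene_id!r} in genome {genome_id!r}"
                )
            members[key] = rec
        return cls(genome_id=genome_id, constituents=(genome_id,), members=members)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class OrthologClusterSet:
    """Sets of putative orthologs as ``(genome_id, gene_id)`` pair sets."""

    clusters: list[frozenset]

    def __post_init__(self):
        seen: dict[GenePair, int] = {}
        for i, cluster in enumerate(self.clusters):
            self.clusters[i] = frozenset(tuple(p) for p in cluster)
            for pair in self.clusters[i]:
                if pair in seen:
                    raise PangenomeInputError(
                        f"gene {pair} appears in more than one cluster"
                    )
                seen[pair] = i

    def validate_against(self, genomes: Sequence[GenomeGeneSet]) -> None:
        known: set[GenePair] = set()
        for g in genomes:
            known |= set(g.members)
        for cluster in self.clusters:
            for pair in cluster:
                if pair not in known:
                    raise PangenomeInputError(
                        f"cluster references unknown gene {pair}"
                    )

    def clusters_of(self) -> dict[GenePair, frozenset]:
        index: dict[GenePair, frozenset] = {}
        for cluster in self.clusters:
            for pair in cluster:
                index[pair] = cluster
        return index


@dataclass
class Family:
    """One gene family: a connected component of the cluster graph."""

    family_id: str
    members: frozenset  # of GenePair
    pan_representatives: frozenset  # members that made it into the pan gene set
    presence: frozenset  # genome ids with at least one member
    category: str = ""
    function_class: str = ""

    @staticmethod
    def canonical_id(members: frozenset) -> str:
        # canonical member-set hash so families are comparable across orders
        text = ";".join(sorted(f"{g}:{x}" for g, x in members))
        return hashlib.sha1(text.encode()).hexdigest()[:12]


@dataclass
class PanGenome:
    families: list[Family]
    genome_ids: tuple[str, ...]
    construction_order: tuple[str, ...]

    @property
    def n_genes(self) -> int:
        return sum(len(f.pan_representatives) for f in self.families)

    def core_families(self) -> set[str]:
        return {f.family_id for f in self.families if f.category == "core"}

    def counts(self, by: str = "family") -> dict[str, int]:
        if by not in ("family", "gene"):
            raise ValueError("by must be 'family' or 'gene'")
        out = {c: 0 for c in CATEGORIES}
        for fam in self.families:
            out[fam.category] += 1 if by == "family" else len(fam.pan_representatives)
        return out


def merge_augment(
    base: GenomeGeneSet,
    subject: GenomeGeneSet,
    clusters: OrthologClusterSet,
    _cluster_index: dict | None = None,
) -> GenomeGeneSet:
    """Merge a subject genome into an augmented base.

    The result keeps all base genes and adds every subject gene that (a) is
    not already a member and (b) shares no ortholog cluster with a base
    gene.  Merging a genome already contained in the base adds nothing.
    """
    index = _cluster_index if _cluster_index is not None else clusters.clusters_of()
    members = dict(base.members)
    base_pairs = set(base.members)
    for pair, rec in subject.members.items():
        if pair in base_pairs:
            continue
        cluster = index.get(pair)
        if cluster is not None and any(p in base_pairs for p in cluster):
            continue
        members[pair] = rec
    constituents = base.constituents
    if subject.genome_id not in constituents:
        constituents = constituents + (subject.genome_id,)
    return GenomeGeneSet(
        genome_id="+".join(constituents), constituents=constituents, members=members
    )


def _families_from_clusters(
    genomes: Sequence[GenomeGeneSet],
    clusters: OrthologClusterSet,
    pan_members: set[GenePair],
) -> list[Family]:
    graph = nx.Graph()
    for genome in genomes:
        graph.add_nodes_from(genome.members)
    for cluster in clusters.clusters:
        pairs = sorted(cluster)
        graph.add_nodes_from(pairs)
        for a, b in zip(pairs, pairs[1:]):
            graph.add_edge(a, b)
    families = []
    for component in nx.connected_components(graph):
        members = frozenset(component)
        presence = frozenset(g for g, _ in members)
        reps = frozenset(p for p in members if p in pan_members)
        families.append(
            Family(
                family_id=Family.canonical_id(members),
                members=members,
                pan_representatives=reps,
                presence=presence,
            )
        )
    families.sort(key=lambda f: f.family_id)
    return families


def _categorize(families: list[Family], genome_ids: Sequence[str]) -> None:
    all_genomes = frozenset(genome_ids)
    for fam in families:
        if fam.presence == all_genomes:
            fam.category = "core"
        elif len(fam.presence) == 1:
            fam.category = "unique"
        else:
            fam.category = "dispensable"


def build_pangenome(
    genomes: Sequence[GenomeGeneSet],
    clusters: OrthologClusterSet,
) -> PanGenome:
    """Iterative augmented-genome merging over the given genome order."""
    if len(genomes) < 2:
        raise PangenomeInputError("need at least two genomes")
    ids = [g.genome_id for g in genomes]
    if len(set(ids)) != len(ids):
        raise PangenomeInputError(f"duplicate genome ids in {ids}")
    clusters.validate_against(genomes)
    index = clusters.clusters_of()

    augmented = genomes[0]
    for subject in genomes[1:]:
        augmented = merge_augment(augmented, subject, clusters, _cluster_index=index)

    families = _families_from_clusters(genomes, clusters, set(augmented.members))
    _categorize(families, ids)
    return PanGenome(
        families=families,
        genome_ids=tuple(sorted(ids)),
        construction_order=tuple(ids),
    )


def best_pangenome(
    genomes: Sequence[GenomeGeneSet],
    clusters: OrthologClusterSet,
    orders: Sequence[Sequence[str]] | None = None,
) -> PanGenome:
    """Build one pan-genome per genome ordering and keep the largest.

    The pan gene count depends on the merge order; the pan-genome with the
    highest gene count is returned (capturing the fullest gene repertoire),
    with ties broken by the lexicographically smallest order so the result
    is deterministic.  ``orders`` defaults to all permutations.
    """
    by_id = {g.genome_id: g for g in genomes}
    if len(by_id) != len(list(genomes)):
        raise PangenomeInputError("duplicate genome ids")
    if orders is None:
        orders = sorted(itertools.permutations(sorted(by_id)))
    if not orders:
        raise PangenomeInputError("orders must be non-empty")

    best: PanGenome | None = None
    best_key: tuple | None = None
    for order in orders:
        pan = build_pangenome([by_id[g] for g in order], clusters)
        # maximize gene count; among equals prefer the smallest order
        key = (-pan.n_genes, tuple(order))
        if best_key is None or key < best_key:
            best, best_key = pan, key
    assert best is not None
    return best


def partition_categories(pan: PanGenome, by: str = "family") -> tuple[int, int, int]:
    """(core, dispensable, unique) counts; they always sum to the total."""
    counts = pan.counts(by=by)
    return counts["core"], counts["dispensable"], counts["unique"]


@dataclass
class FunctionRules:
    """Annotation-keyword rules plus explicit per-gene overrides.

    ``keywords`` is an ordered list of (substring, class) pairs matched
    case-insensitively against member annotations; ``explicit`` maps gene
    ids to classes and wins over keywords.  Families matching nothing (or
    without any annotation) default to ``hypothetical``.
    """

    keywords: list[tuple[str, str]] = field(default_factory=list)
    explicit: dict[str, str] = field(default_factory=dict)
    default: str = "hypothetical"

    def __post_init__(self):
        for _, cls in self.keywords:
            if cls not in FUNCTION_CLASSES:
                raise PangenomeInputError(f"invalid function class {cls!r}")
        for gene, cls in self.explicit.items():
            if cls not in FUNCTION_CLASSES:
                raise PangenomeInputError(
                    f"invalid function class {cls!r} for gene {gene!r}"
                )
        if self.default not in FUNCTION_CLASSES:
            raise PangenomeInputError(f"invalid default class {self.default!r}")


def classify_functions(
    pan: PanGenome,
    rules: FunctionRules,
    annotations: dict[GenePair, str] | None = None,
) -> PanGenome:
    """Label every family metabolic / non-metabolic / hypothetical.

    ``annotations`` maps gene pairs to annotation text (taken from the
    gene tables); when omitted, only explicit rules and the default apply.
    """
    annotations = annotations or {}
    labelled = []
    for fam in pan.families:
        cls = None
        for genome, gene in sorted(fam.members):
            if gene in rules.explicit:
                cls = rules.explicit[gene]
                break
        if cls is None:
            texts = [
                annotations.get(pair, "").lower() for pair in sorted(fam.members)
            ]
            for keyword, keyword_cls in rules.keywords:
                if any(keyword.lower() in t for t in texts if t):
                    cls = keyword_cls
                    break
        labelled.append(replace(fam, function_class=cls or rules.default))
    return PanGenome(
        families=labelled,
        genome_ids=pan.genome_ids,
        construction_order=pan.construction_order,
    )


# -- fallback clustering -----------------------------------------------------

def rbh_clusters(
    similarities: pd.DataFrame | Iterable[tuple],
    threshold: float = 30.0,
) -> OrthologClusterSet:
    """Reciprocal-best-hit + single-linkage clusters from all-vs-all hits.

    ``similarities`` rows are ``(query_genome, query_gene, subject_genome,
    subject_gene, percent_identity)``.  For each gene and each other
    genome the best hit is kept; a reciprocal best pair at ≥ ``threshold``
    identity becomes an edge, and connected components become clusters.
    The default threshold (30% identity) mirrors the usual
    moderate-confidence homology cut.
    """
    if isinstance(similarities, pd.DataFrame):
        rows = similarities.itertuples(index=False)
    else:
        rows = iter(similarities)
    best: dict[tuple[GenePair, str], tuple[float, GenePair]] = {}
    for qg, qx, sg, sx, ident in rows:
        if qg == sg:
            continue
        ident = float(ident)
        key = ((qg, qx), sg)
        if key not in best or ident > best[key][0]:
            best[key] = (ident, (sg, sx))
    graph = nx.Graph()
    for (query, sg), (ident, subject) in best.items():
        if ident < threshold:
            continue
        back = best.get((subject, query[0]))
        if back is not None and back[1] == query and back[0] >= threshold:
            graph.add_edge(query, subject)
    components = [frozenset(c) for c in nx.connected_components(graph) if len(c) > 1]
    return OrthologClusterSet(sorted(components, key=lambda c: sorted(c)))


# -- TSV / JSON interfaces ---------------------------------------------------

_GENE_COLUMNS = ["genome_id", "gene_id", "locus_tag", "annotation"]
_CLUSTER_COLUMNS = ["cluster_id", "genome_id", "gene_id"]


def _read_tsv(path, columns: list[str]) -> pd.DataFrame:
    head = pd.read_csv(path, sep="\t", header=None, nrows=1, dtype=str)
    has_header = list(head.iloc[0].str.lower()) == columns
    df = pd.read_csv(
        path, sep="\t", header=0 if has_header else None, dtype=str,
        names=None if has_header else columns, keep_default_na=False,
    )
    if has_header:
        df.columns = [c.lower() for c in df.columns]
    if list(df.columns)[: len(columns)] != columns:
        raise PangenomeInputError(
            f"expected columns {columns}, found {list(df.columns)}"
        )
    return df


def read_gene_tables(path) -> list[GenomeGeneSet]:
    """Gene table TSV: genome_id, gene_id, locus_tag, annotation."""
    df = _read_tsv(path, _GENE_COLUMNS)
    genomes = []
    for genome_id, group in df.groupby("genome_id", sort=True):
        records = [
            GeneRecord(
                gene_id=row.gene_id, locus_tag=row.locus_tag,
                annotation=row.annotation,
            )
            for row in group.itertuples(index=False)
        ]
        genomes.append(GenomeGeneSet.from_records(str(genome_id), records))
    return genomes


def read_clusters_tsv(path) -> OrthologClusterSet:
    """Cluster TSV: cluster_id, genome_id, gene_id (one member per line)."""
    df = _read_tsv(path, _CLUSTER_COLUMNS)
    grouped: dict[str, set[GenePair]] = {}
    for row in df.itertuples(index=False):
        grouped.setdefault(row.cluster_id, set()).add((row.genome_id, row.gene_id))
    return OrthologClusterSet([frozenset(v) for _, v in sorted(grouped.items())])


def write_pangenome_tsv(pan: PanGenome, path) -> None:
    rows = []
    for fam in pan.families:
        presence = "".join(
            "1" if g in fam.presence else "0" for g in pan.genome_ids
        )
        rows.append({
            "family_id": fam.family_id,
            "presence": presence,
            "n_genomes": len(fam.presence),
            "category": fam.category,
            "function_class": fam.function_class or "",
            "members": ";".join(f"{g}:{x}" for g, x in sorted(fam.members)),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def summary_json(pan: PanGenome) -> str:
    return json.dumps(
        {
            "genomes": list(pan.genome_ids),
            "construction_order": list(pan.construction_order),
            "n_genes": pan.n_genes,
            "n_families": len(pan.families),
            "families_by_category": pan.counts(by="family"),
            "genes_by_category": pan.counts(by="gene"),
        },
        indent=1,
    )
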