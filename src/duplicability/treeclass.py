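"""Gene-family tree pruning and singleton/duplicable classification.

A gene family is represented by a rooted, branch-length-annotated gene tree
whose leaves are labelled ``species|gene_id`` over the six study species
(human, chimp, gorilla, orangutan, gibbon, macaque).  Families are classified
by the genetic-distance rule: a great-ape species carrying >=2 gene copies is
taken to harbour a *recent* (post-speciation) duplication when the patristic
distance A between its two most closely related paralogs is strictly smaller
than the distances B and C from each paralog to the gibbon ortholog.  If no
duplicated species passes this test, an ancestral duplication followed by
lineage-specific loss cannot be ruled out and the family is excluded.

Families with multiple macaque and/or gibbon copies indicate pre-primate
duplications; where the topology decomposes cleanly into subtrees each with
exactly one macaque and one gibbon gene, the subtrees are retained as
separate families.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy

SPECIES: tuple[str, ...] = ("human", "chimp", "gorilla", "orangutan", "gibbon", "macaque")
GREAT_APES: tuple[str, ...] = ("human", "chimp", "gorilla", "orangutan")
OUTGROUPS: tuple[str, ...] = ("gibbon", "macaque")

LABEL_SEP = "|"


def make_label(species: str, gene_id: str) -> str:
    return f"{species}{LABEL_SEP}{gene_id}"


def split_label(label: str) -> tuple[str, str]:
    species, _, gene = label.partition(LABEL_SEP)
    return species, gene


@dataclass
class GeneFamilyTree:
    """A species-labelled gene tree (dendropy container underneath)."""

    tree: dendropy.Tree
    family_id: str = "family"

    @classmethod
    def from_newick(cls, newick: str, family_id: str = "family") -> "GeneFamilyTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
        tree.is_rooted = True  # trees are treated as rooted as given
        return cls(tree=tree, family_id=family_id)

    def to_newick(self) -> str:
        s = self.tree.as_string(schema="newick", suppress_rooting=True,
                                unquoted_underscores=True)
        return s.strip() + ("\n" if not s.endswith("\n") else "")

    # -- leaf bookkeeping ---------------------------------------------------

    def leaf_labels(self) -> list[str]:
        return sorted(lf.taxon.label for lf in self.tree.leaf_node_iter())

    def leaf_species(self) -> list[str]:
        return [split_label(lbl)[0] for lbl in self.leaf_labels()]

    def genes_of(self, species: str) -> list[str]:
        return sorted(lbl for lbl in self.leaf_labels()
                      if split_label(lbl)[0] == species)

    # -- distances ----------------------------------------------------------

    def patristic(self, label_a: str, label_b: str) -> float:
        """Sum of branch lengths on the path between two leaves."""
        if label_a == label_b:
            return 0.0
        pdm = self.tree.phylogenetic_distance_matrix()
        ta = self.tree.taxon_namespace.get_taxon(label_a)
        tb = self.tree.taxon_namespace.get_taxon(label_b)
        if ta is None or tb is None:
            raise KeyError(f"leaf not found: {label_a!r} / {label_b!r}")
        return float(pdm.patristic_distance(ta, tb))

    def clone(self) -> "GeneFamilyTree":
        return GeneFamilyTree(tree=self.tree.clone(depth=1), family_id=self.family_id)


@dataclass
class DuplicationEvidence:
    """Distances backing a recent-duplication call for one species."""

    species: str
    paralog_pair: tuple[str, str]
    A: float  # paralog-paralog
    B: float  # paralog 1 - gibbon
    C: float  # paralog 2 - gibbon
    verdict: str  # "recent" | "ancestral_ambiguous"


@dataclass
class ClassificationOutcome:
    label: str  # singleton | duplicable | excluded_missing | excluded_ambiguous_loss | split
    evidence: list[DuplicationEvidence] = field(default_factory=list)
    subtrees: list[GeneFamilyTree] = field(default_factory=list)
    reason: str = ""

    @property
    def duplicated_species(self) -> list[str]:
        return [e.species for e in self.evidence if e.verdict == "recent"]


def prune_to_species(gft: GeneFamilyTree, species_set=SPECIES) -> GeneFamilyTree:
    """Drop leaves outside ``species_set``; collapse unary nodes, summing
    branch lengths, so patristic distances among retained leaves are kept."""
    keep = [lf.taxon for lf in gft.tree.leaf_node_iter()
            if split_label(lf.taxon.label)[0] in species_set]
    if not keep:
        raise ValueError("no leaves left after pruning (excluded_missing)")
    out = gft.clone()
    out.tree.retain_taxa([out.tree.taxon_namespace.get_taxon(t.label) for t in keep])
    # a root with a single child survives retain_taxa: fold it away
    root = out.tree.seed_node
    while len(root.child_nodes()) == 1 and not root.is_leaf():
        child = root.child_nodes()[0]
        out.tree.seed_node = child
        child.parent_node = None
        child.edge.length = None
        root = child
    out.tree.purge_taxon_namespace()
    return out


def copy_counts(gft: GeneFamilyTree) -> dict[str, int]:
    counts = {sp: 0 for sp in SPECIES}
    for sp in gft.leaf_species():
        counts[sp] = counts.get(sp, 0) + 1
    return counts


def duplication_timing_test(A: float, B: float, C: float) -> str:
    """Recent iff the inter-paralog distance is strictly below both
    paralog-to-gibbon distances; ties count as ancestral_ambiguous."""
    if min(A, B, C) < 0:
        raise ValueError("patristic distances must be >= 0")
    return "recent" if (A < B and A < C) else "ancestral_ambiguous"


def closest_paralog_pair(gft: GeneFamilyTree, species: str) -> tuple[str, str, float]:
    """The species' two most closely related paralogs (min patristic
    distance; exact ties broken lexicographically by label)."""
    genes = gft.genes_of(species)
    if len(genes) < 2:
        raise ValueError(f"{species} has <2 copies")
    best = None
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            d = gft.patristic(genes[i], genes[j])
            key = (d, genes[i], genes[j])
            if best is None or key < best:
                best = key
    return best[1], best[2], best[0]


def _species_evidence(gft: GeneFamilyTree, species: str) -> DuplicationEvidence:
    gibbon_genes = gft.genes_of("gibbon")
    if not gibbon_genes:
        raise ValueError("gibbon leaf required for the timing test")
    g = gibbon_genes[0]
    p1, p2, A = closest_paralog_pair(gft, species)
    B = gft.patristic(p1, g)
    C = gft.patristic(p2, g)
    return DuplicationEvidence(species=species, paralog_pair=(p1, p2),
                               A=A, B=B, C=C,
                               verdict=duplication_timing_test(A, B, C))


def split_ancestral_subtrees(gft: GeneFamilyTree) -> list[GeneFamilyTree]:
    """Decompose a multi-macaque/gibbon tree into maximal clean subtrees.

    A clean subtree contains exactly one macaque and one gibbon gene.  If the
    maximal clean clades do not jointly cover every macaque and gibbon leaf
    (interleaved topology), the family is not decomposable and an empty list
    is returned (caller flags it excluded_ambiguous_loss).
    """
    counts = copy_counts(gft)
    if counts["macaque"] <= 1 and counts["gibbon"] <= 1:
        return [gft]

    def clade_counts(node):
        mac = gib = 0
        for lf in node.leaf_iter():
            sp = split_label(lf.taxon.label)[0]
            if sp == "macaque":
                mac += 1
            elif sp == "gibbon":
                gib += 1
        return mac, gib

    clean_roots = []
    for node in gft.tree.preorder_node_iter():
        if any(node is r or _is_descendant(node, r) for r in clean_roots):
            continue
        mac, gib = clade_counts(node)
        if mac == 1 and gib == 1:
            clean_roots.append(node)

    covered_mac = sum(clade_counts(r)[0] for r in clean_roots)
    covered_gib = sum(clade_counts(r)[1] for r in clean_roots)
    if covered_mac != counts["macaque"] or covered_gib != counts["gibbon"] or len(clean_roots) < 2:
        return []

    subtrees = []
    for k, node in enumerate(clean_roots):
        labels = sorted(lf.taxon.label for lf in node.leaf_iter())
        sub = gft.clone()
        sub.tree.retain_taxa([sub.tree.taxon_namespace.get_taxon(l) for l in labels])
        sub.tree.purge_taxon_namespace()
        sub.family_id = f"{gft.family_id}.sub{k + 1}"
        subtrees.append(prune_to_species(sub))
    return subtrees


def _is_descendant(node, ancestor) -> bool:
    p = node.parent_node
    while p is not None:
        if p is ancestor:
            return True
        p = p.parent_node
    return False


def classify_family(gft: GeneFamilyTree) -> ClassificationOutcome:
    """Full QC + classification of a pruned gene-family tree."""
    counts = copy_counts(gft)
    if counts["macaque"] == 0 or counts["gibbon"] == 0:
        return ClassificationOutcome(label="excluded_missing",
                                     reason="no macaque or gibbon ortholog")
    if counts["macaque"] > 1 or counts["gibbon"] > 1:
        subtrees = split_ancestral_subtrees(gft)
        if not subtrees or (len(subtrees) == 1 and subtrees[0] is gft):
            return ClassificationOutcome(
                label="excluded_ambiguous_loss",
                reason="multiple macaque/gibbon copies, not cleanly decomposable")
        return ClassificationOutcome(label="split", subtrees=subtrees)
    if all(counts[sp] <= 1 for sp in GREAT_APES):
        # single macaque/gibbon copy and no great-ape duplication
        return ClassificationOutcome(label="singleton")

    evidence = [_species_evidence(gft, sp) for sp in GREAT_APES if counts[sp] >= 2]
    if any(e.verdict == "recent" for e in evidence):
        return ClassificationOutcome(label="duplicable", evidence=evidence)
    return ClassificationOutcome(label="excluded_ambiguous_loss", evidence=evidence,
                                 reason="all duplicated species consistent with "
                                        "ancestral duplication + loss")


def classification_report(outcomes: dict[str, ClassificationOutcome]):
    """Tabulate outcomes as TSV-ready records (family_id, label, dup_species, A, B, C)."""
    rows = []
    for fam_id in sorted(outcomes):
        oc = outcomes[fam_id]
        if oc.evidence:
            for ev in oc.evidence:
                rows.append(dict(family_id=fam_id, label=oc.label, dup_species=ev.species,
                                 A=ev.A, B=ev.B, C=ev.C))
        else:
            rows.append(dict(family_id=fam_id, label=oc.label, dup_species="",
                             A=float("nan"), B=float("nan"), C=float("nan")))
    return rows
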