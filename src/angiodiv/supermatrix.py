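"""Sequence filtering and greedy composite-terminal selection.

One placeholder terminal represents each genus in a genus-level
supermatrix. Its markers may legitimately come from more than one
congeneric species (a *composite terminal*), but the species set should
be as small as possible while covering as many genetic markers as
possible, and for non-monophyletic genera only species from a single
genus-pure core clade may contribute.

The selection procedure, per genus:

1. sort markers by ascending number of species holding them;
2. for the first uncovered marker, add the candidate species covering
   the most markers overall (ties: highest total relative sequence
   length, then alphabetical species id);
3. repeat until every available marker is covered;
4. for each marker, keep the longest sequence among the chosen species.

Relative sequence length is a sequence's base-pair count divided by the
genus-wide maximum for that marker.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .trees import DatedTree

__all__ = [
    "SequenceRecord", "MonophylyReport", "SelectionResult",
    "dedupe_longest", "relative_length", "classify_monophyly", "greedy_select",
]


@dataclass(frozen=True)
class SequenceRecord:
    species: str
    genus: str
    marker: str
    length: int
    published: bool = True
    date: str = ""  # any orderable timestamp, e.g. ISO "2015-06-01"
    accession: str = ""

    def __post_init__(self):
        if self.length < 1:
            raise ValueError(f"sequence length must be >= 1, got {self.length}")


@dataclass
class MonophylyReport:
    genus: str
    status: str  # "monophyletic" | "non-monophyletic"
    clades: list[frozenset] = field(default_factory=list)
    core: frozenset = frozenset()


@dataclass
class SelectionResult:
    genus: str
    species_used: frozenset
    per_marker: dict[str, SequenceRecord]

    @property
    def composite(self) -> bool:
        return len(self.species_used) > 1


def dedupe_longest(records: list[SequenceRecord]) -> list[SequenceRecord]:
    """Keep one record per (species, marker).

    Precedence: longest; among equal lengths the published record; among
    those the most recently dated. Output order follows first appearance
    of each (species, marker) pair.
    """
    best: dict[tuple, SequenceRecord] = {}
    for rec in records:
        key = (rec.species, rec.marker)
        cur = best.get(key)
        if cur is None or _dedupe_rank(rec) > _dedupe_rank(cur):
            best[key] = rec
    return list(best.values())


def _dedupe_rank(rec: SequenceRecord):
    return (rec.length, rec.published, rec.date)


def relative_length(record: SequenceRecord, genus_marker_max: int) -> float:
    """Length of a sequence divided by the genus-wide maximum for its marker."""
    if genus_marker_max <= 0:
        raise ValueError(
            f"marker {record.marker!r} has no sequences in genus {record.genus!r} "
            "(maximum length 0)"
        )
    if record.length > genus_marker_max:
        raise ValueError("record length exceeds the stated genus maximum")
    return record.length / genus_marker_max


def classify_monophyly(reference_tree: DatedTree,
                       genus_map: dict[str, str],
                       record_counts: dict[str, int] | None = None,
                       ) -> list[MonophylyReport]:
    """Assess genus monophyly on a species-level reference tree.

    A genus is monophyletic iff the MRCA of its tips contains no tips of
    other genera. Otherwise its tips decompose into maximal genus-pure
    clades, and the largest one is selected as the *core* used to
    represent the genus (ties: most deduped sequence records via
    ``record_counts``, then alphabetical first tip). Para- and polyphyly
    are not distinguished: both report status "non-monophyletic" and use
    the same largest-clade rule.
    """
    tips_by_genus: dict[str, list] = defaultdict(list)
    for sp, genus in genus_map.items():
        try:
            tips_by_genus[genus].append(reference_tree.tip_node(sp))
        except KeyError:
            raise ValueError(f"species {sp!r} not found in the reference tree")

    reports = []
    for genus in sorted(tips_by_genus):
        nodes = tips_by_genus[genus]
        labels = frozenset(nd.taxon.label for nd in nodes)
        if len(nodes) == 1:
            reports.append(MonophylyReport(genus, "monophyletic",
                                           [labels], labels))
            continue
        mrca = reference_tree.mrca(labels)
        mrca_tips = frozenset(lf.taxon.label for lf in mrca.leaf_iter())
        if mrca_tips == labels:
            reports.append(MonophylyReport(genus, "monophyletic",
                                           [labels], labels))
            continue
        clades = _maximal_pure_clades(reference_tree, labels)
        core = max(clades, key=lambda c: _core_rank(c, record_counts))
        reports.append(MonophylyReport(genus, "non-monophyletic", clades, core))
    return reports


def _core_rank(clade: frozenset, record_counts: dict[str, int] | None):
    n_rec = sum((record_counts or {}).get(sp, 0) for sp in clade)
    # larger clade, then more records, then lexicographically smallest first tip
    return (len(clade), n_rec, _NegStr(min(clade)))


class _NegStr(str):
    """String with reversed ordering, so max() prefers the alphabetically first."""
    def __lt__(self, other):
        return str.__gt__(self, other)
    def __gt__(self, other):
        return str.__lt__(self, other)


def _maximal_pure_clades(tree: DatedTree, genus_tips: frozenset) -> list[frozenset]:
    """Maximal subtrees whose tips all belong to the genus."""
    clades = []

    def visit(node) -> frozenset | None:
        """Return the node's leaf set if pure, else None (emitting children)."""
        if node.is_leaf():
            lab = node.taxon.label
            return frozenset([lab]) if lab in genus_tips else None
        child_sets = [visit(ch) for ch in node.child_nodes()]
        if all(cs is not None for cs in child_sets):
            return frozenset().union(*child_sets)
        for cs in child_sets:
            if cs is not None:
                clades.append(cs)
        return None

    root_set = visit(tree.tree.seed_node)
    if root_set is not None:
        clades.append(root_set)
    return clades


def greedy_select(genus_records: list[SequenceRecord],
                  core_species: frozenset | None = None) -> SelectionResult:
    """Choose a minimal species set maximizing marker coverage for one genus.

    ``genus_records`` must be deduped records of a single genus; if
    ``core_species`` is given (the monophyly core), records outside it
    are ignored. See the module docstring for the four selection steps.
    """
    if core_species is not None:
        genus_records = [r for r in genus_records if r.species in core_species]
    if not genus_records:
        raise ValueError("no sequence records to select from")
    genus = genus_records[0].genus

    by_marker: dict[str, list[SequenceRecord]] = defaultdict(list)
    by_species: dict[str, dict[str, SequenceRecord]] = defaultdict(dict)
    for rec in genus_records:
        by_marker[rec.marker].append(rec)
        by_species[rec.species][rec.marker] = rec
    marker_max = {m: max(r.length for r in recs) for m, recs in by_marker.items()}

    def total_relative_length(sp: str) -> float:
        return sum(rec.length / marker_max[m]
                   for m, rec in by_species[sp].items())

    # step 1: ascending species count, alphabetical within ties
    ordered = sorted(by_marker, key=lambda m: (len({r.species for r in by_marker[m]}), m))

    species_used: set[str] = set()

    def covered() -> set[str]:
        return {m for sp in species_used for m in by_species[sp]}

    for marker in ordered:
        if marker in covered():
            continue
        candidates = {r.species for r in by_marker[marker]}
        best = max(candidates,
                   key=lambda sp: (len(by_species[sp]),
                                   total_relative_length(sp),
                                   _NegStr(sp)))
        species_used.add(best)

    per_marker = {}
    for marker in ordered:
        pool = [r for r in by_marker[marker] if r.species in species_used]
        if pool:
            per_marker[marker] = max(pool, key=_dedupe_rank)
    return SelectionResult(genus, frozenset(species_used), per_marker)
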