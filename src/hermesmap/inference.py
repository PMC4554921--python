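"""Parsimony protein inference: the minimal set of protein groups.

Shotgun identifications are redundant: homologous sequences, truncated or
partial entries and splice variants all match overlapping peptide sets. The
procedure here collapses that redundancy into the smallest set of protein
groups whose members explain every confidently matched peptide:

1. proteins with identical matched-peptide sets merge into one group;
2. a protein whose peptide set is a strict subset of another protein's set is
   absorbed as a member of that protein's group;
3. the remaining groups are selected by greedy set cover — repeatedly retain
   the group explaining the most not-yet-covered peptides until every peptide
   is covered.

After selection each peptide is re-labelled *unique* (contained only in one
retained group's members) or *shared* (two or more retained groups), the
distinction that drives shared-spectrum apportionment downstream.

All tie-breaks are lexicographic on accession so the result is independent of
database order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

from .errors import ConsistencyError, ParameterError

__all__ = [
    "PeptideProteinMap",
    "ProteinGroup",
    "map_peptides",
    "infer_minimal_set",
    "classify_peptides",
]

#: peptide -> accessions of database proteins containing it
PeptideProteinMap = dict[str, frozenset]


@dataclass(frozen=True)
class ProteinGroup:
    """A retained identification: representative, members and its evidence."""

    representative: str
    members: frozenset
    unique_peptides: frozenset
    shared_peptides: frozenset

    @property
    def peptides(self) -> frozenset:
        return self.unique_peptides | self.shared_peptides


def map_peptides(
    peptides: Iterable[str],
    database: Sequence[tuple[str, str]],
    il_equivalent: bool = False,
) -> tuple[PeptideProteinMap, set]:
    """Exact-substring peptide-to-protein map plus unmatched orphans.

    With ``il_equivalent`` isoleucine and leucine are conflated before
    matching (search engines often cannot distinguish them); accessions are
    reported unchanged. Orphan peptides (matching no database protein) are
    returned separately: they are reported and excluded downstream.
    """
    if not database:
        raise ParameterError("empty database")

    def canon(s: str) -> str:
        return s.replace("I", "L") if il_equivalent else s

    seqs = [(acc, canon(seq)) for acc, seq in database]
    pmap: PeptideProteinMap = {}
    orphans: set = set()
    for pep in sorted(set(peptides)):
        hit = frozenset(acc for acc, seq in seqs if canon(pep) in seq)
        if hit:
            pmap[pep] = hit
        else:
            orphans.add(pep)
    return pmap, orphans


def infer_minimal_set(pmap: PeptideProteinMap) -> list[ProteinGroup]:
    """Minimal set of protein groups explaining every mapped peptide.

    Returns retained groups sorted by representative accession. Cover-redundant
    proteins (whose peptides are all explained by retained groups without
    being a subset of any single one) are dropped, not absorbed.
    """
    if not pmap:
        raise ParameterError("empty peptide-protein map")

    by_protein: dict[str, set] = {}
    for pep, accs in pmap.items():
        for acc in accs:
            by_protein.setdefault(acc, set()).add(pep)

    # phase 1: merge identical matched-peptide sets
    by_set: dict[frozenset, set] = {}
    for acc, peps in by_protein.items():
        by_set.setdefault(frozenset(peps), set()).add(acc)
    # candidate: (peptide set, member accessions)
    cands = {min(members): (peps, set(members)) for peps, members in by_set.items()}

    # phase 2: absorb strict subsets, smallest peptide set first
    active = dict(cands)
    for rep in sorted(active, key=lambda r: (len(active[r][0]), r)):
        peps, members = active[rep]
        supers = [
            r2
            for r2, (p2, _) in active.items()
            if r2 != rep and peps < p2
        ]
        if supers:
            # every superset shares all of this protein's peptides; prefer
            # the largest peptide set, then the smallest accession
            target = min(supers, key=lambda r2: (-len(active[r2][0]), r2))
            active[target][1].update(members)
            del active[rep]

    # phase 3: greedy set cover over the remaining candidate groups
    uncovered = set(pmap)
    retained: dict[str, set] = {}
    while uncovered:
        best = min(
            active,
            key=lambda r: (-len(active[r][0] & uncovered), -len(active[r][0]), r),
        )
        gain = active[best][0] & uncovered
        if not gain:
            raise ConsistencyError("uncoverable peptides remain")  # pragma: no cover
        retained[best] = active[best][1]
        uncovered -= gain
        del active[best]

    # re-label unique/shared with respect to retained groups only
    member_of = {
        acc: rep for rep, members in retained.items() for acc in members
    }
    unique: dict[str, set] = {rep: set() for rep in retained}
    shared: dict[str, set] = {rep: set() for rep in retained}
    for pep, accs in pmap.items():
        owners = {member_of[acc] for acc in accs if acc in member_of}
        if len(owners) == 1:
            unique[next(iter(owners))].add(pep)
        else:
            for rep in owners:
                shared[rep].add(pep)

    groups = [
        ProteinGroup(
            representative=rep,
            members=frozenset(retained[rep]),
            unique_peptides=frozenset(unique[rep]),
            shared_peptides=frozenset(shared[rep]),
        )
        for rep in sorted(retained)
    ]
    for g in groups:
        if not g.peptides:  # pragma: no cover - cover construction forbids it
            raise ConsistencyError(f"group {g.representative} has no peptides")
    return groups


def classify_peptides(
    groups: Sequence[ProteinGroup],
) -> dict[str, tuple[str, Union[str, frozenset]]]:
    """Peptide -> ("unique", representative) or ("shared", representatives).

    The classification covers exactly the peptides carried by the groups and
    is consistent with their unique/shared evidence sets.
    """
    out: dict[str, tuple[str, Union[str, frozenset]]] = {}
    shared_owners: dict[str, set] = {}
    for g in groups:
        for pep in g.unique_peptides:
            if pep in out or pep in shared_owners:
                raise ConsistencyError(f"peptide {pep} labelled twice")
            out[pep] = ("unique", g.representative)
        for pep in g.shared_peptides:
            if pep in out:
                raise ConsistencyError(f"peptide {pep} labelled twice")
            shared_owners.setdefault(pep, set()).add(g.representative)
    for pep, owners in shared_owners.items():
        if len(owners) < 2:
            raise ConsistencyError(f"shared peptide {pep} has a single owner")
        out[pep] = ("shared", frozenset(owners))
    return out
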