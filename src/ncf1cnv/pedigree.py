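"""Haplotype deduction and Mendelian-consistency checking for the NCF1 CNV.

Each chromosome 7 carries an arm configuration of duplicons — a
:class:`Haplotype` of per-chromosome (b, n, c) counts — and a diploid genome
is the component-wise sum of its two haplotypes (a :class:`HaploGenotype`).
Copy-number calls only observe the sum, but transmission through a pedigree
constrains the decomposition: every non-founder inherits exactly one
haplotype from each parent (no recombination within the ~300-kb locus, no
de novo events by default).

The solver enumerates per-individual candidate haplogenotypes from the
called trios, prunes them by iterated parent/child compatibility
(Lange–Goradia-style genotype elimination) and then certifies each surviving
candidate by exhibiting a consistent global assignment via backtracking.
``deduce_haplogenotypes`` therefore returns, per individual, exactly the
haplogenotypes that occur in at least one globally consistent assignment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

from .errors import PedigreeError
from .psv_model import CopyNumberTrio

__all__ = [
    "Haplotype",
    "HaploGenotype",
    "Individual",
    "Pedigree",
    "TransmissionReport",
    "enumerate_haplotype_pairs",
    "check_transmission",
    "deduce_haplogenotypes",
    "parsimonious_assignment",
]

DEFAULT_ARM_BOUND = 3  # largest per-arm duplicon count considered


class Haplotype(NamedTuple):
    """Duplicon counts (b, n, c) on a single chromosome."""

    b: int
    n: int
    c: int

    def __add__(self, other: "Haplotype") -> CopyNumberTrio:  # type: ignore[override]
        return CopyNumberTrio(self.b + other.b, self.n + other.n, self.c + other.c)


#: Unordered pair of haplotypes, canonically sorted.
HaploGenotype = tuple[Haplotype, Haplotype]


def _pair(h1: Haplotype, h2: Haplotype) -> HaploGenotype:
    return (h1, h2) if h1 <= h2 else (h2, h1)


class Individual(NamedTuple):
    iid: str
    father: str | None  # None = founder
    mother: str | None
    sex: str = "0"
    family: str = "FAM"


class Pedigree:
    """Acyclic pedigree; parents either both present in the pedigree or both None."""

    def __init__(self, individuals: Iterable[Individual]):
        self.members: dict[str, Individual] = {}
        for ind in individuals:
            if ind.iid in self.members:
                raise PedigreeError(f"duplicate individual id {ind.iid!r}")
            self.members[ind.iid] = ind
        for ind in self.members.values():
            for pid in (ind.father, ind.mother):
                if pid is not None and pid not in self.members:
                    raise PedigreeError(f"{ind.iid}: parent {pid!r} not in pedigree")
            if (ind.father is None) != (ind.mother is None):
                raise PedigreeError(f"{ind.iid}: exactly one parent recorded")
        self._order = self._toposort()

    def _toposort(self) -> list[str]:
        seen: dict[str, int] = {}  # 0=visiting, 1=done
        order: list[str] = []

        def visit(iid: str, stack: tuple[str, ...]) -> None:
            if seen.get(iid) == 1:
                return
            if seen.get(iid) == 0:
                raise PedigreeError(f"pedigree cycle through {iid!r}")
            seen[iid] = 0
            ind = self.members[iid]
            for pid in (ind.father, ind.mother):
                if pid is not None:
                    visit(pid, stack + (iid,))
            seen[iid] = 1
            order.append(iid)

        for iid in self.members:
            visit(iid, ())
        return order

    @property
    def order(self) -> list[str]:
        """Member ids, parents before children."""
        return list(self._order)

    def founders(self) -> list[str]:
        return [i for i in self._order if self.members[i].father is None]

    def __len__(self) -> int:
        return len(self.members)


def enumerate_haplotype_pairs(
    trio: CopyNumberTrio, bound: int = DEFAULT_ARM_BOUND
) -> set[HaploGenotype]:
    """All unordered pairs of bounded haplotypes summing to ``trio``.

    A count exceeding 2*bound on any arm legitimately yields the empty set.
    """
    pairs: set[HaploGenotype] = set()
    for b1 in range(max(0, trio.b - bound), min(bound, trio.b) + 1):
        for n1 in range(max(0, trio.n - bound), min(bound, trio.n) + 1):
            for c1 in range(max(0, trio.c - bound), min(bound, trio.c) + 1):
                h1 = Haplotype(b1, n1, c1)
                h2 = Haplotype(trio.b - b1, trio.n - n1, trio.c - c1)
                pairs.add(_pair(h1, h2))
    return pairs


def _all_bounded_pairs(bound: int) -> set[HaploGenotype]:
    haps = [Haplotype(*t) for t in itertools.product(range(bound + 1), repeat=3)]
    return {_pair(h1, h2) for h1, h2 in itertools.combinations_with_replacement(haps, 2)}


@dataclass
class TransmissionReport:
    """Outcome of a Mendelian-consistency check over one pedigree."""

    consistent: bool
    witness: dict[str, HaploGenotype] | None
    #: individuals whose genotypes had to be dropped to restore consistency
    #: (empty when consistent; None when no small dropping set was found)
    inconsistent_individuals: list[str] | None = None
    dropped: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.consistent


def _candidate_sets(
    ped: Pedigree,
    trios: Mapping[str, CopyNumberTrio | None],
    bound: int,
    ignore: frozenset[str] = frozenset(),
) -> dict[str, set[HaploGenotype]]:
    universe = _all_bounded_pairs(bound)
    cands: dict[str, set[HaploGenotype]] = {}
    for iid in ped.order:
        trio = trios.get(iid)
        if trio is None or iid in ignore:
            cands[iid] = set(universe)
        else:
            cands[iid] = enumerate_haplotype_pairs(trio, bound)
    return cands


def _child_compatible(child: HaploGenotype, fp: HaploGenotype, mp: HaploGenotype) -> bool:
    h1, h2 = child
    return (h1 in fp and h2 in mp) or (h2 in fp and h1 in mp)


def _prune(ped: Pedigree, cands: dict[str, set[HaploGenotype]]) -> bool:
    """Iterated local (nuclear-family) consistency; returns False on wipe-out."""
    changed = True
    while changed:
        changed = False
        for iid in ped.order:
            ind = ped.members[iid]
            if ind.father is None:
                continue
            fs, ms, cs = cands[ind.father], cands[ind.mother], cands[iid]
            keep_c = {g for g in cs if any(
                _child_compatible(g, fp, mp) for fp in fs for mp in ms)}
            keep_f = {fp for fp in fs if any(
                _child_compatible(g, fp, mp) for g in cs for mp in ms)}
            keep_m = {mp for mp in ms if any(
                _child_compatible(g, fp, mp) for g in cs for fp in keep_f)}
            for key, new in ((iid, keep_c), (ind.father, keep_f), (ind.mother, keep_m)):
                if len(new) != len(cands[key]):
                    cands[key] = new
                    changed = True
            if not keep_c or not keep_f or not keep_m:
                return False
    return all(cands.values())


def _search(
    ped: Pedigree,
    cands: dict[str, set[HaploGenotype]],
    fixed: dict[str, HaploGenotype],
) -> dict[str, HaploGenotype] | None:
    """Backtracking over topological order; returns one witness or None."""
    order = [i for i in ped.order if i not in fixed]
    assign: dict[str, HaploGenotype] = dict(fixed)

    def ok(iid: str, g: HaploGenotype) -> bool:
        ind = ped.members[iid]
        if ind.father is not None and ind.father in assign and ind.mother in assign:
            if not _child_compatible(g, assign[ind.father], assign[ind.mother]):
                return False
        # children already assigned constrain this parent
        for cid, cind in ped.members.items():
            if cid in assign and iid in (cind.father, cind.mother):
                fa, mo = cind.father, cind.mother
                fp = g if fa == iid else assign.get(fa)
                mp = g if mo == iid else assign.get(mo)
                if fp is not None and mp is not None and not _child_compatible(
                    assign[cid], fp, mp
                ):
                    return False
        return True

    def rec(k: int) -> bool:
        if k == len(order):
            return True
        iid = order[k]
        for g in sorted(cands[iid]):
            if ok(iid, g):
                assign[iid] = g
                if rec(k + 1):
                    return True
                del assign[iid]
        return False

    for iid, g in fixed.items():
        if not ok(iid, g):
            return None
    return dict(assign) if rec(0) else None


def check_transmission(
    ped: Pedigree,
    trios: Mapping[str, CopyNumberTrio | None],
    bound: int = DEFAULT_ARM_BOUND,
    max_drop: int = 0,
) -> TransmissionReport:
    """Check that the called trios admit a Mendelian haplotype assignment.

    Returns a witness assignment when consistent.  When inconsistent and
    ``max_drop`` > 0, searches for a smallest set of <= max_drop individuals
    whose genotypes, treated as missing, restore consistency; that set is
    reported, never silently repaired.
    """
    for iid in trios:
        if iid not in ped.members:
            raise PedigreeError(f"trio given for unknown individual {iid!r}")

    def attempt(ignore: frozenset[str]):
        cands = _candidate_sets(ped, trios, bound, ignore)
        if not _prune(ped, cands):
            return None
        return _search(ped, cands, {})

    witness = attempt(frozenset())
    if witness is not None:
        return TransmissionReport(True, witness)

    typed = [i for i in ped.order if trios.get(i) is not None]
    for k in range(1, max_drop + 1):
        for drop in itertools.combinations(typed, k):
            w = attempt(frozenset(drop))
            if w is not None:
                return TransmissionReport(
                    False, None, inconsistent_individuals=list(drop), dropped=list(drop)
                )
    # localise blame without dropping: individuals wiped out by propagation
    cands = _candidate_sets(ped, trios, bound)
    _prune(ped, cands)
    empty = [i for i in ped.order if not cands[i]] or None
    return TransmissionReport(False, None, inconsistent_individuals=empty)


def _enumerate_assignments(
    ped: Pedigree,
    cands: dict[str, set[HaploGenotype]],
    limit: int = 200_000,
):
    """Yield every globally consistent assignment (backtracking, capped)."""
    order = ped.order
    assign: dict[str, HaploGenotype] = {}
    count = 0

    def compatible(iid: str, g: HaploGenotype) -> bool:
        ind = ped.members[iid]
        if ind.father is not None and ind.father in assign and ind.mother in assign:
            return _child_compatible(g, assign[ind.father], assign[ind.mother])
        return True

    def rec(k: int):
        nonlocal count
        if k == len(order):
            count += 1
            if count > limit:
                raise PedigreeError(f"assignment enumeration exceeded {limit} solutions")
            yield dict(assign)
            return
        iid = order[k]
        for g in sorted(cands[iid]):
            if compatible(iid, g):
                assign[iid] = g
                yield from rec(k + 1)
                del assign[iid]

    yield from rec(0)


def parsimonious_assignment(
    ped: Pedigree,
    trios: Mapping[str, CopyNumberTrio | None],
    bound: int = DEFAULT_ARM_BOUND,
) -> dict[str, HaploGenotype] | None:
    """The consistent assignment using the fewest distinct haplotypes.

    Transmission constraints alone rarely pin down arm configurations (a
    constant 0:2:2 lineage is explained equally well by (0,1,1)+(0,1,1) and
    by (0,1,0)+(0,1,2) throughout); published pedigree arm diagrams reflect
    the most parsimonious choice.  Ties break deterministically on the
    sorted haplotype multiset.  Returns None when inconsistent.
    """
    cands = _candidate_sets(ped, trios, bound)
    if not _prune(ped, cands):
        return None
    best: tuple | None = None
    best_assign: dict[str, HaploGenotype] | None = None
    for assign in _enumerate_assignments(ped, cands):
        haps = sorted({h for pair in assign.values() for h in pair})
        key = (len(haps), tuple(haps), tuple(sorted(assign.items())))
        if best is None or key < best:
            best, best_assign = key, assign
    return best_assign


def deduce_haplogenotypes(
    ped: Pedigree,
    trios: Mapping[str, CopyNumberTrio | None],
    bound: int = DEFAULT_ARM_BOUND,
) -> tuple[dict[str, set[HaploGenotype]], TransmissionReport]:
    """Per-individual haplogenotypes surviving the pedigree constraints.

    For each individual, the returned set contains exactly those candidate
    pairs that participate in at least one globally consistent assignment;
    an inconsistent pedigree yields empty sets plus the failure report.
    """
    report = check_transmission(ped, trios, bound)
    if not report.consistent:
        return {iid: set() for iid in ped.order}, report

    cands = _candidate_sets(ped, trios, bound)
    _prune(ped, cands)
    surviving: dict[str, set[HaploGenotype]] = {}
    for iid in ped.order:
        keep: set[HaploGenotype] = set()
        for g in sorted(cands[iid]):
            if _search(ped, cands, {iid: g}) is not None:
                keep.add(g)
        surviving[iid] = keep
    return surviving, report
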