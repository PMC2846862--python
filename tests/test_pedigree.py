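"""Haplotype enumeration, Mendelian-consistency checking and deduction."""

import itertools

import pytest

from ncf1cnv import (
    CopyNumberTrio,
    Haplotype,
    Individual,
    Pedigree,
    check_transmission,
    deduce_haplogenotypes,
    enumerate_haplotype_pairs,
    parsimonious_assignment,
)
from ncf1cnv.errors import PedigreeError
from ncf1cnv.psv_model import CopyNumberTrio as Trio


def brute_pairs(trio, bound):
    """Independent oracle: filter all unordered bounded-haplotype pairs by sum."""
    haps = [Haplotype(*t) for t in itertools.product(range(bound + 1), repeat=3)]
    out = set()
    for h1, h2 in itertools.combinations_with_replacement(haps, 2):
        if (h1.b + h2.b, h1.n + h2.n, h1.c + h2.c) == trio.as_tuple():
            out.add((h1, h2) if h1 <= h2 else (h2, h1))
    return out


def brute_global_assignments(ped, trios, bound):
    """Oracle: enumerate every globally consistent assignment outright."""
    ids = ped.order
    cand = [sorted(brute_pairs(trios[i], bound)) for i in ids]
    solutions = []
    for combo in itertools.product(*cand):
        assign = dict(zip(ids, combo))
        ok = True
        for iid in ids:
            ind = ped.members[iid]
            if ind.father is None:
                continue
            g, fp, mp = assign[iid], assign[ind.father], assign[ind.mother]
            h1, h2 = g
            if not ((h1 in fp and h2 in mp) or (h2 in fp and h1 in mp)):
                ok = False
                break
        if ok:
            solutions.append(assign)
    return solutions


@pytest.mark.parametrize(
    "trio, bound",
    [((0, 2, 2), 3), ((0, 0, 0), 3), ((0, 2, 3), 3), ((1, 2, 3), 3), ((2, 2, 2), 2)],
)
def test_enumeration_matches_brute_force(trio, bound):
    t = Trio(*trio)
    assert enumerate_haplotype_pairs(t, bound) == brute_pairs(t, bound)


def test_enumeration_worked_examples():
    pairs = enumerate_haplotype_pairs(Trio(0, 2, 2), 3)
    assert (Haplotype(0, 1, 1), Haplotype(0, 1, 1)) in pairs
    assert enumerate_haplotype_pairs(Trio(0, 0, 0), 3) == {
        (Haplotype(0, 0, 0), Haplotype(0, 0, 0))
    }
    # arm count above 2*bound is legitimately unrepresentable
    assert enumerate_haplotype_pairs(Trio(7, 0, 0), 3) == set()


def _nuclear(children):
    inds = [Individual("f", None, None), Individual("m", None, None)]
    inds += [Individual(c, "f", "m") for c in children]
    return Pedigree(inds)


def test_mixed_lineages_consistent():
    """4:2 father x 2:2 mother: children may show either lineage's profile."""
    ped = _nuclear(["c1", "c2"])
    trios = {"f": Trio(1, 2, 3), "m": Trio(0, 2, 2),
             "c1": Trio(1, 2, 3), "c2": Trio(0, 2, 2)}
    # c1 needs a (1,1,2)-like haplotype from the father plus a maternal arm
    report = check_transmission(ped, trios)
    assert report.consistent
    # witness re-sums to the inputs and satisfies transmission
    for iid, (h1, h2) in report.witness.items():
        assert (h1 + h2) == trios[iid]
    for cid in ("c1", "c2"):
        h1, h2 = report.witness[cid]
        fp, mp = report.witness["f"], report.witness["m"]
        assert (h1 in fp and h2 in mp) or (h2 in fp and h1 in mp)


def test_child_exceeding_parental_haplotypes_is_inconsistent():
    ped = _nuclear(["c1"])
    trios = {"f": Trio(0, 2, 2), "m": Trio(0, 2, 2), "c1": Trio(5, 2, 5)}
    report = check_transmission(ped, trios)
    assert not report.consistent


def test_inconsistency_localised_by_dropping():
    ped = _nuclear(["c1", "c2"])
    trios = {"f": Trio(0, 2, 2), "m": Trio(0, 2, 2),
             "c1": Trio(0, 2, 2), "c2": Trio(4, 2, 4)}
    report = check_transmission(ped, trios, max_drop=1)
    assert not report.consistent
    assert report.inconsistent_individuals == ["c2"]


def test_constant_lineage_parsimonious_haplogenotype():
    """A three-generation 0:2:2 lineage: the balanced arm pair
    {(0,1,1),(0,1,1)} survives deduction everywhere and is the unique
    most-parsimonious (fewest distinct haplotypes) explanation.

    Transmission constraints alone cannot force uniqueness — the lineage is
    equally consistent with (0,1,0)+(0,1,2) throughout — so deduction keeps
    both and parsimony selects the published-style arms.
    """
    inds = [
        Individual("gf", None, None), Individual("gm", None, None),
        Individual("mo", "gf", "gm"), Individual("fa2", None, None),
        Individual("ch", "fa2", "mo"),
    ]
    ped = Pedigree(inds)
    trios = {i: Trio(0, 2, 2) for i in ped.order}
    deduced, report = deduce_haplogenotypes(ped, trios)
    assert report.consistent
    balanced = (Haplotype(0, 1, 1), Haplotype(0, 1, 1))
    unbalanced = (Haplotype(0, 1, 0), Haplotype(0, 1, 2))
    for iid in ped.order:
        assert balanced in deduced[iid]
        assert unbalanced in deduced[iid]
    best = parsimonious_assignment(ped, trios)
    assert best == {iid: balanced for iid in ped.order}


def test_deduction_matches_brute_force_oracle():
    """Per-individual surviving sets equal the oracle's union over all
    globally consistent assignments (nuclear family of 5, mixed lineages).

    The sib trios force the mother's arms to the unbalanced (0,1,0)+(0,1,2)
    decomposition, so deduction is strictly smaller than raw enumeration."""
    ped = _nuclear(["c1", "c2", "c3"])
    trios = {"f": Trio(1, 2, 3), "m": Trio(0, 2, 2),
             "c1": Trio(1, 2, 3), "c2": Trio(0, 2, 2), "c3": Trio(1, 2, 1)}
    bound = 2
    deduced, report = deduce_haplogenotypes(ped, trios, bound)
    assert report.consistent
    oracle = brute_global_assignments(ped, trios, bound)
    assert oracle
    expected = {i: {a[i] for a in oracle} for i in ped.order}
    assert deduced == expected


def test_member_without_ncf1b_needs_a_b_free_haplotype():
    """In a constant 1:2:3 family, a 0:2:3 member's pairs all lack NCF1B on
    one arm."""
    inds = [Individual("fa", None, None), Individual("mo", None, None),
            Individual("ch", "fa", "mo")]
    ped = Pedigree(inds)
    trios = {"fa": Trio(1, 2, 3), "mo": Trio(1, 2, 3), "ch": Trio(0, 2, 3)}
    deduced, report = deduce_haplogenotypes(ped, trios)
    assert report.consistent
    assert deduced["ch"]
    for h1, h2 in deduced["ch"]:
        assert h1.b == 0 and h2.b == 0


def test_untyped_founder_unconstrained_by_own_genotype():
    inds = [Individual("fa", None, None), Individual("mo", None, None),
            Individual("ch", "fa", "mo")]
    ped = Pedigree(inds)
    trios = {"fa": Trio(1, 2, 3), "mo": None, "ch": Trio(1, 2, 3)}
    report = check_transmission(ped, trios, bound=2)
    assert report.consistent


def test_malformed_pedigree_raises_before_search():
    with pytest.raises(PedigreeError):
        Pedigree([Individual("a", "ghost", "m"), Individual("m", None, None)])
    with pytest.raises(PedigreeError):
        Pedigree([Individual("a", "b", "m"), Individual("b", "a", "m"),
                  Individual("m", None, None)])
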