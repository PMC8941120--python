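import itertools

import numpy as np
import pytest

from thiopair import pairing as pr
from thiopair import synthfix as sf


# independent residue monoisotopic masses (typed from the standard table,
# not taken from the implementation's dependency)
ORACLE_RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
    "Pen": 131.04049,  # Cys + 2 CH2
}
ORACLE_WATER = 18.01056


class TestGrammar:
    def test_two_cys_peptide(self):
        sites = pr.parse_thiol_sequence("WGCGKG{3}CG")
        assert [(s.position, s.kind) for s in sites] == [
            (3, "CYS"), (9, "CYS"),
        ]

    def test_two_pen_peptide(self):
        sites = pr.parse_thiol_sequence("WG[Pen]GKG{3}[Pen]G")
        assert [(s.position, s.kind) for s in sites] == [
            (3, "PEN"), (9, "PEN"),
        ]

    def test_mixed_peptide(self):
        sites = pr.parse_thiol_sequence("WGCG{2}KG{2}CGKG{3}[Pen]GKG{3}CGW")
        kinds = [s.kind for s in sites]
        assert kinds == ["CYS", "CYS", "PEN", "CYS"]

    def test_underscore_synonym(self):
        assert pr.parse_sequence("G_3_C") == ["G", "G", "G", "C"]

    @pytest.mark.parametrize("bad", ["", "X{", "[Sec]", "A{0}", "{3}", "a!"])
    def test_errors(self, bad):
        with pytest.raises(ValueError):
            pr.parse_sequence(bad)


def brute_force_matchings(items):
    """All perfect matchings by explicit recursion (oracle)."""
    items = list(items)
    if not items:
        return [frozenset()]
    first, rest = items[0], items[1:]
    out = []
    for i, other in enumerate(rest):
        remaining = rest[:i] + rest[i + 1:]
        for m in brute_force_matchings(remaining):
            out.append(m | {frozenset({first, other})})
    return out


class TestEnumeration:
    def test_two_plus_two_gives_three_states(self):
        seqs = sf.model_peptide_sequences()
        mols = [
            pr.parse_thiol_sequence(seqs["peptide1"], 0),
            pr.parse_thiol_sequence(seqs["peptide2"], 1),
        ]
        states = pr.enumerate_pairing_states(mols)
        assert len(states) == 3
        topos = sorted(s.topology for s in states)
        assert topos == ["heterodimeric", "heterodimeric", "monomeric"]

    def test_six_sites_give_fifteen_states(self):
        seqs = sf.model_peptide_sequences()
        mols = [
            pr.parse_thiol_sequence(seqs["peptide3"], 0),
            pr.parse_thiol_sequence(seqs["peptide2"], 1),
        ]
        assert len(pr.enumerate_pairing_states(mols)) == 15

    @pytest.mark.parametrize("n", [1, 2, 3, 4, 5])
    def test_double_factorial_count(self, n):
        sites = [
            pr.ThiolSite(molecule=0, position=i + 1, kind="CYS")
            for i in range(2 * n)
        ]
        states = pr.enumerate_pairing_states([sites])
        expected = brute_force_matchings(range(2 * n))
        assert len(states) == len(expected)
        dfact = 1
        for k in range(2 * n - 1, 0, -2):
            dfact *= k
        assert len(states) == dfact

    def test_single_molecule_two_cys(self):
        sites = pr.parse_thiol_sequence("CGGC", 0)
        states = pr.enumerate_pairing_states([sites])
        assert len(states) == 1
        s = states[0]
        assert s.topology == "monomeric"
        assert s.n_cys_cys == 1

    def test_odd_total_forces_one_free_site(self):
        mols = [
            pr.parse_thiol_sequence("CGC", 0),
            pr.parse_thiol_sequence("[Pen]", 1),
        ]
        states = pr.enumerate_pairing_states(mols)
        assert all(s.n_free == 1 for s in states)
        assert len(states) == 3

    def test_counts_sum_invariant(self):
        seqs = sf.model_peptide_sequences()
        mols = [
            pr.parse_thiol_sequence(seqs["peptide3"], 0),
            pr.parse_thiol_sequence(seqs["peptide2"], 1),
        ]
        total = sum(len(m) for m in mols)
        for s in pr.enumerate_pairing_states(mols, allow_free=True):
            assert 2 * len(s.bonds) + s.n_free == total

    def test_allow_free_superset(self):
        mols = [pr.parse_thiol_sequence("CC", 0)]
        strict = pr.enumerate_pairing_states(mols)
        loose = pr.enumerate_pairing_states(mols, allow_free=True)
        assert len(strict) == 1
        assert len(loose) == 2  # bonded, or both free


class TestRanking:
    def test_heterodimers_outrank_cyclic_monomers(self):
        seqs = sf.model_peptide_sequences()
        mols = [
            pr.parse_thiol_sequence(seqs["peptide1"], 0),
            pr.parse_thiol_sequence(seqs["peptide2"], 1),
        ]
        ranked, degenerate = pr.rank_states(
            pr.enumerate_pairing_states(mols)
        )
        assert degenerate  # the two doubly bridged isomers tie
        assert ranked[0].topology == "heterodimeric"
        assert ranked[0].n_cys_pen == 2
        assert ranked[1].topology == "heterodimeric"
        assert ranked[2].topology == "monomeric"

    def test_lone_two_cys_peptide_closes_a_loop(self):
        seqs = sf.model_peptide_sequences()
        mols = [pr.parse_thiol_sequence(seqs["peptide1"], 0)]
        ranked, _ = pr.rank_states(pr.enumerate_pairing_states(mols))
        assert len(ranked) == 1
        assert ranked[0].topology == "monomeric"
        assert ranked[0].n_cys_cys == 1

    def test_three_one_system_top_tier(self):
        seqs = sf.model_peptide_sequences()
        mols = [
            pr.parse_thiol_sequence(seqs["peptide3"], 0),
            pr.parse_thiol_sequence(seqs["peptide2"], 1),
        ]
        ranked, _ = pr.rank_states(pr.enumerate_pairing_states(mols))
        top = [s for s in ranked if abs(s.score - ranked[0].score) <= 1e-9]
        assert len(top) == 6
        assert all(s.n_cys_pen == 3 for s in top)

    def test_ranking_is_a_permutation_with_monotone_scores(self):
        mols = [
            pr.parse_thiol_sequence("CCC", 0),
            pr.parse_thiol_sequence("[Pen][Pen][Pen]", 1),
        ]
        states = pr.enumerate_pairing_states(mols)
        ranked, _ = pr.rank_states(states)
        assert len(ranked) == len(states)
        assert {s.bonds for s in ranked} == {s.bonds for s in states}
        scores = [s.score for s in ranked]
        assert scores == sorted(scores, reverse=True)

    def test_default_weight_ordering(self):
        w = pr.PreferenceWeights()
        assert w.w_cys_pen > w.w_cys_cys > w.w_pen_pen > w.w_free


class TestOrthogonality:
    def test_fixture_design_set_has_one_exception(self):
        designs = sf.heterodimer_design_set()
        matrix = pr.orthogonality_screen(designs)
        cross = {
            pair for pair, (verdict, _) in matrix.items()
            if verdict == "cross-reactive"
        }
        assert cross == {("hd1", "hd2")}

    def test_count_rule_reason_recorded(self):
        designs = sf.heterodimer_design_set()
        matrix = pr.orthogonality_screen(designs)
        verdict, reason = matrix[("hd2", "hd1")]
        assert verdict == "orthogonal"
        assert "Pen sites" in reason

    def test_no_diagonal_entries(self):
        designs = sf.heterodimer_design_set()
        matrix = pr.orthogonality_screen(designs)
        assert all(a != b for a, b in matrix)
        assert len(matrix) == len(designs) * (len(designs) - 1)

    def test_without_backbones_counts_alone_decide(self):
        d1 = pr.HeterodimerDesign("x", cys_sites=(1, 2), pen_sites=(1, 2))
        d2 = pr.HeterodimerDesign("y", cys_sites=(1, 2, 3), pen_sites=(1, 2, 3))
        matrix = pr.orthogonality_screen([d1, d2])
        assert matrix[("x", "y")][0] == "cross-reactive"
        assert matrix[("y", "x")][0] == "orthogonal"


class TestMasses:
    @pytest.mark.parametrize("seq,expected", [
        ("G", 75.03203),
        ("[Pen]", 149.05105),
        ("GK", 203.12699),
    ])
    def test_reference_values(self, seq, expected):
        assert pr.monoisotopic_mass(seq) == pytest.approx(expected, abs=1e-4)

    def test_matches_independent_residue_table(self):
        rng = np.random.default_rng(4)
        letters = list(ORACLE_RESIDUE_MASS)
        for _ in range(50):
            toks = rng.choice(letters, size=rng.integers(1, 20))
            seq = "".join(t if t != "Pen" else "[Pen]" for t in toks)
            expected = sum(ORACLE_RESIDUE_MASS[t] for t in toks) + ORACLE_WATER
            assert pr.monoisotopic_mass(seq) == pytest.approx(expected, abs=1e-4)

    def test_empty_sequence_is_an_error(self):
        with pytest.raises(ValueError):
            pr.monoisotopic_mass("")


def random_thiol_system(rng):
    letters = ["G", "A", "K", "R", "P", "S", "C", "[Pen]", "W"]
    seqs = []
    sites = []
    n_mols = rng.integers(1, 4)
    for m in range(n_mols):
        toks = [letters[i] for i in rng.integers(0, len(letters),
                                                 size=rng.integers(3, 15))]
        seqs.append("".join(toks))
        for pos, t in enumerate(pr.parse_sequence(seqs[-1]), start=1):
            if t in ("C", "Pen"):
                sites.append((m, pos))
    rng.shuffle(sites)
    bonds = []
    while len(sites) >= 2:
        a = sites.pop()
        b = sites.pop()
        if rng.random() < 0.7:
            bonds.append(tuple(sorted((a, b))))
    return seqs, bonds


class TestTrypticDigest:
    def test_unbonded_fragments(self):
        species = pr.tryptic_fragments(["GKGK"])
        assert [f[0].sequence for f, _ in [(s, m) for s, m in species]] == ["GK", "GK"]
        for _, m in species:
            assert m == pytest.approx(203.12699, abs=1e-4)

    def test_bonded_fragments_merge(self):
        species = pr.tryptic_fragments(["CK", "C"], [((0, 1), (1, 1))])
        assert len(species) == 1
        fragments, m = species[0]
        assert {f.sequence for f in fragments} == {"CK", "C"}
        chains = pr.monoisotopic_mass("CK") + pr.monoisotopic_mass("C")
        assert m == pytest.approx(chains - 2.01565, abs=1e-4)

    def test_proline_suppresses_cleavage(self):
        species = pr.tryptic_fragments(["KPGK"])
        assert len(species) == 1
        assert species[0][0][0].sequence == "KPGK"

    def test_bond_to_non_thiol_is_an_error(self):
        with pytest.raises(ValueError, match="thiol"):
            pr.tryptic_fragments(["CK"], [((0, 2), (0, 1))])

    def test_mass_conservation_on_random_systems(self):
        rng = np.random.default_rng(20)
        for _ in range(30):
            seqs, bonds = random_thiol_system(rng)
            species = pr.tryptic_fragments(seqs, bonds)
            total = sum(m for _, m in species)
            expected = sum(
                pr.monoisotopic_mass(s) for s in seqs
            ) - pr.DISULFIDE_LOSS * len(bonds)
            # digestion conserves mass: each cleavage adds one water to each
            # product but the chain sum already counts one water per fragment
            n_frags = sum(len(fs) for fs, _ in species)
            expected += (n_frags - len(seqs)) * pr.WATER
            assert total == pytest.approx(expected, abs=1e-9)

    def test_intrachain_bond_within_one_fragment(self):
        species = pr.tryptic_fragments(["CGC"], [((0, 1), (0, 3))])
        assert len(species) == 1
        assert species[0][1] == pytest.approx(
            pr.monoisotopic_mass("CGC") - 2.01565, abs=1e-4
        )
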