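import numpy as np
import pytest

from thiopair import hashdb as hd
from thiopair import stapler as st
from thiopair import synthfix as sf
from thiopair.geometry import exemplar_from_pair
from thiopair.structio import Atom, Chain, Residue, Structure

from conftest import move_structure, random_rigid


def stripped(s):
    """Backbone-only copy (side chains removed, residues renamed ALA)."""
    out = s.copy()
    for chain in out.chains:
        for i, r in enumerate(chain.residues):
            chain.residues[i] = Residue(
                "ALA", r.seqnum, r.chain_id,
                [Atom(a.name, a.element, a.coord.copy())
                 for a in r.atoms if a.name in ("N", "CA", "C", "O")],
            )
    return out


@pytest.fixture(scope="module")
def scaffold3():
    return sf.bonded_scaffold(3, seed=2)


@pytest.fixture(scope="module")
def scaffold3_db(scaffold3):
    cfg = hd.HashDbConfig(n_perturb=10, rng_seed=3)
    mined = hd.mine_exemplars([scaffold3], cfg)
    return hd.build_database(mined, cfg)


class TestScan:
    def test_source_pair_recovered(self, scaffold3, scaffold3_db):
        hits = st.scan_structure(stripped(scaffold3), scaffold3_db)
        pairs = {p.pair for p in hits}
        assert frozenset({("A", 1), ("A", 5)}) in pairs

    def test_no_partner_in_range_is_empty(self, small_db):
        lone = Structure(
            chains=[Chain("A", sf.ideal_strand("AAAAAA"))], fixture=True
        )
        assert st.scan_structure(lone, small_db) == []

    def test_interchain_only_filter(self, small_db):
        a = sf.ideal_strand("AAAA", chain_id="A")
        b = sf.ideal_strand("AAAA", chain_id="B")
        s = Structure(chains=[Chain("A", a), Chain("B", b)], fixture=True)
        for p in st.scan_structure(s, small_db, interchain_only=True):
            assert p.res_a[0] != p.res_b[0]

    def test_min_seq_sep_respected(self, scaffold3, scaffold3_db):
        for p in st.scan_structure(stripped(scaffold3), scaffold3_db,
                                   min_seq_sep=3):
            if p.res_a[0] == p.res_b[0]:
                assert abs(p.res_a[1] - p.res_b[1]) >= 3

    def test_backbone_incomplete_residue_warns(self, scaffold3_db):
        s = Structure(chains=[Chain("A", [
            Residue("ALA", 1, "A", [Atom("CA", "C", np.zeros(3))]),
        ])], fixture=True)
        with pytest.warns(UserWarning, match="backbone-incomplete"):
            st.scan_structure(s, scaffold3_db)


class TestMinimize:
    def test_fixed_point_at_optimum(self, scaffold3):
        # the scaffold's own bridges are built at canonical geometry
        p = st.Placement(("A", 1), ("A", 5), (0.0, 0.0, 0.0, 0.0))
        geo0 = st._bridge_geometry(
            scaffold3.chain("A").residue(1), scaffold3.chain("A").residue(5),
            *(c for c in _native_chis(scaffold3)),
        )
        p = st.Placement(("A", 1), ("A", 5),
                         (geo0.chi1_a, geo0.chi2_a, geo0.chi1_b, geo0.chi2_b))
        m = st.minimize_disulfide(scaffold3, p)
        assert m.score == pytest.approx(0.0, abs=1e-6)
        assert m.rotamers[0] == pytest.approx(geo0.chi1_a, abs=1e-3)
        assert m.converged

    def test_near_miss_recovers_bond_length(self, scaffold3):
        geo0 = _native_geo(scaffold3)
        p = st.Placement(
            ("A", 1), ("A", 5),
            (geo0.chi1_a + 40.0, 0.0, geo0.chi1_b - 40.0, 0.0),
        )
        m = st.minimize_disulfide(scaffold3, p)
        assert 1.9 <= m.geometry.ss_dist <= 2.2

    def test_score_never_increases(self, scaffold3):
        rng = np.random.default_rng(6)
        params = st.MinimizeParams()
        for _ in range(100):
            chis = rng.uniform(-180, 180, size=2)
            p = st.Placement(("A", 1), ("A", 5), (chis[0], 0.0, chis[1], 0.0))
            before = st.restraint_score(
                st._bridge_geometry(
                    scaffold3.chain("A").residue(1),
                    scaffold3.chain("A").residue(5),
                    chis[0], chis[1],
                ),
                params,
            )
            m = st.minimize_disulfide(scaffold3, p, params)
            assert m.score <= before + 1e-12


def _native_geo(s):
    from thiopair.geometry import disulfide_internal_coords

    return disulfide_internal_coords(
        s.chain("A").residue(1), s.chain("A").residue(5)
    )


def _native_chis(s):
    g = _native_geo(s)
    return g.chi1_a, g.chi1_b


class TestClashes:
    def test_isolated_dipeptide_has_none(self):
        res = sf.ideal_strand("CC", chain_id="A")
        s = Structure(chains=[Chain("A", res)], fixture=True)
        for chi1 in (-60.0, 60.0, 180.0):
            p = st.Placement(("A", 1), ("A", 2), (chi1, 0.0, chi1, 0.0))
            rep = st.check_clashes(s, p)
            assert rep.n_clashes == 0

    def test_constructed_blocker_detected(self):
        res = sf.ideal_strand("CC", chain_id="A")
        s = Structure(chains=[Chain("A", res)], fixture=True)
        p = st.Placement(("A", 1), ("A", 2), (180.0, 0.0, 180.0, 0.0))
        applied = st.apply_placement(s, p)
        sg = applied.chain("A").residue(1).atom("SG").coord
        blocker = Residue(
            "GLY", 50, "A",
            [Atom("N", "N", sg + np.array([1.0, 0, 0])),
             Atom("CA", "C", sg + np.array([2.5, 0.8, 0])),
             Atom("C", "C", sg + np.array([4.0, 1.0, 0]))],
        )
        s2 = s.copy()
        s2.chains[0].residues.append(blocker)
        rep = st.check_clashes(s2, p, cutoff=3.2)
        assert rep.n_clashes >= 1
        assert rep.worst_overlap >= 3.2 - 1.0 - 1e-9

    def test_matches_brute_force_oracle(self, scaffold3):
        """Contacts equal an O(n^2) distance scan with networkx bond paths."""
        import networkx as nx

        p = st.Placement(("A", 11), ("A", 15), (-60.0, 0.0, -60.0, 0.0))
        cutoff = 4.0  # wide cutoff so the oracle sees some contacts
        rep = st.check_clashes(scaffold3, p, cutoff=cutoff)

        applied = st.apply_placement(scaffold3, p)
        graph = nx.Graph()
        atoms = {}
        for chain in applied.chains:
            prev = None
            for res in chain.residues:
                for a in res.atoms:
                    atoms[(chain.chain_id, res.seqnum, a.name)] = a.coord
                names = {a.name for a in res.atoms}
                for u, v in st._RESIDUE_BONDS:
                    if u in names and v in names:
                        graph.add_edge((chain.chain_id, res.seqnum, u),
                                       (chain.chain_id, res.seqnum, v))
                if (
                    prev is not None
                    and ("C" in {a.name for a in prev.atoms})
                    and res.has_atom("N")
                    and np.linalg.norm(
                        prev.atom("C").coord - res.atom("N").coord
                    ) < 2.0
                ):
                    graph.add_edge((chain.chain_id, prev.seqnum, "C"),
                                   (chain.chain_id, res.seqnum, "N"))
                prev = res
        graph.add_edge(("A", 11, "SG"), ("A", 15, "SG"))
        placed = [
            k for k in atoms
            if k[1] in (11, 15) and k[2] in ("CB", "SG", "CG1", "CG2")
        ]
        expected = set()
        for pk in placed:
            for k, coord in atoms.items():
                if k[:2] == pk[:2]:
                    continue  # same residue: rotamer-internal, not a clash
                d = np.linalg.norm(coord - atoms[pk])
                if d >= cutoff:
                    continue
                try:
                    sep = nx.shortest_path_length(graph, pk, k)
                except nx.NetworkXNoPath:
                    sep = 99
                if sep <= 3:
                    continue
                expected.add(tuple(sorted((pk, k))))
        assert {pair for pair, _ in rep.contacts} == expected


class TestPenAccommodation:
    def test_exposed_site_is_accommodated(self):
        mc = sf.macrocyclizable_chain(5)
        p = st.Placement(("A", 1), ("A", 10), (180.0, 0, -60.0, 0))
        m = st.minimize_disulfide(mc, p)
        for site in ("a", "b"):
            rep = st.check_pen_accommodation(mc, m, site)
            assert rep.n_clashes == 0

    def test_blocked_methyl_position_rejected(self):
        mc = sf.macrocyclizable_chain(5)
        p = st.Placement(("A", 1), ("A", 10), (-60.0, 0, 180.0, 0))
        m = st.minimize_disulfide(mc, p)
        pen = st.apply_placement(
            mc, st.Placement(m.res_a, m.res_b, m.rotamers, pen_site="a")
        )
        cg1 = pen.chain("A").residue(1).atom("CG1").coord
        blocked = mc.copy()
        blocked.chains[0].residues.append(
            Residue("GLY", 60, "A",
                    [Atom("N", "N", cg1 + np.array([0.0, 0.0, 1.5])),
                     Atom("CA", "C", cg1 + np.array([1.2, 0.0, 2.2])),
                     Atom("C", "C", cg1 + np.array([2.2, 0.5, 3.0]))])
        )
        rep = st.check_pen_accommodation(blocked, m, "a")
        assert rep.n_clashes >= 1

    def test_pen_clashes_dominate_cys_clashes(self, scaffold3):
        for seq_a, seq_b in [(1, 5), (11, 15), (21, 25)]:
            p = st.Placement(("A", seq_a), ("A", seq_b),
                             (-60.0, 0.0, -60.0, 0.0))
            m = st.minimize_disulfide(scaffold3, p)
            cys = st.check_clashes(scaffold3, m, cutoff=3.6)
            for site in ("a", "b"):
                pen = st.check_pen_accommodation(scaffold3, m, site, cutoff=3.6)
                assert pen.n_clashes >= cys.n_clashes


class TestApplyPlacement:
    def test_pure_and_consistent(self, scaffold3):
        from thiopair.geometry import disulfide_internal_coords

        before = scaffold3.n_atoms
        coords_before = scaffold3.chain("A").residue(1).coords().copy()
        p = st.minimize_disulfide(
            scaffold3,
            st.Placement(("A", 1), ("A", 5), (-60.0, 0.0, -60.0, 0.0)),
        )
        applied = st.apply_placement(scaffold3, p)
        assert scaffold3.n_atoms == before
        assert np.array_equal(
            scaffold3.chain("A").residue(1).coords(), coords_before
        )
        geo = disulfide_internal_coords(
            applied.chain("A").residue(1), applied.chain("A").residue(5)
        )
        assert geo.chi1_a == pytest.approx(p.rotamers[0], abs=1e-6)
        assert geo.ss_dist == pytest.approx(p.geometry.ss_dist, abs=1e-6)

    def test_disjoint_placements_commute(self, scaffold3):
        p1 = st.Placement(("A", 1), ("A", 5), (-60.0, 0.0, 180.0, 0.0))
        p2 = st.Placement(("A", 11), ("A", 15), (60.0, 0.0, -60.0, 0.0))
        s12 = st.apply_placement(st.apply_placement(scaffold3, p1), p2)
        s21 = st.apply_placement(st.apply_placement(scaffold3, p2), p1)
        c12 = np.vstack([r.coords() for r in s12.residues()])
        c21 = np.vstack([r.coords() for r in s21.residues()])
        assert np.abs(c12 - c21).max() < 1e-12

    def test_unknown_residue_is_an_error(self, scaffold3):
        p = st.Placement(("A", 999), ("A", 5), (-60.0, 0, -60.0, 0))
        with pytest.raises(KeyError):
            st.apply_placement(scaffold3, p)


class TestEndToEnd:
    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_rederivation_recall(self, k, exemplar_grid):
        scaffold = sf.bonded_scaffold(k, seed=40 + k)
        cfg = hd.HashDbConfig(n_perturb=10, rng_seed=5)
        mined = hd.mine_exemplars([scaffold], cfg)
        db = hd.build_database(mined + exemplar_grid, cfg)
        found = st.find_disulfides(stripped(scaffold), db)
        expected_pairs = {
            frozenset({("A", 10 * i + 1), ("A", 10 * i + 5)}) for i in range(k)
        }
        assert expected_pairs <= {p.pair for p in found}
        for p in found:
            assert 1.8 <= p.geometry.ss_dist <= 2.3
            assert 60.0 <= abs(p.geometry.chi3) <= 120.0
            assert p.clash.n_clashes == 0

    def test_scan_invariant_under_rigid_motion(self, scaffold3, scaffold3_db):
        base = st.find_disulfides(stripped(scaffold3), scaffold3_db)
        base_set = {
            (p.res_a, p.res_b, round(p.score, 6)) for p in base
        }
        rng = np.random.default_rng(77)
        for _ in range(5):
            rot, trans = random_rigid(rng)
            moved = move_structure(stripped(scaffold3), rot, trans)
            got = st.find_disulfides(moved, scaffold3_db)
            got_set = {(p.res_a, p.res_b, round(p.score, 6)) for p in got}
            assert got_set == base_set
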