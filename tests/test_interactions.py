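import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wins7.interactions import (
    InteractionCriteria,
    donors_acceptors,
    find_cation_pi,
    find_hbonds,
    find_salt_bridges,
    find_vdw_contacts,
    find_water_bridges,
    fingerprint,
)
from wins7.structures import Atom, Chain, Model, Residue, Structure
from wins7.synthetic import make_interaction_fixture


def _mini(res_name, atom_names):
    res = Residue("A", 1, res_name, [Atom(n, n[0], [i, 0, 0])
                                     for i, n in enumerate(atom_names)])
    return res


class TestDonorAcceptorTyping:
    def test_serine_hydroxyl_is_both(self):
        roles = donors_acceptors(_mini("SER", ["N", "CA", "C", "O", "CB", "OG"]))
        assert roles["OG"] == "both"

    def test_backbone_carbonyl_acceptor_only(self):
        roles = donors_acceptors(_mini("ALA", ["N", "CA", "C", "O", "CB"]))
        assert roles["O"] == "acceptor"
        assert roles["N"] == "donor"

    def test_arginine_guanidinium_donors(self):
        roles = donors_acceptors(
            _mini("ARG", ["N", "CA", "C", "O", "CB", "CG", "CD", "NE", "CZ",
                          "NH1", "NH2"])
        )
        assert all(roles[n] == "donor" for n in ("NE", "NH1", "NH2"))

    def test_proline_backbone_n_not_donor(self):
        roles = donors_acceptors(_mini("PRO", ["N", "CA", "C", "O"]))
        assert "N" not in roles

    def test_water_oxygen_both(self):
        wat = Residue("W", 1, "HOH", [Atom("O", "O", [0, 0, 0])])
        assert donors_acceptors(wat) == {"O": "both"}

    def test_nonstandard_residue_warns_and_skips(self):
        import warnings
        with warnings.catch_warnings(record=True) as captured:
            warnings.simplefilter("always")
            roles = donors_acceptors(_mini("XYZ", ["N", "O"]))
        assert roles == {}
        assert any("XYZ" in str(w.message) for w in captured)


class TestHbonds:
    @pytest.mark.parametrize("distance,n_expected", [(2.8, 1), (3.5, 1), (4.5, 0)])
    def test_distance_cutoff(self, distance, n_expected):
        fx = make_interaction_fixture("hbond_pair", distance=distance)
        recs = find_hbonds(fx, "chain A", "chain B")
        assert len(recs) == n_expected
        if recs:
            assert recs[0].distance == pytest.approx(distance, abs=1e-6)

    def test_angle_rule_prunes_backfolded_geometry(self):
        ok = make_interaction_fixture("hbond_pair", distance=2.8, angle=120.0)
        bad = make_interaction_fixture("hbond_pair", distance=2.8, angle=30.0)
        assert len(find_hbonds(ok, "chain A", "chain B")) == 1
        assert len(find_hbonds(bad, "chain A", "chain B")) == 0

    def test_symmetric_in_selections(self, hbond_fixture):
        ab = find_hbonds(hbond_fixture, "chain A", "chain B")
        ba = find_hbonds(hbond_fixture, "chain B", "chain A")
        assert [(r.partner_a, r.partner_b) for r in ab] == [
            (r.partner_a, r.partner_b) for r in ba
        ]


class TestSaltBridges:
    def test_bidentate_guanidinium_carboxylate(self):
        fx = make_interaction_fixture("salt_bridge_pair", distance=3.0)
        recs = find_salt_bridges(fx, "chain A", "chain B")
        assert len(recs) == 2
        partners = {(r.partner_a.split("/")[-1], r.partner_b.split("/")[-1])
                    for r in recs}
        assert partners == {("NH1", "OD1"), ("NH2", "OD2")}

    def test_beyond_cutoff_empty(self):
        fx = make_interaction_fixture("salt_bridge_pair", distance=5.5)
        assert find_salt_bridges(fx, "chain A", "chain B") == []


class TestCationPi:
    def test_cation_above_ring(self):
        fx = make_interaction_fixture("cation_pi", distance=4.0, angle=90.0)
        recs = find_cation_pi(fx, "chain A", "chain B")
        assert len(recs) == 1
        assert recs[0].distance == pytest.approx(4.0, abs=1e-6)

    def test_in_plane_cation_rejected(self):
        fx = make_interaction_fixture("cation_pi", distance=4.0, angle=0.0)
        assert find_cation_pi(fx, "chain A", "chain B") == []

    def test_elevation_threshold_boundary(self):
        below = make_interaction_fixture("cation_pi", distance=4.0, angle=30.0)
        above = make_interaction_fixture("cation_pi", distance=4.0, angle=60.0)
        assert find_cation_pi(below, "chain A", "chain B") == []
        assert len(find_cation_pi(above, "chain A", "chain B")) == 1


class TestVdw:
    def _pair(self, distance):
        ra = Residue("A", 1, "ALA", [Atom("CB", "C", [0, 0, 0])])
        rb = Residue("B", 2, "ALA", [Atom("CB", "C", [distance, 0, 0])])
        return Structure(id="v", models=[Model(chains=[
            Chain("A", [ra]), Chain("B", [rb])])])

    @pytest.mark.parametrize("distance,n", [(3.8, 1), (4.6, 0), (2.5, 0)])
    def test_distance_window(self, distance, n):
        recs = find_vdw_contacts(self._pair(distance), "chain A", "chain B")
        assert len(recs) == n

    def test_dedup_keeps_minimum_per_residue_pair(self):
        ra = Residue("A", 1, "LEU", [Atom("CD1", "C", [0, 0, 0]),
                                     Atom("CD2", "C", [0, 1.5, 0])])
        rb = Residue("B", 2, "ALA", [Atom("CB", "C", [3.6, 0, 0])])
        stx = Structure(id="v", models=[Model(chains=[
            Chain("A", [ra]), Chain("B", [rb])])])
        recs = find_vdw_contacts(stx, "chain A", "chain B")
        assert len(recs) == 1
        assert recs[0].distance == pytest.approx(3.6, abs=1e-9)


class TestWaterBridges:
    def test_single_bridge_found(self):
        fx = make_interaction_fixture("water_bridge", distance=2.9)
        recs = find_water_bridges(fx, "chain P", "chain A", np.zeros(3))
        assert len(recs) == 1
        assert recs[0].waters == ["W/HOH501"]

    def test_single_contact_water_not_a_bridge(self):
        fx = make_interaction_fixture("water_bridge", distance=2.9)
        # strip the protein amide so the water keeps only one polar contact
        for chain in fx.first_model.chains:
            if chain.chain_id == "A":
                chain.residues[0].atoms = [
                    a for a in chain.residues[0].atoms if a.name != "N"
                ]
        assert find_water_bridges(fx, "chain P", "chain A", np.zeros(3)) == []

    def test_water_outside_site_radius_excluded(self):
        fx = make_interaction_fixture("water_bridge", distance=2.9)
        far_center = np.array([50.0, 0.0, 0.0])
        assert find_water_bridges(fx, "chain P", "chain A", far_center) == []

    def test_census_counts_only_qualifying_waters(self):
        """Site census: 3 doubly-coordinated waters in the sphere count; a
        singly-coordinated one and an out-of-site one do not."""
        pep = Residue("P", 1, "GLY", [Atom("C", "C", [-4.1, 0, 0]),
                                      Atom("O", "O", [-2.9, 0, 0])])
        prot = Residue("A", 2, "GLY", [Atom("N", "N", [2.9, 0, 0]),
                                       Atom("CA", "C", [4.3, 0, 0])])
        waters = []
        for i, y in enumerate((1.0, 2.0, 3.0)):  # each reaches both O and N
            waters.append(Residue("W", 500 + i, "HOH",
                                  [Atom("O", "O", [0.0, y * 0.0, 0.0])],
                                  is_hetero=True))
        # give them distinct but still doubly-contacting positions
        waters[0].atoms[0].coords = np.array([0.0, 0.5, 0.0])
        waters[1].atoms[0].coords = np.array([0.0, -0.5, 0.0])
        waters[2].atoms[0].coords = np.array([0.0, 0.0, 0.7])
        lone = Residue("W", 510, "HOH", [Atom("O", "O", [-2.9, 3.4, 0.0])],
                       is_hetero=True)  # only the peptide O in range
        outside = Residue("W", 511, "HOH", [Atom("O", "O", [30.0, 0, 0])],
                          is_hetero=True)
        stx = Structure(id="census", models=[Model(chains=[
            Chain("P", [pep]), Chain("A", [prot]),
            Chain("W", waters + [lone, outside])])])
        recs = find_water_bridges(stx, "chain P", "chain A", np.zeros(3))
        assert sorted(r.waters[0] for r in recs) == [
            "W/HOH500", "W/HOH501", "W/HOH502"
        ]


def test_fingerprint_union_contains_every_kind():
    # assemble one structure carrying all five contact kinds, well separated
    def shifted(stx, offset, chain_map):
        out = []
        for res in stx.residues():
            res2 = Residue(chain_map.get(res.chain_id, res.chain_id),
                           res.seq_id, res.res_name,
                           [Atom(a.name, a.element, a.coords + offset)
                            for a in res.atoms], is_hetero=res.is_hetero)
            out.append(res2)
        return out

    residues = []
    residues += shifted(make_interaction_fixture("hbond_pair", 2.8),
                        np.array([0.0, 0, 0]), {"A": "X", "B": "Y"})
    residues += shifted(make_interaction_fixture("salt_bridge_pair", 3.0),
                        np.array([30.0, 0, 0]), {"A": "X", "B": "Y"})
    residues += shifted(make_interaction_fixture("cation_pi", 4.0),
                        np.array([60.0, 0, 0]), {"A": "X", "B": "Y"})
    residues += shifted(make_interaction_fixture("water_bridge", 2.9),
                        np.array([90.0, 0, 0]), {"P": "X", "A": "Y"})
    ra = Residue("X", 70, "ALA", [Atom("CB", "C", [120.0, 0, 0])])
    rb = Residue("Y", 71, "ALA", [Atom("CB", "C", [123.8, 0, 0])])
    residues += [ra, rb]
    for i, res in enumerate(residues):
        res.seq_id = i + 1  # keep addressing unique per chain
    chains = {}
    for res in residues:
        chains.setdefault(res.chain_id, []).append(res)
    stx = Structure(id="all", models=[Model(chains=[
        Chain(cid, rs) for cid, rs in chains.items()])])

    table = fingerprint(stx, "chain X", "chain Y",
                        site_center=np.array([90.0, 0, 0]))
    kinds = {r.kind for r in table.records}
    assert kinds == {"hbond", "salt_bridge", "cation_pi", "vdw", "water_bridge"}
    df = table.df
    assert set(df.columns) >= {"kind", "partner_a", "partner_b", "distance"}


def test_fingerprint_empty_selections():
    fx = make_interaction_fixture("hbond_pair", 2.8)
    table = fingerprint(fx, "chain Q", "chain Z")
    assert len(table) == 0
    assert table.df.empty


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------

def _random_cloud_structure(seed, n_res=40):
    """Random mix of polar/apolar residues in a compact box."""
    rng = np.random.default_rng(seed)
    chains = {"A": [], "B": []}
    templates = [
        ("SER", [("CB", "C"), ("OG", "O")]),
        ("ALA", [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C")]),
        ("ASP", [("CG", "C"), ("OD1", "O"), ("OD2", "O")]),
        ("ARG", [("CD", "C"), ("NE", "N"), ("CZ", "C"), ("NH1", "N"), ("NH2", "N")]),
    ]
    for i in range(n_res):
        cid = "A" if i % 2 == 0 else "B"
        name, atoms = templates[rng.integers(len(templates))]
        base = rng.uniform(0, 18, 3)
        res = Residue(cid, i + 1, name, [
            Atom(an, el, base + rng.uniform(-0.8, 0.8, 3)) for an, el in atoms
        ])
        chains[cid].append(res)
    return Structure(id=f"cloud{seed}", models=[Model(chains=[
        Chain("A", chains["A"]), Chain("B", chains["B"])])])


def _brute_force_hbonds(stx, criteria):
    """All-pairs oracle, no spatial indexing."""
    out = set()
    sel_a = [(r, a) for r, a in stx.atoms() if r.chain_id == "A"]
    sel_b = [(r, a) for r, a in stx.atoms() if r.chain_id == "B"]
    from wins7.interactions import _antecedent_coord, _angle, atom_id

    def roles(pairs):
        result = []
        for r, a in pairs:
            rl = donors_acceptors(r).get(a.name)
            if rl:
                result.append((r, a, rl))
        return result

    for donors, acceptors in ((roles(sel_a), roles(sel_b)),
                              (roles(sel_b), roles(sel_a))):
        for rd, ad, rld in donors:
            if rld not in ("donor", "both"):
                continue
            for ra, aa, rla in acceptors:
                if rla not in ("acceptor", "both") or rd.key == ra.key:
                    continue
                d = np.linalg.norm(ad.coords - aa.coords)
                if d > criteria.hbond_max_da:
                    continue
                ante = _antecedent_coord(rd, ad.name)
                if ante is not None and _angle(
                    ante, ad.coords, aa.coords
                ) < criteria.hbond_min_angle:
                    continue
                out.add(tuple(sorted([atom_id(rd, ad), atom_id(ra, aa)])))
    return out


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_hbond_finder_matches_brute_force(seed):
    stx = _random_cloud_structure(seed)
    criteria = InteractionCriteria()
    fast = {(r.partner_a, r.partner_b)
            for r in find_hbonds(stx, "chain A", "chain B", criteria)}
    assert fast == _brute_force_hbonds(stx, criteria)


@settings(max_examples=20, derandomize=True, deadline=None)
@given(
    seed=st.integers(0, 100),
    tight=st.floats(2.5, 3.4),
)
def test_tightening_cutoff_shrinks_record_set(seed, tight):
    stx = _random_cloud_structure(seed, n_res=20)
    loose_recs = find_hbonds(stx, "chain A", "chain B", InteractionCriteria())
    tight_recs = find_hbonds(
        stx, "chain A", "chain B", InteractionCriteria(hbond_max_da=tight)
    )
    loose = {(r.partner_a, r.partner_b) for r in loose_recs}
    tightset = {(r.partner_a, r.partner_b) for r in tight_recs}
    assert tightset <= loose


def test_criteria_validation():
    with pytest.raises(ValueError):
        InteractionCriteria(vdw_min=4.5, vdw_max=4.0)
    with pytest.raises(ValueError):
        InteractionCriteria(hbond_max_da=-1.0)
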