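"""Geometric interaction detection: rules, oracle equivalence, exports."""
import numpy as np
import pytest

from conftest import make_residue
from tcrkit.interactions import (ANIONIC_GROUPS, APOLAR_CARBONS,
                                 AROMATIC_RINGS, CATIONIC_GROUPS,
                                 InteractionConfig, InteractionTable,
                                 detect_interactions, export_interactions,
                                 interaction_heatmap, read_interactions)
from tcrkit.model import Chain, ChainType, TCRComplex


def two_chain_complex(chainA_residues, chainB_residues):
    """Minimal complex wrapper: chain A as 'TCR alpha', B as 'peptide'.

    Only the chain lists matter to the detector; the TCR fields are filled
    with the same chains to satisfy the container's type checks.
    """
    a = Chain(id="A", residues=chainA_residues)
    a.chain_type = ChainType.TCR_ALPHA
    b = Chain(id="B", residues=chainB_residues)
    b.chain_type = ChainType.TCR_BETA
    return TCRComplex(alpha_like=a, beta_like=b)


class TestRules:
    def test_salt_bridge_at_centroid_distance(self):
        lys = make_residue("LYS", 1, {"CA": (0, 0, 0), "NZ": (0, 0, 4.0)})
        asp = make_residue("ASP", 1, {"CA": (0, 8, 0), "OD1": (0, 0.5, 8.0),
                                      "OD2": (0, -0.5, 8.0)})
        # NZ to OD centroid distance exactly 4.0
        cx = two_chain_complex([lys], [asp])
        t = detect_interactions(cx)
        kinds = [r.kind for r in t.rows]
        assert kinds.count("saltbridge") == 1
        sb = next(r for r in t.rows if r.kind == "saltbridge")
        assert sb.distance == pytest.approx(4.0)

    @pytest.mark.parametrize("d,expected", [(2.9, 1), (3.5, 1), (3.6, 0)])
    def test_hbond_brackets_cutoff(self, d, expected):
        don = make_residue("ALA", 1, {"N": (0, 0, 0), "CA": (1.4, 0, 0)})
        acc = make_residue("GLY", 1, {"CA": (d + 1.4, 0, 5), "O": (d, 0, 0)})
        cx = two_chain_complex([don], [acc])
        hb = [r for r in detect_interactions(cx).rows if r.kind == "hbond"]
        assert len(hb) == expected

    @pytest.mark.parametrize("d,expected", [(3.9, 1), (4.1, 0)])
    def test_hydrophobic_brackets_cutoff(self, d, expected):
        v1 = make_residue("VAL", 1, {"CA": (0, 0, 9), "CB": (0, 0, 0)})
        v2 = make_residue("VAL", 1, {"CA": (d, 0, 9), "CB": (d, 0, 0)})
        cx = two_chain_complex([v1], [v2])
        rows = [r for r in detect_interactions(cx).rows
                if r.kind == "hydrophobic"]
        assert len(rows) == expected

    def test_hydrophobic_reports_single_shortest_pair(self):
        l1 = make_residue("LEU", 1, {"CA": (0, 0, 9), "CB": (0, 0, 0),
                                     "CG": (0.5, 0, 0)})
        l2 = make_residue("LEU", 1, {"CA": (3, 0, 9), "CB": (3, 0, 0),
                                     "CG": (3.5, 0, 0)})
        rows = [r for r in detect_interactions(
            two_chain_complex([l1], [l2])).rows if r.kind == "hydrophobic"]
        assert len(rows) == 1
        assert rows[0].distance == pytest.approx(2.5)   # CG1 to CB2

    def test_pistacking_parallel_and_tshaped(self):
        def ring(z, tilt_deg, number):
            ang = np.radians(tilt_deg)
            pts = {}
            for i, name in enumerate(("CG", "CD1", "CD2", "CE1", "CE2", "CZ")):
                th = 2 * np.pi * i / 6
                local = np.array([1.4 * np.cos(th), 1.4 * np.sin(th), 0.0])
                R = np.array([[1, 0, 0],
                              [0, np.cos(ang), -np.sin(ang)],
                              [0, np.sin(ang), np.cos(ang)]])
                pts[name] = R @ local + np.array([0, 0, z])
            pts["CA"] = np.array([3.0, 0, z])
            return make_residue("PHE", number, pts)

        parallel = detect_interactions(
            two_chain_complex([ring(0, 0, 1)], [ring(4.0, 10, 1)])).rows
        assert [r.kind for r in parallel].count("pistack") == 1
        tshape = detect_interactions(
            two_chain_complex([ring(0, 0, 1)], [ring(5.0, 85, 1)])).rows
        assert [r.kind for r in tshape].count("pistack") == 1
        mid = detect_interactions(
            two_chain_complex([ring(0, 0, 1)], [ring(4.0, 45, 1)])).rows
        assert [r.kind for r in mid].count("pistack") == 0

    def test_far_apart_atoms_give_empty_table(self):
        a = make_residue("LYS", 1, {"CA": (0, 0, 0), "NZ": (1, 0, 0)})
        b = make_residue("ASP", 1, {"CA": (50, 0, 0), "OD1": (51, 0, 0)})
        assert len(detect_interactions(two_chain_complex([a], [b]))) == 0

    def test_his_is_both_cationic_and_aromatic(self):
        assert "HIS" in CATIONIC_GROUPS and "HIS" in AROMATIC_RINGS


def _random_toy_chains(rng, n_res=12):
    """Two chains of random residues with rule-relevant atoms at random
    positions in a 14 A box (well under 200 atoms)."""
    names = ["ALA", "VAL", "LEU", "LYS", "ARG", "ASP", "GLU", "SER", "THR",
             "PHE", "TYR", "HIS", "ASN", "GLN", "GLY", "TRP"]
    atom_sets = {
        "ALA": ("N", "CA", "C", "O", "CB"),
        "VAL": ("N", "CA", "C", "O", "CB", "CG1", "CG2"),
        "LEU": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2"),
        "LYS": ("N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ"),
        "ARG": ("N", "CA", "C", "O", "CB", "CG", "NE", "NH1", "NH2"),
        "ASP": ("N", "CA", "C", "O", "CB", "OD1", "OD2"),
        "GLU": ("N", "CA", "C", "O", "CB", "CG", "OE1", "OE2"),
        "SER": ("N", "CA", "C", "O", "CB", "OG"),
        "THR": ("N", "CA", "C", "O", "CB", "OG1", "CG2"),
        "PHE": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
        "TYR": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2",
                "CZ", "OH"),
        "HIS": ("N", "CA", "C", "O", "CB", "CG", "ND1", "CD2", "CE1", "NE2"),
        "ASN": ("N", "CA", "C", "O", "CB", "OD1", "ND2"),
        "GLN": ("N", "CA", "C", "O", "CB", "CG", "OE1", "NE2"),
        "GLY": ("N", "CA", "C", "O"),
        "TRP": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "NE1", "CE2",
                "CE3", "CZ2", "CZ3", "CH2"),
    }
    chains = []
    for _ in range(2):
        residues = []
        for i in range(n_res):
            name = names[rng.integers(len(names))]
            center = rng.uniform(0, 14, 3)
            atoms = {an: center + rng.uniform(-1.2, 1.2, 3)
                     for an in atom_sets[name]}
            residues.append(make_residue(name, i + 1, atoms))
        chains.append(residues)
    return chains


def brute_force_interactions(cx, cfg=None):
    """Independent all-pairs re-application of the documented rules."""
    from tcrkit.interactions import (SIDECHAIN_ACCEPTORS, SIDECHAIN_DONORS)
    cfg = cfg or InteractionConfig()
    out = set()
    entries = [(ch, r, i) for ch in cx.chains
               for i, r in enumerate(ch.standard_residues)]
    for x in range(len(entries)):
        for y in range(x + 1, len(entries)):
            ch1, r1, i1 = entries[x]
            ch2, r2, i2 = entries[y]
            if ch1.id == ch2.id:
                continue        # interchain scope
            key12 = (ch1.id, r1.key, ch2.id, r2.key)
            # hbonds
            for dres, ares, fwd in ((r1, r2, True), (r2, r1, False)):
                dnames = list(SIDECHAIN_DONORS.get(dres.name, ()))
                if dres.name != "PRO" and dres.atom("N"):
                    dnames.append("N")
                anames = list(SIDECHAIN_ACCEPTORS.get(ares.name, ()))
                for bb in ("O", "OXT"):
                    if ares.atom(bb):
                        anames.append(bb)
                for dn in dnames:
                    if not dres.atom(dn):
                        continue
                    for an in anames:
                        if not ares.atom(an):
                            continue
                        d = np.linalg.norm(dres.atom(dn).coords
                                           - ares.atom(an).coords)
                        if d <= cfg.hbond_max:
                            pair = (dn, an) if fwd else (an, dn)
                            out.add(("hbond", key12, pair))
            # salt bridges
            for cat, ani, fwd in ((r1, r2, True), (r2, r1, False)):
                cn = CATIONIC_GROUPS.get(cat.name)
                an = ANIONIC_GROUPS.get(ani.name)
                if not cn or not an:
                    continue
                cp = [cat.atom(n).coords for n in cn if cat.atom(n)]
                ap = [ani.atom(n).coords for n in an if ani.atom(n)]
                if not cp or not ap:
                    continue
                d = np.linalg.norm(np.mean(cp, 0) - np.mean(ap, 0))
                if d <= cfg.saltbridge_max:
                    out.add(("saltbridge", key12, fwd))
            # hydrophobic (existence; shortest-pair reporting checked via count)
            dmin = None
            for n1 in APOLAR_CARBONS.get(r1.name, ()):
                for n2 in APOLAR_CARBONS.get(r2.name, ()):
                    if r1.atom(n1) and r2.atom(n2):
                        d = np.linalg.norm(r1.atom(n1).coords
                                           - r2.atom(n2).coords)
                        dmin = d if dmin is None else min(dmin, d)
            if dmin is not None and dmin <= cfg.hydrophobic_max:
                out.add(("hydrophobic", key12, round(float(dmin), 9)))
            # pi stacking
            def ring(res):
                names = AROMATIC_RINGS.get(res.name)
                if not names:
                    return None
                pts = [res.atom(n).coords for n in names if res.atom(n)]
                if len(pts) < 4:
                    return None
                pts = np.vstack(pts)
                c = pts.mean(0)
                _, _, vt = np.linalg.svd(pts - c)
                return c, vt[2]
            g1, g2 = ring(r1), ring(r2)
            if g1 and g2:
                d = np.linalg.norm(g1[0] - g2[0])
                if d <= cfg.pistack_max:
                    ang = np.degrees(np.arccos(min(1.0, abs(g1[1] @ g2[1]))))
                    lo, hi = cfg.pistack_tshape_range
                    if ang <= cfg.pistack_parallel_max or lo <= ang <= hi:
                        out.add(("pistack", key12, round(float(d), 9)))
    return out


def _table_as_set(table):
    out = set()
    for r in table.rows:
        key = (r.chainA, r.residueA, r.chainB, r.residueB)
        if r.kind == "hbond":
            out.add((r.kind, key, (r.atomA, r.atomB)))
        elif r.kind == "saltbridge":
            out.add((r.kind, key, r.resnameA in CATIONIC_GROUPS))
        else:
            out.add((r.kind, key, round(r.distance, 9)))
    return out


class TestOracle:
    def test_matches_brute_force_on_random_complexes(self):
        rng = np.random.default_rng(42)
        for trial in range(50):
            a, b = _random_toy_chains(rng)
            cx = two_chain_complex(a, b)
            got = _table_as_set(detect_interactions(cx))
            want = brute_force_interactions(cx)
            assert got == want, f"trial {trial}"

    def test_symmetric_under_chain_swap(self):
        rng = np.random.default_rng(7)
        a, b = _random_toy_chains(rng)
        t1 = detect_interactions(two_chain_complex(a, b))
        t2 = detect_interactions(two_chain_complex(b, a))
        assert len(t1) > 0

        # chain ids swap with construction order, so compare id-free views:
        # (kind, unordered residue identities, distance)
        def strip(table):
            return {(r.kind, round(r.distance, 9),
                     frozenset((r.resnameA + r.residueA + r.atomA,
                                r.resnameB + r.residueB + r.atomB)))
                    for r in table.rows}

        assert strip(t1) == strip(t2)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(9)
        a, b = _random_toy_chains(rng)
        cx = two_chain_complex(a, b)
        base = _table_as_set(detect_interactions(cx))
        from conftest import apply_rigid, random_rotation
        apply_rigid(cx, random_rotation(rng), rng.normal(size=3) * 30)
        moved = detect_interactions(cx)
        assert {(k, key, e if not isinstance(e, float) else round(e, 6))
                for k, key, e in _table_as_set(moved)} == \
               {(k, key, e if not isinstance(e, float) else round(e, 6))
                for k, key, e in base}


class TestHeatmapAndExport:
    def test_empty_table_all_zero_matrix(self):
        a = make_residue("ALA", 1, {"CA": (0, 0, 0)})
        b = make_residue("GLY", 1, {"CA": (50, 0, 0)})
        cx = two_chain_complex([a], [b])
        hm = interaction_heatmap(detect_interactions(cx), "A", "B")
        assert hm.total == 0
        assert hm.matrix.shape == (1, 1)

    def test_cell_sum_equals_interaction_count(self, toy_complex):
        table = detect_interactions(toy_complex)
        pep, mhc = toy_complex.peptide.id, toy_complex.mhc_chains[0].id
        n_pair = sum(1 for r in table.rows
                     if {r.chainA, r.chainB} == {pep, mhc})
        hm = interaction_heatmap(table, pep, mhc)
        assert hm.total == n_pair
        assert hm.matrix.shape == (9, 180)

    def test_unknown_chain_raises(self, toy_complex):
        table = detect_interactions(toy_complex)
        with pytest.raises(Exception, match="chain"):
            interaction_heatmap(table, "Z", "A")

    def test_csv_round_trip(self, tmp_path, toy_complex):
        table = detect_interactions(toy_complex)
        assert len(table) > 0
        path = tmp_path / "inter.csv"
        export_interactions(table, str(path))
        back = read_interactions(str(path))
        assert len(back) == len(table)
        assert [vars(r) for r in back.rows] == [vars(r) for r in table.rows]

    def test_empty_table_exports_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        export_interactions(InteractionTable(), str(path))
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 and lines[0].startswith("kind,")


def test_scope_all_includes_intrachain(toy_complex):
    inter = detect_interactions(toy_complex, scope="interchain")
    both = detect_interactions(toy_complex, scope="all")
    assert len(both) >= len(inter)
    assert any(r.chainA == r.chainB for r in both.rows)
    assert all(r.chainA != r.chainB for r in inter.rows)
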