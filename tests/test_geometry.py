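"""Geometric observables checked against independent brute-force oracles."""

import numpy as np
import pytest

from e2chase.geometry import (
    ContactCriteria,
    Frame,
    PocketSpec,
    ThioesterSite,
    classify_base_catalysis,
    detect_hbonds,
    detect_salt_bridges,
    geometry_report,
    interaction_frequencies,
    orientation_angle,
    per_residue_rmsf,
    pocket_volume,
    sidechain_dihedrals,
    signed_plane_offset,
)
from e2chase.synthetic import (
    ToyGeometrySpec,
    gen_fluctuating_ensemble,
    gen_thioester_frame,
    toy_site,
)


def make_frame(atoms):
    """atoms: list of (name, resname, resseq, chain, element, xyz)."""
    return Frame(
        names=[a[0] for a in atoms], resnames=[a[1] for a in atoms],
        resseqs=[a[2] for a in atoms], chains=[a[3] for a in atoms],
        elements=[a[4] for a in atoms],
        coords=np.array([a[5] for a in atoms], dtype=float),
    )


def plane_site_frame(ne_xyz, cav_xyz=(0.0, 0.0, 5.0)):
    """Minimal frame: plane through SG(origin), C(x), O(xy); probe NE2; cavity ref."""
    return make_frame([
        ("SG", "CYS", 87, "A", "S", (0.0, 0.0, 0.0)),
        ("C", "GLY", 76, "B", "C", (1.8, 0.0, 0.0)),
        ("O", "GLY", 76, "B", "O", (2.4, 1.1, 0.0)),
        ("NE2", "HIS", 94, "A", "N", ne_xyz),
        ("CAV", "DUM", 999, "A", "C", cav_xyz),
    ])


MINIMAL_SITE = ThioesterSite(
    sg="A:87:SG", carbonyl_c="B:76:C", carbonyl_o="B:76:O", his_ne="A:94:NE2",
    ring=("A:94:NE2",) * 5, cavity_ref="A:999:CAV",
)


class TestSignedPlaneOffset:
    def test_in_plane_probe_is_zero(self):
        f = plane_site_frame((3.0, -2.0, 0.0))
        assert signed_plane_offset(f, MINIMAL_SITE) == pytest.approx(0.0, abs=1e-12)

    def test_positive_displacement_along_oriented_normal(self):
        f = plane_site_frame((1.0, 1.0, 3.0))
        assert signed_plane_offset(f, MINIMAL_SITE) == pytest.approx(3.0, abs=1e-12)

    def test_sign_flips_under_reflection_through_plane(self):
        above = plane_site_frame((1.0, 1.0, 2.5))
        below = plane_site_frame((1.0, 1.0, -2.5))
        assert signed_plane_offset(above, MINIMAL_SITE) == pytest.approx(
            -signed_plane_offset(below, MINIMAL_SITE), abs=1e-12)

    def test_against_brute_force_point_plane_distance(self):
        """100 seeded random configurations vs an explicit cross-product oracle."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            pts = rng.uniform(-10, 10, size=(5, 3))
            s, c, o, ne, cav = pts
            if np.linalg.norm(np.cross(c - s, o - s)) < 1e-3:
                continue
            f = make_frame([
                ("SG", "CYS", 87, "A", "S", s), ("C", "GLY", 76, "B", "C", c),
                ("O", "GLY", 76, "B", "O", o), ("NE2", "HIS", 94, "A", "N", ne),
                ("CAV", "DUM", 999, "A", "C", cav),
            ])
            # independent oracle: unsigned point-plane distance, signed by the
            # side the cavity reference falls on
            n = np.cross(c - s, o - s)
            dist = abs(np.dot(n, ne - s)) / np.linalg.norm(n)
            same_side = np.sign(np.dot(n, ne - s)) == np.sign(np.dot(n, cav - s))
            expected = dist if same_side else -dist
            assert signed_plane_offset(f, MINIMAL_SITE) == pytest.approx(
                expected, abs=1e-10)

    def test_collinear_plane_atoms_rejected(self):
        f = make_frame([
            ("SG", "CYS", 87, "A", "S", (0.0, 0.0, 0.0)),
            ("C", "GLY", 76, "B", "C", (1.0, 0.0, 0.0)),
            ("O", "GLY", 76, "B", "O", (2.0, 0.0, 0.0)),
            ("NE2", "HIS", 94, "A", "N", (0.0, 1.0, 0.0)),
            ("CAV", "DUM", 999, "A", "C", (0.0, 0.0, 5.0)),
        ])
        with pytest.raises(ValueError, match="collinear"):
            signed_plane_offset(f, MINIMAL_SITE)


class TestOrientationAngle:
    def test_constructed_angles(self, site):
        for target in (30.0, 90.0, 120.0, 180.0):
            f = gen_thioester_frame(ToyGeometrySpec(offset=2.0, angle=target, seed=1))
            assert orientation_angle(f, site) == pytest.approx(target, abs=1e-6)

    def test_against_law_of_cosines(self, toy_frame, site):
        """Angle from COM/vertex/carbonyl distances via the law of cosines."""
        ring_idx = [toy_frame.atom_index(s) for s in site.ring]
        com = toy_frame.com(ring_idx)
        ne = toy_frame.xyz(site.his_ne)
        c = toy_frame.xyz(site.carbonyl_c)
        a = np.linalg.norm(com - c)
        b = np.linalg.norm(com - ne)
        cc = np.linalg.norm(ne - c)
        expected = np.degrees(np.arccos((b**2 + cc**2 - a**2) / (2 * b * cc)))
        assert orientation_angle(toy_frame, site) == pytest.approx(expected, abs=1e-9)


class TestBaseCatalysisClassifier:
    def test_three_angstrom_offset_compatible(self):
        assert classify_base_catalysis(3.0, 120.0)

    def test_far_offset_incompatible(self):
        assert not classify_base_catalysis(10.0, 120.0)

    def test_angle_window(self):
        assert not classify_base_catalysis(2.0, 40.0, angle_window=(90.0, 180.0))

    def test_ensemble_compatible_fraction(self, site):
        frames = [gen_thioester_frame(ToyGeometrySpec(offset=off, angle=120.0, seed=s))
                  for s, off in enumerate([1.0, 2.0, 3.0, 6.0, 8.0])]
        report = geometry_report(frames, site)
        assert report["compatible"].mean() == pytest.approx(3 / 5)


class TestHydrogenBonds:
    @staticmethod
    def hbond_frame(d_a_dist, angle_deg):
        """Donor N at origin, H on +x; acceptor placed at given D-A distance and D-H-A angle."""
        d = np.zeros(3)
        h = np.array([1.0, 0.0, 0.0])
        # acceptor position giving the requested angle at H
        theta = np.radians(180.0 - angle_deg)
        direction = np.array([np.cos(theta), np.sin(theta), 0.0])
        # choose |H-A| so that |D-A| = d_a_dist
        b = 2 * np.dot(h - d, direction)
        c = np.linalg.norm(h - d) ** 2 - d_a_dist**2
        ha = (-b + np.sqrt(b**2 - 4 * c)) / 2
        a = h + ha * direction
        return make_frame([
            ("N", "XXX", 1, "A", "N", d), ("H", "XXX", 1, "A", "H", h),
            ("O", "YYY", 2, "A", "O", a),
        ])

    def test_ideal_geometry_detected(self):
        f = self.hbond_frame(2.9, 165.0)
        hits = detect_hbonds(f, ContactCriteria(), ["A:1:N"], ["A:2:O"])
        assert len(hits) == 1
        _, _, _, d, ang = hits[0]
        assert d == pytest.approx(2.9, abs=1e-9)
        assert ang == pytest.approx(165.0, abs=1e-9)

    def test_long_distance_not_detected(self):
        f = self.hbond_frame(3.5, 165.0)
        assert detect_hbonds(f, ContactCriteria(), ["A:1:N"], ["A:2:O"]) == []

    def test_bent_geometry_not_detected(self):
        f = self.hbond_frame(2.9, 120.0)
        assert detect_hbonds(f, ContactCriteria(), ["A:1:N"], ["A:2:O"]) == []

    def test_donor_without_hydrogen_skipped_with_warning(self):
        f = make_frame([("N", "XXX", 1, "A", "N", (0, 0, 0)),
                        ("O", "YYY", 2, "A", "O", (2.8, 0, 0))])
        with pytest.warns(UserWarning, match="no hydrogen"):
            assert detect_hbonds(f, ContactCriteria(), ["A:1:N"], ["A:2:O"]) == []

    def test_matches_all_pairs_brute_force(self):
        """Dense random frames vs an O(n^2) scan over donors x hydrogens x acceptors."""
        rng = np.random.default_rng(8)
        crit = ContactCriteria()
        for trial in range(5):
            atoms, donors, acceptors = [], [], []
            for i in range(12):
                d = rng.uniform(0, 8, 3)
                atoms.append((f"N", "XXX", 10 + i, "A", "N", d))
                atoms.append((f"H", "XXX", 10 + i, "A", "H",
                              d + rng.normal(0, 0.4, 3) * 0.8))
                donors.append(f"A:{10 + i}:N")
            for i in range(12):
                atoms.append((f"O", "YYY", 50 + i, "B", "O", rng.uniform(0, 8, 3)))
                acceptors.append(f"B:{50 + i}:O")
            f = make_frame(atoms)
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                got = {(h[0], h[1], h[2]) for h in
                       detect_hbonds(f, crit, donors, acceptors)}
            expected = set()
            for dsel in donors:
                di = f.atom_index(dsel)
                for hi in range(len(f)):
                    if f.elements[hi] != "H":
                        continue
                    if np.linalg.norm(f.coords[hi] - f.coords[di]) > crit.dh_cutoff:
                        continue
                    for asel in acceptors:
                        ai = f.atom_index(asel)
                        dv = f.coords[di] - f.coords[hi]
                        av = f.coords[ai] - f.coords[hi]
                        cosang = np.dot(dv, av) / (np.linalg.norm(dv) * np.linalg.norm(av))
                        ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                        if (np.linalg.norm(f.coords[ai] - f.coords[di]) <= crit.da_cutoff
                                and ang >= crit.angle_deg):
                            key = ((f.chains[di], f.resseqs[di], f.names[di]),
                                   (f.chains[hi], f.resseqs[hi], f.names[hi]),
                                   (f.chains[ai], f.resseqs[ai], f.names[ai]))
                            expected.add(key)
            assert got == expected


class TestSaltBridges:
    @staticmethod
    def two_group_frame(dist):
        return make_frame([
            ("NZ", "LYS", 1, "A", "N", (0.0, 0.0, 0.0)),
            ("OD1", "ASP", 2, "A", "O", (dist, 0.0, 0.0)),
        ])

    def test_within_cutoff(self):
        f = self.two_group_frame(4.9)
        hits = detect_salt_bridges(f, ContactCriteria(), {"K1": ["A:1:NZ"]},
                                   {"D2": ["A:2:OD1"]})
        assert len(hits) == 1
        assert hits[0][2] == pytest.approx(4.9)

    def test_beyond_cutoff(self):
        f = self.two_group_frame(5.1)
        assert detect_salt_bridges(f, ContactCriteria(), {"K1": ["A:1:NZ"]},
                                   {"D2": ["A:2:OD1"]}) == []

    def test_empty_groups_rejected(self):
        f = self.two_group_frame(3.0)
        with pytest.raises(ValueError):
            detect_salt_bridges(f, ContactCriteria(), {}, {"D2": ["A:2:OD1"]})

    def test_matches_brute_force_com_scan(self):
        rng = np.random.default_rng(23)
        for _ in range(5):
            atoms, cats, ans = [], {}, {}
            for i in range(6):
                base = rng.uniform(0, 15, 3)
                atoms.append(("CZ", "ARG", 100 + i, "A", "C", base))
                atoms.append(("NH1", "ARG", 100 + i, "A", "N",
                              base + rng.normal(0, 0.5, 3)))
                cats[f"R{i}"] = [f"A:{100 + i}:CZ", f"A:{100 + i}:NH1"]
            for i in range(6):
                base = rng.uniform(0, 15, 3)
                atoms.append(("OE1", "GLU", 200 + i, "B", "O", base))
                atoms.append(("OE2", "GLU", 200 + i, "B", "O",
                              base + rng.normal(0, 0.5, 3)))
                ans[f"E{i}"] = [f"B:{200 + i}:OE1", f"B:{200 + i}:OE2"]
            f = make_frame(atoms)
            crit = ContactCriteria()
            got = {(c, a) for c, a, _ in detect_salt_bridges(f, crit, cats, ans)}
            expected = set()
            for cl, csels in cats.items():
                ccom = f.com([f.atom_index(s) for s in csels])
                for al, asels in ans.items():
                    acom = f.com([f.atom_index(s) for s in asels])
                    if np.linalg.norm(ccom - acom) <= crit.sb_cutoff:
                        expected.add((cl, al))
            assert got == expected


class TestInteractionFrequencies:
    @staticmethod
    def ser_asp_frame(bonded):
        """Ser OG donating to Asp OD1 when *bonded*, else retracted."""
        og = np.array([0.0, 0.0, 0.0])
        hg = og + np.array([0.96, 0.0, 0.0])
        od1 = og + np.array([2.8 if bonded else 6.0, 0.0, 0.0])
        return make_frame([
            ("OG", "SER", 5, "A", "O", og), ("HG", "SER", 5, "A", "H", hg),
            ("N", "SER", 5, "A", "N", og + [0, 3, 0]),
            ("O", "SER", 5, "A", "O", og + [0, -3, 0]),
            ("OD1", "ASP", 9, "B", "O", od1),
            ("OD2", "ASP", 9, "B", "O", od1 + [0, 1.1, 0]),
            ("CG", "ASP", 9, "B", "C", od1 + [0.6, 0.55, 0]),
            ("N", "ASP", 9, "B", "N", od1 + [0, 4, 0]),
            ("O", "ASP", 9, "B", "O", od1 + [0, -4, 0]),
        ])

    def test_always_and_never(self):
        always = [self.ser_asp_frame(True) for _ in range(4)]
        never = [self.ser_asp_frame(False) for _ in range(4)]
        fa = interaction_frequencies(always, [("A:5", "B:9")])
        fn = interaction_frequencies(never, [("A:5", "B:9")])
        assert fa[0]["DA"] == 1.0
        assert fn[0]["DA"] == 0.0

    def test_partial_occupancy(self):
        frames = [self.ser_asp_frame(i < 3) for i in range(10)]
        freq = interaction_frequencies(frames, [("A:5", "B:9")])
        assert freq[0]["DA"] == pytest.approx(0.3)

    def test_absent_residue_rejected(self):
        frames = [self.ser_asp_frame(True)]
        with pytest.raises(ValueError, match="absent"):
            interaction_frequencies(frames, [("A:5", "C:1")])


class TestDihedrals:
    @staticmethod
    def chain_frame(phi_deg):
        """Four-atom chain with the torsion about the central bond set to phi."""
        phi = np.radians(phi_deg)
        pts = [
            np.array([1.0, 1.0, 0.0]),
            np.array([0.0, 0.0, 0.0]),
            np.array([1.5, 0.0, 0.0]),
            np.array([1.5, 0.0, 0.0]) + np.array(
                [1.0, np.cos(phi), np.sin(phi)]),
        ]
        # torsion measured N-CA-CB-CG: first atom defines the reference plane
        return make_frame([
            ("N", "HIS", 94, "A", "N", pts[0]), ("CA", "HIS", 94, "A", "C", pts[1]),
            ("CB", "HIS", 94, "A", "C", pts[2]), ("CG", "HIS", 94, "A", "C", pts[3]),
            ("ND1", "HIS", 94, "A", "N", pts[3] + [1.0, 0.3, 0.2]),
        ])

    def test_cis_is_zero(self):
        chi1, _ = sidechain_dihedrals(self.chain_frame(0.0), "A", 94)
        assert chi1 == pytest.approx(0.0, abs=1e-9)

    def test_trans_is_180(self):
        chi1, _ = sidechain_dihedrals(self.chain_frame(180.0), "A", 94)
        assert abs(chi1) == pytest.approx(180.0, abs=1e-9)

    def test_against_normal_vector_oracle(self):
        """Random conformers vs an independent two-plane-normal dihedral oracle."""
        rng = np.random.default_rng(31)
        for _ in range(50):
            pts = rng.uniform(-5, 5, (5, 3))
            f = make_frame([
                ("N", "HIS", 94, "A", "N", pts[0]),
                ("CA", "HIS", 94, "A", "C", pts[1]),
                ("CB", "HIS", 94, "A", "C", pts[2]),
                ("CG", "HIS", 94, "A", "C", pts[3]),
                ("ND1", "HIS", 94, "A", "N", pts[4]),
            ])
            chi1, chi2 = sidechain_dihedrals(f, "A", 94)

            def oracle(p1, p2, p3, p4):
                n1 = np.cross(p2 - p1, p3 - p2)
                n2 = np.cross(p3 - p2, p4 - p3)
                cosphi = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
                phi = np.degrees(np.arccos(np.clip(cosphi, -1, 1)))
                if np.dot(np.cross(n1, n2), p3 - p2) < 0:
                    phi = -phi
                return phi

            assert chi1 == pytest.approx(oracle(*pts[:4]), abs=1e-9)
            assert chi2 == pytest.approx(oracle(*pts[1:5]), abs=1e-9)

    def test_missing_atom_named(self):
        f = make_frame([("N", "HIS", 94, "A", "N", (0, 0, 0)),
                        ("CA", "HIS", 94, "A", "C", (1, 0, 0)),
                        ("CB", "HIS", 94, "A", "C", (1, 1, 0))])
        with pytest.raises(ValueError, match="CG"):
            sidechain_dihedrals(f, "A", 94)


class TestRmsf:
    def test_identical_frames_zero(self, toy_frame):
        frames = [toy_frame, toy_frame, toy_frame]
        rmsf = per_residue_rmsf(frames, fit_selection=["A:87:SG", "B:76:C",
                                                       "B:76:O", "A:999:CAV"])
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in rmsf.values())

    def test_single_oscillating_atom(self):
        """One atom swinging +/-d along x in a rigid body has RMSF = d."""
        base = make_frame([
            ("CA", "GLY", i, "A", "C", (3.0 * i, 0.0, 0.0)) for i in range(1, 5)
        ] + [("CB", "ALA", 9, "A", "C", (0.0, 5.0, 0.0))])
        d = 0.7
        f1 = Frame(names=list(base.names), resnames=list(base.resnames),
                   resseqs=list(base.resseqs), chains=list(base.chains),
                   elements=list(base.elements), coords=base.coords.copy(), index=0)
        f2 = Frame(names=list(base.names), resnames=list(base.resnames),
                   resseqs=list(base.resseqs), chains=list(base.chains),
                   elements=list(base.elements), coords=base.coords.copy(), index=1)
        f2.coords[4, 0] += 2 * d
        rmsf = per_residue_rmsf([f1, f2], fit_selection=[f"A:{i}:CA"
                                                         for i in range(1, 5)])
        assert rmsf[("A", 9)] == pytest.approx(d, abs=1e-12)
        assert rmsf[("A", 1)] == pytest.approx(0.0, abs=1e-12)

    def test_selection_mismatch_rejected(self, toy_frame):
        other = make_frame([("CA", "GLY", 1, "A", "C", (0, 0, 0))])
        with pytest.raises(ValueError, match="differ"):
            per_residue_rmsf([toy_frame, other])


class TestPocketVolume:
    @staticmethod
    def axis_frame(extra=()):
        """Four distant atoms whose pair midpoints put the sphere centre at the origin."""
        atoms = [
            ("A1", "DUM", 1, "Z", "C", (-50.0, 0.0, 0.0)),
            ("A2", "DUM", 2, "Z", "C", (50.0, 0.0, 0.0)),
            ("A3", "DUM", 3, "Z", "C", (0.0, -50.0, 0.0)),
            ("A4", "DUM", 4, "Z", "C", (0.0, 50.0, 0.0)),
        ]
        return make_frame(atoms + list(extra))

    SPEC = dict(pair1=("Z:1:A1", "Z:2:A2"), pair2=("Z:3:A3", "Z:4:A4"))

    def test_empty_sphere_near_analytic_volume(self):
        """No atoms inside: grid count * spacing^3 within one shell of (4/3)pi r^3."""
        f = self.axis_frame()
        spec = PocketSpec(**self.SPEC, radius=12.0, spacing=0.5, hull=False)
        vol, pts = pocket_volume(f, spec, return_points=True)
        analytic = 4.0 / 3.0 * np.pi * 12.0**3
        shell = 4.0 * np.pi * 12.0**2 * spec.spacing  # one-grid-shell tolerance
        assert abs(vol - analytic) <= shell
        # exact point-count oracle on an independent grid construction
        m = int(np.floor(spec.radius / spec.spacing))
        count = sum(
            1
            for i in range(-m, m + 1) for j in range(-m, m + 1)
            for k in range(-m, m + 1)
            if (i * i + j * j + k * k) * spec.spacing**2 <= spec.radius**2
        )
        assert vol == pytest.approx(count * spec.spacing**3)
        assert len(pts) == count

    def test_fully_packed_sphere_is_zero(self):
        rng = np.random.default_rng(6)
        # lattice of blockers covering the sphere (spacing < 2*exclusion)
        grid = np.arange(-4.0, 4.5, 1.0)
        blockers = [(f"B", "BLK", 1000 + n, "X", "C", (x, y, z))
                    for n, (x, y, z) in enumerate(
                        (x, y, z) for x in grid for y in grid for z in grid)]
        f = self.axis_frame(extra=blockers)
        spec = PocketSpec(**self.SPEC, radius=3.0, spacing=0.5, exclusion=1.09,
                          hull=False)
        assert pocket_volume(f, spec) == 0.0

    def test_single_atom_carves_exclusion_sphere(self):
        """Brute-force per-point check of the heavy-atom deletion rule."""
        atom = ("B", "BLK", 1000, "X", "C", (0.4, -0.2, 0.3))
        f = self.axis_frame(extra=[atom])
        spec = PocketSpec(**self.SPEC, radius=4.0, spacing=0.5, exclusion=1.09,
                          hull=False)
        vol, pts = pocket_volume(f, spec, return_points=True)
        m = int(np.floor(spec.radius / spec.spacing))
        kept = []
        for i in range(-m, m + 1):
            for j in range(-m, m + 1):
                for k in range(-m, m + 1):
                    p = np.array([i, j, k]) * spec.spacing
                    if np.linalg.norm(p) > spec.radius:
                        continue
                    if np.linalg.norm(p - np.array(atom[5])) < spec.exclusion:
                        continue
                    kept.append(p)
        assert vol == pytest.approx(len(kept) * spec.spacing**3)
        got = {tuple(np.round(q, 6)) for q in pts}
        expected = {tuple(np.round(q, 6)) for q in kept}
        assert got == expected

    def test_hull_pruning_restricts_to_atom_envelope(self):
        """With hull pruning, only grid points inside the heavy-atom hull survive."""
        # a tight tetrahedron of atoms around the centre
        tetra = [("T", "TET", 2000 + i, "X", "C", xyz) for i, xyz in enumerate([
            (3.0, 3.0, 3.0), (-3.0, -3.0, 3.0), (-3.0, 3.0, -3.0), (3.0, -3.0, -3.0),
        ])]
        f = make_frame(tetra + [
            ("A1", "DUM", 1, "Z", "C", (-1.0, 0.0, 0.0)),
            ("A2", "DUM", 2, "Z", "C", (1.0, 0.0, 0.0)),
            ("A3", "DUM", 3, "Z", "C", (0.0, -1.0, 0.0)),
            ("A4", "DUM", 4, "Z", "C", (0.0, 1.0, 0.0)),
        ])
        spec_hull = PocketSpec(**self.SPEC, radius=8.0, spacing=0.5, hull=True)
        spec_free = PocketSpec(**self.SPEC, radius=8.0, spacing=0.5, hull=False)
        assert pocket_volume(f, spec_hull) < pocket_volume(f, spec_free)

    def test_hull_without_atoms_rejected(self):
        f = make_frame([
            ("A1", "DUM", 1, "Z", "C", (-1.0, 0.0, 0.0)),
            ("A2", "DUM", 2, "Z", "C", (1.0, 0.0, 0.0)),
        ])
        spec = PocketSpec(pair1=("Z:1:A1", "Z:2:A2"), pair2=("Z:1:A1", "Z:2:A2"),
                          radius=3.0, spacing=0.5, hull=True)
        with pytest.raises(ValueError):
            pocket_volume(f, spec)


class TestRigidBodyInvariance:
    def test_offset_angle_dihedral_contacts_invariant(self, toy_frame, site):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(77)
        off0 = signed_plane_offset(toy_frame, site)
        ang0 = orientation_angle(toy_frame, site)
        for _ in range(5):
            r = Rotation.random(random_state=rng.integers(2**31)).as_matrix()
            t = rng.uniform(-20, 20, 3)
            moved = toy_frame.transformed(r, t)
            assert signed_plane_offset(moved, site) == pytest.approx(off0, abs=1e-9)
            assert orientation_angle(moved, site) == pytest.approx(ang0, abs=1e-9)
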