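"""Geometric observables on coordinate ensembles of the E2-Ub conjugate.

Operates on :class:`Frame` objects (named atoms with coordinates, one frame
per ensemble member) and computes the observables used to judge whether the
catalytic histidine can act as a general base on the thioester:

* signed offset of the His epsilon-nitrogen from the thioester plane
  (through Cys Sgamma and the ubiquitin Gly76 carbonyl C and O), positive
  toward the solvent cavity;
* orientation angle at the epsilon-nitrogen between the imidazole ring
  centre of mass and the carbonyl carbon;
* hydrogen bonds (donor-acceptor distance + donor-H-acceptor angle),
  salt bridges (ion-pair centre-of-mass distance), and their per-ensemble
  interaction frequencies;
* side-chain chi1/chi2 dihedrals;
* per-residue RMSF after least-squares superposition;
* binding-pocket volume by grid flooding with heavy-atom exclusion and
  convex-hull pruning.

Distances are in Angstroms, angles in degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree
from scipy.spatial import QhullError

__all__ = [
    "Frame",
    "ThioesterSite",
    "ContactCriteria",
    "PocketSpec",
    "signed_plane_offset",
    "orientation_angle",
    "classify_base_catalysis",
    "detect_hbonds",
    "detect_salt_bridges",
    "interaction_frequencies",
    "sidechain_dihedrals",
    "per_residue_rmsf",
    "pocket_volume",
    "superpose",
    "geometry_report",
]

# masses for centre-of-mass computations
_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
           "P": 30.974, "SE": 78.971}

# His tautomer dialects -> which ring nitrogen is unprotonated
_HIS_NAMES = {"HIS", "HID", "HIE", "HIP", "HSD", "HSE", "HSP"}
_HIS_UNPROTONATED = {
    "HID": "NE2", "HSD": "NE2",   # delta-protonated -> epsilon N free
    "HIE": "ND1", "HSE": "ND1",   # epsilon-protonated -> delta N free
    "HIS": "NE2", "HSP": None, "HIP": None,  # doubly protonated: none free
}


def _element_from_name(name: str) -> str:
    """Heuristic element assignment from a PDB atom name."""
    stripped = name.strip()
    if not stripped:
        return ""
    if stripped[0].isdigit() or (len(name) >= 1 and name[:1] == "H"):
        return "H"
    if stripped[:2].upper() in ("CL", "BR", "FE", "ZN", "MG", "NA", "SE"):
        return stripped[:2].upper()
    return stripped[0].upper()


@dataclass
class Frame:
    """One set of coordinates: parallel arrays of atom metadata plus (N, 3) xyz.

    Atoms are keyed by ``(chain, resseq, atom name)``; duplicate keys are
    rejected.  His tautomer dialects (HID/HIE/HSD/HSE/...) are normalised to
    HIS on input, with the original name retained in ``tautomers`` so the
    unprotonated ring nitrogen can be identified.
    """

    names: list[str]
    resnames: list[str]
    resseqs: list[int]
    chains: list[str]
    elements: list[str]
    coords: np.ndarray
    index: int = 0
    tautomers: dict[tuple[str, int], str] = field(default_factory=dict)
    _lookup: dict[tuple[str, int, str], int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.names)
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords must be ({n}, 3), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        # normalise His dialects, remember the tautomer
        resnames = []
        for rn, ch, rs in zip(self.resnames, self.chains, self.resseqs):
            if rn in _HIS_NAMES and rn != "HIS":
                self.tautomers.setdefault((ch, rs), rn)
                rn = "HIS"
            resnames.append(rn)
        self.resnames = resnames
        elements = [
            e.strip().upper() if e and e.strip() else _element_from_name(nm)
            for e, nm in zip(self.elements, self.names)
        ]
        self.elements = elements
        lookup: dict[tuple[str, int, str], int] = {}
        for i, key in enumerate(zip(self.chains, self.resseqs, self.names)):
            if key in lookup:
                raise ValueError(f"duplicate atom key {key}")
            lookup[key] = i
        self._lookup = lookup

    def __len__(self) -> int:
        return len(self.names)

    # -- selection --------------------------------------------------------

    @staticmethod
    def parse_selector(sel: str) -> tuple[str, int, str]:
        """Parse a ``chain:resnum:atomname`` selector string."""
        parts = sel.split(":")
        if len(parts) != 3:
            raise ValueError(f"selector must be 'chain:resnum:atomname', got {sel!r}")
        return parts[0], int(parts[1]), parts[2]

    def atom_index(self, sel: "str | tuple[str, int, str]") -> int:
        key = self.parse_selector(sel) if isinstance(sel, str) else tuple(sel)
        try:
            return self._lookup[key]
        except KeyError:
            raise KeyError(f"atom {key} not found in frame {self.index}") from None

    def xyz(self, sel) -> np.ndarray:
        return self.coords[self.atom_index(sel)]

    def residue_atoms(self, chain: str, resseq: int) -> list[int]:
        return [i for i, (c, r) in enumerate(zip(self.chains, self.resseqs))
                if c == chain and r == resseq]

    def residue_name(self, chain: str, resseq: int) -> str:
        idx = self.residue_atoms(chain, resseq)
        if not idx:
            raise KeyError(f"residue {chain}:{resseq} not found")
        return self.resnames[idx[0]]

    def unprotonated_his_nitrogen(self, chain: str, resseq: int) -> str:
        """Name of the unprotonated His ring nitrogen, from the tautomer dialect.

        A plain HIS record defaults to the delta-protonated tautomer (free
        epsilon nitrogen, NE2), the arrangement required for base catalysis.
        """
        name = self.tautomers.get((chain, resseq), "HIS")
        n = _HIS_UNPROTONATED.get(name)
        if n is None:
            raise ValueError(
                f"residue {chain}:{resseq} ({name}) is doubly protonated; "
                "no unprotonated ring nitrogen"
            )
        return n

    def heavy_mask(self) -> np.ndarray:
        return np.array([e != "H" for e in self.elements], dtype=bool)

    def masses(self) -> np.ndarray:
        return np.array([_MASSES.get(e, 12.011) for e in self.elements])

    def com(self, indices) -> np.ndarray:
        """Mass-weighted centre of mass of the given atom indices."""
        idx = np.asarray(indices, dtype=int)
        m = self.masses()[idx]
        return (self.coords[idx] * m[:, None]).sum(axis=0) / m.sum()

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Frame":
        """A copy with coordinates x -> R x + t."""
        return Frame(
            names=list(self.names), resnames=list(self.resnames),
            resseqs=list(self.resseqs), chains=list(self.chains),
            elements=list(self.elements),
            coords=self.coords @ np.asarray(rotation).T + np.asarray(translation),
            index=self.index, tautomers=dict(self.tautomers),
        )


@dataclass(frozen=True)
class ThioesterSite:
    """Atom selectors defining the thioester plane and the histidine probe.

    ``sg``, ``carbonyl_c``, ``carbonyl_o`` span the thioester plane;
    ``his_ne`` is the unprotonated His ring nitrogen probed against it;
    ``ring`` are the five imidazole ring atoms; ``cavity_ref`` is any atom on
    the solvent-cavity side, fixing the positive sense of the plane normal.
    """

    sg: str
    carbonyl_c: str
    carbonyl_o: str
    his_ne: str
    ring: tuple[str, str, str, str, str]
    cavity_ref: str

    def __post_init__(self) -> None:
        if len(self.ring) != 5:
            raise ValueError(f"ring must list exactly 5 atoms, got {len(self.ring)}")


@dataclass(frozen=True)
class ContactCriteria:
    """Geometric cutoffs for hydrogen bonds and salt bridges.

    ``dh_cutoff`` (A) identifies the hydrogen covalently bound to a donor;
    ``da_cutoff`` (A) bounds the donor-acceptor distance; ``angle_deg`` is
    the donor-H-acceptor angle threshold — by default a *minimum* (near-linear
    bonds accepted).  ``literal_hbond`` switches to the literal alternative
    reading in which the angle is a maximum and the H...acceptor distance
    must not exceed ``dh_cutoff``.  ``sb_cutoff`` (A) bounds the ion-pair
    centre-of-mass distance for salt bridges.
    """

    dh_cutoff: float = 1.2
    da_cutoff: float = 3.0
    angle_deg: float = 150.0
    sb_cutoff: float = 5.0
    literal_hbond: bool = False

    def __post_init__(self) -> None:
        for name in ("dh_cutoff", "da_cutoff", "sb_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 < self.angle_deg <= 180):
            raise ValueError("angle_deg must be in (0, 180]")


@dataclass(frozen=True)
class PocketSpec:
    """Grid definition for the active-site pocket volume.

    The inclusion sphere is centred on the axis between two atom pairs: its
    centre is the midpoint of the segment joining the two pair midpoints.
    ``spacing`` sets the flood-grid pitch, ``exclusion`` the heavy-atom
    deletion radius; ``hull`` enables convex-hull pruning against the
    frame's heavy atoms.
    """

    pair1: tuple[str, str]
    pair2: tuple[str, str]
    radius: float = 12.0
    spacing: float = 0.5
    exclusion: float = 1.09
    hull: bool = True

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.spacing <= 0 or self.exclusion <= 0:
            raise ValueError("radius, spacing and exclusion must be > 0")
        if self.spacing >= self.radius:
            raise ValueError("spacing must be smaller than the radius")


# ---------------------------------------------------------------------------
# plane / angle / dihedral
# ---------------------------------------------------------------------------


def _plane_normal(s: np.ndarray, c: np.ndarray, o: np.ndarray) -> np.ndarray:
    n = np.cross(c - s, o - s)
    norm = np.linalg.norm(n)
    if norm < 1e-9:
        raise ValueError("plane atoms are collinear; plane undefined")
    return n / norm


def signed_plane_offset(frame: Frame, site: ThioesterSite) -> float:
    """Signed distance (A) of the His nitrogen from the thioester plane.

    Coordinates are centred on Sgamma; the offset is the dot product of the
    unit plane normal with the centred nitrogen position.  The normal is
    oriented so the cavity reference atom scores positive, i.e. positive
    offsets place the nitrogen on the solvent-cavity side.
    """
    s = frame.xyz(site.sg)
    n_hat = _plane_normal(s, frame.xyz(site.carbonyl_c), frame.xyz(site.carbonyl_o))
    if np.dot(n_hat, frame.xyz(site.cavity_ref) - s) < 0:
        n_hat = -n_hat
    return float(np.dot(n_hat, frame.xyz(site.his_ne) - s))


def _angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    v1, v2 = a - vertex, b - vertex
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-9 or n2 < 1e-9:
        raise ValueError("coincident points; angle undefined")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def orientation_angle(frame: Frame, site: ThioesterSite) -> float:
    """Angle (deg) at the His nitrogen between the imidazole ring COM and the carbonyl C."""
    ring_idx = [frame.atom_index(s) for s in site.ring]
    com = frame.com(ring_idx)
    return _angle_deg(com, frame.xyz(site.his_ne), frame.xyz(site.carbonyl_c))


def classify_base_catalysis(
    offset: float, angle: float, offset_max: float = 3.5,
    angle_window: tuple[float, float] = (0.0, 180.0),
) -> bool:
    """Whether a configuration is compatible with general base catalysis.

    Base abstraction of the nucleophile proton requires the unprotonated
    nitrogen near (roughly 3 A from) the thioester plane with a suitable
    orientation toward the carbonyl.  Default thresholds accept
    ``|offset| <= 3.5`` A at any orientation; the angle window is
    configurable and deliberately carries no tighter default.
    """
    lo, hi = angle_window
    return bool(abs(offset) <= offset_max and lo <= angle <= hi)


def sidechain_dihedrals(
    frame: Frame, chain: str, resseq: int,
    chi1_atoms: tuple[str, str, str, str] = ("N", "CA", "CB", "CG"),
    chi2_atoms: tuple[str, str, str, str] = ("CA", "CB", "CG", "ND1"),
) -> tuple[float, float]:
    """Side-chain chi1/chi2 dihedrals (deg) of one residue, signed in (-180, 180].

    Defaults follow the histidine convention chi1 = N-CA-CB-CG and
    chi2 = CA-CB-CG-Ndelta.
    """

    def get(name: str) -> np.ndarray:
        try:
            return frame.xyz((chain, resseq, name))
        except KeyError:
            raise ValueError(
                f"residue {chain}:{resseq} is missing atom {name!r}"
            ) from None

    def dihedral(p1, p2, p3, p4) -> float:
        # IUPAC sign convention (0 = cis), matching standard MD toolkits
        b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        m1 = np.cross(b2 / np.linalg.norm(b2), n1)
        x, y = np.dot(n1, n2), np.dot(m1, n2)
        ang = float(np.degrees(np.arctan2(y, x)))
        return 180.0 if ang == -180.0 else ang

    chi1 = dihedral(*(get(a) for a in chi1_atoms))
    chi2 = dihedral(*(get(a) for a in chi2_atoms))
    return chi1, chi2


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------


def detect_hbonds(
    frame: Frame, criteria: ContactCriteria, donors: list, acceptors: list,
) -> list[tuple]:
    """Hydrogen bonds among the given donor/acceptor heavy atoms.

    For each donor, hydrogens are identified as H atoms within
    ``dh_cutoff`` of it; a bond is recorded when the donor-acceptor distance
    is within ``da_cutoff`` and the donor-H-acceptor angle passes the
    threshold (a minimum by default, a maximum in literal mode, which then
    also bounds the H...acceptor distance by ``dh_cutoff``).  Donors with no
    attached hydrogen are skipped with a warning.  Output is sorted by
    (donor residue, acceptor residue).

    Returns tuples ``(donor_key, hydrogen_key, acceptor_key, d_DA, angle)``.
    """
    h_idx = np.flatnonzero(~frame.heavy_mask())
    results = []
    for d_sel in donors:
        di = frame.atom_index(d_sel)
        d_xyz = frame.coords[di]
        if h_idx.size:
            dists = np.linalg.norm(frame.coords[h_idx] - d_xyz, axis=1)
            attached = h_idx[dists <= criteria.dh_cutoff]
        else:
            attached = np.array([], dtype=int)
        if attached.size == 0:
            warnings.warn(
                f"donor {d_sel} has no hydrogen within {criteria.dh_cutoff} A; skipped",
                UserWarning, stacklevel=2,
            )
            continue
        for a_sel in acceptors:
            ai = frame.atom_index(a_sel)
            if ai == di:
                continue
            a_xyz = frame.coords[ai]
            d_da = float(np.linalg.norm(a_xyz - d_xyz))
            if d_da > criteria.da_cutoff:
                continue
            for hi in attached:
                h_xyz = frame.coords[hi]
                ang = _angle_deg(d_xyz, h_xyz, a_xyz)
                if criteria.literal_hbond:
                    ok = (ang <= criteria.angle_deg
                          and np.linalg.norm(a_xyz - h_xyz) <= criteria.dh_cutoff)
                else:
                    ok = ang >= criteria.angle_deg
                if ok:
                    dk = (frame.chains[di], frame.resseqs[di], frame.names[di])
                    hk = (frame.chains[hi], frame.resseqs[hi], frame.names[hi])
                    ak = (frame.chains[ai], frame.resseqs[ai], frame.names[ai])
                    results.append((dk, hk, ak, d_da, ang))
    results.sort(key=lambda r: (r[0][0], r[0][1], r[2][0], r[2][1], r[0][2], r[2][2]))
    return results


def detect_salt_bridges(
    frame: Frame, criteria: ContactCriteria,
    cation_groups: dict[str, list], anion_groups: dict[str, list],
) -> list[tuple[str, str, float]]:
    """Salt bridges: ion-pair centre-of-mass distance not exceeding the cutoff.

    ``cation_groups`` / ``anion_groups`` map a group label to the atom
    selectors forming the charged moiety (e.g. the three guanidinium
    nitrogens+carbon of Arg, the two carboxylate oxygens+carbon of Asp/Glu).
    """
    if not cation_groups or not anion_groups:
        raise ValueError("charged-group definitions must be non-empty")
    cat_com = {lbl: frame.com([frame.atom_index(s) for s in sels])
               for lbl, sels in cation_groups.items()}
    an_com = {lbl: frame.com([frame.atom_index(s) for s in sels])
              for lbl, sels in anion_groups.items()}
    out = []
    for cl in sorted(cat_com):
        for al in sorted(an_com):
            d = float(np.linalg.norm(cat_com[cl] - an_com[al]))
            if d <= criteria.sb_cutoff:
                out.append((cl, al, d))
    return out


# default residue chemistry for pairwise interaction tables
_SIDECHAIN_DONORS = {
    "SER": ["OG"], "THR": ["OG1"], "TYR": ["OH"], "LYS": ["NZ"],
    "ARG": ["NE", "NH1", "NH2"], "ASN": ["ND2"], "GLN": ["NE2"],
    "TRP": ["NE1"], "CYS": ["SG"],
}
_SIDECHAIN_ACCEPTORS = {
    "ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"], "ASN": ["OD1"],
    "GLN": ["OE1"], "SER": ["OG"], "THR": ["OG1"], "TYR": ["OH"],
    "MET": ["SD"],
}
_CATION_GROUPS = {"LYS": ["NZ"], "ARG": ["CZ", "NH1", "NH2"]}
_ANION_GROUPS = {"ASP": ["CG", "OD1", "OD2"], "GLU": ["CD", "OE1", "OE2"]}


def _residue_donors(frame: Frame, chain: str, resseq: int) -> list:
    rn = frame.residue_name(chain, resseq)
    names = ["N"] + list(_SIDECHAIN_DONORS.get(rn, []))
    if rn == "HIS":
        free = frame.tautomers.get((chain, resseq), "HIS")
        protonated = {"HID": ["ND1"], "HSD": ["ND1"], "HIE": ["NE2"],
                      "HSE": ["NE2"], "HIS": ["ND1"],
                      "HIP": ["ND1", "NE2"], "HSP": ["ND1", "NE2"]}[free]
        names += protonated
    present = {frame.names[i] for i in frame.residue_atoms(chain, resseq)}
    return [(chain, resseq, n) for n in names if n in present]


def _residue_acceptors(frame: Frame, chain: str, resseq: int) -> list:
    rn = frame.residue_name(chain, resseq)
    names = ["O"] + list(_SIDECHAIN_ACCEPTORS.get(rn, []))
    if rn == "HIS":
        try:
            names.append(frame.unprotonated_his_nitrogen(chain, resseq))
        except ValueError:
            pass
    present = {frame.names[i] for i in frame.residue_atoms(chain, resseq)}
    return [(chain, resseq, n) for n in names if n in present]


def _residue_charged(frame: Frame, chain: str, resseq: int):
    rn = frame.residue_name(chain, resseq)
    present = {frame.names[i] for i in frame.residue_atoms(chain, resseq)}
    cat = _CATION_GROUPS.get(rn)
    an = _ANION_GROUPS.get(rn)
    cation = [(chain, resseq, n) for n in cat] if cat and set(cat) <= present else None
    anion = [(chain, resseq, n) for n in an] if an and set(an) <= present else None
    return cation, anion


def interaction_frequencies(
    ensemble: list[Frame],
    pairs: list[tuple[str, str]],
    criteria: ContactCriteria | None = None,
) -> list[dict]:
    """Per-residue-pair interaction frequencies over an ensemble.

    For each pair of residues (given as ``chain:resnum`` strings) the
    fraction of frames is reported in which residue 1 donates a hydrogen
    bond to residue 2 (``DA``), accepts one from it (``AD``), or the two
    form a salt bridge (``SB``).  Donor/acceptor/charged-group atoms are
    derived from standard residue chemistry (His tautomer-aware).
    """
    if not ensemble:
        raise ValueError("ensemble must contain at least one frame")
    criteria = criteria or ContactCriteria()

    def parse_res(s: str) -> tuple[str, int]:
        ch, rs = s.split(":")
        return ch, int(rs)

    ref = ensemble[0]
    parsed = []
    for r1, r2 in pairs:
        k1, k2 = parse_res(r1), parse_res(r2)
        for k in (k1, k2):
            if not ref.residue_atoms(*k):
                raise ValueError(f"residue {k[0]}:{k[1]} absent from ensemble")
        parsed.append((k1, k2))

    counts = [dict(DA=0, AD=0, SB=0) for _ in parsed]
    for frame in ensemble:
        for i, (k1, k2) in enumerate(parsed):
            d1, a1 = _residue_donors(frame, *k1), _residue_acceptors(frame, *k1)
            d2, a2 = _residue_donors(frame, *k2), _residue_acceptors(frame, *k2)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                if d1 and a2 and detect_hbonds(frame, criteria, d1, a2):
                    counts[i]["DA"] += 1
                if d2 and a1 and detect_hbonds(frame, criteria, d2, a1):
                    counts[i]["AD"] += 1
            c1, n1 = _residue_charged(frame, *k1)
            c2, n2 = _residue_charged(frame, *k2)
            sb = False
            if c1 and n2 and detect_salt_bridges(
                    frame, criteria, {"1": c1}, {"2": n2}):
                sb = True
            if not sb and c2 and n1 and detect_salt_bridges(
                    frame, criteria, {"2": c2}, {"1": n1}):
                sb = True
            if sb:
                counts[i]["SB"] += 1

    n = len(ensemble)
    return [
        {"res1": f"{k1[0]}:{k1[1]}", "res2": f"{k2[0]}:{k2[1]}",
         "DA": c["DA"] / n, "AD": c["AD"] / n, "SB": c["SB"] / n}
        for (k1, k2), c in zip(parsed, counts)
    ]


# ---------------------------------------------------------------------------
# superposition / RMSF
# ---------------------------------------------------------------------------


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation+translation mapping *mobile* onto *target*."""
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return r, tc - r @ mc


def superpose(frame: Frame, reference: Frame, fit_indices) -> Frame:
    """Superpose *frame* onto *reference*, minimising RMSD over *fit_indices*."""
    r, t = _kabsch(frame.coords[fit_indices], reference.coords[fit_indices])
    return frame.transformed(r, t)


def per_residue_rmsf(
    ensemble: list[Frame],
    fit_selection: list | None = None,
    measure_selection: list | None = None,
) -> dict[tuple[str, int], float]:
    """Per-residue RMSF (A) after superposition onto the first frame.

    Each frame is least-squares-fitted to the first frame over
    *fit_selection* (default: all C-alpha atoms); fluctuations are then
    measured about the ensemble-mean position of each atom in
    *measure_selection* (default: all atoms) and pooled per residue as the
    root of the mean squared fluctuation over the residue's atoms and frames.
    """
    if len(ensemble) < 2:
        raise ValueError("RMSF requires at least two frames")
    ref = ensemble[0]
    keys0 = list(zip(ref.chains, ref.resseqs, ref.names))
    for f in ensemble[1:]:
        if list(zip(f.chains, f.resseqs, f.names)) != keys0:
            raise ValueError("atom selections differ between frames")

    if fit_selection is None:
        fit_idx = [i for i, n in enumerate(ref.names) if n == "CA"]
        if not fit_idx:
            fit_idx = list(range(len(ref)))
    else:
        fit_idx = [ref.atom_index(s) for s in fit_selection]
    if measure_selection is None:
        meas_idx = np.arange(len(ref))
    else:
        meas_idx = np.array([ref.atom_index(s) for s in measure_selection])

    aligned = np.stack(
        [superpose(f, ref, fit_idx).coords[meas_idx] for f in ensemble]
    )  # (frames, atoms, 3)
    mean = aligned.mean(axis=0)
    msf = ((aligned - mean) ** 2).sum(axis=2).mean(axis=0)  # per atom

    out: dict[tuple[str, int], list[float]] = {}
    for j, i in enumerate(meas_idx):
        out.setdefault((ref.chains[i], ref.resseqs[i]), []).append(msf[j])
    return {k: float(np.sqrt(np.mean(v))) for k, v in out.items()}


# ---------------------------------------------------------------------------
# pocket volume
# ---------------------------------------------------------------------------


def pocket_volume(
    frame: Frame, spec: PocketSpec, return_points: bool = False,
):
    """Pocket volume (A^3) by grid flooding.

    A cubic grid with pitch ``spacing`` floods the inclusion sphere (points
    at centre + spacing*(i, j, k), kept while within ``radius`` of the
    centre).  Points strictly closer than ``exclusion`` to any heavy atom
    are deleted (a point exactly at the cutoff is retained); with hull
    pruning enabled, points outside the convex hull of the heavy atoms are
    removed as well.  The volume is the surviving point count times
    ``spacing**3``.
    """
    p1 = 0.5 * (frame.xyz(spec.pair1[0]) + frame.xyz(spec.pair1[1]))
    p2 = 0.5 * (frame.xyz(spec.pair2[0]) + frame.xyz(spec.pair2[1]))
    center = 0.5 * (p1 + p2)

    m = int(np.floor(spec.radius / spec.spacing))
    axis = np.arange(-m, m + 1) * spec.spacing
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    pts = pts[np.linalg.norm(pts, axis=1) <= spec.radius] + center

    heavy = frame.coords[frame.heavy_mask()] if len(frame) else np.empty((0, 3))
    if heavy.shape[0]:
        tree = cKDTree(heavy)
        dmin, _ = tree.query(pts, k=1)
        pts = pts[~(dmin < spec.exclusion)]  # strict <: exactly-at-cutoff retained
    if spec.hull:
        if heavy.shape[0] < 4:
            raise ValueError("convex-hull pruning requires >= 4 heavy atoms")
        try:
            tri = Delaunay(heavy)
        except QhullError as e:
            raise ValueError(f"convex hull of heavy atoms undefined: {e}") from None
        pts = pts[tri.find_simplex(pts) >= 0]

    volume = float(pts.shape[0] * spec.spacing**3)
    return (volume, pts) if return_points else volume


# ---------------------------------------------------------------------------
# per-frame report
# ---------------------------------------------------------------------------


def geometry_report(
    ensemble: list[Frame],
    site: ThioesterSite,
    pocket: PocketSpec | None = None,
    offset_max: float = 3.5,
    angle_window: tuple[float, float] = (0.0, 180.0),
):
    """Per-frame table of offset, orientation angle, catalysis call and pocket volume.

    Returns a pandas DataFrame with columns
    ``frame, offset_A, angle_deg, compatible, volume_A3`` (volume NaN when no
    pocket spec is given).
    """
    import pandas as pd

    rows = []
    for f in ensemble:
        off = signed_plane_offset(f, site)
        ang = orientation_angle(f, site)
        rows.append({
            "frame": f.index,
            "offset_A": off,
            "angle_deg": ang,
            "compatible": classify_base_catalysis(off, ang, offset_max, angle_window),
            "volume_A3": pocket_volume(f, pocket) if pocket is not None else float("nan"),
        })
    return pd.DataFrame(rows)
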