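"""Synthetic test inputs with known ground truth.

Every analysis path in the package has a generator here that produces inputs
from a known truth, so generator -> analysis round trips can be checked
exactly at zero noise and statistically under noise:

* chase time courses under the three-pathway discharge scheme with additive
  Gaussian densitometry noise (including the co-migrating autoubiquitinated
  species folded into the mono-ubiquitin band);
* gel-lane intensity tables (with optional NaOH-treated twin lanes at a
  prescribed resistant fraction);
* toy coordinate frames with a thioester plane, an imidazole-proxy ring and
  a probe nitrogen at prescribed signed offset and orientation angle;
* fluctuating ensembles with per-atom Gaussian jitter and optionally a
  scripted hydrogen-bond on/off schedule.

Noise is additive Gaussian on fractions and unclipped by default: real
densitometry produces slight excursions outside [0, 1] and the fits must
tolerate them.  A single integer seed fans out into per-generator,
per-stream substreams (``numpy.random.SeedSequence``), so adding a generator
never perturbs existing streams.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .densitometry import LaneQuant
from .fitting import ChaseDesign
from .geometry import Frame, ThioesterSite
from .kinetics import KineticParams, TimeCourse, observed_mono_signal

__all__ = [
    "NoiseModel",
    "ToyGeometrySpec",
    "gen_chase",
    "gen_lane_table",
    "gen_thioester_frame",
    "gen_fluctuating_ensemble",
    "toy_site",
]

# stream ids per generator: appending new generators must not disturb these
_STREAM_CHASE = 1
_STREAM_LANES = 2
_STREAM_FRAME = 3
_STREAM_ENSEMBLE = 4


def _rng(seed: int, stream: int, sub: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream, sub]))


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise on fractions; ``clip`` restricts output to [0, 1]."""

    sigma: float = 0.0
    seed: int = 0
    clip: bool = False

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")


def gen_chase(
    truth: KineticParams,
    nus: list[float],
    times: np.ndarray,
    noise: NoiseModel = NoiseModel(),
) -> ChaseDesign:
    """Simulated paired chase experiment: one course per nucleophile concentration.

    Each course is the closed-form mono-ubiquitin band signal at the given
    [Nu] plus i.i.d. Gaussian noise.  Generating parameters are embedded in
    the course labels for traceability.
    """
    times = np.asarray(times, dtype=float)
    courses = []
    for i, nu in enumerate(nus):
        tc = observed_mono_signal(truth, nu, times)
        sig = tc.signal
        if noise.sigma > 0:
            sig = sig + _rng(noise.seed, _STREAM_CHASE, i).normal(0.0, noise.sigma,
                                                                  size=sig.shape)
            if noise.clip:
                sig = np.clip(sig, 0.0, 1.0)
        courses.append(
            TimeCourse(
                times=times.copy(), signal=sig, nu=float(nu),
                observable="mono_band",
                label=(f"synthetic k1={truth.k1:g} k2={truth.k2:g} "
                       f"k3={truth.k3:g} E2L0={truth.E2L0:g} "
                       f"sigma={noise.sigma:g} seed={noise.seed}"),
                replicate=str(i + 1),
            )
        )
    return ChaseDesign(courses=courses)


def gen_lane_table(
    times: np.ndarray,
    modified_fractions: np.ndarray,
    scale: float = 1000.0,
    background: float = 0.0,
    noise: NoiseModel = NoiseModel(),
    naoh_resistant: float | None = None,
    condition: str = "synthetic",
) -> list[LaneQuant]:
    """Gel-lane intensity tables from known modified fractions.

    Per time point one untreated lane is emitted with
    ``modified_total = f*scale + background`` and ``unmodified = (1-f)*scale``,
    plus (when *naoh_resistant* is given) a NaOH-treated twin in which the
    alkali-labile share of the modification reverts to the unmodified band.
    With zero noise and matching background subtraction, densitometry
    recovers the input fractions exactly, and the NaOH partition returns
    *naoh_resistant*.
    """
    if background < 0:
        raise ValueError(f"background must be >= 0, got {background}")
    times = np.asarray(times, dtype=float)
    fr = np.asarray(modified_fractions, dtype=float)
    if times.shape != fr.shape:
        raise ValueError("times and modified_fractions must have equal length")
    if np.any((fr < 0) | (fr > 1)):
        raise ValueError("modified fractions must lie in [0, 1]")
    rng = _rng(noise.seed, _STREAM_LANES)

    def _jitter(value: float) -> float:
        if noise.sigma > 0:
            value += rng.normal(0.0, noise.sigma * scale)
        return max(value, 0.0)

    lanes: list[LaneQuant] = []
    for i, (t, f) in enumerate(zip(times, fr)):
        lanes.append(
            LaneQuant(
                lane_id=f"{condition}/t{t:g}",
                intensities={
                    "modified_total": _jitter(f * scale + background),
                    "unmodified": _jitter((1.0 - f) * scale),
                },
                treatment="none", time_min=float(t), condition=condition,
            )
        )
        if naoh_resistant is not None:
            r = float(naoh_resistant)
            if not (0.0 <= r <= 1.0):
                raise ValueError("naoh_resistant must be in [0, 1]")
            lanes.append(
                LaneQuant(
                    lane_id=f"{condition}+NaOH/t{t:g}",
                    intensities={
                        "modified_total": _jitter(r * f * scale + background),
                        "unmodified": _jitter((1.0 - r * f) * scale),
                    },
                    treatment="NaOH", time_min=float(t), condition=condition,
                )
            )
    if background > 0:
        lanes.append(
            LaneQuant(
                lane_id=f"{condition}/-ATP",
                intensities={"background": background, "unmodified": scale},
                treatment="no_ATP", condition=condition,
            )
        )
    return lanes


# ---------------------------------------------------------------------------
# toy geometry
# ---------------------------------------------------------------------------

# imidazole-proxy pentagon: ring order NE2-CD2-CG-ND1-CE1, bond length ~1.37 A
_RING_ORDER = ("NE2", "CD2", "CG", "ND1", "CE1")
_RING_ELEMENTS = ("N", "C", "C", "N", "C")
_RING_SIDE = 1.37


@dataclass(frozen=True)
class ToyGeometrySpec:
    """Prescription for a toy thioester-site frame.

    ``offset`` is the signed distance (A) of the probe nitrogen from the
    thioester plane (positive toward the cavity reference), ``angle`` the
    orientation angle (deg) at the nitrogen between ring COM and carbonyl
    carbon.  ``n_decoys`` uniformly seeded bystander atoms fill a cube of
    edge ``box``.
    """

    offset: float = 3.0
    angle: float = 120.0
    n_decoys: int = 20
    box: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.offset) > self.box:
            raise ValueError(
                f"|offset| = {abs(self.offset)} exceeds the box size {self.box}"
            )
        if not (0.0 <= self.angle <= 180.0):
            raise ValueError(f"angle must be in [0, 180], got {self.angle}")
        if self.n_decoys < 0:
            raise ValueError("n_decoys must be >= 0")


def toy_site() -> ThioesterSite:
    """The :class:`ThioesterSite` matching :func:`gen_thioester_frame` output."""
    return ThioesterSite(
        sg="A:87:SG",
        carbonyl_c="B:76:C",
        carbonyl_o="B:76:O",
        his_ne="A:94:NE2",
        ring=tuple(f"A:94:{n}" for n in _RING_ORDER),
        cavity_ref="A:999:CAV",
    )


def _perpendicular(v: np.ndarray) -> np.ndarray:
    """Any unit vector perpendicular to *v*."""
    trial = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(trial, v)) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    w = np.cross(v, trial)
    return w / np.linalg.norm(w)


def gen_thioester_frame(spec: ToyGeometrySpec) -> Frame:
    """A toy frame whose measured plane offset and orientation angle equal the spec.

    The thioester plane is z = 0 (Sgamma at the origin, carbonyl C and O in
    the plane), the cavity reference sits on +z, and the probe nitrogen is
    placed at the prescribed signed offset.  A regular-pentagon imidazole
    proxy (3 C + 2 N, so the ring centre of mass is mass-weighted exactly as
    the analysis computes it) is oriented so the COM-N-carbonyl angle equals
    the prescribed value.  Decoy atoms are seeded uniformly in the box.
    """
    s = np.zeros(3)
    c = np.array([1.78, 0.0, 0.0])
    o = c + np.array([0.62, 1.06, 0.0])
    cav = np.array([0.0, 0.0, 5.0])
    ne = np.array([2.0, 2.5, float(spec.offset)])

    # direction making the prescribed angle with the N->carbonyl-C direction
    v1 = c - ne
    v1 /= np.linalg.norm(v1)
    w = _perpendicular(v1)
    theta = np.radians(spec.angle)
    v2 = np.cos(theta) * v1 + np.sin(theta) * w

    # pentagon in local 2-D coordinates, probe vertex at (0, R)
    circumradius = _RING_SIDE / (2.0 * np.sin(np.pi / 5.0))
    angles = np.pi / 2.0 + np.arange(5) * 2.0 * np.pi / 5.0
    verts2d = circumradius * np.column_stack([np.cos(angles), np.sin(angles)])
    from .geometry import _MASSES

    masses = np.array([_MASSES[e] for e in _RING_ELEMENTS])
    com2d = (verts2d * masses[:, None]).sum(axis=0) / masses.sum()
    u = com2d - verts2d[0]           # probe-vertex -> COM, local
    u_len = np.linalg.norm(u)
    e1 = u / u_len
    e2 = np.array([-e1[1], e1[0]])   # local in-plane perpendicular

    bigE1 = v2
    bigE2 = _perpendicular(v2)
    ring_xyz = []
    for v in verts2d:
        d = v - verts2d[0]
        a, b = np.dot(d, e1), np.dot(d, e2)
        ring_xyz.append(ne + a * bigE1 + b * bigE2)

    names = ["SG", "C", "O"] + list(_RING_ORDER) + ["CAV"]
    resnames = ["CYS", "GLY", "GLY"] + ["HID"] * 5 + ["DUM"]
    resseqs = [87, 76, 76] + [94] * 5 + [999]
    chains = ["A", "B", "B"] + ["A"] * 5 + ["A"]
    elements = ["S", "C", "O"] + list(_RING_ELEMENTS) + ["C"]
    coords = [s, c, o] + ring_xyz + [cav]

    rng = _rng(spec.seed, _STREAM_FRAME)
    for i in range(spec.n_decoys):
        names.append("C")
        resnames.append("DEC")
        resseqs.append(500 + i)
        chains.append("D")
        elements.append("C")
        coords.append(rng.uniform(-spec.box / 2.0, spec.box / 2.0, size=3))

    return Frame(names=names, resnames=resnames, resseqs=resseqs, chains=chains,
                 elements=elements, coords=np.array(coords))


def gen_fluctuating_ensemble(
    base: Frame,
    sigma,
    n_frames: int,
    seed: int = 0,
    contact_schedule: "tuple | None" = None,
) -> list[Frame]:
    """Gaussian-jittered copies of *base*, optionally with a scripted contact.

    ``sigma`` is a scalar (A, isotropic per coordinate) or a mapping from
    ``(chain, resseq, name)`` keys to per-atom sigmas (unlisted atoms get 0).
    ``contact_schedule`` is ``(donor_sel, hydrogen_sel, acceptor_sel, on)``
    with ``on`` a boolean per frame: in "on" frames the hydrogen and acceptor
    are placed in ideal bonding geometry behind the donor (D-H 1.0 A, D...A
    2.8 A, collinear); in "off" frames the acceptor is retracted to 6 A, so
    interaction frequencies are known exactly by construction.
    """
    if n_frames < 2:
        raise ValueError("need n_frames >= 2")
    if np.isscalar(sigma):
        sig = np.full(len(base), float(sigma))
    else:
        sig = np.zeros(len(base))
        for key, v in sigma.items():
            sig[base.atom_index(key)] = float(v)
    rng = _rng(seed, _STREAM_ENSEMBLE)

    sched = None
    if contact_schedule is not None:
        d_sel, h_sel, a_sel, on = contact_schedule
        if len(on) != n_frames:
            raise ValueError("contact schedule length must equal n_frames")
        sched = (base.atom_index(d_sel), base.atom_index(h_sel),
                 base.atom_index(a_sel), list(on))

    frames = []
    for i in range(n_frames):
        coords = base.coords + rng.normal(0.0, 1.0, size=base.coords.shape) * sig[:, None]
        if sched is not None:
            di, hi, ai, on = sched
            d = base.coords[di]
            direction = np.array([1.0, 0.0, 0.0])
            coords[di] = d
            coords[hi] = d + 1.0 * direction
            coords[ai] = d + (2.8 if on[i] else 6.0) * direction
        frames.append(
            Frame(names=list(base.names), resnames=list(base.resnames),
                  resseqs=list(base.resseqs), chains=list(base.chains),
                  elements=list(base.elements), coords=coords, index=i,
                  tautomers=dict(base.tautomers))
        )
    return frames
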