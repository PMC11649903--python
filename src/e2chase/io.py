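"""Readers and writers for the package's on-disk formats.

* time-course CSV (``time_min, signal, nu_mM, observable, label, replicate``);
* lane CSV (``lane_id, role, intensity, treatment, time_min, condition``);
* multi-model PDB ensembles (read via Biopython, written as fixed-width
  ATOM records; model order defines frame order);
* YAML run configuration (chase designs, thioester-site selectors,
  pocket specs);
* JSON result files stamped with the package version, the seed and a
  configuration digest, so any run is reproducible from its outputs alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .densitometry import LaneQuant
from .fitting import ChaseDesign
from .geometry import Frame, PocketSpec, ThioesterSite
from .kinetics import TimeCourse

__all__ = [
    "read_timecourse_csv",
    "write_timecourse_csv",
    "read_lane_csv",
    "write_lane_csv",
    "read_ensemble_pdb",
    "write_ensemble_pdb",
    "load_design",
    "load_site_config",
    "write_json",
]

_TC_COLUMNS = ["time_min", "signal", "nu_mM", "observable", "label", "replicate"]


def write_timecourse_csv(courses: list[TimeCourse], path) -> None:
    rows = []
    for c in courses:
        for t, s in zip(c.times, c.signal):
            rows.append({"time_min": t, "signal": s, "nu_mM": c.nu,
                         "observable": c.observable, "label": c.label,
                         "replicate": c.replicate})
    pd.DataFrame(rows, columns=_TC_COLUMNS).to_csv(path, index=False)


def read_timecourse_csv(path) -> list[TimeCourse]:
    """Read time courses, one per (label, replicate, nu, observable) group.

    Malformed rows (non-numeric fields, non-monotone times) abort the read
    with the offending row named.
    """
    df = pd.read_csv(path, dtype={"label": str, "replicate": str})
    missing = [c for c in _TC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in ("time_min", "signal", "nu_mM"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            # +2: header line and 1-based numbering
            raise ValueError(f"{path}: non-numeric {col!r} at line {bad[0] + 2}")
        df[col] = pd.to_numeric(df[col])
    df["label"] = df["label"].fillna("")
    df["replicate"] = df["replicate"].fillna("1")

    courses = []
    for (label, rep, nu, obs), grp in df.groupby(
            ["label", "replicate", "nu_mM", "observable"], sort=False, dropna=False):
        try:
            courses.append(TimeCourse(
                times=grp["time_min"].to_numpy(),
                signal=grp["signal"].to_numpy(),
                nu=float(nu), observable=str(obs), label=str(label),
                replicate=str(rep),
            ))
        except ValueError as e:
            first_line = int(grp.index[0]) + 2
            raise ValueError(
                f"{path}: invalid course starting at line {first_line}: {e}"
            ) from None
    return courses


_LANE_COLUMNS = ["lane_id", "role", "intensity", "treatment", "time_min", "condition"]


def write_lane_csv(lanes: list[LaneQuant], path) -> None:
    rows = []
    for lane in lanes:
        for role, inten in lane.intensities.items():
            rows.append({"lane_id": lane.lane_id, "role": role,
                         "intensity": inten, "treatment": lane.treatment,
                         "time_min": lane.time_min, "condition": lane.condition})
    pd.DataFrame(rows, columns=_LANE_COLUMNS).to_csv(path, index=False)


def read_lane_csv(path) -> list[LaneQuant]:
    df = pd.read_csv(path, dtype={"lane_id": str, "role": str, "treatment": str,
                                  "condition": str})
    missing = [c for c in _LANE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    lanes = []
    for (lane_id, treatment, time_min, condition), grp in df.groupby(
            ["lane_id", "treatment", "time_min", "condition"], sort=False,
            dropna=False):
        lanes.append(LaneQuant(
            lane_id=str(lane_id),
            intensities=dict(zip(grp["role"], grp["intensity"].astype(float))),
            treatment=str(treatment),
            time_min=None if pd.isna(time_min) else float(time_min),
            condition="" if pd.isna(condition) else str(condition),
        ))
    return lanes


# ---------------------------------------------------------------------------
# PDB ensembles
# ---------------------------------------------------------------------------


def read_ensemble_pdb(path) -> list[Frame]:
    """Read a (multi-model) PDB file into a list of frames.

    Model order defines frame order; a single-model file yields one frame.
    Duplicate atom keys within a model are rejected.  His tautomer dialects
    are normalised by the Frame constructor.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    parser = PDBParser(QUIET=True, PERMISSIVE=False)
    try:
        structure = parser.get_structure("ensemble", str(path))
    except PDBConstructionException as e:
        raise ValueError(f"{path}: {e}") from None

    frames = []
    for model in structure:
        names, resnames, resseqs, chains, elements, coords = [], [], [], [], [], []
        for chain in model:
            for residue in chain:
                for atom in residue:
                    names.append(atom.get_name())
                    resnames.append(residue.get_resname().strip())
                    resseqs.append(residue.id[1])
                    chains.append(chain.id)
                    elements.append(atom.element or "")
                    coords.append(atom.get_coord())
        frames.append(Frame(names=names, resnames=resnames, resseqs=resseqs,
                            chains=chains, elements=elements,
                            coords=np.array(coords, dtype=float),
                            index=model.serial_num - 1 if model.serial_num else len(frames)))
    if not frames:
        raise ValueError(f"{path}: no models found")
    for i, f in enumerate(frames):
        f.index = i
    return frames


def _format_atom_line(serial: int, name: str, resname: str, chain: str,
                      resseq: int, xyz, element: str) -> str:
    # standard PDB convention: 1-char elements start in column 14
    if len(name) < 4 and len(element) == 1:
        name_field = f" {name:<3s}"
    else:
        name_field = f"{name:<4s}"
    return (f"ATOM  {serial:5d} {name_field} {resname:<3s} {chain:1s}"
            f"{resseq:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}")


def write_ensemble_pdb(frames: list[Frame], path) -> None:
    """Write frames as a multi-model PDB (coordinates to 0.001 A)."""
    lines = []
    multi = len(frames) > 1
    for m, frame in enumerate(frames, start=1):
        if multi:
            lines.append(f"MODEL     {m:4d}")
        # write the original tautomer dialect back out where known
        for i in range(len(frame)):
            resname = frame.tautomers.get(
                (frame.chains[i], frame.resseqs[i]), frame.resnames[i]
            )
            lines.append(_format_atom_line(
                i + 1, frame.names[i], resname, frame.chains[i],
                frame.resseqs[i], frame.coords[i], frame.elements[i],
            ))
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def load_design(path) -> ChaseDesign:
    """Load a chase design from YAML: course CSV paths with fixed nu values.

    Schema::

        courses:
          - csv: pair_nu0.csv        # path relative to the YAML file
            nu: 0.0                  # optional override of the CSV's nu_mM
        shared: [E2L0, k1, k2, k3]   # optional
    """
    path = Path(path)
    cfg = yaml.safe_load(path.read_text())
    if not isinstance(cfg, dict) or "courses" not in cfg:
        raise ValueError(f"{path}: design YAML must contain a 'courses' list")
    courses = []
    for entry in cfg["courses"]:
        csv_path = path.parent / entry["csv"]
        loaded = read_timecourse_csv(csv_path)
        if "nu" in entry:
            for c in loaded:
                c.nu = float(entry["nu"])
        courses.extend(loaded)
    kwargs = {}
    if "shared" in cfg:
        kwargs["shared"] = tuple(cfg["shared"])
    return ChaseDesign(courses=courses, **kwargs)


def load_site_config(path) -> dict:
    """Load thioester-site selectors and optional pocket spec from YAML.

    Returns ``{"site": ThioesterSite, "pocket": PocketSpec | None,
    "offset_max": float, "angle_window": (lo, hi)}``.
    """
    cfg = yaml.safe_load(Path(path).read_text())
    site_cfg = cfg["site"]
    site = ThioesterSite(
        sg=site_cfg["sg"], carbonyl_c=site_cfg["carbonyl_c"],
        carbonyl_o=site_cfg["carbonyl_o"], his_ne=site_cfg["his_ne"],
        ring=tuple(site_cfg["ring"]), cavity_ref=site_cfg["cavity_ref"],
    )
    pocket = None
    if "pocket" in cfg:
        p = cfg["pocket"]
        pocket = PocketSpec(
            pair1=tuple(p["pair1"]), pair2=tuple(p["pair2"]),
            radius=float(p.get("radius", 12.0)),
            spacing=float(p.get("spacing", 0.5)),
            exclusion=float(p.get("exclusion", 1.09)),
            hull=bool(p.get("hull", True)),
        )
    thresholds = cfg.get("thresholds", {})
    return {
        "site": site,
        "pocket": pocket,
        "offset_max": float(thresholds.get("offset_max", 3.5)),
        "angle_window": tuple(thresholds.get("angle_window", (0.0, 180.0))),
    }


def write_json(obj: dict, path, seed: int | None = None,
               config: dict | None = None) -> None:
    """Write a JSON result stamped with version, seed and config digest."""
    from . import __version__

    payload = dict(obj)
    payload["_meta"] = {
        "package": "e2chase",
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config or {}, sort_keys=True, default=str).encode()
        ).hexdigest(),
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=float) + "\n")
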