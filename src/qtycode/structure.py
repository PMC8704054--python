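"""Structure handling: PDB I/O, residue matching, Kabsch superposition, and
idealized helix/bundle generators.

Correspondence between native and QTY-variant models is positional (equal
residue numbers within a designated chain pair): the pairs compared here are
substitution-only variants sharing numbering, so flexible structural
alignment is unnecessary.  RMSD is computed on Cα atoms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from qtycode.seqio import ProteinRecord, SegmentAnnotation


class StructureError(ValueError):
    """Raised for malformed structure input or impossible operations."""


THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class Atom(NamedTuple):
    chain: str
    residue_seq: int
    residue_name: str
    atom_name: str
    element: str
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    bfactor: float = 0.0

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass(frozen=True)
class StructureModel:
    """An ordered collection of atom records (coordinates in Å)."""

    model_id: str
    atoms: tuple[Atom, ...]

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for a in self.atoms:
            key = (a.chain, a.residue_seq, a.atom_name)
            if key in seen:
                raise StructureError(f"duplicate atom {key}")
            seen.add(key)
            if not all(math.isfinite(v) for v in (a.x, a.y, a.z)):
                raise StructureError(f"non-finite coordinate in atom {key}")

    def __len__(self) -> int:
        return len(self.atoms)

    def chains(self) -> tuple[str, ...]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain not in out:
                out.append(a.chain)
        return tuple(out)

    def chain_atoms(self, chain: str) -> tuple[Atom, ...]:
        return tuple(a for a in self.atoms if a.chain == chain)

    def ca_atoms(self, chain: str | None = None) -> tuple[Atom, ...]:
        return tuple(
            a for a in self.atoms
            if a.atom_name == "CA" and (chain is None or a.chain == chain)
        )

    def coords(self, atoms: Iterable[Atom] | None = None) -> np.ndarray:
        sel = tuple(atoms) if atoms is not None else self.atoms
        return np.array([[a.x, a.y, a.z] for a in sel]).reshape(-1, 3)

    def residue_names(self, chain: str) -> dict[int, str]:
        return {a.residue_seq: a.residue_name for a in self.chain_atoms(chain)}


# ---------------------------------------------------------------------------
# PDB fixed-column I/O
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> tuple[Atom, str]:
    """Parse one ATOM/HETATM line; returns (atom, altloc)."""
    try:
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip() or "A"
        resseq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError):
        raise StructureError(f"line {lineno}: malformed coordinate field") from None
    occ_s = line[54:60].strip()
    b_s = line[60:66].strip()
    occ = float(occ_s) if occ_s else 1.0
    bfac = float(b_s) if b_s else 0.0
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        # fall back to the atom-name convention: first alphabetic character
        element = next((c for c in name if c.isalpha()), "C").upper()
    return Atom(chain, resseq, resname, name, element, x, y, z, occ, bfac), altloc


def parse_pdb(
    stream, model_index: int = 0, model_id: str = "model", keep_hetatm: bool = False
) -> StructureModel:
    """Parse PDB text into a StructureModel.

    Only the MODEL block selected by ``model_index`` is read (files without
    MODEL records count as a single block).  Alternate locations are resolved
    to the highest-occupancy conformer, ties broken toward altloc 'A';
    HETATM records are ignored unless ``keep_hetatm``.
    """
    if hasattr(stream, "read"):
        text = stream.read()
    else:
        text = stream
    current_model = 0
    in_wanted = model_index == 0
    best: dict[tuple[str, int, str], tuple[float, str, Atom]] = {}
    order: list[tuple[str, int, str]] = []
    saw_model_records = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec == "MODEL ":
            saw_model_records = True
            in_wanted = current_model == model_index
            current_model += 1
            continue
        if rec == "ENDMDL":
            in_wanted = False
            continue
        if not in_wanted and saw_model_records:
            continue
        if rec == "ATOM  " or (keep_hetatm and rec == "HETATM"):
            atom, altloc = _parse_atom_line(line, lineno)
            key = (atom.chain, atom.residue_seq, atom.atom_name)
            if key not in best:
                order.append(key)
                best[key] = (atom.occupancy, altloc or "A", atom)
            else:
                occ0, alt0, _ = best[key]
                if atom.occupancy > occ0 or (
                    atom.occupancy == occ0 and (altloc or "A") < alt0
                ):
                    best[key] = (atom.occupancy, altloc or "A", atom)
    if not best:
        raise StructureError("no ATOM records")
    return StructureModel(model_id=model_id, atoms=tuple(best[k][2] for k in order))


def write_pdb(model: StructureModel) -> str:
    """Serialize a model as fixed-column PDB text (single MODEL, TER, END)."""
    lines: list[str] = []
    serial = 0
    last_chain = None
    for a in model.atoms:
        if last_chain is not None and a.chain != last_chain:
            lines.append("TER")
        last_chain = a.chain
        serial += 1
        name = a.atom_name if len(a.atom_name) == 4 else f" {a.atom_name:<3}"
        lines.append(
            f"ATOM  {serial:>5} {name}{'':1}{a.residue_name:>3} {a.chain}"
            f"{a.residue_seq:>4}    {a.x:8.3f}{a.y:8.3f}{a.z:8.3f}"
            f"{a.occupancy:6.2f}{a.bfactor:6.2f}          {a.element:>2}"
        )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Residue matching and superposition
# ---------------------------------------------------------------------------

class MatchedPair(NamedTuple):
    residue_seq: int
    pos_a: tuple[float, float, float]
    pos_b: tuple[float, float, float]


def match_residues(
    a: StructureModel,
    b: StructureModel,
    chain_a: str | None = None,
    chain_b: str | None = None,
    atom: str = "CA",
) -> list[MatchedPair]:
    """Pair residues with equal residue numbers possessing the named atom.

    Intersection semantics absorb crystal-structure gaps (missing loops) on
    either side.  Chains default to the first chain of each model.
    """
    chain_a = chain_a or (a.chains()[0] if a.chains() else "")
    chain_b = chain_b or (b.chains()[0] if b.chains() else "")
    map_a = {
        at.residue_seq: at for at in a.chain_atoms(chain_a) if at.atom_name == atom
    }
    map_b = {
        at.residue_seq: at for at in b.chain_atoms(chain_b) if at.atom_name == atom
    }
    common = sorted(set(map_a) & set(map_b))
    if not common:
        raise StructureError("no common residues")
    return [
        MatchedPair(
            r,
            (map_a[r].x, map_a[r].y, map_a[r].z),
            (map_b[r].x, map_b[r].y, map_b[r].z),
        )
        for r in common
    ]


def matched_identity(a: StructureModel, b: StructureModel,
                     pairs: Sequence[MatchedPair],
                     chain_a: str | None = None,
                     chain_b: str | None = None) -> float:
    """Sequence identity (%) over matched residues; guards against mispairing."""
    chain_a = chain_a or a.chains()[0]
    chain_b = chain_b or b.chains()[0]
    names_a = a.residue_names(chain_a)
    names_b = b.residue_names(chain_b)
    same = sum(1 for p in pairs if names_a[p.residue_seq] == names_b[p.residue_seq])
    return 100.0 * same / len(pairs)


@dataclass(frozen=True)
class Superposition:
    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # applied after rotation
    rmsd: float
    n_matched: int
    matched_pairs: tuple[int, ...] = field(default=(), repr=False)

    def transform(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


def kabsch_superpose(
    reference: np.ndarray,
    mobile: np.ndarray,
    matched_pairs: Sequence[int] = (),
) -> Superposition:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    SVD of the covariance matrix with reflection correction guarantees a
    proper rotation (det +1) even for mirror-image inputs.  Inputs must be
    equal-length point sets of at least 3 non-collinear points.
    """
    ref = np.asarray(reference, dtype=float)
    mob = np.asarray(mobile, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise StructureError("point sets must be matching (N, 3) arrays")
    n = ref.shape[0]
    if n < 3:
        raise StructureError("need at least 3 points to superpose")
    ref_c = ref - ref.mean(axis=0)
    mob_c = mob - mob.mean(axis=0)
    # collinear (or coincident) points leave the rotation underdetermined
    if min(np.linalg.matrix_rank(ref_c, tol=1e-8),
           np.linalg.matrix_rank(mob_c, tol=1e-8)) < 2:
        raise StructureError("degenerate (collinear) point configuration")
    h = mob_c.T @ ref_c
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rotation = vt.T @ diag @ u.T
    translation = ref.mean(axis=0) - rotation @ mob.mean(axis=0)
    moved = mob @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return Superposition(
        rotation=rotation,
        translation=translation,
        rmsd=rmsd,
        n_matched=n,
        matched_pairs=tuple(matched_pairs),
    )


def superpose_models(
    reference: StructureModel,
    mobile: StructureModel,
    chain_ref: str | None = None,
    chain_mobile: str | None = None,
    atom: str = "CA",
) -> tuple[Superposition, StructureModel]:
    """Match residues, superpose, and return the transformed mobile model."""
    pairs = match_residues(reference, mobile, chain_ref, chain_mobile, atom)
    ref_pts = np.array([p.pos_a for p in pairs])
    mob_pts = np.array([p.pos_b for p in pairs])
    sup = kabsch_superpose(ref_pts, mob_pts, [p.residue_seq for p in pairs])
    moved_atoms = []
    for a in mobile.atoms:
        p = sup.transform(np.array([[a.x, a.y, a.z]]))[0]
        moved_atoms.append(a._replace(x=float(p[0]), y=float(p[1]), z=float(p[2])))
    moved = StructureModel(
        model_id=f"{mobile.model_id}_superposed", atoms=tuple(moved_atoms)
    )
    return sup, moved


def trim_to_segments(
    model: StructureModel, annotation: SegmentAnnotation
) -> StructureModel:
    """Keep only atoms whose residue number falls inside a TM segment."""
    keep: set[int] = set()
    for seg in annotation.tm_segments:
        keep.update(seg.positions())
    atoms = tuple(a for a in model.atoms if a.residue_seq in keep)
    if not atoms:
        raise StructureError("no atoms remain after trimming to TM segments")
    return StructureModel(model_id=f"{model.model_id}_tm", atoms=atoms)


# ---------------------------------------------------------------------------
# Idealized fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HelixSpec:
    """Canonical α-helix parameters: 1.5 Å rise and 100° twist per residue
    (3.6 residues and 5.4 Å per full turn) on a 2.3 Å Cα cylinder."""

    n_residues: int
    rise_per_residue: float = 1.5
    twist_per_residue: float = 100.0
    radius: float = 2.3

    def __post_init__(self) -> None:
        if self.n_residues < 4:
            raise StructureError("helix needs at least 4 residues")


def build_ideal_helix(
    spec: HelixSpec,
    chain: str = "A",
    start_residue: int = 1,
    residue_names: Sequence[str] | None = None,
    model_id: str = "ideal_helix",
) -> StructureModel:
    """Cα-only ideal helix along +z, poly-alanine unless names are given."""
    atoms = []
    for i in range(spec.n_residues):
        theta = math.radians(i * spec.twist_per_residue)
        name = residue_names[i] if residue_names else "ALA"
        atoms.append(
            Atom(
                chain=chain,
                residue_seq=start_residue + i,
                residue_name=name,
                atom_name="CA",
                element="C",
                x=spec.radius * math.cos(theta),
                y=spec.radius * math.sin(theta),
                z=i * spec.rise_per_residue,
            )
        )
    return StructureModel(model_id=model_id, atoms=tuple(atoms))


def build_bundle(
    n_helices: int,
    helix_spec: HelixSpec,
    bundle_radius: float = 10.0,
    sequence: ProteinRecord | None = None,
    annotation: SegmentAnnotation | None = None,
    model_id: str = "bundle",
) -> StructureModel:
    """Idealized helix bundle: vertical helices, evenly spaced on a circle,
    alternating up/down orientation (antiparallel packing).

    With ``sequence`` and ``annotation`` given, helix i takes the residue
    numbers and names of the i-th TM segment, so the bundle mirrors a 7TM
    topology; otherwise residues are poly-alanine numbered consecutively.
    """
    if n_helices < 1:
        raise StructureError("need at least one helix")
    segments = None
    if sequence is not None and annotation is not None:
        segments = annotation.tm_segments
        if len(segments) != n_helices:
            raise StructureError(
                f"annotation has {len(segments)} TM segments, need {n_helices}"
            )
    atoms: list[Atom] = []
    next_res = 1
    for h in range(n_helices):
        if segments is not None:
            seg = segments[h]
            n_res = seg.end - seg.start + 1
            res_ids = list(seg.positions())
            res_names = [
                ONE_TO_THREE[sequence.sequence[p - 1]] for p in res_ids
            ]
        else:
            n_res = helix_spec.n_residues
            res_ids = list(range(next_res, next_res + n_res))
            res_names = ["ALA"] * n_res
            next_res += n_res
        phi = 2.0 * math.pi * h / n_helices
        cx = bundle_radius * math.cos(phi)
        cy = bundle_radius * math.sin(phi)
        flip = h % 2 == 1
        height = (n_res - 1) * helix_spec.rise_per_residue
        for i in range(n_res):
            theta = math.radians(i * helix_spec.twist_per_residue)
            lx = helix_spec.radius * math.cos(theta)
            ly = helix_spec.radius * math.sin(theta)
            lz = i * helix_spec.rise_per_residue
            if flip:  # rotate 180° about x: antiparallel, still on the circle
                ly, lz = -ly, height - lz
            atoms.append(
                Atom(
                    chain="A",
                    residue_seq=res_ids[i],
                    residue_name=res_names[i],
                    atom_name="CA",
                    element="C",
                    x=cx + lx,
                    y=cy + ly,
                    z=lz - height / 2.0,
                )
            )
    return StructureModel(model_id=model_id, atoms=tuple(atoms))


def fit_helix_axis(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares helical axis: direction and a point on the axis.

    The axis direction is the principal component of single-turn window
    centroids (each centroid sits on the axis of an ideal helix), which is
    robust for short helices where raw-coordinate PCA is biased by the
    helical phase.
    """
    pts = np.asarray(coords, dtype=float)
    w = 4  # ~one turn at 100°/residue
    if len(pts) <= w:
        raise StructureError("too few residues to fit a helix axis")
    centroids = np.array([pts[i : i + w].mean(axis=0) for i in range(len(pts) - w + 1)])
    center = centroids.mean(axis=0)
    _, _, vt = np.linalg.svd(centroids - center)
    axis = vt[0]
    # orient along increasing residue index
    if np.dot(centroids[-1] - centroids[0], axis) < 0:
        axis = -axis
    return axis, center


def helix_geometry(model: StructureModel) -> dict[str, float]:
    """Recover rise/residue, twist/residue, residues per turn and pitch from a
    Cα trace by fitting the helical axis."""
    cas = model.ca_atoms()
    pts = model.coords(cas)
    axis, center = fit_helix_axis(pts)
    proj = (pts - center) @ axis
    rise = float(np.mean(np.diff(proj)))
    radial = pts - center - np.outer(proj, axis)
    # angles about the axis in a fixed orthonormal frame
    ref = radial[0] / np.linalg.norm(radial[0])
    ortho = np.cross(axis, ref)
    angles = np.unwrap(np.arctan2(radial @ ortho, radial @ ref))
    twist = float(np.degrees(np.mean(np.diff(angles))))
    residues_per_turn = 360.0 / abs(twist)
    return {
        "rise_per_residue": rise,
        "twist_per_residue": abs(twist),
        "residues_per_turn": residues_per_turn,
        "pitch": rise * residues_per_turn,
    }
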