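"""Solvent-accessible surface area and hydrophobic-patch detection.

SASA uses the Shrake–Rupley sphere-sampling construction with a
deterministic Fibonacci-spiral point set (no RNG, bit-reproducible).  A
hydrophobic patch is a connected component of solvent-exposed residues from
the hydrophobic set {L, I, V, F} under a Cα-distance adjacency rule; the
hydrophobic exposed fraction is what the QTY substitution collapses.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from qtycode.structure import ONE_TO_THREE, StructureModel, StructureError

#: The four residues the QTY code removes from TM helices.
DEFAULT_HYDROPHOBIC = frozenset({"L", "I", "V", "F"})
#: Optional broader apolar set.
EXTENDED_HYDROPHOBIC = DEFAULT_HYDROPHOBIC | frozenset({"A", "M", "W", "C"})


def default_radii() -> dict[str, float]:
    text = resources.files("qtycode").joinpath("data/vdw_radii.tsv").read_text()
    radii: dict[str, float] = {}
    for raw in io.StringIO(text):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        el, r = line.split("\t")
        radii[el] = float(r)
    return radii


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (Fibonacci spiral)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i  # golden angle increments
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@dataclass(frozen=True)
class SASAResult:
    probe_radius: float
    n_points: int
    per_atom_area: np.ndarray
    per_residue_area: dict[tuple[str, int], float]
    total_area: float


def shrake_rupley_sasa(
    model: StructureModel,
    probe_radius: float = 1.4,
    n_points: int = 960,
    radii: dict[str, float] | None = None,
) -> SASAResult:
    """Per-atom solvent-accessible surface area in Å².

    Each atom's expanded sphere (vdW radius + probe) is sampled with
    ``n_points`` spiral points; the accessible fraction — points inside no
    neighbouring expanded sphere — scales the analytic sphere area.
    """
    if len(model) == 0:
        raise StructureError("empty model")
    radii = radii or default_radii()
    try:
        atom_r = np.array([radii[a.element] for a in model.atoms])
    except KeyError as exc:
        raise StructureError(f"unknown element {exc.args[0]!r}") from None
    expanded = atom_r + probe_radius
    coords = model.coords()
    unit = sphere_points(n_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()
    areas = np.zeros(len(model))
    for i in range(len(model)):
        neighbours = [
            j for j in tree.query_ball_point(coords[i], r=max_reach) if j != i
        ]
        pts = coords[i] + expanded[i] * unit
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > expanded[j] ** 2
            if not accessible.any():
                break
        frac = accessible.sum() / n_points
        areas[i] = frac * 4.0 * np.pi * expanded[i] ** 2
    per_residue: dict[tuple[str, int], float] = {}
    for a, area in zip(model.atoms, areas):
        key = (a.chain, a.residue_seq)
        per_residue[key] = per_residue.get(key, 0.0) + float(area)
    return SASAResult(
        probe_radius=probe_radius,
        n_points=n_points,
        per_atom_area=areas,
        per_residue_area=per_residue,
        total_area=float(areas.sum()),
    )


@dataclass(frozen=True)
class PatchReport:
    hydrophobic_set: frozenset[str]
    exposure_threshold: float
    hydrophobic_fraction: float
    patches: tuple[tuple[tuple[tuple[str, int], ...], float], ...]

    @property
    def largest_patch_area(self) -> float:
        return self.patches[0][1] if self.patches else 0.0


def hydrophobic_patches(
    model: StructureModel,
    sasa: SASAResult,
    hydrophobic_set: frozenset[str] = DEFAULT_HYDROPHOBIC,
    exposure_threshold: float = 10.0,
    adjacency_cutoff: float = 8.0,
) -> PatchReport:
    """Connected components of exposed hydrophobic residues.

    Nodes: residues from ``hydrophobic_set`` with per-residue SASA above
    ``exposure_threshold``.  Edges: Cα–Cα distance ≤ ``adjacency_cutoff``.
    Patches are reported largest-first with their summed exposed areas.
    """
    hydro3 = {ONE_TO_THREE[c] for c in hydrophobic_set}
    cas = {
        (a.chain, a.residue_seq): a.position
        for a in model.atoms
        if a.atom_name == "CA"
    }
    res_name = {(a.chain, a.residue_seq): a.residue_name for a in model.atoms}
    hydro_area = sum(
        area for key, area in sasa.per_residue_area.items()
        if res_name.get(key) in hydro3
    )
    fraction = hydro_area / sasa.total_area if sasa.total_area > 0 else 0.0

    nodes = [
        key
        for key, area in sasa.per_residue_area.items()
        if res_name.get(key) in hydro3 and area > exposure_threshold and key in cas
    ]
    # union-find over the adjacency graph
    parent = {k: k for k in nodes}

    def find(k):
        while parent[k] != k:
            parent[k] = parent[parent[k]]
            k = parent[k]
        return k

    if nodes:
        pts = np.array([cas[k] for k in nodes])
        tree = cKDTree(pts)
        for i, j in tree.query_pairs(r=adjacency_cutoff):
            ri, rj = find(nodes[i]), find(nodes[j])
            if ri != rj:
                parent[ri] = rj
    groups: dict[tuple[str, int], list[tuple[str, int]]] = {}
    for k in nodes:
        groups.setdefault(find(k), []).append(k)
    patches = tuple(
        sorted(
            (
                (tuple(sorted(members)),
                 sum(sasa.per_residue_area[m] for m in members))
                for members in groups.values()
            ),
            key=lambda t: -t[1],
        )
    )
    return PatchReport(
        hydrophobic_set=frozenset(hydrophobic_set),
        exposure_threshold=exposure_threshold,
        hydrophobic_fraction=fraction,
        patches=patches,
    )


@dataclass(frozen=True)
class SurfaceComparison:
    native: PatchReport
    variant: PatchReport
    delta_fraction: float
    delta_largest_patch: float


def compare_surfaces(
    native: StructureModel,
    variant: StructureModel,
    probe_radius: float = 1.4,
    n_points: int = 960,
    hydrophobic_set: frozenset[str] = DEFAULT_HYDROPHOBIC,
    exposure_threshold: float = 10.0,
    adjacency_cutoff: float = 8.0,
) -> SurfaceComparison:
    """Native-vs-variant hydrophobic surface contrast.

    Deltas are variant − native: negative values mean the variant exposes
    less hydrophobic surface.
    """
    reports = []
    for m in (native, variant):
        sasa = shrake_rupley_sasa(m, probe_radius=probe_radius, n_points=n_points)
        reports.append(
            hydrophobic_patches(
                m, sasa, hydrophobic_set, exposure_threshold, adjacency_cutoff
            )
        )
    rn, rv = reports
    return SurfaceComparison(
        native=rn,
        variant=rv,
        delta_fraction=rv.hydrophobic_fraction - rn.hydrophobic_fraction,
        delta_largest_patch=rv.largest_patch_area - rn.largest_patch_area,
    )


def residue_sasa_tsv(model: StructureModel, sasa: SASAResult,
                     report: PatchReport | None = None) -> str:
    """Per-residue SASA (and patch membership) as TSV."""
    patch_of: dict[tuple[str, int], int] = {}
    if report is not None:
        for idx, (members, _area) in enumerate(report.patches, start=1):
            for m in members:
                patch_of[m] = idx
    res_name = {(a.chain, a.residue_seq): a.residue_name for a in model.atoms}
    lines = ["chain\tresidue\tname\tsasa\tpatch"]
    for key in sorted(sasa.per_residue_area):
        chain, seq = key
        patch = patch_of.get(key, 0)
        lines.append(
            f"{chain}\t{seq}\t{res_name[key]}\t"
            f"{sasa.per_residue_area[key]:.2f}\t{patch if patch else '-'}"
        )
    return "\n".join(lines) + "\n"
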