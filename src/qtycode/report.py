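"""End-to-end pair comparison and synthetic-fixture generation.

``run_pair`` composes the substitution engine, physicochemical calculators
and (when structures are supplied) superposition and surface analysis into a
single deterministic report: one TSV row of tabular characteristics plus a
JSON sidecar with events, matched residues and patches.

``synth_fixture`` produces download-free test inputs emulating a 7TM
receptor: a sequence with 7 hydrophobic segments separated by polar loops,
an idealized 7-helix bundle, or a native/variant pair sharing coordinates.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from qtycode import __version__
from qtycode.seqio import (
    ProteinRecord,
    Segment,
    SegmentAnnotation,
    load_segments,
    parse_fasta,
    transmem_from_uniprot_text,
    write_fasta,
    write_segments,
)
from qtycode.qty_engine import (
    QTY_MAP,
    QTYResult,
    SubstitutionMap,
    VariationStats,
    apply_substitution,
    positional_identity,
    variation_stats,
)
from qtycode.physchem import PairPhyschem, pair_physchem
from qtycode.structure import (
    HelixSpec,
    StructureModel,
    build_bundle,
    parse_pdb,
    superpose_models,
    trim_to_segments,
    write_pdb,
)
from qtycode.surface import SurfaceComparison, compare_surfaces


@dataclass(frozen=True)
class PairReport:
    pair_id: str
    identity_pct: float
    stats: VariationStats
    physchem: PairPhyschem
    result: QTYResult
    rmsd: float | None = None
    n_matched: int | None = None
    surface: SurfaceComparison | None = None
    provenance: dict | None = None

    TSV_HEADER = (
        "pair_id\tlength\tidentity_pct\ttotal_variation_pct\t"
        "membrane_variation_pct\tn_events\tpI_native\tpI_variant\tdelta_pI\t"
        "mw_native\tmw_variant\tdelta_mw\tdelta_mw_pct\trmsd\tn_matched\t"
        "hydrophobic_fraction_native\thydrophobic_fraction_variant"
    )

    def tsv_row(self) -> str:
        def fmt(v, nd=3):
            return "-" if v is None else (f"{v:.{nd}f}" if isinstance(v, float) else str(v))

        s, p = self.stats, self.physchem
        fields = [
            self.pair_id,
            str(len(self.result.native)),
            f"{self.identity_pct:.2f}",
            f"{s.total_variation_pct:.2f}",
            f"{s.membrane_variation_pct:.2f}",
            str(s.n_events),
            f"{p.pI_native:.2f}",
            f"{p.pI_variant:.2f}",
            f"{p.delta_pI:.2f}",
            f"{p.mw_native:.2f}",
            f"{p.mw_variant:.2f}",
            f"{p.delta_mw:.2f}",
            f"{p.delta_mw_pct:.2f}",
            fmt(self.rmsd),
            fmt(self.n_matched),
            fmt(self.surface.native.hydrophobic_fraction if self.surface else None, 4),
            fmt(self.surface.variant.hydrophobic_fraction if self.surface else None, 4),
        ]
        return "\t".join(fields)

    def sidecar(self) -> dict:
        out = {
            "pair_id": self.pair_id,
            "provenance": self.provenance or {},
            "events": [
                {"position": e.position, "from": e.source, "to": e.target,
                 "segment": e.segment_label}
                for e in self.result.events
            ],
        }
        if self.surface is not None:
            out["patches_native"] = [
                {"residues": [list(m) for m in members], "area": round(area, 2)}
                for members, area in self.surface.native.patches
            ]
            out["patches_variant"] = [
                {"residues": [list(m) for m in members], "area": round(area, 2)}
                for members, area in self.surface.variant.patches
            ]
            out["delta_fraction"] = self.surface.delta_fraction
            out["delta_largest_patch"] = self.surface.delta_largest_patch
        if self.rmsd is not None:
            out["rmsd"] = self.rmsd
            out["n_matched"] = self.n_matched
        return out


def _load_record(config: dict, base: Path) -> tuple[ProteinRecord, SegmentAnnotation]:
    if "native_fasta" in config:
        records = parse_fasta((base / config["native_fasta"]).read_text())
        record = records[0]
    else:
        raise ValueError("config must name a native_fasta")
    if "segments" in config:
        annotation = load_segments((base / config["segments"]).read_text(), record)
    elif "uniprot_txt" in config:
        annotation = transmem_from_uniprot_text(
            (base / config["uniprot_txt"]).read_text(), record
        )
    else:
        raise ValueError("config must name a segment source (segments | uniprot_txt)")
    return record, annotation


def run_pair(config: dict, base: Path | str = ".") -> PairReport:
    """Execute one native→variant comparison from a config mapping.

    Recognized keys: pair_id, native_fasta, segments | uniprot_txt, map
    (TSV path, default QTY), scope (segment kinds), extra_positions,
    ref_pdb + mobile_pdb (+ chains, trim, surface parameters).
    """
    base = Path(base)
    pair_id = config.get("pair_id", "pair")
    record, annotation = _load_record(config, base)
    sub_map = QTY_MAP
    if "map" in config:
        sub_map = SubstitutionMap.from_tsv((base / config["map"]).read_text())
    scope = frozenset(config.get("scope", ["TM"]))
    extra = tuple(config.get("extra_positions", ()))
    result = apply_substitution(record, annotation, sub_map, scope, extra)
    identity = positional_identity(result.native, result.variant)
    stats = variation_stats(result, annotation)
    phys = pair_physchem(result.native, result.variant)

    rmsd = n_matched = None
    surface = None
    if "ref_pdb" in config and "mobile_pdb" in config:
        ref = parse_pdb((base / config["ref_pdb"]).read_text(), model_id="ref")
        mob = parse_pdb((base / config["mobile_pdb"]).read_text(), model_id="mobile")
        if config.get("trim", False):
            ref = trim_to_segments(ref, annotation)
            mob = trim_to_segments(mob, annotation)
        chains = config.get("chains", {})
        sup, _ = superpose_models(
            ref, mob, chains.get("ref"), chains.get("mobile")
        )
        rmsd, n_matched = round(sup.rmsd, 3), sup.n_matched
        surface = compare_surfaces(
            ref,
            mob,
            n_points=int(config.get("sasa_points", 960)),
            exposure_threshold=float(config.get("exposure_threshold", 10.0)),
            adjacency_cutoff=float(config.get("adjacency_cutoff", 8.0)),
        )

    provenance = {
        "tool_version": __version__,
        "map": sub_map.name,
        "scope": sorted(scope),
        "extra_positions": list(extra),
        "inputs": {
            k: str(config[k])
            for k in ("native_fasta", "segments", "uniprot_txt", "ref_pdb", "mobile_pdb")
            if k in config
        },
    }
    return PairReport(
        pair_id=pair_id,
        identity_pct=identity,
        stats=stats,
        physchem=phys,
        result=result,
        rmsd=rmsd,
        n_matched=n_matched,
        surface=surface,
        provenance=provenance,
    )


def run_batch(configs: list[dict], base: Path | str = ".") -> tuple[list[PairReport], list[dict]]:
    """Run many pairs; failures are recorded per-pair and do not abort the batch."""
    reports: list[PairReport] = []
    failures: list[dict] = []
    for cfg in configs:
        try:
            reports.append(run_pair(cfg, base))
        except Exception as exc:  # noqa: BLE001 — batch isolation by contract
            failures.append({"pair_id": cfg.get("pair_id", "?"), "error": str(exc)})
    return reports, failures


# ---------------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------------

TM_ALPHABET = "LIVFAG"
LOOP_ALPHABET = "DEKRSTNQGP"


def synth_sequence(
    seed: int,
    n_tm: int = 7,
    tm_len_range: tuple[int, int] = (20, 25),
    loop_len_range: tuple[int, int] = (8, 16),
    record_id: str = "synth7tm",
) -> tuple[ProteinRecord, SegmentAnnotation]:
    """Random 7TM-like sequence: hydrophobic helical segments between polar
    loops, deterministic for a given seed."""
    rng = np.random.default_rng(seed)

    def draw(alphabet: str, n: int) -> str:
        return "".join(rng.choice(list(alphabet), size=n))

    parts: list[str] = []
    segments: list[Segment] = []
    pos = 1

    def add(label: str, kind: str, chunk: str) -> None:
        nonlocal pos
        parts.append(chunk)
        segments.append(Segment(label, pos, pos + len(chunk) - 1, kind))
        pos += len(chunk)

    add("NTERM", "NTERM", "M" + draw(LOOP_ALPHABET, int(rng.integers(*loop_len_range))))
    for i in range(1, n_tm + 1):
        add(f"TM{i}", "TM", draw(TM_ALPHABET, int(rng.integers(*tm_len_range))))
        if i < n_tm:
            kind = "ICL" if i % 2 == 1 else "ECL"
            label = f"{kind}{(i + 1) // 2}"
            add(label, kind, draw(LOOP_ALPHABET, int(rng.integers(*loop_len_range))))
    add("CTERM", "CTERM", draw(LOOP_ALPHABET, int(rng.integers(*loop_len_range))))

    record = ProteinRecord(id=record_id, sequence="".join(parts),
                           name="synthetic 7TM fixture")
    annotation = SegmentAnnotation(
        record_id=record.id, segments=tuple(segments), sequence_length=len(record)
    )
    return record, annotation


def synth_fixture(kind: str, outdir: Path | str, seed: int,
                  n_tm: int = 7, helix_spec: HelixSpec | None = None,
                  bundle_radius: float = 10.0) -> list[Path]:
    """Write synthetic fixture files; deterministic for a given seed.

    kinds: ``sequence`` (FASTA + segment TSV), ``bundle`` (PDB of an ideal
    helix bundle), ``pair`` (native + variant FASTA/TSV and two same-geometry
    bundles whose residue names differ by the QTY events).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = helix_spec or HelixSpec(n_residues=22)
    written: list[Path] = []

    def emit(name: str, text: str) -> None:
        p = outdir / name
        p.write_text(text)
        written.append(p)

    if kind == "sequence":
        record, annotation = synth_sequence(seed, n_tm=n_tm)
        emit("synth.fasta", write_fasta([record]))
        emit("synth.segments.tsv", write_segments(annotation))
    elif kind == "bundle":
        bundle = build_bundle(n_tm, spec, bundle_radius)
        emit("bundle.pdb", write_pdb(bundle))
    elif kind == "pair":
        record, annotation = synth_sequence(seed, n_tm=n_tm)
        result = apply_substitution(record, annotation)
        emit("native.fasta", write_fasta([record]))
        emit("variant.fasta", write_fasta([result.variant]))
        emit("synth.segments.tsv", write_segments(annotation))
        native_bundle = build_bundle(
            n_tm, spec, bundle_radius, sequence=record, annotation=annotation,
            model_id="native_bundle",
        )
        variant_bundle = build_bundle(
            n_tm, spec, bundle_radius, sequence=result.variant,
            annotation=dataclasses.replace(annotation, record_id=result.variant.id),
            model_id="variant_bundle",
        )
        emit("native.pdb", write_pdb(native_bundle))
        emit("variant.pdb", write_pdb(variant_bundle))
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return written


def report_tsv(reports: list[PairReport]) -> str:
    lines = [PairReport.TSV_HEADER]
    lines += [r.tsv_row() for r in reports]
    return "\n".join(lines) + "\n"


def report_json(reports: list[PairReport], failures: list[dict]) -> str:
    return json.dumps(
        {"pairs": [r.sidecar() for r in reports], "failures": failures},
        indent=2,
        sort_keys=True,
    )
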