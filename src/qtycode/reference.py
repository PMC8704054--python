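"""Bundled reference data: eight human 7TM receptor sequences with
approximate helical-segment annotations.

The sequences were transcribed offline from their UniProt entries (see
``registry.tsv`` for the accession→name mapping) and the segment tables
place seven ~29-residue helical segments anchored on Kyte–Doolittle
hydropathy peaks and conserved class-A motifs (DRY, NPxxY).  They are
reference fixtures for download-free operation; when network access is
available, freshly fetched UniProt FASTA + flat-file TRANSMEM features can
be substituted through the same CLI options.
"""

from __future__ import annotations

from importlib import resources

from qtycode.seqio import (
    ProteinRecord,
    SegmentAnnotation,
    load_segments,
    parse_fasta,
)


def _data(filename: str) -> str:
    return resources.files("qtycode").joinpath("data/reference").joinpath(filename).read_text()


def list_reference() -> dict[str, str]:
    """Accession → receptor name for every bundled entry."""
    out: dict[str, str] = {}
    for line in _data("registry.tsv").splitlines():
        if not line or line.startswith("#"):
            continue
        acc, name = line.split("\t")
        out[acc] = name
    return out


def load_reference(accession: str) -> tuple[ProteinRecord, SegmentAnnotation]:
    """Load one bundled receptor: (sequence record, segment annotation)."""
    registry = list_reference()
    if accession not in registry:
        by_name = {v: k for k, v in registry.items()}
        if accession in by_name:
            accession = by_name[accession]
        else:
            raise KeyError(
                f"unknown reference {accession!r}; bundled: {sorted(registry)}"
            )
    record = parse_fasta(_data(f"{accession}.fasta"))[0]
    annotation = load_segments(_data(f"{accession}.segments.tsv"), record)
    return record, annotation
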