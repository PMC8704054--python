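# qtycode

Tools for the **QTY code** — the water-solubilizing substitution scheme that
replaces the hydrophobic residues of transmembrane helices (L, I, V, F) with
polar, uncharged residues (L→Q, I→T, V→T, F→Y) — plus the comparison battery
for judging what the substitution does to a receptor:

- **seqio** — FASTA and segment-table I/O, UniProt flat-file TRANSMEM
  features, Kyte–Doolittle sliding-window TM inference as a fallback.
- **qty_engine** — configurable substitution maps applied within annotated
  segments; positional identity, total and membrane variation rates,
  plain-text block alignments (`|` identical, `*` differing).
- **physchem** — average molecular weight and Expasy-style isoelectric point
  (Bjellqvist pKa set, Henderson–Hasselbalch bisection), native-vs-variant
  deltas.
- **structure** — fixed-column PDB I/O, residue matching by number, Kabsch
  SVD superposition with Cα RMSD, idealized α-helix and helix-bundle
  generators (1.5 Å rise, 100° twist per residue), helix-geometry recovery
  by axis fitting.
- **surface** — Shrake–Rupley solvent-accessible surface area with a
  deterministic spiral point set, hydrophobic exposed fraction, and
  connected hydrophobic-patch detection.
- **report / cli** — end-to-end pair reports (TSV + JSON sidecar), batch
  manifests, and deterministic synthetic 7TM fixtures.

## CLI

```sh
# make a variant sequence + event list
qty convert --fasta ccr5.fasta --segments ccr5.segments.tsv \
    --out-fasta ccr5_qty.fasta --events-tsv events.tsv

# identity, variation rates, pI and MW deltas (and the alignment view)
qty stats --fasta ccr5.fasta --segments ccr5.segments.tsv --alignment

# Cα superposition (optionally restricted to TM residues)
qty superpose --ref native.pdb --mobile variant.pdb \
    --segments segs.tsv --fasta native.fasta --trim --out moved.pdb

# SASA + hydrophobic patches
qty sasa --pdb native.pdb --out-tsv sasa.tsv

# batch comparisons from a YAML manifest
qty report --manifest pairs.yaml --out-tsv report.tsv --out-json report.json

# deterministic synthetic fixtures (sequence | bundle | pair)
qty synth --kind pair --out fixtures/ --seed 1
```

A manifest entry names a pair and its inputs:

```yaml
- pair_id: CCR5
  native_fasta: P51681.fasta
  segments: P51681.segments.tsv   # or uniprot_txt: P51681.txt
  # optional: map, scope, extra_positions, ref_pdb, mobile_pdb, trim,
  #           sasa_points, exposure_threshold, adjacency_cutoff
```

Substitution maps are data, not code: `src/qtycode/data/map_qty.tsv` holds
the default; alternative alphabets (e.g. Q/T/Y→A back-substitutions) are
two-column TSV files passed via `--map`.

## Reference data

`src/qtycode/data/reference/` bundles eight human 7TM receptor sequences
(CCR5, CCR9, CXCR2, CXCR4, CCR10, CXCR5, CXCR7/ACKR3, OR1D2) with
approximate helical-segment annotations (seven ~29-residue segments anchored
on hydropathy peaks and conserved class-A motifs). The sequences were
transcribed offline from their UniProt entries; when you have network
access, prefer freshly fetched UniProt FASTA plus flat-file TRANSMEM
features (`qty convert --uniprot-txt ...`). Helical-segment boundaries are
treated strictly as *input*: different boundary choices (and the original
designs' extra loop/C-terminal substitutions) shift identity and delta
values by a few points.

Predicted 3D models are consumed as ordinary PDB files; this package never
runs structure prediction itself.

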