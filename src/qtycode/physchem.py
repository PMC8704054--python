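"""Sequence-level physicochemical properties: molecular weight and pI.

Molecular weights use average residue masses plus one water; isoelectric
points come from a Henderson–Hasselbalch net-charge model with the
Bjellqvist pKa set (the convention of the Expasy Compute pI/MW service),
solved by bisection.  Cysteines are treated as free thiols — no disulfide
correction — again matching Expasy.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources

from qtycode.seqio import AMINO_ACIDS, ProteinRecord, SequenceError
from qtycode.qty_engine import QTYResult, round_half_up


def _read_data(filename: str) -> str:
    return resources.files("qtycode").joinpath("data").joinpath(filename).read_text()


@dataclass(frozen=True)
class MassTable:
    residue_masses: dict[str, float]
    water_mass: float

    def __post_init__(self) -> None:
        missing = AMINO_ACIDS - set(self.residue_masses)
        if missing:
            raise SequenceError(f"mass table missing residues: {sorted(missing)}")
        if any(m <= 0 for m in self.residue_masses.values()) or self.water_mass <= 0:
            raise SequenceError("masses must be positive")

    @classmethod
    def from_tsv(cls, stream) -> "MassTable":
        if isinstance(stream, str):
            stream = io.StringIO(stream)
        masses: dict[str, float] = {}
        water = 18.01524
        for raw in stream:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("water"):
                    water = float(body.split("\t")[1])
                continue
            code, mass = line.split("\t")
            masses[code] = float(mass)
        return cls(residue_masses=masses, water_mass=water)


@dataclass(frozen=True)
class PkaSet:
    """pKa values for side chains and termini.

    ``nterm`` / ``cterm`` map a residue code to its terminal pKa, with the
    ``"default"`` key used for residues without a specific value (Bjellqvist
    assigns residue-specific N-terminal pKas and D/E-specific C-terminal
    ones).
    """

    name: str
    side: dict[str, float]
    nterm: dict[str, float]
    cterm: dict[str, float]

    POSITIVE_SIDE = ("K", "R", "H")
    NEGATIVE_SIDE = ("D", "E", "C", "Y")

    def __post_init__(self) -> None:
        for d in (self.side, self.nterm, self.cterm):
            for v in d.values():
                if not (0.0 < v < 14.0):
                    raise SequenceError(f"pKa {v} outside (0, 14)")
        if "default" not in self.nterm or "default" not in self.cterm:
            raise SequenceError("pKa set needs default terminal values")

    @classmethod
    def from_tsv(cls, stream, name: str = "custom") -> "PkaSet":
        if isinstance(stream, str):
            stream = io.StringIO(stream)
        groups: dict[str, dict[str, float]] = {"side": {}, "nterm": {}, "cterm": {}}
        for raw in stream:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            group, key, val = line.split("\t")
            groups[group][key] = float(val)
        return cls(name=name, side=groups["side"], nterm=groups["nterm"],
                   cterm=groups["cterm"])


def default_mass_table() -> MassTable:
    return MassTable.from_tsv(_read_data("masses_average.tsv"))


def bjellqvist_pkas() -> PkaSet:
    return PkaSet.from_tsv(_read_data("pka_bjellqvist.tsv"), name="bjellqvist")


def lehninger_pkas() -> PkaSet:
    return PkaSet.from_tsv(_read_data("pka_lehninger.tsv"), name="lehninger")


def molecular_weight(record: ProteinRecord, table: MassTable | None = None) -> float:
    """Average molecular mass in Da: sum of residue masses plus one water."""
    table = table or default_mass_table()
    try:
        total = sum(table.residue_masses[c] for c in record.sequence)
    except KeyError as exc:
        raise SequenceError(f"residue {exc.args[0]!r} absent from mass table") from None
    return round(total + table.water_mass, 2)


def net_charge(
    record: ProteinRecord, pH: float, pkas: PkaSet | None = None
) -> float:
    """Henderson–Hasselbalch net charge at a given pH.

    Positive groups (N-terminus, K, R, H) contribute 1/(1+10^(pH−pKa));
    negative groups (C-terminus, D, E, C, Y) contribute −1/(1+10^(pKa−pH)).
    """
    if not (0.0 <= pH <= 14.0):
        raise ValueError("pH must lie in [0, 14]")
    pkas = pkas or bjellqvist_pkas()
    seq = record.sequence

    def pos(pka: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (pH - pka))

    def neg(pka: float) -> float:
        return -1.0 / (1.0 + 10.0 ** (pka - pH))

    charge = pos(pkas.nterm.get(seq[0], pkas.nterm["default"]))
    charge += neg(pkas.cterm.get(seq[-1], pkas.cterm["default"]))
    for code in PkaSet.POSITIVE_SIDE:
        n = seq.count(code)
        if n and code in pkas.side:
            charge += n * pos(pkas.side[code])
    for code in PkaSet.NEGATIVE_SIDE:
        n = seq.count(code)
        if n and code in pkas.side:
            charge += n * neg(pkas.side[code])
    return charge


def isoelectric_point(
    record: ProteinRecord, pkas: PkaSet | None = None, tol: float = 0.001
) -> float:
    """pH of zero net charge, by bisection on [0, 14].

    net_charge is strictly decreasing in pH (every term is), so the root is
    unique; termini guarantee at least one positive and one negative group.
    """
    pkas = pkas or bjellqvist_pkas()
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(record, mid, pkas) > 0.0:
            lo = mid
        else:
            hi = mid
    return round(0.5 * (lo + hi), 2)


@dataclass(frozen=True)
class PairPhyschem:
    pI_native: float
    pI_variant: float
    delta_pI: float
    mw_native: float
    mw_variant: float
    delta_mw: float
    delta_mw_pct: float


def pair_physchem(
    native: ProteinRecord,
    variant: ProteinRecord,
    table: MassTable | None = None,
    pkas: PkaSet | None = None,
) -> PairPhyschem:
    """Native-vs-variant pI and MW deltas (deltas reported unsigned)."""
    if len(native) != len(variant):
        raise SequenceError("pair_physchem expects an equal-length pair")
    table = table or default_mass_table()
    pkas = pkas or bjellqvist_pkas()
    # deltas come from unrounded sums so per-residue rounding cannot leak in
    raw_n = sum(table.residue_masses[c] for c in native.sequence) + table.water_mass
    raw_v = sum(table.residue_masses[c] for c in variant.sequence) + table.water_mass
    mw_n, mw_v = round(raw_n, 2), round(raw_v, 2)
    pi_n = isoelectric_point(native, pkas)
    pi_v = isoelectric_point(variant, pkas)
    delta_mw = round(abs(raw_v - raw_n), 2)
    return PairPhyschem(
        pI_native=pi_n,
        pI_variant=pi_v,
        delta_pI=round(abs(pi_v - pi_n), 2),
        mw_native=mw_n,
        mw_variant=mw_v,
        delta_mw=delta_mw,
        delta_mw_pct=round_half_up(100.0 * delta_mw / mw_n),
    )


def event_mass_delta(result: QTYResult, table: MassTable | None = None) -> float:
    """Signed sum over substitution events of (target − source) residue mass."""
    table = table or default_mass_table()
    return sum(
        table.residue_masses[e.target] - table.residue_masses[e.source]
        for e in result.events
    )
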