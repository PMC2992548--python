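"""Readers and writers for the package's file formats, plus synthetic fixtures.

Formats handled: FASTA (sequences), aligned FASTA (multiple sequence
alignments), PDB v3.3 ATOM/HETATM records (structures), and a 9-column
tab-delimited feature table that carries per-residue annotations from any
source (structure calculations, curated records, predictions) in the four
categories the information system distinguishes: contacts, variable
features, fixed features and variants.

``make_fixture`` emits small synthetic PDB files with programmatically
placed coordinates (ideal helix, extended chain, antiparallel strand pair,
disulfide pair, salt bridge, metal site, fully buried core residue)
together with a manifest of the features the structural detectors must
recover from them.
"""

from __future__ import annotations

import copy
import io
import math
from dataclasses import dataclass, field
from typing import Iterable, TextIO

import numpy as np

from mutexplain._peptide import build_backbone, transform
from mutexplain.aa_knowledge import THREE_TO_ONE

SOURCE_TIERS = ("STRUCTURE", "CURATED", "PREDICTED")
CATEGORIES = ("CONTACT", "VARIABLE", "FIXED", "VARIANT")

_STANDARD_CODES = set("ACDEFGHIKLMNPQRSTVWY")


# ---------------------------------------------------------------------------
# domain types


@dataclass
class SequenceRecord:
    id: str
    residues: str


@dataclass
class AtomRecord:
    serial: int
    name: str
    altloc: str
    residue_name: str
    chain: str
    residue_number: int
    insertion_code: str
    x: float
    y: float
    z: float
    element: str
    is_hetero: bool

    @property
    def coord(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"

    @property
    def is_water(self) -> bool:
        return self.residue_name in ("HOH", "WAT", "DOD")


@dataclass
class Residue:
    chain: str
    number: int
    insertion_code: str
    name: str
    atoms: list = field(default_factory=list)
    is_hetero: bool = False

    @property
    def key(self) -> tuple:
        return (self.chain, self.number, self.insertion_code)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list:
        return [a for a in self.atoms if not a.is_hydrogen]


@dataclass
class Structure:
    atoms: list
    chains: list
    residues: list  # file order; polymer and hetero interleaved as read

    def polymer_residues(self, chain: str | None = None) -> list:
        return [
            r
            for r in self.residues
            if not r.is_hetero and (chain is None or r.chain == chain)
        ]

    def hetero_residues(self) -> list:
        return [r for r in self.residues if r.is_hetero]

    def sequence(self, chain: str | None = None) -> str:
        return "".join(r.one_letter for r in self.polymer_residues(chain))


@dataclass
class FeatureRecord:
    """One annotation attached to a residue or residue range."""

    seq_id: str
    source_tier: str  # STRUCTURE | CURATED | PREDICTED
    category: str     # CONTACT | VARIABLE | FIXED | VARIANT
    feature_type: str
    begin: int  # 1-based inclusive
    end: int
    value: float | str | None = None
    partner: str | None = None
    description: str = ""

    def __post_init__(self):
        if self.source_tier not in SOURCE_TIERS:
            raise ValueError(f"unknown source tier {self.source_tier!r}")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.begin < 1 or self.begin > self.end:
            raise ValueError(
                f"invalid span {self.begin}-{self.end} (need 1 <= begin <= end)"
            )
        if self.category == "VARIABLE":
            try:
                self.value = float(self.value)  # type: ignore[arg-type]
            except (TypeError, ValueError):
                raise ValueError(
                    f"VARIABLE feature {self.feature_type} requires a numeric value, "
                    f"got {self.value!r}"
                ) from None
        if self.category == "FIXED" and isinstance(self.value, float):
            raise ValueError("FIXED feature must not carry a numeric value")

    def covers(self, position: int) -> bool:
        return self.begin <= position <= self.end

    def identity(self) -> tuple:
        return (
            self.seq_id, self.source_tier, self.category, self.feature_type,
            self.begin, self.end, self.value, self.partner, self.description,
        )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(stream: TextIO | str) -> list[SequenceRecord]:
    """Parse FASTA text into records (order preserved, residues uppercased)."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    records: list[SequenceRecord] = []
    current_id: str | None = None
    chunks: list[str] = []
    saw_any = False

    def flush():
        if current_id is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ValueError(f"record {current_id!r} has an empty sequence")
        records.append(SequenceRecord(id=current_id, residues=seq))

    for lineno, raw in enumerate(stream, 1):
        line = raw.strip()
        if not line:
            continue
        saw_any = True
        if line.startswith(">"):
            flush()
            current_id = line[1:].split()[0] if line[1:].strip() else f"seq{lineno}"
            chunks = []
        else:
            if current_id is None:
                raise ValueError(f"line {lineno}: sequence data before first '>' header")
            seq = line.upper()
            bad = set(seq) - _STANDARD_CODES - {"X", "-"}
            if bad:
                raise ValueError(
                    f"line {lineno}: illegal residue character(s) {sorted(bad)}"
                )
            chunks.append(seq)
    if not saw_any:
        raise ValueError("empty FASTA input")
    flush()
    if not records:
        raise ValueError("no sequence records found")
    return records


def read_msa(stream: TextIO | str) -> list[SequenceRecord]:
    """Read an aligned FASTA file; all rows must have equal length."""
    rows = read_fasta(stream)
    width = len(rows[0].residues)
    for r in rows:
        if len(r.residues) != width:
            raise ValueError(
                f"alignment is ragged: record {r.id!r} has length "
                f"{len(r.residues)}, expected {width}"
            )
    return rows


# ---------------------------------------------------------------------------
# PDB

_METALS = {"ZN", "FE", "MG", "MN", "CU", "CA", "NA", "K", "NI", "CO", "MO", "CD"}


def _infer_element(name: str, residue_name: str) -> str:
    stripped = name.strip()
    if residue_name.strip() in _METALS and stripped.upper() in _METALS:
        return stripped.upper()
    # standard PDB: element is the first letter after leading digits
    core = stripped.lstrip("0123456789")
    if not core:
        return "X"
    if core[:1].upper() == "H" or (stripped and stripped[0].isdigit()):
        return "H"
    return core[0].upper()


def read_pdb(stream: TextIO | str) -> Structure:
    """Parse PDB-format text (first MODEL only; altloc blank or 'A' kept)."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    atoms: list[AtomRecord] = []
    model_no = 0
    for lineno, raw in enumerate(stream, 1):
        rec = raw[:6]
        if rec == "MODEL ":
            model_no += 1
            if model_no > 1:
                break
            continue
        if rec == "ENDMDL":
            if model_no >= 1:
                break
            continue
        if rec not in ("ATOM  ", "HETATM"):
            continue
        line = raw.rstrip("\n")
        altloc = line[16] if len(line) > 16 else " "
        if altloc not in (" ", "A"):
            continue
        try:
            serial = int(line[6:11])
            name = line[12:16].strip()
            residue_name = line[17:20].strip()
            chain = line[21] if len(line) > 21 else " "
            residue_number = int(line[22:26])
            icode = line[26] if len(line) > 26 else " "
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except (ValueError, IndexError):
            raise ValueError(f"line {lineno}: unparsable ATOM/HETATM record") from None
        if not all(math.isfinite(v) for v in (x, y, z)):
            raise ValueError(f"line {lineno}: non-finite coordinate")
        element = line[76:78].strip().upper() if len(line) >= 78 else ""
        if not element:
            element = _infer_element(name, residue_name)
        is_het = rec == "HETATM"
        atoms.append(
            AtomRecord(
                serial=serial, name=name, altloc=altloc,
                residue_name=residue_name, chain=chain,
                residue_number=residue_number, insertion_code=icode,
                x=x, y=y, z=z, element=element, is_hetero=is_het,
            )
        )
    polymer = [a for a in atoms if not a.is_hetero]
    if not polymer:
        raise ValueError("no polymer atoms (ATOM records) in input")

    residues: list[Residue] = []
    index: dict[tuple, Residue] = {}
    chains: list[str] = []
    for a in atoms:
        if a.is_water:
            a.is_hetero = True
        key = (a.chain, a.residue_number, a.insertion_code, a.is_hetero)
        if key not in index:
            r = Residue(
                chain=a.chain, number=a.residue_number,
                insertion_code=a.insertion_code, name=a.residue_name,
                is_hetero=a.is_hetero,
            )
            index[key] = r
            residues.append(r)
            if a.chain not in chains:
                chains.append(a.chain)
        index[key].atoms.append(a)
    return Structure(atoms=atoms, chains=chains, residues=residues)


def write_pdb(structure: Structure) -> str:
    """Serialize a Structure back to PDB text (fixtures, debugging)."""
    lines = []
    for a in structure.atoms:
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        rec = "HETATM" if a.is_hetero else "ATOM  "
        lines.append(
            f"{rec}{a.serial:5d} {name}{a.altloc}{a.residue_name:>3s} "
            f"{a.chain}{a.residue_number:4d}{a.insertion_code}   "
            f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {a.element:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# feature table (9-column TSV)

_NCOLS = 9


def read_features(stream: TextIO | str) -> list[FeatureRecord]:
    """Read the 9-column tab-delimited feature table.

    Columns: seq_id, source_tier, category, feature_type, begin, end,
    value, partner, description.  '#' starts a comment line; '.' marks an
    empty optional field.  Tier and category tokens are case-insensitive.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    records: list[FeatureRecord] = []
    for lineno, raw in enumerate(stream, 1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != _NCOLS:
            raise ValueError(
                f"line {lineno}: expected {_NCOLS} tab-separated columns, "
                f"got {len(parts)}"
            )
        seq_id, tier, category, ftype, begin, end, value, partner, desc = parts
        try:
            rec = FeatureRecord(
                seq_id=seq_id,
                source_tier=tier.upper(),
                category=category.upper(),
                feature_type=ftype.upper(),
                begin=int(begin),
                end=int(end),
                value=None if value == "." else value,
                partner=None if partner == "." else partner,
                description="" if desc == "." else desc,
            )
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from None
        records.append(rec)
    return records


def write_features(records: Iterable[FeatureRecord]) -> str:
    """Serialize feature records to the same TSV dialect (lossless)."""
    lines = ["#seq_id\tsource_tier\tcategory\tfeature_type\tbegin\tend\tvalue\tpartner\tdescription"]
    for r in records:
        if r.value is None:
            value = "."
        elif isinstance(r.value, float):
            value = format(r.value, "g")
        else:
            value = str(r.value)
        lines.append(
            "\t".join(
                [
                    r.seq_id, r.source_tier, r.category, r.feature_type,
                    str(r.begin), str(r.end), value,
                    r.partner if r.partner is not None else ".",
                    r.description if r.description else ".",
                ]
            )
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# synthetic fixtures

FIXTURE_KINDS = (
    "ideal_helix", "extended", "antiparallel_sheet",
    "disulfide_pair", "salt_bridge", "metal_site", "clash_core",
)

_HELIX = (-57.0, -47.0)
_STRAND = (-139.0, 135.0)
_EXTENDED = (180.0, 180.0)


class _PdbBuilder:
    def __init__(self):
        self.lines: list[str] = []
        self.serial = 0

    def atom(self, name, resname, chain, resnum, xyz, element=None, hetero=False):
        self.serial += 1
        el = element or name[0]
        pname = name if len(name) >= 4 else f" {name:<3s}"
        rec = "HETATM" if hetero else "ATOM  "
        self.lines.append(
            f"{rec}{self.serial:5d} {pname} {resname:>3s} {chain}{resnum:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {el:>2s}"
        )

    def backbone(self, residues, resname, chain, start_num=1):
        for i, r in enumerate(residues):
            num = start_num + i
            for name in ("N", "CA", "C", "O"):
                self.atom(name, resname, chain, num, r[name])

    def text(self) -> str:
        return "\n".join(self.lines + ["END"]) + "\n"


def _canonicalize_strand(strand):
    """Rigidly move a built strand so its axis runs along +x and its
    carbonyl C=O vectors lie (alternating sign) along the y axis."""
    ca0, can = strand[0]["CA"], strand[-1]["CA"]
    x = can - ca0
    x /= np.linalg.norm(x)
    # mean carbonyl direction of even residues, perpendicular component
    co = np.zeros(3)
    for i in range(0, len(strand), 2):
        co += strand[i]["O"] - strand[i]["C"]
    co -= np.dot(co, x) * x
    y = co / np.linalg.norm(co)
    z = np.cross(x, y)
    rot = np.vstack([x, y, z])  # world -> canonical
    centre = ca0
    return [
        {name: rot @ (xyz - centre) for name, xyz in r.items()} for r in strand
    ]


def _strand_hbond_search(strand1, per):
    """Place an antiparallel partner strand so the pair hydrogen-bonds.

    The partner is the same strand rotated by the antiparallel dyad (180
    degrees about the axis normal to the sheet plane) plus a small
    twist-compensating rotation; the rigid placement is grid-searched to
    maximize the number of inter-strand backbone H-bonds under the same
    electrostatic criterion the detectors use (construction aid only — the
    detectors re-derive everything from the emitted coordinates).

    Returns ``(strand2, bridge_pairs)`` where bridge_pairs are (i, j)
    1-based residue indices (strand1, strand2) joined by mutual bonds.
    """
    dyad = np.array([[-1.0, 0, 0], [0, -1.0, 0], [0, 0, 1.0]])
    coupling = 0.084 * 332.0

    def amide_h(res, prev):
        v1 = prev["C"] - res["N"]
        v2 = res["CA"] - res["N"]
        v1 /= np.linalg.norm(v1)
        v2 /= np.linalg.norm(v2)
        bis = v1 + v2
        return res["N"] - bis / np.linalg.norm(bis)

    def energy(dn, dh, ac, ao):
        return coupling * (
            1.0 / np.linalg.norm(ao - dn)
            + 1.0 / np.linalg.norm(ac - dh)
            - 1.0 / np.linalg.norm(ao - dh)
            - 1.0 / np.linalg.norm(ac - dn)
        )

    bb1 = np.array([r[name] for r in strand1 for name in ("N", "CA", "C", "O")])
    h1 = {i: amide_h(strand1[i], strand1[i - 1]) for i in range(1, per)}

    # translation grid, evaluated in one vectorized pass per dyad twist
    tgrid = np.array(
        [
            [tx, ty, tz]
            for tx in np.arange(-4.0, 18.01, 0.5)
            for ty in np.arange(3.5, 6.51, 0.25)
            for tz in np.arange(-2.0, 2.01, 0.5)
        ]
    )
    coup = 0.084 * 332.0
    best = None
    for rx_deg in (-20.0, -15.0, -10.0, -5.0, 0.0, 5.0, 10.0, 15.0, 20.0):
        rx = np.deg2rad(rx_deg)
        rot = np.array(
            [[1, 0, 0], [0, np.cos(rx), -np.sin(rx)], [0, np.sin(rx), np.cos(rx)]]
        ) @ dyad
        base = transform(strand1, rot, np.zeros(3))
        h2_rel = {i: amide_h(base[i], base[i - 1]) for i in range(1, per)}
        bb2b = np.array([r[name] for r in base for name in ("N", "CA", "C", "O")])
        # steric screen: min inter-backbone separation per translation
        diff_bb = bb2b[None, :, :] - bb1[:, None, :]  # (n1, n2, 3)
        sep = np.linalg.norm(
            diff_bb.reshape(1, -1, 3) + tgrid[:, None, :], axis=2
        ).min(axis=1)
        ok_t = sep >= 2.6
        # pair energies: E = coup * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)
        # donor in strand1, acceptor in rotated strand2 (+t) and vice versa
        pair_ids = []
        diffs = []   # moving-atom minus fixed-atom; r = |diff + t|
        coefs = []
        for di in range(1, per):
            for ai in range(per):
                n1p, h1p = strand1[di]["N"], h1[di]
                c2, o2 = base[ai]["C"], base[ai]["O"]
                pair_ids.append(("AB", di, ai))
                for fixed, moving, cf in (
                    (n1p, o2, 1.0), (h1p, c2, 1.0), (h1p, o2, -1.0), (n1p, c2, -1.0)
                ):
                    diffs.append(moving - fixed)
                    coefs.append(cf)
                n2p, h2p = base[di]["N"], h2_rel[di]
                c1, o1 = strand1[ai]["C"], strand1[ai]["O"]
                pair_ids.append(("BA", di, ai))
                for moving, fixed, cf in (
                    (n2p, o1, 1.0), (h2p, c1, 1.0), (h2p, o1, -1.0), (n2p, c1, -1.0)
                ):
                    diffs.append(moving - fixed)
                    coefs.append(cf)
        diffs = np.array(diffs)          # (4P, 3)
        coefs = np.array(coefs)          # (4P,)
        r = np.linalg.norm(diffs[None, :, :] + tgrid[:, None, :], axis=2)
        inv = coefs / np.clip(r, 0.1, None)
        energies = coup * inv.reshape(len(tgrid), -1, 4).sum(axis=2)  # (T, P)
        bonded = energies < -0.6
        counts = np.where(ok_t, bonded.sum(axis=1), -1)
        totals = np.where(bonded, energies, 0.0).sum(axis=1)
        order = np.lexsort((totals, -counts))
        ti = int(order[0])
        key = (int(counts[ti]), -float(totals[ti]))
        if counts[ti] >= 0 and (best is None or key > best[0]):
            bonds = [pair_ids[p] for p in np.where(bonded[ti])[0]]
            best = (key, tgrid[ti], rot, bonds)
    if best is None or best[0][0] < 2:
        raise RuntimeError("sheet registration search failed")
    _, t, rot, bonds = best
    strand2 = [{k: rot @ v + t for k, v in r.items()} for r in strand1]
    ab = {(d, a) for tag, d, a in bonds if tag == "AB"}
    ba = {(d, a) for tag, d, a in bonds if tag == "BA"}
    bridge_pairs = sorted((i + 1, j + 1) for (i, j) in ab if (j, i) in ba)
    return strand2, bridge_pairs


_FIXTURE_CACHE: dict = {}


def make_fixture(kind: str, size: int = 12) -> tuple[str, dict]:
    """Build a synthetic PDB fixture and its expected-feature manifest.

    Returns ``(pdb_text, manifest)``.  ``size`` is the residue count for the
    chain-like kinds (helix, extended, sheet) and must lie in [4, 50]; the
    site-like kinds use fixed minimal layouts.  Results are cached per
    (kind, size); construction is fully deterministic.
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}")
    if not 4 <= size <= 50:
        raise ValueError(f"size {size} outside [4, 50]")
    cache_key = (kind, size)
    if cache_key in _FIXTURE_CACHE:
        text, manifest = _FIXTURE_CACHE[cache_key]
        return text, copy.deepcopy(manifest)
    text, manifest = _build_fixture(kind, size)
    _FIXTURE_CACHE[cache_key] = (text, manifest)
    return text, copy.deepcopy(manifest)


def _build_fixture(kind: str, size: int) -> tuple[str, dict]:
    b = _PdbBuilder()

    if kind == "ideal_helix":
        res = build_backbone([_HELIX] * size)
        b.backbone(res, "ALA", "A")
        # i+4 -> i backbone H-bonds exist for acceptors 1..size-4
        hbonds = [(i + 4, i) for i in range(1, size - 3)]
        helix = sorted({r for d, a in hbonds for r in range(a + 1, d)})
        return b.text(), {"hbonds": hbonds, "helix_residues": helix,
                          "n_residues": size, "chain": "A"}

    if kind == "extended":
        res = build_backbone([_EXTENDED] * size)
        b.backbone(res, "ALA", "A")
        return b.text(), {"ss": "C" * size, "n_residues": size, "chain": "A"}

    if kind == "antiparallel_sheet":
        per = size // 2
        s1 = _canonicalize_strand(build_backbone([_STRAND] * per))
        s2, bridge_pairs = _strand_hbond_search(s1, per)
        b.backbone(s1, "ALA", "A", 1)
        b.backbone(s2, "ALA", "B", 1)
        strand_residues = sorted(
            {("A", i) for i, _ in bridge_pairs} | {("B", j) for _, j in bridge_pairs}
        )
        return b.text(), {"bridge_pairs": bridge_pairs,
                          "strand_residues": strand_residues,
                          "n_residues": 2 * per, "chains": ["A", "B"]}

    if kind == "disulfide_pair":
        # two cysteines, backbones apart, SG atoms at 2.05 A
        for num, sg_x, side in ((1, 0.0, -1.0), (4, 2.05, 1.0)):
            cb = np.array([sg_x, 1.8, 0.0])
            ca = np.array([sg_x + side * 0.6, 3.2, 0.3])
            n = ca + np.array([side * 1.2, 0.8, 0.0])
            c = ca + np.array([-side * 0.4, 1.0, 1.1])
            o = c + np.array([0.0, 0.4, 1.15])
            b.atom("N", "CYS", "A", num, n)
            b.atom("CA", "CYS", "A", num, ca)
            b.atom("C", "CYS", "A", num, c)
            b.atom("O", "CYS", "A", num, o)
            b.atom("CB", "CYS", "A", num, cb)
            b.atom("SG", "CYS", "A", num, np.array([sg_x, 0.0, 0.0]), element="S")
        return b.text(), {"disulfides": [(1, 4)], "sg_distance": 2.05}

    if kind == "salt_bridge":
        # LYS NZ ... GLU OE1 at 3.5 A
        nz = np.array([0.0, 0.0, 0.0])
        for name, resname, num, base, element in (
            ("NZ", "LYS", 1, nz, "N"),
            ("OE1", "GLU", 4, np.array([3.5, 0.0, 0.0]), "O"),
        ):
            sign = -1.0 if num == 1 else 1.0
            ca = base + np.array([sign * 1.0, 4.0, 0.0])
            b.atom("N", resname, "A", num, ca + np.array([sign * 1.3, 0.6, 0.2]))
            b.atom("CA", resname, "A", num, ca)
            b.atom("C", resname, "A", num, ca + np.array([-sign * 0.6, 1.1, 1.0]))
            b.atom("O", resname, "A", num, ca + np.array([-sign * 0.6, 1.6, 2.1]))
            b.atom("CB", resname, "A", num, ca + np.array([0.0, -1.5, 0.4]))
            b.atom(name, resname, "A", num, base, element=element)
        return b.text(), {"salt_bridges": [(1, 4)], "distance": 3.5}

    if kind == "metal_site":
        ne2 = np.array([0.0, 0.0, 0.0])
        ca = np.array([-1.0, 4.2, 0.0])
        b.atom("N", "HIS", "A", 1, ca + np.array([-1.3, 0.6, 0.2]))
        b.atom("CA", "HIS", "A", 1, ca)
        b.atom("C", "HIS", "A", 1, ca + np.array([0.6, 1.1, 1.0]))
        b.atom("O", "HIS", "A", 1, ca + np.array([0.6, 1.6, 2.1]))
        b.atom("CB", "HIS", "A", 1, ca + np.array([0.0, -1.5, 0.4]))
        b.atom("NE2", "HIS", "A", 1, ne2, element="N")
        b.atom("ZN", "ZN", "B", 1, np.array([2.2, 0.0, 0.0]), element="ZN", hetero=True)
        return b.text(), {"ligand_contacts": [(1, "ZN")], "distance": 2.2, "ion": True}

    # clash_core: central valine-like residue enclosed by a dense shell
    centre = {
        "N": np.array([-0.7, -0.9, 0.0]),
        "CA": np.array([0.0, 0.0, 0.0]),
        "C": np.array([1.0, 0.5, -0.6]),
        "O": np.array([1.3, 1.6, -0.4]),
        "CB": np.array([0.2, 0.3, 1.4]),
    }
    for name, xyz in centre.items():
        b.atom(name, "VAL", "A", 1, xyz)
    # 64 shell atoms on a Fibonacci sphere of radius 4.6 A around CB,
    # grouped into glycine residues of 4 atoms each
    n_shell = 64
    golden = math.pi * (3.0 - math.sqrt(5.0))
    names = ("N", "CA", "C", "O")
    for i in range(n_shell):
        zf = 1.0 - 2.0 * (i + 0.5) / n_shell
        r = math.sqrt(1.0 - zf * zf)
        theta = golden * i
        xyz = centre["CB"] + 4.6 * np.array(
            [r * math.cos(theta), r * math.sin(theta), zf]
        )
        resnum = 2 + i // 4
        b.atom(names[i % 4], "GLY", "A", resnum, xyz)
    return b.text(), {
        "buried_residue": 1,
        "max_asa": 1.0,
        "min_neighbor_count": 20,
        "n_shell_atoms": n_shell,
    }
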