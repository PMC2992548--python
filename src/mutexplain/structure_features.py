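"""Per-residue structural calculations on a 3D structure.

Everything the decision scheme needs from coordinates is computed here:

* solvent-accessible surface area (numerical Shrake-Rupley on a
  deterministic spiral point lattice) and its normalization to relative
  accessibility with a burial classification,
* backbone hydrogen bonds using the DSSP electrostatic energy model with
  geometric placement of the missing amide hydrogen,
* a simplified secondary-structure assignment (helix / strand / coil),
* disulfide bridges, salt bridges, ligand and ion contacts,
* a packing density (neighbour count) used as a clash-risk proxy when a
  mutation puts a larger residue into a tightly packed buried position.

All detectors operate on heavy atoms only and are invariant under rigid
motions of the coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from mutexplain.bio_io import FeatureRecord, Residue, Structure
from mutexplain.config import RunConfig

_BACKBONE = {"N", "CA", "C", "O", "OXT"}

_ACIDIC = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
_BASIC = {"LYS": ("NZ",), "ARG": ("NH1", "NH2", "NE"), "HIS": ("ND1", "NE2")}

_METALS = {"ZN", "FE", "MG", "MN", "CU", "CA", "NA", "K", "NI", "CO", "MO", "CD"}

# DSSP electrostatic coupling constant (kcal/mol when distances are in A)
_COUPLING = 0.084 * 332.0


@dataclass
class HBond:
    donor: tuple    # residue key of the N-H residue
    acceptor: tuple  # residue key of the C=O residue
    energy: float   # kcal/mol


@dataclass
class ResidueFeatures:
    key: tuple
    name: str
    asa: float = 0.0
    rsa: float | None = None
    burial_class: str = "UNKNOWN"
    secondary_structure: str = "C"
    hbonds: list = field(default_factory=list)  # (partner key, role, energy)
    disulfide_partner: tuple | None = None
    salt_bridge_partners: list = field(default_factory=list)
    ligand_contacts: list = field(default_factory=list)  # (het name, min distance)
    neighbor_count: int = 0


@dataclass
class StructuralFeatureSet:
    per_residue: dict  # residue key -> ResidueFeatures
    hbonds: list       # all accepted backbone HBond records
    warnings: list = field(default_factory=list)

    def get(self, key: tuple) -> ResidueFeatures | None:
        return self.per_residue.get(key)


# ---------------------------------------------------------------------------
# accessible surface area


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic spiral (Fibonacci) lattice of n points on the unit sphere."""
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    theta = math.pi * (3.0 - math.sqrt(5.0)) * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def compute_asa(
    structure: Structure,
    probe_radius: float = 1.4,
    n_points: int = 960,
    config: RunConfig | None = None,
) -> tuple[dict, dict]:
    """Shrake-Rupley accessible surface area.

    Returns ``(per_atom, per_residue)`` dictionaries in square Angstrom;
    per-residue values sum the residue's heavy atoms.  Hydrogens and waters
    are excluded entirely.  Deterministic for a fixed lattice size.
    """
    cfg = config or RunConfig()
    if probe_radius <= 0:
        raise ValueError("probe radius must be positive")
    atoms = [a for a in structure.atoms if not a.is_hydrogen and not a.is_water]
    if not atoms:
        raise ValueError("structure has no heavy atoms")
    coords = np.array([[a.x, a.y, a.z] for a in atoms])
    radii = np.array(
        [cfg.vdw_radii.get(a.element, cfg.vdw_default) + probe_radius for a in atoms]
    )
    unit = _sphere_points(n_points)
    per_atom: dict[int, float] = {}
    n_atoms = len(atoms)
    for i in range(n_atoms):
        ri = radii[i]
        pts = coords[i] + ri * unit
        d = np.linalg.norm(coords[i] - coords, axis=1)
        neigh = np.where((d < ri + radii) & (np.arange(n_atoms) != i))[0]
        accessible = np.ones(n_points, dtype=bool)
        for j in neigh:
            dj = np.linalg.norm(pts - coords[j], axis=1)
            accessible &= dj >= radii[j]
        frac = accessible.sum() / n_points
        per_atom[atoms[i].serial] = 4.0 * math.pi * ri * ri * frac
    per_residue: dict[tuple, float] = {}
    for r in structure.residues:
        if r.is_hetero:
            continue
        per_residue[r.key] = sum(
            per_atom.get(a.serial, 0.0) for a in r.heavy_atoms()
        )
    return per_atom, per_residue


def _load_max_asa(path: str) -> dict:
    table = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            code, val = line.split("\t")
            table[code] = float(val)
    return table


def compute_rsa(
    per_residue_asa: dict,
    residues: list,
    config: RunConfig | None = None,
) -> dict:
    """Relative accessibility and burial class per residue key.

    RSA = ASA / max-ASA(residue type), capped; burial classes follow the
    configured thresholds (default: BURIED < 0.07 <= PARTIALLY_BURIED <
    0.25 <= EXPOSED).  Residue types missing from the reference table get
    class UNKNOWN with undefined RSA.
    """
    cfg = config or RunConfig()
    max_asa = _load_max_asa(cfg.max_asa_table)
    out: dict[tuple, tuple] = {}
    for r in residues:
        asa = per_residue_asa.get(r.key)
        if asa is None:
            continue
        code = r.one_letter
        if code not in max_asa:
            out[r.key] = (None, "UNKNOWN")
            continue
        rsa = min(asa / max_asa[code], cfg.rsa_cap)
        if rsa < cfg.buried_rsa:
            cls = "BURIED"
        elif rsa < cfg.exposed_rsa:
            cls = "PARTIALLY_BURIED"
        else:
            cls = "EXPOSED"
        out[r.key] = (rsa, cls)
    return out


# ---------------------------------------------------------------------------
# backbone hydrogen bonds (DSSP energy model)


def _amide_h(residue: Residue, prev: Residue, length: float) -> np.ndarray | None:
    """Place the amide hydrogen on N, opposite the bisector of its bonds.

    Uses the previous residue's carbonyl C and the residue's own CA: H sits
    ``length`` Angstrom from N along the direction opposite the bisector of
    N->C(prev) and N->CA.
    """
    n = residue.atom("N")
    ca = residue.atom("CA")
    c_prev = prev.atom("C")
    if n is None or ca is None or c_prev is None:
        return None
    v1 = c_prev.coord - n.coord
    v2 = ca.coord - n.coord
    v1 /= np.linalg.norm(v1)
    v2 /= np.linalg.norm(v2)
    bis = v1 + v2
    norm = np.linalg.norm(bis)
    if norm < 1e-6:
        return None
    return n.coord - length * bis / norm


def detect_hbonds(
    structure: Structure, config: RunConfig | None = None
) -> tuple[list, list]:
    """Backbone N-H...O=C hydrogen bonds under the DSSP electrostatic model.

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN) kcal/mol, bond
    accepted when E < cutoff (default -0.5).  Prolines and chain-initial
    residues cannot donate (no amide H).  Returns ``(bonds, warnings)``.
    """
    cfg = config or RunConfig()
    bonds: list[HBond] = []
    warnings: list[str] = []
    residues = structure.polymer_residues()
    usable: list = []
    for r in residues:
        if any(r.atom(nm) is None for nm in ("N", "CA", "C", "O")):
            warnings.append(
                f"residue {r.chain}{r.number}{r.insertion_code.strip()} skipped: "
                "incomplete backbone"
            )
            usable.append(None)
        else:
            usable.append(r)
    n_res = len(residues)
    for di in range(n_res):
        donor = usable[di]
        if donor is None or donor.name == "PRO":
            continue
        # the amide H needs the preceding residue of the same chain
        prev = usable[di - 1] if di > 0 else None
        if prev is None or prev.chain != donor.chain:
            continue
        h = _amide_h(donor, prev, cfg.amide_h_length)
        if h is None:
            continue
        n_xyz = donor.atom("N").coord
        for ai in range(n_res):
            acc = usable[ai]
            if acc is None:
                continue
            if acc.chain == donor.chain and abs(ai - di) < 2:
                continue
            o_xyz = acc.atom("O").coord
            c_xyz = acc.atom("C").coord
            r_on = np.linalg.norm(o_xyz - n_xyz)
            if r_on > 5.2:  # beyond any plausible H-bond
                continue
            r_ch = np.linalg.norm(c_xyz - h)
            r_oh = np.linalg.norm(o_xyz - h)
            r_cn = np.linalg.norm(c_xyz - n_xyz)
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                continue
            e = _COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
            if e < cfg.hbond_energy_cutoff:
                bonds.append(HBond(donor=donor.key, acceptor=acc.key, energy=e))
    return bonds, warnings


# ---------------------------------------------------------------------------
# secondary structure (simplified DSSP: H, E, C)


def assign_secondary_structure(
    hbonds: list, structure: Structure
) -> dict:
    """Assign H (helix), E (strand) or C (coil) per residue key.

    Helix: two consecutive i+4 -> i turns mark residues i+1..i+4 (minimal
    helix rule).  Strand: residues in parallel or antiparallel bridges
    (paired backbone bonds).  Helix wins where both apply; everything else
    is coil.  No 3-10/pi/turn/bend subclasses.
    """
    residues = structure.polymer_residues()
    index = {r.key: i for i, r in enumerate(residues)}
    n = len(residues)
    hb = set()
    for b in hbonds:
        di = index.get(b.donor)
        ai = index.get(b.acceptor)
        if di is not None and ai is not None:
            hb.add((di, ai))

    def same_chain(i: int, j: int) -> bool:
        return residues[i].chain == residues[j].chain

    assigned = ["C"] * n
    # strand bridges (within or across chains)
    for i in range(n):
        for j in range(n):
            if same_chain(i, j) and abs(i - j) < 3:
                continue
            anti = ((i, j) in hb and (j, i) in hb) or (
                (i - 1, j + 1) in hb and (j - 1, i + 1) in hb
            )
            par = ((i - 1, j) in hb and (j, i + 1) in hb) or (
                (j - 1, i) in hb and (i, j + 1) in hb
            )
            if anti or par:
                assigned[i] = "E"
    # helices override strands; turns are strictly intra-chain
    turn = [
        (i + 4, i) in hb and i + 4 < n and same_chain(i, i + 4)
        for i in range(n)
    ]
    for i in range(n - 1):
        if turn[i] and turn[i + 1]:
            for k in range(i + 1, min(i + 5, n)):
                assigned[k] = "H"
    return {r.key: s for r, s in zip(residues, assigned)}


# ---------------------------------------------------------------------------
# contacts


def detect_disulfides(structure: Structure, config: RunConfig | None = None) -> list:
    """Cysteine SG-SG pairs within the cutoff; closest pairing wins."""
    cfg = config or RunConfig()
    sgs = []
    for r in structure.polymer_residues():
        if r.name == "CYS":
            sg = r.atom("SG")
            if sg is not None:
                sgs.append((r.key, sg.coord))
    candidates = []
    for i in range(len(sgs)):
        for j in range(i + 1, len(sgs)):
            d = float(np.linalg.norm(sgs[i][1] - sgs[j][1]))
            if d <= cfg.disulfide_cutoff:
                candidates.append((d, sgs[i][0], sgs[j][0]))
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    used: set = set()
    pairs = []
    for d, k1, k2 in candidates:
        if k1 in used or k2 in used:
            continue
        used.update((k1, k2))
        pairs.append((k1, k2, d))
    return pairs


def detect_salt_bridges(structure: Structure, config: RunConfig | None = None) -> list:
    """Acidic-carboxyl to basic-nitrogen contacts within the cutoff."""
    cfg = config or RunConfig()
    acidic, basic = [], []
    for r in structure.polymer_residues():
        if r.name in _ACIDIC:
            for nm in _ACIDIC[r.name]:
                a = r.atom(nm)
                if a is not None:
                    acidic.append((r.key, a.coord))
        if r.name in _BASIC:
            for nm in _BASIC[r.name]:
                a = r.atom(nm)
                if a is not None:
                    basic.append((r.key, a.coord))
    seen = set()
    bridges = []
    for ka, ca in acidic:
        for kb, cb in basic:
            if ka == kb:
                continue
            d = float(np.linalg.norm(ca - cb))
            if d <= cfg.salt_bridge_cutoff:
                pair = (ka, kb)
                if pair not in seen:
                    seen.add(pair)
                    bridges.append((ka, kb, d))
                else:
                    for idx, (pka, pkb, pd) in enumerate(bridges):
                        if (pka, pkb) == pair and d < pd:
                            bridges[idx] = (pka, pkb, d)
    return bridges


def detect_ligand_contacts(structure: Structure, config: RunConfig | None = None) -> dict:
    """Per-residue contacts with non-water hetero entities.

    Returns residue key -> list of ``(het name, min distance, is_ion)``.
    """
    cfg = config or RunConfig()
    het_groups: dict[tuple, list] = {}
    for r in structure.hetero_residues():
        if r.name in ("HOH", "WAT", "DOD"):
            continue
        het_groups[(r.name, r.chain, r.number)] = [
            a.coord for a in r.heavy_atoms()
        ]
    out: dict[tuple, list] = {}
    for r in structure.polymer_residues():
        contacts = []
        rcoords = [a.coord for a in r.heavy_atoms()]
        for (het_name, _, _), hcoords in het_groups.items():
            dmin = min(
                (float(np.linalg.norm(rc - hc)) for rc in rcoords for hc in hcoords),
                default=math.inf,
            )
            if dmin <= cfg.ligand_contact_cutoff:
                contacts.append((het_name, dmin, het_name in _METALS))
        if contacts:
            out[r.key] = sorted(contacts, key=lambda c: c[1])
    return out


def packing_density(
    structure: Structure, residue_key: tuple, config: RunConfig | None = None
) -> int:
    """Heavy atoms of *other* residues within the packing radius of the
    residue's side-chain centroid (CA for glycine)."""
    cfg = config or RunConfig()
    target = None
    for r in structure.residues:
        if r.key == residue_key and not r.is_hetero:
            target = r
            break
    if target is None:
        raise KeyError(f"residue {residue_key} not in structure")
    side = [a.coord for a in target.heavy_atoms() if a.name not in _BACKBONE]
    if not side:
        ca = target.atom("CA")
        if ca is None:
            return 0
        side = [ca.coord]
    centroid = np.mean(side, axis=0)
    count = 0
    for r in structure.residues:
        if r.key == residue_key and r.is_hetero == target.is_hetero:
            continue
        for a in r.heavy_atoms():
            if a.is_water:
                continue
            if float(np.linalg.norm(a.coord - centroid)) <= cfg.packing_radius:
                count += 1
    return count


# ---------------------------------------------------------------------------
# orchestration


def compute_features(
    structure: Structure, config: RunConfig | None = None
) -> StructuralFeatureSet:
    """Run every structural calculation and collate per-residue results."""
    cfg = config or RunConfig()
    _, per_res_asa = compute_asa(structure, cfg.probe_radius, cfg.asa_points, cfg)
    residues = structure.polymer_residues()
    rsa = compute_rsa(per_res_asa, residues, cfg)
    bonds, warnings = detect_hbonds(structure, cfg)
    ss = assign_secondary_structure(bonds, structure)
    disulfides = detect_disulfides(structure, cfg)
    bridges = detect_salt_bridges(structure, cfg)
    ligands = detect_ligand_contacts(structure, cfg)

    per: dict[tuple, ResidueFeatures] = {}
    for r in residues:
        f = ResidueFeatures(key=r.key, name=r.name)
        f.asa = per_res_asa.get(r.key, 0.0)
        f.rsa, f.burial_class = rsa.get(r.key, (None, "UNKNOWN"))
        f.secondary_structure = ss.get(r.key, "C")
        f.ligand_contacts = [(n, d) for n, d, _ in ligands.get(r.key, [])]
        f.neighbor_count = packing_density(structure, r.key, cfg)
        per[r.key] = f
    for b in bonds:
        if b.donor in per:
            per[b.donor].hbonds.append((b.acceptor, "donor", b.energy))
        if b.acceptor in per:
            per[b.acceptor].hbonds.append((b.donor, "acceptor", b.energy))
    for k1, k2, _ in disulfides:
        per[k1].disulfide_partner = k2
        per[k2].disulfide_partner = k1
    for ka, kb, _ in bridges:
        if kb not in per[ka].salt_bridge_partners:
            per[ka].salt_bridge_partners.append(kb)
        if ka not in per[kb].salt_bridge_partners:
            per[kb].salt_bridge_partners.append(ka)
    # mark ION contacts distinctly in ligand lists
    for key, lst in ligands.items():
        per[key].ligand_contacts = [
            (("ION:" + n) if is_ion else n, d) for n, d, is_ion in lst
        ]
    return StructuralFeatureSet(per_residue=per, hbonds=bonds, warnings=warnings)


def _fmt_key(key: tuple) -> str:
    chain, num, icode = key
    return f"{chain}{num}{icode.strip()}"


def to_feature_records(
    features: StructuralFeatureSet,
    structure: Structure,
    mapping,
    seq_id: str,
) -> tuple[list, list]:
    """Re-number structure-derived features onto the submitted sequence.

    ``mapping`` maps the structure's sequential polymer index (1-based) to
    submitted-sequence positions.  Returns ``(records, warnings)``; records
    carry source tier STRUCTURE.  Residues that do not map are dropped with
    a warning.
    """
    from mutexplain.residue_mapping import map_position

    residues = structure.polymer_residues()
    seq_index = {r.key: i + 1 for i, r in enumerate(residues)}

    def to_seq(key: tuple):
        idx = seq_index.get(key)
        if idx is None:
            return None
        return map_position(mapping, idx)

    records: list[FeatureRecord] = []
    warnings: list[str] = []

    def warn_unmapped(key):
        warnings.append(
            f"structure residue {_fmt_key(key)} is not mappable onto the "
            "submitted sequence; derived features dropped"
        )

    seen_pairs = set()
    for key, f in features.per_residue.items():
        pos = to_seq(key)
        if pos is None:
            warn_unmapped(key)
            continue
        records.append(
            FeatureRecord(
                seq_id=seq_id, source_tier="STRUCTURE", category="VARIABLE",
                feature_type="ACCESSIBILITY", begin=pos, end=pos,
                value=round(f.rsa, 4) if f.rsa is not None else 0.0,
                description=f"burial class {f.burial_class}",
            )
        )
        records.append(
            FeatureRecord(
                seq_id=seq_id, source_tier="STRUCTURE", category="VARIABLE",
                feature_type="PACKING", begin=pos, end=pos,
                value=float(f.neighbor_count),
                description="heavy-atom neighbours of the side-chain centroid",
            )
        )
        if f.disulfide_partner is not None:
            ppos = to_seq(f.disulfide_partner)
            pair = tuple(sorted((pos, ppos))) if ppos else (pos,)
            records.append(
                FeatureRecord(
                    seq_id=seq_id, source_tier="STRUCTURE", category="CONTACT",
                    feature_type="DISULFID", begin=pos, end=pos,
                    partner=str(ppos) if ppos is not None else None,
                    description="disulfide bridge",
                )
            )
            seen_pairs.add(pair)
        for pkey in f.salt_bridge_partners:
            ppos = to_seq(pkey)
            records.append(
                FeatureRecord(
                    seq_id=seq_id, source_tier="STRUCTURE", category="CONTACT",
                    feature_type="SALT_BRIDGE", begin=pos, end=pos,
                    partner=str(ppos) if ppos is not None else None,
                    description="salt bridge",
                )
            )
        for name, dist in f.ligand_contacts:
            is_ion = name.startswith("ION:")
            records.append(
                FeatureRecord(
                    seq_id=seq_id, source_tier="STRUCTURE", category="CONTACT",
                    feature_type="METAL_CONTACT" if is_ion else "LIGAND_CONTACT",
                    begin=pos, end=pos, partner=name.removeprefix("ION:"),
                    description=f"contact at {dist:.2f} A",
                )
            )
        for pkey, role, energy in f.hbonds:
            ppos = to_seq(pkey)
            records.append(
                FeatureRecord(
                    seq_id=seq_id, source_tier="STRUCTURE", category="CONTACT",
                    feature_type="HBOND", begin=pos, end=pos,
                    partner=str(ppos) if ppos is not None else None,
                    description=f"backbone hydrogen bond ({role}, "
                                f"{energy:.2f} kcal/mol)",
                )
            )
    # run-length encode secondary structure onto the sequence
    ss_by_pos: dict[int, str] = {}
    for key, f in features.per_residue.items():
        pos = to_seq(key)
        if pos is not None:
            ss_by_pos[pos] = f.secondary_structure
    for ss_type, label in (("H", "alpha-helix"), ("E", "beta-strand")):
        run_start = run_end = None
        for pos in sorted(ss_by_pos):
            if ss_by_pos[pos] == ss_type:
                if run_end is not None and pos == run_end + 1:
                    run_end = pos
                else:
                    if run_start is not None:
                        records.append(_ss_record(seq_id, run_start, run_end, label))
                    run_start = run_end = pos
            elif run_start is not None:
                records.append(_ss_record(seq_id, run_start, run_end, label))
                run_start = run_end = None
        if run_start is not None:
            records.append(_ss_record(seq_id, run_start, run_end, label))
    records.sort(key=lambda r: (r.begin, r.category, r.feature_type, str(r.partner)))
    return records, warnings


def _ss_record(seq_id: str, begin: int, end: int, label: str) -> FeatureRecord:
    return FeatureRecord(
        seq_id=seq_id, source_tier="STRUCTURE", category="FIXED",
        feature_type="SECONDARY_STRUCTURE", begin=begin, end=end,
        description=label,
    )
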