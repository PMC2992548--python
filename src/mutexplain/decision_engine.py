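"""The six-branch decision scheme.

Each branch examines one aspect of the mutated residue and contributes a
paragraph to the report:

1. CONTACTS — interactions with other molecules or atoms (ligands, metals,
   hydrogen bonds, disulfide bridges, ionic interactions);
2. DOMAIN — named structural locations (domains, motifs, transmembrane
   segments, secondary-structure elements);
3. MODIFICATION — post-translational processing such as phosphorylation;
4. VARIANT — variation already known at the position;
5. CONSERVATION — the residue's column in a multiple sequence alignment;
6. PROPERTIES — the biophysical differences between wild-type and mutant
   (size, charge, hydrophobicity), the always-available fallback.

The rule inventory is declarative (``data/rules.yaml``): a rule fires when
all its predicates hold, with a base severity that is downgraded one step
when the best available evidence is prediction-only.  Phrasing lives in a
separate template catalogue so logic and language stay apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import yaml

from mutexplain.aa_knowledge import (
    ONE_TO_THREE,
    compare_residues,
    get_properties,
    special_flags_for_context,
)
from mutexplain.annotation_store import AnnotationStore, resolve
from mutexplain.config import RunConfig
from mutexplain.conservation import ConservationVerdict

BRANCHES = ("CONTACTS", "DOMAIN", "MODIFICATION", "VARIANT", "CONSERVATION", "PROPERTIES")
SEVERITIES = ("INFO", "MODERATE", "SEVERE")
_SEV_RANK = {s: i for i, s in enumerate(SEVERITIES)}

#: side chains able to donate or accept a hydrogen bond
_POLAR = set("STYNQHKRDEWC")

#: feature types examined per aspect
_CONTACT_TYPES = ("DISULFID", "SALT_BRIDGE", "METAL_CONTACT", "LIGAND_CONTACT", "HBOND")
_REGION_TYPES = ("DOMAIN", "REGION", "MOTIF", "REPEAT", "ZN_FING", "TRANSMEM")
_SITE_TYPES = ("ACT_SITE", "SITE", "BINDING", "MOTIF")
_MODIFICATION_TYPES = ("PHOSPHO_SITE", "MOD_RES")
_VARIANT_TYPES = ("VARIANT", "MUTAGEN", "SPLICE_VARIANT")


class InputError(ValueError):
    """Invalid user input (as opposed to an internal failure)."""


@dataclass
class MutationRequest:
    seq_id: str
    position: int  # 1-based
    wild_type: str
    mutant: str

    def validate(self, sequence: str) -> None:
        get_properties(self.wild_type)
        get_properties(self.mutant)
        if self.wild_type == self.mutant:
            raise InputError("wild-type and mutant residue are identical")
        if not 1 <= self.position <= len(sequence):
            raise InputError(
                f"position {self.position} outside sequence 1..{len(sequence)}"
            )
        found = sequence[self.position - 1]
        if found != self.wild_type:
            raise InputError(
                f"sequence conflict at position {self.position}: expected "
                f"wild-type {self.wild_type}, sequence has {found}"
            )


@dataclass
class Finding:
    branch: str
    severity: str
    rule_id: str
    sentence_key: str
    rendered_text: str
    evidence: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "branch": self.branch,
            "severity": self.severity,
            "rule_id": self.rule_id,
            "sentence_key": self.sentence_key,
            "rendered_text": self.rendered_text,
            "evidence": self.evidence,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Finding":
        return cls(
            branch=d["branch"], severity=d["severity"], rule_id=d["rule_id"],
            sentence_key=d["sentence_key"], rendered_text=d["rendered_text"],
            evidence=d["evidence"],
        )


@lru_cache(maxsize=1)
def load_rules() -> tuple:
    text = resources.files("mutexplain").joinpath("data", "rules.yaml").read_text()
    rules = yaml.safe_load(text)
    for r in rules:
        if r["branch"] not in BRANCHES or r["severity"] not in SEVERITIES:
            raise ValueError(f"malformed rule {r.get('id')}")
    return tuple(tuple(sorted(r.items())) for r in rules)  # hashable snapshot


def _rules() -> list[dict]:
    return [dict(r) for r in load_rules()]


@lru_cache(maxsize=1)
def load_sentences() -> dict:
    text = resources.files("mutexplain").joinpath("data", "sentences.yaml").read_text()
    return yaml.safe_load(text)


def _record_evidence(rec) -> dict:
    return {
        "kind": "record",
        "tier": rec.source_tier,
        "category": rec.category,
        "feature_type": rec.feature_type,
        "begin": rec.begin,
        "end": rec.end,
        "value": rec.value,
        "partner": rec.partner,
        "description": rec.description,
    }


def _computed_evidence(name: str, value) -> dict:
    return {"kind": "computed", "name": name, "value": value}


def _downgrade(severity: str) -> str:
    idx = max(_SEV_RANK[severity] - 1, 0)
    return SEVERITIES[idx]


def _change_summary(delta, cfg: RunConfig) -> str:
    parts = []
    if abs(delta.d_volume) >= cfg.volume_threshold:
        parts.append(f"the mutant is {delta.direction_labels['size']} "
                     f"({delta.d_volume:+.1f} cubic Angstrom)")
    if abs(delta.d_hydrophobicity) >= cfg.hydrophobicity_threshold:
        parts.append(f"the mutant is {delta.direction_labels['hydrophobicity']} "
                     f"({delta.d_hydrophobicity:+.1f})")
    if delta.d_charge != 0:
        parts.append(delta.direction_labels["charge"])
    return "; ".join(parts) if parts else "no major property differences"


class _Context:
    """Predicate values plus the evidence behind each, for one request."""

    def __init__(self):
        self.flags: dict[str, bool] = {}
        self.evidence: dict[str, list] = {}
        self.prediction_only: dict[str, bool] = {}

    def set(self, name: str, value: bool, evidence=None, prediction_only=False):
        self.flags[name] = value
        self.evidence[name] = evidence or []
        self.prediction_only[name] = prediction_only


def build_context(
    request: MutationRequest,
    annotation,
    verdict: ConservationVerdict | None,
    cfg: RunConfig,
) -> tuple[_Context, dict]:
    """Evaluate every predicate the rule catalogue can reference.

    Returns the context plus the substitution dictionary used to render
    sentences.
    """
    ctx = _Context()
    delta = compare_residues(request.wild_type, request.mutant, cfg.aa_table)
    flags = special_flags_for_context(request.mutant, request.wild_type, cfg.aa_table)
    wild_props = get_properties(request.wild_type, cfg.aa_table)
    mut_props = get_properties(request.mutant, cfg.aa_table)

    def res(ftype):
        return resolve(annotation, ftype)

    # ---- contacts -------------------------------------------------------
    disulf = res("DISULFID")
    ctx.set("at_disulfide", bool(disulf.best),
            [_record_evidence(r) for r in disulf.best], disulf.prediction_only)
    ctx.set("wild_is_cys", request.wild_type == "C")
    ctx.set("mutant_not_cys", request.mutant != "C")
    salt = res("SALT_BRIDGE")
    ctx.set("at_salt_bridge", bool(salt.best),
            [_record_evidence(r) for r in salt.best], salt.prediction_only)
    charge_lost_or_flipped = delta.d_charge != 0 and wild_props.charge != 0
    ctx.set("charge_lost_or_flipped", charge_lost_or_flipped,
            [_computed_evidence("d_charge", delta.d_charge)])
    metal = res("METAL_CONTACT")
    lig = res("LIGAND_CONTACT")
    lig_best = metal.best + lig.best
    ctx.set("at_ligand_contact", bool(lig_best),
            [_record_evidence(r) for r in lig_best],
            metal.prediction_only and lig.prediction_only)
    size_or_charge = abs(delta.d_volume) >= cfg.volume_threshold or delta.d_charge != 0
    ctx.set("size_or_charge_change", size_or_charge,
            [_computed_evidence("d_volume", delta.d_volume),
             _computed_evidence("d_charge", delta.d_charge)])
    hb = res("HBOND")
    # backbone bonds survive any substitution; only side-chain-mediated
    # hydrogen bonds are at risk from the mutation
    hb_side = [r for r in hb.best
               if "backbone" not in (r.description or "").lower()]
    ctx.set("at_hbond", bool(hb_side),
            [_record_evidence(r) for r in hb_side], hb.prediction_only)
    ctx.set("polar_capacity_lost",
            request.wild_type in _POLAR and request.mutant not in _POLAR)

    # ---- domain ---------------------------------------------------------
    tm = res("TRANSMEM")
    ctx.set("in_transmem", bool(tm.best),
            [_record_evidence(r) for r in tm.best], tm.prediction_only)
    charge_gained = mut_props.charge != 0 and mut_props.charge != wild_props.charge
    ctx.set("charge_gained", charge_gained,
            [_computed_evidence("d_charge", delta.d_charge)])
    ctx.set("hydrophobicity_changed",
            abs(delta.d_hydrophobicity) >= cfg.hydrophobicity_threshold,
            [_computed_evidence("d_hydrophobicity", delta.d_hydrophobicity)])
    site_recs, site_pred = [], True
    for ftype in _SITE_TYPES:
        r = res(ftype)
        site_recs += r.best
        if r.best:
            site_pred = site_pred and r.prediction_only
    ctx.set("in_active_site", bool(site_recs),
            [_record_evidence(r) for r in site_recs],
            site_pred if site_recs else False)

    ss = res("SECONDARY_STRUCTURE")
    helix_recs = [r for r in ss.best
                  if "helix" in f"{r.description} {r.value}".lower()]
    strand_recs = [r for r in ss.best
                   if "strand" in f"{r.description} {r.value}".lower()
                   or "beta" in f"{r.description} {r.value}".lower()]
    ctx.set("in_helix", bool(helix_recs),
            [_record_evidence(r) for r in helix_recs], ss.prediction_only)
    ctx.set("in_strand", bool(strand_recs),
            [_record_evidence(r) for r in strand_recs], ss.prediction_only)
    ctx.set("helix_breaker_gained", flags.get("HELIX_BREAKER") == "gained",
            [_computed_evidence("HELIX_BREAKER", "gained")])
    ctx.set("mutant_is_proline", request.mutant == "P")
    region_recs, region_pred = [], True
    for ftype in _REGION_TYPES:
        if ftype == "TRANSMEM":
            continue  # handled by the membrane-specific rules
        r = res(ftype)
        region_recs += r.best
        if r.best:
            region_pred = region_pred and r.prediction_only
    ctx.set("in_named_region", bool(region_recs),
            [_record_evidence(r) for r in region_recs],
            region_pred if region_recs else False)

    # ---- modification ---------------------------------------------------
    mod_recs, mod_pred = [], True
    for ftype in _MODIFICATION_TYPES:
        r = res(ftype)
        mod_recs += r.best
        if r.best:
            mod_pred = mod_pred and r.prediction_only
    ctx.set("at_phospho_site", bool(mod_recs),
            [_record_evidence(r) for r in mod_recs],
            mod_pred if mod_recs else False)
    acceptor = flags.get("PHOSPHO_ACCEPTOR")
    ctx.set("phospho_acceptor_lost", acceptor == "lost")
    ctx.set("phospho_acceptor_kept", acceptor == "retained")

    # ---- variants -------------------------------------------------------
    var_recs = []
    for ftype in _VARIANT_TYPES:
        var_recs += res(ftype).best
    exact = [r for r in var_recs
             if r.partner is not None and r.partner.upper() == request.mutant]
    other = [r for r in var_recs if r not in exact]
    ctx.set("variant_exact_match", bool(exact), [_record_evidence(r) for r in exact])
    ctx.set("variant_other", bool(other), [_record_evidence(r) for r in other])

    # ---- conservation ---------------------------------------------------
    v = verdict or ConservationVerdict(verdict="NO_DATA")
    cons_ev = [_computed_evidence("conservation_verdict", v.verdict),
               _computed_evidence("wild_frequency", v.wild_frequency),
               _computed_evidence("mutant_frequency", v.mutant_frequency)]
    ctx.set("cons_strict_and_unseen",
            v.verdict in ("INVARIANT", "HIGHLY_CONSERVED") and not v.mutant_observed,
            cons_ev)
    ctx.set("cons_moderate",
            v.verdict == "CONSERVED"
            or (v.verdict == "HIGHLY_CONSERVED" and v.mutant_observed),
            cons_ev)
    ctx.set("cons_variable_seen", v.verdict == "VARIABLE" and v.mutant_observed,
            cons_ev)

    # ---- properties -----------------------------------------------------
    acc = res("ACCESSIBILITY")
    rsa_value = None
    if acc.best:
        vals = [r.value for r in acc.best if isinstance(r.value, float)]
        if vals:
            rsa_value = min(vals)
    buried = rsa_value is not None and rsa_value < cfg.buried_rsa
    exposed = rsa_value is not None and rsa_value >= cfg.exposed_rsa
    acc_ev = [_record_evidence(r) for r in acc.best]
    ctx.set("is_buried", buried, acc_ev, acc.prediction_only)
    ctx.set("is_exposed", exposed, acc_ev, acc.prediction_only)
    ctx.set("hydrophobicity_decreased",
            delta.d_hydrophobicity <= -cfg.hydrophobicity_threshold,
            [_computed_evidence("d_hydrophobicity", delta.d_hydrophobicity)])
    ctx.set("volume_increased", delta.d_volume >= cfg.volume_threshold,
            [_computed_evidence("d_volume", delta.d_volume)])
    pack = res("PACKING")
    pack_val = None
    if pack.best:
        vals = [r.value for r in pack.best if isinstance(r.value, float)]
        if vals:
            pack_val = max(vals)
    ctx.set("densely_packed",
            pack_val is not None and pack_val >= cfg.packing_dense_threshold,
            [_record_evidence(r) for r in pack.best], pack.prediction_only)
    ctx.set("any_significant_change",
            size_or_charge
            or abs(delta.d_hydrophobicity) >= cfg.hydrophobicity_threshold,
            [_computed_evidence("d_volume", delta.d_volume),
             _computed_evidence("d_hydrophobicity", delta.d_hydrophobicity),
             _computed_evidence("d_charge", delta.d_charge)])

    # ---- sentence substitutions ----------------------------------------
    summary = _change_summary(delta, cfg)
    change_sentence_bits = []
    if delta.d_volume != 0:
        change_sentence_bits.append(
            f"The mutant residue is {delta.direction_labels['size']} than the "
            f"wild-type residue ({delta.d_volume:+.1f} cubic Angstrom)."
        )
    if delta.d_hydrophobicity != 0:
        change_sentence_bits.append(
            f"The mutant residue is {delta.direction_labels['hydrophobicity']} "
            f"({delta.d_hydrophobicity:+.1f} on the hydrophobicity scale)."
        )
    if delta.d_charge != 0:
        change_sentence_bits.append(
            f"The substitution changes the formal charge "
            f"({delta.direction_labels['charge']}: {wild_props.charge:+d} to "
            f"{mut_props.charge:+d})."
        )
    if not change_sentence_bits:
        change_sentence_bits.append(
            "The two residues have very similar size, charge and hydrophobicity."
        )

    def detail(records, fallback):
        descs = sorted({r.description for r in records if r.description})
        return "; ".join(descs) if descs else fallback

    subs = {
        "wild": request.wild_type,
        "mutant": request.mutant,
        "wild_name": wild_props.name,
        "mutant_name": mut_props.name,
        "wild_three": ONE_TO_THREE[request.wild_type],
        "mutant_three": ONE_TO_THREE[request.mutant],
        "position": request.position,
        "d_volume": delta.d_volume,
        "d_hydrophobicity": delta.d_hydrophobicity,
        "d_charge": delta.d_charge,
        "charge_label": delta.direction_labels["charge"],
        "hydrophobicity_label": delta.direction_labels["hydrophobicity"],
        "size_label": delta.direction_labels["size"],
        "change_summary": summary,
        "change_sentence": " ".join(change_sentence_bits),
        "disulfide_detail": detail(disulf.best, "with a partner cysteine"),
        "salt_bridge_detail": detail(salt.best, "ionic interaction"),
        "ligand_names": ", ".join(
            sorted({r.partner or r.description or r.feature_type for r in lig_best})
        ) or "a bound ligand",
        "region_detail": detail(tm.best + site_recs + region_recs, "annotated region"),
        "variant_detail": detail(exact + other, "previously reported variation"),
        "conservation_word": "invariant" if v.verdict == "INVARIANT" else "highly conserved",
        "wild_freq_pct": (
            f"{100 * v.wild_frequency:.0f}" if v.wild_frequency is not None else "?"
        ),
        "mutant_freq_pct": (
            f"{100 * v.mutant_frequency:.0f}" if v.mutant_frequency is not None else "?"
        ),
    }
    return ctx, subs


def _branch_findings(branch: str, ctx: _Context, subs: dict) -> list[Finding]:
    sentences = load_sentences()
    findings: list[Finding] = []
    fired = False
    fallback_rule = None
    for rule in _rules():
        if rule["branch"] != branch:
            continue
        if rule.get("fallback"):
            fallback_rule = rule
            continue
        if all(ctx.flags.get(p, False) for p in rule["when"]):
            evidence = []
            prediction_only = False
            has_records = False
            for p in rule["when"]:
                evidence.extend(ctx.evidence.get(p, []))
                if any(e.get("kind") == "record" for e in ctx.evidence.get(p, [])):
                    has_records = True
                    prediction_only = prediction_only or ctx.prediction_only.get(p, False)
            severity = rule["severity"]
            if rule.get("tier_sensitive") and has_records and prediction_only:
                severity = _downgrade(severity)
            findings.append(
                Finding(
                    branch=branch,
                    severity=severity,
                    rule_id=rule["id"],
                    sentence_key=rule["sentence"],
                    rendered_text=sentences[rule["sentence"]].format(**subs),
                    evidence=evidence,
                )
            )
            fired = True
    if not fired and fallback_rule is not None:
        findings.append(
            Finding(
                branch=branch,
                severity=fallback_rule["severity"],
                rule_id=fallback_rule["id"],
                sentence_key=fallback_rule["sentence"],
                rendered_text=sentences[fallback_rule["sentence"]].format(**subs),
                evidence=[_computed_evidence("property_comparison", subs["change_summary"])],
            )
        )
    findings.sort(key=lambda f: (-_SEV_RANK[f.severity], f.sentence_key, f.rule_id))
    return findings


def run_scheme(
    request: MutationRequest,
    store: AnnotationStore,
    verdict: ConservationVerdict | None = None,
    config: RunConfig | None = None,
) -> list[Finding]:
    """Run all six branches in their fixed order and collect findings.

    Deterministic for identical inputs.  Every branch may stay silent
    except PROPERTIES, which always contributes at least one finding.
    """
    cfg = config or RunConfig()
    request.validate(store.sequence)
    annotation = store.query_residue(request.position)
    ctx, subs = build_context(request, annotation, verdict, cfg)
    findings: list[Finding] = []
    for branch in BRANCHES:
        findings.extend(_branch_findings(branch, ctx, subs))
    return findings
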