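"""Assemble and render the mutation report (Markdown and JSON).

The report is a single self-contained document: a provenance header
stating which method the analysis is based on (deposited structure,
homology model — possibly with a low-identity warning — or sequence only)
and every pinned parameter; then six fixed-order aspect sections, one per
decision-scheme branch, each holding that branch's findings or an explicit
"no information" line; then accumulated warnings and a glossary of the
technical terms the text used.  Terms are linked at their first occurrence
only, longest match first, case-insensitively.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

from mutexplain.decision_engine import BRANCHES, SEVERITIES, Finding

SECTION_TITLES = {
    "CONTACTS": "Contacts",
    "DOMAIN": "Structural domain",
    "MODIFICATION": "Modifications",
    "VARIANT": "Variants",
    "CONSERVATION": "Conservation",
    "PROPERTIES": "Amino acid properties",
}

_NO_INFO = "No information available for this aspect."


@dataclass
class MutationReport:
    title: str
    header: dict                      # method provenance + pinned parameters
    sections: dict = field(default_factory=dict)  # branch -> list[Finding]
    warnings: list = field(default_factory=list)
    glossary_terms: list = field(default_factory=list)

    def __post_init__(self):
        for b in BRANCHES:
            self.sections.setdefault(b, [])

    @property
    def findings(self) -> list:
        return [f for b in BRANCHES for f in self.sections[b]]


def build_report(
    title: str,
    header: dict,
    findings: list,
    warnings: list | None = None,
) -> MutationReport:
    report = MutationReport(title=title, header=header, warnings=list(warnings or []))
    for f in findings:
        report.sections[f.branch].append(f)
    # collect glossary terms appearing anywhere in the rendered text
    text = " ".join(f.rendered_text for f in findings)
    report.glossary_terms = [t for t, _ in _find_terms(text)]
    return report


# ---------------------------------------------------------------------------
# glossary


@lru_cache(maxsize=1)
def load_glossary() -> tuple:
    text = resources.files("mutexplain").joinpath("data", "glossary.tsv").read_text()
    entries = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        term, definition = line.split("\t")
        entries.append((term, definition))
    # longest terms first so multi-word terms win over their substrings
    entries.sort(key=lambda e: (-len(e[0]), e[0]))
    return tuple(entries)


def _anchor(term: str) -> str:
    return "glossary-" + re.sub(r"[^a-z0-9]+", "-", term.lower()).strip("-")


def _find_terms(text: str) -> list:
    """Glossary terms present in the text, in order of first occurrence."""
    found = []
    low = text.lower()
    for term, definition in load_glossary():
        idx = low.find(term.lower())
        if idx >= 0:
            found.append((term, idx))
    found.sort(key=lambda t: t[1])
    return [(t, i) for t, i in found]


def link_glossary(text: str) -> str:
    """Mark each glossary term at its first occurrence with a Markdown link.

    Longest match, case-insensitive; later occurrences stay plain.  The
    link target is an anchor into the report's own glossary section.
    """
    linked: list[str] = []
    consumed: list[tuple[int, int]] = []  # spans already linked (term overlap)
    out = text
    offset = 0
    matches = []
    low = text.lower()
    for term, _ in load_glossary():
        idx = low.find(term.lower())
        if idx < 0:
            continue
        span = (idx, idx + len(term))
        if any(s < span[1] and span[0] < e for s, e in consumed):
            continue  # overlaps a longer term already linked
        consumed.append(span)
        matches.append((idx, term))
    for idx, term in sorted(matches, reverse=True):
        original = text[idx:idx + len(term)]
        out = out[:idx] + f"[{original}](#{_anchor(term)})" + out[idx + len(term):]
    return out


# ---------------------------------------------------------------------------
# Markdown


def render_markdown(report: MutationReport) -> str:
    """Render the full report as one self-contained Markdown document."""
    lines = [f"# {report.title}", ""]
    lines.append("**Method and provenance**")
    lines.append("")
    for key in sorted(report.header):
        lines.append(f"- {key}: {report.header[key]}")
    lines.append("")
    for branch in BRANCHES:
        lines.append(f"## {SECTION_TITLES[branch]}")
        lines.append("")
        findings = report.sections[branch]
        if not findings:
            lines.append(_NO_INFO)
        else:
            for f in findings:
                lines.append(f"**[{f.severity}]** {link_glossary(f.rendered_text)}")
                lines.append("")
        lines.append("")
    lines.append("### Warnings")
    lines.append("")
    if report.warnings:
        for w in report.warnings:
            lines.append(f"- {w}")
    else:
        lines.append("None.")
    lines.append("")
    lines.append("### Glossary")
    lines.append("")
    glossary = dict(load_glossary())
    if report.glossary_terms:
        for term in report.glossary_terms:
            definition = glossary.get(term, "")
            lines.append(f'- <a id="{_anchor(term)}"></a>**{term}** — {definition}')
    else:
        lines.append("No technical terms to explain.")
    lines.append("")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# JSON


def report_to_dict(report: MutationReport) -> dict:
    return {
        "title": report.title,
        "header": report.header,
        "sections": [
            {
                "branch": b,
                "title": SECTION_TITLES[b],
                "findings": [f.to_dict() for f in report.sections[b]],
            }
            for b in BRANCHES
        ],
        "warnings": list(report.warnings),
        "glossary_terms": list(report.glossary_terms),
    }


def validate_report_dict(d: dict) -> None:
    """Structural validation of the JSON document; raises on any violation."""
    for key in ("title", "header", "sections", "warnings", "glossary_terms"):
        if key not in d:
            raise ValueError(f"report JSON missing key {key!r}")
    if not isinstance(d["header"], dict):
        raise ValueError("header must be an object")
    sections = d["sections"]
    if [s.get("branch") for s in sections] != list(BRANCHES):
        raise ValueError("sections must list the six branches in fixed order")
    for s in sections:
        for f in s["findings"]:
            for key in ("branch", "severity", "rule_id", "sentence_key",
                        "rendered_text", "evidence"):
                if key not in f:
                    raise ValueError(f"finding missing key {key!r}")
            if f["severity"] not in SEVERITIES:
                raise ValueError(f"unknown severity {f['severity']!r}")
            if f["branch"] != s["branch"]:
                raise ValueError("finding filed under the wrong branch")
            if not isinstance(f["evidence"], list):
                raise ValueError("evidence must be a list")


def render_json(report: MutationReport) -> str:
    """Schema-validated JSON rendering (deterministic byte output)."""
    d = report_to_dict(report)
    validate_report_dict(d)
    return json.dumps(d, indent=2, sort_keys=True) + "\n"


def report_from_json(text: str) -> MutationReport:
    """Parse a JSON rendering back into an equal in-memory report."""
    d = json.loads(text)
    validate_report_dict(d)
    report = MutationReport(
        title=d["title"],
        header=d["header"],
        warnings=list(d["warnings"]),
        glossary_terms=list(d["glossary_terms"]),
    )
    for s in d["sections"]:
        report.sections[s["branch"]] = [Finding.from_dict(f) for f in s["findings"]]
    return report
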