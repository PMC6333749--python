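"""ACMG/AMP evidence-code combining.

Evidence codes (PVS1, PS1-4, PM1-6, PP1-5 on the pathogenic side; BA1,
BS1-4, BP1-7 on the benign side) are counted into strength buckets and
matched against the published combining clauses to yield one of five
classes: pathogenic, likely pathogenic, VUS, likely benign, benign. The
clause table is packaged data (``data/acmg_rules.tsv``), not hard-coded
logic, so strength re-specifications and guideline revisions slot in.

Contradictory evidence resolves to VUS (``fired_rule="conflict"``), per the
guideline's own provision: either a pathogenic-side and a benign-side clause
firing simultaneously, or evidence present on both sides with neither side's
clauses satisfied.

Evidence *assignment* is the caller's job: deciding that, say, PM2 applies
requires population databases. Two assignments are automated as optional
helpers — PM2 from an absent/zero sidecar population frequency, and PM5
from a same-codon lookup against a user-supplied known-pathogenic table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional

import pandas as pd

from .variants import Variant, codon_from_cds

__all__ = [
    "EvidenceCode",
    "Classification",
    "VOCABULARY",
    "parse_codes",
    "classify",
    "suggest_pm2",
    "suggest_pm5",
]

VOCABULARY: frozenset[str] = frozenset(
    ["PVS1"]
    + [f"PS{i}" for i in range(1, 5)]
    + [f"PM{i}" for i in range(1, 7)]
    + [f"PP{i}" for i in range(1, 6)]
    + ["BA1"]
    + [f"BS{i}" for i in range(1, 5)]
    + [f"BP{i}" for i in range(1, 8)]
)

#: strength bucket implied by a code's prefix
_DEFAULT_STRENGTH = {
    "PVS": "pvs",
    "PS": "ps",
    "PM": "pm",
    "PP": "pp",
    "BA": "ba",
    "BS": "bs",
    "BP": "bp",
}

STRENGTH_BUCKETS = ("pvs", "ps", "pm", "pp", "ba", "bs", "bp")


class AcmgError(ValueError):
    pass


@dataclass(frozen=True)
class EvidenceCode:
    value: str
    strength_override: Optional[str] = None  # one of STRENGTH_BUCKETS

    def __post_init__(self) -> None:
        if self.value not in VOCABULARY:
            raise AcmgError(
                f"unknown evidence code {self.value!r}; valid codes: "
                + ", ".join(sorted(VOCABULARY))
            )
        if self.strength_override is not None and (
            self.strength_override not in STRENGTH_BUCKETS
        ):
            raise AcmgError(f"unknown strength {self.strength_override!r}")

    @property
    def strength(self) -> str:
        if self.strength_override:
            return self.strength_override
        prefix = re.match(r"[A-Z]+", self.value).group(0)
        return _DEFAULT_STRENGTH[prefix]


@dataclass(frozen=True)
class Classification:
    value: str  # pathogenic | likely_pathogenic | VUS | likely_benign | benign
    fired_rule: str


def parse_codes(text: str) -> frozenset[EvidenceCode]:
    """Parse a comma-separated code list; case-insensitive, deduplicated."""
    codes = set()
    for tok in text.split(","):
        tok = tok.strip().upper()
        if not tok:
            continue
        codes.add(EvidenceCode(tok))
    return frozenset(codes)


def _load_clauses() -> list[dict]:
    with resources.files("vpanel.data").joinpath("acmg_rules.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    clauses = df.to_dict("records")
    for c in clauses:
        if c["class"] not in (
            "pathogenic",
            "likely_pathogenic",
            "benign",
            "likely_benign",
        ):
            raise AcmgError(f"bad class in rule file: {c['class']!r}")
    return clauses


_CLAUSES: Optional[list[dict]] = None


def _clauses() -> list[dict]:
    global _CLAUSES
    if _CLAUSES is None:
        _CLAUSES = _load_clauses()
    return _CLAUSES


def _counts(codes: Iterable[EvidenceCode]) -> dict[str, int]:
    counts = dict.fromkeys(STRENGTH_BUCKETS, 0)
    for c in set(codes):
        counts[c.strength] += 1
    return counts


def _satisfied(clause: dict, counts: dict[str, int]) -> bool:
    return all(counts[b] >= clause[b] for b in STRENGTH_BUCKETS)


def classify(codes: Iterable[EvidenceCode]) -> Classification:
    """Apply the combining table to a set of evidence codes.

    Deterministic and order-independent; clauses for the stronger class are
    tried first on each side. No clause satisfied -> VUS (``default_vus``);
    both sides satisfied -> VUS (``conflict``).
    """
    counts = _counts(codes)
    path_hit = None
    benign_hit = None
    for clause in _clauses():
        side_benign = clause["class"] in ("benign", "likely_benign")
        if _satisfied(clause, counts):
            if side_benign and benign_hit is None:
                benign_hit = clause
            elif not side_benign and path_hit is None:
                path_hit = clause
    if path_hit and benign_hit:
        return Classification(value="VUS", fired_rule="conflict")
    if path_hit:
        return Classification(value=path_hit["class"], fired_rule=path_hit["clause_id"])
    if benign_hit:
        return Classification(
            value=benign_hit["class"], fired_rule=benign_hit["clause_id"]
        )
    # no clause fired: evidence on both sides is still a conflict
    has_path = any(counts[b] for b in ("pvs", "ps", "pm", "pp"))
    has_benign = any(counts[b] for b in ("ba", "bs", "bp"))
    if has_path and has_benign:
        return Classification(value="VUS", fired_rule="conflict")
    return Classification(value="VUS", fired_rule="default_vus")


def suggest_pm2(v: Variant) -> bool:
    """PM2 helper: absent-from-controls = no or zero population frequency."""
    return v.pop_af is None or v.pop_af == 0.0


_CDS_POS_RE = re.compile(r"c\.(\d+)")
_PROT_POS_RE = re.compile(r"p\.[A-Za-z*]{1,3}(\d+)")


def _residue_of(v: Variant) -> Optional[int]:
    if v.protein_change:
        m = _PROT_POS_RE.search(v.protein_change)
        if m:
            return int(m.group(1))
    if v.cds_change:
        m = _CDS_POS_RE.search(v.cds_change)
        if m:
            return codon_from_cds(int(m.group(1)))
    return None


def suggest_pm5(
    v: Variant, known_pathogenic: Iterable[Variant]
) -> bool:
    """PM5 helper: a *different* missense change at the same residue of the
    same gene is already known pathogenic."""
    if v.consequence != "missense" or v.gene is None:
        return False
    res = _residue_of(v)
    if res is None:
        return False
    for k in known_pathogenic:
        if k.gene != v.gene or k.consequence != "missense":
            continue
        if k.key == v.key:
            continue
        if _residue_of(k) == res:
            return True
    return False
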