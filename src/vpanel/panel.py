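"""Virtual-panel construction: rank genes by consilient phenotype count.

Given a patient's core phenotypes (ontology term ids, optionally plus an
inheritance pattern), every gene in the annotation store is scored by how
many of the query criteria its disease annotations satisfy. A phenotype
criterion is satisfied when the gene is annotated to the query term itself
or to any more specific term in its descendant closure (patient queries are
typically category-level, e.g. "Puberty and gonadal disorders"); an optional
bidirectional mode additionally accepts annotated ancestors, for the case
where the patient term is more specific than the annotation. The inheritance
criterion, when present, counts as one additional criterion and is satisfied
either through the gene's recorded inheritance modes or through an annotated
mode-of-inheritance ontology term.

The panel is the resulting tiering: genes grouped by criterion count in
descending order, the field's "virtual panel" restricted to which exome
variants are interpreted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional

from .annotations import AnnotationStore, Mode, format_modes, parse_inheritance
from .ontology import Ontology, UnknownTermError

logger = logging.getLogger(__name__)

__all__ = [
    "PhenotypeQuery",
    "GeneMatch",
    "VirtualPanel",
    "match_gene",
    "build_panel",
    "export_panel",
    "parse_panel_json",
    "MODE_TERM_IDS",
]

#: mode-of-inheritance ontology terms (HPO ids), used when an ontology
#: models inheritance as annotatable terms rather than a table column
MODE_TERM_IDS: dict[Mode, str] = {
    Mode.AD: "HP:0000006",
    Mode.AR: "HP:0000007",
    Mode.XD: "HP:0001423",
    Mode.XR: "HP:0001419",
    Mode.MT: "HP:0001427",
}


class PanelError(ValueError):
    pass


@dataclass(frozen=True)
class PhenotypeQuery:
    """Ordered core phenotypes plus an optional inheritance criterion."""

    terms: tuple[str, ...]
    inheritance: Optional[frozenset[Mode]] = None

    @classmethod
    def create(
        cls, terms: list[str] | tuple[str, ...], inheritance: Optional[str] = None
    ) -> "PhenotypeQuery":
        inh = parse_inheritance(inheritance) if inheritance else None
        return cls(terms=tuple(terms), inheritance=inh)

    @property
    def n_criteria(self) -> int:
        return len(self.terms) + (1 if self.inheritance else 0)


@dataclass(frozen=True)
class GeneMatch:
    gene: str
    count: int
    matched_terms: dict[str, frozenset[str]] = field(default_factory=dict)
    inheritance_matched: bool = False
    # tie-break metadata
    n_annotated_hits: int = 0
    n_disease_records: int = 0

    def sort_key(self) -> tuple:
        """Within-tier ordering: most distinct annotated hits first, then
        most supporting disease records, then gene symbol."""
        return (-self.n_annotated_hits, -self.n_disease_records, self.gene)


@dataclass
class VirtualPanel:
    query: PhenotypeQuery
    tiers: dict[int, list[GeneMatch]]
    provenance: dict = field(default_factory=dict)

    def tier_of(self, gene: str) -> Optional[int]:
        g = gene.strip().upper()
        for count, matches in self.tiers.items():
            if any(m.gene == g for m in matches):
                return count
        return None

    @property
    def genes(self) -> list[str]:
        return [m.gene for ms in self.tiers.values() for m in ms]


def _resolve_query(q: PhenotypeQuery, o: Ontology) -> list[str]:
    resolved: list[str] = []
    bad: list[str] = []
    for t in q.terms:
        try:
            r = o.resolve(t)
        except UnknownTermError:
            bad.append(t)
            continue
        if r not in resolved:  # duplicates collapse after resolution
            resolved.append(r)
    if bad:
        raise PanelError(f"query terms not resolvable in ontology: {bad}")
    return resolved


def match_gene(
    gene: str,
    q: PhenotypeQuery,
    o: Ontology,
    store: AnnotationStore,
    bidirectional: bool = False,
) -> GeneMatch:
    """Score one gene against the query: the consilient-phenotype count."""
    query_terms = _resolve_query(q, o)
    annotated = {o.resolve(t, allow_obsolete=True) for t in store.gene_terms(gene)}

    matched: dict[str, frozenset[str]] = {}
    for qt in query_terms:
        closure = o.descendants_or_self(qt)
        if bidirectional:
            closure = closure | o.ancestors_or_self(qt)
        hits = frozenset(annotated & closure)
        if hits:
            matched[qt] = hits

    inheritance_matched = False
    if q.inheritance:
        if q.inheritance & store.gene_modes(gene):
            inheritance_matched = True
        else:
            # a gene annotated to the matching mode-of-inheritance term
            for mode in q.inheritance:
                moi = MODE_TERM_IDS.get(mode)
                if moi and moi in o and annotated & o.descendants_or_self(moi):
                    inheritance_matched = True
                    break

    count = len(matched) + (1 if inheritance_matched else 0)
    return GeneMatch(
        gene=store._key(gene),
        count=count,
        matched_terms=matched,
        inheritance_matched=inheritance_matched,
        n_annotated_hits=len(set().union(*matched.values())) if matched else 0,
        n_disease_records=len(store.gene_diseases(gene)),
    )


def build_panel(
    q: PhenotypeQuery,
    o: Ontology,
    store: AnnotationStore,
    min_count: int = 1,
    bidirectional: bool = False,
) -> VirtualPanel:
    """Score every gene in the store and tier by descending criterion count.

    Genes below *min_count* are dropped. Deterministic for fixed inputs:
    within a tier genes are ordered by :meth:`GeneMatch.sort_key`.
    """
    if not q.terms:
        raise PanelError("empty phenotype query")
    if not store.genes:
        logger.warning("empty annotation store: panel will be empty")
    by_count: dict[int, list[GeneMatch]] = {}
    for gene in sorted(store.genes):
        m = match_gene(gene, q, o, store, bidirectional=bidirectional)
        if m.count >= max(min_count, 1):
            by_count.setdefault(m.count, []).append(m)
    tiers = {
        count: sorted(by_count[count], key=GeneMatch.sort_key)
        for count in sorted(by_count, reverse=True)
    }
    provenance = {
        "n_terms": len(o),
        "n_records": len(store),
        "min_count": min_count,
        "bidirectional": bidirectional,
    }
    return VirtualPanel(query=q, tiers=tiers, provenance=provenance)


def _panel_to_dict(p: VirtualPanel) -> dict:
    return {
        "query": {
            "terms": list(p.query.terms),
            "inheritance": format_modes(p.query.inheritance)
            if p.query.inheritance
            else None,
        },
        "tiers": {
            str(count): [
                {
                    "gene": m.gene,
                    "count": m.count,
                    "matched_terms": {k: sorted(v) for k, v in m.matched_terms.items()},
                    "inheritance_matched": m.inheritance_matched,
                    "n_annotated_hits": m.n_annotated_hits,
                    "n_disease_records": m.n_disease_records,
                }
                for m in matches
            ]
            for count, matches in p.tiers.items()
        },
        "provenance": p.provenance,
    }


def export_panel(
    p: VirtualPanel,
    format: str = "tsv",
    gene_coords: Optional[dict[str, tuple[str, int, int]]] = None,
) -> str:
    """Serialize a panel: ``tsv`` (tier, gene, matched criteria), ``json``
    (full structure, round-trippable), or ``bed`` (0-based half-open
    intervals; requires *gene_coords*)."""
    if format == "tsv":
        lines = ["tier\tgene\tmatched_criteria"]
        for count, matches in p.tiers.items():
            for m in matches:
                crits = sorted(m.matched_terms)
                if m.inheritance_matched:
                    crits.append("inheritance")
                lines.append(f"{count}\t{m.gene}\t{','.join(crits)}")
        return "\n".join(lines) + "\n"
    if format == "json":
        return json.dumps(_panel_to_dict(p), indent=2, sort_keys=True) + "\n"
    if format == "bed":
        if gene_coords is None:
            raise PanelError("bed export requires gene coordinates")
        lines = []
        for matches in p.tiers.values():
            for m in matches:
                if m.gene not in gene_coords:
                    raise PanelError(f"no coordinates for gene {m.gene}")
                chrom, start, end = gene_coords[m.gene]
                lines.append(f"{chrom}\t{start}\t{end}\t{m.gene}")
        return "\n".join(lines) + ("\n" if lines else "")
    raise PanelError(f"unknown export format: {format}")


def parse_panel_json(text: str) -> VirtualPanel:
    """Inverse of ``export_panel(..., format='json')``."""
    d = json.loads(text)
    inh = d["query"].get("inheritance")
    q = PhenotypeQuery(
        terms=tuple(d["query"]["terms"]),
        inheritance=parse_inheritance(inh) if inh else None,
    )
    tiers: dict[int, list[GeneMatch]] = {}
    for count_s, matches in d["tiers"].items():
        tiers[int(count_s)] = [
            GeneMatch(
                gene=m["gene"],
                count=m["count"],
                matched_terms={
                    k: frozenset(v) for k, v in m["matched_terms"].items()
                },
                inheritance_matched=m["inheritance_matched"],
                n_annotated_hits=m["n_annotated_hits"],
                n_disease_records=m["n_disease_records"],
            )
            for m in matches
        ]
    tiers = {c: tiers[c] for c in sorted(tiers, reverse=True)}
    return VirtualPanel(query=q, tiers=tiers, provenance=d.get("provenance", {}))
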