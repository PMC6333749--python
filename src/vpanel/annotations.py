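"""Gene-disease-phenotype-inheritance association store.

This is the knowledge layer the virtual panel is built against: rows linking
a gene symbol to a disease, one of the disease's phenotype terms, and the
disease's mode(s) of inheritance. The TSV dialect is column-compatible with
the HPO ``genes_to_phenotype`` download (columns ``gene_symbol``,
``disease_id``, ``hpo_id``, ``inheritance``), so real annotation releases
can be dropped in; the test fixtures are written in the same dialect.

Gene symbols are normalized to uppercase and pushed through an optional
alias map before storage, so queries via an alias (e.g. GPR56 for ADGRG1)
see the same records.
"""

from __future__ import annotations

import enum
import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Optional, Union

import pandas as pd

from .ontology import OntologyError, normalize_term_id

logger = logging.getLogger(__name__)

__all__ = [
    "Mode",
    "parse_inheritance",
    "format_modes",
    "AssociationRecord",
    "AnnotationStore",
    "AnnotationError",
    "load_annotations",
]


class AnnotationError(ValueError):
    pass


class Mode(str, enum.Enum):
    """Atomic Mendelian inheritance modes."""

    AD = "AD"
    AR = "AR"
    XD = "XD"
    XR = "XR"
    MT = "MT"
    UNKNOWN = "UNKNOWN"

    def __str__(self) -> str:
        return self.value


#: canonical evaluation order for rule dispatch
MODE_ORDER = (Mode.AD, Mode.AR, Mode.XD, Mode.XR, Mode.MT, Mode.UNKNOWN)

_TOKEN_MAP = {
    "AD": {Mode.AD},
    "AR": {Mode.AR},
    "XD": {Mode.XD},
    "XR": {Mode.XR},
    "XLD": {Mode.XD},
    "XLR": {Mode.XR},
    "MT": {Mode.MT},
    "AD/AR": {Mode.AD, Mode.AR},
    "XD/XR": {Mode.XD, Mode.XR},
    "UNKNOWN": {Mode.UNKNOWN},
    "": {Mode.UNKNOWN},
}


def parse_inheritance(token: Optional[str], strict: bool = False) -> frozenset[Mode]:
    """Decompose an inheritance token into the atomic modes it permits.

    Compound tokens like ``AD/AR`` map to both atomic modes. Unknown tokens
    map to ``{UNKNOWN}`` with a warning (hard error in *strict* mode).
    """
    raw = "" if token is None else str(token).strip()
    modes = _TOKEN_MAP.get(raw.upper())
    if modes is None:
        if strict:
            raise AnnotationError(f"unknown inheritance token: {raw!r}")
        logger.warning("unknown inheritance token %r; treating as UNKNOWN", raw)
        modes = {Mode.UNKNOWN}
    return frozenset(modes)


def format_modes(modes: frozenset[Mode]) -> str:
    return "/".join(m.value for m in MODE_ORDER if m in modes)


def normalize_gene(symbol: str, alias_map: Optional[dict[str, str]] = None) -> str:
    sym = symbol.strip().upper()
    if not sym:
        raise AnnotationError("empty gene symbol")
    if alias_map:
        sym = alias_map.get(sym, sym)
    return sym


@dataclass(frozen=True)
class AssociationRecord:
    gene: str
    disease_id: str
    phenotype: str
    modes: frozenset[Mode]


class AnnotationStore:
    """Deduplicated association records with gene-keyed indices."""

    def __init__(
        self,
        records: frozenset[AssociationRecord],
        alias_map: Optional[dict[str, str]] = None,
    ):
        self.records = records
        self.alias_map = dict(alias_map or {})
        self._terms: dict[str, set[str]] = {}
        self._modes: dict[str, set[Mode]] = {}
        self._diseases: dict[str, set[str]] = {}
        for r in records:
            self._terms.setdefault(r.gene, set()).add(r.phenotype)
            self._modes.setdefault(r.gene, set()).update(r.modes)
            self._diseases.setdefault(r.gene, set()).add(r.disease_id)

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationStore):
            return NotImplemented
        return self.records == other.records and self.alias_map == other.alias_map

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self._terms)

    def _key(self, gene: str) -> str:
        return normalize_gene(gene, self.alias_map)

    def gene_terms(self, gene: str) -> frozenset[str]:
        """Union of phenotype terms over all of the gene's disease records."""
        return frozenset(self._terms.get(self._key(gene), ()))

    def gene_modes(self, gene: str) -> frozenset[Mode]:
        """Union of atomic inheritance modes; {UNKNOWN} for unknown genes."""
        modes = self._modes.get(self._key(gene))
        if not modes:
            return frozenset({Mode.UNKNOWN})
        return frozenset(modes)

    def gene_diseases(self, gene: str) -> frozenset[str]:
        return frozenset(self._diseases.get(self._key(gene), ()))


def _read_tsv(stream: Union[str, Path, IO[str]]) -> pd.DataFrame:
    if isinstance(stream, str) and "\n" in stream:
        stream = io.StringIO(stream)
    return pd.read_csv(
        stream, sep="\t", comment="#", dtype=str, keep_default_na=False
    )


def load_alias_map(stream: Union[str, Path, IO[str]]) -> dict[str, str]:
    """Load an alias TSV (columns ``alias``, ``primary_symbol``)."""
    df = _read_tsv(stream)
    missing = {"alias", "primary_symbol"} - set(df.columns)
    if missing:
        raise AnnotationError(f"alias table missing columns: {sorted(missing)}")
    return {
        a.strip().upper(): p.strip().upper()
        for a, p in zip(df["alias"], df["primary_symbol"])
        if a.strip() and p.strip()
    }


def load_annotations(
    stream: Union[str, Path, IO[str]],
    alias_stream: Union[str, Path, IO[str], None] = None,
    strict: bool = False,
) -> AnnotationStore:
    """Load an annotation TSV into an :class:`AnnotationStore`.

    Malformed rows (missing gene or unparseable phenotype id) are skipped
    with a warning, or raise in *strict* mode. Duplicate rows collapse.
    """
    alias_map = load_alias_map(alias_stream) if alias_stream is not None else {}
    df = _read_tsv(stream)
    required = {"gene_symbol", "disease_id", "hpo_id", "inheritance"}
    missing = required - set(df.columns)
    if missing:
        raise AnnotationError(f"annotation table missing columns: {sorted(missing)}")

    records: set[AssociationRecord] = set()
    dropped = 0
    for row in df.itertuples(index=False):
        try:
            gene = normalize_gene(str(row.gene_symbol), alias_map)
            phenotype = normalize_term_id(str(row.hpo_id))
        except (AnnotationError, OntologyError) as exc:
            if strict:
                raise AnnotationError(f"malformed annotation row {tuple(row)}: {exc}")
            dropped += 1
            logger.warning("skipping malformed annotation row %s: %s", tuple(row), exc)
            continue
        records.add(
            AssociationRecord(
                gene=gene,
                disease_id=str(row.disease_id).strip(),
                phenotype=phenotype,
                modes=parse_inheritance(row.inheritance, strict=strict),
            )
        )
    logger.info(
        "loaded %d association records (%d rows read, %d dropped)",
        len(records), len(df), dropped,
    )
    return AnnotationStore(frozenset(records), alias_map)
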