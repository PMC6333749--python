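"""Cohort-level replay: per-patient inheritance evaluation and diagnostic yield.

Input is a sequencing-results table, one row per reported variant, with
columns ``patient_id``, ``sex``, ``gene``, ``position`` (``chrN:pos``),
``nucleotide_change`` (HGVS c.), ``protein_change`` (HGVS p.),
``inheritance``, plus optional ``phenotypes`` and ``zygosity``. ``ND`` rows
mark patients with no candidate finding.

Each patient's findings are grouped by gene into a :class:`GeneCallSet` and
pushed through the inheritance-consistency rules. A patient is *diagnostic*
if at least one gene group is consistent, *excluded* if every group fails on
inheritance grounds (the single-heterozygous-AR situation), and *negative*
with no findings. The diagnostic rate is diagnostic patients over the whole
cohort.

Zygosity reconstruction, when the table carries none: autosomal variants are
treated as heterozygous (recessive diagnoses appear as two rows = compound
het) and X-linked variants in males as hemizygous. An explicit ``zygosity``
column overrides this.
"""

from __future__ import annotations

import io
import json
import logging
import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import IO, Optional, Union

import pandas as pd

from .annotations import Mode, parse_inheritance
from .inheritance import GeneCallSet, evaluate_gene
from .variants import Variant, is_x_chrom

logger = logging.getLogger(__name__)

__all__ = [
    "Finding",
    "CohortRecord",
    "CohortResult",
    "CohortError",
    "load_cohort",
    "evaluate_cohort",
    "yield_report",
    "result_from_json",
]


class CohortError(ValueError):
    pass


@dataclass(frozen=True)
class Finding:
    gene: str
    position: str
    nucleotide_change: str
    protein_change: str
    modes: frozenset[Mode]
    zygosity: Optional[str] = None  # explicit override, else reconstructed


@dataclass
class CohortRecord:
    patient_id: str
    sex: str = "unknown"
    phenotypes: tuple[str, ...] = ()
    findings: tuple[Finding, ...] = ()


@dataclass
class CohortResult:
    per_patient: dict[str, str]  # patient_id -> diagnostic|excluded|negative
    n_candidate_positive: int
    n_excluded: int
    n_diagnostic: int
    rate: float

    @property
    def n_patients(self) -> int:
        return len(self.per_patient)


_ND = {"ND", "N.D.", "-", ""}

_POSITION_RE = re.compile(r"^(chr)?([0-9XYM]+[T]?):(\d+)$", re.IGNORECASE)
_SUBST_RE = re.compile(r"([ACGT]+)\s*>\s*([ACGT]+)")


def _parse_position(text: str) -> tuple[str, int]:
    m = _POSITION_RE.match(text.strip())
    if m is None:
        raise CohortError(f"unparseable position {text!r}")
    chrom = m.group(2).upper()
    return f"chr{chrom}", int(m.group(3))


def _reconstruct_variant(f: Finding, sex: str) -> Variant:
    chrom, pos = _parse_position(f.position)
    m = _SUBST_RE.search(f.nucleotide_change)
    # ref/alt only need to differ; inheritance rules read zygosity + chrom
    ref, alt = (m.group(1), m.group(2)) if m else ("N", "<ALT>")
    zyg = f.zygosity
    if zyg is None:
        zyg = "hemi" if (is_x_chrom(chrom) and sex == "male") else "het"
    return Variant(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        zygosity=zyg,
        gene=f.gene,
        cds_change=f.nucleotide_change or None,
        protein_change=f.protein_change or None,
    )


def load_cohort(
    stream: Union[str, Path, IO[str]], strict: bool = False
) -> list[CohortRecord]:
    """Load the per-variant cohort TSV into one record per patient."""
    if isinstance(stream, str) and "\n" in stream:
        stream = io.StringIO(stream)
    df = pd.read_csv(stream, sep="\t", comment="#", dtype=str, keep_default_na=False)
    required = {
        "patient_id",
        "sex",
        "gene",
        "position",
        "nucleotide_change",
        "protein_change",
        "inheritance",
    }
    missing = required - set(df.columns)
    if missing:
        raise CohortError(f"cohort table missing columns: {sorted(missing)}")

    records: dict[str, CohortRecord] = {}
    seen_rows: set[tuple[str, str, str]] = set()
    for row in df.itertuples(index=False):
        d = row._asdict()
        pid = d["patient_id"].strip()
        if not pid:
            raise CohortError("row without patient_id")
        sex = d["sex"].strip().lower() or "unknown"
        rec = records.setdefault(
            pid,
            CohortRecord(
                patient_id=pid,
                sex=sex,
                phenotypes=tuple(
                    p.strip()
                    for p in d.get("phenotypes", "").split(";")
                    if p.strip()
                ),
            ),
        )
        gene = d["gene"].strip().upper()
        if gene in _ND:
            continue
        key = (pid, gene, d["nucleotide_change"].strip())
        if key in seen_rows:
            if strict:
                raise CohortError(f"duplicate finding row {key}")
            logger.warning("duplicate finding row %s skipped", key)
            continue
        seen_rows.add(key)
        rec.findings = rec.findings + (
            Finding(
                gene=gene,
                position=d["position"].strip(),
                nucleotide_change=d["nucleotide_change"].strip(),
                protein_change=d["protein_change"].strip(),
                modes=parse_inheritance(d["inheritance"]),
                zygosity=d.get("zygosity", "").strip().lower() or None,
            ),
        )
    logger.info("loaded %d patients (%d finding rows)", len(records), len(seen_rows))
    return list(records.values())


def _patient_status(rec: CohortRecord) -> str:
    if not rec.findings:
        return "negative"
    by_gene: dict[str, list[Finding]] = {}
    for f in rec.findings:
        by_gene.setdefault(f.gene, []).append(f)
    statuses = []
    for gene, fs in by_gene.items():
        modes = frozenset().union(*(f.modes for f in fs))
        calls = GeneCallSet(
            gene=gene,
            modes=modes,
            variants=tuple(_reconstruct_variant(f, rec.sex) for f in fs),
            patient_sex=rec.sex if rec.sex in ("male", "female") else "unknown",
        )
        statuses.append(evaluate_gene(calls).status)
    if "consistent" in statuses:
        return "diagnostic"
    return "excluded"


def evaluate_cohort(records: list[CohortRecord]) -> CohortResult:
    """Evaluate every patient and aggregate the diagnostic yield."""
    if not records:
        raise CohortError("empty cohort: diagnostic rate is undefined")
    per_patient = {r.patient_id: _patient_status(r) for r in records}
    n_diag = sum(1 for s in per_patient.values() if s == "diagnostic")
    n_excl = sum(1 for s in per_patient.values() if s == "excluded")
    return CohortResult(
        per_patient=per_patient,
        n_candidate_positive=n_diag + n_excl,
        n_excluded=n_excl,
        n_diagnostic=n_diag,
        rate=n_diag / len(per_patient),
    )


def _pct(rate: float) -> str:
    return str(
        (Decimal(str(rate)) * 100).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    )


def yield_report(r: CohortResult, format: str = "tsv") -> str:
    """Render per-patient verdicts plus the aggregate yield block."""
    if format == "tsv":
        lines = ["patient_id\tstatus"]
        lines += [f"{pid}\t{status}" for pid, status in r.per_patient.items()]
        lines.append(
            "#aggregate\tcandidate_positive={} excluded={} diagnostic={} "
            "rate={}/{}={}%".format(
                r.n_candidate_positive,
                r.n_excluded,
                r.n_diagnostic,
                r.n_diagnostic,
                r.n_patients,
                _pct(r.rate),
            )
        )
        return "\n".join(lines) + "\n"
    if format == "json":
        return (
            json.dumps(
                {
                    "per_patient": r.per_patient,
                    "n_candidate_positive": r.n_candidate_positive,
                    "n_excluded": r.n_excluded,
                    "n_diagnostic": r.n_diagnostic,
                    "rate": r.rate,
                    "rate_percent": _pct(r.rate),
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
    raise CohortError(f"unknown report format: {format}")


def result_from_json(text: str) -> CohortResult:
    d = json.loads(text)
    return CohortResult(
        per_patient=d["per_patient"],
        n_candidate_positive=d["n_candidate_positive"],
        n_excluded=d["n_excluded"],
        n_diagnostic=d["n_diagnostic"],
        rate=d["rate"],
    )
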