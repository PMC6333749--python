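"""Proband variant intake, pre-filtering and panel intersection.

Variants come from a VCF (one record per site, any number of ALT alleles)
plus a sidecar annotation TSV keyed by (chrom, pos, ref, alt) that carries
the gene symbol, coding consequence, population allele frequency and HGVS
c./p. strings. Keeping gene/consequence assignment in a sidecar table — the
output of whatever annotator the lab runs — isolates panel-based
interpretation from transcript-database churn.

Coordinate conventions: VCF positions are 1-based; BED exports elsewhere in
the package are 0-based half-open. CDS position -> codon arithmetic for
HGVS cross-checks lives here (``codon_from_cds``).
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Optional, Union

import pandas as pd
from cyvcf2 import VCF

from .annotations import Mode
from .panel import VirtualPanel

logger = logging.getLogger(__name__)

__all__ = [
    "Variant",
    "FilterConfig",
    "VariantError",
    "read_variants",
    "prefilter",
    "filter_by_panel",
    "codon_from_cds",
    "CONSEQUENCES",
]

CONSEQUENCES = (
    "missense",
    "nonsense",
    "frameshift",
    "splice_site",
    "inframe_indel",
    "synonymous",
    "other",
)

_X_NAMES = {"X", "CHRX"}


def is_x_chrom(chrom: str) -> bool:
    return chrom.strip().upper() in _X_NAMES


class VariantError(ValueError):
    pass


@dataclass(frozen=True)
class Variant:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    zygosity: str  # het | hom | hemi
    gene: Optional[str] = None
    consequence: Optional[str] = None
    pop_af: Optional[float] = None
    cds_change: Optional[str] = None
    protein_change: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VariantError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise VariantError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.zygosity not in ("het", "hom", "hemi"):
            raise VariantError(f"bad zygosity {self.zygosity!r}")
        if self.pop_af is not None and not (0.0 <= self.pop_af <= 1.0):
            raise VariantError(f"pop_af out of [0,1]: {self.pop_af}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class FilterConfig:
    """Pre-filter thresholds applied before panel intersection.

    Frequency cut-offs follow common clinical practice for dominant vs
    recessive candidate screening and are fully overridable; a missing
    population frequency is treated as 0 (novel = potentially pathogenic).
    """

    max_af_dominant: float = 0.001
    max_af_recessive: float = 0.01
    consequence_whitelist: frozenset[str] = frozenset(
        {"missense", "nonsense", "frameshift", "splice_site", "inframe_indel"}
    )
    min_panel_tier: int = 1

    def __post_init__(self) -> None:
        for f in (self.max_af_dominant, self.max_af_recessive):
            if not (0.0 <= f <= 1.0):
                raise VariantError(f"frequency threshold out of [0,1]: {f}")
        if not self.consequence_whitelist:
            raise VariantError("consequence whitelist must be non-empty")


def _load_sidecar(
    sidecar: Union[str, Path, IO[str]], strict: bool
) -> dict[tuple[str, int, str, str], dict]:
    if isinstance(sidecar, str) and "\n" in sidecar:
        sidecar = io.StringIO(sidecar)
    df = pd.read_csv(sidecar, sep="\t", comment="#", dtype=str, keep_default_na=False)
    required = {"chrom", "pos", "ref", "alt", "gene", "consequence"}
    missing = required - set(df.columns)
    if missing:
        raise VariantError(f"sidecar missing columns: {sorted(missing)}")
    table: dict[tuple[str, int, str, str], dict] = {}
    for row in df.itertuples(index=False):
        d = row._asdict()
        try:
            pos = int(d["pos"])
            af = float(d["pop_af"]) if d.get("pop_af", "").strip() else None
            if af is not None and not (0.0 <= af <= 1.0):
                raise ValueError(f"pop_af out of range: {af}")
        except ValueError as exc:
            if strict:
                raise VariantError(f"malformed sidecar row {tuple(row)}: {exc}")
            logger.warning("skipping malformed sidecar row %s: %s", tuple(row), exc)
            continue
        table[(d["chrom"], pos, d["ref"], d["alt"])] = {
            "gene": d["gene"].strip().upper() or None,
            "consequence": d["consequence"].strip() or None,
            "pop_af": af,
            "cds_change": d.get("cds_change", "").strip() or None,
            "protein_change": d.get("protein_change", "").strip() or None,
        }
    return table


def read_variants(
    vcf_path: Union[str, Path],
    sidecar: Union[str, Path, IO[str]],
    sample: str,
    strict: bool = False,
) -> list[Variant]:
    """Read the named sample's carried ALT alleles as annotated Variants.

    Genotype mapping: 0/1 -> het, 1/1 -> hom, haploid 1 -> hemi; multiallelic
    genotypes decompose into one Variant per carried ALT allele. Sites absent
    from the sidecar are retained with gene/consequence unset.
    """
    vcf = VCF(str(vcf_path))
    if sample not in vcf.samples:
        raise VariantError(
            f"sample {sample!r} not in VCF (samples: {vcf.samples})"
        )
    si = vcf.samples.index(sample)
    table = _load_sidecar(sidecar, strict=strict)

    out: list[Variant] = []
    for rec in vcf:
        gt = rec.genotypes[si]
        alleles = [a for a in gt[:-1] if a >= 0]
        if not alleles:
            continue
        for ai, alt in enumerate(rec.ALT, start=1):
            n = alleles.count(ai)
            if n == 0:
                continue
            if len(alleles) == 1:
                zyg = "hemi"
            elif n == len(alleles):
                zyg = "hom"
            else:
                zyg = "het"
            ann = table.get((rec.CHROM, rec.POS, rec.REF, alt), {})
            out.append(
                Variant(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    zygosity=zyg,
                    **ann,
                )
            )
    logger.info("read %d carried variants for sample %s", len(out), sample)
    return out


def prefilter(
    vs: list[Variant],
    cfg: FilterConfig,
    modes: Optional[dict[str, frozenset[Mode]]] = None,
) -> list[Variant]:
    """Consequence + population-frequency screen, before panel intersection.

    The frequency threshold is picked by the gene's most permissive mode:
    genes with a recessive (AR) mode tolerate the higher recessive cut-off,
    everything else uses the dominant cut-off. Missing pop_af passes.
    """
    modes = modes or {}
    kept = []
    for v in vs:
        if v.consequence not in cfg.consequence_whitelist:
            continue
        gene_modes = modes.get(v.gene, frozenset())
        cutoff = (
            cfg.max_af_recessive if Mode.AR in gene_modes else cfg.max_af_dominant
        )
        af = v.pop_af if v.pop_af is not None else 0.0
        if af <= cutoff:
            kept.append(v)
    logger.info("prefilter: %d -> %d variants", len(vs), len(kept))
    return kept


def filter_by_panel(
    vs: list[Variant], p: VirtualPanel, min_tier: int = 1
) -> list[Variant]:
    """Keep variants whose gene sits in a panel tier of count >= *min_tier*.

    Gene-less variants are dropped; input order is preserved; idempotent.
    """
    tier_by_gene = {m.gene: count for count, ms in p.tiers.items() for m in ms}
    kept = [
        v
        for v in vs
        if v.gene is not None and tier_by_gene.get(v.gene.upper(), -1) >= min_tier
    ]
    logger.info("panel filter (min_tier=%d): %d -> %d variants", min_tier, len(vs), len(kept))
    return kept


def codon_from_cds(cds_pos: int) -> int:
    """1-based codon index affected by a CDS position: ceil(pos / 3).

    c.430 falls in codon 144, c.640 in codon 214 — the arithmetic that links
    an HGVS c. substitution to the residue number in its p. notation.
    """
    if cds_pos < 1:
        raise VariantError(f"CDS position must be >= 1, got {cds_pos}")
    return math.ceil(cds_pos / 3)
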