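"""Inheritance-pattern consistency rules.

A gene's surviving variants only support a diagnosis if their zygosities can
realize the gene's mode of inheritance: one heterozygous hit in a strictly
autosomal-recessive gene leaves an intact allele and is excluded, while two
distinct heterozygous hits are provisionally consistent as a compound
heterozygote until parental genotypes confirm the trans configuration.

Rules per atomic mode (any permitted mode succeeding makes the gene
consistent):

====  =========================================================
AD    >= 1 het or hom variant
AR    >= 1 hom, or >= 2 distinct het (phase unconfirmed without trio data)
XD    >= 1 variant, either sex
XR    male: >= 1 hemi/het call on X; female: hom or >= 2 het
MT    >= 1 variant (heteroplasmy not modeled)
UNK   >= 1 variant (lenient: unknown mode never excludes a finding)
====  =========================================================

Unknown patient sex is treated as female for X-linked recessive rules — the
stricter reading, avoiding false-positive diagnoses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from .annotations import MODE_ORDER, Mode
from .variants import Variant, is_x_chrom

logger = logging.getLogger(__name__)

__all__ = ["GeneCallSet", "ConsistencyVerdict", "evaluate_gene", "confirm_phase"]

SEXES = ("male", "female", "unknown")


@dataclass(frozen=True)
class GeneCallSet:
    gene: str
    modes: frozenset[Mode]
    variants: tuple[Variant, ...]
    patient_sex: str = "unknown"

    def __post_init__(self) -> None:
        if not self.modes:
            raise ValueError("modes must be non-empty ({UNKNOWN} is allowed)")
        if self.patient_sex not in SEXES:
            raise ValueError(f"bad patient_sex {self.patient_sex!r}")


@dataclass(frozen=True)
class ConsistencyVerdict:
    status: str  # consistent | excluded_inheritance | no_candidate
    rule_fired: str
    phase_confirmed: bool = False


def _distinct(variants: tuple[Variant, ...]) -> list[Variant]:
    seen: dict[tuple, Variant] = {}
    for v in variants:
        seen.setdefault(v.key, v)
    return list(seen.values())


def _mode_rule(mode: Mode, c: GeneCallSet) -> Optional[str]:
    """Return the fired rule name if *mode* is realizable, else None."""
    vs = _distinct(c.variants)
    zygs = [v.zygosity for v in vs]
    if mode is Mode.AD:
        if any(z in ("het", "hom") for z in zygs):
            return "ad_single_hit"
    elif mode is Mode.AR:
        if any(z == "hom" for z in zygs):
            return "ar_homozygous"
        if sum(z == "het" for z in zygs) >= 2:
            return "ar_compound_het_unphased"
    elif mode is Mode.XD:
        if vs:
            return "xd_any_hit"
    elif mode is Mode.XR:
        on_x = [v for v in vs if is_x_chrom(v.chrom)]
        if c.patient_sex == "male":
            if any(v.zygosity in ("hemi", "het") for v in on_x):
                return "xr_male_hemizygous"
        else:  # female, or unknown treated as female (stricter)
            if any(v.zygosity == "hom" for v in on_x):
                return "xr_female_homozygous"
            if sum(v.zygosity == "het" for v in on_x) >= 2:
                return "xr_female_biallelic"
    elif mode is Mode.MT:
        if vs:
            return "mt_lenient"
    elif mode is Mode.UNKNOWN:
        if vs:
            return "unknown_mode_lenient"
    return None


def evaluate_gene(c: GeneCallSet) -> ConsistencyVerdict:
    """Decide whether the call set realizes any permitted inheritance mode."""
    if not c.variants:
        return ConsistencyVerdict(status="no_candidate", rule_fired="no_variants")
    for mode in MODE_ORDER:
        if mode not in c.modes:
            continue
        rule = _mode_rule(mode, c)
        if rule is not None:
            return ConsistencyVerdict(status="consistent", rule_fired=rule)
    return ConsistencyVerdict(
        status="excluded_inheritance",
        rule_fired="no_mode_satisfied:" + "/".join(m.value for m in MODE_ORDER if m in c.modes),
    )


def confirm_phase(
    c: GeneCallSet,
    parental_genotypes: dict[tuple[str, int, str, str], str],
) -> ConsistencyVerdict:
    """Refine a provisional AR compound-het verdict with parental origins.

    *parental_genotypes* maps a variant key to ``maternal`` / ``paternal`` /
    ``absent``. One maternal-only plus one paternal-only variant confirms the
    trans configuration; all known origins on the same parent is a cis
    configuration (one intact allele) and excludes the gene; an ``absent``
    variant leaves phase open (possible de novo, flagged by the caller).
    """
    base = evaluate_gene(c)
    if base.status != "consistent" or base.rule_fired != "ar_compound_het_unphased":
        return base
    vs = _distinct(c.variants)
    origins = []
    missing = []
    for v in vs:
        o = parental_genotypes.get(v.key)
        if o is None:
            missing.append(v.key)
        elif o not in ("maternal", "paternal", "absent"):
            raise ValueError(f"bad parental origin {o!r} for {v.key}")
        else:
            origins.append(o)
    if missing:
        logger.warning(
            "no parental genotype for %s; phase left unconfirmed", missing
        )
    known = [o for o in origins if o != "absent"]
    if "maternal" in known and "paternal" in known:
        return ConsistencyVerdict(
            status="consistent", rule_fired="ar_compound_het_trans", phase_confirmed=True
        )
    if not missing and len(known) == len(vs) and len(set(known)) == 1:
        return ConsistencyVerdict(
            status="excluded_inheritance", rule_fired="cis_configuration"
        )
    return base
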