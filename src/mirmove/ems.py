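"""EMS bulked-pool candidate-mutation filtering.

A bulked-segregant resequencing design yields two variant tables: the
non-mutagenized parent and a pool of phenotypically selected mutants. The
causal mutation is expected to be (i) absent from the parent, (ii) an
EMS-type transition (EMS alkylates guanine, producing G:C -> A:T
transitions), (iii) fixed in the pool (allele fraction ~ 1), and (iv)
protein-affecting (missense or splice-site). Variant tables are consumed
with precomputed allele fractions and effect annotations; alignment and
variant calling are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

EFFECTS_DEFAULT = frozenset({"missense", "splice"})
AF_MIN_DEFAULT = 0.99  # "fixed in the pool", tolerating sequencing error

_CANONICAL = {("G", "A"), ("C", "T")}
_ALL_TRANSITIONS = _CANONICAL | {("A", "G"), ("T", "C")}

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "allele_fraction", "effect"]


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    allele_fraction: float
    effect: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if not 0.0 <= self.allele_fraction <= 1.0:
            raise ValueError("allele_fraction must be in [0, 1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def _keys(table: pd.DataFrame) -> pd.Series:
    return pd.Series(
        list(zip(table["chrom"], table["pos"], table["ref"], table["alt"])),
        index=table.index,
    )


def subtract_parent(pool: pd.DataFrame, parent: pd.DataFrame) -> pd.DataFrame:
    """Pool variants absent from the parent, keyed by (chrom, pos, ref, alt)."""
    for name, tab in (("pool", pool), ("parent", parent)):
        missing = {"chrom", "pos", "ref", "alt"} - set(tab.columns)
        if missing:
            raise ValueError(f"{name} table missing columns: {sorted(missing)}")
    if pool.empty:
        return pool.copy()
    parent_keys = set(_keys(parent)) if not parent.empty else set()
    mask = ~_keys(pool).isin(parent_keys)
    return pool.loc[mask].reset_index(drop=True)


def is_ems_transition(ref: str, alt: str, mode: str = "canonical") -> bool:
    """True iff (ref, alt) is an EMS-type transition.

    ``canonical``: G->A or C->T on the reference strand (the G:C -> A:T
    chemistry of EMS alkylation). ``all-transitions`` additionally accepts
    A->G and T->C. Non-SNV alleles raise ``ValueError``.
    """
    ref, alt = ref.upper(), alt.upper()
    if len(ref) != 1 or len(alt) != 1 or not {ref, alt} <= set("ACGT"):
        raise ValueError(f"non-SNV alleles: {ref!r} -> {alt!r}")
    if mode == "canonical":
        return (ref, alt) in _CANONICAL
    if mode == "all-transitions":
        return (ref, alt) in _ALL_TRANSITIONS
    raise ValueError(f"unknown mode {mode!r}")


def candidate_filter(
    variants: pd.DataFrame,
    af_min: float = AF_MIN_DEFAULT,
    effects: Iterable[str] = EFFECTS_DEFAULT,
    mode: str = "canonical",
    effect_aliases: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Candidate causal mutations: EMS transitions fixed in the pool with a
    protein-affecting annotation.

    Keeps variants that are EMS transitions (``mode``), have
    ``allele_fraction >= af_min`` and an effect in ``effects``; output is
    sorted by (chrom, pos). ``effect_aliases`` optionally maps annotation
    strings from external callers onto the internal effect vocabulary before
    filtering. Idempotent; output is a subset of the input.
    """
    if not 0.0 < af_min <= 1.0:
        raise ValueError("af_min must be in (0, 1]")
    missing = set(VARIANT_COLUMNS) - set(variants.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    effects = set(effects)
    df = variants.copy()
    eff = df["effect"].astype(str)
    if effect_aliases:
        eff = eff.map(lambda e: effect_aliases.get(e, e))
    keep = (
        df.apply(lambda r: is_ems_transition(r["ref"], r["alt"], mode=mode), axis=1)
        & (df["allele_fraction"] >= af_min)
        & eff.isin(effects)
    )
    out = df.loc[keep].sort_values(["chrom", "pos"], kind="stable")
    return out.reset_index(drop=True)


@dataclass
class FilterReport:
    """Counts surviving each filtering stage."""

    n_pool: int
    n_after_subtraction: int
    n_ems: int
    n_fixed: int
    n_candidates: int


def run_filter(
    pool: pd.DataFrame,
    parent: pd.DataFrame,
    af_min: float = AF_MIN_DEFAULT,
    effects: Iterable[str] = EFFECTS_DEFAULT,
    mode: str = "canonical",
    effect_aliases: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Full pipeline: parental subtraction then the three-part candidate
    filter, with a stage-by-stage report."""
    specific = subtract_parent(pool, parent)
    if specific.empty:
        return specific, FilterReport(len(pool), 0, 0, 0, 0)
    ems_mask = specific.apply(
        lambda r: is_ems_transition(r["ref"], r["alt"], mode=mode), axis=1
    )
    fixed_mask = ems_mask & (specific["allele_fraction"] >= af_min)
    candidates = candidate_filter(
        specific, af_min=af_min, effects=effects, mode=mode,
        effect_aliases=effect_aliases,
    )
    report = FilterReport(
        n_pool=len(pool),
        n_after_subtraction=len(specific),
        n_ems=int(ems_mask.sum()),
        n_fixed=int(fixed_mask.sum()),
        n_candidates=len(candidates),
    )
    return candidates, report
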